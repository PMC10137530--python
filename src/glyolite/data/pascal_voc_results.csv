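method,params,gflops,map50,fps_gpu,fps_cpu
YOLOv5-mbv3-small,3.59,6.4,69.1,61.35,15.11
YOLOv5-mbv3-large,5.25,10.3,77,54.95,8.01
YOLOv5-ShuffleNetv2,0.45,1.4,56.7,61.35,19.19
YOLOv3-Tiny,8.71,13,57.7,277.78,7.58
YOLOv5-s,7.11,16.4,77.8,69.93,8.08
YOLOv5-lite-g,5.32,15.3,78.2,70.42,7.86
YOLOv5s-Ghost,3.73,8.3,77,61.73,8.29
GL-YOLO,7.08,16.4,82.5,51.55,6.43
GL-YOLO-Lite,4.42,3.4,80,56.82,11.07
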