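method,params,gflops,map50,fps_gpu,fps_cpu
YOLOv5-mbv3-small,3.54,6.3,80.1,55.25,13.40
YOLOv5-mbv3-large,5.2,10.3,83.9,47.62,7.50
YOLOv5-ShuffleNetv2,0.44,1.3,70.9,52.91,18.32
YOLOv3-Tiny,8.67,12.9,69.6,243.90,6.83
YOLOv5-s,7.05,16.3,85.7,73.53,7.03
YOLOv5-lite-g,5.3,15.1,85.5,62.89,6.98
YOLOv5s-Ghost,3.68,8.1,86.1,56.18,7.71
GL-YOLO,7.03,16.2,89.1,49.75,5.51
GL-YOLO-Lite,4.41,3.3,88.5,52.63,9.89
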