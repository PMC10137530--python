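"""Model assembly: table fidelity, the conv calculus, profiling, decode."""

import numpy as np
import pytest
import yaml

from glyolite import blocks
from glyolite.model import (ConfigError, Model, config_path, decode_predictions,
                            letterbox, nms)
from glyolite.profile import ConvUnitSpec, count_flops, count_parameters, profile_model
from glyolite.reparam import convert_model_to_deploy


# ------------------------------------------------- closed-form conv calculus

@pytest.mark.parametrize("spec,expected", [
    (ConvUnitSpec(3, 3, 3, 32), 896),       # first conv of the entry stage
    (ConvUnitSpec(3, 3, 12, 32), 3488),     # conv inside the focus module
    (ConvUnitSpec(1, 1, 1, 1), 2),          # one weight + one bias
])
def test_count_parameters_closed_form(spec, expected):
    assert count_parameters(spec) == expected


@pytest.mark.parametrize("spec,hw,expected", [
    (ConvUnitSpec(3, 3, 3, 32), (320, 320), 91_750_400),
    (ConvUnitSpec(3, 3, 12, 32), (320, 320), 357_171_200),
    (ConvUnitSpec(1, 1, 1, 1), (1, 1), 2),
])
def test_count_flops_closed_form(spec, hw, expected):
    assert count_flops(spec, *hw) == expected


def test_focus_to_conv_ratio_is_about_four():
    conv_p = count_parameters(ConvUnitSpec(3, 3, 3, 32))
    focus_p = count_parameters(ConvUnitSpec(3, 3, 12, 32))
    conv_f = count_flops(ConvUnitSpec(3, 3, 3, 32), 320, 320)
    focus_f = count_flops(ConvUnitSpec(3, 3, 12, 32), 320, 320)
    assert focus_p / conv_p == pytest.approx(3.89, abs=0.01)
    assert focus_f / conv_f == pytest.approx(3.89, abs=0.01)


# ----------------------------------------------------------- table fidelity

EXPECTED_LITE_MODULES = (
    ["Stem"]
    + ["RepConv", "CoT3"] * 3
    + ["RepConv", "SPP", "CoT3"]
    + ["ConvUnit", "Upsample", "Concat", "C3"] * 2
    + ["ConvUnit", "Concat", "C3"] * 2
    + ["SimAM", "Detect"]
)


def test_lite_table_structure():
    m = Model("gl_yolo_lite", nc=20)
    names = [type(layer).__name__ for layer in m.layers]
    assert names == EXPECTED_LITE_MODULES
    assert len(m.layers) == 26  # layers 0-24 plus the detection head
    # repeat counts at depth multiple 0.33: 3 -> 1, 9 -> 3
    assert [len(m.layers[i].m) for i in (2, 4, 6, 9)] == [1, 3, 3, 1]
    # lightweight head: every head stage runs at 64 actual channels (128 nominal)
    for i in (13, 17, 20, 23):
        assert m.layers[i].cv3.conv.c2 == 64


def test_config_rows_match_expected_input_refs():
    cfg = yaml.safe_load(open(config_path("gl_yolo_lite")))
    rows = cfg["backbone"] + cfg["head"]
    assert rows[12][0] == [-1, 6] and rows[16][0] == [-1, 4]
    assert rows[19][0] == [-1, 14] and rows[22][0] == [-1, 10]
    assert rows[25][0] == [17, 20, 24]
    assert rows[24][2] == "SimAM"


def test_unknown_module_and_dangling_ref_rejected():
    bad = {
        "nc": 1, "anchors": [[10, 10, 20, 20, 30, 30]],
        "backbone": [[-1, 1, "Warp", [64]]], "head": [],
    }
    with pytest.raises(ConfigError, match="unknown module"):
        Model(bad)
    bad2 = {
        "nc": 1, "anchors": [[10, 10, 20, 20, 30, 30]],
        "backbone": [[5, 1, "Conv", [64, 3, 2]]], "head": [],
    }
    with pytest.raises(ConfigError, match="out of range"):
        Model(bad2)


def test_empty_table_rejected():
    with pytest.raises(ConfigError, match="empty"):
        Model({"nc": 1, "anchors": [], "backbone": [], "head": []})


# ------------------------------------------------------- whole-model counts

@pytest.mark.parametrize("name,nc,deploy,params_m,gflops", [
    ("yolov5s", 20, False, 7.11, 16.4),
    ("gl_yolo", 20, False, 7.08, 16.4),
    ("gl_yolo_stem", 20, False, 7.09, 4.5),
    ("gl_yolo_lite", 20, True, 4.42, 3.4),
    ("gl_yolo_lite", 1, True, 4.41, 3.3),
])
def test_profiled_tables(name, nc, deploy, params_m, gflops):
    m = Model(name, nc=nc)
    if deploy:
        convert_model_to_deploy(m)
    rep = profile_model(m, 640)
    assert rep.params_millions == params_m
    assert rep.gflops == gflops


def test_profile_totals_equal_layer_sums():
    rep = profile_model(Model("yolov5s", nc=20), 640)
    assert rep.total_params == sum(l.params for l in rep.layers)
    assert rep.total_macs == sum(l.macs for l in rep.layers)


def test_convention_a_hand_sum_on_pure_conv_net():
    """Profiler MACs on a conv-only net equal the closed-form layer sum."""
    cfg = {
        "nc": 1, "width_multiple": 1.0, "depth_multiple": 1.0,
        "anchors": [[10, 10, 20, 20, 30, 30]],
        "backbone": [
            [-1, 1, "Conv", [8, 3, 2]],
            [-1, 1, "Conv", [16, 3, 2]],
            [-1, 1, "Conv", [32, 1, 1]],
        ],
        "head": [],
    }
    m = Model(cfg)
    rep = profile_model(m, 640)
    # hand sum of kernel MACs (convention A minus the bias adds)
    expected = (
        3 * 3 * 3 * 8 * 320 * 320
        + 3 * 3 * 8 * 16 * 160 * 160
        + 1 * 1 * 16 * 32 * 160 * 160
    )
    assert rep.total_macs == expected


def test_simam_layer_contributes_zero_parameters():
    counts = {
        type(layer).__name__: layer.num_parameters()
        for layer in Model("gl_yolo_lite", nc=1).layers
    }
    assert counts["SimAM"] == 0


def test_stem_stride_ledger():
    m = Model("gl_yolo_lite", nc=1)
    shapes = m.layer_shapes(640)
    assert shapes[0][1] == 160                      # stem output stride 4
    assert m.detect.strides.tolist() == [16.0, 32.0, 64.0]
    base = Model("yolov5s", nc=1)
    assert (m.detect.strides == 2 * base.detect.strides).all()


def test_detect_anchor_areas_ascending():
    a = Model("gl_yolo_lite", nc=1).detect.anchors.reshape(-1, 2)
    areas = a[:, 0] * a[:, 1]
    assert (np.diff(areas) > 0).all()


# ------------------------------------------------------------------ decode

class TestDecode:
    def test_all_zero_logits_yield_no_detections(self):
        raw = [np.zeros((1, 3, 4, 4, 6), dtype=np.float32)]
        anchors = [np.array([[10, 10], [20, 20], [30, 30]], dtype=np.float32)]
        out = decode_predictions(raw, anchors, [16], conf_thres=0.25)
        assert out[0].shape == (0, 6)

    def test_duplicate_boxes_suppressed(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8]), iou_thres=0.45)
        assert keep.tolist() == [0]

    def test_hand_encoded_box_decodes_within_half_pixel(self):
        """Invert the grid decode by hand and check the round trip."""
        stride, cell, anchor = 16.0, (2, 3), np.array([40.0, 24.0])
        target_xy = np.array([(cell[1] + 0.7) * stride, (cell[0] + 0.4) * stride])
        target_wh = np.array([55.0, 30.0])
        # invert: sig(t) = (offset + 0.5) / 2 for xy; sqrt(wh/anchor)/2 for wh
        inv = lambda p: np.log(p / (1 - p))
        t_x = inv((0.7 + 0.5) / 2)
        t_y = inv((0.4 + 0.5) / 2)
        t_w = inv(np.sqrt(target_wh[0] / anchor[0]) / 2)
        t_h = inv(np.sqrt(target_wh[1] / anchor[1]) / 2)
        raw = np.full((1, 3, 5, 5, 6), -20.0, dtype=np.float32)
        raw[0, 1, cell[0], cell[1]] = [t_x, t_y, t_w, t_h, 10.0, 10.0]
        anchors = [np.array([[10, 10], anchor, [100, 100]], dtype=np.float32)]
        det = decode_predictions([raw], anchors, [stride], conf_thres=0.25)[0]
        assert len(det) == 1
        x1, y1, x2, y2 = det[0, :4]
        np.testing.assert_allclose(
            [(x1 + x2) / 2, (y1 + y2) / 2], target_xy, atol=0.5
        )
        np.testing.assert_allclose([x2 - x1, y2 - y1], target_wh, atol=0.5)


def test_letterbox_preserves_aspect_and_maps_back():
    img = np.zeros((200, 400, 3), dtype=np.uint8)
    canvas, scale, (px, py) = letterbox(img, 640)
    assert canvas.shape == (640, 640, 3)
    assert scale == pytest.approx(1.6)
    assert (px, py) == (0, 160)
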