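"""Frame I/O, tilt correction, cropping and ROI component averaging."""

import numpy as np
import pytest
import tifffile

from perfcolour import colour
from perfcolour.imaging import (
    ComponentVector,
    Frame,
    Landmarks,
    ROIBox,
    correct_tilt,
    crop_roi,
    extract_components,
    mean_channels,
    read_frames,
    tilt_angle,
)


def _uniform_frame(rgb, shape=(20, 30)):
    px = np.zeros(shape + (3,), dtype=np.uint8)
    px[:] = rgb
    return Frame(px)


# ---------------------------------------------------------------------------
# read_frames


def test_read_frames_sorts_and_assigns_times(tmp_path):
    rng = np.random.default_rng(0)
    for idx in (2, 0, 1):
        tifffile.imwrite(
            tmp_path / f"f_{idx:05d}.tif", rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        )
    frames = read_frames(str(tmp_path), fps=15.0)
    assert len(frames) == 3
    assert [f.t for f in frames] == pytest.approx([0.0, 1 / 15, 2 / 15])
    # sorted content equals per-file content in index order
    ref = tifffile.imread(tmp_path / "f_00000.tif")
    assert np.array_equal(frames[0].pixels, ref)


def test_read_frames_empty_and_inconsistent(tmp_path):
    with pytest.raises(IOError):
        read_frames(str(tmp_path))
    tifffile.imwrite(tmp_path / "a.tif", np.zeros((4, 4, 3), dtype=np.uint8))
    tifffile.imwrite(tmp_path / "b.tif", np.zeros((5, 4, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        read_frames(str(tmp_path))


def test_read_frames_rescales_16bit(tmp_path, caplog):
    tifffile.imwrite(tmp_path / "a.tif", np.full((4, 4, 3), 65535, dtype=np.uint16))
    with caplog.at_level("WARNING"):
        frames = read_frames(str(tmp_path))
    assert frames[0].pixels.dtype == np.uint8
    assert np.all(frames[0].pixels == 255)
    assert any("16-bit" in r.message for r in caplog.records)


def test_last_frame_time_at_protocol_length(tmp_path):
    # index/fps arithmetic: 1500 frames at 15 fps end at t = 99.933 s
    assert (1500 - 1) / 15.0 == pytest.approx(99.9333, abs=1e-3)


# ---------------------------------------------------------------------------
# correct_tilt


def test_tilt_noop_when_horizontal():
    fr = _uniform_frame((10, 20, 30))
    out = correct_tilt(fr, Landmarks((2, 10), (25, 10)))
    assert np.array_equal(out.pixels, fr.pixels)


def test_tilt_angle_and_landmark_swap():
    lm = Landmarks((10.0, 10.0), (30.0, 30.0))
    assert tilt_angle(lm) == pytest.approx(45.0, abs=1e-9)
    assert tilt_angle(Landmarks(lm.elbow, lm.wrist)) == pytest.approx(45.0, abs=1e-9)
    with pytest.raises(ValueError):
        Landmarks((5, 5), (5, 5))


def test_tilt_correction_straightens_a_line():
    """A bright stripe along the landmark axis becomes horizontal."""
    px = np.zeros((60, 60, 3), dtype=np.uint8)
    wrist, elbow = (15.0, 15.0), (45.0, 45.0)
    for k in range(31):
        x, y = 15 + k, 15 + k
        px[y, x] = 255
    fr = Frame(px)
    lm = Landmarks(wrist, elbow)
    out = correct_tilt(fr, lm)
    out_swapped = correct_tilt(fr, Landmarks(elbow, wrist))
    assert np.array_equal(out.pixels, out_swapped.pixels)
    # midpoint (30, 30) is the rotation centre: the stripe should now lie
    # along row 30
    row_mass = out.pixels[:, :, 0].sum(axis=1).astype(float)
    assert row_mass.argmax() == 30
    assert row_mass[30] > 0.5 * 255 * 31


# ---------------------------------------------------------------------------
# crop_roi / mean_channels


def test_crop_roi_shapes_and_bounds():
    fr = _uniform_frame((1, 2, 3), shape=(200, 150))
    full = crop_roi(fr, ROIBox(0, 0, 150, 200))
    assert np.array_equal(full.pixels, fr.pixels)
    box = crop_roi(fr, ROIBox(5, 10, 130, 140))
    assert box.pixels.shape == (140, 130, 3)
    with pytest.raises(ValueError):
        crop_roi(fr, ROIBox(30, 70, 130, 140))


def test_crop_is_a_view_free_copy():
    fr = _uniform_frame((9, 9, 9), shape=(10, 10))
    roi = crop_roi(fr, ROIBox(0, 0, 5, 5))
    roi.pixels[:] = 0
    assert np.all(fr.pixels == 9)


def test_mean_channels():
    assert np.allclose(mean_channels(_uniform_frame((10, 20, 30))), [10, 20, 30])
    px = np.zeros((1, 2, 3), dtype=np.uint8)
    px[0, 0, 0], px[0, 1, 0] = 0, 255
    assert mean_channels(Frame(px))[0] == pytest.approx(127.5)


# ---------------------------------------------------------------------------
# extract_components


def test_uniform_roi_equals_single_pixel(vc_default):
    rgb = (204, 160, 140)
    fr = _uniform_frame(rgb, shape=(30, 40))
    cv = extract_components(fr, ROIBox(2, 3, 20, 25), vc_default)
    hsv = colour.rgb_to_hsv(rgb)
    lab = colour.srgb_to_lab(rgb)
    jch = colour.srgb_to_jch(rgb, vc_default)
    single = ComponentVector(*rgb, *hsv, *lab, *jch)
    assert np.allclose(cv.as_array(), single.as_array(), atol=1e-9)


def test_neutral_and_pure_red_rois(vc_literal):
    gray = extract_components(_uniform_frame((128, 128, 128)), ROIBox(0, 0, 10, 10), vc_literal)
    assert gray.S == 0.0 and abs(gray.astar) < 1e-9 and abs(gray.bstar) < 1e-9
    assert gray.C == pytest.approx(0.0, abs=1e-6)
    red = extract_components(_uniform_frame((255, 0, 0)), ROIBox(0, 0, 10, 10), vc_literal)
    assert red.H == 0.0
    assert red.h == pytest.approx(colour.srgb_to_jch([255, 0, 0], vc_literal)[2], abs=1e-9)


def test_hue_averaging_modes(vc_default):
    """Half H=10 deg, half H=30 deg pixels average to 20 deg arithmetically."""
    # construct constant-V, constant-S pixels at two hues
    def hsv_pixel(h_deg):
        # inverse hexcone for S=100, V=100, hue in [0,60): R=255, G rises
        assert 0 <= h_deg < 60
        return (255, int(round(255 * h_deg / 60.0)), 0)

    px = np.zeros((2, 2, 3), dtype=np.uint8)
    px[0, :] = hsv_pixel(10.002353)  # closest 8-bit hues to 10 and 30 deg
    px[1, :] = hsv_pixel(30.0)
    h10 = colour.rgb_to_hsv(px[0, 0])[0]
    h30 = colour.rgb_to_hsv(px[1, 0])[0]
    cv = extract_components(Frame(px), ROIBox(0, 0, 2, 2), vc_default)
    assert cv.H == pytest.approx((h10 + h30) / 2.0, abs=1e-9)
    cv_circ = extract_components(Frame(px), ROIBox(0, 0, 2, 2), vc_default, circular_hue=True)
    assert cv_circ.H == pytest.approx((h10 + h30) / 2.0, abs=0.05)


def test_mean_first_differs_from_per_pixel(vc_default):
    px = np.zeros((1, 2, 3), dtype=np.uint8)
    px[0, 0] = (250, 10, 10)
    px[0, 1] = (10, 10, 250)
    fr = Frame(px)
    per_pixel = extract_components(fr, ROIBox(0, 0, 2, 1), vc_default)
    merged = extract_components(fr, ROIBox(0, 0, 2, 1), vc_default, mean_first=True)
    assert per_pixel.R == merged.R  # linear component agrees
    assert abs(per_pixel.S - merged.S) > 1.0  # nonlinear components do not


def test_permutation_invariance(vc_default):
    rng = np.random.default_rng(5)
    px = rng.integers(0, 256, size=(6, 7, 3)).astype(np.uint8)
    fr = Frame(px)
    cv = extract_components(fr, ROIBox(0, 0, 7, 6), vc_default)
    flat = px.reshape(-1, 3)
    shuffled = flat[rng.permutation(len(flat))].reshape(6, 7, 3)
    cv2 = extract_components(Frame(shuffled), ROIBox(0, 0, 7, 6), vc_default)
    assert np.allclose(cv.as_array(), cv2.as_array(), atol=1e-9)


def test_tilt_crop_commutes_with_translation(vc_default):
    """Shifting frame + landmarks + box together leaves the ROI unchanged."""
    rng = np.random.default_rng(8)
    big = np.zeros((80, 90, 3), dtype=np.uint8)
    big[20:50, 25:65] = rng.integers(40, 220, size=(30, 40, 3))
    lm = Landmarks((30.0, 28.0), (58.0, 40.0))
    box = ROIBox(34, 26, 16, 12)
    dx, dy = 6, 9
    shifted = np.zeros_like(big)
    shifted[dy:, dx:] = big[:-dy, :-dx]
    lm2 = Landmarks((30.0 + dx, 28.0 + dy), (58.0 + dx, 40.0 + dy))
    box2 = ROIBox(34 + dx, 26 + dy, 16, 12)
    roi1 = crop_roi(correct_tilt(Frame(big), lm), box)
    roi2 = crop_roi(correct_tilt(Frame(shifted), lm2), box2)
    assert np.allclose(
        roi1.pixels.astype(float), roi2.pixels.astype(float), atol=1.0
    )
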