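"""Colour-conversion correctness: fixed points, independent oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfcolour import colour

# ---------------------------------------------------------------------------
# sRGB transfer function and the XYZ matrix


def test_srgb_transfer_fixed_points_and_midgray():
    assert np.allclose(colour.srgb_to_linear([0, 0, 0]), 0.0)
    assert np.allclose(colour.srgb_to_linear([255, 255, 255]), 1.0)
    # closed form: ((128/255 + 0.055)/1.055)**2.4
    expected = ((128 / 255 + 0.055) / 1.055) ** 2.4
    assert np.allclose(colour.srgb_to_linear([128, 128, 128]), expected, atol=1e-12)
    assert abs(expected - 0.2158605) < 5e-7


@pytest.mark.parametrize("bad", [[-1, 0, 0], [0, 256, 0]])
def test_srgb_range_check(bad):
    with pytest.raises(ValueError):
        colour.srgb_to_linear(bad)


def test_xyz_matrix_columns_and_white():
    assert np.allclose(colour.linear_to_xyz_d65([0, 0, 0]), 0.0)
    white = colour.linear_to_xyz_d65([1, 1, 1])
    assert np.allclose(white, [95.047, 100.0, 108.883], atol=2e-3)
    red = colour.linear_to_xyz_d65([1, 0, 0])
    assert np.allclose(red, [41.2456, 21.2673, 1.9334], atol=1e-3)


# ---------------------------------------------------------------------------
# HSV


def test_hsv_primary_hues_and_achromatic():
    hsv = colour.rgb_to_hsv([[255, 0, 0], [0, 255, 0], [0, 0, 255]])
    assert np.allclose(hsv[:, 0], [0.0, 120.0, 240.0])
    assert np.allclose(hsv[:, 1], 100.0) and np.allclose(hsv[:, 2], 100.0)
    gray = colour.rgb_to_hsv([128, 128, 128])
    assert gray[1] == 0.0 and gray[0] == 0.0
    assert colour.rgb_to_hsv([0, 0, 0])[2] == 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 255)] * 3))
def test_hsv_matches_skimage_oracle(rgb):
    """Hexcone HSV agrees with the scikit-image implementation (rescaled)."""
    from skimage.color import rgb2hsv

    ours = colour.rgb_to_hsv(rgb)
    ref = rgb2hsv(np.asarray(rgb, dtype=float).reshape(1, 1, 3) / 255.0).ravel()
    assert ours[0] == pytest.approx((ref[0] * 360.0) % 360.0, abs=1e-9)
    assert ours[1] == pytest.approx(ref[1] * 100.0, abs=1e-9)
    assert ours[2] == pytest.approx(ref[2] * 100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# CIELAB


def _lab_reference(rgb):
    """Independent scalar implementation of the sRGB -> Lab chain."""
    lin = []
    for v in rgb:
        c = v / 255.0
        lin.append(c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4)
    M = [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
    xyz = [100.0 * sum(M[i][j] * lin[j] for j in range(3)) for i in range(3)]
    wn = [100.0 * sum(row) for row in M]

    def f(t):
        eps = (6.0 / 29.0) ** 3
        return t ** (1 / 3) if t > eps else t / (3 * (6 / 29) ** 2) + 4.0 / 29.0

    fx, fy, fz = (f(xyz[i] / wn[i]) for i in range(3))
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def test_lab_white_and_neutral_axis():
    assert np.allclose(colour.srgb_to_lab([255, 255, 255]), [100.0, 0.0, 0.0], atol=1e-9)
    lab = colour.srgb_to_lab([128, 128, 128])
    assert abs(lab[1]) < 1e-9 and abs(lab[2]) < 1e-9


@pytest.mark.parametrize("rgb", [(255, 0, 0), (12, 200, 99), (70, 70, 200), (1, 2, 3)])
def test_lab_matches_independent_formula(rgb):
    ours = colour.srgb_to_lab(rgb)
    ref = _lab_reference(rgb)
    assert np.allclose(ours, ref, atol=1e-6)


def test_lab_close_to_skimage():
    from skimage.color import rgb2lab

    rng = np.random.default_rng(7)
    rgb = rng.integers(0, 256, size=(50, 3))
    ours = colour.srgb_to_lab(rgb)
    ref = rgb2lab(rgb.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)
    assert np.max(np.abs(ours - ref)) < 5e-3


def test_lab_white_luminance_guard():
    with pytest.raises(ValueError):
        colour.xyz_to_lab([50, 50, 50], white=[95.0, 0.0, 108.0])


def test_red_channel_increase_raises_astar():
    base = colour.srgb_to_lab([120, 120, 120])
    prev = base[1]
    for r in (130, 150, 180, 220):
        a = colour.srgb_to_lab([r, 120, 120])[1]
        assert a > prev
        prev = a


# ---------------------------------------------------------------------------
# 8-bit Lab dialect


def test_scaled8_printed_examples():
    assert np.allclose(colour.scaled8_to_lab([255, 128, 128]), [100.0, 0.0, 0.0])
    assert np.allclose(colour.scaled8_to_lab([0, 128, 128]), [0.0, 0.0, 0.0])
    assert np.allclose(colour.scaled8_to_lab([51, 228, 28]), [20.0, 100.0, -100.0])
    with pytest.raises(ValueError):
        colour.scaled8_to_lab([256, 0, 0])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 255)] * 3))
def test_scaled8_round_trip(scaled):
    back = colour.lab_to_scaled8(colour.scaled8_to_lab(scaled))
    assert np.allclose(back, scaled, atol=1e-9)


# ---------------------------------------------------------------------------
# Viewing conditions and CIECAM02


def test_viewing_condition_derivations():
    vc_full = colour.derive_viewing_conditions([95.047, 100.0, 108.883], Yb=20.0)
    assert vc_full.n == pytest.approx(0.2, abs=1e-12)
    assert vc_full.z == pytest.approx(1.48 + np.sqrt(0.2), abs=1e-9)
    vc_lit = colour.derive_viewing_conditions(
        [95.047, 100.0, 108.883], Yb=20.0, mode="literal"
    )
    assert vc_lit.z == pytest.approx(1.68, abs=1e-12)
    assert vc_full.Aw > 0 and 0 < vc_full.n <= 1 and vc_full.D == 1.0
    vc_nod = colour.derive_viewing_conditions(LA=318.31, discount_illuminant=False)
    assert 0 < vc_nod.D < 1


def test_viewing_condition_guards():
    with pytest.raises(ValueError):
        colour.derive_viewing_conditions(LA=-1.0)
    with pytest.raises(ValueError):
        colour.derive_viewing_conditions(Yb=0.0)
    with pytest.raises(ValueError):
        colour.derive_viewing_conditions(mode="nonsense")


def test_ciecam02_published_verification_stimuli():
    """Forward model reproduces the published CIE verification values."""
    vc = colour.derive_viewing_conditions(
        [95.05, 100.0, 108.88], LA=318.31, Yb=20.0, discount_illuminant=False
    )
    J, C, h = colour.ciecam02_forward([19.01, 20.00, 21.78], vc)
    assert J == pytest.approx(41.731, abs=0.1)
    assert h == pytest.approx(219.048, abs=0.1)
    assert C == pytest.approx(0.1047, abs=0.01)
    vc2 = colour.derive_viewing_conditions(
        [95.05, 100.0, 108.88], LA=31.83, Yb=20.0, discount_illuminant=False
    )
    J2, C2, h2 = colour.ciecam02_forward([57.06, 43.06, 31.96], vc2)
    assert J2 == pytest.approx(65.96, abs=0.1)
    assert h2 == pytest.approx(19.56, abs=0.1)
    assert C2 == pytest.approx(48.57, abs=0.1)


def test_ciecam02_white_and_neutral(vc_default, vc_literal):
    J, C, h = colour.ciecam02_forward(np.asarray(vc_default.XYZw), vc_default)
    assert J == pytest.approx(100.0, abs=1e-6)
    Jl, Cl, hl = colour.srgb_to_jch([128, 128, 128], vc_literal)
    assert Cl == pytest.approx(0.0, abs=1e-6)
    assert hl == 0.0


def test_ciecam02_luminance_monotone(vc_default):
    """Scaling XYZ toward black never increases lightness J."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        xyz = rng.uniform(1, 95, size=3)
        J_prev = colour.ciecam02_forward(xyz, vc_default)[0]
        for k in (0.8, 0.5, 0.2, 0.05):
            J = colour.ciecam02_forward(xyz * k, vc_default)[0]
            assert J <= J_prev + 1e-9
            J_prev = J


def test_hue_ranges_and_determinism(vc_default, vc_literal):
    rng = np.random.default_rng(11)
    rgb = rng.integers(0, 256, size=(200, 3))
    for vc in (vc_default, vc_literal):
        jch = colour.srgb_to_jch(rgb, vc)
        assert np.all((jch[:, 2] >= 0) & (jch[:, 2] < 360))
        assert np.all(jch[:, 1] >= 0)
        assert np.array_equal(jch, colour.srgb_to_jch(rgb, vc))
    hsv = colour.rgb_to_hsv(rgb)
    assert np.all((hsv[:, 0] >= 0) & (hsv[:, 0] < 360))


def test_literal_hue_falls_when_redness_weakens(vc_literal, vc_default):
    """The literal-dialect hue axis is reversed relative to the HSV hue.

    Weakening redness (more green/blue light) raises the HSV hue but lowers
    the literal JCh hue — the sign structure that characterises the
    pressure-response features — while the standard hue co-rotates with HSV.
    """
    base = np.array([204.0, 160.0, 140.0])
    pale = base + np.array([0.0, 12.0, 6.0])
    dH = colour.rgb_to_hsv(pale)[0] - colour.rgb_to_hsv(base)[0]
    dh_lit = colour.srgb_to_jch(pale, vc_literal)[2] - colour.srgb_to_jch(base, vc_literal)[2]
    dh_std = colour.srgb_to_jch(pale, vc_default)[2] - colour.srgb_to_jch(base, vc_default)[2]
    assert dH > 0 and dh_lit < 0 and dh_std > 0
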