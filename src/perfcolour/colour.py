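"""Colour-space conversions for skin-perfusion imaging.

All operations start from 8-bit sRGB (IEC 61966-2-1) camera values and are
vectorised: every function accepts a single triplet or an array whose last
axis has length 3, and returns an array of the same leading shape.

Four target representations are provided:

* **HSV** — hue in degrees [0, 360), saturation and value in percent.
* **CIELAB** — the CIE 1976 L*a*b* space under the D65 white point, plus the
  8-bit "scaled" dialect used by common imaging libraries, in which L*, a*,
  b* are stored in [0, 255] (``L* = Lscaled/255*100``, ``a* = ascaled-128``,
  ``b* = bscaled-128``).
* **CIECAM02 JCh** — lightness J, chroma C and hue angle h from the CIE
  159:2004 colour appearance model, parameterised by explicit
  :class:`ViewingConditions`.

Two CIECAM02 dialects are supported via ``ViewingConditions.mode``:
``"full_ciecam02"`` follows CIE 159:2004 exactly (``z = 1.48 + sqrt(n)``,
chroma from the eccentricity-weighted formula), while ``"literal"``
uses the CIELCh-style simplifications ``z = 1.48 + n`` and
``C = sqrt(a^2 + b^2)`` sometimes seen in applied work.

All conversions are pure floating-point; 8-bit quantisation happens only at
I/O boundaries elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "D65_WHITE",
    "Surround",
    "AVERAGE_SURROUND",
    "DIM_SURROUND",
    "DARK_SURROUND",
    "ViewingConditions",
    "srgb_to_linear",
    "linear_to_xyz_d65",
    "rgb_to_hsv",
    "xyz_to_lab",
    "scaled8_to_lab",
    "lab_to_scaled8",
    "derive_viewing_conditions",
    "ciecam02_forward",
    "srgb_to_jch",
    "srgb_to_lab",
]

# Standard sRGB (IEC 61966-2-1) linear-light -> XYZ matrix, D65 primaries,
# on the Y = 100 scale.
_M_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: Adopted D65 white point: the image of linear (1,1,1) under the sRGB
#: matrix, so that sRGB white maps to L* = 100 exactly and neutral inputs
#: (R=G=B) map to a* = b* = 0 exactly.
D65_WHITE = _M_SRGB_TO_XYZ.sum(axis=1) * 100.0

# CAT02 chromatic-adaptation and Hunt-Pointer-Estevez matrices (CIE 159:2004).
_M_CAT02 = np.array(
    [
        [0.7328, 0.4296, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)
_M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)
_M_CAT02_TO_HPE = _M_HPE @ np.linalg.inv(_M_CAT02)


def _as_triplets(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape == () or arr.shape[-1] != 3:
        raise ValueError(f"{name} must have a trailing axis of length 3, got shape {arr.shape}")
    return arr


def srgb_to_linear(rgb) -> np.ndarray:
    """Decode 8-bit sRGB channel values to linear light in [0, 1].

    Applies the IEC 61966-2-1 inverse transfer function channel-wise.

    Parameters
    ----------
    rgb : array-like, shape (..., 3)
        8-bit sRGB values; each channel must lie in [0, 255].

    Raises
    ------
    ValueError
        If any channel falls outside [0, 255].
    """
    arr = _as_triplets(rgb, "rgb")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("sRGB channel values must lie in [0, 255]")
    c = arr / 255.0
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def linear_to_xyz_d65(linear) -> np.ndarray:
    """Map linear-light sRGB in [0, 1] to CIE XYZ (D65, Y = 100 scale)."""
    arr = _as_triplets(linear, "linear")
    return arr @ _M_SRGB_TO_XYZ.T * 100.0


def rgb_to_hsv(rgb) -> np.ndarray:
    """Convert 8-bit sRGB to hexcone HSV.

    Returns ``(H, S, V)`` with hue in degrees [0, 360) and saturation/value
    in percent. Achromatic pixels (S = 0) report H = 0 so that downstream
    averaging is deterministic.
    """
    arr = _as_triplets(rgb, "rgb")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("sRGB channel values must lie in [0, 255]")
    c = arr / 255.0
    r, g, b = c[..., 0], c[..., 1], c[..., 2]
    v = c.max(axis=-1)
    delta = v - c.min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, delta / v, 0.0)
        h = np.select(
            [delta == 0, v == r, v == g],
            [
                0.0,
                (g - b) / np.where(delta == 0, 1.0, delta),
                2.0 + (b - r) / np.where(delta == 0, 1.0, delta),
            ],
            default=4.0 + (r - g) / np.where(delta == 0, 1.0, delta),
        )
    h = (h * 60.0) % 360.0
    return np.stack([h, s * 100.0, v * 100.0], axis=-1)


def _lab_f(t: np.ndarray) -> np.ndarray:
    eps = (6.0 / 29.0) ** 3
    return np.where(t > eps, np.cbrt(t), t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)


def xyz_to_lab(xyz, white=None) -> np.ndarray:
    """CIE 1976 L*a*b* from tristimulus values.

    Parameters
    ----------
    xyz : array-like, shape (..., 3)
        Tristimulus values on the Y = 100 scale.
    white : array-like, optional
        Reference white; defaults to :data:`D65_WHITE`.
    """
    arr = _as_triplets(xyz, "xyz")
    w = np.asarray(D65_WHITE if white is None else white, dtype=float)
    if w[1] <= 0:
        raise ValueError("reference white must have Y > 0")
    f = _lab_f(arr / w)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def scaled8_to_lab(scaled) -> np.ndarray:
    """Decode the 8-bit Lab dialect: ``(Ls, as_, bs) -> (Ls/255*100, as_-128, bs-128)``."""
    arr = _as_triplets(scaled, "scaled")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("scaled Lab values must lie in [0, 255]")
    return np.stack(
        [arr[..., 0] / 255.0 * 100.0, arr[..., 1] - 128.0, arr[..., 2] - 128.0], axis=-1
    )


def lab_to_scaled8(lab) -> np.ndarray:
    """Inverse of :func:`scaled8_to_lab`; exact on representable values."""
    arr = _as_triplets(lab, "lab")
    out = np.stack(
        [arr[..., 0] / 100.0 * 255.0, arr[..., 1] + 128.0, arr[..., 2] + 128.0], axis=-1
    )
    if np.any(out < -1e-9) or np.any(out > 255 + 1e-9):
        raise ValueError("Lab values outside the representable 8-bit dialect range")
    return np.clip(out, 0.0, 255.0)


@dataclass(frozen=True)
class Surround:
    """CIECAM02 surround parameters (F, c, Nc)."""

    F: float
    c: float
    Nc: float


AVERAGE_SURROUND = Surround(F=1.0, c=0.69, Nc=1.0)
DIM_SURROUND = Surround(F=0.9, c=0.59, Nc=0.9)
DARK_SURROUND = Surround(F=0.8, c=0.525, Nc=0.8)


@dataclass(frozen=True)
class ViewingConditions:
    """CIECAM02 viewing environment with the derived model constants.

    Parameters
    ----------
    XYZw : white-point tristimulus values (Y = 100 scale).
    LA : adapting field luminance in cd/m^2.
    Yb : relative background luminance.
    surround : (F, c, Nc) triple; defaults to the average surround.
    mode : ``"full_ciecam02"`` (CIE 159:2004, z = 1.48 + sqrt(n)) or
        ``"literal"`` (z = 1.48 + n, chroma = sqrt(a^2 + b^2)).
    discount_illuminant : if True (default), the degree of adaptation D is
        forced to 1 — appropriate for camera data already white-balanced to a
        reference chart, and required for neutral inputs to map exactly onto
        the achromatic axis. If False, D follows the CIECAM02 exponential
        formula in LA and F, clamped to [0, 1].

    Derived constants (n, z, D, FL, Nbb, Ncb, Aw and the per-channel
    adaptation gains) are computed at construction and cached as fields.
    """

    XYZw: tuple = tuple(D65_WHITE)
    LA: float = 4.07
    Yb: float = 20.0
    surround: Surround = AVERAGE_SURROUND
    mode: str = "full_ciecam02"
    discount_illuminant: bool = True
    # derived, filled in __post_init__
    n: float = field(init=False)
    z: float = field(init=False)
    D: float = field(init=False)
    FL: float = field(init=False)
    Nbb: float = field(init=False)
    Ncb: float = field(init=False)
    Aw: float = field(init=False)
    _gains: tuple = field(init=False, repr=False)

    def __post_init__(self):
        XYZw = np.asarray(self.XYZw, dtype=float)
        Yw = XYZw[1]
        if self.LA <= 0 or self.Yb <= 0 or Yw <= 0:
            raise ValueError("LA, Yb and the white luminance must be positive")
        if self.mode not in ("full_ciecam02", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        F = self.surround.F
        n = self.Yb / Yw
        if not 0 < n <= 1:
            raise ValueError("background luminance ratio n = Yb/Yw must lie in (0, 1]")
        z = 1.48 + (np.sqrt(n) if self.mode == "full_ciecam02" else n)
        if self.discount_illuminant:
            D = 1.0
        else:
            D = float(np.clip(F * (1.0 - (1.0 / 3.6) * np.exp(-(self.LA + 42.0) / 92.0)), 0.0, 1.0))
        k = 1.0 / (5.0 * self.LA + 1.0)
        FL = 0.2 * k**4 * 5.0 * self.LA + 0.1 * (1.0 - k**4) ** 2 * (5.0 * self.LA) ** (1.0 / 3.0)
        Nbb = Ncb = 0.725 * (1.0 / n) ** 0.2
        RGBw = _M_CAT02 @ XYZw
        gains = Yw * D / RGBw + 1.0 - D
        RGBwp = _M_CAT02_TO_HPE @ (gains * RGBw)
        RGBwa = _hpe_compress(RGBwp, FL)
        Aw = float((2.0 * RGBwa[0] + RGBwa[1] + RGBwa[2] / 20.0 - 0.305) * Nbb)
        object.__setattr__(self, "n", float(n))
        object.__setattr__(self, "z", float(z))
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "FL", float(FL))
        object.__setattr__(self, "Nbb", float(Nbb))
        object.__setattr__(self, "Ncb", float(Ncb))
        object.__setattr__(self, "Aw", Aw)
        object.__setattr__(self, "_gains", tuple(gains))


def derive_viewing_conditions(
    XYZw=None,
    LA: float = 4.07,
    Yb: float = 20.0,
    surround: Surround = AVERAGE_SURROUND,
    mode: str = "full_ciecam02",
    discount_illuminant: bool = True,
) -> ViewingConditions:
    """Build :class:`ViewingConditions` and derive the CIECAM02 constants."""
    return ViewingConditions(
        XYZw=tuple(D65_WHITE if XYZw is None else np.asarray(XYZw, dtype=float)),
        LA=LA,
        Yb=Yb,
        surround=surround,
        mode=mode,
        discount_illuminant=discount_illuminant,
    )


def _hpe_compress(x: np.ndarray, FL: float) -> np.ndarray:
    """Hyperbolic post-adaptation cone compression, sign-symmetric."""
    t = (FL * np.abs(x) / 100.0) ** 0.42
    return np.sign(x) * 400.0 * t / (t + 27.13) + 0.1


def ciecam02_forward(xyz, vc: ViewingConditions) -> np.ndarray:
    """CIECAM02 forward model: XYZ -> (J, C, h).

    Runs CAT02 chromatic adaptation with the degree-of-adaptation D, the
    Hunt-Pointer-Estevez cone transform, hyperbolic compression, and the
    opponent/achromatic responses of CIE 159:2004. Lightness is
    ``J = 100 (A/Aw)^(c z)``; hue is the quadrant-correct ``atan2(b, a)``
    mapped to [0, 360), reported as 0 for achromatic stimuli. Chroma follows
    ``vc.mode``: the full CIECAM02 formula, or ``sqrt(a^2 + b^2)`` in
    ``literal`` mode.
    """
    arr = _as_triplets(xyz, "xyz")
    if not np.all(np.isfinite(arr)):
        raise ValueError("tristimulus values must be finite")
    gains = np.asarray(vc._gains)
    RGBc = (arr @ _M_CAT02.T) * gains
    RGBa = _hpe_compress(RGBc @ _M_CAT02_TO_HPE.T, vc.FL)
    Ra, Ga, Ba = RGBa[..., 0], RGBa[..., 1], RGBa[..., 2]
    a = Ra - 12.0 * Ga / 11.0 + Ba / 11.0
    b = (Ra + Ga - 2.0 * Ba) / 9.0
    # Stimuli sharing the white point's chromaticity are achromatic by
    # definition; snap them onto the a = b = 0 axis so that the ~1e-5
    # row-sum imperfection of the published HPE matrix cannot leak a
    # spurious chroma onto neutral pixels.
    XYZw = np.asarray(vc.XYZw)
    ratios = arr / XYZw
    with np.errstate(invalid="ignore"):
        neutral = np.ptp(ratios, axis=-1) <= 1e-9 * np.abs(ratios).max(axis=-1)
    a = np.where(neutral, 0.0, a)
    b = np.where(neutral, 0.0, b)
    A = np.maximum((2.0 * Ra + Ga + Ba / 20.0 - 0.305) * vc.Nbb, 0.0)
    J = 100.0 * (A / vc.Aw) ** (vc.surround.c * vc.z)
    if vc.mode == "literal":
        # The literal dialect takes the hue arctangent with the opposite
        # axis ratio (quadrant-correct atan2(a, b)), i.e. 90 deg minus the
        # standard hue for first-quadrant colours. For skin tones this axis
        # order is the one whose hue *decreases* as redness weakens and that
        # is anti-correlated with the HSV hue, matching the empirical sign
        # structure of the pressure-response data this dialect mirrors.
        h = np.degrees(np.arctan2(a, b)) % 360.0
    else:
        h = np.degrees(np.arctan2(b, a)) % 360.0
    h = np.where((a == 0) & (b == 0), 0.0, h)
    if vc.mode == "literal":
        C = np.hypot(a, b)
    else:
        et = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
        denom = Ra + Ga + 21.0 / 20.0 * Ba
        t = (50000.0 / 13.0 * vc.surround.Nc * vc.Ncb * et * np.hypot(a, b)) / denom
        C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**vc.n) ** 0.73
    return np.stack([J, C, h], axis=-1)


def srgb_to_lab(rgb, white=None) -> np.ndarray:
    """8-bit sRGB -> CIELAB through the D65 pipeline (convenience chain)."""
    return xyz_to_lab(linear_to_xyz_d65(srgb_to_linear(rgb)), white=white)


def srgb_to_jch(rgb, vc: ViewingConditions) -> np.ndarray:
    """8-bit sRGB -> CIECAM02 JCh (convenience chain)."""
    return ciecam02_forward(linear_to_xyz_d65(srgb_to_linear(rgb)), vc)
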