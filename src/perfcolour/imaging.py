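"""Frame handling: TIFF I/O, tilt correction, ROI cropping and component averaging.

The recording protocol fixes the camera above the forearm; the region of
interest (ROI) is the rectangle of skin compressed by the pressure plate.
Small tilt deviations from body movement are corrected by rotating each frame
so the wrist-elbow axis is horizontal, after which the ROI is cropped and the
12 colour components (mean R, G, B; mean H, S, V; mean L*, a*, b*; mean J, C,
h) are averaged over its pixels.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import rotate as _sk_rotate

from . import colour
from .colour import ViewingConditions

logger = logging.getLogger(__name__)

__all__ = [
    "COMPONENT_NAMES",
    "Frame",
    "ROIBox",
    "Landmarks",
    "ComponentVector",
    "read_frames",
    "correct_tilt",
    "crop_roi",
    "mean_channels",
    "extract_components",
]

#: Canonical order of the 12 colour components used throughout the package.
COMPONENT_NAMES = ("R", "G", "B", "H", "S", "V", "Lstar", "astar", "bstar", "J", "C", "h")


@dataclass
class Frame:
    """One acquired image: an (height, width, 3) 8-bit sRGB raster at time ``t`` (s)."""

    pixels: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"frame must be (H, W, 3), got {self.pixels.shape}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned crop rectangle: top-left (x0, y0), half-open extent width x height."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI extent must be at least 1x1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")


@dataclass(frozen=True)
class Landmarks:
    """Wrist and elbow reference points as (x, y) pixel coordinates."""

    wrist: tuple
    elbow: tuple

    def __post_init__(self):
        if tuple(self.wrist) == tuple(self.elbow):
            raise ValueError("wrist and elbow landmarks must be distinct")


@dataclass
class ComponentVector:
    """The 12 ROI-averaged colour components of one frame."""

    R: float
    G: float
    B: float
    H: float
    S: float
    V: float
    Lstar: float
    astar: float
    bstar: float
    J: float
    C: float
    h: float

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in COMPONENT_NAMES})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in COMPONENT_NAMES], dtype=float)


def read_frames(pattern: str, fps: float = 15.0) -> list[Frame]:
    """Read a TIFF frame sequence.

    Files matching ``pattern`` (a glob, or a directory in which case all
    ``*.tif``/``*.tiff`` files are taken) are sorted by filename; acquisition
    times are assigned as ``index / fps``. 16-bit inputs are rescaled to
    8-bit with a logged warning.

    Raises
    ------
    IOError
        If no file matches.
    ValueError
        If frames have inconsistent dimensions.
    """
    if os.path.isdir(pattern):
        paths = sorted(
            glob.glob(os.path.join(pattern, "*.tif")) + glob.glob(os.path.join(pattern, "*.tiff"))
        )
    else:
        paths = sorted(glob.glob(pattern))
    if not paths:
        raise IOError(f"no TIFF files match {pattern!r}")
    frames = []
    shape = None
    for i, p in enumerate(paths):
        px = tifffile.imread(p)
        if px.dtype == np.uint16:
            logger.warning("%s is 16-bit; rescaling to 8-bit", p)
            px = (px / 257.0).round().astype(np.uint8)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"{p}: expected an (H, W, 3) RGB raster, got {px.shape}")
        if shape is None:
            shape = px.shape
        elif px.shape != shape:
            raise ValueError(f"{p}: frame shape {px.shape} differs from first frame {shape}")
        frames.append(Frame(px, t=i / fps))
    return frames


def correct_tilt(frame: Frame, lm: Landmarks) -> Frame:
    """Rotate the frame so the wrist-elbow segment is horizontal.

    The rotation centre is the midpoint of the segment; interpolation is
    bilinear; pixels rotated in from outside the frame are filled with 0.
    The landmark order is normalised so the wrist-side point is on the left,
    making the result invariant to swapping the two landmarks.
    """
    p1 = np.asarray(lm.wrist, dtype=float)
    p2 = np.asarray(lm.elbow, dtype=float)
    if p2[0] < p1[0] or (p2[0] == p1[0] and p2[1] < p1[1]):
        p1, p2 = p2, p1
    d = p2 - p1
    angle = np.degrees(np.arctan2(d[1], d[0]))
    if angle == 0.0:
        return Frame(frame.pixels.copy(), t=frame.t)
    centre = (p1 + p2) / 2.0
    out = _sk_rotate(
        frame.pixels.astype(float),
        angle,
        center=(centre[0], centre[1]),
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    return Frame(np.clip(out, 0, 255).astype(frame.pixels.dtype), t=frame.t)


def tilt_angle(lm: Landmarks) -> float:
    """Signed angle (degrees) of the wrist-elbow segment above horizontal."""
    p1 = np.asarray(lm.wrist, dtype=float)
    p2 = np.asarray(lm.elbow, dtype=float)
    if p2[0] < p1[0] or (p2[0] == p1[0] and p2[1] < p1[1]):
        p1, p2 = p2, p1
    d = p2 - p1
    return float(np.degrees(np.arctan2(d[1], d[0])))


def crop_roi(frame: Frame, box: ROIBox) -> Frame:
    """Extract exactly ``box.height`` rows x ``box.width`` columns.

    A box that exceeds the frame bounds is an error, never silently clamped.
    """
    if box.x0 + box.width > frame.width or box.y0 + box.height > frame.height:
        raise ValueError(
            f"ROI {box} exceeds frame bounds {frame.width}x{frame.height}"
        )
    px = frame.pixels[box.y0 : box.y0 + box.height, box.x0 : box.x0 + box.width].copy()
    return Frame(px, t=frame.t)


def mean_channels(roi: Frame) -> np.ndarray:
    """Arithmetic mean of R, G, B over all ROI pixels (floating point)."""
    if roi.pixels.size == 0:
        raise ValueError("ROI is empty")
    return roi.pixels.reshape(-1, 3).mean(axis=0)


def _mean_angle_deg(deg: np.ndarray) -> float:
    rad = np.radians(deg)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)


def extract_components(
    frame: Frame,
    box: ROIBox,
    vc: ViewingConditions,
    *,
    circular_hue: bool = False,
    mean_first: bool = False,
    lab_scaled8: bool = False,
) -> ComponentVector:
    """Average the 12 colour components over the ROI pixels.

    By default every pixel is converted to HSV, CIELAB and CIECAM02 JCh and
    each component is averaged arithmetically (matching the per-pixel mean
    definition of the component formulas; skin hues sit far from the 0/360
    wrap, so the arithmetic hue mean is safe). Options:

    circular_hue : average H and h as circular quantities instead.
    mean_first : convert the ROI-mean RGB once instead of per pixel — the two
        orders differ for the nonlinear spaces.
    lab_scaled8 : report L*, a*, b* in the 8-bit scaled dialect.
    """
    roi = crop_roi(frame, box)
    if mean_first:
        pixels = mean_channels(roi)[None, :]
    else:
        pixels = roi.pixels.reshape(-1, 3).astype(float)
    hsv = colour.rgb_to_hsv(pixels)
    lab = colour.srgb_to_lab(pixels)
    jch = colour.srgb_to_jch(pixels, vc)
    rgb_mean = pixels.mean(axis=0)
    if circular_hue:
        logger.info("averaging hue components circularly")
        H = _mean_angle_deg(hsv[:, 0])
        h = _mean_angle_deg(jch[:, 2])
    else:
        H = float(hsv[:, 0].mean())
        h = float(jch[:, 2].mean())
    Lab = lab.mean(axis=0)
    if lab_scaled8:
        Lab = colour.lab_to_scaled8(Lab)
    return ComponentVector(
        R=float(rgb_mean[0]),
        G=float(rgb_mean[1]),
        B=float(rgb_mean[2]),
        H=H,
        S=float(hsv[:, 1].mean()),
        V=float(hsv[:, 2].mean()),
        Lstar=float(Lab[0]),
        astar=float(Lab[1]),
        bstar=float(Lab[2]),
        J=float(jch[:, 0].mean()),
        C=float(jch[:, 1].mean()),
        h=h,
    )
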