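"""Synthetic stand-ins for the pressure-response recordings.

The subject recordings behind the study design are not redistributable, so
two seeded generators emulate them:

* :func:`simulate_feature_dataset` draws feature tables directly — paired
  multivariate-normal samples whose class separation is parameterised by
  standardized effect sizes (defaults d = 2.28 for h, 2.29 for a*, −2.29 for
  H) and whose within-class correlation follows the observed component
  correlation matrix (r(H, a*) = −0.78, r(H, h) = −0.98, r(a*, h) = 0.78).
  Pairing is induced by a shared per-subject random effect.

* :func:`simulate_sequence` renders TIFF-ready frame sequences of a skin
  patch following the pressure protocol: stable baseline, a linear blanch
  ramp while the cuff compresses, a residual blanch immediately after
  release, and a reactive-hyperaemia overshoot decaying back to baseline.
  The dynamics are phenomenological (piecewise ramp plus exponentials) — the
  study constrains the direction and timing of the colour change, not a
  haemodynamic model.

Both generators are bit-reproducible from their seed.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .features import FeatureTable, ProtocolTiming
from .imaging import COMPONENT_NAMES, Frame, Landmarks, ROIBox

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSimParams",
    "SkinDynamicsParams",
    "simulate_feature_dataset",
    "simulate_sequence",
    "write_fixture_set",
    "DEFAULT_EFFECT_SIZES",
    "DEFAULT_CORRELATIONS",
]

#: Standardized class-0 minus class-1 mean differences (paired d_z) of the
#: three discriminative components; positive means the component decreases
#: after release.
DEFAULT_EFFECT_SIZES = {"h": 2.28, "astar": 2.29, "H": -2.29}

#: Pairwise within-class correlations among the three components.
DEFAULT_CORRELATIONS = {("H", "astar"): -0.78, ("H", "h"): -0.98, ("astar", "h"): 0.78}

# Typical raw-scale values of the 12 components for a light-intermediate
# (Fitzpatrick II-III) skin tone under the package's default viewing
# conditions; only shift/scale conventions, not fitted quantities.
_DEFAULT_MEANS = {
    "R": 204.0, "G": 160.0, "B": 140.0,
    "H": 18.8, "S": 31.4, "V": 80.0,
    "Lstar": 69.4, "astar": 13.4, "bstar": 16.7,
    "J": 61.4, "C": 20.8, "h": 45.5,
}
_DEFAULT_SDS = {
    "R": 6.0, "G": 6.0, "B": 6.0,
    "H": 1.5, "S": 2.5, "V": 2.5,
    "Lstar": 2.5, "astar": 1.5, "bstar": 1.5,
    "J": 2.5, "C": 1.5, "h": 2.0,
}


@dataclass
class FeatureSimParams:
    """Parameters of the feature-level generator.

    components : subset of the 12 component names to generate.
    n_per_class : subjects (= samples per class); 20 matches the study size.
    class0_mean, class0_sd : per-component baseline mean and SD (raw scale);
        defaults are typical light-intermediate skin values.
    effect_sizes : per-component standardized mean differences d (class 0
        minus class 1, in units of the component SD). With the default
        subject-effect share these are simultaneously the population paired
        d_z values.
    correlation : within-class correlation matrix aligned with
        ``components``; built from :data:`DEFAULT_CORRELATIONS` when None.
    subject_effect_share : fraction of within-class variance attributable to
        the shared per-subject random effect. At 0.5 the SD of the paired
        differences equals the component SD, so the configured effect size
        is exactly the population d_z.
    """

    components: tuple = ("H", "astar", "h")
    n_per_class: int = 20
    class0_mean: dict = field(default_factory=dict)
    class0_sd: dict = field(default_factory=dict)
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    correlation: np.ndarray | None = None
    subject_effect_share: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.components = tuple(self.components)
        unknown = set(self.components) - set(COMPONENT_NAMES)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0 <= self.subject_effect_share < 1:
            raise ValueError("subject_effect_share must lie in [0, 1)")
        self.class0_mean = {**{c: _DEFAULT_MEANS[c] for c in self.components}, **self.class0_mean}
        self.class0_sd = {**{c: _DEFAULT_SDS[c] for c in self.components}, **self.class0_sd}
        if any(self.class0_sd[c] <= 0 for c in self.components):
            raise ValueError("component SDs must be positive")

    def correlation_matrix(self) -> np.ndarray:
        p = len(self.components)
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (p, p) or not np.allclose(corr, corr.T, atol=1e-9):
                raise ValueError("correlation must be a symmetric matrix matching components")
            if not np.allclose(np.diag(corr), 1.0):
                raise ValueError("correlation must have a unit diagonal")
            return corr
        corr = np.eye(p)
        for (ci, cj), r in DEFAULT_CORRELATIONS.items():
            if ci in self.components and cj in self.components:
                i, j = self.components.index(ci), self.components.index(cj)
                corr[i, j] = corr[j, i] = r
        return corr


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Square-root factor of a correlation matrix, repairing mild PSD violations."""
    w, V = np.linalg.eigh(corr)
    if w.min() < -0.05:
        raise ValueError(
            f"correlation matrix is not positive semidefinite (min eigenvalue {w.min():.3f})"
        )
    if w.min() < -1e-9:
        warnings.warn(
            "correlation matrix has slightly negative eigenvalues; repairing to nearest PSD",
            stacklevel=3,
        )
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_feature_dataset(params: FeatureSimParams = FeatureSimParams()) -> FeatureTable:
    """Draw a paired two-class feature table.

    Per subject i, class-0 and class-1 rows share a random effect s_i and
    get independent residuals, all with the configured correlation:

        x0_i = mu + SD * (s_i + e0_i)
        x1_i = mu - d * SD + SD * (s_i + e1_i)

    where Var(s) = rho, Var(e) = 1 - rho (rho = subject_effect_share), so
    the within-class covariance of each component pair follows the
    correlation matrix exactly and the per-subject differences have
    SD = sqrt(2 (1 - rho)) * SD.
    """
    p = params
    comps = list(p.components)
    k = len(comps)
    corr = p.correlation_matrix()
    L = _psd_factor(corr)
    rng = np.random.default_rng(p.seed)
    rho = p.subject_effect_share
    n = p.n_per_class
    s = rng.standard_normal((n, k)) @ L.T * np.sqrt(rho)
    e0 = rng.standard_normal((n, k)) @ L.T * np.sqrt(1.0 - rho)
    e1 = rng.standard_normal((n, k)) @ L.T * np.sqrt(1.0 - rho)
    mu = np.array([p.class0_mean[c] for c in comps])
    sd = np.array([p.class0_sd[c] for c in comps])
    d = np.array([p.effect_sizes.get(c, 0.0) for c in comps])
    x0 = mu + sd * (s + e0)
    x1 = mu - d * sd + sd * (s + e1)
    width = max(2, len(str(n)))
    sids = [f"S{i + 1:0{width}d}" for i in range(n)]
    rows = []
    for label, x in ((0, x0), (1, x1)):
        df = pd.DataFrame(x, columns=comps)
        df.insert(0, "label", label)
        df.insert(0, "subject_id", sids)
        rows.append(df)
    data = (
        pd.concat(rows)
        .sort_values(["subject_id", "label"], kind="stable")
        .reset_index(drop=True)
    )
    return FeatureTable(data)


@dataclass
class SkinDynamicsParams:
    """Parameters of the image-level blanch/reperfusion generator.

    baseline_rgb : mean resting skin tone (8-bit sRGB); default is a
        light-intermediate (Fitzpatrick II-III-like) tone.
    blanch_shift : RGB displacement at full compression. The default raises
        green and blue (less haemoglobin absorption) which weakens redness:
        a* falls, the HSV hue rises and the literal-dialect JCh hue falls.
    settle_s : how long the residual blanch persists after cuff release
        before reperfusion takes over; the class-1 frame (1 s post-release
        by default) falls inside this window.
    blanch_decay_s : exponential time constant of the blanch fading once
        reperfusion starts.
    hyperemia_amplitude : strength of the reactive-hyperaemia overshoot
        (fraction of the blanch magnitude, applied along ``hyperemia_shift``).
    hyperemia_tau_s : decay time constant of the overshoot.
    texture_sd : SD of the static per-pixel skin texture (seeded, constant
        over time).
    sensor_noise_sd : SD of the per-frame, per-pixel sensor noise.
    frame_shape : (rows, cols) of the generated frames.
    roi : the rectangle following the dynamics; defaults to a 130 x 140
        patch. Outside-ROI pixels are stationary.
    landmarks : wrist/elbow points written into the fixture manifest.
    """

    baseline_rgb: tuple = (204.0, 160.0, 140.0)
    blanch_shift: tuple = (0.0, 12.0, 6.0)
    settle_s: float = 2.0
    blanch_decay_s: float = 3.0
    hyperemia_amplitude: float = 0.6
    hyperemia_shift: tuple = (10.0, -6.0, -3.0)
    hyperemia_tau_s: float = 10.0
    texture_sd: float = 2.5
    sensor_noise_sd: float = 1.5
    frame_shape: tuple = (150, 200)
    roi: ROIBox = ROIBox(35, 5, 130, 140)
    landmarks: Landmarks = Landmarks((20.0, 75.0), (180.0, 75.0))
    seed: int = 0

    def __post_init__(self):
        if self.texture_sd < 0 or self.sensor_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if min(self.settle_s, self.blanch_decay_s, self.hyperemia_tau_s) <= 0:
            raise ValueError("time constants must be positive")
        rows, cols = self.frame_shape
        if self.roi.y0 + self.roi.height > rows or self.roi.x0 + self.roi.width > cols:
            raise ValueError("ROI does not fit inside frame_shape")


def blanch_fraction(t: np.ndarray, p: SkinDynamicsParams, timing: ProtocolTiming) -> np.ndarray:
    """Blanch level in [0, 1] at time t: ramp up under compression, hold, decay."""
    t = np.asarray(t, dtype=float)
    t_on = timing.baseline_s
    t_off = timing.baseline_s + timing.compression_s
    t_rep = t_off + p.settle_s
    ramp = np.clip((t - t_on) / timing.compression_s, 0.0, 1.0)
    decay = np.exp(-np.maximum(t - t_rep, 0.0) / p.blanch_decay_s)
    return np.where(t < t_off, ramp, decay)


def hyperemia_level(t: np.ndarray, p: SkinDynamicsParams, timing: ProtocolTiming) -> np.ndarray:
    """Reactive-hyperaemia overshoot: rises after the residual-blanch window, decays."""
    t = np.asarray(t, dtype=float)
    t_rep = timing.baseline_s + timing.compression_s + p.settle_s
    u = np.maximum(t - t_rep, 0.0)
    level = p.hyperemia_amplitude * (1.0 - np.exp(-u / 2.0)) * np.exp(-u / p.hyperemia_tau_s)
    return np.where(t <= t_rep, 0.0, level)


def simulate_sequence(
    p: SkinDynamicsParams = SkinDynamicsParams(),
    timing: ProtocolTiming = ProtocolTiming(),
) -> tuple[list[Frame], pd.DataFrame]:
    """Render one subject's frame sequence plus its ground-truth trace.

    Returns ``(frames, truth)`` where ``truth`` has one row per frame with
    the blanch fraction, hyperaemia level and a perfusion scalar
    (1 - blanch + hyperaemia). The per-pixel texture is static and seeded;
    sensor noise is redrawn per frame; all pixels are clipped to [0, 255]
    and the clipped fraction is logged.
    """
    rng = np.random.default_rng(p.seed)
    rows, cols = p.frame_shape
    n = timing.n_frames
    t = np.arange(n) / timing.fps
    base = np.asarray(p.baseline_rgb, dtype=float)
    texture = rng.normal(0.0, p.texture_sd, size=(rows, cols, 3)) if p.texture_sd else 0.0
    still = base + texture
    blanch = blanch_fraction(t, p, timing)
    hyper = hyperemia_level(t, p, timing)
    shift_b = np.asarray(p.blanch_shift, dtype=float)
    shift_h = np.asarray(p.hyperemia_shift, dtype=float)
    ys, xs = p.roi.y0, p.roi.x0
    frames = []
    clipped = 0
    for i in range(n):
        px = still + rng.normal(0.0, p.sensor_noise_sd, size=(rows, cols, 3))
        px[ys : ys + p.roi.height, xs : xs + p.roi.width] += (
            blanch[i] * shift_b + hyper[i] * shift_h
        )
        clipped += int(np.sum((px < 0) | (px > 255)))
        frames.append(Frame(np.clip(px, 0, 255).round().astype(np.uint8), t=float(t[i])))
    frac = clipped / (n * rows * cols * 3)
    if frac > 0:
        logger.info("clipped %.4f%% of generated pixel values", 100 * frac)
    truth = pd.DataFrame(
        {"t": t, "blanch": blanch, "hyperemia": hyper, "perfusion": 1.0 - blanch + hyper}
    )
    truth.attrs["clip_fraction"] = frac
    return frames, truth


def write_fixture_set(
    out_dir: str,
    n_subjects: int = 20,
    seeds=None,
    params: SkinDynamicsParams = SkinDynamicsParams(),
    timing: ProtocolTiming = ProtocolTiming(),
    tone_jitter_sd: tuple = (4.0, 3.0, 3.0),
) -> dict:
    """Write per-subject TIFF sequences and a JSON manifest.

    Each subject's baseline tone is jittered around ``params.baseline_rgb``
    (seeded) to emulate tone diversity within a light-intermediate cohort.
    The manifest records the ROI, landmarks, timing, per-subject seeds and
    truth-trace paths — everything needed to run the pipeline offline.
    Re-running with the same seeds reproduces identical files.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seeds is None:
        seeds = list(range(1, n_subjects + 1))
    if len(seeds) != n_subjects:
        raise ValueError("need one seed per subject")
    os.makedirs(out_dir, exist_ok=True)
    subjects = {}
    for k, seed in enumerate(seeds):
        sid = f"S{k + 1:02d}"
        rng = np.random.default_rng(seed)
        tone = np.asarray(params.baseline_rgb) + rng.normal(0, tone_jitter_sd, size=3)
        sp = SkinDynamicsParams(
            baseline_rgb=tuple(tone),
            blanch_shift=params.blanch_shift,
            settle_s=params.settle_s,
            blanch_decay_s=params.blanch_decay_s,
            hyperemia_amplitude=params.hyperemia_amplitude,
            hyperemia_shift=params.hyperemia_shift,
            hyperemia_tau_s=params.hyperemia_tau_s,
            texture_sd=params.texture_sd,
            sensor_noise_sd=params.sensor_noise_sd,
            frame_shape=params.frame_shape,
            roi=params.roi,
            landmarks=params.landmarks,
            seed=seed,
        )
        frames, truth = simulate_sequence(sp, timing)
        sdir = os.path.join(out_dir, sid)
        os.makedirs(sdir, exist_ok=True)
        for i, fr in enumerate(frames):
            tifffile.imwrite(os.path.join(sdir, f"frame_{i:05d}.tif"), fr.pixels)
        truth_path = os.path.join(sdir, "truth.csv")
        truth.to_csv(truth_path, index=False)
        subjects[sid] = {
            "dir": sid,
            "seed": int(seed),
            "baseline_rgb": [float(v) for v in tone],
            "truth": os.path.join(sid, "truth.csv"),
        }
    manifest = {
        "n_subjects": n_subjects,
        "fps": timing.fps,
        "timing": {
            "baseline_s": timing.baseline_s,
            "compression_s": timing.compression_s,
            "post_s": timing.post_s,
            "pressure_mmHg": timing.pressure_mmHg,
        },
        "roi": {
            "x0": params.roi.x0, "y0": params.roi.y0,
            "width": params.roi.width, "height": params.roi.height,
        },
        "landmarks": {
            "wrist": list(params.landmarks.wrist),
            "elbow": list(params.landmarks.elbow),
        },
        "subjects": subjects,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
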