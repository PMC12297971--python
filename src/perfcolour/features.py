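"""Representative-frame selection, feature-table assembly and standardization.

Each subject contributes exactly two samples: class 0 from a stable-baseline
frame before cuff inflation, and class 1 from a frame immediately after cuff
release (early reperfusion, while the skin is still residually blanched).
The 12 ROI-averaged colour components of those frames form the feature table
that the classifier and the statistics consume; all components are z-scored
before modelling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .colour import ViewingConditions
from .imaging import COMPONENT_NAMES, Frame, Landmarks, ROIBox, correct_tilt, extract_components

__all__ = [
    "ProtocolTiming",
    "FeatureTable",
    "select_frames",
    "build_feature_table",
    "standardize",
]


@dataclass(frozen=True)
class ProtocolTiming:
    """Pressure-protocol phases: baseline, cuff compression, post-release (seconds)."""

    baseline_s: float = 10.0
    compression_s: float = 30.0
    post_s: float = 60.0
    fps: float = 15.0
    pressure_mmHg: float = 80.0

    def __post_init__(self):
        if min(self.baseline_s, self.compression_s, self.post_s, self.fps) <= 0:
            raise ValueError("all protocol durations and fps must be positive")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.compression_s + self.post_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_s * self.fps))


@dataclass
class FeatureTable:
    """Samples x 12 colour components with binary labels and subject IDs.

    ``data`` holds one row per (subject, class) sample with columns
    ``subject_id``, ``label`` (0 = baseline, 1 = post-release) and the 12
    components in canonical order. After :func:`standardize`, ``scale_``
    stores the per-column means and SDs for the inverse transform.
    """

    data: pd.DataFrame
    standardized: bool = False
    scale_: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        missing = [c for c in ("subject_id", "label") if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        if not set(self.data["label"]).issubset({0, 1}):
            raise ValueError("labels must be 0 or 1")

    @property
    def components(self) -> list[str]:
        return [c for c in COMPONENT_NAMES if c in self.data.columns]

    def X(self, components=None) -> np.ndarray:
        cols = list(components) if components is not None else self.components
        return self.data[cols].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    def class_values(self, component: str):
        """Paired per-subject values of one component: (class-0, class-1) arrays."""
        wide = self.data.pivot(index="subject_id", columns="label", values=component)
        return wide[0].to_numpy(), wide[1].to_numpy()

    def to_csv(self, path, sidecar: str | None = None) -> None:
        cols = ["subject_id", "label"] + self.components
        self.data[cols].to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(
                    {"standardized": self.standardized, "scale": self.scale_}, fh, indent=2
                )

    @classmethod
    def from_csv(cls, path, sidecar: str | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        standardized, scale = False, None
        if sidecar is not None:
            with open(sidecar) as fh:
                meta = json.load(fh)
            standardized, scale = meta.get("standardized", False), meta.get("scale")
        return cls(df, standardized=standardized, scale_=scale)


def select_frames(
    n_frames: int,
    timing: ProtocolTiming,
    *,
    baseline_offset_s: float = 0.0,
    settle_s: float = 1.0,
) -> tuple[int, int]:
    """Pick the representative class-0 and class-1 frame indices.

    Class 0 is taken at the baseline midpoint (plus ``baseline_offset_s``);
    class 1 at the first frame at or after cuff release plus ``settle_s``
    (default 1 s), i.e. in the early reperfusion phase while the residual
    blanch is still visible.
    """
    t0 = timing.baseline_s / 2.0 + baseline_offset_s
    t1 = timing.baseline_s + timing.compression_s + settle_s
    i0 = int(round(t0 * timing.fps))
    i1 = int(math.ceil(t1 * timing.fps - 1e-9))
    if not (0 <= i0 < n_frames and 0 <= i1 < n_frames):
        raise ValueError(
            f"sequence of {n_frames} frames does not cover the selection times "
            f"t0={t0:.2f}s (index {i0}) and t1={t1:.2f}s (index {i1})"
        )
    return i0, i1


def build_feature_table(
    sequences: dict[str, list[Frame]],
    rois: dict[str, ROIBox] | ROIBox,
    vc: ViewingConditions,
    timing: ProtocolTiming,
    landmarks: dict[str, Landmarks] | Landmarks | None = None,
    *,
    baseline_offset_s: float = 0.0,
    settle_s: float = 1.0,
    **extract_opts,
) -> FeatureTable:
    """Assemble the per-subject two-class feature table.

    Parameters
    ----------
    sequences : mapping of subject_id to its ordered frame sequence.
    rois : one ROI box, or a per-subject mapping.
    vc : CIECAM02 viewing conditions for the JCh components.
    timing : the pressure protocol (frame selection is derived from it).
    landmarks : optional wrist/elbow points (single or per subject); when
        given, tilt correction is applied before cropping.

    Returns exactly two rows per subject, ordered by (subject, class).
    """
    if len(sequences) == 0:
        raise ValueError("at least one subject sequence is required")
    subject_ids = list(sequences)
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject IDs")
    rows = []
    for sid in subject_ids:
        frames = sequences[sid]
        roi = rois[sid] if isinstance(rois, dict) else rois
        lm = landmarks[sid] if isinstance(landmarks, dict) else landmarks
        try:
            i0, i1 = select_frames(
                len(frames), timing, baseline_offset_s=baseline_offset_s, settle_s=settle_s
            )
            for label, idx in ((0, i0), (1, i1)):
                frame = frames[idx]
                if lm is not None:
                    frame = correct_tilt(frame, lm)
                cv = extract_components(frame, roi, vc, **extract_opts)
                rows.append({"subject_id": sid, "label": label, **cv.as_series().to_dict()})
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for subject {sid!r}: {exc}") from exc
    df = pd.DataFrame(rows).sort_values(["subject_id", "label"], kind="stable")
    return FeatureTable(df.reset_index(drop=True))


def standardize(table: FeatureTable, components=None) -> FeatureTable:
    """Z-score each component column over all rows (classes pooled, SD with n-1).

    Stores the column means and SDs in ``scale_`` for the inverse transform.
    Idempotent: standardizing an already-standardized table changes nothing
    beyond floating-point noise.

    Raises
    ------
    ValueError
        If the table has fewer than 2 rows or any component column is
        constant (named in the message).
    """
    cols = list(components) if components is not None else table.components
    if len(table.data) < 2:
        raise ValueError("standardization requires at least 2 rows")
    df = table.data.copy()
    means, sds = {}, {}
    for c in cols:
        mu = df[c].mean()
        sd = df[c].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"component {c!r} is constant; cannot standardize")
        df[c] = (df[c] - mu) / sd
        means[c], sds[c] = float(mu), float(sd)
    return replace(
        table, data=df, standardized=True, scale_={"mean": means, "sd": sds}
    )
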