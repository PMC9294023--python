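"""Composite regional integrity scoring.

Each of the 15 regions of interest combines a grey-matter index (summed
cortical thickness, or summed TIV-normalised volume for subcortical and
infratentorial regions) with a white-matter index (summed FA).  Both indices
are min-max scaled to [0, 1] across the cohort and added, giving a composite
score in [0, 2] per ROI per subject; higher scores indicate better-preserved
tissue.  The long-association-fibre ROI is the stated exception: it has no
grey-matter members and its two FA inputs are scaled separately, so its
composite is the sum of those two scaled indices and lives on the same scale.

Scaling is cohort-level: the min and max of each index are taken over the
analysed sample and persisted (:class:`ScalingParams`) so new subjects can be
projected with frozen parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ReducedFeatureMatrix


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ROIDefinition:
    name: str
    gm_members: tuple[str, ...]
    wm_members: tuple[str, ...]
    wm_scaling_mode: str = "pooled"  # pooled | separate

    def __post_init__(self):
        if self.wm_scaling_mode not in ("pooled", "separate"):
            raise ScoringError(f"unknown wm_scaling_mode {self.wm_scaling_mode!r}")
        if not self.wm_members:
            raise ScoringError(f"ROI {self.name!r}: wm_members must be non-empty")
        gm_modalities = {m.split("_", 1)[0] for m in self.gm_members}
        if len(gm_modalities) > 1:
            raise ScoringError(f"ROI {self.name!r}: gm_members mix modalities "
                               f"{sorted(gm_modalities)}")


def load_roi_definitions(path: str | Path | None = None) -> list[ROIDefinition]:
    """Load the 15 ROI definitions (packaged default unless *path* given)."""
    if path is None:
        text = resources.files("alsclust.config").joinpath("roi_definitions.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [
        ROIDefinition(
            name=entry["name"],
            gm_members=tuple(entry.get("gm_members") or ()),
            wm_members=tuple(entry["wm_members"]),
            wm_scaling_mode=entry.get("wm_scaling_mode", "pooled"),
        )
        for entry in raw["rois"]
    ]


@dataclass
class ScalingParams:
    """Observed cohort min/max per scaled index, keyed '<roi>/<index>'."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def add(self, key: str, lo: float, hi: float) -> None:
        if hi <= lo:
            raise ScoringError(f"degenerate scaling for {key!r}: min == max == {lo}")
        self.bounds[key] = (float(lo), float(hi))

    def apply(self, key: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[key]
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, lo, hi) for k, (lo, hi) in self.bounds.items()],
            columns=["index", "min", "max"],
        )


@dataclass
class CompositeScoreMatrix:
    """N x 15 matrix of composite regional integrity scores in [0, 2]."""

    scores: pd.DataFrame          # columns = ROI names, canonical order
    scaling: ScalingParams

    @property
    def subject_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def roi_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path, index_label="subject_id")


def min_max_scale(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Scale a vector to [0, 1] by its observed range.

    Returns ``(scaled, min, max)``; the cohort minimum maps to 0 and the
    maximum to 1.  Raises on fewer than two values or a constant vector, for
    which the scaling is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ScoringError("min-max scaling needs a 1-D vector of length >= 2")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ScoringError(f"constant vector (min == max == {lo}); scaling undefined")
    return (x - lo) / (hi - lo), lo, hi


def roi_raw_indices(
    matrix: ReducedFeatureMatrix, roi: ROIDefinition
) -> tuple[pd.Series | None, list[pd.Series]]:
    """Row-wise summed raw indices for one ROI, before scaling.

    Returns ``(gm_index, wm_indices)``: the grey-matter index is the sum of
    the ROI's thickness or volume-fraction members (``None`` when the ROI has
    none); in pooled mode the white-matter list holds the single summed FA
    index, in separate mode one entry per FA member.
    """
    df = matrix.values
    for col in (*roi.gm_members, *roi.wm_members):
        if col not in df.columns:
            raise ScoringError(f"ROI {roi.name!r}: member column {col!r} not in matrix")
    gm = df[list(roi.gm_members)].sum(axis=1) if roi.gm_members else None
    if roi.wm_scaling_mode == "pooled":
        wm = [df[list(roi.wm_members)].sum(axis=1)]
    else:
        wm = [df[m] for m in roi.wm_members]
    return gm, wm


def composite_scores(
    matrix: ReducedFeatureMatrix,
    roi_defs: list[ROIDefinition] | None = None,
) -> CompositeScoreMatrix:
    """Compute the N x 15 composite score matrix.

    For each ROI the two indices (GM sum and WM sum, or the two separately
    scaled FA values for the long-association ROI) are min-max scaled over the
    cohort and added, so each score lies in [0, 2] with the extremes attained
    at the cohort extremes.
    """
    roi_defs = roi_defs if roi_defs is not None else load_roi_definitions()
    scaling = ScalingParams()
    cols = {}
    for roi in roi_defs:
        gm, wm = roi_raw_indices(matrix, roi)
        indices = ([] if gm is None else [("gm", gm)])
        indices += [(f"wm{i}" if len(wm) > 1 else "wm", w) for i, w in enumerate(wm, 1)]
        if len(indices) != 2:
            raise ScoringError(f"ROI {roi.name!r}: expected exactly 2 indices, "
                               f"got {len(indices)}")
        total = np.zeros(len(matrix.values))
        for tag, raw in indices:
            scaled, lo, hi = min_max_scale(raw.to_numpy())
            scaling.add(f"{roi.name}/{tag}", lo, hi)
            total = total + scaled
        cols[roi.name] = total
    scores = pd.DataFrame(cols, index=matrix.values.index)
    return CompositeScoreMatrix(scores=scores, scaling=scaling)
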