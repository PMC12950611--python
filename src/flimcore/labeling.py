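"""Histology-to-fresh-core registration and point labeling.

Histology annotations live on the coordinate axis of the fixed, sectioned
core, whose length differs from the fresh core by uniform shrinkage or
stretching.  Under the uniform-deformation assumption a histology position
x maps to the fresh core as x * fresh_length / histology_length.  Each scan
point takes the label of the interval containing its mapped position
(half-open [start, end) convention), and a fixed number of points
straddling every label transition is excluded to limit mislabeling from
imperfect registration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import CoordinateError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTrack",
    "map_to_fresh_coordinates",
    "assign_labels",
    "exclude_transitions",
    "build_labeled_dataset",
]


@dataclass
class AnnotationTrack:
    """Labeled, non-overlapping intervals on a core's histology axis."""

    core_id: str
    histology_length_mm: float
    intervals: List[Tuple[str, float, float]]  # (label, start_mm, end_mm)

    def __post_init__(self):
        if self.histology_length_mm <= 0:
            raise InvalidParameterError("histology_length_mm must be > 0")
        prev_end = -np.inf
        for lbl, s, e in sorted(self.intervals, key=lambda iv: iv[1]):
            if s < -1e-9 or e > self.histology_length_mm + 1e-9:
                raise InvalidParameterError(
                    f"interval ({lbl}, {s}, {e}) outside [0, {self.histology_length_mm}]"
                )
            if s < prev_end - 1e-9:
                raise InvalidParameterError("annotation intervals overlap")
            prev_end = e


def map_to_fresh_coordinates(
    x_hist: float, fresh_length: float, histology_length: float
) -> float:
    """Map a histology-axis position onto the fresh core assuming uniform
    deformation: x * fresh_length / histology_length."""
    if fresh_length <= 0 or histology_length <= 0:
        raise InvalidParameterError("lengths must be positive")
    x = np.asarray(x_hist, float)
    if np.any(x < -1e-9) or np.any(x > histology_length + 1e-9):
        raise CoordinateError(
            f"position {x_hist} outside [0, {histology_length}]"
        )
    result = x * (fresh_length / histology_length)
    return float(result) if np.isscalar(x_hist) else result


def assign_labels(
    records: pd.DataFrame,
    track: AnnotationTrack,
    fresh_length: float,
) -> pd.Series:
    """Label of the mapped annotation interval containing each record.

    Intervals follow the half-open [start, end) convention after mapping to
    fresh coordinates; the final interval end is treated as closed so the
    distal tip of the core is not orphaned.  Positions outside every
    interval get ``None`` (unlabeled).
    """
    pos = records["position_mm"].to_numpy(float)
    scale = fresh_length / track.histology_length_mm
    labels: List[Optional[str]] = [None] * len(pos)
    ivals = sorted(track.intervals, key=lambda iv: iv[1])
    last_end = max((e for _, _, e in ivals), default=0.0) * scale
    for lbl, s_h, e_h in ivals:
        s, e = s_h * scale, e_h * scale
        for i, x in enumerate(pos):
            if s <= x < e or (x == e == last_end):
                labels[i] = lbl
    return pd.Series(labels, index=records.index, dtype=object)


def exclude_transitions(
    labeled: pd.DataFrame,
    n_exclude: int = 25,
    group_cols: Tuple[str, ...] = ("core_id", "pass_index"),
    label_col: str = "label",
) -> pd.Series:
    """Boolean mask flagging points near label transitions.

    Within each core/pass, records are taken in position order; wherever
    consecutive labels differ, the ``n_exclude`` points nearest the
    transition are flagged -- ceil(n/2) on the earlier side, floor(n/2) on
    the later side -- clipped at the core ends.  Flags from multiple
    transitions union.  Unlabeled gaps count as their own label, so entering
    or leaving an unlabeled stretch is also a transition.
    """
    if n_exclude < 0:
        raise InvalidParameterError("n_exclude must be >= 0")
    mask = np.zeros(len(labeled), bool)
    before = (n_exclude + 1) // 2
    after = n_exclude // 2
    frame = labeled.reset_index(drop=True)
    for _, grp in frame.groupby(list(group_cols), sort=False):
        order = grp["position_mm"].to_numpy(float).argsort(kind="stable")
        idx = grp.index.to_numpy()[order]
        lab = frame.loc[idx, label_col].to_numpy(object)
        n = len(idx)
        for i in range(n - 1):
            if lab[i] != lab[i + 1]:
                lo = max(0, i - before + 1)
                hi = min(n, i + 1 + after)
                mask[idx[lo:hi]] = True
    return pd.Series(mask, index=labeled.index, name="excluded")


def build_labeled_dataset(
    features: pd.DataFrame,
    tracks: Dict[str, AnnotationTrack],
    fresh_lengths: Dict[str, float],
    n_exclude: int = 25,
) -> pd.DataFrame:
    """Attach annotation labels and the transition-exclusion mask to a
    feature table.

    ``tracks`` and ``fresh_lengths`` are keyed by core_id.  Cores without an
    annotation track stay unlabeled (logged).  Returns a copy of the
    features with ``label`` and ``excluded`` columns; a per-patient,
    per-class count table is attached as ``.attrs['provenance']``.
    """
    out = features.reset_index(drop=True).copy()  # a unique index is required
    out["label"] = pd.Series([None] * len(out), index=out.index, dtype=object)
    for core_id, grp in out.groupby("core_id", sort=False):
        track = tracks.get(core_id)
        if track is None:
            logger.warning("no annotation track for core %s; left unlabeled", core_id)
            continue
        out.loc[grp.index, "label"] = assign_labels(
            grp, track, fresh_lengths[core_id]
        )
    out["excluded"] = exclude_transitions(out, n_exclude=n_exclude)
    included = out[~out["excluded"] & out["label"].notna()]
    out.attrs["provenance"] = {
        str(patient): dict(grp)
        for patient, grp in included.groupby(["patient_id", "label"])
        .size()
        .unstack(fill_value=0)
        .iterrows()
    }
    return out
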