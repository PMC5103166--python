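"""Calibration-set design.

Three steps mirror the calibration-development procedure for a germplasm
collection whose spectral variability is unknown up front:

1. spectral-diversity selection of samples in principal-component space
   (greedy max--min on the PC1/PC3 plane, a Kennard--Stone-style surrogate
   for the original visual pick);
2. augmentation with samples predicted extreme by a preliminary model, to
   extend the concentration range of the final calibration set;
3. a ranked 3:1 calibration/validation split that keeps both concentration
   endpoints in the calibration set, so external validation never
   extrapolates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SelectionPlan", "select_diverse", "select_extremes", "rank_split"]


@dataclass
class SelectionPlan:
    """Which sample plays which role in calibration development."""

    diverse_ids: list[str]
    extreme_ids: list[str]
    calibration_ids: list[str]
    validation_ids: list[str]
    pca_axes: tuple[int, int] = (1, 3)

    def __post_init__(self):
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation sets must be disjoint")
        if set(self.diverse_ids) & set(self.extreme_ids):
            raise ValueError("extreme ids must be disjoint from diverse ids")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.diverse_ids:
            rows.append({"sample_id": sid, "selected_as": "diverse"})
        for sid in self.extreme_ids:
            rows.append({"sample_id": sid, "selected_as": "extreme"})
        frame = pd.DataFrame(rows)
        role = {sid: "calibration" for sid in self.calibration_ids}
        role.update({sid: "validation" for sid in self.validation_ids})
        frame["split"] = frame["sample_id"].map(role)
        return frame


def select_diverse(scores: np.ndarray, ids, axes=(1, 3), n_select: int = 100):
    """Greedy max--min selection in a 2-D principal-component plane.

    ``scores`` is the full n x n_components PCA score matrix; ``axes`` are
    1-based component numbers (default the PC1/PC3 plane, where PC3 carries
    the storage-compound bands rather than baseline/particle-size effects).
    Starts from the point farthest from the centroid, then repeatedly adds
    the point with the largest minimum distance to the selected set.
    Deterministic: ids are sorted before index tie-breaking, so the result
    does not depend on input order.
    """
    scores = np.asarray(scores, float)
    ids = [str(s) for s in ids]
    n = len(ids)
    if scores.shape[0] != n:
        raise ValueError("scores row count must match ids")
    if n_select > n:
        raise ValueError(f"cannot select {n_select} of {n} samples")
    a, b = axes
    pts = scores[:, [a - 1, b - 1]]
    order = np.argsort(np.array(ids, dtype=object), kind="stable")
    pts = pts[order]
    sorted_ids = [ids[i] for i in order]
    centroid = pts.mean(axis=0)
    d0 = np.linalg.norm(pts - centroid, axis=1)
    first = int(np.argmax(d0))  # argmax takes the lowest index on ties
    selected = [first]
    min_dist = np.linalg.norm(pts - pts[first], axis=1)
    while len(selected) < n_select:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return [sorted_ids[i] for i in selected]


def select_extremes(predictions: pd.Series, n_select: int, exclude=()) -> list[str]:
    """Samples with extreme predicted values, excluding already-chosen ids.

    Takes ceil(n/2) largest and floor(n/2) smallest predicted values among
    the non-excluded samples.  ``predictions`` maps sample_id -> predicted
    concentration (the preliminary model's output).
    """
    excl = set(map(str, exclude))
    avail = predictions[[str(i) not in excl for i in predictions.index]]
    if n_select > len(avail):
        raise ValueError(f"cannot select {n_select} of {len(avail)} available")
    n_hi = (n_select + 1) // 2
    n_lo = n_select // 2
    ranked = avail.sort_values(kind="stable")
    lo = [str(i) for i in ranked.index[:n_lo]]
    hi = [str(i) for i in ranked.index[len(ranked) - n_hi:]]
    return hi + lo


def rank_split(values: pd.Series, ratio=(3, 1)):
    """Ranked calibration/validation split (default 3:1).

    Samples are ranked ascending by reference value (ties broken by id);
    every (cal+val)-th sample — ranks 4, 8, 12, ... for 3:1 — goes to the
    validation set.  Both endpoints always stay in calibration: if the top
    rank falls on a validation slot it is swapped with its lower neighbour,
    so the validation range is contained in the calibration range.
    """
    if len(values) < sum(ratio):
        raise ValueError(f"need at least {sum(ratio)} samples for a {ratio} split")
    step = sum(ratio)
    df = pd.DataFrame({"id": [str(i) for i in values.index], "value": values.values})
    df = df.sort_values(["value", "id"], kind="stable").reset_index(drop=True)
    n = len(df)
    val_ranks = set(range(step, n + 1, step))  # 1-based ranks
    if n in val_ranks:  # keep the maximum in calibration
        val_ranks.discard(n)
        val_ranks.add(n - 1)
    val_ids = [df.loc[r - 1, "id"] for r in sorted(val_ranks)]
    cal_ids = [df.loc[i, "id"] for i in range(n) if (i + 1) not in val_ranks]
    return cal_ids, val_ids
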