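"""Stratified map assessment and unbiased area estimation.

The central object is an *area-proportion error matrix*: rows are map
classes (the sampling strata), columns are reference classes, and each
cell holds the estimated areal proportion

    p_ij = W_i * n_ij / n_i

where W_i is stratum i's mapped-area weight and n_ij its sample
cross-tabulation.  From the matrix follow the overall accuracy (diagonal
sum), user's accuracy (row-conditional), producer's accuracy
(column-conditional), and the *adjusted* area of class k — its reference
column sum times the total mapped area — with standard stratified
variance estimators and z = 1.96 margins throughout.

Segmented field statistics inherit a size/count bias from over- or
under-merging; a ratio estimator against hand-digitized polygons at
validation sites (adjusted = raw x digitized/segmented) corrects both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AreaErrorMatrix",
    "AccuracyReport",
    "AreaEstimate",
    "BiasAdjustment",
    "build_area_matrix",
    "accuracy_metrics",
    "estimate_area",
    "adjust_field_stats",
    "collapse_reference_labels",
]

Z95 = 1.96


@dataclass
class AreaErrorMatrix:
    """Class-wise area-proportion confusion matrix with sample counts.

    ``proportions[i, j]`` is the areal proportion mapped as class i and
    referenced as class j (fractions summing to 1); ``n[i]`` is the number
    of sample points in map stratum i; ``area_total`` the mapped area (in
    km^2 or any consistent unit).
    """

    classes: tuple[str, ...]
    proportions: np.ndarray
    n: np.ndarray
    area_total: float | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.n = np.asarray(self.n)
        k = len(self.classes)
        if self.proportions.shape != (k, k):
            raise ValueError("proportion matrix shape mismatch with classes")
        if np.any(self.proportions < 0) or np.any(self.n < 0):
            raise ValueError("proportions and counts must be non-negative")
        if abs(self.proportions.sum() - 1.0) > 1e-6:
            raise ValueError("proportions must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        """Mapped-area stratum weights W_i (row sums)."""
        return self.proportions.sum(axis=1)

    @classmethod
    def from_percentages(
        cls,
        classes: Sequence[str],
        percent: np.ndarray,
        n: Sequence[int],
        area_total: float | None = None,
    ) -> "AreaErrorMatrix":
        """Ingest a printed matrix whose cells are areal percentages."""
        p = np.asarray(percent, dtype=float) / 100.0
        p = p / p.sum()  # absorb rounding of the printed percentages
        return cls(tuple(classes), p, np.asarray(n), area_total)


def build_area_matrix(
    points: pd.DataFrame,
    strata_weights: Mapping[str, float],
    classes: Sequence[str] | None = None,
    area_total: float | None = None,
) -> AreaErrorMatrix:
    """Stratified area-proportion matrix from labelled reference points.

    ``points`` needs columns ``map_class`` (the stratum) and ``ref_class``;
    ``strata_weights`` are the mapped-area proportions W_i (summing to 1).
    """
    if not {"map_class", "ref_class"} <= set(points.columns):
        raise ValueError("points need map_class and ref_class columns")
    if abs(sum(strata_weights.values()) - 1.0) > 1e-6:
        raise ValueError("strata weights must sum to 1")
    if classes is None:
        classes = sorted(strata_weights)
    k = len(classes)
    prop = np.zeros((k, k))
    n = np.zeros(k, dtype=int)
    for i, ci in enumerate(classes):
        sub = points[points["map_class"] == ci]
        n[i] = len(sub)
        if n[i] == 0:
            raise ValueError(f"empty stratum {ci!r}")
        for j, cj in enumerate(classes):
            n_ij = int((sub["ref_class"] == cj).sum())
            prop[i, j] = strata_weights[ci] * n_ij / n[i]
    return AreaErrorMatrix(tuple(classes), prop, n, area_total)


@dataclass
class AccuracyReport:
    classes: tuple[str, ...]
    overall: float
    overall_margin: float
    users: dict[str, float]
    users_margin: dict[str, float]
    producers: dict[str, float]
    producers_margin: dict[str, float]


def accuracy_metrics(matrix: AreaErrorMatrix) -> AccuracyReport:
    """Overall, user's and producer's accuracy with 95% margins of error.

    Variances follow the standard stratified estimators for proportion
    error matrices; a zero row or column total leaves that metric NaN.
    """
    p = matrix.proportions
    W = matrix.weights
    n = matrix.n.astype(float)
    k = len(matrix.classes)
    row = p.sum(axis=1)
    col = p.sum(axis=0)

    overall = float(np.trace(p))
    with np.errstate(invalid="ignore", divide="ignore"):
        users = np.where(row > 0, np.diag(p) / row, np.nan)
        producers = np.where(col > 0, np.diag(p) / col, np.nan)

    v_overall = float(
        np.nansum(W**2 * users * (1 - users) / np.maximum(n - 1, 1))
    )
    users_margin = {}
    producers_margin = {}
    for i, ci in enumerate(matrix.classes):
        vu = users[i] * (1 - users[i]) / max(n[i] - 1, 1)
        users_margin[ci] = Z95 * float(np.sqrt(vu)) if np.isfinite(vu) else np.nan
        # producer's variance (stratified; reference-column conditional)
        Pj = producers[i]
        if not np.isfinite(Pj) or col[i] <= 0:
            producers_margin[ci] = np.nan
            continue
        Nhat_j = col[i]
        term1 = (row[i] ** 2) * (1 - Pj) ** 2 * users[i] * (1 - users[i]) / max(
            n[i] - 1, 1
        )
        term2 = 0.0
        for m in range(k):
            if m == i:
                continue
            q = p[m, i] / W[m] if W[m] > 0 else 0.0
            term2 += W[m] ** 2 * q * (1 - q) / max(n[m] - 1, 1)
        v_prod = (term1 + Pj**2 * term2) / Nhat_j**2
        producers_margin[ci] = Z95 * float(np.sqrt(v_prod))
    return AccuracyReport(
        classes=matrix.classes,
        overall=overall,
        overall_margin=Z95 * float(np.sqrt(v_overall)),
        users={c: float(users[i]) for i, c in enumerate(matrix.classes)},
        users_margin=users_margin,
        producers={c: float(producers[i]) for i, c in enumerate(matrix.classes)},
        producers_margin=producers_margin,
    )


@dataclass
class AreaEstimate:
    classes: tuple[str, ...]
    proportions: dict[str, float]
    proportion_margins: dict[str, float]
    areas: dict[str, float] | None
    area_margins: dict[str, float] | None


def estimate_area(matrix: AreaErrorMatrix) -> AreaEstimate:
    """Sample-adjusted class areas from reference-column proportions.

    Class k's adjusted proportion is the k-th column sum; its standard
    error is the stratified estimator
    ``sqrt(sum_i W_i^2 q_ik (1 - q_ik) / (n_i - 1))`` with
    ``q_ik = p_ik / W_i``; areas scale by the total mapped area and always
    sum to it exactly.
    """
    p = matrix.proportions
    W = matrix.weights
    n = matrix.n.astype(float)
    col = p.sum(axis=0)
    se = np.zeros_like(col)
    for kk in range(len(matrix.classes)):
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(W > 0, p[:, kk] / W, 0.0)
        se[kk] = np.sqrt(
            np.sum(W**2 * q * (1 - q) / np.maximum(n - 1, 1))
        )
    props = {c: float(col[i]) for i, c in enumerate(matrix.classes)}
    margins = {c: Z95 * float(se[i]) for i, c in enumerate(matrix.classes)}
    areas = margins_a = None
    if matrix.area_total is not None:
        areas = {c: v * matrix.area_total for c, v in props.items()}
        margins_a = {c: v * matrix.area_total for c, v in margins.items()}
    return AreaEstimate(matrix.classes, props, margins, areas, margins_a)


@dataclass
class BiasAdjustment:
    """Ratio correction of segmented field size/count statistics."""

    size_ratio: float
    count_ratio: float
    adjusted_mean_size: float
    adjusted_count: float


def adjust_field_stats(
    map_mean_size: float,
    map_count: float,
    digitized_mean_size: float,
    segmented_mean_size: float,
    digitized_count: float,
    segmented_count: float,
) -> BiasAdjustment:
    """Correct map-wide field statistics with validation-site ratios.

    ``r_size = digitized / segmented`` mean size at validation cells;
    adjusted map size = raw x r_size (count analogous).
    """
    if segmented_mean_size <= 0 or segmented_count <= 0:
        raise ValueError("segmented validation statistics must be positive")
    r_size = digitized_mean_size / segmented_mean_size
    r_count = digitized_count / segmented_count
    return BiasAdjustment(
        size_ratio=r_size,
        count_ratio=r_count,
        adjusted_mean_size=map_mean_size * r_size,
        adjusted_count=map_count * r_count,
    )


def collapse_reference_labels(points: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Collapse four-level reference labels to their binary parents.

    "unsure but likely X" becomes X; returns the collapsed table and the
    unsure fraction (reported as metadata, not used in the matrix)."""
    out = points.copy()
    unsure = out["ref_class"].str.startswith("unsure")
    out.loc[unsure, "ref_class"] = (
        out.loc[unsure, "ref_class"]
        .str.replace("unsure but likely ", "", regex=False)
        .str.strip()
    )
    return out, (float(unsure.mean()) if len(out) else 0.0)
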