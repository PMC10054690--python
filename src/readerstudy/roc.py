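"""Per-observer ROC analysis with diagonal group averaging.

Each observer's ordinal confidence scores (0 = no annotation, 1-5 =
confidence) are compared against the slice-level reference standard by
sweeping the decision rule "call positive if score >= t" over the distinct
scores the observer actually used, so the number of operating points depends
on how many confidence levels that observer used.  AUC is the trapezoidal
area, identical to the tie-corrected Mann-Whitney statistic.

Group curves are formed by diagonal averaging: each member curve is
intersected with the family of lines tpr = b - fpr (perpendicular to the
chance diagonal), and the intersection points are averaged across readers at
each offset b.  Group AUC uncertainty uses a two-way bootstrap that
resamples readers and cases jointly, with a normal z-test for group
differences; this targets the same reader-and-case variability as
U-statistic MRMC estimators while remaining assumption-light.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .study_data import ReferenceStandard, ScoreMatrix

__all__ = [
    "ROCCurve",
    "GroupAUCSummary",
    "AUCComparison",
    "roc_curve",
    "auc",
    "diagonal_average",
    "group_auc_summary",
    "compare_group_auc",
    "operating_point",
]

#: number of uniformly spaced offsets in [0, 2] for diagonal averaging
DEFAULT_GRID_SIZE = 201


@dataclass(frozen=True)
class ROCCurve:
    """A monotone piecewise-linear ROC curve with its trapezoidal AUC."""

    points: np.ndarray  # (n, 2) array of (fpr, tpr), from (0,0) to (1,1)
    auc: float
    observer_id: str | None = None
    n_thresholds: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("curve needs at least the two endpoint vertices")
        if not (np.allclose(pts[0], (0.0, 0.0)) and np.allclose(pts[-1], (1.0, 1.0))):
            raise ValueError("curve must start at (0,0) and end at (1,1)")
        if (np.diff(pts, axis=0) < -1e-12).any():
            raise ValueError("fpr and tpr must be non-decreasing along the curve")

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class GroupAUCSummary:
    """Diagonally averaged group AUC with a two-way bootstrap CI."""

    group: str
    mean_auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class AUCComparison:
    """z-test for the difference in diagonally averaged AUC between groups."""

    group_a: str
    group_b: str
    delta: float  # mean AUC(A) - mean AUC(B)
    z: float
    p_value: float
    n_boot: int
    seed: int


def _scores_and_truth(
    scores, reference: ReferenceStandard | Sequence[bool] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Align a per-slice score vector with the reference truth."""
    if isinstance(reference, ReferenceStandard):
        if isinstance(scores, pd.Series):
            scores = scores.reindex(reference.slice_labels.index)
            if scores.isna().any():
                raise ValueError("scores missing for some reference slices")
        truth = reference.slice_labels.to_numpy()
    else:
        truth = np.asarray(reference).astype(bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != truth.shape or s.ndim != 1:
        raise ValueError("scores and reference must be aligned 1-D vectors")
    if not truth.any() or truth.all():
        raise ValueError(
            "reference standard must contain at least one positive and one "
            "negative slice"
        )
    return s, truth


def roc_curve(
    scores,
    reference: ReferenceStandard | Sequence[bool] | np.ndarray,
    observer_id: str | None = None,
) -> ROCCurve:
    """ROC curve for one observer's ordinal scores against the reference.

    One operating point per distinct score value t (decision rule: positive
    iff score >= t), ordered by decreasing threshold, preceded by (0,0) (the
    rule that calls nothing positive).  The lowest threshold calls every
    slice positive, so the curve always ends at (1,1).
    """
    s, truth = _scores_and_truth(scores, reference)
    thresholds = np.unique(s)[::-1]  # decreasing
    n_pos = truth.sum()
    n_neg = (~truth).sum()
    pts = [(0.0, 0.0)]
    for t in thresholds:
        called = s >= t
        pts.append(
            (
                float((called & ~truth).sum()) / n_neg,
                float((called & truth).sum()) / n_pos,
            )
        )
    curve_auc = float(np.trapezoid([p[1] for p in pts], [p[0] for p in pts]))
    return ROCCurve(
        points=np.asarray(pts),
        auc=curve_auc,
        observer_id=observer_id,
        n_thresholds=len(thresholds) + 1,
    )


def auc(scores, reference: ReferenceStandard | Sequence[bool] | np.ndarray) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann-Whitney probability that a random positive slice scores
    higher than a random negative one, with ties counted 1/2.
    """
    return roc_curve(scores, reference).auc


def _offsets(curve: ROCCurve) -> np.ndarray:
    """Curve vertices parameterized by offset b = fpr + tpr (monotone in b)."""
    return curve.fpr + curve.tpr


def _intersect(curve: ROCCurve, grid: np.ndarray) -> np.ndarray:
    """Intersection points of a curve with the lines tpr = b - fpr, b in grid.

    Along a monotone ROC curve the offset b = fpr + tpr increases from 0 to
    2, so the intersection with each perpendicular line is unique and linear
    interpolation on the vertex parameterization solves it exactly.
    """
    b = _offsets(curve)
    # guard against repeated offsets from zero-length segments
    keep = np.concatenate([[True], np.diff(b) > 1e-15])
    b = b[keep]
    fpr = np.interp(grid, b, curve.fpr[keep])
    tpr = np.interp(grid, b, curve.tpr[keep])
    return np.column_stack([fpr, tpr])


def diagonal_average(
    curves: Sequence[ROCCurve], grid_size: int = DEFAULT_GRID_SIZE
) -> ROCCurve:
    """Average ROC curves along lines perpendicular to the chance diagonal.

    For each offset b on a grid over [0, 2] the line tpr = b - fpr cuts each
    member curve in exactly one point; those points are averaged across
    curves.  The grid is the union of ``grid_size`` uniform offsets and
    every input curve's own vertex offsets, so averaging identical curves
    reproduces them exactly and the endpoints (0,0) and (1,1) are preserved.
    """
    if not curves:
        raise ValueError("need at least one curve to average")
    grid = np.linspace(0.0, 2.0, grid_size)
    vertex_offsets = np.concatenate([_offsets(c) for c in curves])
    grid = np.unique(np.concatenate([grid, vertex_offsets]))
    pts = np.mean([_intersect(c, grid) for c in curves], axis=0)
    return ROCCurve(
        points=pts,
        auc=float(np.trapezoid(pts[:, 1], pts[:, 0])),
        n_thresholds=len(grid),
    )


def _group_curves(
    scores: pd.DataFrame, truth: np.ndarray
) -> list[ROCCurve]:
    return [
        roc_curve(scores[col].to_numpy(), truth, observer_id=str(col))
        for col in scores.columns
    ]


def _as_frame(scores: ScoreMatrix | pd.DataFrame) -> pd.DataFrame:
    return scores.scores if isinstance(scores, ScoreMatrix) else scores


def _aligned_truth(
    scores: pd.DataFrame, reference: ReferenceStandard | Sequence[bool] | np.ndarray
) -> np.ndarray:
    if isinstance(reference, ReferenceStandard):
        truth = reference.slice_labels.reindex(scores.index)
        if truth.isna().any():
            raise ValueError("reference standard missing labels for some slices")
        return truth.to_numpy().astype(bool)
    truth = np.asarray(reference).astype(bool)
    if truth.shape[0] != scores.shape[0]:
        raise ValueError("reference length does not match score matrix")
    return truth


def _stratified_case_resample(
    rng: np.random.Generator, truth: np.ndarray
) -> np.ndarray:
    """Resample slice indices with replacement within each truth stratum.

    Keeps at least one positive and one negative slice in every bootstrap
    resample, so ROC curves stay well defined.
    """
    pos = np.flatnonzero(truth)
    neg = np.flatnonzero(~truth)
    idx = np.concatenate(
        [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
    )
    return idx


def _mean_group_auc(values: np.ndarray, truth: np.ndarray) -> float:
    """Diagonally averaged AUC for a score matrix (columns = readers)."""
    curves = [
        roc_curve(values[:, j], truth) for j in range(values.shape[1])
    ]
    return diagonal_average(curves).auc


def group_auc_summary(
    scores: ScoreMatrix | pd.DataFrame,
    reference: ReferenceStandard | Sequence[bool] | np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    group: str = "group",
) -> GroupAUCSummary:
    """Diagonally averaged group AUC with a two-way bootstrap CI.

    The point estimate is the AUC of the diagonal average of the members'
    ROC curves.  The CI resamples readers (columns) and slices (rows,
    stratified by reference label) jointly in each bootstrap replicate and
    takes percentile endpoints.  Deterministic given ``seed``.
    """
    frame = _as_frame(scores)
    if frame.shape[1] < 2:
        raise ValueError("a group AUC summary needs at least 2 observers")
    truth = _aligned_truth(frame, reference)
    values = frame.to_numpy(dtype=float)
    point = _mean_group_auc(values, truth)
    rng = np.random.default_rng(seed)
    m = values.shape[1]
    stats = np.empty(n_boot)
    for i in range(n_boot):
        readers = rng.integers(0, m, size=m)
        idx = _stratified_case_resample(rng, truth)
        stats[i] = _mean_group_auc(values[np.ix_(idx, readers)], truth[idx])
    lo, hi = np.quantile(stats, [0.025, 0.975])
    return GroupAUCSummary(
        group=group,
        mean_auc=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
    )


def compare_group_auc(
    scores_a: ScoreMatrix | pd.DataFrame,
    scores_b: ScoreMatrix | pd.DataFrame,
    reference: ReferenceStandard | Sequence[bool] | np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    group_a: str = "A",
    group_b: str = "B",
) -> AUCComparison:
    """z-test for the difference in diagonally averaged AUC between groups.

    The bootstrap standard error of the difference resamples slices once per
    replicate (shared between groups, stratified by truth — the cases are
    common to both reader groups) and readers independently within each
    group.  z = delta / SE with a two-sided normal p-value.  When the
    bootstrap distribution is degenerate (e.g., a group compared with
    itself) the difference carries no evidence and p = 1.
    """
    frame_a, frame_b = _as_frame(scores_a), _as_frame(scores_b)
    if frame_a.shape[1] < 2 or frame_b.shape[1] < 2:
        raise ValueError("each group needs at least 2 observers")
    if not frame_a.index.equals(frame_b.index):
        raise ValueError("both groups must rate the same slices")
    truth = _aligned_truth(frame_a, reference)
    va = frame_a.to_numpy(dtype=float)
    vb = frame_b.to_numpy(dtype=float)
    delta = _mean_group_auc(va, truth) - _mean_group_auc(vb, truth)
    rng = np.random.default_rng(seed)
    ma, mb = va.shape[1], vb.shape[1]
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = _stratified_case_resample(rng, truth)
        ra = rng.integers(0, ma, size=ma)
        rb = rng.integers(0, mb, size=mb)
        diffs[i] = _mean_group_auc(va[np.ix_(idx, ra)], truth[idx]) - _mean_group_auc(
            vb[np.ix_(idx, rb)], truth[idx]
        )
    se = float(np.std(diffs, ddof=1))
    if se < 1e-12:
        z = 0.0 if abs(delta) < 1e-12 else float(np.sign(delta)) * np.inf
    else:
        z = delta / se
    p = 1.0 if z == 0.0 else float(2.0 * norm.sf(abs(z)))
    return AUCComparison(
        group_a=group_a,
        group_b=group_b,
        delta=float(delta),
        z=float(z),
        p_value=max(p, np.finfo(float).tiny),
        n_boot=n_boot,
        seed=seed,
    )


def operating_point(
    curve: ROCCurve, target_sensitivity: float, interpolate: bool = False
) -> tuple[float, float]:
    """(sensitivity, specificity) pair meeting a target sensitivity.

    Without interpolation, returns the curve vertex with the smallest
    sensitivity >= target (ties broken toward the smaller false-positive
    rate).  With ``interpolate=True``, walks along the piecewise-linear
    curve to the exact point where sensitivity reaches the target.
    """
    if not 0.0 <= target_sensitivity <= 1.0:
        raise ValueError(f"target sensitivity must be in [0, 1], got {target_sensitivity}")
    fpr, tpr = curve.fpr, curve.tpr
    if interpolate:
        # tpr is non-decreasing along the curve; invert by interpolation.
        # np.interp needs strictly usable x; collapse flat tpr runs keeping
        # the leftmost (smallest fpr) point of each run.
        keep = np.concatenate([[True], np.diff(tpr) > 1e-15])
        f = float(np.interp(target_sensitivity, tpr[keep], fpr[keep]))
        return (target_sensitivity, 1.0 - f)
    meets = np.flatnonzero(tpr >= target_sensitivity - 1e-12)
    candidates = meets[tpr[meets] <= tpr[meets].min() + 1e-12]
    best = candidates[np.argmin(fpr[candidates])]
    return (float(tpr[best]), 1.0 - float(fpr[best]))
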