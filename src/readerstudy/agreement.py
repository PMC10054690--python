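"""Inter- and intra-observer agreement statistics with resampling inference.

Implements the agreement machinery of a multi-reader slice-level study:

* Fleiss' kappa — chance-corrected agreement among a fixed panel of raters,
  with chance agreement from pooled category proportions (Fleiss 1971);
* Cohen's kappa — chance-corrected agreement between two readings of the
  same slices, with chance from the two marginal distributions;
* unanimity percentage agreement — the percentage of slices on which every
  rater in a group gives the same diagnosis;
* percentile bootstrap confidence intervals (resampling slices, observers
  fixed) and permutation tests (re-partitioning observers into groups).

Kappa can be undefined when expected chance agreement is 1 (e.g., every cell
a single category); this is raised as :class:`UndefinedKappaError` rather
than returned as NaN, and such resamples are dropped (and counted) during
bootstrap/permutation inference, since the estimand is conditional on the
statistic being defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .study_data import LabelMatrix

__all__ = [
    "UndefinedKappaError",
    "AgreementEstimate",
    "GroupComparison",
    "fleiss_kappa",
    "cohen_kappa",
    "pct_agreement",
    "kappa_interpretation",
    "bootstrap_ci",
    "permutation_test",
]

DEFAULT_N_BOOT = 2000
DEFAULT_N_PERM = 10_000
DEFAULT_CI_LEVEL = 0.95

#: float slack when comparing permuted against observed statistics, so that
#: exact ties (e.g. identical groups, delta 0) count as at-least-as-extreme
_TIE_EPS = 1e-12


class UndefinedKappaError(ValueError):
    """Kappa is undefined because expected chance agreement equals 1."""


@dataclass(frozen=True)
class AgreementEstimate:
    """A point estimate of an agreement metric with a bootstrap CI."""

    metric: str
    value: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    seed: int
    n_dropped: int = 0  # resamples on which the metric was undefined


@dataclass(frozen=True)
class GroupComparison:
    """A permutation test of an agreement metric between two observer groups."""

    metric: str
    group_a: str
    group_b: str
    delta: float  # metric(A) - metric(B)
    p_value: float
    n_perm: int
    seed: int
    n_dropped: int = 0


def _as_bool_matrix(labels: LabelMatrix | np.ndarray) -> np.ndarray:
    if isinstance(labels, LabelMatrix):
        return labels.values()
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError("label matrix must be 2-dimensional (slices x observers)")
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError("label matrix must be binary")
    return arr.astype(bool)


def fleiss_kappa(labels: LabelMatrix | np.ndarray) -> float:
    """Fleiss' multi-rater kappa for binary slice-level diagnoses.

    With m raters and per-slice positive counts k_i, observed agreement is
    the mean over slices of P_i = (k_i^2 + (m-k_i)^2 - m) / (m(m-1)), and
    chance agreement is p^2 + q^2 with p the pooled positive proportion.
    kappa = (P_bar - P_e) / (1 - P_e).

    Raises :class:`UndefinedKappaError` when P_e = 1 (all cells one
    category), where the statistic has no value.
    """
    arr = _as_bool_matrix(labels)
    n, m = arr.shape
    if m < 2:
        raise ValueError(f"Fleiss' kappa needs at least 2 observers, got {m}")
    if n < 2:
        raise ValueError(f"Fleiss' kappa needs at least 2 slices, got {n}")
    k = arr.sum(axis=1)  # positive votes per slice
    p_bar = float(np.mean((k**2 + (m - k) ** 2 - m) / (m * (m - 1))))
    p = float(k.sum()) / (n * m)
    p_e = p**2 + (1.0 - p) ** 2
    if 1.0 - p_e < _TIE_EPS:
        raise UndefinedKappaError(
            "all ratings fall in a single category; chance agreement is 1"
        )
    return (p_bar - p_e) / (1.0 - p_e)


def cohen_kappa(
    labels_a: Sequence[bool] | np.ndarray, labels_b: Sequence[bool] | np.ndarray
) -> float:
    """Cohen's kappa between two binary readings of the same slices.

    Chance agreement comes from the product of the two readings' marginal
    distributions.  Raises :class:`UndefinedKappaError` when the marginals
    make chance agreement 1 (both readings constant and identical).
    """
    a = np.asarray(labels_a).astype(bool)
    b = np.asarray(labels_b).astype(bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("the two readings must be 1-D and of equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    p_o = float(np.mean(a == b))
    pa, pb = float(a.mean()), float(b.mean())
    p_e = pa * pb + (1.0 - pa) * (1.0 - pb)
    if 1.0 - p_e < _TIE_EPS:
        raise UndefinedKappaError(
            "both readings constant with identical marginals; chance agreement is 1"
        )
    return (p_o - p_e) / (1.0 - p_e)


def pct_agreement(labels: LabelMatrix | np.ndarray) -> float:
    """Unanimity percentage agreement for a group of observers.

    The percentage of slices on which every observer in the group gives the
    same diagnosis (all positive or all negative); no reference standard is
    involved.  For two observers this coincides with simple pairwise
    percentage agreement.
    """
    arr = _as_bool_matrix(labels)
    n, m = arr.shape
    if m < 2:
        raise ValueError(f"percentage agreement needs at least 2 observers, got {m}")
    unanimous = (arr.all(axis=1) | (~arr).all(axis=1)).sum()
    return 100.0 * float(unanimous) / n


_KAPPA_BANDS = (
    # upper edge inclusive: boundary values belong to the lower band
    (0.0, "poor"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


def kappa_interpretation(kappa: float) -> str:
    """Qualitative band for a kappa value.

    Values at or below 0 are "poor"; values above 0, 0.2 and 0.4 are
    "slight", "fair" and "moderate"; the conventional Landis–Koch extension
    labels values above 0.6 and 0.8 "substantial" and "almost perfect".
    Boundary values fall in the lower band (kappa = 0.2 is "slight").
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper:
            return label
    return _KAPPA_BANDS[-1][1]  # pragma: no cover - kappa == 1 handled above


# ---------------------------------------------------------------------------
# Resampling inference
# ---------------------------------------------------------------------------

_METRICS: dict[str, Callable[[np.ndarray], float]] = {
    "fleiss_kappa": fleiss_kappa,
    "pct_agreement": pct_agreement,
    "cohen_kappa": lambda arr: cohen_kappa(arr[:, 0], arr[:, 1]),
}


def _resolve_metric(metric: str | Callable[[np.ndarray], float]):
    if callable(metric):
        return getattr(metric, "__name__", "custom"), metric
    try:
        return metric, _METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; expected one of {sorted(_METRICS)}"
        ) from None


def bootstrap_ci(
    metric: str | Callable[[np.ndarray], float],
    labels: LabelMatrix | np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: int = 0,
) -> AgreementEstimate:
    """Percentile bootstrap CI for an agreement metric, resampling slices.

    Slices (cases) are resampled with replacement while the observer panel
    stays fixed, matching a design where readers are a fixed panel and cases
    are the sampling unit.  For ``metric="cohen_kappa"`` the label matrix
    must have exactly two columns (the two readings).  Resamples on which
    kappa is undefined are dropped and counted; a warning is emitted if more
    than 1% are dropped.  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    name, fn = _resolve_metric(metric)
    arr = _as_bool_matrix(labels)
    if name == "cohen_kappa" and arr.shape[1] != 2:
        raise ValueError("cohen_kappa bootstrap expects a 2-column label matrix")
    value = fn(arr)  # propagates UndefinedKappaError on the observed data
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    stats: list[float] = []
    n_dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            stats.append(fn(arr[idx]))
        except UndefinedKappaError:
            n_dropped += 1
    if n_dropped > 0.01 * n_boot:
        warnings.warn(
            f"{n_dropped}/{n_boot} bootstrap resamples dropped "
            f"(undefined {name}); CI is conditional on the statistic being defined",
            stacklevel=2,
        )
    if not stats:
        raise UndefinedKappaError("metric undefined on every bootstrap resample")
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return AgreementEstimate(
        metric=name,
        value=float(value),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_boot=n_boot,
        seed=seed,
        n_dropped=n_dropped,
    )


def permutation_test(
    metric: str | Callable[[np.ndarray], float],
    labels_a: LabelMatrix | np.ndarray,
    labels_b: LabelMatrix | np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Two-sided permutation test for a metric difference between groups.

    The observed statistic is metric(A) - metric(B).  The null distribution
    re-partitions the pooled observers (columns) into groups of the original
    sizes, preserving the within-slice correlation structure; p is the
    add-one-corrected tail proportion (1 + #{|d*| >= |d|}) / (1 + n_perm),
    so the smallest attainable p is 1/(n_perm + 1).  Permutations on which
    the metric is undefined are dropped and counted.  Deterministic given
    ``seed``.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    name, fn = _resolve_metric(metric)
    arr_a = _as_bool_matrix(labels_a)
    arr_b = _as_bool_matrix(labels_b)
    if arr_a.shape[0] != arr_b.shape[0]:
        raise ValueError("both groups must rate the same slices")
    m_a, m_b = arr_a.shape[1], arr_b.shape[1]
    if m_a < 2 or m_b < 2:
        raise ValueError("each group needs at least 2 observers")
    observed = fn(arr_a) - fn(arr_b)
    pooled = np.hstack([arr_a, arr_b])
    m = m_a + m_b
    rng = np.random.default_rng(seed)
    n_extreme = 0
    n_valid = 0
    n_dropped = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        try:
            delta = fn(pooled[:, perm[:m_a]]) - fn(pooled[:, perm[m_a:]])
        except UndefinedKappaError:
            n_dropped += 1
            continue
        n_valid += 1
        if abs(delta) >= abs(observed) - _TIE_EPS:
            n_extreme += 1
    if n_valid == 0:
        raise UndefinedKappaError("metric undefined on every permutation")
    p = (1.0 + n_extreme) / (1.0 + n_valid)
    return GroupComparison(
        metric=name,
        group_a=group_a,
        group_b=group_b,
        delta=float(observed),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        n_dropped=n_dropped,
    )
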