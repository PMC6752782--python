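"""Agreement statistics: percent exact agreement, Cohen's kappa,
one-way random-effects ICC(1,1), review-clustered bootstrap confidence
intervals, interpretation labels, and a contingency-table reconstruction
utility.

These statistics are implemented from scratch (they are the analytic
core of the package); established libraries are used only as
independent cross-checks in the test suite.

Conventions
-----------
Contingency tables are square arrays with instrument 1 (PEDro) on the
rows and instrument 2 (CROB) on the columns; for 2x2 tables the first
row/column is the positive category, so ``table[0, 0]`` counts trials
positive on both instruments and ``table[1, 1]`` trials negative on
both.  Statistics that are not calculable (no variation, empty table)
return ``nan`` rather than raising, mirroring the "not calculable"
entries that degenerate item tables produce in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_EPS = 1e-12


class InconsistentTableError(ValueError):
    """Raised when printed summary numbers imply an impossible table."""


class UndefinedReplicatesError(RuntimeError):
    """Raised when too many bootstrap replicates are not calculable."""

    def __init__(self, fraction: float):
        self.fraction = fraction
        super().__init__(
            f"statistic undefined in {fraction:.1%} of bootstrap replicates"
        )


# ---------------------------------------------------------------------------
# point estimates
# ---------------------------------------------------------------------------


def percent_exact_agreement(table) -> float:
    """100 * (diagonal mass) / n for a square contingency table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("table must be square")
    n = t.sum()
    if n <= 0:
        return float("nan")
    return 100.0 * float(np.trace(t)) / float(n)


def cohen_kappa(table) -> float:
    """Unweighted Cohen's kappa for a square contingency table.

    kappa = (P_o - P_e) / (1 - P_e) with P_o the observed diagonal
    proportion and P_e the chance agreement from the marginal products.
    Returns ``nan`` when P_e = 1 (all marginal mass in one category on
    both sides), where kappa is not calculable.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("table must be square")
    n = t.sum()
    if n <= 0:
        return float("nan")
    p = t / n
    po = float(np.trace(p))
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if 1.0 - pe < _EPS:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def batched_kappa(tables: np.ndarray) -> np.ndarray:
    """Vectorized Cohen's kappa over a stack of square tables (..., k, k)."""
    t = np.asarray(tables, dtype=float)
    n = t.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = t / n[..., None, None]
        po = np.trace(p, axis1=-2, axis2=-1)
        pe = np.einsum("...i,...i->...", p.sum(axis=-1), p.sum(axis=-2))
        out = (po - pe) / (1.0 - pe)
    out = np.where((n > 0) & (1.0 - pe >= _EPS), out, np.nan)
    return out


def batched_percent_agreement(tables: np.ndarray) -> np.ndarray:
    t = np.asarray(tables, dtype=float)
    n = t.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * np.trace(t, axis1=-2, axis2=-1) / n
    return np.where(n > 0, out, np.nan)


def kappa_variance(table) -> float:
    """Large-sample variance of Cohen's kappa (Fleiss, Cohen & Everitt).

    Used for the unclustered (normal-approximation) confidence
    intervals of the between-review reliability analysis.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    k = cohen_kappa(t)
    if n <= 1 or math.isnan(k):
        return float("nan")
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    term_a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - k)) ** 2
        for i in range(p.shape[0])
    )
    term_b = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if i != j:
                term_b += p[i, j] * (col[i] + row[j]) ** 2
    term_b *= (1.0 - k) ** 2
    term_c = (k - pe * (1.0 - k)) ** 2
    return (term_a + term_b - term_c) / (n * (1.0 - pe) ** 2)


def kappa_normal_ci(table, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for kappa (not cluster-adjusted)."""
    k = cohen_kappa(table)
    var = kappa_variance(table)
    if math.isnan(k) or math.isnan(var) or var < 0:
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return (k - half, min(k + half, 1.0))


def icc_oneway(scores1, scores2) -> float:
    """ICC(1,1): one-way random-effects intraclass correlation, k = 2.

    Subjects (trials) are random; the two measurements per subject are
    the two instruments' scores on a common scale.  With MSB/MSW the
    between/within-subject mean squares,

        ICC = (MSB - MSW) / (MSB + (k - 1) * MSW).

    Returns ``nan`` when the total variance is zero.
    """
    x = np.asarray(scores1, dtype=float)
    y = np.asarray(scores2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores must be two equal-length 1-d sequences")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    k = 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    subj_means = data.mean(axis=1)
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - subj_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom < _EPS:
        return float("nan")
    return float((msb - msw) / denom)


def icc_oneway_f_ci(scores1, scores2, level: float = 0.95) -> tuple[float, float]:
    """Exact F-distribution CI for ICC(1,1) (Shrout & Fleiss form)."""
    x = np.asarray(scores1, dtype=float)
    y = np.asarray(scores2, dtype=float)
    n, k = x.size, 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    subj_means = data.mean(axis=1)
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - subj_means[:, None]) ** 2) / (n * (k - 1))
    if msw < _EPS or msb < _EPS:
        return (float("nan"), float("nan"))
    f = msb / msw
    alpha = 1.0 - level
    df1, df2 = n - 1, n * (k - 1)
    fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    return ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))


# ---------------------------------------------------------------------------
# interpretation labels
# ---------------------------------------------------------------------------

#: Landis & Koch categories for kappa (closed printed ranges).
_KAPPA_LABELS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def interpret_label(value: float, scale: str = "kappa") -> str:
    """Map a kappa or ICC value to its conventional verbal category.

    Kappa uses the Landis & Koch bands (<0 poor, 0.00-0.20 slight,
    0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80 substantial,
    0.81-1.00 almost perfect); ICC uses the Fleiss bands (<0.40 poor,
    0.40-0.75 fair to good, >0.75 excellent).  Boundary values belong
    to the band in which they are conventionally printed.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "not calculable"
    if scale == "kappa":
        if value < 0.0:
            return "poor"
        for hi, label in _KAPPA_LABELS:
            if value <= hi + _EPS:
                return label
        return "almost perfect"
    if scale == "icc":
        if value < 0.40:
            return "poor"
        if value <= 0.75 + _EPS:
            return "fair to good"
        return "excellent"
    raise ValueError(f"unknown scale {scale!r}; expected 'kappa' or 'icc'")


# ---------------------------------------------------------------------------
# clustered bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootConfig:
    """Clustered-bootstrap settings: replicates, level, seed."""

    n_boot: int = 5000
    level: float = 0.95
    seed: int = 0


@dataclass(frozen=True)
class BootstrapCI:
    low: float
    high: float
    n_boot: int
    n_undefined: int = 0
    method: str = "cluster percentile"


def _percentile_interval(
    reps: np.ndarray, level: float, max_undefined: float
) -> BootstrapCI:
    n_boot = reps.size
    defined = reps[~np.isnan(reps)]
    frac_undef = 1.0 - defined.size / n_boot
    if frac_undef > max_undefined:
        raise UndefinedReplicatesError(frac_undef)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(defined, [alpha, 1.0 - alpha])
    return BootstrapCI(float(lo), float(hi), n_boot, n_boot - defined.size)


def cluster_bootstrap_ci(
    data: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    cluster: str,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    max_undefined: float = 0.5,
) -> BootstrapCI:
    """Percentile CI from a cluster (review-level) bootstrap.

    Whole clusters are resampled with replacement, the same number of
    clusters per replicate as in the original data, keeping every row
    of a sampled cluster (duplicated clusters count as distinct).  The
    statistic is evaluated on each replicate; replicates where it is
    ``nan`` are dropped and counted, and an error is raised if more
    than ``max_undefined`` of them are dropped.
    """
    groups = data.groupby(cluster, sort=True).indices
    ids = list(groups)
    n_clusters = len(ids)
    if n_clusters < 2:
        raise ValueError("cluster bootstrap requires at least 2 clusters")
    positions = [np.asarray(groups[c]) for c in ids]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_clusters, n_clusters)
        idx = np.concatenate([positions[i] for i in pick])
        reps[b] = statistic(data.take(idx))
    return _percentile_interval(reps, level, max_undefined)


def cluster_bootstrap_table_ci(
    cluster_tables: np.ndarray,
    statistic: str | Callable[[np.ndarray], np.ndarray] = "kappa",
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    max_undefined: float = 0.5,
) -> BootstrapCI:
    """Cluster bootstrap for statistics of a summed contingency table.

    ``cluster_tables`` has shape (n_clusters, k, k): one contingency
    table per cluster, summing to the pooled table.  Because kappa and
    percent agreement depend on the data only through the pooled table,
    resampling clusters reduces to summing resampled per-cluster
    tables, which is fully vectorized here.  Results are identical in
    distribution to :func:`cluster_bootstrap_ci` with the equivalent
    row-level statistic.
    """
    tables = np.asarray(cluster_tables, dtype=float)
    if tables.ndim != 3:
        raise ValueError("cluster_tables must have shape (n_clusters, k, k)")
    n_clusters = tables.shape[0]
    if n_clusters < 2:
        raise ValueError("cluster bootstrap requires at least 2 clusters")
    if statistic == "kappa":
        stat_fn = batched_kappa
    elif statistic == "percent_agreement":
        stat_fn = batched_percent_agreement
    else:
        stat_fn = statistic
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, n_clusters, size=(n_boot, n_clusters))
    summed = tables[idx].sum(axis=1)
    reps = np.asarray(stat_fn(summed), dtype=float)
    return _percentile_interval(reps, level, max_undefined)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementResult:
    """One item comparison: n, % exact agreement, kappa, CI, label."""

    n: int
    percent_agreement: float
    kappa: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    label: str = field(default="not calculable")
    ci_method: str = "cluster percentile"

    @property
    def calculable(self) -> bool:
        return not math.isnan(self.kappa)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "label": self.label,
            "ci_method": self.ci_method,
        }


@dataclass(frozen=True)
class IccResult:
    """Summary-score agreement: ICC(1,1), CI, Fleiss label."""

    n: int
    icc: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    label: str = field(default="not calculable")
    ci_method: str = "cluster percentile"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "label": self.label,
            "ci_method": self.ci_method,
        }


# ---------------------------------------------------------------------------
# table reconstruction from printed summaries
# ---------------------------------------------------------------------------


def reconstruct_two_by_two(
    n: int, percent_agreement: float, marginal1: int, marginal2: int
) -> np.ndarray:
    """Solve the 2x2 table implied by n, % agreement and the marginals.

    With A = round(n * percent / 100) trials on the diagonal, and m1,
    m2 the positive marginals of the two instruments, the cells are

        a = (A + m1 + m2 - n) / 2,  b = m1 - a,  c = m2 - a,  d = A - a.

    Because a printed percentage carries 1-decimal precision, A is
    allowed to shift by +/-1 to reach an integral, non-negative table;
    anything further is an inconsistency error.
    """
    a_target = int(math.floor(n * percent_agreement / 100.0 + 0.5))
    for diag in sorted({a_target, a_target - 1, a_target + 1},
                       key=lambda v: abs(v - a_target)):
        total = diag + marginal1 + marginal2 - n
        if total % 2 != 0:
            continue
        a = total // 2
        b = marginal1 - a
        c = marginal2 - a
        d = diag - a
        if min(a, b, c, d) >= 0:
            return np.array([[a, b], [c, d]], dtype=int)
    raise InconsistentTableError(
        f"no feasible 2x2 table for n={n}, agreement={percent_agreement}, "
        f"marginals=({marginal1}, {marginal2})"
    )


def make_result(
    table: np.ndarray,
    ci: BootstrapCI | tuple[float, float] | None = None,
    ci_method: str = "cluster percentile",
) -> AgreementResult:
    """Bundle a contingency table (+ optional CI) into an AgreementResult."""
    t = np.asarray(table)
    k = cohen_kappa(t)
    if isinstance(ci, BootstrapCI):
        lo, hi, method = ci.low, ci.high, ci.method
    elif ci is not None:
        lo, hi = ci
        method = ci_method
    else:
        lo = hi = float("nan")
        method = "none"
    return AgreementResult(
        n=int(t.sum()),
        percent_agreement=percent_exact_agreement(t),
        kappa=k,
        ci_low=lo,
        ci_high=hi,
        label=interpret_label(k, "kappa"),
        ci_method=method,
    )
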