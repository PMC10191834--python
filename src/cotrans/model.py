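"""Poisson/binomial co-expression model and the genomes-per-cell estimator.

A cell exposed to an equimolar mix of ``k`` reporter vectors receives, for
each color, an i.i.d. Poisson(lambda/k) number of expressed genomes.  A color
is *expressed* when at least one of its genomes expresses, so each color is an
independent Bernoulli trial with success probability ``p = 1 - exp(-lambda/k)``
and the number of distinct colors per cell is Binomial(k, p).  Inverting the
binomial mean of observed color counts gives the point estimator

    lambda_hat = -k * ln(1 - S / (k * N)),    S = sum_i i * r_i,

where ``r_i`` is the number of cells expressing exactly ``i`` distinct colors
and ``N = sum_i r_i``.  When every cell expresses all ``k`` colors the
estimator diverges; :func:`lambda_lower_bound` provides finite lower bounds
for that saturated regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ColorCountTable",
    "DoseSeries",
    "ExpressionModel",
    "LambdaEstimate",
    "SaturatedTableError",
    "bootstrap_ci",
    "color_count_pmf",
    "estimate_lambda",
    "expected_counts",
    "expression_probability",
    "lambda_lower_bound",
    "point_estimate",
]

#: Search bracket and tolerance for all bound-finding root searches.
_BRACKET = (1e-6, 200.0)
_XTOL = 1e-9


class SaturatedTableError(ValueError):
    """Raised when an operation that needs a finite estimate gets a saturated table."""


@dataclass(frozen=True)
class ColorCountTable:
    """Counts of cells expressing exactly 0..k distinct reporters."""

    counts: tuple[int, ...]
    label: str = ""
    dose: float | None = None

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(c < 0 for c in counts):
            raise ValueError("color-class counts must be non-negative")
        if np.any(np.asarray(self.counts, dtype=float) != np.asarray(counts, dtype=float)):
            raise ValueError("color-class counts must be integers")
        if len(counts) < 3:
            raise ValueError("need counts for classes 0..k with k >= 2")
        if self.dose is not None and not self.dose > 0:
            raise ValueError("dose must be strictly positive")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        """Number of reporters."""
        return len(self.counts) - 1

    @property
    def n_cells(self) -> int:
        return int(sum(self.counts))

    @property
    def expressed_color_total(self) -> int:
        """S = sum_i i * r_i, the total number of expressed colors over all cells."""
        return int(sum(i * r for i, r in enumerate(self.counts)))

    @property
    def saturated(self) -> bool:
        """True iff every counted cell expressed all k colors."""
        return self.n_cells > 0 and self.counts[-1] == self.n_cells


@dataclass(frozen=True)
class DoseSeries:
    """Ordered (dose, counts) pairs at strictly increasing positive doses."""

    entries: tuple[tuple[float, ColorCountTable], ...]

    def __post_init__(self) -> None:
        entries = tuple((float(d), t) for d, t in self.entries)
        doses = [d for d, _ in entries]
        if any(d <= 0 for d in doses):
            raise ValueError("doses must be strictly positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)


def expression_probability(lam: float, k: int = 3) -> float:
    """Probability that a given color is expressed in a cell.

    Per-color genome counts are Poisson(lam / k), so a color expresses with
    probability ``1 - exp(-lam / k)``.

    Parameters
    ----------
    lam
        Mean number of expressed genomes per cell, >= 0.
    k
        Number of colors in the mix, >= 2.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not math.isfinite(lam) or lam < 0:
        raise ValueError(f"lambda must be finite and >= 0, got {lam}")
    return -math.expm1(-lam / k)


@dataclass(frozen=True)
class ExpressionModel:
    """Forward model at a fixed lambda: per-color probability and class pmf."""

    lam: float
    k: int = 3

    def __post_init__(self) -> None:
        expression_probability(self.lam, self.k)  # validates

    @property
    def p(self) -> float:
        return expression_probability(self.lam, self.k)

    @property
    def class_probs(self) -> np.ndarray:
        return color_count_pmf(self)


def color_count_pmf(model: ExpressionModel) -> np.ndarray:
    """P(cell expresses exactly i of k colors), i = 0..k; Binomial(k, p).

    Computed directly (k is small); 1 - p = exp(-lam/k) is used exactly to
    avoid cancellation at small lambda.
    """
    k, p = model.k, model.p
    q = math.exp(-model.lam / k)
    return np.array([math.comb(k, i) * p**i * q ** (k - i) for i in range(k + 1)])


def expected_counts(model: ExpressionModel, n_cells: int) -> np.ndarray:
    """Expected real-valued class counts for ``n_cells`` cells."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    return n_cells * color_count_pmf(model)


@dataclass(frozen=True)
class LambdaEstimate:
    """Estimated genomes-per-cell with optional CI and saturation flag."""

    lambda_hat: float
    method: Literal["point", "lower_bound_binomial", "lower_bound_extrapolation"]
    saturated: bool = False
    ci_low: float | None = None
    ci_high: float | None = None
    alpha: float | None = None
    n_cells: int | None = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if math.isfinite(self.lambda_hat) and self.lambda_hat < 0:
            raise ValueError("finite lambda_hat must be >= 0")
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and math.isfinite(self.lambda_hat)
            and not (self.ci_low <= self.lambda_hat <= self.ci_high)
        ):
            raise ValueError("CI must bracket the point estimate")


def point_estimate(counts: Sequence[float]) -> float:
    """The raw estimator on a (possibly real-valued) class-count vector.

    Accepts expected counts as well as observed integers; returns ``inf``
    when the vector is saturated (S == k*N).
    """
    r = np.asarray(counts, dtype=float)
    if r.ndim != 1 or len(r) < 3:
        raise ValueError("need a vector of class counts for i = 0..k, k >= 2")
    if np.any(r < 0):
        raise ValueError("class counts must be non-negative")
    n = r.sum()
    if n <= 0:
        raise ValueError("empty table: N must be > 0")
    k = len(r) - 1
    s = r @ np.arange(k + 1)
    if s >= k * n:
        return math.inf
    return -k * math.log1p(-s / (k * n))


def estimate_lambda(counts: ColorCountTable | Sequence[int]) -> LambdaEstimate:
    """Point estimator ``-k * ln(1 - S / (k N))``.

    Returns a saturated (infinite) estimate when every cell expressed all k
    colors; callers should fall through to :func:`lambda_lower_bound` then.
    """
    table = counts if isinstance(counts, ColorCountTable) else ColorCountTable(tuple(counts))
    n = table.n_cells
    if n == 0:
        raise ValueError("empty table: N must be > 0")
    s = table.expressed_color_total
    k = table.k
    if s == k * n:
        return LambdaEstimate(math.inf, method="point", saturated=True, n_cells=n)
    lam = -k * math.log1p(-s / (k * n))
    return LambdaEstimate(lam, method="point", saturated=False, n_cells=n)


def bootstrap_ci(
    counts: ColorCountTable | Sequence[int],
    n_boot: int = 10_000,
    level: float = 0.95,
    *,
    seed: int,
) -> LambdaEstimate:
    """Percentile bootstrap CI from multinomial resampling of the N cells.

    Resamples that saturate (all cells in all-color class) have no finite
    point estimate; they are mapped to that resample's binomial lower bound
    at ``alpha = (1 - level) / 2`` and the saturation fraction is reported in
    ``extra["saturation_fraction"]``.
    """
    table = counts if isinstance(counts, ColorCountTable) else ColorCountTable(tuple(counts))
    if table.n_cells == 0:
        raise ValueError("empty table: N must be > 0")
    if table.saturated:
        raise SaturatedTableError(
            "saturated table has no finite point estimate; use lambda_lower_bound"
        )
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    n, k = table.n_cells, table.k
    point = estimate_lambda(table)
    rng = np.random.default_rng(seed)
    probs = np.asarray(table.counts, dtype=float) / n
    resamples = rng.multinomial(n, probs, size=n_boot)

    s = resamples @ np.arange(k + 1)
    sat = s == k * n
    lam = np.full(n_boot, np.nan)
    lam[~sat] = -k * np.log1p(-s[~sat] / (k * n))
    if sat.any():
        sat_table = ColorCountTable((0,) * k + (n,))
        lb = lambda_lower_bound(sat_table, alpha=(1 - level) / 2).lambda_hat
        lam[sat] = lb

    lo, hi = np.quantile(lam, [(1 - level) / 2, 1 - (1 - level) / 2])
    # percentile endpoints can land below/above the plug-in estimate's value
    lo = min(lo, point.lambda_hat)
    hi = max(hi, point.lambda_hat)
    return LambdaEstimate(
        point.lambda_hat,
        method="point",
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=1 - level,
        n_cells=n,
        extra={"saturation_fraction": float(sat.mean()), "n_boot": n_boot},
    )


def _all_color_prob(lam: float, k: int) -> float:
    """P(cell expresses all k colors) = p^k."""
    return expression_probability(lam, k) ** k


def _binomial_lower_bound(table: ColorCountTable, alpha: float) -> float:
    n, k = table.n_cells, table.k
    m = n - table.counts[-1]  # cells NOT expressing all k colors
    if m == n:
        raise ValueError("no all-color cells: lower bound undefined")

    def tail(lam: float) -> float:
        # f(lam) = 1 - p^k is the per-cell miss probability, decreasing in lam,
        # so the CDF below is increasing in lam.
        f = 1.0 - _all_color_prob(lam, k)
        return stats.binom.cdf(m, n, f) - alpha

    lo, hi = _BRACKET
    if tail(lo) > 0 or tail(hi) < 0:
        raise ValueError(
            f"lower bound root not bracketed in {_BRACKET}; alpha={alpha} incompatible with data"
        )
    return float(optimize.brentq(tail, lo, hi, xtol=_XTOL))


def _two_color_fraction(lam: float, k: int) -> float:
    p = expression_probability(lam, k)
    return math.comb(k, 2) * p**2 * (1 - p) ** (k - 2)


def _extrapolation_lower_bound(series: DoseSeries, target_dose: float, k: int) -> float:
    if len(series) < 2:
        raise ValueError("extrapolation needs at least 2 lower-dose tables")
    if target_dose <= 0:
        raise ValueError("target dose must be positive")
    log_d, log_f2 = [], []
    for dose, table in series.entries:
        if table.k != k:
            raise ValueError("all tables in the series must share k")
        f2 = table.counts[2] / table.n_cells
        if f2 <= 0:
            raise ValueError("two-color fraction must be positive at every fitted dose")
        log_d.append(math.log(dose))
        log_f2.append(math.log(f2))
    slope, intercept = np.polyfit(log_d, log_f2, 1)
    f2_pred = math.exp(intercept + slope * math.log(target_dose))

    # f2(p) is unimodal with its max at p = 2/k * ... for k=3 at p=2/3; take
    # the high-lambda branch p in (p_max, 1).
    p_max = 2 / k  # argmax of C(k,2) p^2 (1-p)^(k-2)
    f2_at_max = math.comb(k, 2) * p_max**2 * (1 - p_max) ** (k - 2)
    if not 0 < f2_pred < f2_at_max:
        raise ValueError(
            f"predicted two-color fraction {f2_pred:.4g} outside invertible range (0, {f2_at_max:.4g})"
        )

    def gap(lam: float) -> float:
        return _two_color_fraction(lam, k) - f2_pred

    lam_at_pmax = -k * math.log1p(-p_max)
    return float(optimize.brentq(gap, lam_at_pmax + 1e-9, _BRACKET[1], xtol=_XTOL))


def lambda_lower_bound(
    data: ColorCountTable | Sequence[int] | DoseSeries,
    alpha: float = 0.05,
    method: Literal["binomial", "extrapolation"] = "binomial",
    *,
    target_dose: float | None = None,
    k: int = 3,
) -> LambdaEstimate:
    """Finite lower bound on lambda for (near-)saturated samples.

    ``binomial``
        The largest lambda rejected at level ``alpha`` by the observed number
        of non-all-color cells: solves ``P(Binomial(N, 1 - p^k) <= m) = alpha``
        with ``m = N - r_k``.  For ``m = 0`` this reduces to
        ``(p^k)^N = alpha`` (rule-of-three style zero-event bound).
    ``extrapolation``
        Straight-line fit of log two-color fraction against log dose over the
        lower doses of a :class:`DoseSeries`, prediction at ``target_dose``,
        and inversion of the two-color class probability on its high-lambda
        branch.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method == "binomial":
        if isinstance(data, DoseSeries):
            raise TypeError("binomial method takes a single ColorCountTable")
        table = data if isinstance(data, ColorCountTable) else ColorCountTable(tuple(data))
        if table.n_cells == 0:
            raise ValueError("empty table: N must be > 0")
        lb = _binomial_lower_bound(table, alpha)
        return LambdaEstimate(
            lb,
            method="lower_bound_binomial",
            saturated=table.saturated,
            alpha=alpha,
            n_cells=table.n_cells,
        )
    if method == "extrapolation":
        if not isinstance(data, DoseSeries):
            raise TypeError("extrapolation method takes a DoseSeries")
        if target_dose is None:
            raise ValueError("extrapolation requires target_dose")
        lb = _extrapolation_lower_bound(data, target_dose, k)
        return LambdaEstimate(
            lb,
            method="lower_bound_extrapolation",
            saturated=True,
            alpha=alpha,
            extra={"target_dose": target_dose},
        )
    raise ValueError(f"unknown method {method!r}")
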