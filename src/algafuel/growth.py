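"""Batch-culture growth kinetics: specific growth rate and doubling time.

During balanced exponential growth the cell density obeys
``N(t) = N(t0) * exp(mu * (t - t0))``, so the specific growth rate between
two observations is ``mu = ln(N2/N1) / (t2 - t1)`` (per day) and the
doubling time ``k = ln 2 / mu`` (days).  A real batch curve also has a lag
phase and a stationary phase, so :func:`fit_exponential_phase` estimates mu
by least squares on ``ln N`` either inside a user-given time window or
inside an automatically chosen one: the contiguous run of at least four
observations whose log-linear fit maximises R^2, ties broken toward the
larger window and then the earlier start.  The window used is always
reported alongside the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, ValidationError

__all__ = [
    "GrowthCurve",
    "GrowthRateResult",
    "ConditionGrowthSummary",
    "specific_growth_rate",
    "doubling_time",
    "fit_exponential_phase",
    "summarize_condition",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthCurve:
    """A cell-density time series for one flask.

    ``observations`` is a sequence of ``(t days, N cells/mL)`` pairs with
    strictly increasing times and positive densities.
    """

    condition_label: str
    observations: tuple[tuple[float, float], ...]
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        obs = tuple((float(t), float(n)) for t, n in self.observations)
        object.__setattr__(self, "observations", obs)
        if len(obs) < 2:
            raise ValidationError("a growth curve needs at least 2 observations")
        times = [t for t, _ in obs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("observation times must be strictly increasing")
        if any(n <= 0 for _, n in obs):
            raise ValidationError("cell densities must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.observations])

    @property
    def densities(self) -> np.ndarray:
        return np.array([n for _, n in self.observations])


@dataclass(frozen=True)
class GrowthRateResult:
    """A fitted (mu, k) pair with the window that produced it.

    ``mu * k == ln 2`` exactly (k is derived from mu, never fitted
    separately).  ``fit_r2`` is 1.0 for a two-point fit.
    """

    condition_label: str
    replicate_id: str
    mu: float
    k: float
    window: tuple[float, float]
    fit_r2: float
    n_points: int


def specific_growth_rate(n1: float, n2: float, t1: float, t2: float) -> float:
    """Two-point specific growth rate ``ln(N2/N1)/(t2 - t1)`` in 1/day."""
    if n1 <= 0 or n2 <= 0:
        raise DomainError("cell counts must be positive")
    if t2 <= t1:
        raise DomainError(f"t2 must exceed t1, got t1={t1}, t2={t2}")
    return math.log(n2 / n1) / (t2 - t1)


def doubling_time(mu: float) -> float:
    """Doubling time ``ln 2 / mu`` in days; requires mu > 0."""
    if mu <= 0:
        raise DomainError(f"doubling time requires mu > 0, got {mu}")
    return LN2 / mu


def _loglinear_fit(t: np.ndarray, log_n: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of log density against time."""
    if len(t) == 2:
        slope = (log_n[1] - log_n[0]) / (t[1] - t[0])
        return slope, 1.0
    res = stats.linregress(t, log_n)
    return float(res.slope), float(res.rvalue**2)


def fit_exponential_phase(
    curve: GrowthCurve,
    window: tuple[float, float] | None = None,
    min_points: int = 4,
    noise_factor: float = 3.0,
) -> GrowthRateResult:
    """Estimate mu (and k) for one curve.

    With ``window=(t_start, t_end)``, regress ln N on t over the
    observations falling inside it (inclusive); two points reduce to the
    exact two-point formula.

    Without a window, the exponential phase is located automatically: every
    contiguous run of at least ``min_points`` observations is fitted, the
    counting-noise floor is estimated as the median residual mean square of
    the minimal windows, and windows whose residual mean square exceeds
    ``noise_factor`` times that floor are discarded — these are the fits
    reaching into the lag or stationary phase, which pick up systematic
    residuals.  Among the remaining (statistically clean) windows the one
    with the greatest fitted log-increase, slope times span, wins; ties go
    to the larger window and then the earlier start.  That criterion
    selects the longest stretch of genuine exponential rise: a clean window
    sitting on the stationary plateau has near-zero slope, and a short
    lucky sub-window a smaller span, so both lose to the full exponential
    phase.  (Ranking windows by raw R^2 does not work here: R^2 is not
    comparable across window sizes, and under noise a short, spuriously
    collinear window routinely outscores the true exponential stretch.)
    Curves shorter than ``min_points`` use all observations.

    k is reported as ``ln 2 / mu`` when mu > 0 and NaN otherwise (a
    non-growing culture has no doubling time).
    """
    t = curve.times
    log_n = np.log(curve.densities)

    if window is not None:
        t_start, t_end = window
        if t_end <= t_start:
            raise DomainError(f"degenerate window ({t_start}, {t_end})")
        mask = (t >= t_start) & (t <= t_end)
        if mask.sum() < 2:
            raise DomainError(
                f"window ({t_start}, {t_end}) contains fewer than 2 observations"
            )
        idx = np.flatnonzero(mask)
        best = (int(idx[0]), int(idx[-1]))
        slope, r2 = _loglinear_fit(t[idx], log_n[idx])
    else:
        n = len(t)
        size = min(min_points, n)
        candidates = []  # (rms, width, start, slope, r2)
        for width in range(size, n + 1):
            for start in range(0, n - width + 1):
                sl = slice(start, start + width)
                slope_w, r2_w = _loglinear_fit(t[sl], log_n[sl])
                resid = log_n[sl] - (
                    np.mean(log_n[sl]) + slope_w * (t[sl] - np.mean(t[sl]))
                )
                dof = max(width - 2, 1)
                candidates.append(
                    (float(np.sum(resid**2)) / dof, width, start, slope_w, r2_w)
                )
        noise_floor = float(
            np.median([c[0] for c in candidates if c[1] == size])
        )
        eligible = [
            c for c in candidates if c[0] <= noise_factor * noise_floor + 1e-12
        ]
        if not eligible:
            eligible = [min(candidates)]

        def log_increase(c):
            _, width_c, start_c, slope_c, _ = c
            span = t[start_c + width_c - 1] - t[start_c]
            return slope_c * span

        _, width, start, slope, r2 = max(
            eligible, key=lambda c: (log_increase(c), c[1], -c[2])
        )
        best = (start, start + width - 1)

    i0, i1 = best
    mu = float(slope)
    k = LN2 / mu if mu > 0 else math.nan
    return GrowthRateResult(
        condition_label=curve.condition_label,
        replicate_id=curve.replicate_id,
        mu=mu,
        k=k,
        window=(float(t[i0]), float(t[i1])),
        fit_r2=float(r2),
        n_points=i1 - i0 + 1,
    )


@dataclass(frozen=True)
class ConditionGrowthSummary:
    """Mean +/- sample SD of mu and k over the replicates of one condition.

    k is summarised from the per-replicate doubling times, not recomputed
    from the mean mu (the two differ because 1/mu is convex).  With a single
    replicate the SDs are reported as 0 and ``single_replicate`` is set.
    """

    condition_label: str
    n_replicates: int
    mu_mean: float
    mu_sd: float
    k_mean: float
    k_sd: float
    single_replicate: bool


def summarize_condition(results: Iterable[GrowthRateResult]) -> ConditionGrowthSummary:
    """Mean +/- SD (n-1 denominator) of mu and k across replicates."""
    results = list(results)
    if not results:
        raise DomainError("cannot summarise an empty collection of results")
    labels = {r.condition_label for r in results}
    if len(labels) > 1:
        raise ValidationError(f"mixed conditions in one summary: {sorted(labels)}")
    mus = np.array([r.mu for r in results])
    ks = np.array([r.k for r in results])
    single = len(results) == 1
    return ConditionGrowthSummary(
        condition_label=results[0].condition_label,
        n_replicates=len(results),
        mu_mean=float(np.mean(mus)),
        mu_sd=0.0 if single else float(np.std(mus, ddof=1)),
        k_mean=float(np.mean(ks)),
        k_sd=0.0 if single else float(np.std(ks, ddof=1)),
        single_replicate=single,
    )


def plot_growth_curves(curves: Sequence[GrowthCurve], path: str) -> None:
    """Save a simple semilog growth-curve figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.semilogy(
            curve.times, curve.densities, marker="o", markersize=3,
            label=f"{curve.condition_label} / {curve.replicate_id}",
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("cell density (cells/mL)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
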