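"""Chao richness estimation, sampling completeness, bootstrap CIs and rarefaction.

Chao's nonparametric estimator extrapolates asymptotic richness from the
counts of the rarest observed species: with abundance data, singletons and
doubletons (species seen once/twice); with incidence data, uniques and
duplicates (species in one/two sampling units). Checklist data are
presence/absence, so the incidence analogue over sampling units is the
default entry point; the formulas are identical in the two framings.

Completeness is observed / estimated richness. Confidence intervals use a
percentile bootstrap over sampling units (default 100 replicates at 95%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)


def chao_estimate(
    s_obs: int, q1: int, q2: int, variant: str = "classic"
) -> float:
    """Chao lower-bound richness estimate from rare-species counts.

    classic:        S_obs + q1^2 / (2 q2)          (falls back to the
                    bias-corrected form when q2 = 0)
    bias_corrected: S_obs + q1 (q1 - 1) / (2 (q2 + 1))
    """
    if min(s_obs, q1, q2) < 0:
        raise ValueError("counts must be non-negative")
    if q1 + q2 > s_obs:
        raise ValueError("q1 + q2 cannot exceed observed richness")
    if variant not in ("classic", "bias_corrected"):
        raise ValueError("variant must be 'classic' or 'bias_corrected'")
    if variant == "classic" and q2 > 0:
        return s_obs + q1**2 / (2 * q2)
    return s_obs + q1 * (q1 - 1) / (2 * (q2 + 1))


def completeness(s_obs: int, estimate: float) -> float:
    """Fraction of the estimated richness that was observed, in (0, 1]."""
    if estimate <= 0:
        raise ValueError("estimate must be positive")
    if s_obs <= 0:
        raise ValueError("observed richness must be positive")
    if estimate < s_obs:
        raise ValueError("estimate cannot be below observed richness")
    return s_obs / estimate


@dataclass
class RichnessEstimate:
    s_obs: int
    q1: int
    q2: int
    estimate: float
    completeness: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int | None = None
    level: float | None = None


def _incidence_counts(table: pd.DataFrame | np.ndarray) -> tuple[int, int, int, np.ndarray]:
    """(S_obs, Q1, Q2, per-species unit frequencies) from a units x species table."""
    arr = np.asarray(table, dtype=float) > 0
    freq = arr.sum(axis=0)
    freq = freq[freq > 0]
    return int(len(freq)), int((freq == 1).sum()), int((freq == 2).sum()), freq


def incidence_estimate(
    table: pd.DataFrame | np.ndarray,
    variant: str = "classic",
    n_bootstrap: int = 100,
    level: float = 0.95,
    seed: int | None = None,
) -> RichnessEstimate:
    """Chao estimate and completeness for a sampling-units x species table.

    Rows are sampling units (surveys, sub-sites); cells are presence counts
    or 0/1 incidences. The bootstrap resamples units with replacement.
    """
    s_obs, q1, q2, _ = _incidence_counts(table)
    if s_obs == 0:
        raise ValueError("no species observed")
    est = chao_estimate(s_obs, q1, q2, variant)
    comp = completeness(s_obs, est)
    ci_low = ci_high = None
    arr = np.asarray(table, dtype=float)
    if n_bootstrap and arr.shape[0] >= 2:
        def stat(resampled: np.ndarray) -> float:
            so, b1, b2, _ = _incidence_counts(resampled)
            return chao_estimate(so, b1, b2, variant) if so else 0.0

        ci_low, ci_high = bootstrap_ci(arr, stat, n_bootstrap, level, seed)
    return RichnessEstimate(
        s_obs, q1, q2, est, comp, ci_low, ci_high, n_bootstrap, level
    )


def bootstrap_ci(
    samples: np.ndarray | pd.DataFrame,
    statistic: Callable[[np.ndarray], float],
    n_bootstrap: int = 100,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of row-resampled data."""
    arr = np.asarray(samples)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 resampling units")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        reps[b] = statistic(arr[idx])
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def rarefaction_curve(
    incidence_by_sample: pd.DataFrame | np.ndarray,
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Expected species richness as a function of sampling effort.

    ``incidence_by_sample`` is a sampling-units x species table (rows are
    units). For effort t <= T (the observed number of units) the classic
    hypergeometric interpolation is used:

        S(t) = S_obs - sum_i C(T - Y_i, t) / C(T, t)

    with Y_i the number of units containing species i. Beyond T the
    Chao-based asymptotic extrapolation

        S(T + t*) = S_obs + Q0_hat [1 - (1 - Q1 / (Q1 + T Q0_hat))^t*]

    is used, capped at 2T with a warning. Returns a DataFrame with columns
    ``effort`` and ``richness``; the curve is non-decreasing.
    """
    arr = np.asarray(incidence_by_sample, dtype=float) > 0
    t_total = arr.shape[0]
    if t_total < 1:
        raise ValueError("need at least one sampling unit")
    s_obs, q1, q2, freq = _incidence_counts(arr)
    if grid is None:
        grid = list(range(1, 2 * t_total + 1))
    grid = [float(g) for g in grid]
    if any(g <= 0 for g in grid):
        raise ValueError("effort levels must be positive")
    if any(g > 2 * t_total for g in grid):
        warnings.warn("extrapolation beyond 2T is unreliable; capping at 2T")
        grid = [min(g, 2.0 * t_total) for g in grid]

    # Chao2-style estimate of the number of undetected species
    if q2 > 0:
        q0_hat = (t_total - 1) / t_total * q1**2 / (2 * q2)
    else:
        q0_hat = (t_total - 1) / t_total * q1 * (q1 - 1) / 2

    def interp(t: float) -> float:
        # C(T - Y_i, t) / C(T, t) via log-gammas; zero when T - Y_i < t
        t = int(round(t))
        keep = (t_total - freq) >= t
        if not keep.any():
            return float(s_obs)
        f = freq[keep]
        logratio = (
            gammaln(t_total - f + 1)
            - gammaln(t_total - f - t + 1)
            - gammaln(t_total + 1)
            + gammaln(t_total - t + 1)
        )
        return float(s_obs - np.exp(logratio).sum())

    def extrap(t: float) -> float:
        t_star = t - t_total
        if q0_hat == 0 or q1 == 0:
            return float(s_obs)
        return float(
            s_obs + q0_hat * (1.0 - (1.0 - q1 / (q1 + t_total * q0_hat)) ** t_star)
        )

    rich = [interp(g) if g <= t_total else extrap(g) for g in grid]
    return pd.DataFrame({"effort": grid, "richness": rich})


def completeness_report(
    tables: dict[str, pd.DataFrame | np.ndarray],
    variant: str = "classic",
    n_bootstrap: int = 100,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group (e.g. per-area) Chao/completeness summary table."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for (label, table), child in zip(tables.items(), ss.spawn(len(tables))):
        est = incidence_estimate(
            table,
            variant=variant,
            n_bootstrap=n_bootstrap,
            level=level,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        row = {"group": label}
        row.update(vars(est))
        rows.append(row)
    return pd.DataFrame(rows)
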