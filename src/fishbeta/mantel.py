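"""Permutation Mantel tests between dissimilarity and geographical-driver matrices.

The statistic is the Pearson or Spearman correlation between the
upper-triangle entries of two distance matrices over the same areas. The
null distribution is built by applying a common random row/column
permutation to the second matrix and recomputing the statistic; p-values
use the add-one correction p = (k + 1) / (n_perm + 1) so they are never
zero. Spearman uses midrank ties. The default tail is two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .beta_partition import DissimilarityMatrix

TAILS = ("greater", "less", "two_sided")
METHODS = ("spearman", "pearson")


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str
    tail: str
    seed: int | None


def driver_to_matrix(
    values: Mapping[str, float] | Sequence[float],
    labels: Sequence[str] | None = None,
) -> DissimilarityMatrix:
    """Pairwise absolute differences of a per-area scalar driver.

    Distance matrices measured directly (e.g. waterway distances) should be
    wrapped in :class:`DissimilarityMatrix` and passed to
    :func:`mantel_test` as-is.
    """
    if isinstance(values, Mapping):
        labels = list(values.keys())
        vec = np.array([values[k] for k in labels], dtype=float)
    else:
        vec = np.asarray(values, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(len(vec))]
    if not np.isfinite(vec).all():
        raise ValueError("driver values must be finite")
    mat = np.abs(vec[:, None] - vec[None, :])
    if np.ptp(vec) == 0:
        import logging

        logging.getLogger(__name__).warning(
            "constant driver vector gives a zero matrix; Mantel is undefined against it"
        )
    return DissimilarityMatrix(list(labels), mat, index="driver")


def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined: constant off-diagonal values")
    return float((x * y).sum() / denom)


def _as_matrix(d) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(d, DissimilarityMatrix):
        return d.values, d.labels
    arr = np.asarray(d, dtype=float)
    return arr, None


def mantel_test(
    d1,
    d2,
    method: str = "spearman",
    tail: str = "two_sided",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """Permutation test of matrix association.

    ``d1`` and ``d2`` are DissimilarityMatrix objects (labels must match in
    order) or plain square arrays of identical shape, with at least 3 rows.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    m1, l1 = _as_matrix(d1)
    m2, l2 = _as_matrix(d2)
    if m1.shape != m2.shape:
        raise ValueError("matrices differ in size")
    if l1 is not None and l2 is not None and l1 != l2:
        raise ValueError("matrix labels differ or are ordered differently")
    n = m1.shape[0]
    if n < 3:
        raise ValueError("need at least 3 areas")

    x = _tri(m1)
    r_obs = _corr(x, _tri(m2), method)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = _corr(x, _tri(m2[np.ix_(perm, perm)]), method)
        if tail == "greater":
            hit = r_perm >= r_obs - 1e-12
        elif tail == "less":
            hit = r_perm <= r_obs + 1e-12
        else:
            hit = abs(r_perm) >= abs(r_obs) - 1e-12
        exceed += hit
    p = (exceed + 1) / (n_permutations + 1)
    return MantelResult(r_obs, float(p), n_permutations, method, tail, seed)


def mantel_grid(
    beta: Mapping[str, Mapping[str, DissimilarityMatrix]],
    drivers: Mapping[str, DissimilarityMatrix],
    method: str = "spearman",
    tail: str = "two_sided",
    n_permutations: int = 9999,
    seed: int | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Mantel r and p for each beta index x period x driver combination.

    ``beta`` maps period -> index -> matrix. Each cell uses a distinct
    child seed spawned deterministically from ``seed``; the seed used is
    recorded in the output. ``holm`` adds Holm-adjusted p-values across all
    cells.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    cells = [
        (period, idx, drv)
        for period in beta
        for idx in beta[period]
        for drv in drivers
    ]
    children = ss.spawn(len(cells))
    import logging

    log = logging.getLogger(__name__)
    for (period, idx, drv), child in zip(cells, children):
        cell_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            res = mantel_test(
                beta[period][idx],
                drivers[drv],
                method=method,
                tail=tail,
                n_permutations=n_permutations,
                seed=cell_seed,
            )
            r, p = res.r, res.p
        except ValueError as exc:
            # e.g. a constant dissimilarity matrix (all areas nested identically)
            log.warning("mantel %s/%s vs %s undefined: %s", period, idx, drv, exc)
            r = p = float("nan")
        rows.append(
            {
                "period": period,
                "beta_index": idx,
                "driver": drv,
                "r": r,
                "p": p,
                "n_permutations": n_permutations,
                "seed": cell_seed,
            }
        )
    df = pd.DataFrame(rows)
    if holm and len(df):
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, pos in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[pos])
            adj[pos] = min(1.0, running)
        df["p_holm"] = adj
    return df
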