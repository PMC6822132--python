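"""Pairwise Sørensen dissimilarity and its turnover/nestedness partition.

For two assemblages with ``a`` shared species and ``b``, ``c`` species
unique to each side, total compositional dissimilarity is the Sørensen
index

    beta_sor = (b + c) / (2a + b + c)

which Baselga's partition splits into a richness-insensitive spatial
turnover component (the Simpson dissimilarity)

    beta_sim = min(b, c) / (a + min(b, c))

and a nestedness-resultant component

    beta_sne = |b - c| / (2a + b + c) * a / (a + min(b, c))

so that beta_sor = beta_sim + beta_sne holds exactly. The absolute value
in beta_sne makes the component symmetric and non-negative; the raw signed
difference would break both symmetry and the additive identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .occurrence_io import IncidenceMatrix, SpeciesAttributes

logger = logging.getLogger(__name__)

INDICES = ("sor", "sim", "sne")


class DegeneratePairWarning(UserWarning):
    """One assemblage of a pair is empty; the partition uses its limit values."""


@dataclass(frozen=True)
class PairComponents:
    """Shared (a) and side-unique (b, c) species counts for one area pair."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("components must be non-negative")


def pair_components(x: np.ndarray, y: np.ndarray) -> PairComponents:
    """Component counts from two presence vectors over the same species axis."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("presence vectors have mismatched species axes")
    return PairComponents(
        a=int(np.sum(x & y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
    )


def _check_nonempty_pair(p: PairComponents) -> None:
    if p.a + p.b + p.c == 0:
        raise ValueError("dissimilarity undefined for two empty assemblages")


def _one_side_empty(p: PairComponents) -> bool:
    return p.a == 0 and min(p.b, p.c) == 0 and max(p.b, p.c) > 0


def sorensen(p: PairComponents) -> float:
    """Total Sørensen dissimilarity: 0 for identical sets, 1 for disjoint."""
    _check_nonempty_pair(p)
    return (p.b + p.c) / (2 * p.a + p.b + p.c)


def simpson_turnover(p: PairComponents) -> float:
    """Spatial turnover (Simpson dissimilarity); 0 for nested pairs.

    A pair where one assemblage is empty is treated as the limit of a
    vanishing subset: pure nestedness, so turnover 0 (with a warning).
    """
    _check_nonempty_pair(p)
    if _one_side_empty(p):
        warnings.warn(
            "one assemblage empty: turnover defined as 0 (pure nestedness)",
            DegeneratePairWarning,
            stacklevel=2,
        )
        return 0.0
    return min(p.b, p.c) / (p.a + min(p.b, p.c))


def nestedness_component(p: PairComponents) -> float:
    """Nestedness-resultant dissimilarity; equals beta_sor minus beta_sim."""
    _check_nonempty_pair(p)
    if _one_side_empty(p):
        warnings.warn(
            "one assemblage empty: nestedness equals total dissimilarity",
            DegeneratePairWarning,
            stacklevel=2,
        )
        return sorensen(p)
    return (abs(p.b - p.c) / (2 * p.a + p.b + p.c)) * (p.a / (p.a + min(p.b, p.c)))


_SCALARS = {"sor": sorensen, "sim": simpson_turnover, "sne": nestedness_component}


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity among areas for one index and period."""

    labels: list[str]
    values: np.ndarray
    index: str
    period: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major pair order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def pair_value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def pairwise_matrix(m: IncidenceMatrix, index: str) -> DissimilarityMatrix:
    """Evaluate one dissimilarity index over all unordered area pairs."""
    if index not in INDICES:
        raise ValueError(f"index must be one of {INDICES}")
    scalar = _SCALARS[index]
    pres = m.data.to_numpy(dtype=bool)
    n = pres.shape[0]
    if n < 2:
        raise ValueError("need at least 2 areas")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                val = scalar(pair_components(pres[i], pres[j]))
            except ValueError as exc:
                raise ValueError(
                    f"pair ({m.areas[i]}, {m.areas[j]}): {exc}"
                ) from exc
            out[i, j] = out[j, i] = val
    return DissimilarityMatrix(m.areas, out, index, m.period)


def beta_matrices(m: IncidenceMatrix) -> dict[str, DissimilarityMatrix]:
    """All three matrices (sor, sim, sne) for one incidence matrix."""
    return {idx: pairwise_matrix(m, idx) for idx in INDICES}


@dataclass
class GroupBetaSummary:
    """Mean and sample SD of each index over a group of area pairs."""

    group: str
    n_pairs: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def formatted(self, index: str, digits: int = 2) -> str:
        m, s = self.mean[index], self.sd[index]
        if np.isnan(s):
            return f"{m:.{digits}f}"
        return f"{m:.{digits}f} ± {s:.{digits}f}"


def _summarize(group: str, rows: dict[str, np.ndarray]) -> GroupBetaSummary:
    n = len(next(iter(rows.values())))
    means = {k: float(np.mean(v)) for k, v in rows.items()}
    sds = {k: float(np.std(v, ddof=1)) if n > 1 else float("nan") for k, v in rows.items()}
    return GroupBetaSummary(group, n, means, sds)


def area_focal_summary(
    matrices: Mapping[str, DissimilarityMatrix],
    grand_mean: bool = True,
) -> list[GroupBetaSummary]:
    """Per-area mean ± SD over the pairs involving each area.

    The optional grand-mean row is the unweighted mean of per-area means
    (each pair contributes to two areas, so this is not the all-pairs mean).
    """
    labels = matrices["sor"].labels
    out: list[GroupBetaSummary] = []
    for i, area in enumerate(labels):
        rows = {}
        for idx, dm in matrices.items():
            vals = np.delete(dm.values[i], i)
            rows[idx] = vals
        out.append(_summarize(area, rows))
    if grand_mean and out:
        rows = {
            idx: np.array([s.mean[idx] for s in out]) for idx in matrices
        }
        out.append(_summarize("Mean", rows))
    return out


def subset_summary(
    m: IncidenceMatrix,
    subsets: Mapping[str, Sequence[str]],
) -> list[GroupBetaSummary]:
    """Recompute the pairwise partition on species subsets and summarize.

    ``subsets`` maps a group label (a family, natives-only, ...) to the
    species list defining it. Groups whose subset yields no defined pair
    (e.g. species absent from every area) are omitted with a warning.
    """
    out: list[GroupBetaSummary] = []
    for label, species in subsets.items():
        sub = m.subset_species(species)
        occupied = sub.data.to_numpy().sum(axis=1) > 0
        if occupied.sum() < 2:
            logger.warning("subset %r has <2 occupied areas; omitted", label)
            continue
        keep = [a for a, occ in zip(sub.areas, occupied) if occ]
        sub = IncidenceMatrix(sub.data.loc[keep], sub.period)
        rows = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegeneratePairWarning)
            for idx in INDICES:
                rows[idx] = pairwise_matrix(sub, idx).condensed()
        out.append(_summarize(label, rows))
    return out


def origin_and_family_subsets(
    m: IncidenceMatrix, attrs: SpeciesAttributes
) -> dict[str, list[str]]:
    """Standard subset spec: all species, natives, exotics, each family."""
    species = m.species
    subsets: dict[str, list[str]] = {
        "All species": list(species),
        "Native species": sorted(attrs.natives(species)),
        "Introduced exotic species": sorted(attrs.introduced(species)),
    }
    fams = attrs.table.loc[attrs.table.index.isin(species), "family"].dropna()
    for fam in sorted(fams.unique()):
        subsets[fam] = sorted(attrs.family_members(fam) & set(species))
    return subsets


def summary_frame(summaries: Sequence[GroupBetaSummary]) -> pd.DataFrame:
    """Tabular report with numeric columns and 'mean ± SD' strings."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"group": s.group, "n_pairs": s.n_pairs}
        for idx in INDICES:
            row[f"beta_{idx}_mean"] = s.mean[idx]
            row[f"beta_{idx}_sd"] = s.sd[idx]
            row[f"beta_{idx}"] = s.formatted(idx)
        rows.append(row)
    return pd.DataFrame(rows)
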