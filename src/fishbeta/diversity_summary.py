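"""Alpha/gamma richness and extirpation, introduction and ecotype-loss accounting.

Percentages are printed to one decimal using round-half-up (the convention
that reproduces published basin summary tables from their integer counts),
applied through the single :func:`round1` helper so every report rounds the
same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .occurrence_io import ECOTYPE_AXES, RED_LIST, IncidenceMatrix, SpeciesAttributes

logger = logging.getLogger(__name__)


def round1(x: float) -> float:
    """Round half-up to one decimal place."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def alpha_richness(m: IncidenceMatrix) -> pd.Series:
    """Species richness per area (row sums of the incidence matrix)."""
    return m.data.sum(axis=1).astype(int)


def gamma_richness(m: IncidenceMatrix) -> int:
    """Total richness: number of species present in at least one area."""
    if not m.species:
        return 0
    return int((m.data.sum(axis=0) > 0).sum())


@dataclass
class ExtirpationSummary:
    """Per-area native losses and exotic introductions between two periods."""

    area: str
    n_hist_native: int
    n_curr_native: int
    n_extirpated: int
    pct_extirpated: float | None
    n_introduced: int
    pct_introduced: float | None


def extirpation_summary(
    hist: IncidenceMatrix,
    curr: IncidenceMatrix,
    attrs: SpeciesAttributes,
    area: str,
) -> ExtirpationSummary:
    """Count native losses and introductions in one area.

    A native species counts as extirpated from the area when present
    historically but absent currently. The introduction percentage is taken
    over the current total assemblage (current natives + introduced).
    """
    hist_nat = attrs.natives(hist.presence(area))
    curr_present = curr.presence(area)
    curr_nat = attrs.natives(curr_present)
    introduced = attrs.introduced(curr_present)
    colonists = curr_nat - hist_nat
    if colonists:
        logger.warning(
            "area %s: %d native species present currently but not historically",
            area,
            len(colonists),
        )
    n_ext = len(hist_nat - curr_nat)
    if hist_nat:
        pct_ext = round1(100 * n_ext / len(hist_nat))
    else:
        logger.warning("area %s has no historical natives; percentage undefined", area)
        pct_ext = None
    denom = len(curr_nat) + len(introduced)
    pct_intro = round1(100 * len(introduced) / denom) if denom else None
    return ExtirpationSummary(
        area=area,
        n_hist_native=len(hist_nat),
        n_curr_native=len(curr_nat),
        n_extirpated=n_ext,
        pct_extirpated=pct_ext,
        n_introduced=len(introduced),
        pct_introduced=pct_intro,
    )


def extirpation_table(
    hist: IncidenceMatrix,
    curr: IncidenceMatrix,
    attrs: SpeciesAttributes,
) -> pd.DataFrame:
    """Per-area summary for every area, in incidence row order."""
    rows = [
        vars(extirpation_summary(hist, curr, attrs, area)) for area in hist.areas
    ]
    return pd.DataFrame(rows)


def mean_extirpation_pct(summaries: Sequence[ExtirpationSummary]) -> float:
    """Unweighted mean of per-area extirpation percentages, rounded once."""
    vals = [s.pct_extirpated for s in summaries if s.pct_extirpated is not None]
    if not vals:
        raise ValueError("no summaries with a defined extirpation percentage")
    return round1(float(np.mean(vals)))


def ecotype_loss(
    hist: IncidenceMatrix,
    curr: IncidenceMatrix,
    attrs: SpeciesAttributes,
    axis: str,
) -> pd.DataFrame:
    """Basin-wide loss per ecotype category on one axis.

    A species counts as extirpated only if present somewhere historically
    and absent from every area currently. Species without a category on the
    axis are excluded (logged). Categories with no classified historical
    species are omitted.
    """
    if axis not in ECOTYPE_AXES:
        raise ValueError(f"axis must be one of {ECOTYPE_AXES}")
    hist_species = {s for s in hist.species if (hist.data[s] > 0).any()}
    curr_species = {s for s in curr.species if s in curr.data.columns and (curr.data[s] > 0).any()}
    classified = {
        s: attrs.category(s, axis)
        for s in hist_species
    }
    unknown = [s for s, cat in classified.items() if pd.isna(cat)]
    if unknown:
        logger.info("%d species lack a %s category and are excluded", len(unknown), axis)
    rows = []
    cats = sorted({cat for cat in classified.values() if pd.notna(cat)})
    if not cats:
        raise ValueError(f"no species classified on axis {axis!r}")
    for cat in cats:
        members = {s for s, c in classified.items() if c == cat}
        lost = {s for s in members if s not in curr_species}
        rows.append(
            {
                "axis": axis,
                "category": cat,
                "n_historical": len(members),
                "n_extirpated": len(lost),
                "pct_extirpated": round1(100 * len(lost) / len(members)),
            }
        )
    return pd.DataFrame(rows)


def redlist_tally(attrs: SpeciesAttributes, species_set: Sequence[str]) -> dict[str, int]:
    """Count species per red-list class; classes absent from the set report 0."""
    counts = dict.fromkeys(RED_LIST, 0)
    for s in species_set:
        cls = attrs.red_list_class(s)
        if pd.notna(cls):
            counts[cls] += 1
    return counts
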