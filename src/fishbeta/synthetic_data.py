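"""Synthetic two-period metacommunities with tunable nestedness/turnover structure.

The generator emulates a basin-scale checklist study: a regional species
pool distributed over a handful of areas along a one-dimensional waterway
axis, surveyed in a historical and a current period. Spatial structure in
the historical period mixes two mechanisms per species:

* **nested** (probability ``1 - turnover_weight``): the species occupies
  every area whose richness-gradient value exceeds a uniform draw, so
  ranges are prefixes of the areas ranked by the gradient and poorer
  assemblages are perfect subsets of richer ones;
* **turnover** (probability ``turnover_weight``): the species occupies a
  contiguous window of areas centred on a uniform position along the
  waterway axis, so composition is replaced along the axis.

The current period deletes each native species wholesale with a
probability determined by its ecological-type categories (trait-dependent
extirpation), optionally thins surviving occurrences per area, and adds a
few introduced exotic species in 1-3 random areas. Geographical drivers
(waterway distance, drainage area, annual runoff) come along for Mantel
testing. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .beta_partition import DissimilarityMatrix
from .occurrence_io import IncidenceMatrix, SpeciesAttributes

#: Default six basin units, ordered as in the study region's summary tables.
DEFAULT_AREAS = (
    "Poyang Lake",
    "Ganjiang River",
    "Fuhe River",
    "Xinjiang River",
    "Raohe River",
    "Xiuhe River",
)

# Expected historical richness fractions of the pool per area; with the
# default pool of 212 these span roughly 83-181 species across the six areas.
DEFAULT_GRADIENT = (0.717, 0.854, 0.599, 0.651, 0.401, 0.392)

# Waterway-axis coordinates (km along the main stem); the two richest units
# sit centrally, the tributary headwaters at the ends.
DEFAULT_POSITIONS = (250.0, 150.0, 350.0, 450.0, 600.0, 0.0)

# Per-area drainage area (km^2) and annual average runoff (1e8 m^3):
# realistic magnitudes for a large subtropical lake basin.
DEFAULT_DRAINAGE = (162000.0, 82800.0, 16500.0, 17600.0, 15300.0, 14700.0)
DEFAULT_RUNOFF = (1500.0, 686.0, 129.0, 181.0, 123.0, 126.0)

# Basin-wide extirpation probabilities by life habit: migratory species are
# the most exposed (dams cut river-lake migration routes), mountain-stream
# specialists intermediate, residents least.
DEFAULT_EXTIRPATION = {
    "migration": 0.367,
    "mountain_stream": 0.325,
    "settlement": 0.158,
}

_FAMILIES = (
    ("Cypriniformes", "Cyprinidae", 0.45),
    ("Cypriniformes", "Cobitidae", 0.08),
    ("Cypriniformes", "Homalopteridae", 0.04),
    ("Siluriformes", "Bagridae", 0.08),
    ("Siluriformes", "Siluridae", 0.04),
    ("Siluriformes", "Sisoridae", 0.03),
    ("Perciformes", "Gobiidae", 0.07),
    ("Perciformes", "Serranidae", 0.05),
    ("Perciformes", "Eleotridae", 0.03),
    ("Perciformes", "Channidae", 0.03),
    ("Clupeiformes", "Engraulidae", 0.03),
    ("Anguilliformes", "Anguillidae", 0.02),
    ("Osmeriformes", "Salangidae", 0.03),
    ("Beloniformes", "Hemiramphidae", 0.02),
)

_LIFE_HABIT_P = {"settlement": 0.62, "migration": 0.23, "mountain_stream": 0.15}
_FEEDING_P = {"carnivorous": 0.40, "omnivorous": 0.40, "herbivorous": 0.20}
_WATER_LAYER_P = {"demersal": 0.45, "lower": 0.35, "upper": 0.20}
_RED_LIST_P = {"LC": 0.65, "NT": 0.05, "VU": 0.05, "EN": 0.02, "CR": 0.04, "DD": 0.09, "NE": 0.10}


@dataclass
class SyntheticConfig:
    """Generator knobs; the defaults describe the reference study system."""

    n_areas: int = 6
    area_names: Sequence[str] = DEFAULT_AREAS
    pool_size: int = 212
    richness_gradient: Sequence[float] = DEFAULT_GRADIENT
    turnover_weight: float = 0.2
    turnover_window: float = 0.35  # window width as a fraction of the axis length
    extirpation_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXTIRPATION)
    )
    area_thinning: float = 0.0  # extra per-area occurrence loss in the current period
    n_introduced: int = 9
    area_positions: Sequence[float] = DEFAULT_POSITIONS
    drainage_area: Sequence[float] = DEFAULT_DRAINAGE
    annual_runoff: Sequence[float] = DEFAULT_RUNOFF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ValueError("need at least 2 areas")
        for name, seq in (
            ("area_names", self.area_names),
            ("richness_gradient", self.richness_gradient),
            ("area_positions", self.area_positions),
            ("drainage_area", self.drainage_area),
            ("annual_runoff", self.annual_runoff),
        ):
            if len(seq) != self.n_areas:
                raise ValueError(f"{name} must have length n_areas={self.n_areas}")
        if not all(0 < g <= 1 for g in self.richness_gradient):
            raise ValueError("richness_gradient fractions must lie in (0, 1]")
        if not 0 <= self.turnover_weight <= 1:
            raise ValueError("turnover_weight must lie in [0, 1]")
        if not 0 < self.turnover_window <= 1:
            raise ValueError("turnover_window must lie in (0, 1]")
        probs = list(self.extirpation_prob.values()) + [self.area_thinning]
        if not all(0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.pool_size < max(
            2, int(np.ceil(self.pool_size * max(self.richness_gradient)))
        ):
            raise ValueError("pool too small for the requested richness gradient")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("area_names", "richness_gradient", "area_positions",
                  "drainage_area", "annual_runoff"):
            d[k] = list(d[k])
        d["extirpation_prob"] = dict(d["extirpation_prob"])
        return d


@dataclass
class SyntheticTruth:
    """A generated dataset plus the ground truth behind it."""

    historical: IncidenceMatrix
    current: IncidenceMatrix
    attributes: SpeciesAttributes
    distance: DissimilarityMatrix
    drainage_area: pd.Series
    annual_runoff: pd.Series
    extirpated: dict[str, bool]
    config: SyntheticConfig


def _window_coverage(positions: np.ndarray, window: float) -> np.ndarray:
    """Probability that a uniform window centre covers each area."""
    lo, hi = float(positions.min()), float(positions.max())
    span = hi - lo
    if span == 0:
        return np.ones_like(positions)
    half = 0.5 * window * span
    left = np.maximum(positions - half, lo)
    right = np.minimum(positions + half, hi)
    return (right - left) / span


def _nested_occupancy(config: SyntheticConfig) -> np.ndarray:
    """Per-area occupancy thresholds for the nested mechanism.

    Calibrated so the *mixture* of mechanisms has expected per-area
    richness pool_size * richness_gradient: the turnover mechanism
    contributes its window-coverage probability, and the nested thresholds
    absorb the remainder (clipped into [0, 1]).
    """
    g = np.asarray(config.richness_gradient, dtype=float)
    w = config.turnover_weight
    if w >= 1.0:
        return g
    p_win = _window_coverage(np.asarray(config.area_positions, float), config.turnover_window)
    return np.clip((g - w * p_win) / (1.0 - w), 0.0, 1.0)


def _draw_categorical(rng: np.random.Generator, table: Mapping[str, float], size: int):
    keys = list(table)
    p = np.asarray([table[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=size, p=p)


def _species_extirpation_prob(
    attrs_row: pd.Series, prob_map: Mapping[str, float]
) -> float:
    """Combine category-specific risks: 1 - prod(1 - p) over matching categories."""
    keep = 1.0
    for axis in ("life_habit", "feeding", "water_layer"):
        cat = attrs_row[axis]
        if pd.notna(cat) and cat in prob_map:
            keep *= 1.0 - prob_map[cat]
    return 1.0 - keep


def generate_attributes(
    rng: np.random.Generator, names: Sequence[str], origin: str
) -> pd.DataFrame:
    orders, families, weights = zip(*_FAMILIES)
    w = np.asarray(weights) / sum(weights)
    fam_idx = rng.choice(len(families), size=len(names), p=w)
    return pd.DataFrame(
        {
            "species": list(names),
            "order": [orders[i] for i in fam_idx],
            "family": [families[i] for i in fam_idx],
            "origin": origin,
            "life_habit": _draw_categorical(rng, _LIFE_HABIT_P, len(names)),
            "feeding": _draw_categorical(rng, _FEEDING_P, len(names)),
            "water_layer": _draw_categorical(rng, _WATER_LAYER_P, len(names)),
            "red_list": _draw_categorical(rng, _RED_LIST_P, len(names)),
        }
    )


def generate_metacommunity(config: SyntheticConfig | None = None) -> SyntheticTruth:
    """Generate a full two-period dataset with known ground truth.

    Random draws happen in a fixed documented order (species attributes,
    then historical ranges, then extirpations, then introductions), so the
    output is bit-identical for a given config and seed.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    areas = list(config.area_names)
    positions = np.asarray(config.area_positions, dtype=float)
    n = config.n_areas

    native_names = [f"Species {i + 1:03d}" for i in range(config.pool_size)]
    attr_frames = [generate_attributes(rng, native_names, "native")]

    # --- historical ranges -------------------------------------------------
    occupancy = _nested_occupancy(config)
    lo, hi = float(positions.min()), float(positions.max())
    half_window = 0.5 * config.turnover_window * max(hi - lo, 1.0)
    hist = np.zeros((n, config.pool_size), dtype=np.int8)
    mech_turnover = rng.random(config.pool_size) < config.turnover_weight
    u_nested = rng.random(config.pool_size)
    centres = rng.uniform(lo, hi, size=config.pool_size)
    for s in range(config.pool_size):
        if mech_turnover[s]:
            inside = np.abs(positions - centres[s]) <= half_window
            if not inside.any():
                inside[np.argmin(np.abs(positions - centres[s]))] = True
            hist[:, s] = inside
        else:
            hist[:, s] = u_nested[s] < occupancy

    present_hist = hist.sum(axis=0) > 0
    # species the gradient never placed anywhere are dropped from the pool
    kept = [native_names[i] for i in range(config.pool_size) if present_hist[i]]
    hist = hist[:, present_hist]

    # --- current period: trait-dependent extirpation -----------------------
    attrs_df = attr_frames[0].set_index("species")
    ext_prob = np.array(
        [
            _species_extirpation_prob(attrs_df.loc[sp], config.extirpation_prob)
            for sp in kept
        ]
    )
    extirpate = rng.random(len(kept)) < ext_prob
    curr = hist.copy()
    curr[:, extirpate] = 0
    if config.area_thinning > 0:
        thin = rng.random(curr.shape) < config.area_thinning
        curr[thin & (curr == 1)] = 0
        # thinning may silently extirpate a species from every area
        extirpate = extirpate | (curr.sum(axis=0) == 0)

    # --- introduced exotics -------------------------------------------------
    intro_names = [f"Exotic {i + 1:02d}" for i in range(config.n_introduced)]
    intro = np.zeros((n, config.n_introduced), dtype=np.int8)
    for s in range(config.n_introduced):
        k = int(rng.integers(1, min(3, n) + 1))
        where = rng.choice(n, size=k, replace=False)
        intro[where, s] = 1
    if intro_names:
        attr_frames.append(generate_attributes(rng, intro_names, "introduced"))

    hist_df = pd.DataFrame(hist, index=pd.Index(areas, name="area"), columns=kept)
    hist_df = hist_df[sorted(hist_df.columns)]
    curr_cols = kept + intro_names
    curr_all = np.concatenate([curr, intro], axis=1) if intro_names else curr
    curr_df = pd.DataFrame(curr_all, index=pd.Index(areas, name="area"), columns=curr_cols)
    curr_df = curr_df.loc[:, curr_df.sum(axis=0) > 0]
    curr_df = curr_df[sorted(curr_df.columns)]

    attrs_table = pd.concat(attr_frames, ignore_index=True)
    attrs_table = attrs_table[attrs_table["species"].isin(set(kept) | set(intro_names))]
    attributes = SpeciesAttributes(attrs_table.reset_index(drop=True))

    distance, drainage, runoff = driver_data(config)
    return SyntheticTruth(
        historical=IncidenceMatrix(hist_df, "historical"),
        current=IncidenceMatrix(curr_df, "current"),
        attributes=attributes,
        distance=distance,
        drainage_area=drainage,
        annual_runoff=runoff,
        extirpated={sp: bool(flag) for sp, flag in zip(kept, extirpate)},
        config=config,
    )


def driver_data(
    config: SyntheticConfig,
) -> tuple[DissimilarityMatrix, pd.Series, pd.Series]:
    """Waterway distance matrix plus per-area drainage and runoff scalars."""
    positions = np.asarray(config.area_positions, dtype=float)
    if not np.isfinite(positions).all():
        raise ValueError("area positions must be finite")
    dist = np.abs(positions[:, None] - positions[None, :])
    labels = list(config.area_names)
    return (
        DissimilarityMatrix(labels, dist, index="waterway_distance"),
        pd.Series(config.drainage_area, index=labels, name="drainage_area"),
        pd.Series(config.annual_runoff, index=labels, name="annual_runoff"),
    )


def write_dataset(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in the same plain-text formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records = truth.historical.to_records() + truth.current.to_records()
    checklist = pd.DataFrame(
        [{"species": r.species, "area": r.area, "period": r.period} for r in records]
    )
    paths["checklist"] = outdir / "checklist.csv"
    checklist.to_csv(paths["checklist"], index=False)

    paths["attributes"] = outdir / "attributes.csv"
    truth.attributes.to_csv(paths["attributes"])

    paths["distance"] = outdir / "waterway_distance.csv"
    truth.distance.to_frame().to_csv(paths["distance"], index_label="area")

    paths["scalars"] = outdir / "area_drivers.csv"
    pd.DataFrame(
        {
            "drainage_area": truth.drainage_area,
            "annual_runoff": truth.annual_runoff,
        }
    ).to_csv(paths["scalars"], index_label="area")

    paths["config"] = outdir / "config.json"
    paths["config"].write_text(json.dumps(truth.config.to_dict(), indent=1))
    return paths
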