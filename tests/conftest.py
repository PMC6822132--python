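import numpy as np
import pandas as pd
import pytest

from fishbeta.occurrence_io import (
    ChecklistRecord,
    IncidenceMatrix,
    SpeciesAttributes,
    build_incidence,
)

# Published per-area counts for the six-basin reference system: historical
# natives, current natives (a subset), and established introduced exotics.
TABLE1_COUNTS = {
    "Poyang Lake": (152, 107, 4),
    "Ganjiang River": (181, 136, 8),
    "Fuhe River": (127, 57, 1),
    "Xinjiang River": (138, 52, 1),
    "Raohe River": (85, 45, 3),
    "Xiuhe River": (83, 77, 7),
}

TABLE1_PCT = {
    "Poyang Lake": (29.6, 3.6),
    "Ganjiang River": (24.9, 5.6),
    "Fuhe River": (55.1, 1.7),
    "Xinjiang River": (62.3, 1.9),
    "Raohe River": (47.1, 6.3),
    "Xiuhe River": (7.2, 8.3),
}


def build_two_period_dataset(counts=None):
    """Checklist-derived matrices whose per-area counts match ``counts``.

    Each area gets its own native species; the current natives are a subset
    of the historical ones, and introduced exotics appear only currently.
    """
    counts = counts or TABLE1_COUNTS
    records, attr_rows = [], []
    for ai, (area, (n_hist, n_curr, n_intro)) in enumerate(counts.items()):
        for k in range(n_hist):
            name = f"Native {ai:02d} {k:03d}"
            records.append(ChecklistRecord(name, area, "historical"))
            if k < n_curr:
                records.append(ChecklistRecord(name, area, "current"))
            attr_rows.append({"species": name, "origin": "native"})
        for k in range(n_intro):
            name = f"Exotic {ai:02d} {k:02d}"
            records.append(ChecklistRecord(name, area, "current"))
            attr_rows.append({"species": name, "origin": "introduced"})
    areas = list(counts)
    hist = build_incidence(records, "historical", areas)
    curr = build_incidence(records, "current", areas)
    attrs = SpeciesAttributes(pd.DataFrame(attr_rows))
    return hist, curr, attrs


@pytest.fixture(scope="session")
def table1_dataset():
    return build_two_period_dataset()


@pytest.fixture(scope="session")
def default_truth():
    from fishbeta.synthetic_data import SyntheticConfig, generate_metacommunity

    return generate_metacommunity(SyntheticConfig(seed=42))


def random_incidence(rng, n_areas=5, n_species=30, p=0.5, period="historical"):
    data = (rng.random((n_areas, n_species)) < p).astype(int)
    df = pd.DataFrame(
        data,
        index=[f"A{i}" for i in range(n_areas)],
        columns=[f"s{j:03d}" for j in range(n_species)],
    )
    # every area and the matrix itself must be non-empty for beta indices
    data[:, 0] = 1
    df.iloc[:, 0] = 1
    return IncidenceMatrix(df, period)
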