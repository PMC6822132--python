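import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishbeta.beta_partition import (
    DegeneratePairWarning,
    DissimilarityMatrix,
    PairComponents,
    area_focal_summary,
    beta_matrices,
    nestedness_component,
    pair_components,
    pairwise_matrix,
    simpson_turnover,
    sorensen,
    subset_summary,
    summary_frame,
)
from fishbeta.occurrence_io import IncidenceMatrix

from .conftest import random_incidence


def set_oracle(x, y):
    """Independent component counts via Python set arithmetic."""
    sx = {i for i, v in enumerate(x) if v}
    sy = {i for i, v in enumerate(y) if v}
    return len(sx & sy), len(sx - sy), len(sy - sx)


class TestPairComponents:
    def test_hand_example(self):
        x = [1, 1, 1, 0, 0]
        y = [0, 1, 1, 1, 1]
        p = pair_components(x, y)
        assert (p.a, p.b, p.c) == (2, 1, 2)

    def test_identical_sets(self):
        x = [1] * 7
        p = pair_components(x, x)
        assert (p.a, p.b, p.c) == (7, 0, 0)

    def test_matches_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            x = rng.random(40) < 0.5
            y = rng.random(40) < 0.5
            p = pair_components(x, y)
            assert (p.a, p.b, p.c) == set_oracle(x, y)

    def test_mismatched_axes_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            pair_components([1, 0], [1, 0, 1])


class TestScalarIndices:
    def test_hand_values(self):
        p = PairComponents(a=2, b=1, c=3)
        assert sorensen(p) == pytest.approx(0.5)
        assert simpson_turnover(p) == pytest.approx(1 / 3)
        assert nestedness_component(p) == pytest.approx(0.5 - 1 / 3)

    def test_endpoints(self):
        same = PairComponents(a=5, b=0, c=0)
        assert sorensen(same) == 0.0
        disjoint = PairComponents(a=0, b=2, c=3)
        assert sorensen(disjoint) == 1.0
        assert simpson_turnover(disjoint) == 1.0

    def test_nested_pair_has_zero_turnover(self):
        p = PairComponents(a=2, b=0, c=3)
        assert simpson_turnover(p) == 0.0
        assert nestedness_component(p) == pytest.approx(3 / 7)
        assert nestedness_component(p) == pytest.approx(sorensen(p))

    def test_balanced_uniques_have_zero_nestedness(self):
        p = PairComponents(a=3, b=4, c=4)
        assert nestedness_component(p) == 0.0

    def test_one_empty_assemblage_is_pure_nestedness(self):
        p = PairComponents(a=0, b=4, c=0)
        with pytest.warns(DegeneratePairWarning):
            assert simpson_turnover(p) == 0.0
        with pytest.warns(DegeneratePairWarning):
            assert nestedness_component(p) == 1.0
        assert sorensen(p) == 1.0

    def test_two_empty_assemblages_undefined(self):
        p = PairComponents(a=0, b=0, c=0)
        for fn in (sorensen, simpson_turnover, nestedness_component):
            with pytest.raises(ValueError, match="empty"):
                fn(p)

    @given(
        a=st.integers(0, 100),
        b=st.integers(0, 100),
        c=st.integers(0, 100),
    )
    @settings(max_examples=300, derandomize=True)
    def test_additive_identity_and_bounds(self, a, b, c):
        if a + b + c == 0:
            return
        p = PairComponents(a, b, c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegeneratePairWarning)
            s, t, n = sorensen(p), simpson_turnover(p), nestedness_component(p)
        assert abs(s - (t + n)) < 1e-12
        assert 0 <= t <= s <= 1
        if b * c == 0 and a > 0:
            assert n == pytest.approx(s)


class TestPairwiseMatrix:
    def nested_matrix(self):
        data = pd.DataFrame(
            [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0]],
            index=["A", "B", "C"],
            columns=list("wxyz"),
        )
        return IncidenceMatrix(data, "historical")

    def test_nested_areas_have_zero_turnover_everywhere(self):
        dm = pairwise_matrix(self.nested_matrix(), "sim")
        assert np.allclose(dm.values, 0.0)

    def test_sor_equals_sim_plus_sne_elementwise(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = random_incidence(rng, n_areas=4, n_species=25)
            mats = beta_matrices(m)
            assert np.allclose(
                mats["sor"].values,
                mats["sim"].values + mats["sne"].values,
                atol=1e-12,
            )

    def test_two_area_matrix_matches_scalars(self):
        data = pd.DataFrame(
            [[1, 1, 1, 0, 0], [0, 1, 1, 1, 1]], index=["A", "B"], columns=list("vwxyz")
        )
        m = IncidenceMatrix(data, "current")
        p = pair_components(data.loc["A"], data.loc["B"])
        assert pairwise_matrix(m, "sor").pair_value("A", "B") == pytest.approx(sorensen(p))

    def test_absent_species_do_not_affect_pairs(self):
        rng = np.random.default_rng(3)
        m = random_incidence(rng, n_areas=3, n_species=20)
        padded = IncidenceMatrix(
            m.data.assign(ghost1=0, ghost2=0)[sorted(m.species + ["ghost1", "ghost2"])],
            m.period,
        )
        for idx in ("sor", "sim", "sne"):
            assert np.allclose(
                pairwise_matrix(m, idx).values, pairwise_matrix(padded, idx).values
            )

    def test_relabeling_permutes_consistently(self):
        rng = np.random.default_rng(5)
        m = random_incidence(rng, n_areas=4, n_species=20)
        perm = [2, 0, 3, 1]
        m2 = IncidenceMatrix(m.data.iloc[perm], m.period)
        d1 = pairwise_matrix(m, "sor").values
        d2 = pairwise_matrix(m2, "sor").values
        assert np.allclose(d1[np.ix_(perm, perm)], d2)


class TestGroupSummary:
    def test_constant_matrix_gives_mean_v_sd_zero(self):
        v = 0.42
        n = 4
        vals = np.full((n, n), v)
        np.fill_diagonal(vals, 0.0)
        dm = DissimilarityMatrix([f"A{i}" for i in range(n)], vals, "sor")
        mats = {"sor": dm, "sim": dm, "sne": dm}
        for s in area_focal_summary(mats, grand_mean=False):
            assert s.mean["sor"] == pytest.approx(v)
            assert s.sd["sor"] == pytest.approx(0.0)

    def test_area_focal_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        m = random_incidence(rng, n_areas=4, n_species=30)
        mats = beta_matrices(m)
        out = area_focal_summary(mats, grand_mean=True)
        labels = mats["sor"].labels
        for i, area in enumerate(labels):
            pair_vals = [
                mats["sor"].pair_value(area, other) for other in labels if other != area
            ]
            assert out[i].mean["sor"] == pytest.approx(np.mean(pair_vals))
            assert out[i].sd["sor"] == pytest.approx(np.std(pair_vals, ddof=1))
        grand = out[-1]
        assert grand.group == "Mean"
        assert grand.mean["sor"] == pytest.approx(
            np.mean([s.mean["sor"] for s in out[:-1]])
        )

    def test_empty_subset_is_omitted(self, caplog):
        rng = np.random.default_rng(2)
        m = random_incidence(rng, n_areas=3, n_species=10)
        with caplog.at_level("WARNING"):
            out = subset_summary(m, {"ghosts": ["not a species"]})
        assert out == []
        assert any("omitted" in msg for msg in caplog.messages)

    def test_subset_recomputation_matches_direct(self):
        rng = np.random.default_rng(13)
        m = random_incidence(rng, n_areas=4, n_species=30)
        keep = m.species[:15]
        (summary,) = subset_summary(m, {"half": keep})
        direct = pairwise_matrix(m.subset_species(keep), "sor").condensed()
        assert summary.mean["sor"] == pytest.approx(direct.mean())

    def test_summary_frame_formats_mean_pm_sd(self):
        rng = np.random.default_rng(4)
        m = random_incidence(rng, n_areas=3, n_species=12)
        df = summary_frame(area_focal_summary(beta_matrices(m)))
        assert "beta_sor" in df.columns
        assert "±" in df["beta_sor"].iloc[0]
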