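"""q95 scaling, on/off gating, profile clustering, prevalence, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

import pathmotif as pm
from pathmotif.profiles import ScaledPathwayMatrix

from conftest import toy_state_matrix


def pathway(genes):
    padded = list(genes) + [f"pad{i}" for i in range(max(0, 7 - len(genes)))]
    return pm.PathwayDefinition("pw", padded)


def scaled_from(values, genes=None):
    m = toy_state_matrix(values, genes=genes)
    return pm.scale_pathway(m, pm.PathwayDefinition("pw", m.gene_names))


class TestPathwayDefinition:
    def test_fewer_than_7_genes_rejected(self):
        with pytest.raises(ValueError):
            pm.PathwayDefinition("small", ["a", "b", "c", "d", "e"])

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            pm.PathwayDefinition("dup", ["a"] * 7)

    def test_json_roundtrip(self, tmp_path):
        pw = pm.PathwayDefinition("tgfb", [f"r{i}" for i in range(11)],
                                  roles={"r0": "receptor"})
        pw.to_json(tmp_path / "pw.json")
        back = pm.PathwayDefinition.from_json(tmp_path / "pw.json")
        assert back.genes == pw.genes and back.roles == pw.roles


class TestScaling:
    def test_q95_linear_interpolation(self):
        """Column 0..100: q95 = 95, so 95 scales to 1 and 100 clips to 1."""
        col = np.arange(101.0)
        values = np.column_stack([col] * 7)
        p = scaled_from(values)
        assert p.scale_factors.iloc[0] == pytest.approx(95.0)
        assert p.values.iloc[95, 0] == pytest.approx(1.0)
        assert p.values.iloc[100, 0] == pytest.approx(1.0)  # clipped
        assert p.values.iloc[19, 0] == pytest.approx(19 / 95)

    def test_all_zero_gene_stays_zero(self):
        values = np.ones((10, 7))
        values[:, 3] = 0.0
        p = scaled_from(values)
        assert (p.values.iloc[:, 3] == 0).all()

    def test_constant_positive_gene_scales_to_one(self):
        p = scaled_from(np.full((10, 7), 4.2))
        assert (p.values.to_numpy() == 1.0).all()

    def test_missing_genes_reported_and_dropped(self):
        m = toy_state_matrix(np.ones((5, 7)))
        pw = pm.PathwayDefinition("pw", m.gene_names[:5] + ["absent1", "absent2"])
        p = pm.scale_pathway(m, pw)
        assert p.missing_genes == ["absent1", "absent2"]
        assert list(p.values.columns) == m.gene_names[:5]

    def test_idempotent_when_q95_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (200, 7))
        x[:20] = 1.0  # >5% of states at the max → q95 = 1 per gene
        p1 = scaled_from(x)
        m2 = toy_state_matrix(p1.values.to_numpy(), genes=list(p1.values.columns))
        p2 = pm.scale_pathway(m2, pm.PathwayDefinition("pw", list(p1.values.columns)))
        np.testing.assert_allclose(p2.values.to_numpy(), p1.values.to_numpy())


class TestOnMask:
    def test_two_genes_above_threshold_is_on(self):
        x = np.zeros((1, 7))
        x[0, :2] = [0.4, 0.35]
        p = ScaledPathwayMatrix(pd.DataFrame(x), pd.Series(1.0, index=range(7)),
                                pd.Series([True]))
        assert pm.pathway_on_mask(p).iloc[0]

    def test_single_strong_gene_is_off(self):
        x = np.zeros((1, 7))
        x[0, 0] = 0.9
        p = ScaledPathwayMatrix(pd.DataFrame(x), pd.Series(1.0, index=range(7)),
                                pd.Series([False]))
        assert not pm.pathway_on_mask(p).iloc[0]

    def test_everything_below_threshold_gives_empty_on_set(self):
        p = scaled_from(np.full((5, 7), 1.0) * np.linspace(0.1, 0.2, 5)[:, None])
        # q95 scaling rescales; recompute with explicit threshold on raw values
        mask = pm.pathway_on_mask(p, threshold=1.01)
        assert not mask.any()
        with pytest.raises(ValueError):
            pm.cluster_profiles(
                ScaledPathwayMatrix(p.values, p.scale_factors, mask), 2
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        x=arrays(float, (6, 7), elements=st.floats(0, 1)),
        dt=st.floats(0, 0.5),
        dg=st.integers(0, 3),
    )
    def test_monotone_in_threshold_and_min_genes(self, x, dt, dg):
        """Raising either gate parameter never turns an off state on."""
        p = ScaledPathwayMatrix(pd.DataFrame(x), pd.Series(1.0, index=range(7)),
                                pd.Series([True] * 6))
        loose = pm.pathway_on_mask(p, threshold=0.3, min_genes_on=2)
        tight = pm.pathway_on_mask(p, threshold=0.3 + dt, min_genes_on=2 + dg)
        assert not (tight & ~loose).any()


class TestClusterProfiles:
    def test_duplicated_orthogonal_profiles_split_perfectly(self):
        base = np.zeros((20, 7))
        base[:10, 0] = 1.0
        base[10:, 1] = 1.0
        p = ScaledPathwayMatrix(pd.DataFrame(base), pd.Series(1.0, index=range(7)),
                                pd.Series([True] * 20))
        lab = pm.cluster_profiles(p, 2)
        assert adjusted_rand_score(np.repeat([0, 1], 10), lab.labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        p = ScaledPathwayMatrix(pd.DataFrame(rng.uniform(0.2, 1, (8, 7))),
                                pd.Series(1.0, index=range(7)),
                                pd.Series([True] * 8))
        lab = pm.cluster_profiles(p, 8)
        assert lab.labels.nunique() == 8

    def test_recovers_planted_assignment(self, atlas, scaled):
        lab = pm.cluster_profiles(scaled, 6)
        truth = atlas["states"].state_meta["profile_truth"].astype(int)
        ari = adjusted_rand_score(truth.loc[lab.labels.index], lab.labels)
        assert ari >= 0.95

    def test_partition_invariant_to_state_order(self, scaled):
        lab = pm.cluster_profiles(scaled, 6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(scaled.values.shape[0])
        shuffled = ScaledPathwayMatrix(
            scaled.values.iloc[perm], scaled.scale_factors,
            scaled.on_mask.iloc[perm],
        )
        lab2 = pm.cluster_profiles(shuffled, 6)
        joined = pd.concat([lab.labels, lab2.labels], axis=1).dropna()
        assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) == 1.0


class TestGenePrevalence:
    def test_counts_by_enumeration(self):
        x = np.array([
            [0.9, 0.4, 0.0, 0.0, 0.0, 0.0, 0.5],
            [0.8, 0.0, 0.2, 0.0, 0.0, 0.0, 0.4],
            [0.0, 0.0, 0.0, 0.1, 0.0, 0.0, 0.0],
            [1.0, 0.3, 0.3, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        ])
        p = ScaledPathwayMatrix(pd.DataFrame(x), pd.Series(1.0, index=range(7)),
                                pd.Series((x >= 0.3).sum(1) >= 2))
        prev = pm.gene_prevalence(p)
        # on-states are rows 0, 1, 3; count per gene of values >= 0.3
        assert prev.tolist() == [3, 2, 1, 0, 0, 0, 2]

    def test_ubiquitous_and_silent_genes(self, scaled):
        prev = pm.gene_prevalence(scaled)
        assert prev.max() <= scaled.n_on
        assert (prev >= 0).all()


class TestGenePairCorrelations:
    def test_11_genes_give_55_pairs(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.3, 1, (30, 11))
        p = ScaledPathwayMatrix(pd.DataFrame(x, columns=[f"g{i}" for i in range(11)]),
                                pd.Series(1.0, index=range(11)),
                                pd.Series([True] * 30))
        df = pm.gene_pair_correlations(p)
        assert len(df) == 55

    def test_duplicated_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0.3, 1, 30)
        x = np.column_stack([col, col, rng.uniform(0, 1, (30, 5))])
        p = ScaledPathwayMatrix(pd.DataFrame(x), pd.Series(1.0, index=range(7)),
                                pd.Series([True] * 30))
        df = pm.gene_pair_correlations(p)
        pair = df[(df.gene_a == 0) & (df.gene_b == 1)]
        assert pair["rho"].iloc[0] == pytest.approx(1.0)

    def test_null_columns_rarely_significant(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.3, 1, (500, 11))
        p = ScaledPathwayMatrix(pd.DataFrame(x), pd.Series(1.0, index=range(11)),
                                pd.Series([True] * 500))
        df = pm.gene_pair_correlations(p)
        assert abs(df["rho"].mean()) < 0.05
        assert df["significant"].mean() <= 0.10  # ≈ alpha with BH correction

    def test_constant_gene_reported_undefined(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.3, 1, (20, 7))
        x[:, 0] = 0.5
        p = ScaledPathwayMatrix(pd.DataFrame(x), pd.Series(1.0, index=range(7)),
                                pd.Series([True] * 20))
        df = pm.gene_pair_correlations(p)
        involving = df[(df.gene_a == 0) | (df.gene_b == 0)]
        assert involving["undefined"].all()
        assert not involving["significant"].any()
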