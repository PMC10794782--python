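"""Adjusted mutual information, label extension, rescaling and matching."""

import math

import numpy as np
import pandas as pd
import pytest

import pathmotif as pm
from pathmotif.interpathway import profile_centroids
from pathmotif.profiles import ProfileLabeling, ScaledPathwayMatrix


def brute_force_ami(u, v):
    """AMI from first principles: MI, entropies, and the hypergeometric
    expected MI, normalized by max entropy. Feasible for tiny n only."""
    u, v = np.asarray(u), np.asarray(v)
    n = len(u)
    uu, vv = np.unique(u), np.unique(v)
    a = np.array([(u == x).sum() for x in uu])
    b = np.array([(v == y).sum() for y in vv])
    mi = 0.0
    for i, x in enumerate(uu):
        for j, y in enumerate(vv):
            nij = ((u == x) & (v == y)).sum()
            if nij:
                mi += (nij / n) * math.log(n * nij / (a[i] * b[j]))
    hu = -sum((ai / n) * math.log(ai / n) for ai in a)
    hv = -sum((bj / n) * math.log(bj / n) for bj in b)
    emi = 0.0
    lg = math.lgamma
    for ai in a:
        for bj in b:
            for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                lp = (lg(ai + 1) + lg(bj + 1) + lg(n - ai + 1) + lg(n - bj + 1)
                      - lg(n + 1) - lg(nij + 1) - lg(ai - nij + 1)
                      - lg(bj - nij + 1) - lg(n - ai - bj + nij + 1))
                emi += (nij / n) * math.log(n * nij / (ai * bj)) * math.exp(lp)
    denom = max(hu, hv) - emi
    if denom == 0:
        return 1.0
    return (mi - emi) / denom


def series(values, n=None):
    values = list(values)
    return pd.Series(values, index=[f"s{i}" for i in range(len(values))])


class TestExtendLabels:
    def make(self, labels, on):
        ids = [f"s{i}" for i in range(len(on))]
        on = pd.Series(on, index=ids)
        lab = ProfileLabeling(
            pd.Series(labels, index=on.index[on]), np.empty((0, 4)),
            len(set(labels)) if labels else 0,
        )
        return lab, on

    def test_off_states_get_zero(self):
        lab, on = self.make([1, 2, 1, 2, 1, 1],
                            [True, True, False, True, False, True,
                             False, False, True, True])
        full = pm.extend_labels(lab, on)
        assert (full == 0).sum() == 4
        assert (full.loc[on[on].index] == lab.labels).all()

    def test_all_on_is_identity(self):
        lab, on = self.make([1, 2, 2], [True, True, True])
        assert (pm.extend_labels(lab, on) == lab.labels).all()

    def test_all_off_is_constant_zero(self):
        lab, on = self.make([], [False, False])
        assert (pm.extend_labels(lab, on) == 0).all()

    def test_labeled_but_off_state_is_inconsistent(self):
        ids = ["s0", "s1"]
        lab = ProfileLabeling(pd.Series([1, 1], index=ids), np.empty((0, 4)), 1)
        on = pd.Series([True, False], index=ids)
        with pytest.raises(ValueError):
            pm.extend_labels(lab, on)


class TestPairwiseAMI:
    def test_identical_labelings_score_one(self):
        u = series(np.random.default_rng(0).integers(0, 5, 100))
        ami = pm.pairwise_ami({"a": u, "b": u.copy()})
        assert ami.loc["a", "b"] == pytest.approx(1.0)
        assert (np.diag(ami) == 1.0).all()

    def test_invariant_to_label_renaming(self):
        u = series(np.random.default_rng(1).integers(0, 4, 80))
        renamed = u.map({0: 17, 1: 3, 2: 99, 3: 0})
        ami = pm.pairwise_ami({"a": u, "b": renamed})
        assert ami.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_first_principles_formula(self):
        """sklearn-backed AMI equals a from-scratch implementation at n=20."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            u = rng.integers(0, 3, 20)
            v = rng.integers(0, 4, 20)
            ami = pm.pairwise_ami({"a": series(u), "b": series(v)}).loc["a", "b"]
            assert ami == pytest.approx(brute_force_ami(u, v), abs=1e-10)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        labs = {f"p{i}": series(rng.integers(0, 6, 50)) for i in range(3)}
        ami = pm.pairwise_ami(labs)
        np.testing.assert_allclose(ami.values, ami.values.T)

    def test_mismatched_state_sets_rejected(self):
        a = series([1, 2, 1])
        b = pd.Series([1, 2], index=["x", "y"])
        with pytest.raises(ValueError):
            pm.pairwise_ami({"a": a, "b": b})

    def test_single_labeling_rejected(self):
        with pytest.raises(ValueError):
            pm.pairwise_ami({"a": series([1, 2])})


class TestRescaleToReference:
    def make_ref(self, ng=7):
        df = pd.DataFrame(np.zeros((2, ng)), columns=[f"g{j}" for j in range(ng)])
        return ScaledPathwayMatrix(df, pd.Series(1.0, index=df.columns),
                                   pd.Series([True, True]))

    def test_dev_q95_maps_to_one(self):
        rng = np.random.default_rng(0)
        dev = pd.DataFrame(rng.uniform(0, 8, (200, 7)),
                           columns=[f"g{j}" for j in range(7)])
        out = pm.rescale_to_reference(dev, self.make_ref())
        q95 = dev.quantile(0.95)
        for g in dev.columns:
            row = (dev[g] - q95[g]).abs().idxmin()
            assert out.loc[row, g] == pytest.approx(
                (dev.loc[row, g] - dev[g].min()) / (q95[g] - dev[g].min()),
                abs=1e-9,
            )
        assert out.to_numpy().max() <= 1.0

    def test_identity_when_range_already_unit(self):
        dev = pd.DataFrame(np.tile(np.linspace(0, 1, 101)[:, None], (1, 7)),
                           columns=[f"g{j}" for j in range(7)])
        out = pm.rescale_to_reference(dev, self.make_ref())
        np.testing.assert_allclose(
            out.to_numpy(), np.clip(dev.to_numpy() / 0.95, 0, 1), atol=1e-12
        )

    def test_constant_gene_maps_to_zero(self):
        dev = pd.DataFrame(np.ones((10, 7)), columns=[f"g{j}" for j in range(7)])
        out = pm.rescale_to_reference(dev, self.make_ref())
        assert (out.to_numpy() == 0).all()

    def test_unknown_genes_dropped(self):
        dev = pd.DataFrame(np.ones((10, 2)), columns=["g0", "zzz"])
        out = pm.rescale_to_reference(dev, self.make_ref())
        assert list(out.columns) == ["g0"]


class TestStageMeans:
    def test_single_cell_per_stage(self):
        cells = pd.DataFrame([[0.2, 0.4], [0.6, 0.8]], index=["c0", "c1"])
        stages = pd.Series(["early", "late"], index=["c0", "c1"])
        means = pm.stage_mean_profiles(cells, stages)
        np.testing.assert_allclose(means.loc["early"], [0.2, 0.4])

    def test_arithmetic_mean(self):
        cells = pd.DataFrame([[0.2], [0.4]], index=["c0", "c1"])
        stages = pd.Series(["t0", "t0"], index=["c0", "c1"])
        assert pm.stage_mean_profiles(cells, stages).iloc[0, 0] == pytest.approx(0.3)

    def test_categorical_stage_order_preserved(self):
        cells = pd.DataFrame(np.arange(8).reshape(4, 2), index=list("abcd"))
        stages = pd.Series(pd.Categorical(["late", "early", "late", "early"],
                                          categories=["early", "late"],
                                          ordered=True), index=list("abcd"))
        means = pm.stage_mean_profiles(cells, stages)
        assert list(means.index) == ["early", "late"]


class TestMatching:
    def refs(self):
        return pd.DataFrame([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], index=[1, 2])

    def test_exact_centroid_matches_with_zero_distance(self):
        pid, d = pm.match_nearest_profile(np.array([0.0, 1.0, 0.0]), self.refs())
        assert pid == 2 and d == pytest.approx(0.0, abs=1e-12)

    def test_tie_goes_to_smaller_id_with_warning(self):
        with pytest.warns(UserWarning):
            pid, _ = pm.match_nearest_profile(np.array([1.0, 1.0, 0.0]), self.refs())
        assert pid == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            pm.match_nearest_profile(np.ones(3), pd.DataFrame(columns=[0, 1, 2]))

    def test_self_consistency_of_labels_and_centroids(self, scaled, labeling):
        """Matching each on-state to its pathway's centroids returns its own
        profile for nearly all states."""
        refs = profile_centroids(scaled, labeling)
        hits = 0
        for sid, row in scaled.on_values.iterrows():
            pid, _ = pm.match_nearest_profile(row.to_numpy(), refs)
            hits += pid == labeling.labels[sid]
        assert hits / len(labeling.labels) >= 0.95
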