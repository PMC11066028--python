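"""Heterogeneity-calling tests: the exact rule cascade, fraction
conservation and monotonicity properties, the merged cell-cycle arithmetic,
and the Mann-Whitney association against a hand-ranked computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellfp import heterogeneity as het
from cellfp.heterogeneity import (
    HeterogeneityParams,
    classify_heterogeneity,
    crop_category_assignment,
    top2_localizations,
)


class TestTop2:
    def test_one_hot_crops(self):
        probs = pd.DataFrame({"A": [1.0, 1.0], "B": [0.0, 0.0], "C": [0.0, 0.0]})
        loc1, loc2, pairs = top2_localizations(probs)
        assert loc1 == "A" and loc2 == "B"  # runner-up by column order on ties
        np.testing.assert_array_equal(pairs, [[1, 0], [1, 0]])

    def test_mean_ordering(self):
        probs = pd.DataFrame({"A": [0.6, 0.6], "B": [0.3, 0.3], "C": [0.1, 0.1]})
        loc1, loc2, _ = top2_localizations(probs)
        assert (loc1, loc2) == ("A", "B")

    def test_tie_broken_by_column_index(self):
        probs = pd.DataFrame({"x": [0.4], "y": [0.4], "z": [0.2]})
        loc1, loc2, _ = top2_localizations(probs)
        assert (loc1, loc2) == ("x", "y")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            top2_localizations(pd.DataFrame({"A": [1.0]}))


class TestRuleCascade:
    def test_confident_primary_is_single(self):
        call = classify_heterogeneity(np.tile([0.9, 0.05], (20, 1)))
        assert call.verdict == "single" and call.c1 == 1.0

    def test_all_mixed_is_AND(self):
        call = classify_heterogeneity(np.tile([0.50, 0.40], (20, 1)))
        assert call.m == 1.0 and call.verdict == "AND"

    def test_split_population_is_OR(self):
        pairs = np.vstack([np.tile([0.90, 0.02], (10, 1)), np.tile([0.02, 0.90], (10, 1))])
        call = classify_heterogeneity(pairs)
        assert call.c1 == 0.5 and call.c2 == 0.5 and call.m == 0.0
        assert call.verdict == "OR"

    def test_low_confidence_everywhere_is_undetermined(self):
        call = classify_heterogeneity(np.tile([0.2, 0.2], (20, 1)))
        assert call.k_lc == 1.0 and call.verdict == "undetermined"

    def test_or_threshold_boundary(self):
        # c2 exactly at 0.08 is not strictly greater -> single
        pairs = np.vstack([np.tile([0.9, 0.0], (92, 1)), np.tile([0.0, 0.9], (8, 1))])
        assert classify_heterogeneity(pairs).verdict == "single"
        pairs = np.vstack([np.tile([0.9, 0.0], (91, 1)), np.tile([0.0, 0.9], (9, 1))])
        assert classify_heterogeneity(pairs).verdict == "OR"

    def test_min_c1_c2_switch(self):
        # c1 below threshold blocks OR under the alternative statistic
        pairs = np.vstack([np.tile([0.9, 0.0], (5, 1)), np.tile([0.0, 0.9], (95, 1))])
        literal = classify_heterogeneity(pairs)
        assert literal.verdict == "OR"  # min(1, c2) = 0.95
        alt = classify_heterogeneity(
            pairs, HeterogeneityParams(or_statistic="min_c1_c2")
        )
        assert alt.verdict == "single"  # min(c1, c2) = 0.05

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fraction_conservation(self, seed):
        g = np.random.default_rng(seed)
        pairs = g.dirichlet([1, 1, 1], size=30)[:, :2]
        call = classify_heterogeneity(pairs)
        assert call.c1 + call.c2 + call.m + call.k_lc == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.45), st.floats(0.5, 1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_raising_beta_only_moves_crops_into_mixed(self, seed, b1, b2):
        g = np.random.default_rng(seed)
        pairs = g.dirichlet([1, 1, 1], size=40)[:, :2]
        lo = crop_category_assignment(pairs, HeterogeneityParams(beta=min(b1, b2)))
        hi = crop_category_assignment(pairs, HeterogeneityParams(beta=max(b1, b2)))
        # crops may move 0/1 -> 2 but never 2 -> 0/1; 3 is beta-independent
        assert ((lo == 3) == (hi == 3)).all()
        moved = lo != hi
        assert (hi[moved] == 2).all()
        assert np.isin(lo[moved], [0, 1]).all()


class TestCellCycleArithmetic:
    def test_member_average_and_merge(self):
        p4 = np.array([[0.1, 0.2, 0.3, 0.4]])  # (G1, S, MA, T)
        merged = np.column_stack([p4[:, 3] + p4[:, 0], p4[:, 1], p4[:, 2]])
        np.testing.assert_allclose(merged, [[0.5, 0.2, 0.3]])
        ens = het.merge_member_probs([p4, p4, p4])
        np.testing.assert_allclose(ens, p4, atol=1e-9)
        assert merged.sum() == pytest.approx(1.0)

    def test_ensemble_probability_is_member_mean(self, rng):
        members = [rng.dirichlet(np.ones(4), size=6) for _ in range(3)]
        ens = het.merge_member_probs(members)
        np.testing.assert_allclose(ens, np.mean(members, axis=0), atol=1e-9)


class TestAssociation:
    def test_identical_distributions_no_link(self):
        pairs = np.vstack([np.tile([0.95, 0.0], (30, 1)), np.tile([0.0, 0.95], (30, 1))])
        stage = pd.DataFrame({"T/G1": np.full(60, 0.5), "S/G2": np.full(60, 0.3),
                              "M/A": np.full(60, 0.2)})
        links = het.cellcycle_association(pairs, stage, protein_id="P")
        assert links.empty

    def test_u_statistic_matches_hand_ranking(self):
        # 4 vs 4 toy: group1 = [1,2,3,4], group2 = [5,6,7,8]
        pairs = np.vstack([np.tile([0.9, 0.0], (4, 1)), np.tile([0.0, 0.9], (4, 1))])
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8.0]) / 10.0
        stage = pd.DataFrame({"M/A": vals})
        links = het.cellcycle_association(pairs, stage, p_threshold=1.0, protein_id="P")
        # all group2 values exceed group1: U = R1 - n1(n1+1)/2 = 10 - 10 = 0
        assert links.U.iloc[0] == pytest.approx(0.0)

    def test_planted_stage_shift_detected(self, rng):
        n = 100
        pairs = np.vstack([np.tile([0.95, 0.0], (n, 1)), np.tile([0.0, 0.95], (n, 1))])
        ma = np.concatenate([rng.beta(2, 10, n), rng.beta(10, 2, n)])
        stage = pd.DataFrame({"M/A": ma, "T/G1": 1 - ma})
        links = het.cellcycle_association(pairs, stage, protein_id="P",
                                          loc1="nucleus", loc2="cytoplasm")
        assert set(links.stage) == {"M/A", "T/G1"}
        assert (links.p < 1e-3).all()
        ma_row = links[links.stage == "M/A"].iloc[0]
        assert ma_row.localization == "cytoplasm"

    def test_empty_group_skipped_with_warning(self):
        pairs = np.tile([0.9, 0.0], (10, 1))
        stage = pd.DataFrame({"M/A": np.linspace(0, 1, 10)})
        with pytest.warns(UserWarning):
            links = het.cellcycle_association(pairs, stage, protein_id="P")
        assert links.empty


class TestEnsembleTraining:
    def stage_data(self, n_per=24, seed=0):
        """Crops whose channel layout encodes the stage (planted signal)."""
        g = np.random.default_rng(seed)
        X, y = [], []
        for si, stage in enumerate(het.STAGE_CLASSES):
            for _ in range(n_per):
                im = g.normal(0, 0.1, size=(2, 16, 16))
                im[0, 2 + si * 3 : 5 + si * 3, :] += 2.0  # nuclear-band position
                if stage != "G1":
                    im[1, :, 10:] += 1.0  # "bud" in the cytosolic channel
                X.append(im)
                y.append(stage)
        return np.array(X), np.array(y)

    def test_planted_stage_signal_recovered(self):
        X, y = self.stage_data()
        ens = het.CellCycleEnsemble(
            n_conv_blocks=1, base_channels=4, feature_dim=8, epochs=40,
            batch_size=16, augment=False, random_state=0,
        ).fit(X, y)
        merged = ens.predict_proba_merged(X).to_numpy()
        truth = {"G1": 0, "T": 0, "S": 1, "MA": 2}
        acc = np.mean(merged.argmax(1) == [truth[s] for s in y])
        assert acc > 2 / 3  # > 2x chance on 3 merged classes
        probs = ens.predict_proba(X)
        member_mean = np.mean([m.predict_proba(X) for m in ens.members_], axis=0)
        np.testing.assert_allclose(probs, member_mean, atol=1e-9)

    def test_missing_class_rejected(self):
        X, y = self.stage_data(n_per=6)
        keep = y != "T"
        with pytest.raises(ValueError, match="T"):
            het.CellCycleEnsemble(epochs=1).fit(X[keep], y[keep])

    def test_merged_probabilities_sum_to_one(self):
        X, y = self.stage_data(n_per=8)
        ens = het.CellCycleEnsemble(
            n_conv_blocks=1, base_channels=4, feature_dim=8, epochs=2,
            batch_size=16, augment=False, random_state=1,
        ).fit(X, y)
        merged = ens.predict_proba_merged(X[:10])
        np.testing.assert_allclose(merged.sum(axis=1), 1.0, atol=1e-6)
        a = ens.predict_proba(X[:5])
        b = ens.predict_proba(X[:5])
        np.testing.assert_allclose(a, b, atol=1e-7)  # deterministic inference
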