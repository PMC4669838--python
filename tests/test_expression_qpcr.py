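"""ddCt arithmetic, group statistics, and concordance rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbdseq.expression_qpcr import (
    FoldChangeResult,
    compare_groups,
    concordance_report,
    delta_ct,
    delta_ct_table,
    fold_change,
)
from mbdseq.synthetic_data import simulate_qpcr


def _table(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])


def _two_group_table(dct_a, dct_b, gene="g", ref_ct=20.0):
    rows = []
    for i, d in enumerate(dct_a, 1):
        rows.append((f"control_r{i}", "control", "Hprt", i, ref_ct))
        rows.append((f"control_r{i}", "control", gene, i, ref_ct + d))
    for i, d in enumerate(dct_b, 1):
        rows.append((f"dex_r{i}", "dex", "Hprt", i, ref_ct))
        rows.append((f"dex_r{i}", "dex", gene, i, ref_ct + d))
    return _table(rows)


class TestDeltaCt:
    def test_simple_difference(self):
        assert delta_ct(25.0, 20.0) == 5.0
        assert delta_ct(20.0, 20.0) == 0.0

    def test_computed_per_replicate_not_on_group_means(self):
        # replicate-wise contract: each sample's target Ct minus that
        # sample's own reference Ct, before any averaging
        rows = [
            ("s1", "g1", "Hprt", 1, 20.0),
            ("s1", "g1", "tgt", 1, 25.0),
            ("s2", "g1", "Hprt", 2, 22.0),
            ("s2", "g1", "tgt", 2, 26.0),
        ]
        dct = delta_ct_table(_table(rows))
        by_sample = dct.set_index("sample")["delta_ct"]
        assert by_sample["s1"] == 5.0
        assert by_sample["s2"] == 4.0  # not 25.5 - 21.0 applied per sample

    def test_missing_reference_names_the_sample(self):
        rows = [
            ("s1", "g1", "Hprt", 1, 20.0),
            ("s1", "g1", "tgt", 1, 25.0),
            ("s2", "g1", "tgt", 2, 26.0),
        ]
        with pytest.raises(ValueError, match="s2"):
            delta_ct_table(_table(rows))


class TestFoldChange:
    def test_identities(self):
        assert fold_change([1.0, 1.0], [1.0, 1.0]).fold == pytest.approx(1.0)
        assert fold_change([0.0, 0.0], [1.0, 1.0]).fold == pytest.approx(2.0)
        # ddCt of 1.1203 cycles corresponds to ~0.46-fold knockdown
        assert fold_change([1.1203], [0.0]).fold == pytest.approx(0.46, abs=0.001)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8),
           st.lists(st.floats(-5, 5), min_size=2, max_size=8))
    def test_antisymmetry(self, a, b):
        f_ab = fold_change(a, b).fold
        f_ba = fold_change(b, a).fold
        assert f_ab * f_ba == pytest.approx(1.0, rel=1e-9)

    def test_reference_invariance(self):
        # adding a constant to every Ct of a sample cancels in dCt
        base = _two_group_table([1.0, 1.2, 0.9], [0.1, 0.0, -0.1])
        shifted = base.copy()
        for sample, delta in [("control_r1", 3.0), ("dex_r2", -2.0)]:
            shifted.loc[shifted["sample"] == sample, "ct"] += delta
        for tbl in (base, shifted):
            dct = delta_ct_table(tbl)
            t = dct[dct["group"] == "dex"]["delta_ct"].to_numpy()
            c = dct[dct["group"] == "control"]["delta_ct"].to_numpy()
            res = fold_change(t, c)
        base_res = fold_change(
            delta_ct_table(base).query("group == 'dex'")["delta_ct"].to_numpy(),
            delta_ct_table(base).query("group == 'control'")["delta_ct"].to_numpy(),
        )
        assert res.fold == pytest.approx(base_res.fold)


class TestCompareGroups:
    def test_identical_groups_give_zero_t(self):
        tbl = _two_group_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = compare_groups(tbl)
        assert out.iloc[0]["statistic"] == pytest.approx(0.0)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_pooled_t_matches_hand_computation(self):
        # a=[1,2,3], b=[2,4,6]: means 2, 4; s2p = (2*1 + 2*4)/4 = 2.5
        # t = (2-4)/sqrt(2.5*(1/3+1/3)) = -1.549193...
        tbl = _two_group_table([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        out = compare_groups(tbl)
        # group order in the comparison is alphabetical: control vs dex
        assert out.iloc[0]["statistic"] == pytest.approx(-1.5491933, abs=1e-6)

    def test_three_groups_run_anova_with_bonferroni(self):
        rows = []
        for grp, shift in [("a", 0.0), ("b", 0.0), ("c", 4.0)]:
            for i, d in enumerate([1.0, 1.1, 0.9, 1.05], 1):
                rows.append((f"{grp}_r{i}", grp, "Hprt", i, 20.0))
                rows.append((f"{grp}_r{i}", grp, "tgt", i, 21.0 + d + shift))
        out = compare_groups(_table(rows))
        omnibus = out[out["comparison"] == "omnibus"].iloc[0]
        assert omnibus["test"] == "anova"
        assert omnibus["p_value"] < 0.05
        pairwise = out[out["test"] == "t-test (Bonferroni)"]
        assert len(pairwise) == 3
        assert (pairwise["p_adjusted"] >= pairwise["p_value"] - 1e-12).all()
        ab = pairwise[pairwise["comparison"] == "a vs b"].iloc[0]
        ac = pairwise[pairwise["comparison"] == "a vs c"].iloc[0]
        assert ab["p_adjusted"] > 0.05
        assert ac["p_adjusted"] < 0.05

    def test_bonferroni_pairwise_type_one_error_controlled(self):
        # simulation oracle: under the null the family-wise rate of any
        # significant adjusted pairwise test stays at or below alpha
        rng = np.random.default_rng(30)
        n_rep, hits = 400, 0
        for _ in range(n_rep):
            rows = []
            for grp in ("a", "b", "c"):
                for i in range(1, 5):
                    rows.append((f"{grp}_r{i}", grp, "Hprt", i, 20.0))
                    rows.append((f"{grp}_r{i}", grp, "tgt", i, 22.0 + rng.normal(0, 0.3)))
            out = compare_groups(_table(rows))
            pairwise = out[out["test"] == "t-test (Bonferroni)"]
            if len(pairwise) and (pairwise["p_adjusted"] < 0.05).any():
                hits += 1
        rate = hits / n_rep
        assert rate <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_too_few_replicates_rejected(self):
        rows = [
            ("a_r1", "a", "Hprt", 1, 20.0),
            ("a_r1", "a", "tgt", 1, 22.0),
            ("b_r1", "b", "Hprt", 1, 20.0),
            ("b_r1", "b", "tgt", 1, 23.0),
            ("b_r2", "b", "Hprt", 2, 20.0),
            ("b_r2", "b", "tgt", 2, 23.0),
        ]
        with pytest.raises(ValueError, match="< 2 replicates"):
            compare_groups(_table(rows))


class TestConcordance:
    def _fold(self, gene, fold):
        return FoldChangeResult(gene, 0, 0, 0, 0, -np.log2(fold), fold)

    def test_rules(self):
        folds = {
            "up_hypo": self._fold("up_hypo", 1.8),
            "up_hyper": self._fold("up_hyper", 1.8),
            "down_hyper": self._fold("down_hyper", 0.5),
            "flat": self._fold("flat", 1.1),
            "orphan_fold": self._fold("orphan_fold", 2.0),
        }
        statuses = {
            "up_hypo": "hypomethylated_in_b",
            "up_hyper": "hypermethylated_in_b",
            "down_hyper": "hypermethylated_in_b",
            "flat": "unchanged",
            "orphan_status": "hypomethylated_in_b",
        }
        rep = concordance_report(folds, statuses).set_index("gene")
        assert rep.loc["up_hypo", "concordance"] == "concordant"
        assert rep.loc["up_hyper", "concordance"] == "discordant"
        assert rep.loc["down_hyper", "concordance"] == "concordant"
        assert rep.loc["flat", "concordance"] == "unscored"
        assert rep.loc["orphan_fold", "concordance"] == "unscored"
        assert rep.loc["orphan_status", "concordance"] == "unscored"

    def test_summary_fraction(self):
        folds = {"a": self._fold("a", 2.0), "b": self._fold("b", 0.5)}
        statuses = {"a": "hypomethylated_in_b", "b": "hypomethylated_in_b"}
        rep = concordance_report(folds, statuses)
        assert rep.attrs["concordant_fraction"] == pytest.approx(0.5)


class TestRecoveryFromSimulatedPlates:
    def test_folds_recovered_within_fifteen_percent(self):
        # estimator recovery at plate-level noise: mean estimate over
        # repeated simulated experiments, folds spanning 0.4-3
        for fold in (0.4, 0.46, 1.0, 2.0, 3.0):
            est = []
            for seed in range(30):
                tbl = simulate_qpcr(
                    {"g": {"control": 1.0, "dex": fold}},
                    replicates=6, noise_sd=0.2, seed=seed,
                )
                dct = delta_ct_table(tbl)
                t = dct[dct["group"] == "dex"]["delta_ct"].to_numpy()
                c = dct[dct["group"] == "control"]["delta_ct"].to_numpy()
                est.append(fold_change(t, c).fold)
            assert np.mean(est) == pytest.approx(fold, rel=0.15)
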