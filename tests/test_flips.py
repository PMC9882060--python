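import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import skew_chain
from halfcell import flips as hflips
from halfcell import skew as hskew
from halfcell.synthetic import SimConfig, generate_experiment


def skew_from_array(arr, conditions):
    values = pd.DataFrame(arr, index=[f"p{i}" for i in range(len(arr))],
                          columns=[f"g{i:03d}" for i in range(arr.shape[1])])
    values.index.name = "pair_id"
    return hskew.SkewMatrix(
        values=values, pair_condition=pd.Series(conditions, index=values.index)
    )


class TestClassify:
    @pytest.mark.parametrize(
        "mc, mk, significant, expected",
        [
            (0.4, -0.3, True, "anti_correlated"),
            (0.4, 0.02, True, "lost"),
            (0.4, 0.6, True, "retained"),
            (-0.4, 0.3, True, "anti_correlated"),
            (0.4, -0.3, False, "not_significant"),
            (0.03, -0.3, True, "retained"),  # control side below min_effect
        ],
    )
    def test_rules(self, mc, mk, significant, expected):
        assert hflips.classify(mc, mk, significant, min_effect=0.05) == expected


class TestSelectCandidates:
    def test_k_at_least_gene_count_selects_all(self):
        rng = np.random.default_rng(0)
        sk = skew_from_array(rng.normal(0, 0.05, (8, 10)),
                             ["control"] * 4 + ["kd"] * 4)
        cand = hflips.select_candidates(sk, k=100)
        assert sorted(cand.genes) == sorted(sk.values.columns)

    def test_flipped_genes_dominate_top_loadings(self):
        # 30 genes flip sign under kd, the rest are null: the flipped genes
        # must occupy (nearly all of) the top-30 loadings
        cfg = SimConfig(n_genes=1000, frac_regionalized=0.03, kd_frac_flip=1.0,
                        kd_frac_loss=0.0, noise_sd=0.1, seed=21)
        matrix, sheet, truth = generate_experiment(cfg)
        _, skew, _ = skew_chain(matrix, sheet)
        flipped = set(truth.genes_in_class("flipped"))
        assert len(flipped) == 30
        cand = hflips.select_candidates(skew, k=30)
        assert len(flipped & set(cand.genes)) >= 27

    def test_null_conditions_give_small_selection_t(self):
        # kd simulated with control parameters: the selection component's
        # condition |t| should look like a null t statistic
        t_values = []
        for seed in range(20):
            cfg = SimConfig(n_genes=400, kd_frac_flip=0.0, kd_frac_loss=0.0,
                            seed=seed)
            matrix, sheet, _ = generate_experiment(cfg)
            _, skew, _ = skew_chain(matrix, sheet)
            cand = hflips.select_candidates(skew, k=10)
            t_values.append(abs(cand.condition_t))
        df = len(skew.values) - 2
        assert np.median(t_values) < stats.t.ppf(0.975, df)

    def test_invalid_k_rejected(self):
        sk = skew_from_array(np.zeros((4, 3)), ["control"] * 2 + ["kd"] * 2)
        with pytest.raises(ValueError):
            hflips.select_candidates(sk, k=0)


class TestTestCandidates:
    def run(self, ctrl_rows, kd_rows, **kwargs):
        arr = np.array(ctrl_rows + kd_rows, dtype=float)
        sk = skew_from_array(arr, ["control"] * len(ctrl_rows) + ["kd"] * len(kd_rows))
        cand = hflips.select_candidates(sk, k=arr.shape[1])
        return hflips.test_candidates(cand, sk, **kwargs)

    def test_identical_groups_not_significant(self):
        res = self.run([[0.5], [0.5]], [[0.5], [0.5]])
        row = res.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0
        assert row["class"] == "not_significant"

    def test_clear_flip_detected_with_hand_welch_oracle(self):
        ctrl = [0.4, 0.5, 0.45]
        kd = [-0.4, -0.45, -0.5]
        res = self.run([[c] for c in ctrl], [[k] for k in kd],
                       significance_mode="raw", alpha=0.05, min_effect=0.05)
        row = res.iloc[0]
        # independent Welch arithmetic
        m1, m2 = np.mean(ctrl), np.mean(kd)
        v1, v2 = np.var(ctrl, ddof=1), np.var(kd, ddof=1)
        t_expected = (m1 - m2) / np.sqrt(v1 / 3 + v2 / 3)
        assert row["t"] == pytest.approx(t_expected)
        assert row["class"] == "anti_correlated"

    def test_bh_adjustment_arithmetic(self):
        # classic BH on {0.01, 0.02, 0.04} -> {0.03, 0.03, 0.04}
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04])

    def test_label_symmetry_negates_t(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(0, 0.05, (8, 6))
        arr[:4, :3] += 0.1  # some structure
        sk = skew_from_array(arr, ["control"] * 4 + ["kd"] * 4)
        sk_swapped = hskew.SkewMatrix(
            values=sk.values,
            pair_condition=sk.pair_condition.map({"control": "kd", "kd": "control"}),
        )
        cand = hflips.select_candidates(sk, k=6)
        res = hflips.test_candidates(cand, sk)
        res_sw = hflips.test_candidates(cand, sk_swapped)
        np.testing.assert_allclose(res_sw["t"].to_numpy(), -res["t"].to_numpy())
        np.testing.assert_allclose(res_sw["p"].to_numpy(), res["p"].to_numpy())
        flipped = res["class"] == "anti_correlated"
        np.testing.assert_array_equal(
            (res_sw["class"] == "anti_correlated").to_numpy(), flipped.to_numpy()
        )

    def test_untestable_gene_excluded_from_bh(self):
        arr = np.array(
            [[0.5, 0.1], [0.4, np.nan], [-0.5, np.nan], [-0.4, 0.2]]
        )
        sk = skew_from_array(arr, ["control", "control", "kd", "kd"])
        cand = hflips.select_candidates(sk, k=2)
        res = hflips.test_candidates(cand, sk)
        g1 = res.loc["g001"]
        assert not g1["testable"]
        assert g1["class"] == "untestable"
        assert np.isnan(g1["q"])

    def test_zero_call_outcome_reported_without_error(self):
        # a knockdown with no real effect must come back with zero flip calls,
        # not an exception (one construct in the field data behaved this way)
        cfg = SimConfig(n_genes=200, kd_frac_flip=0.0, kd_frac_loss=0.0, seed=5)
        matrix, sheet, _ = generate_experiment(cfg)
        _, skew, _ = skew_chain(matrix, sheet)
        cand = hflips.select_candidates(skew, k=200)
        res = hflips.test_candidates(cand, skew)
        assert (res["class"] == "anti_correlated").sum() == 0


class TestOverlapWithReference:
    def results_frame(self, genes, mc, mk, cls):
        return pd.DataFrame(
            {"mean_control": mc, "mean_kd": mk, "class": cls},
            index=pd.Index(genes, name="gene_id"),
        )

    def test_empty_reference_gives_zero_overlap(self):
        res = self.results_frame(["g1"], [0.4], [-0.4], ["anti_correlated"])
        ref = pd.DataFrame(columns=["gene_id", "side"])
        out = hflips.overlap_with_reference(res, ref)
        assert out["n_overlap"] == 0 and out["n_flipped"] == 1

    def test_matching_reference_fully_concordant(self):
        res = self.results_frame(
            ["g1", "g2"], [0.4, -0.3], [-0.4, 0.3],
            ["anti_correlated", "anti_correlated"],
        )
        ref = pd.DataFrame({"gene_id": ["g1", "g2"], "side": ["A", "P"]})
        out = hflips.overlap_with_reference(res, ref)
        assert out["n_overlap"] == 2
        assert out["table"]["concordant"].all()

    def test_heatmap_rows_are_zscored(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(0, 0.1, (6, 3))
        sk = skew_from_array(arr, ["control"] * 3 + ["kd"] * 3)
        res = self.results_frame(
            list(sk.values.columns), [0.4] * 3, [-0.4] * 3, ["anti_correlated"] * 3
        )
        ref = pd.DataFrame({"gene_id": list(sk.values.columns),
                            "side": ["A", "A", "A"]})
        out = hflips.overlap_with_reference(res, ref, skew=sk)
        hm = out["heatmap"].to_numpy()
        np.testing.assert_allclose(hm.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(hm.std(axis=1), 1.0, atol=1e-12)
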