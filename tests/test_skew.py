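import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import adjusted_from_values, skew_chain
from halfcell import skew as hskew
from halfcell.io import ValidationError


def matrix_from_log1p(values, columns):
    """TPM matrix whose log1p equals the given values."""
    return pd.DataFrame(np.expm1(values), columns=columns,
                        index=[f"g{i}" for i in range(np.shape(values)[0])])


class TestLog1Adjust:
    def test_offset_is_mean_log1p(self):
        tpm = matrix_from_log1p(np.array([[0.0], [2.0], [4.0]]), ["s1"])
        adj = hskew.log1_adjust(tpm)
        assert adj.offsets["s1"] == pytest.approx(2.0)
        np.testing.assert_allclose(adj.values["s1"], [2.0, 4.0, 6.0])

    def test_all_zero_column_stays_zero(self):
        tpm = pd.DataFrame({"s1": [0.0, 0.0, 0.0]})
        adj = hskew.log1_adjust(tpm)
        assert adj.offsets["s1"] == 0.0
        assert (adj.values["s1"] == 0.0).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            hskew.log1_adjust(pd.DataFrame())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=20))
    def test_adjustment_preserves_within_sample_ranking(self, tpms):
        tpm = pd.DataFrame({"s1": tpms})
        adj = hskew.log1_adjust(tpm)
        order = np.argsort(tpm["s1"].to_numpy(), kind="stable")
        sorted_adjusted = adj.values["s1"].to_numpy()[order]
        assert (np.diff(sorted_adjusted) >= 0).all()


class TestFilterGenes:
    def make(self, adj_rows, tpm_value=10.0):
        values = pd.DataFrame(adj_rows, columns=[f"s{i}" for i in
                                                 range(len(adj_rows[0]))])
        values.index = [f"g{i}" for i in range(len(adj_rows))]
        tpm = pd.DataFrame(tpm_value, index=values.index, columns=values.columns)
        return tpm, adjusted_from_values(values)

    def test_dispersion_boundary_is_strict(self):
        # [0, 2, 4]: mean 2, sample variance 4 -> dispersion exactly 2,
        # which fails the strict "< 2" rule
        tpm, adj = self.make([[0.0, 2.0, 4.0]])
        report = hskew.filter_genes(tpm, adj, min_mean_tpm=0.0, max_dispersion=2.0)
        assert report["dispersion"].iloc[0] == pytest.approx(2.0)
        assert not report["pass_dispersion"].iloc[0]

    def test_constant_nonzero_gene_passes_dispersion(self):
        tpm, adj = self.make([[3.0, 3.0, 3.0]])
        report = hskew.filter_genes(tpm, adj, min_mean_tpm=0.0)
        assert report["dispersion"].iloc[0] == 0.0
        assert report["pass_dispersion"].iloc[0]

    def test_zero_mean_adjusted_fails_dispersion(self):
        tpm, adj = self.make([[0.0, 0.0, 0.0]], tpm_value=0.0)
        report = hskew.filter_genes(tpm, adj, min_mean_tpm=0.0)
        assert not report["pass_dispersion"].iloc[0]

    def test_abundance_cutoff_inclusive(self):
        tpm, adj = self.make([[1.0, 1.0, 1.0]], tpm_value=1.0)
        report = hskew.filter_genes(tpm, adj, min_mean_tpm=1.0)
        assert report["pass_abundance"].iloc[0]

    def test_nonpositive_dispersion_ceiling_rejected(self):
        tpm, adj = self.make([[1.0, 1.0]])
        with pytest.raises(ValueError):
            hskew.filter_genes(tpm, adj, max_dispersion=0.0)

    def test_retained_set_matches_brute_force_recount(self, small_experiment):
        matrix, sheet, _ = small_experiment
        adj = hskew.log1_adjust(matrix)
        report = hskew.filter_genes(matrix, adj, 1.0, 2.0)
        # independent two-pass recount, gene by gene
        expected = []
        for g in matrix.index:
            tpm_row = matrix.loc[g].to_numpy()
            adj_row = np.log1p(matrix).loc[g].to_numpy() + np.log1p(matrix).mean(
                axis=0).to_numpy()
            mean_ok = tpm_row.mean() >= 1.0
            m = adj_row.mean()
            disp_ok = m > 0 and (adj_row.var(ddof=1) / m) < 2.0
            expected.append(mean_ok and disp_ok)
        np.testing.assert_array_equal(report["retained"].to_numpy(),
                                      np.array(expected))


class TestComputeSkew:
    def toy(self, a, p):
        values = pd.DataFrame({"p1_A": a, "p1_P": p},
                              index=[f"g{i}" for i in range(len(a))])
        sheet = pd.DataFrame(
            {"sample_id": ["p1_A", "p1_P"], "pair_id": ["p1", "p1"],
             "half": ["A", "P"], "condition": ["control", "control"],
             "batch": ["", ""]}
        )
        return hskew.compute_skew(adjusted_from_values(values), sheet)

    def test_arithmetic(self):
        skew = self.toy([3.0, 2.0], [1.0, 2.0])
        assert skew.values.iloc[0, 0] == pytest.approx(0.5)
        assert skew.values.iloc[0, 1] == pytest.approx(0.0)

    def test_zero_denominator_is_missing_not_zero(self):
        skew = self.toy([0.0], [0.0])
        assert np.isnan(skew.values.iloc[0, 0])

    def test_unpaired_sample_rejected(self):
        values = pd.DataFrame({"p1_A": [1.0]}, index=["g0"])
        sheet = pd.DataFrame(
            {"sample_id": ["p1_A"], "pair_id": ["p1"], "half": ["A"],
             "condition": ["control"], "batch": [""]}
        )
        with pytest.raises(ValidationError):
            hskew.compute_skew(adjusted_from_values(values), sheet)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            min_size=1, max_size=10,
        )
    )
    def test_bounded_and_antisymmetric(self, pairs):
        a = [x for x, _ in pairs]
        p = [y for _, y in pairs]
        fwd = self.toy(a, p).values.to_numpy()
        rev = self.toy(p, a).values.to_numpy()
        finite = ~np.isnan(fwd)
        assert (np.abs(fwd[finite]) <= 1.0 + 1e-12).all()
        np.testing.assert_allclose(rev[finite], -fwd[finite], atol=1e-12)


class TestSummarizeSkew:
    def test_constant_skews(self):
        values = pd.DataFrame(0.25, index=["p1", "p2"], columns=["g1", "g2"])
        values.index.name = "pair_id"
        skew = hskew.SkewMatrix(
            values=values,
            pair_condition=pd.Series(["control", "control"], index=["p1", "p2"]),
        )
        per_gene, per_condition = hskew.summarize_skew(skew)
        assert (per_gene["mean_skew"] == 0.25).all()
        assert (per_gene["sd_skew"] == 0.0).all()
        assert per_condition.loc["control", "sd"] == 0.0

    def test_normal_sample_has_near_zero_excess_kurtosis(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.2, size=(40, 500)).clip(-1, 1)
        values = pd.DataFrame(vals, index=[f"p{i}" for i in range(40)],
                              columns=[f"g{i}" for i in range(500)])
        skew = hskew.SkewMatrix(
            values=values,
            pair_condition=pd.Series("control", index=values.index),
        )
        _, per_condition = hskew.summarize_skew(skew)
        assert abs(per_condition.loc["control", "excess_kurtosis"]) < 0.1
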