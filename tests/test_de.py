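"""Normalization, differential tests, DE criterion and the ddCt calculator."""

import numpy as np
import pandas as pd
import pytest

from plaqomics.de import (
    OmicsMatrix,
    ddct,
    fpkm,
    nb_test,
    protein_test,
    size_factors,
)
from plaqomics.simulate import SimConfig, simulate_counts


def matrix(values, groups=None, layer="mrna"):
    df = pd.DataFrame(values)
    df.index = [f"f{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    if groups is None:
        half = df.shape[1] // 2
        groups = ["stable"] * half + ["unstable"] * (df.shape[1] - half)
    return OmicsMatrix(
        values=df, groups=pd.Series(groups, index=df.columns), layer=layer
    )


class TestOmicsMatrix:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            matrix([[1, -2], [3, 4]])

    def test_missing_group_label_rejected(self):
        df = pd.DataFrame([[1, 2]], columns=["a", "b"])
        with pytest.raises(ValueError):
            OmicsMatrix(values=df, groups=pd.Series({"a": "stable"}))

    def test_tsv_round_trip(self, tmp_path):
        om = matrix([[1, 2, 3, 4], [5, 6, 7, 8]])
        om.to_tsv(tmp_path / "m.tsv", tmp_path / "s.tsv")
        back = OmicsMatrix.from_tsv(tmp_path / "m.tsv", tmp_path / "s.tsv")
        assert back.values.equals(om.values)
        assert (back.groups == om.groups).all()


class TestSizeFactors:
    def test_doubled_column_closed_form(self):
        # column2 = 2 x column1 exactly: factors proportional to (1, 2),
        # rescaled to geometric mean 1 -> (1/sqrt(2), sqrt(2))
        rng = np.random.default_rng(41)
        col = rng.integers(1, 500, size=100)
        om = matrix(np.column_stack([col, 2 * col]), groups=["stable", "unstable"])
        sf = size_factors(om)
        assert sf.to_numpy() == pytest.approx(
            [1 / np.sqrt(2), np.sqrt(2)], rel=1e-12
        )

    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 51)
        om = matrix(np.column_stack([col, col, col]),
                    groups=["stable", "stable", "unstable"])
        assert size_factors(om).to_numpy() == pytest.approx([1, 1, 1])

    def test_single_sample_factor_one(self):
        om = matrix(np.arange(1, 11).reshape(-1, 1), groups=["stable"])
        assert size_factors(om).to_numpy() == pytest.approx([1.0])

    def test_fallback_to_library_size_with_warning(self):
        om = matrix([[0, 4], [6, 0]], groups=["stable", "unstable"])
        with pytest.warns(RuntimeWarning):
            sf = size_factors(om)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)


class TestFpkm:
    def test_hand_computed_example(self):
        # count 10, length 1 kb, library 1e6 -> FPKM 10
        values = np.zeros((2, 1))
        values[0, 0] = 10
        values[1, 0] = 1e6 - 10
        om = matrix(values, groups=["stable"])
        lengths = pd.Series([1000, 500], index=om.feature_ids)
        out = fpkm(om, lengths)
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm_and_length_proportionality(self):
        om = matrix([[0, 10], [10, 10]], groups=["stable", "unstable"])
        lengths = pd.Series([1000, 2000], index=om.feature_ids)
        out = fpkm(om, lengths)
        assert out.iloc[0, 0] == 0.0
        doubled = fpkm(om, lengths * 2)
        assert np.allclose(doubled.to_numpy(), out.to_numpy() / 2)

    def test_zero_library_column_all_zero(self):
        om = matrix([[0, 5], [0, 5]], groups=["stable", "unstable"])
        out = fpkm(om, pd.Series([100, 100], index=om.feature_ids))
        assert (out["s0"] == 0).all()

    def test_nonpositive_length_rejected(self):
        om = matrix([[1, 2]], groups=["stable", "unstable"])
        with pytest.raises(ValueError):
            fpkm(om, pd.Series([0], index=om.feature_ids))


class TestNbTest:
    def test_all_zero_feature_not_de(self):
        rng = np.random.default_rng(42)
        values = rng.integers(10, 100, size=(5, 10))
        values[0, :] = 0
        om = matrix(values)
        res = nb_test(om)
        assert res.iloc[0]["pvalue"] == 1.0
        assert res.iloc[0]["log2FoldChange"] == 0.0
        assert not res.iloc[0]["is_de"]

    def test_group_swap_negates_lfc_keeps_p(self):
        om, _ = simulate_counts(SimConfig(seed=43, n_features=200, frac_de=0.2))
        res = nb_test(om)
        swapped = nb_test(om, group_a="unstable", group_b="stable")
        assert np.allclose(
            res["log2FoldChange"], -swapped["log2FoldChange"], atol=1e-12
        )
        assert np.allclose(res["pvalue"], swapped["pvalue"], atol=1e-12)

    def test_bh_q_dominates_p_and_respects_criterion(self):
        om, _ = simulate_counts(SimConfig(seed=44, n_features=500, frac_de=0.1))
        res = nb_test(om)
        assert (res["qvalue"] >= res["pvalue"] - 1e-12).all()
        # is_de is exactly the printed criterion on raw p
        expected = (res["log2FoldChange"].abs() > 1.0) & (res["pvalue"] < 0.05)
        assert (res["is_de"] == expected).all()

    def test_planted_effects_recovered(self):
        cfg = SimConfig(seed=45, n_features=1000, frac_de=0.1, planted_lfc=2.0,
                        nb_dispersion=0.1)
        om, truth = simulate_counts(cfg)
        res = nb_test(om)
        recovered = set(res.index[res["is_de"]]) & set(truth.de_features)
        assert len(recovered) / len(truth.de_features) >= 0.8

    def test_requires_two_samples_per_group(self):
        om = matrix([[1, 2], [3, 4]], groups=["stable", "unstable"])
        with pytest.raises(ValueError):
            nb_test(om)


class TestProteinTest:
    def test_identical_groups_not_de(self):
        col = np.full(5, 1000.0)
        om = matrix(np.tile(col, (10, 1)).T.reshape(5, 10) * 0 + 1000.0,
                    layer="protein")
        res = protein_test(om)
        assert (res["log2FoldChange"] == 0).all()
        assert not res["is_de"].any()

    def test_fourfold_ratio_gives_lfc_two(self):
        rng = np.random.default_rng(46)
        base = rng.uniform(100, 200, size=(20, 5))
        values = np.concatenate([base, 4 * base], axis=1)
        om = matrix(values, layer="protein")
        res = protein_test(om)
        # exact in log2 space only when within-group spread cancels; the
        # construction makes group2 exactly 4x group1 sample-wise
        assert res["log2FoldChange"].to_numpy() == pytest.approx(2.0, abs=1e-9)

    def test_all_missing_protein_flagged_and_excluded_from_q(self):
        values = np.abs(np.random.default_rng(47).normal(1000, 10, (3, 10)))
        values[0, :] = 0.0
        om = matrix(values, layer="protein")
        res = protein_test(om)
        assert res.iloc[0]["low_n"]
        assert not res.iloc[0]["is_de"]
        assert np.isnan(res.iloc[0]["qvalue"])

    def test_zeros_treated_as_missing_not_values(self):
        rng = np.random.default_rng(48)
        values = rng.uniform(500, 600, size=(2, 10))
        values[0, 0] = 0.0  # one missing observation, still testable
        om = matrix(values, layer="protein")
        res = protein_test(om)
        assert not res.iloc[0]["low_n"]
        assert np.isfinite(res.iloc[0]["pvalue"])


class TestDdct:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])

    def test_worked_case_fold_four(self):
        # target 20 / ref 15 in unstable; target 22 / ref 15 in stable:
        # ddCt = (20-15) - (22-15) = -2 -> fold 4
        rows = []
        for s in range(3):
            rows += [
                (f"u{s}", "unstable", "TGT", 20.0),
                (f"u{s}", "unstable", "REF", 15.0),
                (f"s{s}", "stable", "TGT", 22.0),
                (f"s{s}", "stable", "REF", 15.0),
            ]
        res = ddct(self.table(rows), target="TGT", reference="REF")
        fold = dict(zip(res["group"], res["fold_change"]))
        assert fold["stable"] == pytest.approx(1.0)
        assert fold["unstable"] == pytest.approx(4.0)

    def test_zero_ddct_fold_one(self):
        rows = [
            ("u1", "unstable", "TGT", 21.0), ("u1", "unstable", "REF", 16.0),
            ("s1", "stable", "TGT", 25.0), ("s1", "stable", "REF", 20.0),
        ]
        res = ddct(self.table(rows), target="TGT", reference="REF")
        assert res["fold_change"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_per_sample_shift_invariance(self):
        rows = [
            ("u1", "unstable", "TGT", 20.0), ("u1", "unstable", "REF", 15.0),
            ("s1", "stable", "TGT", 22.0), ("s1", "stable", "REF", 15.0),
        ]
        base = ddct(self.table(rows), target="TGT", reference="REF")
        shifted_rows = [
            (s, g, gene, ct + (3.0 if s == "u1" else 0.0))
            for s, g, gene, ct in rows
        ]
        shifted = ddct(self.table(shifted_rows), target="TGT", reference="REF")
        assert np.allclose(base["fold_change"], shifted["fold_change"])

    def test_missing_reference_sample_dropped_with_warning(self):
        rows = [
            ("u1", "unstable", "TGT", 20.0), ("u1", "unstable", "REF", 15.0),
            ("u2", "unstable", "TGT", 19.0),  # no reference Ct
            ("s1", "stable", "TGT", 22.0), ("s1", "stable", "REF", 15.0),
        ]
        with pytest.warns(RuntimeWarning):
            res = ddct(self.table(rows), target="TGT", reference="REF")
        fold = dict(zip(res["group"], res["fold_change"]))
        assert fold["unstable"] == pytest.approx(4.0)
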