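import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subsea.data import CNVMatrix, MutationTable, SubtypeAnnotation
from subsea.genomic import (binarize_mutations, filter_by_frequency,
                            subtype_specific_cnv, subtype_specific_mutations)


def _table(rows):
    return MutationTable(pd.DataFrame(rows, columns=[
        "Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]))


def _subtypes(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return SubtypeAnnotation(pd.Series(labels, index=ids))


class TestBinarize:
    def test_multiple_hits_collapse_to_one(self):
        t = _table([("s1", "TP53", "Missense_Mutation"),
                    ("s1", "TP53", "Missense_Mutation")])
        mat = binarize_mutations(t, ["s1", "s2"])
        assert mat.loc["TP53", "s1"] == 1
        assert mat.loc["TP53", "s2"] == 0

    def test_empty_table_gives_zero_matrix(self):
        t = _table([])
        with pytest.warns(UserWarning, match="all zero"):
            mat = binarize_mutations(t, ["s1", "s2"])
        assert mat.shape == (0, 2)

    def test_silent_variants_do_not_qualify(self):
        t = _table([("s1", "TP53", "Silent")])
        with pytest.warns(UserWarning):
            mat = binarize_mutations(t, ["s1"])
        assert (mat.to_numpy() == 0).all()

    def test_matches_counting_oracle(self, rng):
        genes = [f"g{i}" for i in range(8)]
        samples = [f"s{i}" for i in range(12)]
        rows = [(rng.choice(samples), rng.choice(genes), "Missense_Mutation")
                for _ in range(60)]
        mat = binarize_mutations(_table(rows), samples)
        for g in mat.index:
            for s in samples:
                expected = any(r[0] == s and r[1] == g for r in rows)
                assert mat.loc[g, s] == int(expected)

    def test_idempotent_indicator(self, rng):
        rows = [(f"s{i % 5}", f"g{i % 3}", "Missense_Mutation") for i in range(20)]
        mat = binarize_mutations(_table(rows), [f"s{i}" for i in range(5)])
        pd.testing.assert_frame_equal((mat > 0).astype(int), mat)


class TestFrequencyFilter:
    def test_strict_inequality_boundary(self):
        mat = pd.DataFrame(0, index=["g1", "g2", "g3"], columns=[f"s{i}" for i in range(100)])
        mat.iloc[0, :2] = 1   # 2% -> kept
        mat.iloc[1, :1] = 1   # exactly 1% -> dropped
        kept = filter_by_frequency(mat, min_rate=0.01)
        assert kept == ["g1"]

    def test_enumeration_toy(self):
        mat = pd.DataFrame(0, index=["a", "b", "c"], columns=[f"s{i}" for i in range(100)])
        mat.loc["a", ["s0", "s1"]] = 1
        mat.loc["b", "s0"] = 1
        assert filter_by_frequency(mat, 0.01) == ["a"]

    def test_invalid_rate(self):
        mat = pd.DataFrame([[1]], index=["g"], columns=["s"])
        with pytest.raises(ValueError):
            filter_by_frequency(mat, 0.0)


class TestMutationSpecificity:
    def test_uniform_exact_rates_give_p_one(self):
        # identical 50% rate in both subtypes
        mat = pd.DataFrame([[1, 0, 1, 0, 1, 0, 1, 0]], index=["g"],
                           columns=[f"s{i}" for i in range(8)])
        sub = _subtypes(["A"] * 4 + ["B"] * 4)
        out = subtype_specific_mutations(mat, sub)
        assert out.loc[0, "chi2"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_fully_separated_two_by_two(self):
        # 10/10 mutated in A, 0/10 in B -> chi2 = 20 without correction
        mat = pd.DataFrame([[1] * 10 + [0] * 10], index=["g"],
                           columns=[f"s{i}" for i in range(20)])
        sub = _subtypes(["A"] * 10 + ["B"] * 10)
        out = subtype_specific_mutations(mat, sub)
        assert out.loc[0, "chi2"] == pytest.approx(20.0)
        assert out.loc[0, "p"] == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-6)

    def test_degenerate_genes_excluded(self):
        mat = pd.DataFrame([[1, 1, 1, 1], [0, 0, 0, 0], [1, 0, 1, 0]],
                           index=["all", "none", "ok"],
                           columns=[f"s{i}" for i in range(4)])
        sub = _subtypes(["A", "A", "B", "B"])
        out = subtype_specific_mutations(mat, sub)
        assert set(out["gene"]) == {"ok"}

    def test_order_invariance(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, (5, 30)),
                           index=[f"g{i}" for i in range(5)],
                           columns=[f"s{i}" for i in range(30)])
        mat.iloc[:, 0] = [1, 0, 1, 0, 1]  # avoid degenerate rows
        mat.iloc[:, 1] = [0, 1, 0, 1, 0]
        sub = _subtypes(["A"] * 15 + ["B"] * 15)
        out1 = subtype_specific_mutations(mat, sub)
        shuffled = mat.iloc[rng.permutation(5), rng.permutation(30)]
        out2 = subtype_specific_mutations(shuffled, sub)
        merged = out1.merge(out2, on="gene", suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["chi2_1"], merged["chi2_2"])

    def test_unlabeled_samples_rejected(self):
        mat = pd.DataFrame([[1, 0]], index=["g"], columns=["s0", "sX"])
        sub = _subtypes(["A", "A", "B", "B"], ids=["s0", "s1", "s2", "s3"])
        with pytest.raises(ValueError, match="without subtype"):
            subtype_specific_mutations(mat, sub)


class TestCNVSpecificity:
    def test_all_neutral_empty_results(self):
        cnv = CNVMatrix(pd.DataFrame(0, index=["g1", "g2"],
                                     columns=[f"s{i}" for i in range(8)]))
        sub = _subtypes(["A"] * 4 + ["B"] * 4)
        amp, dele = subtype_specific_cnv(cnv, sub)
        assert amp.empty and dele.empty

    def test_planted_amplification_directionality(self):
        vals = pd.DataFrame(0, index=["gAmp"], columns=[f"s{i}" for i in range(20)])
        vals.iloc[0, :8] = 2  # amplified only in subtype A
        cnv = CNVMatrix(vals)
        sub = _subtypes(["A"] * 10 + ["B"] * 10)
        amp, dele = subtype_specific_cnv(cnv, sub)
        assert amp.loc[0, "gene"] == "gAmp" and bool(amp.loc[0, "specific"])
        assert dele.empty  # never deleted -> degenerate for the del family

    def test_mixed_amp_del_match_contingency_oracle(self, rng):
        n = 40
        sub = _subtypes(["A"] * 20 + ["B"] * 20)
        vals = rng.integers(-2, 3, (4, n))
        vals[0, :20] = 2  # planted amp in A
        vals[1, 20:] = -2  # planted del in B
        cnv = CNVMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(4)],
                                     columns=[f"s{i}" for i in range(n)]))
        amp, dele = subtype_specific_cnv(cnv, sub)
        labels = np.array(["A"] * 20 + ["B"] * 20)
        for frame, direction in ((amp, 1), (dele, -1)):
            for _, row in frame.iterrows():
                vec = cnv.values.loc[row["gene"]].to_numpy()
                ind = (vec * direction) > 0
                table = pd.crosstab(ind, labels)
                chi2 = stats.chi2_contingency(table, correction=False)[0]
                assert row["chi2"] == pytest.approx(chi2)

    def test_high_level_only_flag(self):
        vals = pd.DataFrame([[1, 1, 0, 0, 2, 2, 0, 0]], index=["g"],
                            columns=[f"s{i}" for i in range(8)])
        cnv = CNVMatrix(vals)
        sub = _subtypes(["A"] * 4 + ["B"] * 4)
        amp_all, _ = subtype_specific_cnv(cnv, sub)
        amp_high, _ = subtype_specific_cnv(cnv, sub, high_level_only=True)
        assert amp_all.loc[0, "n_A"] == 2 and amp_all.loc[0, "n_B"] == 2
        assert amp_high.loc[0, "n_A"] == 0 and amp_high.loc[0, "n_B"] == 2
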