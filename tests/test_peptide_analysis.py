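import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrforest import peptide_analysis as pa
from tcrforest.core_io import AMINO_ACIDS, ContractError, PairRecord


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook unit-cost Levenshtein DP, the independent oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


peptide = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=11)


class TestLevenshteinSimilarity:
    def test_identical_is_one(self):
        assert pa.levenshtein_similarity("GILGFVFTL", "GILGFVFTL") == 1.0

    def test_single_substitution(self):
        assert pa.levenshtein_similarity("GILGFVFTL", "GILGFVFTV") == pytest.approx(1 - 1 / 9)

    def test_totally_different_is_zero(self):
        assert pa.levenshtein_similarity("AAAAAAAA", "WWWWWWWW") == 0.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            pa.levenshtein_similarity("", "GILGFVFTL")

    @given(a=peptide, b=peptide)
    @settings(max_examples=200, deadline=None)
    def test_matches_dp_oracle_and_symmetry(self, a, b):
        s = pa.levenshtein_similarity(a, b)
        assert s == pytest.approx(1 - dp_edit_distance(a, b) / max(len(a), len(b)))
        assert s == pa.levenshtein_similarity(b, a)
        assert (s == 1.0) == (a == b)
        assert 0.0 <= s <= 1.0


class TestFpAttribution:
    def _eval_set(self, fp_peptides):
        """One TN + one FP per listed peptide occurrence."""
        records, probs, truth = [], [], []
        for pep in fp_peptides:
            records.append(PairRecord("CASSLGTDTQYF", pep))
            probs.append(0.9)
            truth.append(0)
        records.append(PairRecord("CASSLGTDTQYF", "YLQPRTFLLK"))
        probs.append(0.1)
        truth.append(0)
        return records, probs, truth

    def test_single_source_peptide_share_one(self):
        records, probs, truth = self._eval_set(["GILGFVFTL"] * 3)
        table, dominant = pa.fp_attribution(records, probs, truth)
        assert table.iloc[0]["fp_share"] == 1.0
        assert dominant == ["GILGFVFTL"]

    def test_even_split_cutoff_half(self):
        peps = ["GILGFVFTL", "NLVPMVATV", "GLCTLVAML", "ELAGIGILTV"]
        records, probs, truth = self._eval_set(peps * 2)   # 2 FPs each
        table, dominant = pa.fp_attribution(records, probs, truth, share_cutoff=0.5)
        assert len(dominant) == 2
        assert table["fp_share"].sum() == pytest.approx(1.0)

    def test_top_n_override(self):
        records, probs, truth = self._eval_set(
            ["GILGFVFTL"] * 5 + ["NLVPMVATV"] * 3 + ["GLCTLVAML"])
        _, dominant = pa.fp_attribution(records, probs, truth, top_n=2)
        assert dominant == ["GILGFVFTL", "NLVPMVATV"]

    def test_no_fps_flagged_empty(self):
        records = [PairRecord("CASSLGTDTQYF", "GILGFVFTL")]
        table, dominant = pa.fp_attribution(records, [0.1], [0])
        assert table.empty and dominant == []

    def test_counts_conserved(self, rng):
        peps = rng.choice(["GILGFVFTL", "NLVPMVATV", "GLCTLVAML"], size=200)
        records = [PairRecord("CASSLGTDTQYF", p) for p in peps]
        probs = rng.random(200)
        truth = rng.integers(0, 2, 200)
        table, _ = pa.fp_attribution(records, probs, truth)
        total_fp = int(((probs >= 0.5) & (truth == 0)).sum())
        assert int(table["n_fp"].sum()) == total_fp
        assert table["fp_share"].sum() == pytest.approx(1.0)


class TestClusterPeptides:
    def _family(self, stem, n):
        return [stem[:-1] + aa for aa in AMINO_ACIDS[:n]]

    def test_planted_families_recovered(self):
        fam_a = self._family("GILGFVFTL", 5)
        fam_b = self._family("QQWWEERRTYV", 5)
        assign, reps = pa.cluster_peptides(fam_a + fam_b, n_clusters=2, seed=0)
        a_ids = {assign[p] for p in fam_a}
        b_ids = {assign[p] for p in fam_b}
        assert len(a_ids) == len(b_ids) == 1 and a_ids != b_ids
        assert len(reps) == 2

    def test_singletons_when_k_equals_n(self):
        peps = self._family("GILGFVFTL", 4)
        assign, reps = pa.cluster_peptides(peps, n_clusters=4, seed=0)
        assert sorted(reps) == sorted(peps)
        assert len(set(assign.values())) == 4

    def test_deterministic_and_medoid_property(self):
        peps = self._family("GILGFVFTL", 6) + self._family("QQWWEERRTYV", 6)
        a1 = pa.cluster_peptides(peps, 3, seed=4)
        a2 = pa.cluster_peptides(peps, 3, seed=4)
        assert a1 == a2
        assign, reps = a1
        # each representative belongs to its own cluster
        for c, rep in enumerate(reps):
            assert assign[rep] == c

    def test_too_few_peptides(self):
        with pytest.raises(ValueError):
            pa.cluster_peptides(["GILGFVFTL"], n_clusters=2)


class TestSimilarityBins:
    def test_identical_proportions_rmse_zero(self):
        train = [PairRecord("CASSLGTDTQYF", "GILGFVFTL", label=1)]
        out = pa.similarity_bin_rmse("GILGFVFTV", train, representative_calls=[1])
        assert len(out) == 1
        assert out.iloc[0]["rmse"] == 0.0

    def test_orthogonal_proportions_closed_form(self):
        # training bin all-binding (1,0,0) vs predictions all-non-binding (0,1,0)
        train = [PairRecord("CASSLGTDTQYF", "GILGFVFTL", label=1)]
        out = pa.similarity_bin_rmse("GILGFVFTV", train, representative_calls=[0])
        assert out.iloc[0]["rmse"] == pytest.approx(np.sqrt(2 / 3))

    def test_mix_category_detected(self):
        train = [PairRecord("CASSLGTDTQYF", "GILGFVFTL", label=1),
                 PairRecord("CASSPGQGDYEQYF", "GILGFVFTL", label=0)]
        out = pa.similarity_bin_rmse("GILGFVFTV", train, representative_calls=[1, 0])
        assert out.iloc[0]["prop_mix"] == 1.0
        assert out.iloc[0]["rmse"] == 0.0        # representative called both ways = mix

    def test_empty_bins_omitted_single_row(self):
        # both training observations are of the same peptide -> one bin
        train = [PairRecord("CASSLGTDTQYF", "GILGFVFTL", label=1),
                 PairRecord("CASSPGQGDYEQYF", "GILGFVFTL", label=1)]
        out = pa.similarity_bin_rmse("GILGFVFTV", train, [1], bin_width=0.1)
        assert len(out) == 1
        assert out.iloc[0]["n_peptides"] == 1
        assert out.iloc[0]["bin_lo"] == pytest.approx(0.8)

    def test_no_training_peptides_is_error(self):
        with pytest.raises(ValueError):
            pa.similarity_bin_rmse("GILGFVFTL", [], [1])


class TestPeptideSpecificModel:
    def test_too_few_records_is_error(self):
        records = [PairRecord("CASSLGTDTQYF", "GILGFVFTL", label=1)] * 3
        with pytest.raises(ContractError):
            pa.train_peptide_specific_model(records, "GILGFVFTL")

    def test_single_class_is_error(self):
        records = [PairRecord(f"CASSLGTDTQ{aa}F", "GILGFVFTL", label=1)
                   for aa in AMINO_ACIDS[:12]]
        with pytest.raises(ContractError, match="single class"):
            pa.train_peptide_specific_model(records, "GILGFVFTL", min_records=10)
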