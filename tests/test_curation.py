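import pytest

from tcrforest import curation
from tcrforest.core_io import ContractError, PairRecord
from tcrforest.synthetic_data import SyntheticConfig, generate_repertoire


def _rec(cdr3b="CASSLGTDTQYF", peptide="GILGFVFTL", label=1, source=None):
    return PairRecord(cdr3b, peptide, label=label, source=source)


class TestMergeAndDeduplicate:
    def test_shared_pair_appears_once_with_merged_sources(self):
        a = [_rec(source="vdjdb")]
        b = [_rec(source="iedb"), _rec(peptide="NLVPMVATV", source="iedb")]
        c = [_rec(source="mcpas")]
        merged = curation.merge_and_deduplicate([a, b, c])
        assert len(merged) == 2
        assert merged[0].source == "vdjdb+iedb+mcpas"

    def test_disjoint_sources_concatenate(self):
        sources = [[_rec(peptide=f"GILGFVFT{aa}", label=1)
                    for aa in chunk]
                   for chunk in ("AC", "DEF", "GHIK", "LMNPQ", "RSTVWY")]
        merged = curation.merge_and_deduplicate(sources)
        assert len(merged) == 2 + 3 + 4 + 5 + 6

    def test_same_pair_opposite_labels_both_kept(self):
        merged = curation.merge_and_deduplicate([[_rec(label=1)], [_rec(label=0)]])
        assert len(merged) == 2     # conflict removal is a separate step


class TestRemoveConflicts:
    def test_conflicted_key_dropped_and_reported(self):
        records = [_rec(label=1), _rec(label=0), _rec(peptide="NLVPMVATV", label=1)]
        kept, report = curation.remove_conflicts(records)
        assert [r.peptide for r in kept] == ["NLVPMVATV"]
        assert report.removed_keys == [("CASSLGTDTQYF", "GILGFVFTL")]
        assert report.counts[("CASSLGTDTQYF", "GILGFVFTL")] == (1, 1)

    def test_no_conflicts_is_identity(self):
        records = [_rec(label=1), _rec(peptide="NLVPMVATV", label=0)]
        kept, report = curation.remove_conflicts(records)
        assert kept == records and report.removed_keys == []

    def test_exhaustive_over_keys(self):
        # 10 keys, 2 of them conflicted -> 8 survive; verified by scan
        records = []
        for i in range(10):
            pep = f"GILGFVFT{'ACDEFGHIKL'[i]}"
            records.append(_rec(peptide=pep, label=1))
            if i < 2:
                records.append(_rec(peptide=pep, label=0))
        kept, report = curation.remove_conflicts(records)
        assert len({r.key() for r in kept}) == 8
        assert len(report.removed_keys) == 2
        labels_by_key = {}
        for r in kept:
            labels_by_key.setdefault(r.key(), set()).add(r.label)
        assert all(len(v) == 1 for v in labels_by_key.values())

    def test_mhc_mode_key_includes_allele(self):
        from tcrforest.core_io import parse_hla_name
        a = PairRecord("CASSLGTDTQYF", "GILGFVFTL", hla=parse_hla_name("A0201"), label=1)
        b = PairRecord("CASSLGTDTQYF", "GILGFVFTL", hla=parse_hla_name("A0101"), label=0)
        kept, _ = curation.remove_conflicts([a, b], with_mhc=True)
        assert len(kept) == 2       # different alleles: no conflict


class TestMakeSubsets:
    @pytest.fixture(scope="class")
    def records(self):
        recs, _ = generate_repertoire(SyntheticConfig(n_pairs=330, seed=3))
        unique = curation.merge_and_deduplicate([recs])
        kept, _ = curation.remove_conflicts(unique)
        return kept

    def test_sizes_and_disjointness(self, records):
        ds = curation.make_subsets(records, size_range=(50, 60), n_subsets=5, seed=7)
        subsets = [ds.train] + ds.tests
        assert len(subsets) == 5
        assert all(50 <= len(s) <= 60 for s in subsets)
        keys = [frozenset(r.key() for r in s) for s in subsets]
        for i in range(5):
            for j in range(i + 1, 5):
                assert not keys[i] & keys[j]

    def test_deterministic_under_seed(self, records):
        a = curation.make_subsets(records, (50, 60), 5, seed=7)
        b = curation.make_subsets(records, (50, 60), 5, seed=7)
        assert a.train == b.train and a.tests == b.tests

    def test_insufficient_records_is_error(self, records):
        with pytest.raises(ContractError):
            curation.make_subsets(records, (100, 110), 5, seed=7)

    def test_peptide_diversity_spread(self, records):
        # stratification at near-full capacity: frequent peptides reach
        # every subset via proportional round-robin dealing
        ds = curation.make_subsets(records, (100, 110), 3, seed=7)
        from collections import Counter
        frequent = {p for p, n in Counter(r.peptide for r in records).items() if n >= 4}
        assert frequent
        for s in [ds.train] + ds.tests:
            peps = {r.peptide for r in s}
            missing = frequent - peps
            assert len(missing) <= max(1, len(frequent) // 10)


class TestSampleNegatives:
    def _records(self, n_pos, n_neg):
        pos = [_rec(peptide="GILGFVFTL", cdr3b=f"CASSLGTDTQ{'ACDEFGHIKLMNPQRSTVWY'[i % 20]}F", label=1)
               for i in range(n_pos)]
        neg = [_rec(peptide="NLVPMVATV", cdr3b="CAS" + "ACDEFGHIKLMNPQRSTVWY"[i % 20] * 6, label=0)
               for i in range(n_neg)]
        return pos + neg

    def test_exact_ratio_when_pool_suffices(self):
        recs, _ = generate_repertoire(SyntheticConfig(n_pairs=5000, seed=5))
        out = curation.sample_negatives(recs, ratio=10, seed=1)
        n_pos = sum(r.label for r in recs)
        assert sum(r.label == 1 for r in out) == n_pos        # no positive dropped
        assert sum(r.label == 0 for r in out) == 10 * n_pos   # exactly 10x

    def test_pool_smaller_than_quota_keeps_all(self):
        recs = self._records(100, 500)
        out = curation.sample_negatives(recs, ratio=10, seed=0)
        assert len(out) == 600

    def test_bad_ratio_is_error(self):
        with pytest.raises(ValueError):
            curation.sample_negatives(self._records(2, 2), ratio=0)

    def test_deterministic(self):
        recs, _ = generate_repertoire(SyntheticConfig(n_pairs=2000, seed=5))
        assert (curation.sample_negatives(recs, 10, seed=9)
                == curation.sample_negatives(recs, 10, seed=9))


class TestWildtypeNegatives:
    peptides = [f"SIINFEKL{aa}" for aa in "ACDEFGHIKL"]
    tcrs = [f"CASSLGTDT{aa}YF" for aa in "ACDEFGHIKL"]

    def test_unique_label0_pairs(self):
        out = curation.generate_wildtype_negatives(self.peptides, self.tcrs, 50, seed=1)
        assert len(out) == 50
        assert all(r.label == 0 and r.source == "generated-wildtype" for r in out)
        assert len({(r.cdr3b, r.peptide) for r in out}) == 50

    def test_capacity_exceeded_is_error(self):
        with pytest.raises(ValueError):
            curation.generate_wildtype_negatives(self.peptides, self.tcrs, 101, seed=1)

    def test_collisions_with_known_pairs_avoided(self):
        known = [PairRecord(t, p, label=1) for t in self.tcrs for p in self.peptides[:5]]
        out = curation.generate_wildtype_negatives(
            self.peptides, self.tcrs, 50, seed=1, exclude=known)
        forbidden = {(r.cdr3b, r.peptide) for r in known}
        assert all((r.cdr3b, r.peptide) not in forbidden for r in out)


class TestUnseenPeptideSplit:
    @pytest.fixture(scope="class")
    def records(self):
        recs, _ = generate_repertoire(
            SyntheticConfig(n_pairs=3000, binding_fraction=0.1,
                            n_distinct_peptides=100, seed=13))
        kept, _ = curation.remove_conflicts(recs)
        return kept

    def test_peptides_partitioned_not_observations(self, records):
        split = curation.unseen_peptide_split(records, 0.8, seed=2, n_test_sets=3)
        train_peps = {r.peptide for r in split.train}
        for t in split.tests:
            assert not train_peps & {r.peptide for r in t}
        # every observation follows its peptide's side
        n = len(split.train) + sum(map(len, split.tests))
        assert n == len(records)

    def test_train_fraction_of_peptides(self, records):
        split = curation.unseen_peptide_split(records, 0.8, seed=2)
        train_peps = {r.peptide for r in split.train}
        test_peps = set().union(*({r.peptide for r in t} for t in split.tests))
        frac = len(train_peps) / (len(train_peps) + len(test_peps))
        assert abs(frac - 0.8) < 0.05

    def test_category_stratification_includes_generated(self, records):
        wt = curation.generate_wildtype_negatives(
            [f"LLFGYPVY{aa}" for aa in "ACDEFGHIKLMNPQRSTVWY"],
            [r.cdr3b for r in records[:50]], 100, seed=4)
        split = curation.unseen_peptide_split(records, 0.8, wildtype_negatives=wt, seed=2)
        train_sources = {r.source for r in split.train}
        test_sources = set().union(*({r.source for r in t} for t in split.tests))
        assert "generated-wildtype" in train_sources
        assert "generated-wildtype" in test_sources

    def test_deterministic(self, records):
        a = curation.unseen_peptide_split(records, 0.8, seed=2)
        b = curation.unseen_peptide_split(records, 0.8, seed=2)
        assert a.train == b.train and a.tests == b.tests

    def test_too_few_peptides_is_error(self):
        records = [_rec(peptide="GILGFVFTL", label=1),
                   _rec(peptide="NLVPMVATV", label=0)]
        with pytest.raises(ContractError):
            curation.unseen_peptide_split(records, 0.8)
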