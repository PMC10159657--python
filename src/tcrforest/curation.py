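"""Merging, deduplication, conflict removal, splitting and class balancing.

Mirrors the preprocessing of a multi-database TCR–peptide collection:
per-source tables are merged into a non-redundant, non-conflicted pair
list, cut into disjoint peptide-diverse subsets for training/testing, and
class-balanced by downsampling the (vastly larger) non-binding class to a
fixed binding:non-binding ratio. A peptide-disjoint splitter supports the
unseen-peptide generalization experiment, with generated "wild-type"
negatives to balance the peptide categories.

The duplicate/conflict key is (cdr3b, peptide) without MHC and
(cdr3b, peptide, hla) with MHC. All randomized operations are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field

from .core_io import ContractError, PairRecord, require_valid


@dataclass
class ConflictReport:
    removed_keys: list[tuple] = field(default_factory=list)
    counts: dict[tuple, tuple[int, int]] = field(default_factory=dict)  # key -> (n_pos, n_neg)


@dataclass
class DatasetSplit:
    train: list[PairRecord]
    tests: list[list[PairRecord]]
    seed: int
    mode: str  # "with-MHC" | "without-MHC"


@dataclass
class UnseenPeptideSplit:
    train: list[PairRecord]
    tests: list[list[PairRecord]]
    train_peptide_fraction: float


def merge_and_deduplicate(sources: list[list[PairRecord]],
                          with_mhc: bool = False) -> list[PairRecord]:
    """Merge sources keeping each (key, label) combination once.

    Source tags of merged duplicates are concatenated with ``+`` in first-seen
    order, so provenance survives deduplication.
    """
    seen: dict[tuple, int] = {}
    out: list[PairRecord] = []
    for source in sources:
        for rec in require_valid(source):
            k = rec.key(with_mhc) + (rec.label,)
            if k in seen:
                prev = out[seen[k]]
                tags = [t for t in (prev.source or "").split("+") if t]
                if rec.source and rec.source not in tags:
                    tags.append(rec.source)
                out[seen[k]] = PairRecord(cdr3b=prev.cdr3b, peptide=prev.peptide,
                                          hla=prev.hla, label=prev.label,
                                          source="+".join(tags) or None,
                                          proba=prev.proba)
            else:
                seen[k] = len(out)
                out.append(rec)
    return out


def remove_conflicts(records: list[PairRecord],
                     with_mhc: bool = False) -> tuple[list[PairRecord], ConflictReport]:
    """Drop every key observed with both labels; report the removed keys.

    Both sides of a conflicted key are removed — keeping either would inject
    label noise with no principled tiebreak.
    """
    labels_by_key: dict[tuple, set[int]] = defaultdict(set)
    counts: dict[tuple, list[int]] = defaultdict(lambda: [0, 0])
    for rec in records:
        k = rec.key(with_mhc)
        if rec.label is not None:
            labels_by_key[k].add(rec.label)
            if rec.label == 1:
                counts[k][0] += 1
            else:
                counts[k][1] += 1
    conflicted = {k for k, labs in labels_by_key.items() if labs >= {0, 1}}
    kept = [rec for rec in records if rec.key(with_mhc) not in conflicted]
    report = ConflictReport(
        removed_keys=sorted(conflicted),
        counts={k: tuple(counts[k]) for k in sorted(conflicted)},
    )
    return kept, report


def make_subsets(records: list[PairRecord],
                 size_range: tuple[int, int] = (70_000, 75_000),
                 n_subsets: int = 2,
                 seed: int = 0,
                 with_mhc: bool = False) -> DatasetSplit:
    """Cut disjoint, peptide-diverse random subsets of bounded size.

    Stratified on peptide identity: each peptide's records are dealt
    round-robin across subsets (proportional allocation), so every subset
    sees close to the global peptide spectrum. Subsets are filled to a
    common target size within ``size_range``; leftover records stay
    unassigned. First subset is train, the rest are tests.
    """
    lo, hi = size_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid size_range")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if len(records) < n_subsets * lo:
        raise ContractError(
            f"{len(records)} records cannot fill {n_subsets} subsets of >= {lo}")
    keys = [r.key(with_mhc) for r in records]
    if len(set(keys)) != len(keys):
        raise ContractError(
            "records contain duplicate keys; curate first "
            "(merge_and_deduplicate + remove_conflicts)")
    target = min(hi, len(records) // n_subsets)

    rng = random.Random(seed)
    by_peptide: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        by_peptide[rec.peptide].append(i)
    peptides = sorted(by_peptide)
    rng.shuffle(peptides)

    # proportional (largest-remainder-free) allocation: every peptide
    # contributes ~capacity/|records| of its observations, dealt round-robin
    capacity = target * n_subsets
    frac = capacity / len(records)
    subsets: list[list[PairRecord]] = [[] for _ in range(n_subsets)]
    cursor = rng.randrange(n_subsets)
    cum = 0.0
    for pep in peptides:
        idxs = by_peptide[pep]
        rng.shuffle(idxs)
        start = cum
        cum += len(idxs) * frac
        quota = int(cum + 1e-9) - int(start + 1e-9)
        for i in idxs[:quota]:
            for _ in range(n_subsets):      # skip full subsets
                if len(subsets[cursor]) < target:
                    break
                cursor = (cursor + 1) % n_subsets
            else:
                break
            subsets[cursor].append(records[i])
            cursor = (cursor + 1) % n_subsets

    assert all(lo <= len(s) <= hi for s in subsets)
    _assert_disjoint([[r.key(with_mhc) for r in s] for s in subsets])
    return DatasetSplit(train=subsets[0], tests=subsets[1:], seed=seed,
                        mode="with-MHC" if with_mhc else "without-MHC")


def _assert_disjoint(key_lists: list[list[tuple]]) -> None:
    seen: set[tuple] = set()
    for keys in key_lists:
        ks = set(keys)
        inter = seen & ks
        if inter:
            raise AssertionError(f"subsets share keys, e.g. {next(iter(inter))}")
        seen |= ks


def sample_negatives(records: list[PairRecord], ratio: float = 10,
                     seed: int = 0) -> list[PairRecord]:
    """Downsample non-binding records to ``ratio`` × the binding count.

    Every binding record is kept; non-binding records are drawn uniformly
    without replacement (all of them when the pool is smaller than the
    quota). Output preserves the input's relative order.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    pos_idx = [i for i, r in enumerate(records) if r.label == 1]
    neg_idx = [i for i, r in enumerate(records) if r.label == 0]
    if not pos_idx or not neg_idx:
        raise ContractError("need both binding and non-binding records")
    quota = int(ratio * len(pos_idx))
    rng = random.Random(seed)
    keep_neg = set(neg_idx) if len(neg_idx) <= quota else set(rng.sample(neg_idx, quota))
    keep = set(pos_idx) | keep_neg
    return [r for i, r in enumerate(records) if i in keep]


def peptide_category(peptide: str, records_by_peptide: dict[str, list[PairRecord]]) -> str:
    """binding / non-binding / mix / generated, by the peptide's observations."""
    recs = records_by_peptide[peptide]
    if all((r.source or "").startswith("generated") for r in recs):
        return "generated"
    labels = {r.label for r in recs}
    if labels >= {0, 1}:
        return "mix"
    return "binding" if labels == {1} else "non-binding"


def generate_wildtype_negatives(wildtype_peptides: list[str],
                                known_tcrs: list[str],
                                n_pairs: int,
                                seed: int = 0,
                                exclude: list[PairRecord] | None = None) -> list[PairRecord]:
    """Random non-binding pairs from unmutated self peptides × known TCRs.

    The self-tolerance assumption — wild-type peptides do not elicit T-cell
    responses — lets these pairs serve as label-0 ground truth. Sampled
    combinations are unique and never collide with a supplied labeled pair.
    """
    if not wildtype_peptides or not known_tcrs:
        raise ValueError("both peptide and TCR lists must be non-empty")
    forbidden = {(r.cdr3b, r.peptide) for r in (exclude or [])}
    capacity = len(wildtype_peptides) * len(known_tcrs) - len(forbidden)
    if n_pairs > capacity:
        raise ValueError(f"n_pairs={n_pairs} exceeds {capacity} available combinations")
    rng = random.Random(seed)
    chosen: set[tuple[str, str]] = set()
    out: list[PairRecord] = []
    while len(out) < n_pairs:
        pair = (rng.choice(known_tcrs), rng.choice(wildtype_peptides))
        if pair in chosen or pair in forbidden:
            continue
        chosen.add(pair)
        out.append(PairRecord(cdr3b=pair[0], peptide=pair[1], label=0,
                              source="generated-wildtype"))
    return out


def unseen_peptide_split(records: list[PairRecord],
                         train_peptide_fraction: float = 0.8,
                         wildtype_negatives: list[PairRecord] | None = None,
                         n_test_sets: int = 1,
                         seed: int = 0) -> UnseenPeptideSplit:
    """Partition by peptide, not by observation: test peptides are unseen.

    The train/test cut is stratified over the four peptide categories
    (mix / binding-only / non-binding-only / generated wild-type) so the
    training peptide set stays balanced across them. Every observation
    follows its peptide's side; generated negatives join the pool first.
    """
    if not 0 < train_peptide_fraction < 1:
        raise ValueError("train_peptide_fraction must be in (0,1)")
    pool = list(records) + list(wildtype_negatives or [])
    by_peptide: dict[str, list[PairRecord]] = defaultdict(list)
    for rec in pool:
        by_peptide[rec.peptide].append(rec)
    peptides = sorted(by_peptide)
    if len(peptides) < 10:
        raise ContractError(f"only {len(peptides)} distinct peptides; need >= 10")

    rng = random.Random(seed)
    by_category: dict[str, list[str]] = defaultdict(list)
    for pep in peptides:
        by_category[peptide_category(pep, by_peptide)].append(pep)

    train_peps: set[str] = set()
    test_peps: list[str] = []
    for cat in sorted(by_category):
        peps = by_category[cat]
        rng.shuffle(peps)
        n_train = round(train_peptide_fraction * len(peps))
        train_peps.update(peps[:n_train])
        test_peps.extend(peps[n_train:])

    train = [r for pep in sorted(train_peps) for r in by_peptide[pep]]
    rng.shuffle(test_peps)
    tests: list[list[PairRecord]] = [[] for _ in range(n_test_sets)]
    for i, pep in enumerate(test_peps):
        tests[i % n_test_sets].extend(by_peptide[pep])

    for t in tests:
        overlap = train_peps & {r.peptide for r in t}
        assert not overlap, f"peptide leak: {overlap}"
    return UnseenPeptideSplit(train=train, tests=tests,
                              train_peptide_fraction=train_peptide_fraction)
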