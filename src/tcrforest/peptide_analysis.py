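"""Dominant-peptide attribution, ratio titration, per-peptide models, and
peptide-similarity analyses.

A small number of over-represented ("dominant") epitopes can account for
most false-positive predictions. This module makes that diagnosis
quantitative: per-peptide false-positive attribution with a cumulative-
share dominant set, retraining experiments that titrate the
binding:non-binding ratio of the chosen peptides while leaving all other
records untouched, peptide-specific models, and Levenshtein-similarity
clustering/binning of peptides with label-proportion RMSE against a
representative's predictions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Sequence

import edlib
import numpy as np
import pandas as pd

from . import classifier as clf
from .classifier import TrainedModel
from .core_io import ContractError, PairRecord
from .encoding import PseudoSequenceMap, SubstitutionMatrix, encode_batch
from .evaluation import EvalReport, metrics_report

LABEL_CATEGORIES = ("binding", "non-binding", "mix")


# ---------------------------------------------------------------- FP attribution

def fp_attribution(records: Sequence[PairRecord], probabilities, truth,
                   threshold: float = 0.5,
                   top_n: int | None = None,
                   share_cutoff: float = 0.95) -> tuple[pd.DataFrame, list[str]]:
    """Attribute false positives to peptides; find the dominant set.

    Returns a per-peptide table (n_pairs, n_binding, n_fp, fp_share,
    binding_share, sorted by n_fp descending) and the dominant set: the
    ``top_n`` peptides, or else the smallest prefix whose cumulative
    fp_share reaches ``share_cutoff``. With zero false positives the table
    is empty and the dominant set empty (flagged, not an error).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(truth, dtype=int)
    if not (len(records) == p.size == t.size):
        raise ValueError("records, probabilities, truth must align")
    calls = clf.classify(p, threshold)
    rows: dict[str, dict] = {}
    total_binding = int((t == 1).sum())
    for rec, call, tr in zip(records, calls, t):
        row = rows.setdefault(rec.peptide,
                              {"peptide": rec.peptide, "n_pairs": 0,
                               "n_binding": 0, "n_fp": 0})
        row["n_pairs"] += 1
        row["n_binding"] += int(tr == 1)
        row["n_fp"] += int(call == 1 and tr == 0)
    table = pd.DataFrame(sorted(rows.values(),
                                key=lambda r: (-r["n_fp"], r["peptide"])))
    total_fp = int(table["n_fp"].sum())
    if total_fp == 0:
        return table.iloc[0:0], []
    table["fp_share"] = table["n_fp"] / total_fp
    table["binding_share"] = (table["n_binding"] / total_binding
                              if total_binding else 0.0)
    if top_n is not None:
        dominant = table["peptide"].head(top_n).tolist()
    else:
        cum = table["fp_share"].cumsum()
        n_dom = int(np.searchsorted(cum.values, share_cutoff - 1e-12) + 1)
        dominant = table["peptide"].head(n_dom).tolist()
    return table, dominant


# ---------------------------------------------------------------- ratio titration

def _retarget_ratio(records: list[PairRecord], target_ratio: float,
                    rng: random.Random) -> list[PairRecord]:
    """Downsample one class of ``records`` to binding:non-binding = target."""
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if not pos or not neg:
        raise ContractError("chosen peptides need records of both classes")
    current = len(pos) / len(neg)
    if abs(current - target_ratio) < 1e-12:
        return records
    if current > target_ratio:          # too many positives
        n_keep = int(round(target_ratio * len(neg)))
        if n_keep < 1:
            raise ValueError(f"ratio {target_ratio} would leave no binding records")
        pos = rng.sample(pos, n_keep)
    else:                               # too many negatives
        n_keep = int(round(len(pos) / target_ratio))
        if n_keep < 1:
            raise ValueError(f"ratio {target_ratio} would leave no non-binding records")
        neg = rng.sample(neg, n_keep)
    return pos + neg


def ratio_titration(train: Sequence[PairRecord], test: Sequence[PairRecord],
                    chosen_peptides: set[str] | Sequence[str],
                    target_ratios: Sequence[float],
                    seed: int = 0,
                    n_trees: int = clf.DEFAULT_N_TREES,
                    threshold: float = 0.5,
                    mode: str = "pair",
                    matrix: SubstitutionMatrix | None = None,
                    pseudo_map: PseudoSequenceMap | None = None) -> pd.DataFrame:
    """Retrain at several binding:non-binding ratios for the chosen peptides.

    For each target ratio only the chosen peptides' records are re-sampled;
    the other peptides' records are bit-identical across ratios. Each
    retrained model is evaluated on the fixed test set in three groups:
    overall, chosen peptides only, and all other peptides. Ratios are
    binding/non-binding quotients (e.g. 0.051 ≈ 1:20).
    """
    chosen = set(chosen_peptides)
    base_chosen = [r for r in train if r.peptide in chosen]
    others = [r for r in train if r.peptide not in chosen]
    X_test = encode_batch(list(test), mode, matrix, pseudo_map)
    y_test = np.array([r.label for r in test], dtype=int)
    groups = {
        "overall": np.arange(len(test)),
        "dominant": np.array([i for i, r in enumerate(test) if r.peptide in chosen], dtype=int),
        "others": np.array([i for i, r in enumerate(test) if r.peptide not in chosen], dtype=int),
    }
    rows = []
    for i_ratio, ratio in enumerate(target_ratios):
        rng = random.Random(seed * 100_003 + i_ratio)
        retargeted = _retarget_ratio(base_chosen, ratio, rng)
        train_records = others + retargeted     # others bit-identical by construction
        X = encode_batch(train_records, mode, matrix, pseudo_map)
        y = np.array([r.label for r in train_records], dtype=int)
        model = clf.train(X, y, n_trees=n_trees, seed=seed, mode=mode)
        probs = clf.predict_proba(model, X_test)
        for group, idx in groups.items():
            if idx.size == 0:
                continue
            rep = metrics_report(probs[idx], y_test[idx], threshold, stratum=group)
            rows.append({"target_ratio": ratio, "group": group, **rep.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- per-peptide models

def train_peptide_specific_model(records: Sequence[PairRecord], peptide: str,
                                 seed: int = 0,
                                 min_records: int = 10,
                                 test_fraction: float = 0.3,
                                 n_trees: int = clf.DEFAULT_N_TREES,
                                 threshold: float = 0.5,
                                 matrix: SubstitutionMatrix | None = None,
                                 ) -> tuple[TrainedModel, EvalReport]:
    """Train and evaluate a model on one peptide's pairs only.

    With the peptide fixed, all discriminative signal must come from the
    CDR3β block. The peptide's records are split into train/held-out parts
    stratified by label.
    """
    subset = [r for r in records if r.peptide == peptide]
    if len(subset) < min_records:
        raise ContractError(
            f"{len(subset)} records for {peptide}; need >= {min_records}")
    labels = {r.label for r in subset}
    if labels != {0, 1}:
        raise ContractError(f"peptide {peptide} has a single class {labels}")
    rng = random.Random(seed)
    train_set: list[PairRecord] = []
    test_set: list[PairRecord] = []
    for lab in (0, 1):
        group = [r for r in subset if r.label == lab]
        rng.shuffle(group)
        n_test = max(1, int(round(test_fraction * len(group))))
        if n_test >= len(group):
            raise ContractError(f"too few label-{lab} records to split")
        test_set.extend(group[:n_test])
        train_set.extend(group[n_test:])
    X = encode_batch(train_set, "pair", matrix)
    y = np.array([r.label for r in train_set], dtype=int)
    model = clf.train(X, y, n_trees=n_trees, seed=seed, mode="pair")
    probs = clf.predict_proba(model, encode_batch(test_set, "pair", matrix))
    report = metrics_report(probs, [r.label for r in test_set], threshold,
                            stratum=peptide)
    return model, report


# ---------------------------------------------------------------- similarity

def levenshtein_similarity(a: str, b: str) -> float:
    """1 − editdistance(a, b) / max(|a|, |b|), in [0, 1]."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def similarity_matrix(peptides: Sequence[str]) -> np.ndarray:
    n = len(peptides)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = levenshtein_similarity(peptides[i], peptides[j])
    return sim


def cluster_peptides(peptides: Sequence[str], n_clusters: int = 6,
                     seed: int = 0, max_iter: int = 100,
                     ) -> tuple[dict[str, int], list[str]]:
    """Medoid partitioning (PAM-style) on the pairwise similarity matrix.

    Returns (peptide → cluster id, representatives), where each cluster's
    representative is its medoid — the member with maximal mean
    within-cluster similarity. Deterministic under the seed.
    """
    peptides = list(dict.fromkeys(peptides))    # distinct, order-preserving
    n = len(peptides)
    if n < n_clusters:
        raise ValueError(f"{n} distinct peptides < {n_clusters} clusters")
    sim = similarity_matrix(peptides)
    rng = random.Random(seed)
    medoids = sorted(rng.sample(range(n), n_clusters))
    for _ in range(max_iter):
        # assign to nearest medoid; ties to the lowest-index medoid
        assign = np.array([max(range(n_clusters),
                               key=lambda c: (sim[i, medoids[c]], -c))
                           for i in range(n)])
        new_medoids = []
        for c in range(n_clusters):
            members = np.flatnonzero(assign == c)
            if members.size == 0:       # re-seed an empty cluster deterministically
                members = np.array([medoids[c]])
            mean_sim = sim[np.ix_(members, members)].mean(axis=1)
            new_medoids.append(int(members[np.argmax(mean_sim)]))
        new_medoids = sorted(new_medoids)
        if new_medoids == medoids:
            break
        medoids = new_medoids
    assignment = {peptides[i]: int(assign[i]) for i in range(n)}
    representatives = [peptides[m] for m in medoids]
    return assignment, representatives


# ---------------------------------------------------------------- label proportions

def label_proportions(records: Sequence[PairRecord]) -> np.ndarray:
    """(binding, non-binding, mix) peptide-category proportions.

    Categories are per peptide: binding-only, non-binding-only, or mix
    (observed with both labels); the vector is over distinct peptides and
    sums to 1 for non-empty input.
    """
    by_pep: dict[str, set[int]] = {}
    for r in records:
        by_pep.setdefault(r.peptide, set()).add(r.label)
    counts = np.zeros(3)
    for labs in by_pep.values():
        if labs >= {0, 1}:
            counts[2] += 1
        elif labs == {1}:
            counts[0] += 1
        else:
            counts[1] += 1
    total = counts.sum()
    return counts / total if total else counts


def predicted_label_proportions(calls: Sequence[int]) -> np.ndarray:
    """(binding, non-binding, mix) proportions of one peptide's predicted calls.

    A representative peptide whose pairs are called both ways is itself a
    "mix" peptide, so the mix component is 1 when both call values occur.
    """
    calls = np.asarray(calls, dtype=int)
    if calls.size == 0:
        raise ValueError("no predictions for the representative")
    kinds = set(calls.tolist())
    if kinds == {0, 1}:
        return np.array([0.0, 0.0, 1.0])
    return np.array([1.0, 0.0, 0.0]) if kinds == {1} else np.array([0.0, 1.0, 0.0])


def similarity_bin_rmse(representative: str,
                        training_records: Sequence[PairRecord],
                        representative_calls: Sequence[int],
                        bin_width: float = 0.1) -> pd.DataFrame:
    """Per-similarity-bin RMSE between training and predicted label proportions.

    Training peptides are binned by Levenshtein similarity to the
    representative over [0, 1]; each non-empty bin's 3-component label-
    proportion vector (binding / non-binding / mix) is compared with the
    representative's predicted-label proportion vector:
    RMSE = sqrt(mean((p_train − p_pred)²)). Empty bins are omitted.
    """
    if not training_records:
        raise ValueError("no training peptides")
    pred = predicted_label_proportions(representative_calls)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    by_bin: dict[int, list[PairRecord]] = {}
    for rec in training_records:
        s = levenshtein_similarity(representative, rec.peptide)
        b = min(int(s / bin_width), len(edges) - 2)
        by_bin.setdefault(b, []).append(rec)
    rows = []
    for b in sorted(by_bin):
        props = label_proportions(by_bin[b])
        rmse = float(np.sqrt(np.mean((props - pred) ** 2)))
        rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1],
                     "n_peptides": len({r.peptide for r in by_bin[b]}),
                     "prop_binding": props[0], "prop_non_binding": props[1],
                     "prop_mix": props[2], "rmse": rmse})
    return pd.DataFrame(rows)
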