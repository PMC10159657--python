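"""Fixed-length numeric encodings of TCR–peptide(–HLA) observations.

Each residue of a sequence is embedded as its row of the BLOSUM62
substitution matrix (20 log-odds scores against the ordered amino-acid
alphabet ``ARNDCQEGHILKMFPSTWYV``). A sequence of length L ≤ max_len
becomes a 20 × max_len matrix, right-padded with zero columns, flattened
position-major (blocks of 20 scores per position). The two modes are:

* pair mode — CDR3β padded to 19 (380 values) then peptide padded to 11
  (220 values): 600 features.
* pmhc mode — the 600 pair features followed by the encoding of the HLA
  34-residue pseudo-sequence (680 values): 1280 features.

The pseudo-sequence is the NetMHCpan-style compact MHC representation:
the 34 residues of the mature class-I heavy chain at the peptide-contact
positions listed in ``data/class1_contact_positions.txt``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import (
    AMINO_ACIDS,
    PSEUDO_SEQUENCE_LENGTH,
    ContractError,
    HlaAllele,
    PairRecord,
    validate_record,
)

CDR3B_MAX_LEN = 19
PEPTIDE_MAX_LEN = 11
N_ALPHABET = 20

PAIR_FEATURES = N_ALPHABET * (CDR3B_MAX_LEN + PEPTIDE_MAX_LEN)          # 600
HLA_FEATURES = N_ALPHABET * PSEUDO_SEQUENCE_LENGTH                      # 680
PMHC_FEATURES = PAIR_FEATURES + HLA_FEATURES                            # 1280
assert PAIR_FEATURES == 600 and HLA_FEATURES == 680 and PMHC_FEATURES == 1280


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20×20 integer substitution matrix over AMINO_ACIDS order."""

    scores: np.ndarray
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.scores.shape != (N_ALPHABET, N_ALPHABET):
            raise ValueError("substitution matrix must be 20x20")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        return cls._from_biopython(substitution_matrices.load("BLOSUM62"), "BLOSUM62")

    @classmethod
    def from_file(cls, path: str | Path) -> "SubstitutionMatrix":
        """Read an NCBI-style whitespace-delimited matrix file."""
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.read(str(path))
        return cls._from_biopython(mat, Path(path).stem)

    @classmethod
    def _from_biopython(cls, mat, name: str) -> "SubstitutionMatrix":
        scores = np.zeros((N_ALPHABET, N_ALPHABET), dtype=np.int64)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                scores[i, j] = int(mat[a, b])
        return cls(scores=scores, name=name)

    def row(self, residue: str) -> np.ndarray:
        idx = AMINO_ACIDS.find(residue)
        if idx < 0:
            raise ValueError(f"residue {residue!r} outside the 20-letter alphabet")
        return self.scores[idx]


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = SubstitutionMatrix.blosum62()
    return _DEFAULT_MATRIX


def encode_sequence(seq: str, max_len: int,
                    matrix: SubstitutionMatrix | None = None) -> np.ndarray:
    """Encode one sequence as a flat vector of 20·max_len BLOSUM scores.

    Position block j (entries 20j..20j+19) holds the matrix row of residue
    j for j < len(seq); blocks at and beyond len(seq) are exactly zero
    (padding, never gap scores).
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) > max_len:
        raise ValueError(f"sequence length {len(seq)} exceeds max_len {max_len}")
    matrix = matrix or default_matrix()
    out = np.zeros(N_ALPHABET * max_len, dtype=np.float64)
    for j, res in enumerate(seq):
        out[N_ALPHABET * j: N_ALPHABET * (j + 1)] = matrix.row(res)
    return out


def encode_pair(record: PairRecord,
                matrix: SubstitutionMatrix | None = None) -> np.ndarray:
    """600-feature pair-mode vector: CDR3β block (380) then peptide block (220)."""
    result = validate_record(record)
    if not result.accepted:
        raise ContractError(f"invalid record: {','.join(result.reasons)}")
    vec = np.concatenate([
        encode_sequence(record.cdr3b, CDR3B_MAX_LEN, matrix),
        encode_sequence(record.peptide, PEPTIDE_MAX_LEN, matrix),
    ])
    assert vec.shape == (PAIR_FEATURES,)
    return vec


class PseudoSequenceMap:
    """Contact positions and allele → 34-aa pseudo-sequence lookup.

    ``positions`` are 1-based indices into the mature class-I heavy chain.
    Lookups can be populated from a two-column table, from full sequences
    (FASTA), or extended one allele at a time.
    """

    def __init__(self, positions: Sequence[int] | None = None,
                 lookup: dict[str, str] | None = None) -> None:
        self.positions = list(positions) if positions is not None else load_contact_positions()
        if len(self.positions) != PSEUDO_SEQUENCE_LENGTH:
            raise ValueError(f"expected {PSEUDO_SEQUENCE_LENGTH} contact positions")
        self.lookup: dict[str, str] = {}
        for name, pseudo in (lookup or {}).items():
            self.add(name, pseudo)

    def add(self, allele_name: str, pseudo: str) -> None:
        if len(pseudo) != PSEUDO_SEQUENCE_LENGTH:
            raise ValueError("pseudo-sequence must have 34 residues")
        self.lookup[allele_name] = pseudo

    def extract(self, full_sequence: str) -> str:
        """Pull the 34 contact residues out of a mature heavy-chain sequence."""
        if len(full_sequence) < max(self.positions):
            raise ValueError(
                f"heavy-chain sequence of length {len(full_sequence)} shorter than "
                f"largest contact position {max(self.positions)}"
            )
        return "".join(full_sequence[p - 1] for p in self.positions)

    def add_from_sequence(self, allele_name: str, full_sequence: str) -> str:
        pseudo = self.extract(full_sequence)
        self.add(allele_name, pseudo)
        return pseudo

    @classmethod
    def from_table(cls, path: str | Path) -> "PseudoSequenceMap":
        """Two-column whitespace/tab table: allele name, 34-aa pseudo-sequence."""
        lookup = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pseudo = line.split()[:2]
            lookup[name] = pseudo
        return cls(lookup=lookup)

    @classmethod
    def from_alleles(cls, alleles: Iterable[HlaAllele]) -> "PseudoSequenceMap":
        pm = cls()
        for allele in alleles:
            if allele.pseudo_sequence:
                pm.add(allele.name, allele.pseudo_sequence)
            elif allele.full_sequence:
                pm.add_from_sequence(allele.name, allele.full_sequence)
        return pm


def load_contact_positions() -> list[int]:
    text = resources.files("tcrforest.data").joinpath(
        "class1_contact_positions.txt").read_text()
    positions = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        positions.extend(int(tok) for tok in line.split())
    assert len(positions) == PSEUDO_SEQUENCE_LENGTH
    return positions


def bundled_synthetic_pseudo_map() -> PseudoSequenceMap:
    """The bundled SYNTHETIC allele panel (for tests and examples).

    The strings are generated stand-ins, not real IMGT/HLA-derived
    pseudo-sequences; supply a full-sequence FASTA for real alleles.
    """
    path = resources.files("tcrforest.data").joinpath("synthetic_class1_pseudosequences.tsv")
    lookup = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, pseudo = line.split("\t")[:2]
        lookup[name] = pseudo
    return PseudoSequenceMap(lookup=lookup)


def hla_pseudo_sequence(allele: HlaAllele,
                        pseudo_map: PseudoSequenceMap | None = None) -> str:
    """Resolve an allele to its 34-residue pseudo-sequence.

    Resolution order: an explicit pseudo_sequence on the allele; extraction
    from its full heavy-chain sequence; the lookup table.
    """
    if allele.pseudo_sequence:
        return allele.pseudo_sequence
    pm = pseudo_map or bundled_synthetic_pseudo_map()
    if allele.full_sequence:
        return pm.extract(allele.full_sequence)
    if allele.name in pm.lookup:
        return pm.lookup[allele.name]
    raise KeyError(f"no pseudo-sequence resolvable for {allele.name}")


def encode_pmhc(record: PairRecord,
                matrix: SubstitutionMatrix | None = None,
                pseudo_map: PseudoSequenceMap | None = None) -> np.ndarray:
    """1280-feature pmhc-mode vector: 600 pair features + 680 HLA features."""
    if record.hla is None:
        raise ContractError("pmhc mode requires an HLA allele on the record")
    pseudo = hla_pseudo_sequence(record.hla, pseudo_map)
    vec = np.concatenate([
        encode_pair(record, matrix),
        encode_sequence(pseudo, PSEUDO_SEQUENCE_LENGTH, matrix),
    ])
    assert vec.shape == (PMHC_FEATURES,)
    return vec


def encode_batch(records: Sequence[PairRecord], mode: str = "pair",
                 matrix: SubstitutionMatrix | None = None,
                 pseudo_map: PseudoSequenceMap | None = None) -> np.ndarray:
    """Encode a batch; row i equals the single-record encoding of record i."""
    if mode not in ("pair", "pmhc"):
        raise ValueError(f"unknown mode {mode!r}")
    matrix = matrix or default_matrix()
    n_features = PAIR_FEATURES if mode == "pair" else PMHC_FEATURES
    out = np.empty((len(records), n_features), dtype=np.float64)
    for i, rec in enumerate(records):
        try:
            out[i] = encode_pair(rec, matrix) if mode == "pair" else encode_pmhc(
                rec, matrix, pseudo_map)
        except (ValueError, KeyError, ContractError) as exc:
            raise ContractError(f"record {i} not encodable: {exc}") from exc
    return out
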