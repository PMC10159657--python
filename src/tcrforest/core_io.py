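"""Domain types, sequence validation, and pair-table readers/writers.

The central record is a single TCR–peptide observation: a CDR3β amino-acid
sequence (the hypervariable loop of the TCR beta chain, 8–19 residues), a
peptide epitope (8–11 residues), an optional class-I HLA allele, and an
optional binary binding label (1 = binding, 0 = non-binding).

Pair tables are plain delimited text (comma or tab, autodetected) with a
header; canonical column names are ``CDR3b``, ``epitope``, ``HLA``,
``binder`` and ``prediction_proba``. Arbitrary source schemas are mapped to
these via a column-name mapping.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_SET = frozenset(AMINO_ACIDS)

CDR3B_LENGTH_RANGE = (8, 19)
PEPTIDE_LENGTH_RANGE = (8, 11)
PSEUDO_SEQUENCE_LENGTH = 34

CANONICAL_COLUMNS = {
    "cdr3b": "CDR3b",
    "peptide": "epitope",
    "hla": "HLA",
    "label": "binder",
    "proba": "prediction_proba",
    "source": "source",
}


class ContractError(ValueError):
    """Raised when an operation receives input violating its contract."""


@dataclass(frozen=True)
class HlaAllele:
    """A class-I HLA allele at two-field (protein) resolution.

    ``name`` is canonical WHO nomenclature, e.g. ``HLA-A*02:01``.
    ``full_sequence`` optionally carries the mature heavy-chain protein;
    ``pseudo_sequence`` the 34 peptide-contact residues.
    """

    name: str
    full_sequence: str | None = None
    pseudo_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.pseudo_sequence is not None:
            if len(self.pseudo_sequence) != PSEUDO_SEQUENCE_LENGTH:
                raise ContractError(
                    f"pseudo_sequence must have length {PSEUDO_SEQUENCE_LENGTH}, "
                    f"got {len(self.pseudo_sequence)}"
                )
            bad = set(self.pseudo_sequence) - _AA_SET
            if bad:
                raise ContractError(f"pseudo_sequence has non-standard residues {sorted(bad)}")


@dataclass(frozen=True)
class PairRecord:
    """One CDR3β–peptide(–HLA) observation with optional binary label."""

    cdr3b: str
    peptide: str
    hla: HlaAllele | None = None
    label: int | None = None
    source: str | None = None
    proba: float | None = None

    def key(self, with_mhc: bool = False) -> tuple:
        if with_mhc:
            return (self.cdr3b, self.peptide, self.hla.name if self.hla else None)
        return (self.cdr3b, self.peptide)


@dataclass
class ValidationResult:
    accepted: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    n_input: int
    n_valid: int
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_valid + len(self.rejects) == self.n_input


def _check_sequence(seq: str, length_range: tuple[int, int], what: str) -> list[str]:
    reasons = []
    lo, hi = length_range
    if not lo <= len(seq) <= hi:
        reasons.append(f"{what}-length")
    if set(seq) - _AA_SET:
        reasons.append(f"{what}-alphabet")
    return reasons


def validate_record(record: PairRecord) -> ValidationResult:
    """Accept or reject one record against the domain invariants.

    Reason codes distinguish length violations (``cdr3b-length``,
    ``peptide-length``), alphabet violations (``cdr3b-alphabet``,
    ``peptide-alphabet``) and a non-binary label (``bad-label``).
    Rejection is a value, never an exception.
    """
    if not record.cdr3b or not record.peptide:
        raise ContractError("record must have non-empty cdr3b and peptide")
    reasons = _check_sequence(record.cdr3b, CDR3B_LENGTH_RANGE, "cdr3b")
    reasons += _check_sequence(record.peptide, PEPTIDE_LENGTH_RANGE, "peptide")
    if record.label is not None and record.label not in (0, 1):
        reasons.append("bad-label")
    return ValidationResult(accepted=not reasons, reasons=reasons)


def require_valid(records: Iterable[PairRecord]) -> list[PairRecord]:
    """Contract guard used by downstream modules: reject-worthy input raises."""
    out = []
    for i, rec in enumerate(records):
        res = validate_record(rec)
        if not res.accepted:
            raise ContractError(f"record {i} invalid: {','.join(res.reasons)}")
        out.append(rec)
    return out


_HLA_PATTERNS = [
    # HLA-A*02:01, A*02:01, with optional extra fields / expression suffix
    re.compile(r"^(?:HLA-)?([A-Z])\*(\d{2,3}):(\d{2,3})(?::\d{2,3})*[NLSCAQ]?$"),
    # legacy 4-digit: A0201 or A*0201
    re.compile(r"^(?:HLA-)?([A-Z])\*?(\d{2})(\d{2})$"),
]


def parse_hla_name(text: str) -> HlaAllele:
    """Normalize common HLA nomenclature dialects to two-field resolution.

    ``"A0201"``, ``"A*0201"``, ``"HLA-A*02:01:05"`` all normalize to
    ``HLA-A*02:01``. Higher-field suffixes are truncated: synonymous and
    non-coding differences do not change the protein, hence not the
    pseudo-sequence.
    """
    if not text or not text.strip():
        raise ValueError("empty HLA name")
    s = text.strip().upper()
    for pat in _HLA_PATTERNS:
        m = pat.match(s)
        if m:
            gene, group, prot = m.groups()[:3]
            return HlaAllele(name=f"HLA-{gene}*{int(group):02d}:{int(prot):02d}")
    raise ValueError(f"unparseable HLA nomenclature: {text!r}")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


_TRUE_LABELS = {"1", "1.0", "true", "binder", "binding", "yes"}
_FALSE_LABELS = {"0", "0.0", "false", "non-binder", "nonbinder", "non-binding", "no"}


def _parse_label(raw: str, label_map: Mapping[str, int] | None) -> int:
    s = raw.strip().lower()
    if label_map is not None:
        if raw.strip() in label_map:
            return int(label_map[raw.strip()])
        if s in {str(k).lower() for k in label_map}:
            for k, v in label_map.items():
                if str(k).lower() == s:
                    return int(v)
        raise ValueError(f"label {raw!r} not in schema label map")
    if s in _TRUE_LABELS:
        return 1
    if s in _FALSE_LABELS:
        return 0
    raise ValueError(f"unparseable label value {raw!r}")


def read_pair_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    label_map: Mapping[str, int] | None = None,
) -> tuple[list[PairRecord], ValidationReport]:
    """Read a delimited pair table into validated records plus a report.

    ``schema`` maps logical field names (``cdr3b``, ``peptide``, and
    optionally ``hla``, ``label``, ``source``, ``proba``) to the file's
    column names; canonical names are assumed when omitted. Row order is
    preserved for valid records; invalid rows become report entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or {})
    colnames = {k: schema.get(k, v) for k, v in CANONICAL_COLUMNS.items()}

    delim = _sniff_delimiter(path)
    records: list[PairRecord] = []
    rejects: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for logical in ("cdr3b", "peptide"):
            if colnames[logical] not in header:
                raise KeyError(f"missing column {colnames[logical]!r} for field {logical!r}")
        has = {k: colnames[k] in header for k in colnames}
        for i, row in enumerate(reader):
            cdr3b = (row[colnames["cdr3b"]] or "").strip().upper()
            peptide = (row[colnames["peptide"]] or "").strip().upper()
            if not cdr3b or not peptide:
                rejects.append((i, "empty-sequence"))
                continue
            hla = None
            if has["hla"] and (row[colnames["hla"]] or "").strip():
                try:
                    hla = parse_hla_name(row[colnames["hla"]])
                except ValueError:
                    rejects.append((i, "bad-hla"))
                    continue
            label = None
            if has["label"] and (row[colnames["label"]] or "").strip():
                label = _parse_label(row[colnames["label"]], label_map)
            proba = None
            if has["proba"] and (row[colnames["proba"]] or "").strip():
                proba = float(row[colnames["proba"]])
            source = row[colnames["source"]].strip() if has["source"] and row[colnames["source"]] else None
            rec = PairRecord(cdr3b=cdr3b, peptide=peptide, hla=hla, label=label,
                             source=source, proba=proba)
            result = validate_record(rec)
            if result.accepted:
                records.append(rec)
            else:
                rejects.append((i, ",".join(result.reasons)))
    report = ValidationReport(n_input=len(records) + len(rejects),
                              n_valid=len(records), rejects=rejects)
    return records, report


def write_pair_table(
    records: Sequence[PairRecord],
    path: str | Path,
    include_probability: bool = False,
    delimiter: str = ",",
) -> None:
    """Write records as a canonical pair table; lossless round trip."""
    path = Path(path)
    cols = ["CDR3b", "epitope", "HLA", "binder", "source"]
    if include_probability:
        cols.append("prediction_proba")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for rec in records:
            row = [
                rec.cdr3b,
                rec.peptide,
                rec.hla.name if rec.hla else "",
                "" if rec.label is None else rec.label,
                rec.source or "",
            ]
            if include_probability:
                row.append("" if rec.proba is None else repr(rec.proba))
            writer.writerow(row)


def read_hla_fasta(path: str | Path) -> dict[str, HlaAllele]:
    """Read full heavy-chain sequences from FASTA keyed by canonical allele name."""
    from Bio import SeqIO

    alleles = {}
    for record in SeqIO.parse(str(path), "fasta"):
        allele = parse_hla_name(record.id)
        alleles[allele.name] = replace(allele, full_sequence=str(record.seq).upper())
    return alleles
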