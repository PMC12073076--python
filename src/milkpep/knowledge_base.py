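"""Protein records, enzyme cleavage specifications, and the peptide-activity table.

This module is the data layer of the pipeline: it reads protein sequences
from FASTA, reads/writes the tab-separated peptide-activity knowledge table
(sequence, activity class, optional IC50 in micromolar, source id), exposes
the built-in digestive-enzyme specificity rules (pepsin at pH > 2, trypsin,
chymotrypsin), and ships the packaged table of di-/tripeptides identified by
LC-MS/MS in duodenally digested milk protein preparations.

Cleavage specificity is modelled as data, not code: each enzyme carries a
list of rules, a rule naming the residues N-terminal to a cut bond (P1) and
the residues that veto the cut when they follow the bond (P1').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "CANONICAL_RESIDUES",
    "ACTIVITY_ACE", "ACTIVITY_DPP4", "ACTIVITY_ANTIOX",
    "SAMPLE_LABELS", "DUODENAL_LABELS",
    "MILK_PROTEIN_ACCESSIONS", "DIGESTIVE_ENZYME_ACCESSIONS",
    "ValidationError", "ParseError",
    "ProteinRecord", "CleavageRule", "EnzymeSpec", "PeptideActivityRecord",
    "IdentifiedPeptide",
    "read_fasta", "write_fasta",
    "read_activity_table", "write_activity_table",
    "builtin_enzymes", "enzymes_to_yaml", "enzymes_from_yaml",
    "load_identified_peptides", "load_digestive_enzymes",
]

#: The 20 canonical amino-acid letters. Modified residues (e.g. oxidised
#: methionine) are out of scope: activity data exist only for unmodified forms.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

ACTIVITY_ACE = "ACE-inhibitor"
ACTIVITY_DPP4 = "DPP-IV-inhibitor"
ACTIVITY_ANTIOX = "antioxidative"

#: Sample labels of the identification study: three milk protein preparations
#: (micellar casein concentrate, MCC with buttermilk permeate, serum protein
#: concentrate), each before ("0") and after duodenal ("D") simulated digestion.
SAMPLE_LABELS = ("MCC-0", "MCC-D", "MBP-0", "MBP-D", "SPC-0", "SPC-D")
DUODENAL_LABELS = ("MCC-D", "MBP-D", "SPC-D")

#: UniProt accessions of the eight bovine milk proteins analysed in silico.
MILK_PROTEIN_ACCESSIONS = (
    "P02662",  # alpha_s1-casein
    "P02663",  # alpha_s2-casein
    "P02666",  # beta-casein
    "P02668",  # kappa-casein
    "P00711",  # alpha-lactalbumin
    "P02754",  # beta-lactoglobulin
    "P02769",  # serum albumin
    "P24627",  # lactoferrin
)

#: UniProt accessions of the digestive proteases (trypsin, pepsin A,
#: chymotrypsinogen A) used by the autolysis screen.
DIGESTIVE_ENZYME_ACCESSIONS = ("P00761", "P00791", "P00766")

_ENZYME_FASTA_NAME = "digestive_enzymes.fasta"


class ValidationError(ValueError):
    """A record violates a domain invariant (alphabet, positivity, ...)."""


class ParseError(ValueError):
    """An input file is malformed."""


def _check_sequence(sequence: str, *, context: str, min_len: int = 1) -> None:
    if len(sequence) < min_len:
        raise ValidationError(
            f"{context}: sequence {sequence!r} shorter than {min_len} residues"
        )
    for pos, residue in enumerate(sequence, start=1):
        if residue not in CANONICAL_RESIDUES:
            raise ValidationError(
                f"{context}: non-canonical residue {residue!r} at position {pos}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence.

    ``length`` (the residue count N) is the denominator of every release
    statistic downstream.
    """

    accession: str
    sequence: str
    name: str = ""
    variant: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _check_sequence(self.sequence, context=f"protein {self.accession}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageRule:
    """One specificity rule: cut on the carboxyl side of any P1 residue,
    unless the following (P1') residue is blocked."""

    p1_residues: frozenset
    p1prime_blocked: frozenset = frozenset()

    def __post_init__(self) -> None:
        p1 = frozenset(self.p1_residues)
        blocked = frozenset(self.p1prime_blocked)
        if not p1:
            raise ValidationError("cleavage rule with empty P1 residue set")
        for residues, label in ((p1, "P1"), (blocked, "P1'")):
            bad = residues - CANONICAL_RESIDUES
            if bad:
                raise ValidationError(
                    f"cleavage rule {label} set contains non-canonical {sorted(bad)}"
                )
        object.__setattr__(self, "p1_residues", p1)
        object.__setattr__(self, "p1prime_blocked", blocked)

    def fires(self, p1: str, p1prime: str) -> bool:
        """Does this rule cut the bond between residues ``p1`` | ``p1prime``?"""
        return p1 in self.p1_residues and p1prime not in self.p1prime_blocked


@dataclass(frozen=True)
class EnzymeSpec:
    """A protease identity plus its ordered cleavage rules."""

    id: str
    name: str
    ec_number: str
    rules: tuple

    def __post_init__(self) -> None:
        rules = tuple(self.rules)
        if not rules:
            raise ValidationError(f"enzyme {self.id}: no cleavage rules")
        object.__setattr__(self, "rules", rules)

    def cuts(self, p1: str, p1prime: str) -> bool:
        return any(rule.fires(p1, p1prime) for rule in self.rules)


@dataclass(frozen=True)
class PeptideActivityRecord:
    """A peptide, its activity class, and an optional IC50 in micromolar."""

    sequence: str
    activity: str
    ic50_uM: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _check_sequence(self.sequence, context=f"peptide {self.sequence}", min_len=2)
        if self.ic50_uM is not None:
            ic50 = float(self.ic50_uM)
            if not ic50 > 0:
                raise ValidationError(
                    f"peptide {self.sequence}: IC50 must be positive, got {ic50}"
                )
            object.__setattr__(self, "ic50_uM", ic50)


@dataclass(frozen=True)
class IdentifiedPeptide:
    """One row of the packaged identification table: a peptide, its printed
    singly protonated m/z, retention times (minutes) per sample, and the
    accessions of every milk protein containing it."""

    mz_MH: float
    sequence: str
    retention_min: Mapping[str, float]
    sources: tuple

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, context=f"peptide {self.sequence}", min_len=2)
        if not self.sources:
            raise ValidationError(f"peptide {self.sequence}: no protein sources")
        retention = dict(self.retention_min)
        unknown = set(retention) - set(SAMPLE_LABELS)
        if unknown:
            raise ValidationError(
                f"peptide {self.sequence}: unknown sample labels {sorted(unknown)}"
            )
        if not retention:
            raise ValidationError(
                f"peptide {self.sequence}: no retention time in any sample"
            )
        object.__setattr__(self, "retention_min", retention)
        object.__setattr__(self, "sources", tuple(self.sources))


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path) -> list:
    """Read protein records from a FASTA file.

    The first whitespace-separated token of the header is the accession
    (UniProt-style ``db|ACC|NAME`` headers are unwrapped); the remainder is
    kept as the free-text name. Sequences are upper-cased and validated
    against the canonical alphabet.
    """
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed records
        raise ParseError(f"{path}: {exc}") from exc
    for entry in parsed:
        accession = entry.id
        if "|" in accession:
            parts = accession.split("|")
            if len(parts) >= 2 and parts[1]:
                accession = parts[1]
        name = entry.description[len(entry.id):].strip()
        records.append(
            ProteinRecord(accession=accession, sequence=str(entry.seq), name=name)
        )
    if not records:
        warnings.warn(f"{path}: FASTA file contains no sequence entries")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records with normalised ``>accession name`` headers."""
    path = Path(path)
    with path.open("w") as handle:
        for record in records:
            header = record.accession if not record.name else f"{record.accession} {record.name}"
            handle.write(f">{header}\n")
            seq = record.sequence
            for start in range(0, len(seq), 60):
                handle.write(seq[start:start + 60] + "\n")


# ---------------------------------------------------------------------------
# Activity-table I/O

_ACTIVITY_COLUMNS = ["sequence", "activity", "ic50_uM", "source_id"]


def read_activity_table(path) -> list:
    """Read the peptide-activity knowledge table (TSV with header).

    Blank IC50 cells become ``None``. Duplicate (sequence, activity) rows are
    rejected when their IC50 values conflict.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in ("sequence", "activity") if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records = []
    seen = {}
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        raw_ic50 = getattr(row, "ic50_uM", "")
        ic50 = None
        if raw_ic50.strip():
            try:
                ic50 = float(raw_ic50.replace("−", "-"))
            except ValueError as exc:
                raise ParseError(
                    f"{path}, line {row_no}: IC50 {raw_ic50!r} is not a number"
                ) from exc
        record = PeptideActivityRecord(
            sequence=row.sequence,
            activity=row.activity,
            ic50_uM=ic50,
            source_id=getattr(row, "source_id", ""),
        )
        key = (record.sequence, record.activity)
        if key in seen and seen[key].ic50_uM != record.ic50_uM:
            raise ValidationError(
                f"{path}: conflicting IC50 for {key}: "
                f"{seen[key].ic50_uM} vs {record.ic50_uM}"
            )
        seen.setdefault(key, record)
        records.append(record)
    return records


def write_activity_table(records: Iterable[PeptideActivityRecord], path) -> None:
    rows = [
        {
            "sequence": r.sequence,
            "activity": r.activity,
            "ic50_uM": "" if r.ic50_uM is None else repr(r.ic50_uM),
            "source_id": r.source_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ACTIVITY_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Enzyme specifications

def _enzymes_from_mapping(doc: Mapping) -> list:
    enzymes = []
    for item in doc["enzymes"]:
        rules = tuple(
            CleavageRule(
                p1_residues=frozenset(rule["p1"]),
                p1prime_blocked=frozenset(rule.get("p1prime_blocked", [])),
            )
            for rule in item["rules"]
        )
        enzymes.append(
            EnzymeSpec(
                id=item["id"],
                name=item.get("name", item["id"]),
                ec_number=item.get("ec_number", ""),
                rules=rules,
            )
        )
    return enzymes


def enzymes_from_yaml(path) -> list:
    """Load enzyme specifications from a YAML rule file."""
    with Path(path).open() as handle:
        doc = yaml.safe_load(handle)
    return _enzymes_from_mapping(doc)


def enzymes_to_yaml(enzymes: Iterable[EnzymeSpec], path) -> None:
    doc = {
        "enzymes": [
            {
                "id": e.id,
                "name": e.name,
                "ec_number": e.ec_number,
                "rules": [
                    {
                        "p1": sorted(rule.p1_residues),
                        "p1prime_blocked": sorted(rule.p1prime_blocked),
                    }
                    for rule in e.rules
                ],
            }
            for e in enzymes
        ]
    }
    with Path(path).open("w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)


def builtin_enzymes(config_path=None) -> list:
    """The three default gastrointestinal proteases.

    Defaults (packaged in ``data/enzyme_rules.yaml``, overridable via
    ``config_path``): pepsin at pH > 2 cuts after F or L; trypsin cuts after
    K or R unless followed by P; chymotrypsin cuts after F, Y or W unless
    followed by P. These are the conventional specificity models for the
    corresponding enzyme entries in proteolysis-simulation databases.
    """
    if config_path is not None:
        return enzymes_from_yaml(config_path)
    text = resources.files("milkpep.data").joinpath("enzyme_rules.yaml").read_text()
    return _enzymes_from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Packaged fixtures

def load_identified_peptides() -> list:
    """The 36 di-/tripeptides identified by LC-MS/MS in the milk protein
    preparations, with printed [M+H]+ m/z, per-sample retention times and
    candidate source proteins."""
    text = resources.files("milkpep.data").joinpath("identified_peptides.tsv").read_text()
    lines = [line for line in text.splitlines() if line.strip()]
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        cells = dict(zip(header, line.split("\t")))
        retention = {
            label: float(cells[label])
            for label in SAMPLE_LABELS
            if cells.get(label, "").strip()
        }
        rows.append(
            IdentifiedPeptide(
                mz_MH=float(cells["mz_MH"]),
                sequence=cells["sequence"],
                retention_min=retention,
                sources=tuple(cells["sources"].split(";")),
            )
        )
    return rows


def load_digestive_enzymes(path=None) -> list:
    """Sequences of the digestive proteases for the autolysis screen.

    The package does not ship these sequences; download them once, e.g.::

        curl -o digestive_enzymes.fasta \\
            "https://rest.uniprot.org/uniprotkb/accessions?accessions=P00761,P00791,P00766&format=fasta"

    and either pass the path here or drop the file into the package's
    ``data/`` directory as ``digestive_enzymes.fasta``.
    """
    if path is None:
        packaged = resources.files("milkpep.data").joinpath(_ENZYME_FASTA_NAME)
        if not packaged.is_file():
            raise FileNotFoundError(
                "digestive-enzyme FASTA fixture is absent; fetch the sequences of "
                f"{', '.join(DIGESTIVE_ENZYME_ACCESSIONS)} from UniProt "
                f"(see load_digestive_enzymes docstring) and save them as "
                f"data/{_ENZYME_FASTA_NAME} or pass an explicit path"
            )
        with resources.as_file(packaged) as fspath:
            return read_fasta(fspath)
    return read_fasta(path)
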