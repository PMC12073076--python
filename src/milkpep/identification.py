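"""Small-peptide identification from peak lists and presence summaries.

Identification replaces an external spectral-library lookup with matching
against internally generated theoretical spectra: a candidate di-/tripeptide
is scored by the fraction of its theoretical fragment ions found in the
observed peak list. Because isoleucine and leucine are isobaric and
composition-identical dipeptide pairs (e.g. PL / IP) share a precursor and
co-elute, candidates are never resolved below the isomer set: everything
tying for the top score, plus every candidate with the same residue
composition (I and L collapsed), is reported together.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .knowledge_base import (
    DUODENAL_LABELS,
    SAMPLE_LABELS,
    IdentifiedPeptide,
    PeptideActivityRecord,
    ProteinRecord,
)
from .peptide_chem import Spectrum, mz_MH, theoretical_spectrum

__all__ = [
    "IdentificationResult", "PresenceMatrix", "SummaryCounts",
    "identify", "attribute_sources", "autolysis_screen", "summarize",
]

DEFAULT_FRAGMENT_TOL = 0.005   # Da; Q-ToF-scale accuracy
DEFAULT_PRECURSOR_TOL = 0.01   # Da


@dataclass(frozen=True)
class IdentificationResult:
    label: str
    candidate_sequences: Tuple[str, ...]
    matched_peaks: int
    total_candidate_ions: int
    score: float
    precursor_error: Optional[float]
    reason: str = ""

    @property
    def identified(self) -> bool:
        return bool(self.candidate_sequences)


def _collapsed_composition(peptide: str) -> str:
    """Residue composition signature with I/L merged."""
    return "".join(sorted(peptide.replace("I", "L")))


def _count_matched(theory_mzs: Sequence[float], observed_mzs: Sequence[float], tol: float) -> int:
    matched = 0
    for mz in theory_mzs:
        pos = bisect_left(observed_mzs, mz)
        for neighbour in (pos - 1, pos):
            if 0 <= neighbour < len(observed_mzs) and abs(observed_mzs[neighbour] - mz) <= tol:
                matched += 1
                break
    return matched


def identify(
    spectrum: Spectrum,
    candidates: Sequence[str],
    mz_tol: float = DEFAULT_FRAGMENT_TOL,
    precursor_tol: float = DEFAULT_PRECURSOR_TOL,
    min_matched: int = 0,
) -> IdentificationResult:
    """Score candidate peptides against an observed peak list.

    Candidates are first filtered by precursor mass (when the spectrum
    carries one), then ranked by matched-ion fraction; the result reports
    the isomer set of the top scorer. With ``min_matched`` set, a best match
    with fewer matched ions is rejected (decoy robustness).
    """
    if mz_tol <= 0 or precursor_tol <= 0:
        raise ValueError("tolerances must be positive")
    if not candidates:
        raise ValueError("candidate list must be non-empty")

    if spectrum.precursor_mz is not None:
        pool = [c for c in candidates if abs(mz_MH(c) - spectrum.precursor_mz) <= precursor_tol]
        if not pool:
            return IdentificationResult(
                label=spectrum.label, candidate_sequences=(),
                matched_peaks=0, total_candidate_ions=0, score=0.0,
                precursor_error=None,
                reason="no candidate within precursor tolerance",
            )
    else:
        pool = list(candidates)

    observed = spectrum.mz_values
    scored = []
    for candidate in pool:
        theory = theoretical_spectrum(candidate).mz_values
        matched = _count_matched(theory, observed, mz_tol)
        scored.append((matched / len(theory), matched, len(theory), candidate))
    best_score, best_matched, best_total, best_candidate = max(scored)

    if best_matched < min_matched:
        return IdentificationResult(
            label=spectrum.label, candidate_sequences=(),
            matched_peaks=best_matched, total_candidate_ions=best_total,
            score=best_score, precursor_error=None,
            reason=f"best match has {best_matched} ions, fewer than the "
                   f"required {min_matched}",
        )

    top_compositions = {
        _collapsed_composition(c) for score, _, _, c in scored if score >= best_score - 1e-12
    }
    isomer_set = tuple(sorted(
        c for _, _, _, c in scored
        if _collapsed_composition(c) in top_compositions
    ))
    precursor_error = (
        spectrum.precursor_mz - mz_MH(best_candidate)
        if spectrum.precursor_mz is not None else None
    )
    return IdentificationResult(
        label=spectrum.label,
        candidate_sequences=isomer_set,
        matched_peaks=best_matched,
        total_candidate_ions=best_total,
        score=best_score,
        precursor_error=precursor_error,
    )


def attribute_sources(peptide: str, proteins: Iterable[ProteinRecord]) -> List[str]:
    """Accessions of every protein containing the peptide as a substring.

    Short peptides cannot be attributed to an individual protein, so every
    containing protein is listed, in input order.
    """
    return [p.accession for p in proteins if peptide in p.sequence]


@dataclass(frozen=True)
class AutolysisPartition:
    enzyme_possible: Tuple[str, ...]
    milk_only: Tuple[str, ...]


def autolysis_screen(
    peptides: Iterable[str],
    enzyme_proteins: Sequence[ProteinRecord],
) -> AutolysisPartition:
    """Partition peptides by whether protease autolysis could explain them.

    A peptide is "milk-only" iff it occurs in none of the supplied enzyme
    sequences; otherwise it could equally derive from enzyme self-digestion.
    """
    if not enzyme_proteins:
        raise ValueError("enzyme sequences are required for the autolysis screen")
    enzyme_possible, milk_only = [], []
    for peptide in peptides:
        if any(peptide in enzyme.sequence for enzyme in enzyme_proteins):
            enzyme_possible.append(peptide)
        else:
            milk_only.append(peptide)
    return AutolysisPartition(tuple(enzyme_possible), tuple(milk_only))


# ---------------------------------------------------------------------------
# Presence matrix and summary counts

@dataclass(frozen=True)
class PresenceMatrix:
    """Peptides x samples, each cell a retention time in minutes or absent."""

    table: pd.DataFrame  # index: unique sequences; columns: SAMPLE_LABELS

    def __post_init__(self) -> None:
        if list(self.table.columns) != list(SAMPLE_LABELS):
            raise ValueError(f"columns must be exactly {SAMPLE_LABELS}")
        if self.table.index.has_duplicates:
            raise ValueError("peptide rows must be unique")

    @classmethod
    def from_identified(cls, rows: Iterable[IdentifiedPeptide]) -> "PresenceMatrix":
        data = {
            row.sequence: [row.retention_min.get(label) for label in SAMPLE_LABELS]
            for row in rows
        }
        frame = pd.DataFrame.from_dict(
            data, orient="index", columns=list(SAMPLE_LABELS)
        ).astype(float)
        return cls(frame)

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame[list(SAMPLE_LABELS)].astype(float))

    def present(self) -> pd.DataFrame:
        return self.table.notna()


@dataclass(frozen=True)
class SummaryCounts:
    total_peptides: int
    per_sample: Dict[str, int]
    common_duodenal: int
    activities_per_sample: Dict[str, Dict[str, int]] = field(default_factory=dict)


def summarize(
    matrix: PresenceMatrix,
    activity_table: Optional[Iterable[PeptideActivityRecord]] = None,
) -> SummaryCounts:
    """Presence counts per sample, the number of peptides shared by all
    three duodenal samples, and (with an activity table) per-sample counts
    by activity class; a peptide may count in several classes."""
    present = matrix.present()
    per_sample = {label: int(present[label].sum()) for label in SAMPLE_LABELS}
    total = int(present.any(axis=1).sum())
    common = int(present[list(DUODENAL_LABELS)].all(axis=1).sum())

    activities_per_sample: Dict[str, Dict[str, int]] = {}
    if activity_table is not None:
        by_peptide: Dict[str, set] = {}
        for record in activity_table:
            by_peptide.setdefault(record.sequence, set()).add(record.activity)
        for label in SAMPLE_LABELS:
            counts: Dict[str, int] = {}
            for peptide in present.index[present[label]]:
                for activity in by_peptide.get(peptide, ()):
                    counts[activity] = counts.get(activity, 0) + 1
            activities_per_sample[label] = counts
    return SummaryCounts(
        total_peptides=total,
        per_sample=per_sample,
        common_duodenal=common,
        activities_per_sample=activities_per_sample,
    )
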