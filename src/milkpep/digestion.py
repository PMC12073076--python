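"""Exhaustive in-silico proteolysis.

The model is the idealised one used by proteolysis-simulation tools: every
peptide bond whose local context matches the specificity of at least one of
the selected enzymes is cut, with no missed cleavages. The combined action
of several enzymes is the union of their cleavage sites, applied in a single
pass; kinetics and partial hydrolysis are deliberately out of scope.

Coordinates are 1-based and inclusive on both ends, matching the residue
numbering conventions of protein databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .knowledge_base import EnzymeSpec, PeptideActivityRecord, ProteinRecord

__all__ = ["Fragment", "cleavage_sites", "digest", "released_bioactive"]


@dataclass(frozen=True)
class Fragment:
    """A positioned proteolysis product: ``sequence`` equals the parent
    subsequence on [start, end] (1-based, inclusive)."""

    sequence: str
    start: int
    end: int
    parent: str

    def __len__(self) -> int:
        return self.end - self.start + 1


def cleavage_sites(protein: ProteinRecord, enzymes: Sequence[EnzymeSpec]) -> List[int]:
    """Bond indices cut by the combined enzyme action.

    Bond ``i`` (1 <= i <= N-1) joins residues i and i+1; it is cut iff some
    enzyme has a rule with residue i in its P1 set and residue i+1 not in
    that rule's blocked P1' set. The terminal residue has no following bond,
    so a C-terminal K/R/F... never creates a site.
    """
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    seq = protein.sequence
    sites = [
        i
        for i in range(1, len(seq))
        if any(enzyme.cuts(seq[i - 1], seq[i]) for enzyme in enzymes)
    ]
    return sites


def digest(protein: ProteinRecord, enzymes: Sequence[EnzymeSpec]) -> List[Fragment]:
    """Fragments between consecutive cleavage sites, N- to C-terminal.

    Concatenating the fragment sequences reproduces the protein sequence.
    """
    seq = protein.sequence
    sites = cleavage_sites(protein, enzymes)
    bounds = [0] + sites + [len(seq)]
    return [
        Fragment(
            sequence=seq[lo:hi],
            start=lo + 1,
            end=hi,
            parent=protein.accession,
        )
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]


def released_bioactive(
    fragments: Iterable[Fragment],
    table: Iterable[PeptideActivityRecord],
    activity: str,
) -> List[Tuple[Fragment, PeptideActivityRecord]]:
    """Pair each released fragment with the activity-table entries it equals.

    Matching is exact string equality. Length-1 fragments never match: a
    free amino acid is not a peptide.
    """
    by_sequence = {}
    for record in table:
        if record.activity == activity:
            by_sequence.setdefault(record.sequence, []).append(record)
    matches = []
    for fragment in fragments:
        if len(fragment) < 2:
            continue
        for record in by_sequence.get(fragment.sequence, ()):
            matches.append((fragment, record))
    return matches
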