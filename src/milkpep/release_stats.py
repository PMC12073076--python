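"""Release-potential statistics for bioactive peptides.

For a protein of N residues and an activity class, the classical
quantitative parameters of in-silico proteolysis are

* ``a`` — occurrences of active fragments anywhere in the sequence
  (substring instances, overlaps and repeats counted),
* ``d`` — active fragments among the products of the simulated digestion,
* ``A = a / N`` — frequency of occurrence,
* ``A_E = d / N`` — frequency of release by the selected enzymes,
* ``W = A_E / A`` — relative frequency of release (undefined when a = 0),
* ``B = (sum of 1/IC50_i over occurring active fragments with known IC50) / N``
  in 1/uM — activity of occurring fragments,
* ``B_E`` — the same sum restricted to released fragments,
* ``V = B_E / B`` — relative activity of released fragments (undefined when
  B = 0).

Records lacking an IC50 contribute to ``a``/``d`` but are excluded from
``B``/``B_E``. Ratios with a zero denominator are reported as undefined
(``None``), not zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .digestion import digest, released_bioactive
from .knowledge_base import EnzymeSpec, PeptideActivityRecord, ProteinRecord

__all__ = ["ReleaseProfile", "occurrences", "release_profile", "profile_report"]

logger = logging.getLogger(__name__)

#: Display precision of the report tables.
REPORT_DECIMALS = 4


@dataclass(frozen=True)
class ReleaseProfile:
    protein: str
    activity: str
    N: int
    a: int
    d: int
    A: float
    A_E: float
    W: Optional[float]
    B: float
    B_E: float
    V: Optional[float]


def _deduplicate(
    table: Iterable[PeptideActivityRecord], activity: str
) -> List[PeptideActivityRecord]:
    # One record per (sequence, activity); conflicting IC50s are rejected at
    # parse time, so the first record is representative.
    seen = {}
    for record in table:
        if record.activity == activity:
            seen.setdefault(record.sequence, record)
    return list(seen.values())


def occurrences(
    protein: ProteinRecord,
    table: Iterable[PeptideActivityRecord],
    activity: str,
) -> List[Tuple[int, PeptideActivityRecord]]:
    """All (1-based start position, record) substring occurrences.

    Overlapping and repeated occurrences are all counted; ``a`` is the
    length of the returned list.
    """
    seq = protein.sequence
    found = []
    for record in _deduplicate(table, activity):
        needle = record.sequence
        start = seq.find(needle)
        while start != -1:
            found.append((start + 1, record))
            start = seq.find(needle, start + 1)
    found.sort(key=lambda item: (item[0], item[1].sequence))
    return found


def release_profile(
    protein: ProteinRecord,
    enzymes: Sequence[EnzymeSpec],
    table: Iterable[PeptideActivityRecord],
    activity: str,
) -> ReleaseProfile:
    """Compute a, d, A, A_E, W, B, B_E, V for one protein x activity."""
    table = list(table)
    n = protein.length
    occ = occurrences(protein, table, activity)
    released = released_bioactive(
        digest(protein, enzymes), _deduplicate(table, activity), activity
    )
    a = len(occ)
    d = len(released)
    b_sum = sum(1.0 / rec.ic50_uM for _, rec in occ if rec.ic50_uM is not None)
    be_sum = sum(1.0 / rec.ic50_uM for _, rec in released if rec.ic50_uM is not None)
    big_a = a / n
    big_ae = d / n
    big_b = b_sum / n
    big_be = be_sum / n
    w = big_ae / big_a if a > 0 else None
    v = big_be / big_b if big_b > 0 else None
    if w is None:
        logger.warning(
            "W undefined for %s/%s: no occurrences (a = 0)", protein.accession, activity
        )
    if v is None:
        logger.warning(
            "V undefined for %s/%s: B = 0 (no occurring fragment has a known IC50)",
            protein.accession, activity,
        )
    return ReleaseProfile(
        protein=protein.accession, activity=activity, N=n,
        a=a, d=d, A=big_a, A_E=big_ae, W=w, B=big_b, B_E=big_be, V=v,
    )


def profile_report(
    proteins: Iterable[ProteinRecord],
    enzymes: Sequence[EnzymeSpec],
    table: Iterable[PeptideActivityRecord],
    activities: Sequence[str],
    *,
    rounded: bool = True,
) -> pd.DataFrame:
    """One row per protein x activity; values rounded to 4 decimals for
    display when ``rounded`` (full precision retained otherwise)."""
    table = list(table)
    rows = []
    for protein in proteins:
        for activity in activities:
            profile = release_profile(protein, enzymes, table, activity)
            rows.append(vars(profile).copy())
    frame = pd.DataFrame(
        rows, columns=["protein", "activity", "N", "a", "d",
                       "A", "A_E", "W", "B", "B_E", "V"],
    )
    if rounded:
        for col in ("A", "A_E", "W", "B", "B_E", "V"):
            frame[col] = frame[col].round(REPORT_DECIMALS)
    return frame
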