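"""Seeded generators for pipeline-shaped synthetic inputs.

Every generator is a pure function of its arguments and the config seed:
each draws from its own `numpy` Generator stream derived from
``(seed, stream id)``, so adding one generator call never perturbs another.

The defaults emulate the study conditions: eight proteins, an activity
table of 59 short peptides (52 di- and 7 tripeptides) spanning ACE
inhibition, DPP-IV inhibition, and antioxidative activity with log-uniform
IC50s, five-concentration dose-response series read in duplicate with
3-percentage-point Gaussian noise, and Q-ToF-like spectra with a few mDa of
m/z jitter plus uniform decoy peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from .bioassay import ASSAY_ROLES, DoseResponse, PlateReading, logistic_response
from .knowledge_base import (
    ACTIVITY_ACE,
    ACTIVITY_ANTIOX,
    ACTIVITY_DPP4,
    PeptideActivityRecord,
    ProteinRecord,
)
from .peptide_chem import Spectrum, mz_MH, theoretical_spectrum

__all__ = [
    "GeneratorConfig",
    "gen_proteins", "gen_activity_table", "gen_dose_response",
    "gen_spectrum", "gen_plate",
]

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Stream identifiers: one independent substream per generator.
_STREAM_PROTEINS = 1
_STREAM_ACTIVITY = 2
_STREAM_DOSE = 3
_STREAM_SPECTRUM = 4
_STREAM_PLATE = 5


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    # proteins
    n_proteins: int = 8
    protein_length: Tuple[int, int] = (50, 200)
    composition: Tuple[float, ...] = ()  # optional 20 weights, alphabetical order
    # activity table: 52 di- + 7 tripeptides, as in the in-silico release list
    n_dipeptides: int = 52
    n_tripeptides: int = 7
    ic50_range_uM: Tuple[float, float] = (1.0, 1000.0)
    fraction_with_ic50: float = 0.5
    fraction_from_proteins: float = 0.5
    # dose-response
    n_concentrations: int = 5
    n_replicates: int = 2
    response_noise_pct: float = 3.0
    # spectra
    mz_jitter_Da: float = 0.002
    peak_drop_fraction: float = 0.1
    n_decoy_peaks: int = 10

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def gen_proteins(config: GeneratorConfig) -> List[ProteinRecord]:
    """Random proteins with i.i.d. residues (uniform unless a composition
    weighting is supplied)."""
    rng = config._rng(_STREAM_PROTEINS)
    lo, hi = config.protein_length
    weights = None
    if config.composition:
        weights = np.asarray(config.composition, dtype=float)
        weights = weights / weights.sum()
    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_ALPHABET, size=length, p=weights))
        records.append(ProteinRecord(accession=f"SYN{i:03d}", sequence=seq))
    return records


def gen_activity_table(
    config: GeneratorConfig, proteins: List[ProteinRecord]
) -> List[PeptideActivityRecord]:
    """A di-/tripeptide activity table; a configurable share of sequences is
    sampled from substrings of the supplied proteins so that occurrence
    counts downstream are non-trivially positive."""
    rng = config._rng(_STREAM_ACTIVITY)
    activities = [ACTIVITY_ACE, ACTIVITY_DPP4, ACTIVITY_ANTIOX]
    # ACE and DPP-IV inhibitors dominate known short bioactive peptides.
    activity_p = np.array([27.0, 27.0, 5.0])
    activity_p /= activity_p.sum()
    lo, hi = config.ic50_range_uM

    lengths = [2] * config.n_dipeptides + [3] * config.n_tripeptides
    records: List[PeptideActivityRecord] = []
    used = set()
    for idx, length in enumerate(lengths):
        for _ in range(1000):
            if proteins and rng.random() < config.fraction_from_proteins:
                parent = proteins[int(rng.integers(len(proteins)))]
                if parent.length >= length:
                    start = int(rng.integers(parent.length - length + 1))
                    seq = parent.sequence[start:start + length]
                else:
                    continue
            else:
                seq = "".join(rng.choice(_ALPHABET, size=length))
            activity = activities[int(rng.choice(3, p=activity_p))]
            if (seq, activity) not in used:
                used.add((seq, activity))
                break
        ic50 = None
        if rng.random() < config.fraction_with_ic50:
            ic50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        records.append(
            PeptideActivityRecord(
                sequence=seq, activity=activity, ic50_uM=ic50,
                source_id=f"syn:{idx}",
            )
        )
    return records


def gen_dose_response(ic50: float, hill: float, config: GeneratorConfig) -> DoseResponse:
    """Percent responses on the fixed-asymptote logistic curve plus Gaussian
    noise, at concentrations log-spaced one decade either side of the IC50."""
    if ic50 <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be positive")
    rng = config._rng(_STREAM_DOSE)
    log_c = np.linspace(np.log10(ic50) - 1.0, np.log10(ic50) + 1.0, config.n_concentrations)
    responses = logistic_response(log_c, np.log10(ic50), hill)
    responses = responses + rng.normal(0.0, config.response_noise_pct, size=len(log_c))
    return DoseResponse(tuple(10.0 ** log_c), tuple(responses))


def gen_plate(
    assay: str, ic50: float, hill: float, config: GeneratorConfig
) -> List[PlateReading]:
    """Replicated plate readings whose percentages follow a known logistic
    curve; noise enters through the sample-well absorbance."""
    if assay not in ASSAY_ROLES:
        raise ValueError(f"unknown assay {assay!r}")
    rng = config._rng(_STREAM_PLATE)
    log_c = np.linspace(np.log10(ic50) - 1.0, np.log10(ic50) + 1.0, config.n_concentrations)
    readings = []
    for lc in log_c:
        target = float(logistic_response(lc, np.log10(ic50), hill))
        for rep in range(1, config.n_replicates + 1):
            pct = target + float(rng.normal(0.0, config.response_noise_pct))
            if assay == "ACE":
                a1, a3 = 1.0, 0.2
                absorbances = {"A1": a1, "A3": a3, "A2": a1 - pct / 100.0 * (a1 - a3)}
            elif assay == "DPP-IV":
                ac, ace = 1.2, 0.1
                absorbances = {
                    "AC": ac, "ACE": ace, "ASE": 0.1,
                    "AS": 0.1 + pct / 100.0 * (ac - ace),
                }
            elif assay in ("DPPH", "ABTS"):
                control = 0.7
                absorbances = {"control": control, "sample": control * (1.0 - pct / 100.0)}
            else:  # FRAP
                blank = 0.3
                denom = 1.0 - pct / 100.0
                absorbances = {"blank": blank, "sample": blank / max(denom, 1e-6)}
            readings.append(
                PlateReading(
                    assay=assay, absorbances=absorbances,
                    concentration=float(10.0 ** lc), replicate=rep,
                )
            )
    return readings


def gen_spectrum(peptide: str, config: GeneratorConfig) -> Spectrum:
    """A jittered, thinned, decoy-contaminated copy of the theoretical
    spectrum; the precursor peak is always retained."""
    rng = config._rng(_STREAM_SPECTRUM)
    reference = theoretical_spectrum(peptide)
    precursor = mz_MH(peptide)
    fragment_mzs = [mz for mz in reference.mz_values if abs(mz - precursor) > 1e-9]
    keep = [
        mz for mz in fragment_mzs if rng.random() >= config.peak_drop_fraction
    ]
    jittered = [mz + float(rng.normal(0.0, config.mz_jitter_Da)) for mz in keep]
    precursor_obs = precursor + float(rng.normal(0.0, config.mz_jitter_Da))
    decoys = rng.uniform(50.0, precursor, size=config.n_decoy_peaks).tolist()
    peaks = [(mz, 1.0) for mz in jittered + decoys] + [(precursor_obs, 1.0)]
    return Spectrum(peaks=tuple(peaks), precursor_mz=precursor_obs, label=peptide)
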