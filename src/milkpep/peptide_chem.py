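"""Monoisotopic mass and tandem-MS fragment-ion arithmetic for short peptides.

All masses are monoisotopic, in Da. A peptide's neutral mass is the sum of
its residue masses plus one water; the singly protonated ion [M+H]+ adds a
proton mass (not a hydrogen atom: the electron matters at the fourth
decimal). Backbone fragment ions follow the standard a/b/c/x/y/z nomenclature
for singly charged ions:

    b_i = sum(prefix residues) + proton
    a_i = b_i - CO            c_i = b_i + NH3
    y_i = sum(suffix residues) + water + proton
    x_i = y_i + CO - H2       z_i = y_i - NH2

Neutral losses of water, ammonia, and formic acid - the losses routinely
seen in dipeptide spectra - subtract the corresponding molecule mass.

Isoleucine and leucine are mass-identical; anything downstream that matches
by mass must therefore report isomer sets rather than a single sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import yaml

__all__ = [
    "MassConstants", "DEFAULT_CONSTANTS", "PeptideIon", "Spectrum",
    "neutral_mass", "mz_MH", "fragment_ions", "theoretical_spectrum",
]

#: Standard monoisotopic residue (amino-acid minus water) masses, Da.
_RESIDUE_MASSES: Dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

_WATER = 18.010565
_PROTON = 1.0072765
_CO = 27.994915
_NH3 = 17.026549
_NH2 = 16.018724
_CO_MINUS_H2 = 25.979265  # x-ion offset relative to y

_NEUTRAL_LOSSES: Dict[str, float] = {
    "H2O": 18.010565,
    "NH3": 17.026549,
    "HCOOH": 46.005480,
}

ION_SERIES = ("a", "b", "c", "x", "y", "z")


@dataclass(frozen=True)
class MassConstants:
    """The constant set behind every m/z; overridable from YAML so that an
    alternative table can be swapped in without code changes."""

    residue_masses: Mapping[str, float] = field(default_factory=lambda: dict(_RESIDUE_MASSES))
    water: float = _WATER
    proton: float = _PROTON
    neutral_losses: Mapping[str, float] = field(default_factory=lambda: dict(_NEUTRAL_LOSSES))

    def __post_init__(self) -> None:
        missing = set(_RESIDUE_MASSES) - set(self.residue_masses)
        if missing:
            raise ValueError(f"residue masses missing for {sorted(missing)}")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")

    @classmethod
    def from_yaml(cls, path) -> "MassConstants":
        with Path(path).open() as handle:
            doc = yaml.safe_load(handle)
        base = cls()
        residues = dict(base.residue_masses)
        residues.update(doc.get("residue_masses", {}))
        losses = dict(base.neutral_losses)
        losses.update(doc.get("neutral_losses", {}))
        return cls(
            residue_masses=residues,
            water=doc.get("water", base.water),
            proton=doc.get("proton", base.proton),
            neutral_losses=losses,
        )


DEFAULT_CONSTANTS = MassConstants()


@dataclass(frozen=True)
class PeptideIon:
    peptide: str
    series: str  # one of a/b/c/x/y/z or "precursor"
    index: int   # fragment length; full length for the precursor
    mz: float
    charge: int = 1
    loss: Optional[str] = None

    @property
    def label(self) -> str:
        name = f"{self.series}{self.index}" if self.series != "precursor" else "[M+H]+"
        return f"{name}-{self.loss}" if self.loss else name


@dataclass(frozen=True)
class Spectrum:
    """A peak list sorted by m/z."""

    peaks: Tuple[Tuple[float, float], ...]
    precursor_mz: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        peaks = tuple(sorted((float(mz), float(i)) for mz, i in self.peaks))
        if any(i < 0 for _, i in peaks):
            raise ValueError("negative peak intensity")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz_values(self) -> List[float]:
        return [mz for mz, _ in self.peaks]


def _residue_sum(peptide: str, constants: MassConstants) -> float:
    total = 0.0
    for residue in peptide:
        try:
            total += constants.residue_masses[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r} in {peptide!r}") from None
    return total


def neutral_mass(peptide: str, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Monoisotopic neutral mass: sum of residue masses plus water."""
    if not peptide:
        raise ValueError("empty peptide")
    return _residue_sum(peptide, constants) + constants.water


def mz_MH(peptide: str, constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """m/z of the singly protonated molecular ion [M+H]+."""
    return neutral_mass(peptide, constants) + constants.proton


def fragment_ions(
    peptide: str,
    series_set: Iterable[str] = ION_SERIES,
    losses: Iterable[str] = (),
    charge: int = 1,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> List[PeptideIon]:
    """All singly charged backbone fragment ions of the requested series,
    each with and without each requested neutral loss."""
    if len(peptide) < 2:
        raise ValueError("fragment ions require a peptide of length >= 2")
    if charge != 1:
        raise ValueError("only singly charged ions are supported")
    unknown = set(series_set) - set(ION_SERIES)
    if unknown:
        raise ValueError(f"unknown ion series {sorted(unknown)}")
    unknown_losses = set(losses) - set(constants.neutral_losses)
    if unknown_losses:
        raise ValueError(f"unknown neutral losses {sorted(unknown_losses)}")

    series_set = set(series_set)
    ions: List[PeptideIon] = []
    n = len(peptide)
    for i in range(1, n):
        b = _residue_sum(peptide[:i], constants) + constants.proton
        y = _residue_sum(peptide[i:], constants) + constants.water + constants.proton
        base = {
            "a": b - _CO, "b": b, "c": b + _NH3,
            "x": y + _CO_MINUS_H2, "y": y, "z": y - _NH2,
        }
        for series in ION_SERIES:
            if series not in series_set:
                continue
            index = i if series in "abc" else n - i
            mz = base[series]
            ions.append(PeptideIon(peptide=peptide, series=series, index=index, mz=mz))
            for loss in losses:
                ions.append(
                    PeptideIon(
                        peptide=peptide, series=series, index=index,
                        mz=mz - constants.neutral_losses[loss], loss=loss,
                    )
                )
    return ions


def theoretical_spectrum(
    peptide: str,
    constants: MassConstants = DEFAULT_CONSTANTS,
    dedup_tol: float = 1e-4,
) -> Spectrum:
    """Unit-intensity reference spectrum of a di- to pentapeptide.

    Contains every a/b/c/x/y/z ion, its H2O/NH3/HCOOH loss ions, and the
    precursor [M+H]+; peaks closer than ``dedup_tol`` are merged.
    """
    if not 2 <= len(peptide) <= 5:
        raise ValueError("theoretical spectra cover di- to pentapeptides only")
    precursor = mz_MH(peptide, constants)
    mzs = [ion.mz for ion in fragment_ions(
        peptide, ION_SERIES, constants.neutral_losses, constants=constants)]
    mzs.append(precursor)
    mzs = [mz for mz in sorted(mzs) if mz > 0]
    merged: List[float] = []
    for mz in mzs:
        if merged and mz - merged[-1] <= dedup_tol:
            continue
        merged.append(mz)
    return Spectrum(
        peaks=tuple((mz, 1.0) for mz in merged),
        precursor_mz=precursor,
        label=peptide,
    )
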