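"""Plate-assay percentages and four-parameter logistic IC50 estimation.

Each supported assay converts role-labelled absorbances into a percent
activity:

* ACE inhibition:        100 * (A1 - A2) / (A1 - A3)
  (A1 uninhibited reaction, A2 with sample, A3 enzyme-free blank)
* DPP-IV inhibition:     100 * (AS - ASE) / (AC - ACE)
  (sample / sample-no-enzyme / control / substrate-only absorbances)
* DPPH, ABTS scavenging: 100 * (Acontrol - Asample) / Acontrol
* FRAP:                  100 * (Asample - Ablank) / Asample

All five formulas are ratios of absorbances, so percentages are invariant
under a common rescaling of the plate reader.

The IC50 of a preparation is estimated from percent activity at >= 5
concentrations by least squares on the normalized-response logistic with
fixed asymptotes 0 and 100 and a variable slope:

    Y(c) = 100 / (1 + 10 ** ((log10(IC50) - log10(c)) * HillSlope))

Initialisation is deterministic: log10(IC50) starts at the concentration
whose mean response is nearest 50 %, the Hill slope at 1. A fit is flagged
as not converged when the optimiser fails, the slope comes out
non-positive (activity decreasing with dose contradicts the model), or the
estimate falls more than 10x outside the tested concentration range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ASSAY_ROLES", "PlateReading", "DoseResponse", "IC50Estimate",
    "percent_activity", "fit_ic50", "ic50_from_plate", "logistic_response",
]

#: Absorbance roles required by each assay's formula.
ASSAY_ROLES: Dict[str, Tuple[str, ...]] = {
    "ACE": ("A1", "A2", "A3"),
    "DPP-IV": ("AS", "ASE", "AC", "ACE"),
    "DPPH": ("control", "sample"),
    "ABTS": ("control", "sample"),
    "FRAP": ("sample", "blank"),
}


@dataclass(frozen=True)
class PlateReading:
    """Role-labelled absorbances of one well group at one concentration."""

    assay: str
    absorbances: Mapping[str, float]
    concentration: float  # mg/mL
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_ROLES:
            raise ValueError(f"unknown assay {self.assay!r}")
        missing = set(ASSAY_ROLES[self.assay]) - set(self.absorbances)
        if missing:
            raise ValueError(f"{self.assay} reading missing roles {sorted(missing)}")
        if any(v < 0 for v in self.absorbances.values()):
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class DoseResponse:
    concentrations: Tuple[float, ...]  # mg/mL
    responses: Tuple[float, ...]       # percent activity
    assay: str = ""

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        resp = tuple(float(r) for r in self.responses)
        if len(conc) != len(resp):
            raise ValueError("concentrations and responses differ in length")
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be positive")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)


@dataclass(frozen=True)
class IC50Estimate:
    ic50: float            # mg/mL
    hill_slope: float
    standard_error: float  # mg/mL, asymptotic
    converged: bool
    message: str = ""


def percent_activity(reading: PlateReading) -> float:
    """Apply the assay's percentage formula to one reading."""
    a = reading.absorbances
    if reading.assay == "ACE":
        num, den = a["A1"] - a["A2"], a["A1"] - a["A3"]
        roles = "A1 - A3"
    elif reading.assay == "DPP-IV":
        num, den = a["AS"] - a["ASE"], a["AC"] - a["ACE"]
        roles = "AC - ACE"
    elif reading.assay in ("DPPH", "ABTS"):
        num, den = a["control"] - a["sample"], a["control"]
        roles = "control"
    else:  # FRAP
        num, den = a["sample"] - a["blank"], a["sample"]
        roles = "sample"
    if den == 0:
        raise ZeroDivisionError(
            f"{reading.assay} percentage undefined: denominator {roles} is zero"
        )
    return 100.0 * num / den


def logistic_response(log10_c, log10_ic50: float, hill: float):
    """Normalized-response inhibition curve on the log10 concentration axis."""
    return 100.0 / (1.0 + 10.0 ** ((log10_ic50 - np.asarray(log10_c)) * hill))


def fit_ic50(data: DoseResponse) -> IC50Estimate:
    """Least-squares IC50 and Hill slope from a dose-response series."""
    if len(data.concentrations) < 5:
        raise ValueError("at least 5 concentration points are required")
    x = np.log10(np.asarray(data.concentrations, dtype=float))
    y = np.asarray(data.responses, dtype=float)

    start = x[int(np.argmin(np.abs(y - 50.0)))]
    try:
        params, cov = curve_fit(
            logistic_response, x, y, p0=[start, 1.0], maxfev=10000
        )
    except RuntimeError as exc:
        return IC50Estimate(
            ic50=float("nan"), hill_slope=float("nan"),
            standard_error=float("nan"), converged=False,
            message=f"optimiser failed: {exc}",
        )
    log_ic50, hill = params
    ic50 = 10.0 ** log_ic50
    se_log = math.sqrt(cov[0, 0]) if np.isfinite(cov[0, 0]) else float("nan")
    se = math.log(10.0) * ic50 * se_log  # delta method

    message = ""
    converged = True
    if hill <= 0:
        converged = False
        message = "non-positive Hill slope: responses do not increase with dose"
    elif not (min(data.concentrations) / 10.0 <= ic50 <= max(data.concentrations) * 10.0):
        converged = False
        message = "IC50 more than 10x outside the tested concentration range"
    elif not np.isfinite(se):
        converged = False
        message = "covariance not estimable"
    return IC50Estimate(
        ic50=ic50, hill_slope=hill, standard_error=se,
        converged=converged, message=message,
    )


def ic50_from_plate(readings: Iterable[PlateReading]) -> IC50Estimate:
    """Plate to IC50: a percentage per reading, then the logistic fit on the
    replicate-level points.

    Replicates are fitted as individual points rather than averaged first:
    for a balanced design the point estimate is identical, but the residual
    degrees of freedom stay honest, so the asymptotic standard error is not
    anticonservative (with 5 averaged points and 2 parameters, +/-2 SE
    intervals would cover well below their nominal level).
    """
    per_concentration: Dict[float, List[float]] = {}
    assay = ""
    for reading in readings:
        assay = reading.assay
        per_concentration.setdefault(reading.concentration, []).append(
            percent_activity(reading)
        )
    if len(per_concentration) < 5:
        raise ValueError(
            f"at least 5 concentrations are required, got {len(per_concentration)}"
        )
    concentrations, responses = [], []
    for conc in sorted(per_concentration):
        for pct in per_concentration[conc]:
            concentrations.append(conc)
            responses.append(pct)
    return fit_ic50(DoseResponse(tuple(concentrations), tuple(responses), assay=assay))
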