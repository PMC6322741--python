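"""Drug-combination validation statistics.

Conventions: ``f`` values are fractional *inhibition* in [0, 1] (0 = no
effect, 1 = complete kill); dose-response tables carry fractional
*viability* (1 = untreated level).  Converters are provided.

* Excess Over Bliss: EOB = f_AB - (f_A + f_B - f_A * f_B); positive values
  indicate a supra-additive combination under Bliss independence.
* Combination index (Chou-Talalay, fixed-ratio form): CI = d1/D1 + d2/D2
  where D is the single-agent IC50 and d the dose of each drug in the
  IC50-achieving combination.  CI <= 0.8 is called strong synergy,
  0.8 < CI < 1 borderline, CI >= 1 additive/antagonistic.
* IC50 by log-dose linear interpolation of the first 0.5 crossing; a curve
  that never reaches 0.5 yields a censored sentinel, not a number.
* One-sided Fisher exact test for prediction-vs-outcome 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DoseResponse",
    "IC50Result",
    "SynergyCall",
    "excess_over_bliss",
    "viability_to_inhibition",
    "inhibition_to_viability",
    "ic50_interpolate",
    "combination_index",
    "fisher_exact_1sided",
]

STRONG_SYNERGY_CI = 0.8


def viability_to_inhibition(v: float) -> float:
    return 1.0 - v


def inhibition_to_viability(f: float) -> float:
    return 1.0 - f


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return value


def excess_over_bliss(fa: float, fb: float, fab: float) -> float:
    """Observed combined inhibition minus the Bliss independence expectation."""
    fa = _check_fraction("fa", fa)
    fb = _check_fraction("fb", fb)
    fab = _check_fraction("fab", fab)
    return fab - (fa + fb - fa * fb)


@dataclass
class DoseResponse:
    """Mean fractional viability at strictly increasing doses (uM)."""

    doses: np.ndarray
    responses: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.ndim != 1 or self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must be equal-length vectors")
        if self.doses.size < 2:
            raise ValueError("need at least two doses")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any((self.responses < 0) | (self.responses > 1)):
            raise ValueError("responses must be fractions in [0, 1]")


@dataclass(frozen=True)
class IC50Result:
    """Interpolated IC50 in uM, or a censoring sentinel when no crossing exists."""

    value: float | None
    censored: str | None = None  # 'above_max' or 'below_min'

    @property
    def is_censored(self) -> bool:
        return self.censored is not None


def ic50_interpolate(dr: DoseResponse) -> IC50Result:
    """Log-dose linear interpolation of the first downward 0.5 crossing."""
    r = dr.responses
    d = dr.doses
    if np.all(r > 0.5):
        return IC50Result(None, censored="above_max")
    if r[0] < 0.5:
        return IC50Result(None, censored="below_min")
    hits = np.flatnonzero(r == 0.5)
    below = np.flatnonzero(r < 0.5)
    first_below = below[0] if below.size else len(r)
    if hits.size and hits[0] < first_below:
        return IC50Result(float(d[hits[0]]))
    i = first_below  # r[i-1] > 0.5 > r[i]
    ld1, ld2 = np.log10(d[i - 1]), np.log10(d[i])
    frac = (r[i - 1] - 0.5) / (r[i - 1] - r[i])
    return IC50Result(float(10 ** (ld1 + frac * (ld2 - ld1))))


@dataclass(frozen=True)
class SynergyCall:
    ci: float
    label: str  # strong_synergy | borderline | additive_or_antagonistic


def combination_index(d1: float, big_d1: float, d2: float, big_d2: float) -> SynergyCall:
    """CI = d1/D1 + d2/D2 with the study's labelling cutpoints."""
    for name, v in (("d1", d1), ("D1", big_d1), ("d2", d2), ("D2", big_d2)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    ci = d1 / big_d1 + d2 / big_d2
    if ci <= STRONG_SYNERGY_CI:
        label = "strong_synergy"
    elif ci < 1.0:
        label = "borderline"
    else:
        label = "additive_or_antagonistic"
    return SynergyCall(float(ci), label)


def fisher_exact_1sided(table) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 count table.

    The tail covers tables at least as concordant as observed (odds ratio
    greater), i.e. the hypergeometric upper tail on the [0, 0] cell.  All
    four margins must be positive.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(np.int64)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    return float(stats.fisher_exact(t, alternative="greater")[1])
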