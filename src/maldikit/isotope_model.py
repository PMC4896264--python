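"""Averagine isotope-distribution model.

A peptide of known mass but unknown sequence is modelled with the
*averagine* composition — a hypothetical average amino-acid residue,
C 4.9384, H 7.7583, N 1.3577, O 1.4773, S 0.0417 per 111.1254 Da.  Scaling
this monomer to the target mass and rounding to an integer elemental formula
gives a composition whose aggregated (unit-spaced) isotopologue distribution
is obtained by convolving the natural isotope abundances of the elements.

The model predicts the well-known behaviour of peptide envelopes in
singly-charged MALDI/TOF spectra: at low mass the monoisotopic peak
dominates, while above roughly 1,700–1,900 Da the second isotopologue
overtakes it.  :func:`crossover_mass` locates that crossover on a mass grid;
it serves as the validation oracle for the deisotoping heuristic's
``crossover_mass`` parameter and drives realistic synthetic envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "IsotopeDistribution",
    "averagine_formula",
    "averagine_distribution",
    "crossover_mass",
]

# Monoisotopic masses (Da) and unit-spaced natural isotope abundance
# vectors (entry k = relative abundance of the +k Da isotopologue),
# standard IUPAC representative values.
_ELEMENTS: dict[str, tuple[float, tuple[float, ...]]] = {
    "C": (12.0, (0.9893, 0.0107)),
    "H": (1.0078250319, (0.999885, 0.000115)),
    "N": (14.0030740052, (0.99636, 0.00364)),
    "O": (15.9949146221, (0.99757, 0.00038, 0.00205)),
    "S": (31.97207069, (0.9499, 0.0075, 0.0425, 0.0, 0.0001)),
}

# Averagine monomer: average elemental composition per residue.
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254

_MAX_LEN = 64  # isotopologue tail length kept during convolution


@dataclass(frozen=True, slots=True)
class IsotopeDistribution:
    """Aggregated isotopologue distribution of a molecular species.

    ``rel_abundances[k]`` is the relative abundance of the isotopologue
    +k Da above the monoisotopic mass; entries are normalized to sum 1.
    """

    mass: float
    rel_abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.rel_abundances):
            raise ValidationError("isotope abundances must be non-negative")
        if abs(sum(self.rel_abundances) - 1.0) > 1e-9:
            raise ValidationError("isotope abundances must sum to 1")


def averagine_formula(mass: float) -> dict[str, int]:
    """Integer averagine elemental formula for a monoisotopic mass.

    C, N, O and S counts are rounded from the scaled monomer; the hydrogen
    count is then adjusted so the monoisotopic formula mass matches the
    target within ±1 Da.
    """
    if mass <= 0:
        raise ValidationError("mass must be positive")
    units = mass / _AVERAGINE_MASS
    counts = {
        el: int(round(_AVERAGINE[el] * units)) for el in ("C", "N", "O", "S")
    }
    heavy_mass = sum(_ELEMENTS[el][0] * n for el, n in counts.items())
    h_mass = _ELEMENTS["H"][0]
    counts["H"] = max(int(round((mass - heavy_mass) / h_mass)), 0)
    return counts


def _element_power(vec: tuple[float, ...], n: int) -> np.ndarray:
    """Convolve an element's isotope vector with itself n times (n atoms)."""
    result = np.array([1.0])
    base = np.asarray(vec, dtype=float)
    while n:
        if n & 1:
            result = np.convolve(result, base)[:_MAX_LEN]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:_MAX_LEN]
    return result


def averagine_distribution(mass: float, n_isotopes: int = 4) -> IsotopeDistribution:
    """Aggregated isotope distribution of the averagine peptide of ``mass`` Da.

    Returns the first ``n_isotopes`` relative abundances, renormalized to
    sum 1.
    """
    if n_isotopes < 2:
        raise ValidationError("n_isotopes must be >= 2")
    formula = averagine_formula(mass)
    dist = np.array([1.0])
    for el, n in formula.items():
        if n:
            dist = np.convolve(dist, _element_power(_ELEMENTS[el][1], n))[:_MAX_LEN]
    head = dist[:n_isotopes]
    head = head / head.sum()
    return IsotopeDistribution(mass, tuple(float(x) for x in head))


def crossover_mass(
    mz_lo: float, mz_hi: float, step: float = 1.0
) -> Optional[float]:
    """Smallest scanned mass at which the +1 isotopologue exceeds the
    monoisotopic peak.

    Scans ``mz_lo`` to ``mz_hi`` inclusive on a grid of ``step`` Da and
    returns the first mass where entry 1 of the averagine distribution is
    strictly greater than entry 0, or ``None`` if no crossover occurs in the
    range.
    """
    if not mz_lo < mz_hi:
        raise ValidationError("mz_lo must be below mz_hi")
    if step <= 0:
        raise ValidationError("step must be positive")
    for mass in np.arange(mz_lo, mz_hi + step / 2, step):
        d = averagine_distribution(float(mass), 2).rel_abundances
        if d[1] > d[0]:
            return float(mass)
    return None
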