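"""Per-spectrum preprocessing.

Four operations applied to each replicate spectrum before averaging:

* analysis-range restriction to a closed m/z interval,
* isotopic-peak joining — collapsing isotopic envelopes (peaks ~1 Da apart
  for singly-charged ions) onto the monoisotopic peak with summed abundance,
* internal-standard normalization — fixing a designated reference peak to
  an abundance of exactly 100.00 and scaling everything else accordingly,
* piecewise-linear threshold filtering — discarding peaks at or below an
  intensity cutoff interpolated between user-supplied anchor points.

The joining heuristic is a greedy left-to-right scan.  A group grows while
the next peak sits within ``1 ± iso_delta`` Da of the group's last member,
the group stays within ``max_isotopic_peaks``, and the abundance pattern is
admissible for the group's mass region.  Below ``crossover_mass`` the
monoisotopic peak of a peptide dominates its envelope, so abundances must
decrease strictly along the group; above it the second isotopologue can
overtake the first, so the maximum may sit at member 1 or member 2 with a
strict decrease afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import NormalizationPeakNotFound, ValidationError
from .formats import Peak, Spectrum

__all__ = [
    "IsoParams",
    "IsotopicGroup",
    "ThresholdLine",
    "restrict_range",
    "join_isotopic_peaks",
    "normalize",
    "build_threshold",
    "apply_threshold",
]

MAX_THRESHOLD_ANCHORS = 6


@dataclass(frozen=True, slots=True)
class IsoParams:
    """Tunables of the isotopic joining step.

    ``iso_delta`` is the tolerance (Da) on the nominal 1 Da spacing between
    consecutive isotopologues of a singly-charged ion; ``crossover_mass`` is
    the m/z above which the second isotopologue may exceed the monoisotopic
    peak (~1,700 Da for typical peptides).
    """

    max_isotopic_peaks: int = 4
    iso_delta: float = 0.1
    crossover_mass: float = 1700.0

    def __post_init__(self) -> None:
        if self.max_isotopic_peaks < 1:
            raise ValidationError("max_isotopic_peaks must be >= 1")
        if not 0 < self.iso_delta < 0.5:
            raise ValidationError("iso_delta must lie in (0, 0.5) Da")
        if self.crossover_mass <= 0:
            raise ValidationError("crossover_mass must be positive")


@dataclass(frozen=True, slots=True)
class IsotopicGroup:
    """An isotopic envelope collapsed onto its monoisotopic peak.

    ``monoisotopic`` carries the first member's m/z and the summed abundance
    of all members; singleton groups are their own monoisotopic peak.
    """

    monoisotopic: Peak
    members: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("an isotopic group needs at least one member")
        if self.monoisotopic.mz != self.members[0].mz:
            raise ValidationError("monoisotopic m/z must equal the first member's")


@dataclass(frozen=True, slots=True)
class ThresholdLine:
    """Piecewise-linear intensity cutoff over m/z.

    ``anchors`` are (m/z, threshold) points ascending in m/z and spanning the
    analysis range; the threshold between anchors is linear interpolation.
    """

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValidationError("a threshold line needs at least two anchors")
        for (m1, _), (m2, _) in zip(self.anchors, self.anchors[1:]):
            if not m1 < m2:
                raise ValidationError("threshold anchors must ascend in m/z")
        if any(t < 0 for _, t in self.anchors):
            raise ValidationError("threshold values must be non-negative")

    def value_at(self, mz) -> np.ndarray:
        xs = [m for m, _ in self.anchors]
        ys = [t for _, t in self.anchors]
        return np.interp(mz, xs, ys)


def restrict_range(spectrum: Spectrum, mz_min: float, mz_max: float) -> Spectrum:
    """Keep only peaks inside the closed interval [mz_min, mz_max]."""
    if not mz_min < mz_max:
        raise ValidationError(f"inverted m/z range [{mz_min}, {mz_max}]")
    return spectrum.replace_peaks(
        p for p in spectrum.peaks if mz_min <= p.mz <= mz_max
    )


def _pattern_admissible(
    abundances: Sequence[float], first_mz: float, crossover_mass: float
) -> bool:
    """Envelope abundance-shape rule.

    Below the crossover mass the abundances must decrease strictly along the
    group.  Above it the maximum may sit at member 1 or member 2, with a
    strict decrease after the maximum.
    """
    if len(abundances) == 1:
        return True
    dec_from_0 = all(a > b for a, b in zip(abundances, abundances[1:]))
    if first_mz <= crossover_mass:
        return dec_from_0
    dec_from_1 = abundances[1] > abundances[0] and all(
        a > b for a, b in zip(abundances[1:], abundances[2:])
    )
    return dec_from_0 or dec_from_1


def join_isotopic_peaks(
    spectrum: Spectrum, params: IsoParams = IsoParams()
) -> tuple[Spectrum, list[IsotopicGroup]]:
    """Collapse isotopic envelopes onto their monoisotopic peaks.

    Greedy left-to-right scan over the m/z-sorted peaks.  Each group is
    replaced by one peak at the first member's m/z carrying the summed
    abundance; ungrouped peaks pass through as singleton groups.  Total
    abundance is conserved.

    Returns the reduced spectrum and the full partition into groups
    (singletons included).
    """
    groups: list[IsotopicGroup] = []
    members: list[Peak] = []

    def close() -> None:
        if not members:
            return
        summed = math.fsum(p.abundance for p in members)
        groups.append(IsotopicGroup(Peak(members[0].mz, summed), tuple(members)))
        members.clear()

    for peak in spectrum.peaks:
        if members:
            spacing = peak.mz - members[-1].mz
            ok = (
                len(members) < params.max_isotopic_peaks
                and (1 - params.iso_delta) <= spacing <= (1 + params.iso_delta)
                and _pattern_admissible(
                    [p.abundance for p in members] + [peak.abundance],
                    members[0].mz,
                    params.crossover_mass,
                )
            )
            if not ok:
                close()
        members.append(peak)
    close()

    reduced = spectrum.replace_peaks(g.monoisotopic for g in groups)
    return reduced, groups


def normalize(spectrum: Spectrum, norm_mz: float, norm_tol: float = 0.3) -> Spectrum:
    """Scale abundances so the internal-standard peak reads exactly 100.00.

    The normalization peak is the one nearest to ``norm_mz`` within
    ``±norm_tol`` Da (ties broken toward lower m/z).  All m/z values are
    unchanged.  Raises :class:`NormalizationPeakNotFound` when no peak lies
    in the window.
    """
    if not norm_tol > 0:
        raise ValidationError("norm_tol must be positive")
    candidates = [
        (abs(p.mz - norm_mz), p.mz, i)
        for i, p in enumerate(spectrum.peaks)
        if abs(p.mz - norm_mz) <= norm_tol
    ]
    if not candidates:
        raise NormalizationPeakNotFound(
            f"no peak within ±{norm_tol} Da of m/z {norm_mz} "
            f"in spectrum {spectrum.label!r}"
        )
    _, _, idx = min(candidates)
    ref = spectrum.peaks[idx]
    if ref.abundance == 0:
        raise ValidationError(
            f"normalization peak at m/z {ref.mz} has zero abundance"
        )
    scale = 100.0 / ref.abundance
    new_peaks = [
        Peak(p.mz, 100.0 if i == idx else p.abundance * scale)
        for i, p in enumerate(spectrum.peaks)
    ]
    return spectrum.replace_peaks(new_peaks)


def build_threshold(
    anchor_pairs: Sequence[tuple[float, float]], mz_min: float, mz_max: float
) -> ThresholdLine:
    """Build a threshold line from 1–6 anchors, extended to span the range.

    If no anchor sits at a range bound, the nearest anchor's threshold value
    is held constant out to that bound.
    """
    if not 1 <= len(anchor_pairs) <= MAX_THRESHOLD_ANCHORS:
        raise ValidationError(
            f"between 1 and {MAX_THRESHOLD_ANCHORS} threshold anchors allowed, "
            f"got {len(anchor_pairs)}"
        )
    anchors = sorted((float(m), float(t)) for m, t in anchor_pairs)
    for (m1, _), (m2, _) in zip(anchors, anchors[1:]):
        if m1 == m2:
            raise ValidationError(f"duplicate threshold anchor at m/z {m1}")
    if anchors[0][0] > mz_min:
        anchors.insert(0, (float(mz_min), anchors[0][1]))
    if anchors[-1][0] < mz_max:
        anchors.append((float(mz_max), anchors[-1][1]))
    return ThresholdLine(tuple(anchors))


def apply_threshold(spectrum: Spectrum, line: ThresholdLine) -> Spectrum:
    """Keep peaks whose abundance is strictly above the interpolated cutoff."""
    if spectrum.peaks:
        lo, hi = spectrum.peaks[0].mz, spectrum.peaks[-1].mz
        if lo < line.anchors[0][0] or hi > line.anchors[-1][0]:
            raise ValidationError(
                "threshold line does not cover the spectrum's m/z extent"
            )
    cut = line.value_at([p.mz for p in spectrum.peaks])
    return spectrum.replace_peaks(
        p for p, t in zip(spectrum.peaks, cut) if p.abundance > t
    )
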