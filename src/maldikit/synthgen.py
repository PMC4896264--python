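"""Seeded generator of synthetic multi-sample MALDI/TOF peak-list files.

Emulates centroided peak lists from a small differential-proteomics study:
a handful of peptide species, each present in a subset of samples, measured
in several technical replicates per sample.  Every present species
contributes an isotopic envelope whose shape follows the averagine model
(first 3–4 isotopologues at unit spacing), with a whole-envelope m/z jitter
per replicate (instrument calibration shifts move the envelope rigidly) and
multiplicative abundance noise.  Each replicate also carries an
internal-standard peak near ``norm_mz`` and a floor of low-intensity noise
peaks placed away from the planted species so ground truth stays
unambiguous.

Everything is reproducible from ``SynthSpec.seed``; ``generate`` returns
the block-format file content together with the ground truth needed by
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .formats import Peak, SampleBlock, Spectrum, format_blocks
from .isotope_model import averagine_distribution

__all__ = ["Species", "SynthSpec", "GroundTruth", "default_species", "generate"]

# Noise peaks keep clear of a planted envelope: this margin below the
# monoisotopic mass and past the last isotopologue.
_EXCLUDE_BELOW = 2.0
_EXCLUDE_ABOVE = 1.0


@dataclass(frozen=True, slots=True)
class Species:
    """A planted peptide: monoisotopic m/z, base abundance, per-sample presence."""

    mass: float
    base_abundance: float
    incidence: tuple[bool, ...]


@dataclass(frozen=True, slots=True)
class SynthSpec:
    """Study design of a synthetic data set.

    Defaults describe a small case/control comparison: 2 samples with 4
    technical replicates each, 10 peptide species in the 800–2,500 Da
    acquisition window, 0.02 Da replicate-to-replicate m/z jitter, 10 %
    abundance CV, a spiked internal standard at the angiotensin II [M+H]+
    mass (1046.54 Da, abundance 250), and 15 low-intensity noise peaks per
    spectrum.
    """

    n_samples: int = 2
    n_replicates: int = 4
    species: Optional[tuple[Species, ...]] = None
    mz_jitter_sd: float = 0.02
    abundance_cv: float = 0.1
    n_noise_peaks: int = 15
    noise_abundance: tuple[float, float] = (0.5, 3.0)
    norm_mz: float = 1046.54
    norm_abundance: float = 250.0
    mz_range: tuple[float, float] = (800.0, 2500.0)
    n_isotopologues: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_replicates < 1:
            raise ValidationError("need at least one sample and one replicate")
        if self.mz_jitter_sd < 0 or self.abundance_cv < 0 or self.n_noise_peaks < 0:
            raise ValidationError("jitter, CV and noise counts must be >= 0")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValidationError("inverted m/z range")
        if self.species is not None:
            for sp in self.species:
                if not lo <= sp.mass <= hi:
                    raise ValidationError(
                        f"species mass {sp.mass} outside range {self.mz_range}"
                    )
                if len(sp.incidence) != self.n_samples:
                    raise ValidationError(
                        "incidence pattern length must equal n_samples"
                    )


@dataclass
class GroundTruth:
    """What was planted, and what each replicate actually realized.

    ``realized[s][r]`` maps species index -> (monoisotopic m/z as emitted,
    total envelope abundance) for each present species; ``norm_peaks[s][r]``
    is the internal standard's realized (mz, abundance).
    """

    species: list[Species]
    incidence: list[list[bool]]  # [species][sample]
    realized: list[list[dict[int, tuple[float, float]]]]
    norm_peaks: list[list[tuple[float, float]]]

    def to_json(self) -> str:
        payload = {
            "species": [
                {
                    "mass": sp.mass,
                    "base_abundance": sp.base_abundance,
                    "incidence": list(sp.incidence),
                }
                for sp in self.species
            ],
            "realized": [
                [{str(k): list(v) for k, v in rep.items()} for rep in sample]
                for sample in self.realized
            ],
            "norm_peaks": [[list(v) for v in sample] for sample in self.norm_peaks],
        }
        return json.dumps(payload, indent=1)


def default_species(
    rng: np.ndarray, n_species: int, n_samples: int,
    mz_range: tuple[float, float], norm_mz: float,
) -> tuple[Species, ...]:
    """Draw a panel of species: ~60 % present in every sample, the rest
    unique to one sample in rotation (case/control style markers)."""
    lo, hi = mz_range
    masses: list[float] = []
    while len(masses) < n_species:
        m = float(rng.uniform(lo + 5, hi - 6))
        if abs(m - norm_mz) < 8 or any(abs(m - x) < 10 for x in masses):
            continue
        masses.append(m)
    masses.sort()
    n_shared = max(1, int(round(0.6 * n_species))) if n_samples > 1 else n_species
    species = []
    uniq = 0
    for i, m in enumerate(masses):
        if i < n_shared or n_samples == 1:
            inc = tuple(True for _ in range(n_samples))
        else:
            inc = tuple(j == uniq % n_samples for j in range(n_samples))
            uniq += 1
        base = float(rng.uniform(50, 500))
        species.append(Species(m, base, inc))
    return tuple(species)


def _envelope(
    rng, sp: Species, spec: SynthSpec
) -> tuple[list[Peak], tuple[float, float]]:
    dist = averagine_distribution(sp.mass, spec.n_isotopologues).rel_abundances
    jitter = float(rng.normal(0.0, spec.mz_jitter_sd)) if spec.mz_jitter_sd else 0.0
    factor = max(float(1.0 + rng.normal(0.0, spec.abundance_cv)), 0.05)
    mono_ab = sp.base_abundance * factor
    peaks = []
    lo, hi = spec.mz_range
    for k, rel in enumerate(dist):
        mz = sp.mass + k + jitter
        if not lo <= mz <= hi:
            continue
        peaks.append(Peak(mz, mono_ab * rel / dist[0]))
    total = sum(p.abundance for p in peaks)
    return peaks, (sp.mass + jitter, total)


def _noise_peaks(rng, spec: SynthSpec, taken: Sequence[float]) -> list[Peak]:
    lo, hi = spec.mz_range
    exclude = [(m - _EXCLUDE_BELOW, m + spec.n_isotopologues + _EXCLUDE_ABOVE)
               for m in taken]
    peaks: list[Peak] = []
    attempts = 0
    while len(peaks) < spec.n_noise_peaks and attempts < 100 * (spec.n_noise_peaks + 1):
        attempts += 1
        mz = float(rng.uniform(lo, hi))
        if any(a <= mz <= b for a, b in exclude):
            continue
        if any(abs(mz - p.mz) < 0.05 for p in peaks):
            continue
        ab = float(rng.uniform(*spec.noise_abundance))
        peaks.append(Peak(mz, ab))
    return peaks


def generate(spec: SynthSpec) -> tuple[str, GroundTruth]:
    """Generate a block-format peak-list file and its ground truth.

    Deterministic given ``spec`` (the seed drives a dedicated RNG); the
    emitted text always parses with :func:`maldikit.formats.read_block_file`.
    """
    rng = np.random.default_rng(spec.seed)
    species = spec.species
    if species is None:
        species = default_species(
            rng, 10, spec.n_samples, spec.mz_range, spec.norm_mz
        )

    exclusion_centres = [sp.mass for sp in species] + [spec.norm_mz]
    blocks = []
    realized: list[list[dict[int, tuple[float, float]]]] = []
    norm_records: list[list[tuple[float, float]]] = []
    for s in range(spec.n_samples):
        spectra = []
        sample_real: list[dict[int, tuple[float, float]]] = []
        sample_norm: list[tuple[float, float]] = []
        for r in range(spec.n_replicates):
            peaks: list[Peak] = []
            rep_real: dict[int, tuple[float, float]] = {}
            # internal standard
            njit = float(rng.normal(0.0, spec.mz_jitter_sd)) if spec.mz_jitter_sd else 0.0
            nfac = max(float(1.0 + rng.normal(0.0, spec.abundance_cv)), 0.05)
            norm_peak = Peak(spec.norm_mz + njit, spec.norm_abundance * nfac)
            peaks.append(norm_peak)
            sample_norm.append((norm_peak.mz, norm_peak.abundance))
            # planted species
            for i, sp in enumerate(species):
                if not sp.incidence[s]:
                    continue
                env, real = _envelope(rng, sp, spec)
                peaks.extend(env)
                rep_real[i] = real
            peaks.extend(_noise_peaks(rng, spec, exclusion_centres))
            peaks.sort(key=lambda p: p.mz)
            label = f"sample{s + 1}" if r == 0 else f"rep{r + 1}"
            spectra.append(
                Spectrum(label, tuple(peaks), (f"sample{s + 1}", r))
            )
            sample_real.append(rep_real)
        label_row: list[str] = []
        for sp_obj in spectra:
            label_row += [sp_obj.label, ""]
        blocks.append(
            SampleBlock(f"sample{s + 1}", tuple(spectra), tuple(label_row))
        )
        realized.append(sample_real)
        norm_records.append(sample_norm)

    truth = GroundTruth(
        species=list(species),
        incidence=[[sp.incidence[s] for s in range(spec.n_samples)]
                   for sp in species],
        realized=realized,
        norm_peaks=norm_records,
    )
    return format_blocks(blocks), truth
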