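"""Shared fixtures and random-input builders for the maldikit test suite."""

from __future__ import annotations

import numpy as np
import pytest

from maldikit.formats import Peak, SampleBlock, Spectrum


def random_spectrum(rng: np.random.Generator, n_peaks: int | None = None,
                    mz_lo: float = 800.0, mz_hi: float = 2500.0) -> Spectrum:
    """Random peak list with a mix of ~1 Da spacings (isotope-like) and
    larger gaps, integer-valued abundances so that sums are exact."""
    if n_peaks is None:
        n_peaks = int(rng.integers(1, 25))
    mzs: list[float] = []
    mz = mz_lo + float(rng.uniform(0, 50))
    for _ in range(n_peaks):
        mzs.append(mz)
        if rng.random() < 0.5:
            mz += float(rng.uniform(0.9, 1.1))  # isotope-like spacing
        else:
            mz += float(rng.uniform(1.5, 40.0))
    abundances = rng.integers(1, 10_000, size=n_peaks).astype(float)
    peaks = tuple(Peak(m, a) for m, a in zip(mzs, abundances))
    return Spectrum("random", peaks)


def random_block(rng: np.random.Generator, block_index: int = 0) -> SampleBlock:
    """Random sample block shaped like what the reader itself produces, so
    write → read must be the identity on it."""
    n_spectra = int(rng.integers(1, 5))
    sample_id = f"s{block_index + 1}"
    spectra = []
    label_cells: list[str] = []
    for i in range(n_spectra):
        n_peaks = int(rng.integers(0, 9))
        mzs = np.sort(rng.uniform(800, 2500, size=n_peaks))
        while len(set(mzs)) != n_peaks:  # enforce strict ascent
            mzs = np.sort(rng.uniform(800, 2500, size=n_peaks))
        abunds = rng.uniform(0, 500, size=n_peaks)
        if n_peaks and rng.random() < 0.3:
            abunds[int(rng.integers(0, n_peaks))] = 0.0  # genuine zero intensity
        label = sample_id if i == 0 else f"{sample_id}r{i + 1}"
        peaks = tuple(Peak(float(m), float(a)) for m, a in zip(mzs, abunds))
        spectra.append(Spectrum(label, peaks, (sample_id, i)))
        label_cells += [label, ""]
    return SampleBlock(sample_id, tuple(spectra), tuple(label_cells))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160302)


@pytest.fixture
def fig2_text() -> str:
    """A three-replicate block in the documented layout, with zero padding."""
    rows = [
        "SampleA\t\trep2\t\trep3\t",
        "m/z\tabund\tm/z\tabund\tm/z\tabund",
        "800.3\t12.5\t800.31\t11.0\t800.29\t13.2",
        "1046.54\t250.0\t1046.55\t245.1\t1046.53\t255.5",
        "1200.7\t42.0\t1200.72\t40.9\t0\t0",
        "2499.9\t7.1\t0\t0\t0\t0",
    ]
    return "\n".join(rows) + "\n"
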