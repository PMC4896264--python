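# Methods

## Scope and data model

`maldikit` operates on centroided peak lists — (m/z, abundance) pairs —
from singly-charged MALDI/TOF acquisitions, not on profile-mode traces.
The in-memory model mirrors the study design: a `Spectrum` is one technical
replicate, a `SampleBlock` collects the replicates of one biological
sample, an `AverageSpectrum` is the per-sample consensus, and an
`Alignment` is the final peak-by-sample matrix. All abundances are in
arbitrary intensity units; all masses in Da.

## Preprocessing

**Range restriction** keeps peaks in the closed interval
`[mz_min, mz_max]` (defaults 800–2,500 Da, the usual low-molecular-weight
serum profiling window). Peaks exactly at a bound are retained; the
closed-interval convention is tested explicitly. Restriction runs before
isotopic joining, so an envelope straddling the range boundary is truncated
before joining; with the default window the affected region is a few Da at
each edge.

**Isotopic joining** is a greedy left-to-right scan over the m/z-sorted
peaks. A group grows while three conditions hold for the next peak:

1. its spacing from the group's *last* member lies within
   `1 ± iso_delta` Da (chain rule — an n-member envelope spans ~n−1 Da);
2. the group stays within `max_isotopic_peaks` members;
3. the abundance pattern remains admissible: strictly decreasing along the
   group when the first member's m/z is at or below `crossover_mass`, and
   above it, peaked at member 1 or member 2 with a strict decrease after
   the maximum. Ties in abundance are treated as inadmissible — a flat
   pair is not evidence of an isotopic relationship.

Each group is replaced by one peak at the first (monoisotopic) member's m/z
carrying the group's summed abundance (`math.fsum`, so the per-group sum is
correctly rounded and the spectrum total is conserved). Defaults:
`max_isotopic_peaks = 4`, `iso_delta = 0.1` Da, `crossover_mass = 1700` Da.
The delta and envelope-size defaults suit typical MALDI/TOF mass accuracy
(tens of ppm, i.e. ≤0.1 Da in this window) and peptide envelope lengths at
these masses; both are user-settable because instrument performance varies.
The abundance-pattern rule is this package's concretization of the
qualitative physics — the exact admissible shapes depend on elemental
composition, which is unknown for anonymous peaks.

**The averagine model** (module `isotope_model`) supplies an independent
check on the crossover default. A peptide of given mass is assigned the
averagine composition (C 4.9384, H 7.7583, N 1.3577, O 1.4773, S 0.0417
per 111.1254 Da), C/N/O/S counts rounded to integers and the hydrogen count
adjusted to land within ±1 Da of the target mass. The aggregated,
unit-spaced isotopologue distribution — what a MALDI/TOF at this resolution
actually reports — is the convolution of the elements' natural isotope
abundance vectors (standard IUPAC representative values, embedded as
constants; no fine structure). The +1/monoisotopic abundance ratio grows
strictly with mass over 800–3,000 Da, so the crossover is unique; a 1 Da
scan places it at 1,842 Da. The joining default of 1,700 Da is deliberately
below that model value: real peptide compositions scatter around averagine,
and the admissibility rule above the crossover also *permits* (rather than
requires) a dominant +1 member, so an early crossover setting is the
conservative choice.

**Normalization** rescales a spectrum so the internal-standard peak —
the peak nearest `norm_mz` within `±norm_tol` (default 0.3 Da; equidistant
ties go to the lower m/z for determinism) — reads exactly 100.00. The
matched peak is assigned 100.0 outright rather than multiplied by
`100/a`, avoiding a one-ulp residual; all other abundances are scaled by
that factor, m/z values untouched. A spectrum lacking the standard either
passes through unscaled with a warning or fails the run, per
`on_missing_norm_peak`.

**Threshold filtering** interpolates linearly through 1–6 user anchors.
Anchors are extended to span the analysis range by holding the first/last
threshold value constant out to the bounds, so a single anchor yields a
flat cutoff. (The extension may push the stored anchor count to 8; the
six-anchor limit applies to user input.) Peaks survive only with abundance
*strictly above* the interpolated line. Both normalization and threshold
filtering are off unless configured.

The pipeline stage order is restrict → join → normalize → threshold.
Joining before normalization means envelope sums, not raw monoisotopic
intensities, are what get scaled — consistent with summed abundance being
the species' quantity of interest. This ordering is a package choice and is
documented here because plausible alternatives exist (e.g. thresholding
before normalization changes which peaks are compared against the line).

## Averaging and alignment

Both stages use one primitive, `group_peaks`: pool all (spectrum, peak)
pairs, sort by m/z (ties broken by spectrum index), and walk the pool once.
A peak joins the open group when its m/z lies within `delta` of the group's
*running mean* and its spectrum is not yet represented; either failure
closes the group and opens a new one at that peak. Testing against the
running mean (rather than the first or last member) is symmetric and
bounds group drift — the observed group diameter never exceeds 2·delta.
The same-spectrum conflict closing the group (rather than skipping the
peak) keeps the pass deterministic and single-sweep; it can split a group
that a more global matcher would keep whole, which is accepted and covered
by the brute-force equivalence tests.

A support policy converts to a concrete minimum count as: all → n;
all-but-one → max(1, n−1); majority → ⌊n/2⌋+1 (the smallest count strictly
over 50 %); at-least-two → min(2, n); any → 1; user k → min(k, n). A group
is reported when its support is **≥** the resolved minimum — with a strict
inequality the "all spectra" policy would be unsatisfiable, so ≥ is the
only consistent reading.

Defaults: `rep_delta = avg_delta = 0.3` Da, replicate policy `majority`,
alignment policy `any` — demanding for averaging (sporadic acquisition
artefacts are suppressed), permissive for alignment (rare,
possibly-discriminating signals are preserved for downstream differential
analysis). Means in consensus peaks and alignment rows are computed over
*contributing* spectra only; a missing signal is an empty cell, never a
zero.

## Synthetic data generator

`synthgen` emulates the smallest realistic differential study: 2 samples ×
4 replicates, 10 peptide species in 800–2,500 Da (about 60 % present in
every sample, the rest unique to one sample in rotation, base abundances
50–500), an internal standard at 1046.54 Da (the angiotensin II [M+H]+
mass) with abundance 250, replicate m/z jitter of σ = 0.02 Da, 10 %
multiplicative abundance noise, and 15 uniform noise peaks per spectrum at
abundance 0.5–3. Envelope shapes come from the averagine model (first 4
isotopologues, unit spacing). Jitter is shared across an envelope's
members — calibration error moves a spectrum rigidly — while noise peaks
move independently; abundance noise is likewise shared across an envelope
so the envelope shape stays admissible for the joining rule. Noise peaks
keep 2 Da below and 1 Da past each planted envelope and the standard so
ground truth stays unambiguous.

What the generator does *not* emulate — peak-shape/resolution effects,
m/z-dependent calibration drift (warping), detector saturation, chemical
background that correlates across replicates, real spectrum-to-spectrum
peak-count variation — bounds what the recovery tests show: they
demonstrate that the chain of joining, normalization, filtering, averaging
and alignment is correct and loss-free under the stated noise model, not
that the parameter defaults are optimal for any particular instrument.

## Numerical and format conventions

* Floats are serialized with `repr`, the shortest string that round-trips
  exactly, making write → read the identity and repeated runs byte-identical.
* A (0, 0) column pair is zero padding and is dropped on read; a pair with
  positive m/z and abundance exactly 0 is a genuine zero-intensity peak
  and is kept.
* Decimal commas are rejected with a pointed error; block separators are
  any row whose first cell starts with a backslash (trailing cells from
  spreadsheet exports are tolerated); unsorted input spectra are sorted
  with a warning rather than rejected.
* Abundance conservation under joining is exact (`fsum` per group); across
  groups the *total* of rounded group sums can differ from the raw total
  by rounding only when abundances are not exactly summable — the
  conservation tests therefore use integer-valued abundances, where every
  sum is exact in double precision.
* The label row is stored verbatim: the format in the wild carries either
  one label per spectrum or one per sample, so the reader accepts both and
  takes the sample id from the first non-empty label cell (falling back to
  an ordinal).

## Test problem sizes

Property and equivalence suites run at sizes where exhaustive oracles are
feasible and the full suite stays fast: brute-force grouping equivalence on
500 random pools of ≤ 15 peaks (all 2^(n−1) contiguous partitions
enumerated), joining equivalence on spectra of ≤ 12 peaks, conservation on
1,000 random spectra, round-trip fidelity on 100 random block files, and
end-to-end recovery on 20 seeded synthetic studies. The recovery criterion
— exact incidence recovery and mean-m/z error < 0.03 Da ≈ 3σ/√n at the
generator's jitter — is checked against the final alignment.

## Known limitations

* No charge-state deconvolution: everything assumes singly-charged ions.
* The greedy joiner cannot split overlapping envelopes of different
  species, and a least-squares averagine envelope fit is out of scope.
* No dynamic baseline estimation; the piecewise-linear threshold is static.
* Bit-compatibility with other alignment implementations is not claimed;
  the window semantics (running-mean test, conflict-closes-group) are this
  package's documented choice.
* mzML is not read or written; input is the block TSV/CSV layout only.
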