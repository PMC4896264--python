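# maldikit

Automated preprocessing of MALDI/TOF peak-list spectra for comparative
proteomics.

Serum-profiling studies acquire each biological sample several times on a
MALDI/TOF instrument, producing a handful of technical-replicate peak lists
per sample. Before any differential analysis can happen those lists need a
chain of routine but error-prone steps: collapsing isotopic envelopes,
normalizing intensities against an internal standard, removing background
signals, averaging replicates into a consensus spectrum per sample, and
aligning the consensus spectra from different samples into a single
peak-by-sample matrix. `maldikit` automates the whole chain as a library
and a command-line tool, for mass-spectrometry analysts who want a
reproducible pipeline from raw exported peak lists to an alignment table
ready for statistics.

## What it computes

* **Isotopic joining.** For singly-charged ions, a molecular species appears
  as an envelope of peaks spaced ~1 Da apart. Consecutive peaks whose
  spacing lies within `1 ± δ_iso` Da are joined greedily (up to a maximum
  envelope size) when their abundance pattern is physically plausible:
  strictly decreasing for envelopes starting at m/z ≤ M_c, and peaked at
  member 1 or 2 (then strictly decreasing) above M_c. The envelope is
  replaced by its monoisotopic peak carrying the summed abundance, so total
  abundance is conserved exactly. The crossover mass M_c defaults to
  1,700 Da; the package's averagine isotope model (composition
  C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇ per 111.1254 Da, convolved elemental
  isotope abundances) locates the actual +1/monoisotopic crossover at
  1,842 Da on a 1 Da scan, consistent with that default.
* **Normalization.** The peak nearest a stated reference mass (within
  ±`norm_tol`) is fixed to an abundance of exactly 100.00 and every other
  abundance is scaled by the same factor.
* **Threshold filtering.** A piecewise-linear intensity cutoff through up
  to six (m/z, value) anchors; only peaks strictly above the interpolated
  line survive.
* **Averaging and alignment.** Equivalent signals across spectra are found
  by pooling all peaks, sorting by m/z, and growing groups whose members
  stay within `δ` of the group's running mean with at most one peak per
  spectrum. Groups supported by enough spectra (policies: all, all but
  one, majority >50 %, at least two, any, or a user count) become consensus
  peaks (replicate averaging) or alignment rows (cross-sample alignment)
  with arithmetic-mean m/z and abundance over the contributing spectra.

Input and output use a simple block-structured TSV/CSV layout: one block
per sample, one (m/z, abundance) column pair per replicate, shorter spectra
zero-padded, blocks separated by a `\\` row.

## Worked example

Generate a synthetic two-sample study (4 replicates each, 10 planted
peptide species, internal standard at 1046.54 Da) and run the pipeline:

```
$ maldikit synth --seed 7 --out example.tsv --truth truth.json
$ maldikit run example.tsv --out-dir out \
      --norm-mz 1046.54 --threshold 800:5 --threshold 2500:5 -v
INFO read 2 sample block(s) from example.tsv
INFO sample1/1: 48 peaks -> 48 in range -> 24 joined -> 9 filtered
...
INFO sample1: average spectrum with 9 peaks from 4 replicate(s)
wrote 40 file(s) to out
```

Each replicate's 48 raw peaks collapse to 24 after isotopic joining (the 10
planted envelopes and the internal standard lose their +1/+2/+3 members)
and to 9 after the 5-unit threshold removes the noise floor — the planted
species present in that sample plus the standard. The final alignment
(`out/alignment.tsv`) begins:

```
n_spectra  mz_avg              sample1            sample2            abund_avg ...
2          813.8872125416963   813.8809212459028  813.8935038374897  117.909...
2          1046.5372701805932  1046.528518183751  1046.5460221774351 100.0 ...
```

Column 1 counts the samples presenting the signal; empty cells mark samples
in which a signal is absent. The internal standard reads exactly 100.0 in
every column. Per-spectrum "original", "filtered" and "isotopic groups"
files, per-sample average spectra, and HTML renderings of the tabular
reports are written alongside.

The `--profile quick|bright|standard` option controls how many parameters
are exposed: `quick` only the m/z range and normalization mass, `bright`
additionally the two support policies, `standard` everything.

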