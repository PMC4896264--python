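"""End-to-end orchestration: read → restrict → join → normalize → threshold
→ average → align → write.

Three parameter profiles mirror the tool's original search interfaces:

* ``quick`` — exposes only the analysis m/z range and the normalization
  peak mass; everything else runs with defaults.
* ``bright`` — additionally exposes the two support policies that govern
  replicate averaging and cross-sample alignment.
* ``standard`` — exposes every parameter.

Per input spectrum the run writes an "original", a "filtered" and an
"isotopic groups" file; per sample the average spectrum plus the alignment
of its replicates; and globally the alignment of the average spectra.
Normalization is skipped (with a warning) when no normalization mass is
configured, and threshold filtering is skipped when no anchors are given —
both stages are off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from . import align as align_mod
from . import formats
from .errors import NormalizationPeakNotFound, ValidationError
from .preprocess import (
    IsoParams,
    apply_threshold,
    build_threshold,
    join_isotopic_peaks,
    normalize,
    restrict_range,
)

__all__ = ["Params", "RunReport", "load_profile", "run", "PROFILES"]

logger = logging.getLogger("maldikit")


@dataclass(frozen=True, slots=True)
class Params:
    """Full parameter set of one pipeline run."""

    mz_min: float = 800.0
    mz_max: float = 2500.0
    norm_mz: Optional[float] = None
    norm_tol: float = 0.3
    threshold_anchors: tuple[tuple[float, float], ...] = ()
    iso: IsoParams = field(default_factory=IsoParams)
    align: align_mod.AlignParams = field(default_factory=align_mod.AlignParams)
    profile: str = "standard"
    on_missing_norm_peak: str = "warn_skip"
    html: bool = True

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValidationError("mz_min must be below mz_max")
        if self.on_missing_norm_peak not in ("warn_skip", "fail"):
            raise ValidationError(
                "on_missing_norm_peak must be 'warn_skip' or 'fail'"
            )
        if len(self.threshold_anchors) > 6:
            raise ValidationError("at most 6 threshold anchors")


# Which override keys each profile exposes.
_QUICK_KEYS = {"mz_min", "mz_max", "norm_mz"}
_BRIGHT_KEYS = _QUICK_KEYS | {"rep_min_signals", "avg_min_signals"}
_STANDARD_KEYS = _BRIGHT_KEYS | {
    "norm_tol",
    "threshold_anchors",
    "max_isotopic_peaks",
    "iso_delta",
    "crossover_mass",
    "rep_delta",
    "avg_delta",
    "on_missing_norm_peak",
    "html",
}

PROFILES = {
    "quick": _QUICK_KEYS,
    "bright": _BRIGHT_KEYS,
    "standard": _STANDARD_KEYS,
}


def load_profile(name: str, overrides: Optional[dict] = None) -> Params:
    """Build a :class:`Params` from a profile name plus user overrides.

    ``quick`` and ``bright`` reject overrides of parameters they do not
    expose; the full set is available through the ``standard`` profile.
    """
    if name not in PROFILES:
        raise ValidationError(
            f"unknown profile {name!r}; choose quick, bright or standard"
        )
    overrides = dict(overrides or {})
    allowed = PROFILES[name]
    for key in overrides:
        if key not in _STANDARD_KEYS:
            raise ValidationError(f"unknown parameter {key!r}")
        if key not in allowed:
            raise ValidationError(
                f"parameter {key!r} is not exposed by the {name!r} profile; "
                "use the standard profile to set it"
            )

    iso_kwargs = {
        k: overrides.pop(k)
        for k in ("max_isotopic_peaks", "iso_delta", "crossover_mass")
        if k in overrides
    }
    align_kwargs = {}
    for k in ("rep_delta", "avg_delta"):
        if k in overrides:
            align_kwargs[k] = overrides.pop(k)
    for k in ("rep_min_signals", "avg_min_signals"):
        if k in overrides:
            v = overrides.pop(k)
            if isinstance(v, str):
                v = align_mod.SupportPolicy.parse(v)
            align_kwargs[k] = v
    if "threshold_anchors" in overrides:
        overrides["threshold_anchors"] = tuple(
            (float(m), float(t)) for m, t in overrides["threshold_anchors"]
        )
    return Params(
        profile=name,
        iso=IsoParams(**iso_kwargs),
        align=align_mod.AlignParams(**align_kwargs),
        **overrides,
    )


@dataclass
class RunReport:
    """Per-stage peak counts, warnings and the output-file manifest."""

    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    manifest: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def run(input_path, params: Params, out_dir) -> RunReport:
    """Execute the full pipeline on a block peak-list file.

    Writes the complete output family under ``out_dir`` and returns a
    :class:`RunReport`.  The run is deterministic: identical input and
    parameters produce byte-identical TSV outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    blocks = formats.read_block_file(input_path)
    logger.info("read %d sample block(s) from %s", len(blocks), input_path)

    line = None
    if params.threshold_anchors:
        line = build_threshold(params.threshold_anchors, params.mz_min, params.mz_max)
    else:
        report.warn("no threshold anchors given; threshold filtering skipped")
    if params.norm_mz is None:
        report.warn("no normalization mass given; normalization skipped")

    def emit(path: Path, writer, *args) -> None:
        writer(*args, path)
        report.manifest.append(str(path.relative_to(out)))

    avg_spectra = []
    for block in blocks:
        filtered_spectra = []
        for spectrum in block.spectra:
            key = f"{block.sample_id}/{spectrum.source[1] + 1}"
            counts = {"original": len(spectrum)}
            stem = f"{_safe(block.sample_id)}_rep{spectrum.source[1] + 1}"
            emit(out / f"{stem}_original.tsv", formats.write_peak_list, spectrum)

            spec = restrict_range(spectrum, params.mz_min, params.mz_max)
            counts["restricted"] = len(spec)
            spec, groups = join_isotopic_peaks(spec, params.iso)
            counts["joined"] = len(spec)
            emit(
                out / f"{stem}_isotopic_groups.tsv",
                formats.write_isotopic_groups_report, groups,
            )
            if params.html:
                formats.write_isotopic_groups_report(
                    groups, out / f"{stem}_isotopic_groups.html", mode="html"
                )
                report.manifest.append(f"{stem}_isotopic_groups.html")

            if params.norm_mz is not None:
                try:
                    spec = normalize(spec, params.norm_mz, params.norm_tol)
                except NormalizationPeakNotFound as exc:
                    if params.on_missing_norm_peak == "fail":
                        raise
                    report.warn(f"{key}: {exc}; spectrum left unscaled")
            if line is not None:
                spec = apply_threshold(spec, line)
            counts["filtered"] = len(spec)
            if len(spec) == 0:
                report.warn(f"{key}: no peaks survive filtering")
            emit(out / f"{stem}_filtered.tsv", formats.write_peak_list, spec)
            report.stage_counts[key] = counts
            logger.info(
                "%s: %d peaks -> %d in range -> %d joined -> %d filtered",
                key, counts["original"], counts["restricted"],
                counts["joined"], counts["filtered"],
            )
            filtered_spectra.append(spec)

        avg = align_mod.average_replicates(
            formats.SampleBlock(block.sample_id, tuple(filtered_spectra),
                                block.label_row),
            params.align,
        )
        avg_spectra.append(avg)
        stem = f"{_safe(block.sample_id)}_average"
        emit(out / f"{stem}.tsv", formats.write_average_spectrum, avg)
        rep_alignment = align_mod.replicate_alignment(avg)
        emit(out / f"{stem}_alignment.tsv", formats.write_alignment, rep_alignment)
        if params.html:
            formats.write_alignment(
                rep_alignment, out / f"{stem}_alignment.html", mode="html"
            )
            report.manifest.append(f"{stem}_alignment.html")
        logger.info(
            "%s: average spectrum with %d peaks from %d replicate(s)",
            block.sample_id, len(avg.peaks), len(block.spectra),
        )

    if len(avg_spectra) >= 2:
        alignment = align_mod.align_spectra(avg_spectra, params.align)
        emit(out / "alignment.tsv", formats.write_alignment, alignment)
        if params.html:
            formats.write_alignment(alignment, out / "alignment.html", mode="html")
            report.manifest.append("alignment.html")
        logger.info("global alignment: %d rows across %d samples",
                    len(alignment.rows), len(avg_spectra))
    else:
        report.warn("fewer than two samples; no cross-sample alignment written")
    return report
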