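"""Delta-window grouping of peaks across spectra.

The same primitive serves two stages of the pipeline: averaging technical
replicates of one sample into a consensus ("average") spectrum, and aligning
average spectra from different samples into a peak-by-sample matrix.

Grouping pools the peaks of all spectra, sorts them by m/z, and walks the
pool with a single pass: a peak joins the open group when its m/z lies
within ``delta`` of the group's running mean and its spectrum is not yet
represented in the group; otherwise the group closes and a new one opens.
A support policy (all / all-but-one / majority / at-least-two / any /
user-defined count) then decides which groups carry enough spectra to be
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ValidationError
from .formats import Alignment, AlignmentRow, Peak, SampleBlock, Spectrum

__all__ = [
    "SupportPolicy",
    "AlignParams",
    "AveragePeak",
    "AverageSpectrum",
    "resolve_min_signals",
    "group_peaks",
    "average_replicates",
    "align_spectra",
]

_POLICY_KINDS = ("all", "all_but_one", "majority", "at_least_two", "any", "user")


@dataclass(frozen=True, slots=True)
class SupportPolicy:
    """How many spectra must present a signal for it to be reported.

    ``kind`` is one of ``all``, ``all_but_one``, ``majority`` (strictly
    >50 %), ``at_least_two``, ``any``, or ``user`` with an explicit count
    ``user_k``.
    """

    kind: str = "any"
    user_k: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _POLICY_KINDS:
            raise ValidationError(
                f"unknown support policy {self.kind!r}; choose from {_POLICY_KINDS}"
            )
        if self.kind == "user" and self.user_k < 1:
            raise ValidationError("user_k must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "SupportPolicy":
        """Parse ``"majority"`` or ``"user:3"`` style strings."""
        if ":" in text:
            kind, _, k = text.partition(":")
            return cls(kind.strip(), int(k))
        return cls(text.strip())


@dataclass(frozen=True, slots=True)
class AlignParams:
    """Deltas and support policies for replicate averaging and alignment.

    A demanding policy suits averaging (sporadic acquisition artefacts are
    dropped), while a permissive one suits alignment (rare signals are kept
    for downstream differential analysis) — hence the asymmetric defaults.
    """

    rep_delta: float = 0.3
    rep_min_signals: SupportPolicy = field(
        default_factory=lambda: SupportPolicy("majority")
    )
    avg_delta: float = 0.3
    avg_min_signals: SupportPolicy = field(
        default_factory=lambda: SupportPolicy("any")
    )

    def __post_init__(self) -> None:
        if self.rep_delta <= 0 or self.avg_delta <= 0:
            raise ValidationError("alignment deltas must be positive")


@dataclass(frozen=True, slots=True)
class AveragePeak:
    """One consensus peak: means over the contributing replicates.

    ``provenance[i]`` is the (mz, abundance) pair contributed by replicate
    ``i``, or ``None`` when that replicate lacks the signal.
    """

    mean_mz: float
    mean_abundance: float
    support: int
    provenance: tuple[Optional[tuple[float, float]], ...]


@dataclass(frozen=True, slots=True)
class AverageSpectrum:
    """Consensus spectrum of one sample's replicates."""

    sample_id: str
    peaks: tuple[AveragePeak, ...]
    replicate_labels: tuple[str, ...] = ()


def resolve_min_signals(policy: SupportPolicy, n_spectra: int) -> int:
    """Resolve a support policy to a concrete minimum count for n spectra."""
    if n_spectra < 1:
        raise ValidationError("n_spectra must be >= 1")
    n = n_spectra
    if policy.kind == "all":
        return n
    if policy.kind == "all_but_one":
        return max(1, n - 1)
    if policy.kind == "majority":
        return n // 2 + 1
    if policy.kind == "at_least_two":
        return min(2, n)
    if policy.kind == "any":
        return 1
    return min(policy.user_k, n)


def group_peaks(
    peak_lists: Sequence[Sequence[Peak]], delta: float
) -> list[list[tuple[int, Peak]]]:
    """Partition the pooled peaks of several spectra into m/z groups.

    Pools all (spectrum index, peak) pairs, sorts by m/z, and walks the pool
    opening a group at the first unassigned peak.  A peak joins the open
    group when (a) its m/z differs from the group's current mean by at most
    ``delta`` and (b) its spectrum has no peak in the group yet; when either
    test fails the group closes and a new one opens at that peak.  Every
    peak ends up in exactly one group.
    """
    if delta <= 0:
        raise ValidationError("delta must be positive")
    pool = sorted(
        ((peak, idx) for idx, peaks in enumerate(peak_lists) for peak in peaks),
        key=lambda t: (t[0].mz, t[1]),
    )
    groups: list[list[tuple[int, Peak]]] = []
    current: list[tuple[int, Peak]] = []
    mz_sum = 0.0
    seen: set[int] = set()
    for peak, idx in pool:
        if current:
            mean = mz_sum / len(current)
            if abs(peak.mz - mean) > delta or idx in seen:
                groups.append(current)
                current, mz_sum, seen = [], 0.0, set()
        current.append((idx, peak))
        mz_sum += peak.mz
        seen.add(idx)
    if current:
        groups.append(current)
    return groups


def _group_stats(group: Sequence[tuple[int, Peak]]) -> tuple[float, float]:
    mean_mz = math.fsum(p.mz for _, p in group) / len(group)
    mean_ab = math.fsum(p.abundance for _, p in group) / len(group)
    return mean_mz, mean_ab


def average_replicates(
    block: SampleBlock, params: AlignParams = AlignParams()
) -> AverageSpectrum:
    """Average a sample's (preprocessed) replicate spectra into a consensus.

    Equivalent signals across replicates are grouped with ``rep_delta``;
    groups supported by at least ``resolve_min_signals(rep_min_signals, n)``
    replicates become consensus peaks whose m/z and abundance are the
    arithmetic means over the contributing replicates.
    """
    n = len(block.spectra)
    min_sig = resolve_min_signals(params.rep_min_signals, n)
    groups = group_peaks([s.peaks for s in block.spectra], params.rep_delta)
    peaks = []
    for group in groups:
        if len(group) < min_sig:
            continue
        mean_mz, mean_ab = _group_stats(group)
        prov: list[Optional[tuple[float, float]]] = [None] * n
        for idx, p in group:
            prov[idx] = (p.mz, p.abundance)
        peaks.append(AveragePeak(mean_mz, mean_ab, len(group), tuple(prov)))
    peaks.sort(key=lambda p: p.mean_mz)
    return AverageSpectrum(
        block.sample_id,
        tuple(peaks),
        tuple(s.label for s in block.spectra),
    )


def replicate_alignment(avg: AverageSpectrum) -> Alignment:
    """Render an average spectrum's provenance as an alignment table."""
    rows = []
    for p in avg.peaks:
        rows.append(
            AlignmentRow(
                support=p.support,
                mean_mz=p.mean_mz,
                per_spectrum_mz=tuple(
                    None if v is None else v[0] for v in p.provenance
                ),
                mean_abundance=p.mean_abundance,
                per_spectrum_abundance=tuple(
                    None if v is None else v[1] for v in p.provenance
                ),
            )
        )
    labels = avg.replicate_labels or tuple(
        f"{avg.sample_id}:{i + 1}"
        for i in range(len(avg.peaks[0].provenance) if avg.peaks else 0)
    )
    return Alignment(labels, tuple(rows))


def align_spectra(
    avg_spectra: Sequence[AverageSpectrum], params: AlignParams = AlignParams()
) -> Alignment:
    """Align average spectra from different samples into a peak matrix.

    Groups consensus peaks across samples with ``avg_delta``; groups
    supported by at least ``resolve_min_signals(avg_min_signals, n)``
    samples become alignment rows with per-sample m/z and abundance columns
    (missing signals are empty, not zero).
    """
    if len(avg_spectra) < 2:
        raise ValidationError("alignment needs at least two average spectra")
    n = len(avg_spectra)
    min_sig = resolve_min_signals(params.avg_min_signals, n)
    peak_lists = [
        [Peak(p.mean_mz, p.mean_abundance) for p in a.peaks] for a in avg_spectra
    ]
    groups = group_peaks(peak_lists, params.avg_delta)
    rows = []
    for group in groups:
        if len(group) < min_sig:
            continue
        mean_mz, mean_ab = _group_stats(group)
        per_mz: list[Optional[float]] = [None] * n
        per_ab: list[Optional[float]] = [None] * n
        for idx, p in group:
            per_mz[idx] = p.mz
            per_ab[idx] = p.abundance
        rows.append(
            AlignmentRow(len(group), mean_mz, tuple(per_mz), mean_ab, tuple(per_ab))
        )
    rows.sort(key=lambda r: r.mean_mz)
    return Alignment(tuple(a.sample_id for a in avg_spectra), tuple(rows))
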