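"""Consensus segment calling from multi-sample signal and methylation tracks.

Formalizes the visual identification of consistent genomic segments:

* enrichment segments (S/A/B-style) - bins whose signal reaches a per-track
  quantile in a consensus fraction of tracks, merged and length-filtered;
* hypomethylated regions (H-style) - per-sample runs of low methylation
  fraction, intersected across samples for consistency.

The per-track quantile normalizes sequencing-depth differences between
samples (the display-level equivalent is per-track auto-scaling). Bins with
no data count as zero signal and not-enriched, so consensus support stays
comparable across tracks with missing coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

VALID_ASSAYS = {"ChIP", "DNase", "ATAC"}


@dataclass
class SignalTrack:
    """Per-interval signal for one sample (1-based inclusive intervals)."""

    sample_id: str
    assay: str
    intervals: list[tuple[int, int, float]]
    mark: str | None = None

    def __post_init__(self) -> None:
        if self.assay not in VALID_ASSAYS:
            raise ValueError(f"assay must be one of {sorted(VALID_ASSAYS)}, got {self.assay!r}")
        prev_end = None
        for start, end, value in self.intervals:
            if end < start:
                raise ValueError(f"{self.sample_id}: inverted interval ({start}, {end})")
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{self.sample_id}: invalid signal value {value!r}")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{self.sample_id}: intervals must be sorted and non-overlapping")
            prev_end = end


@dataclass
class MethylationTrack:
    """Per-interval methylation fraction (0..1) for one sample."""

    sample_id: str
    intervals: list[tuple[int, int, float]]
    age_label: str = ""

    def __post_init__(self) -> None:
        for start, end, frac in self.intervals:
            if end < start:
                raise ValueError(f"{self.sample_id}: inverted interval ({start}, {end})")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{self.sample_id}: methylation fraction {frac} outside [0, 1]")


@dataclass(frozen=True)
class SegmentCall:
    interval: tuple[int, int]
    label: str
    support: float
    mean_signal: float
    n_tracks: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support {self.support} outside [0, 1]")
        if self.interval[1] <= self.interval[0]:
            raise ValueError(f"empty segment interval {self.interval}")

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1


@dataclass
class CallerParams:
    """Tunable thresholds for consensus segment and HMR calling.

    Defaults target kb-scale consensus segments over pileup-density tracks:
    200 bp bins, per-track 0.75 enrichment quantile, consensus in 70% of
    tracks, merging across gaps up to 2 kb, minimum call length 500 bp; HMRs
    are runs of >= 3 bins at methylation fraction <= 0.3.
    """

    bin_size: int = 200
    enrich_quantile: float = 0.75
    consensus_fraction: float = 0.7
    merge_gap: int = 2000
    min_length: int = 500
    hmr_threshold: float = 0.3
    hmr_min_cpg_bins: int = 3

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.merge_gap < 0 or self.min_length <= 0 or self.hmr_min_cpg_bins <= 0:
            raise ValueError("bin_size, min_length and hmr_min_cpg_bins must be positive")
        for name in ("enrich_quantile", "consensus_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.hmr_threshold < 1.0:
            raise ValueError(f"hmr_threshold must be in (0, 1), got {self.hmr_threshold}")


def _bin_grid(region: tuple[int, int], bin_size: int) -> np.ndarray:
    start, end = region
    if end < start:
        raise ValueError(f"empty region {region}")
    length = end - start + 1
    if bin_size > length:
        raise ValueError(f"bin_size {bin_size} exceeds region length {length}")
    edges = np.arange(start, end + 2, bin_size)
    if edges[-1] != end + 1:
        edges = np.append(edges, end + 1)
    return edges  # bin i covers [edges[i], edges[i+1]-1]


def bin_track(
    intervals: list[tuple[int, int, float]],
    region: tuple[int, int],
    bin_size: int,
    warn_missing: bool = True,
    sample_id: str = "",
) -> np.ndarray:
    """Coverage-weighted mean value per bin; bases with no data count as 0."""
    edges = _bin_grid(region, bin_size)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    covered = np.zeros(n_bins)
    for start, end, value in intervals:
        s, e = max(start, region[0]), min(end, region[1])
        if e < s:
            continue
        first = int(np.searchsorted(edges, s, side="right") - 1)
        last = int(np.searchsorted(edges, e, side="right") - 1)
        for b in range(first, last + 1):
            lo = max(s, int(edges[b]))
            hi = min(e, int(edges[b + 1]) - 1)
            n = hi - lo + 1
            sums[b] += value * n
            covered[b] += n
    widths = np.diff(edges)
    if warn_missing and (covered < widths).any():
        warnings.warn(
            f"track {sample_id or '<unnamed>'}: {(covered < widths).sum()} of {n_bins} bins "
            "have missing coverage; missing bases treated as 0",
            stacklevel=2,
        )
    return sums / widths


def _merge_bins(mask: np.ndarray, edges: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Merge flagged bins into intervals, bridging gaps <= merge_gap bases."""
    segments: list[tuple[int, int]] = []
    for b in np.flatnonzero(mask):
        start, end = int(edges[b]), int(edges[b + 1]) - 1
        if segments and start - segments[-1][1] - 1 <= merge_gap:
            segments[-1] = (segments[-1][0], end)
        else:
            segments.append((start, end))
    return segments


def call_consensus_segments(
    tracks: list[SignalTrack],
    region: tuple[int, int],
    params: CallerParams | None = None,
    label_prefix: str = "S",
    strand: str = "+",
) -> list[SegmentCall]:
    """Segments enriched in a consensus fraction of signal tracks.

    Per track, bin means are compared with that track's ``enrich_quantile``
    within the region; a bin with positive signal at or above the quantile is
    enriched. Bins enriched in >= ``consensus_fraction`` of tracks are merged
    across gaps <= ``merge_gap`` and filtered to >= ``min_length``. Segments
    are labeled in transcription-direction order for the given strand.
    """
    if not tracks:
        raise ValueError("at least one track is required")
    params = params or CallerParams()
    edges = _bin_grid(region, params.bin_size)
    binned = np.vstack(
        [
            bin_track(t.intervals, region, params.bin_size, sample_id=t.sample_id)
            for t in tracks
        ]
    )
    thresholds = np.quantile(binned, params.enrich_quantile, axis=1, keepdims=True)
    enriched = (binned >= thresholds) & (binned > 0)
    support = enriched.mean(axis=0)
    consensus = support >= params.consensus_fraction
    merged = _merge_bins(consensus, edges, params.merge_gap)
    calls: list[SegmentCall] = []
    kept = [(s, e) for s, e in merged if e - s + 1 >= params.min_length]
    if strand == "-":
        kept = kept[::-1]
    for i, (s, e) in enumerate(kept, start=1):
        first = int(np.searchsorted(edges, s, side="right") - 1)
        last = int(np.searchsorted(edges, e, side="right") - 1)
        calls.append(
            SegmentCall(
                interval=(s, e),
                label=f"{label_prefix}{i}",
                support=float(support[first : last + 1].mean()),
                mean_signal=float(binned[:, first : last + 1].mean()),
                n_tracks=len(tracks),
            )
        )
    return calls


def call_hmrs(
    tracks: list[MethylationTrack],
    region: tuple[int, int],
    params: CallerParams | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Per-sample hypomethylated regions.

    For each sample, maximal runs of >= ``hmr_min_cpg_bins`` bins with mean
    methylation fraction <= ``hmr_threshold``, merged across gaps <=
    ``merge_gap``.
    """
    if not tracks:
        raise ValueError("at least one track is required")
    params = params or CallerParams()
    edges = _bin_grid(region, params.bin_size)
    out: dict[str, list[tuple[int, int]]] = {}
    for track in tracks:
        binned = bin_track(track.intervals, region, params.bin_size, warn_missing=False)
        low = binned <= params.hmr_threshold
        # drop runs shorter than the minimum before merging across gaps
        runs: list[tuple[int, int]] = []
        b = 0
        n_bins = len(low)
        while b < n_bins:
            if not low[b]:
                b += 1
                continue
            run_start = b
            while b < n_bins and low[b]:
                b += 1
            if b - run_start >= params.hmr_min_cpg_bins:
                runs.append((int(edges[run_start]), int(edges[b]) - 1))
        merged: list[tuple[int, int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] - 1 <= params.merge_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        out[track.sample_id] = merged
    return out


def consistent_hmrs(
    per_sample: dict[str, list[tuple[int, int]]],
    min_samples: int | None = None,
    min_reciprocal_overlap: float = 0.5,
    label_prefix: str = "H",
    strand: str = "+",
) -> list[SegmentCall]:
    """Consensus HMRs covered by >= ``min_samples`` samples.

    A consensus HMR is a maximal interval covered by per-sample HMRs in at
    least ``min_samples`` samples, additionally requiring a reciprocal
    overlap of ``min_reciprocal_overlap`` with a contributing HMR in that
    many samples (guards against thin slivers of deep stacks).
    """
    n = len(per_sample)
    if min_samples is None:
        min_samples = n
    if n < min_samples:
        raise ValueError(f"{n} samples provided but min_samples={min_samples}")
    events: list[tuple[int, int]] = []
    for hmrs in per_sample.values():
        for s, e in hmrs:
            events.append((s, 1))
            events.append((e + 1, -1))
    events.sort()
    candidates: list[tuple[int, int]] = []
    depth = 0
    open_start: int | None = None
    for pos, delta in events:
        new_depth = depth + delta
        if depth < min_samples <= new_depth:
            open_start = pos
        elif new_depth < min_samples <= depth and open_start is not None:
            candidates.append((open_start, pos - 1))
            open_start = None
        depth = new_depth
    calls: list[SegmentCall] = []
    kept: list[tuple[int, int, float]] = []
    for s, e in candidates:
        length = e - s + 1
        n_support = 0
        for hmrs in per_sample.values():
            ok = False
            for hs, he in hmrs:
                ov = min(e, he) - max(s, hs) + 1
                if ov <= 0:
                    continue
                if ov / length >= min_reciprocal_overlap and ov / (he - hs + 1) >= min_reciprocal_overlap:
                    ok = True
                    break
            if ok:
                n_support += 1
        if n_support >= min_samples:
            kept.append((s, e, n_support / n))
    if strand == "-":
        kept = kept[::-1]
    for i, (s, e, frac) in enumerate(kept, start=1):
        calls.append(SegmentCall((s, e), f"{label_prefix}{i}", frac, 0.0, n))
    return calls
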