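"""Genomic binning of homozygous variants and mapping-interval calling.

The mapping signal in pooled-segregant sequencing is a contiguous stretch
of bins enriched for variants homozygous in the mutant pool.  Counts are
accumulated in fixed 1 Mbp bins anchored at coordinate 1, and the
interval is called with an explicit formalization of "returned to
background levels": the genome-wide median bin count is the background,
a median + k x MAD threshold qualifies peaks, and the interval is the
maximal run of contiguous bins above background containing the global
maximum.  Other qualifying runs are reported as secondary peaks with
their widths, so that narrow telomeric artifacts (sharp, one- or
two-bin peaks caused by reference-stock divergence) can be recognized
and discounted rather than silently dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .filtering import is_canonical_ems
from .variant_io import HOMOZYGOUS, VariantSet

logger = logging.getLogger(__name__)

PREDICATE_HOMOZYGOUS = "homozygous"
PREDICATE_HOMOZYGOUS_EMS = "homozygous_ems"

#: scale factor making the median absolute deviation consistent with the
#: standard deviation of a normal distribution
MAD_SCALE = 1.4826


@dataclass
class BinTrack:
    """Per-chromosome counts of qualifying variants in fixed-width bins."""

    chrom: str
    bin_size: int
    chrom_length: int
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        n_bins = math.ceil(self.chrom_length / self.bin_size)
        if len(self.counts) == 0:
            self.counts = np.zeros(n_bins, dtype=int)
        elif len(self.counts) != n_bins:
            raise ValueError(
                f"{self.chrom}: {len(self.counts)} bins != ceil(length/bin_size)"
                f" = {n_bins}"
            )

    def bin_start(self, index: int) -> int:
        return index * self.bin_size + 1

    def bin_end(self, index: int) -> int:
        return min((index + 1) * self.bin_size, self.chrom_length)


@dataclass
class MappingInterval:
    """A called peak region, on bin boundaries, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    peak_bin: int
    background_level: float
    peak_count: int
    secondary: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def bin_variants(
    vs: VariantSet,
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
    predicate: str = PREDICATE_HOMOZYGOUS,
) -> list[BinTrack]:
    """Count qualifying variants per fixed-width bin on each chromosome.

    ``predicate='homozygous'`` counts homozygous calls;
    ``'homozygous_ems'`` additionally requires a canonical EMS change.
    Each variant increments exactly one bin, index floor((pos-1)/bin_size).
    """
    if predicate not in (PREDICATE_HOMOZYGOUS, PREDICATE_HOMOZYGOUS_EMS):
        raise ValueError(f"unknown predicate {predicate!r}")
    tracks = {
        chrom: BinTrack(chrom=chrom, bin_size=bin_size, chrom_length=length)
        for chrom, length in chrom_lengths.items()
    }
    for rec in vs:
        if rec.chrom not in tracks:
            raise ValueError(f"variant {rec.chrom}:{rec.pos}: undeclared chromosome")
        if rec.pos > tracks[rec.chrom].chrom_length:
            raise ValueError(
                f"variant {rec.chrom}:{rec.pos}: beyond declared length "
                f"{tracks[rec.chrom].chrom_length}"
            )
        if rec.zygosity != HOMOZYGOUS:
            continue
        if predicate == PREDICATE_HOMOZYGOUS_EMS and not is_canonical_ems(
            rec.ref, rec.alt
        ):
            continue
        tracks[rec.chrom].counts[(rec.pos - 1) // bin_size] += 1
    return [tracks[c] for c in chrom_lengths]


def call_interval(tracks: list[BinTrack], k_mad: float = 5.0) -> list[MappingInterval]:
    """Call the primary mapping interval and any secondary peaks.

    background = genome-wide median bin count; threshold = background +
    k_mad x scaled MAD.  The primary interval is the maximal run of
    contiguous bins, each strictly above background, containing the
    global maximum bin, provided that maximum exceeds the threshold.
    Other runs whose own maximum exceeds the threshold are returned as
    secondary intervals.  Returns an empty list (with a logged notice)
    when no bin rises above the threshold.
    """
    if not tracks:
        raise ValueError("call_interval requires at least one BinTrack")
    all_counts = np.concatenate([t.counts for t in tracks])
    background = float(np.median(all_counts))
    mad = float(np.median(np.abs(all_counts - background))) * MAD_SCALE
    threshold = background + k_mad * mad

    # locate the global maximum bin
    peak_track, peak_bin, peak_count = None, -1, -np.inf
    for t in tracks:
        if len(t.counts) == 0:
            continue
        i = int(np.argmax(t.counts))
        if t.counts[i] > peak_count:
            peak_track, peak_bin, peak_count = t, i, int(t.counts[i])
    if peak_track is None or peak_count <= threshold:
        logger.info(
            "no mapping interval: max bin count %s <= threshold %.2f "
            "(background %.2f)", peak_count, threshold, background,
        )
        return []

    intervals: list[MappingInterval] = []
    for t in tracks:
        above = t.counts > background
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            run_peak = int(i + np.argmax(t.counts[i : j + 1]))
            run_max = int(t.counts[run_peak])
            is_primary = t is peak_track and i <= peak_bin <= j
            if is_primary or run_max > threshold:
                intervals.append(
                    MappingInterval(
                        chrom=t.chrom,
                        start=t.bin_start(i),
                        end=t.bin_end(j),
                        peak_bin=run_peak,
                        background_level=background,
                        peak_count=run_max,
                        secondary=not is_primary,
                    )
                )
            i = j + 1
    intervals.sort(key=lambda iv: (iv.secondary, -iv.peak_count))
    for iv in intervals:
        logger.info(
            "%s interval %s:%d-%d (peak %d, background %.2f, width %d bp)",
            "secondary" if iv.secondary else "primary",
            iv.chrom, iv.start, iv.end, iv.peak_count,
            iv.background_level, iv.width,
        )
    return intervals
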