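"""Fine-mapping indel marker selection and primer-window design.

Indels of 15 bp or more inside the mapping interval are resolvable as
PCR product-size differences on a 3.5% agarose gel.  Primer windows are
placed 100-150 bp from the indel on each side; primer length 18-24 nt,
GC fraction 40-60% and a homopolymer cap of 4 are standard PCR defaults
(a GC-fraction proxy is used instead of a nearest-neighbour melting
model — a deliberate simplification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .variant_io import HOMOZYGOUS, VariantRecord, VariantSet, chrom_length, fetch

logger = logging.getLogger(__name__)


@dataclass
class IndelMarker:
    """A designed indel-length PCR marker."""

    chrom: str
    pos: int
    ref: str
    alt: str
    indel_len: int
    left_primer_window: tuple[int, int]
    right_primer_window: tuple[int, int]
    wt_product: int
    mut_product: int

    @property
    def expected_size_diff(self) -> int:
        return abs(self.indel_len)


def select_indels(
    vs: VariantSet,
    interval,
    min_indel_len: int = 15,
    require_homozygous: bool = True,
) -> list[VariantRecord]:
    """Indels within the interval with |length| >= min_indel_len.

    By default only indels homozygous in the mutant pool qualify (the
    same 0.99-frequency standard applied to candidate SNPs); pass
    ``require_homozygous=False`` to relax.
    """
    picked = [
        rec
        for rec in vs.sorted()
        if rec.is_indel
        and abs(rec.indel_len) >= min_indel_len
        and interval.contains(rec.chrom, rec.pos)
        and (not require_homozygous or rec.zygosity == HOMOZYGOUS)
    ]
    logger.info(
        "select_indels: %d of %d records qualify (>=%d bp, in %s:%d-%d)",
        len(picked), len(vs), min_indel_len,
        interval.chrom, interval.start, interval.end,
    )
    return picked


def _indel_span(rec: VariantRecord) -> tuple[int, int]:
    """Reference footprint of a left-anchored VCF-style indel."""
    return rec.pos, rec.pos + max(len(rec.ref), 1) - 1


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def design_flanks(
    indel: VariantRecord,
    genome,
    flank_min: int = 100,
    flank_max: int = 150,
    primer_len: tuple[int, int] = (18, 24),
    gc_range: tuple[float, float] = (0.40, 0.60),
    max_homopolymer: int = 4,
) -> IndelMarker | None:
    """Pick flanking primer windows for one indel, or None.

    On each side the first window (scanning the flank distance outward
    from ``flank_min`` and primer lengths short to long) whose 3' end
    lies ``flank_min``..``flank_max`` bases from the indel, whose GC
    fraction is within ``gc_range`` and which contains no homopolymer
    run longer than ``max_homopolymer`` is used.  The windows never
    overlap the indel footprint; the expected wild-type/mutant product
    sizes differ by exactly |indel_len|.
    """
    span_start, span_end = _indel_span(indel)
    length = chrom_length(genome, indel.chrom)

    left = None
    for f in range(flank_min, flank_max + 1):
        end3 = span_start - f
        for plen in range(primer_len[0], primer_len[1] + 1):
            start = end3 - plen + 1
            if start < 1:
                continue
            seq = fetch(genome, indel.chrom, start, end3)
            if _acceptable(seq, gc_range, max_homopolymer):
                left = (start, end3)
                break
        if left:
            break

    right = None
    for f in range(flank_min, flank_max + 1):
        end3 = span_end + f  # 3' end of the reverse primer (leftmost base)
        for plen in range(primer_len[0], primer_len[1] + 1):
            end = end3 + plen - 1
            if end > length:
                continue
            seq = fetch(genome, indel.chrom, end3, end)
            if _acceptable(seq, gc_range, max_homopolymer):
                right = (end3, end)
                break
        if right:
            break

    if left is None or right is None:
        logger.info(
            "design_flanks: no qualifying primer window for %s:%d (%+d bp)",
            indel.chrom, indel.pos, indel.indel_len,
        )
        return None

    wt_product = right[1] - left[0] + 1
    mut_product = wt_product + indel.indel_len
    return IndelMarker(
        chrom=indel.chrom,
        pos=indel.pos,
        ref=indel.ref,
        alt=indel.alt,
        indel_len=indel.indel_len,
        left_primer_window=left,
        right_primer_window=right,
        wt_product=wt_product,
        mut_product=mut_product,
    )


def _acceptable(seq: str, gc_range, max_homopolymer) -> bool:
    if "N" in seq:
        return False
    return (
        gc_range[0] <= _gc_fraction(seq) <= gc_range[1]
        and _max_homopolymer(seq) <= max_homopolymer
    )


def design_markers(
    vs: VariantSet,
    interval,
    genome,
    min_indel_len: int = 15,
    require_homozygous: bool = True,
    **flank_kwargs,
) -> list[IndelMarker]:
    """Select qualifying indels and design primer windows for each."""
    markers = []
    for rec in select_indels(vs, interval, min_indel_len, require_homozygous):
        marker = design_flanks(rec, genome, **flank_kwargs)
        if marker is not None:
            markers.append(marker)
    return markers
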