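"""Readers and writers for the formats a BSA-Seq pipeline touches.

Supported formats: 6-column samtools pileup, VCF 4.x (read via cyvcf2,
written with a minimal single-sample emitter), background site-list TSV
panels, per-bin TSV, GFF3 gene models (via gffutils) and FASTA (via
pyfaidx).  All in-memory coordinates are 1-based, matching the pileup/VCF
convention; BED export is the only place 0-based half-open coordinates
appear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

BASE_ORDER = "ACGT"

#: pileup symbols that consume one base-quality character
_SCORABLE = set(".,*><") | set("ACGTNacgtn")

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
REFERENCE = "reference"


class PileupParseError(ValueError):
    """A pileup line that does not follow the samtools pileup grammar."""


class PanelParseError(ValueError):
    """A site-list TSV row that cannot be parsed."""


@dataclass
class PileupRecord:
    """One position of pooled read evidence from a samtools pileup file."""

    chrom: str
    pos: int
    ref_base: str
    depth: int
    bases: str
    quals: str

    def tokenize(self) -> tuple[list[str], list[str]]:
        """Split the base string into per-read symbols and attached indels.

        Returns ``(symbols, indels)`` where ``symbols`` aligns one-to-one
        with the quality string (read starts ``^X``, read ends ``$`` and
        indel descriptors carry no quality of their own) and ``indels``
        holds signed indel strings such as ``+2TT`` or ``-3AAA``.
        """
        symbols: list[str] = []
        indels: list[str] = []
        s, i, n = self.bases, 0, len(self.bases)
        while i < n:
            c = s[i]
            if c == "^":
                if i + 1 >= n:
                    raise PileupParseError(
                        f"{self.chrom}:{self.pos}: dangling '^' in base string"
                    )
                i += 2  # '^' plus the mapping-quality character
            elif c == "$":
                i += 1
            elif c in "+-":
                j = i + 1
                while j < n and s[j].isdigit():
                    j += 1
                if j == i + 1:
                    raise PileupParseError(
                        f"{self.chrom}:{self.pos}: '{c}' not followed by a length"
                    )
                ln = int(s[i + 1 : j])
                if j + ln > n:
                    raise PileupParseError(
                        f"{self.chrom}:{self.pos}: truncated indel sequence"
                    )
                indels.append(s[i : j + ln])
                i = j + ln
            elif c in _SCORABLE:
                symbols.append(c)
                i += 1
            else:
                raise PileupParseError(
                    f"{self.chrom}:{self.pos}: unexpected character {c!r}"
                )
        if len(symbols) != len(self.quals):
            raise PileupParseError(
                f"{self.chrom}:{self.pos}: {len(symbols)} scorable bases vs "
                f"{len(self.quals)} quality characters"
            )
        return symbols, indels


@dataclass
class VariantRecord:
    """One site's variant evidence with a quality-adjusted allele frequency."""

    chrom: str
    pos: int
    ref: str
    alt: str
    total_qdepth: int
    alt_count: int
    freq: float
    zygosity: str
    is_indel: bool = False
    indel_len: int = 0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def position_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def zygosity_of(freq: float, hom_threshold: float = 0.99) -> str:
    if freq >= hom_threshold:
        return HOMOZYGOUS
    if freq > 0:
        return HETEROZYGOUS
    return REFERENCE


def make_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    total_qdepth: int,
    alt_count: int,
    hom_threshold: float = 0.99,
) -> VariantRecord:
    """Build a VariantRecord, deriving frequency, zygosity and indel fields."""
    freq = alt_count / total_qdepth if total_qdepth else 0.0
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        total_qdepth=total_qdepth,
        alt_count=alt_count,
        freq=freq,
        zygosity=zygosity_of(freq, hom_threshold),
        is_indel=len(ref) != len(alt),
        indel_len=len(alt) - len(ref),
    )


class VariantSet:
    """Keyed collection of VariantRecords (key = chrom, pos, ref, alt)."""

    def __init__(self, records: Iterable[VariantRecord] = ()) -> None:
        self._records: dict[tuple, VariantRecord] = {}
        self.n_skipped = 0
        for rec in records:
            self.add(rec)

    def add(self, rec: VariantRecord) -> None:
        self._records[rec.key] = rec

    def get(self, key: tuple) -> VariantRecord | None:
        return self._records.get(key)

    def keys(self) -> set[tuple]:
        return set(self._records)

    def position_keys(self) -> set[tuple]:
        return {(r.chrom, r.pos) for r in self}

    def __contains__(self, key: tuple) -> bool:
        return key in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self._records.values())

    def sorted(self) -> list[VariantRecord]:
        return sorted(self, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantSet):
            return NotImplemented
        return self.keys() == other.keys()


@dataclass
class SitePanel:
    """A named background panel of (chrom, pos, ref, alt) keys."""

    label: str
    keys: set[tuple] = field(default_factory=set)

    def position_keys(self) -> set[tuple]:
        return {(c, p) for (c, p, _r, _a) in self.keys}

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: tuple) -> bool:
        return key in self.keys


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def parse_pileup_line(line: str, lineno: int = 0) -> PileupRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 6:
        raise PileupParseError(
            f"line {lineno}: expected 6 tab-separated columns, got {len(fields)}"
        )
    chrom, pos_s, ref, depth_s, bases, quals = fields
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError as exc:
        raise PileupParseError(f"line {lineno}: non-integer coordinate/depth") from exc
    if pos < 1:
        raise PileupParseError(f"line {lineno}: position {pos} < 1")
    ref = ref.upper()
    if ref not in set("ACGTN"):
        raise PileupParseError(f"line {lineno}: reference base {ref!r}")
    rec = PileupRecord(chrom, pos, ref, depth, bases, quals)
    try:
        rec.tokenize()  # validate early so errors carry the line number
    except PileupParseError as exc:
        raise PileupParseError(f"line {lineno}: {exc}") from exc
    return rec


def read_pileup(path: str | Path) -> Iterator[PileupRecord]:
    """Stream PileupRecords from a 6-column samtools pileup file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            yield parse_pileup_line(line, lineno)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, hom_threshold: float = 0.99) -> VariantSet:
    """Read a VCF into a VariantSet, one record per ALT allele.

    Allele frequency is taken from per-sample allele depths (AD) when
    present, otherwise from a Varscan-style FREQ+DP pair.  Records without
    usable depth information are skipped with a warning and counted in
    ``result.n_skipped``.
    """
    from cyvcf2 import VCF

    out = VariantSet()
    skipped = 0
    vcf = VCF(str(path))
    for var in vcf:
        ref = var.REF
        for ai, alt in enumerate(var.ALT):
            if alt == ref:
                logger.warning("%s:%s: ALT equals REF, rejected", var.CHROM, var.POS)
                skipped += 1
                continue
            total, alt_count = _vcf_depths(var, ai)
            if total is None or total <= 0:
                logger.warning(
                    "%s:%s: no usable depth information, skipped", var.CHROM, var.POS
                )
                skipped += 1
                continue
            out.add(
                make_variant(
                    var.CHROM, var.POS, ref, alt, int(total), int(alt_count),
                    hom_threshold=hom_threshold,
                )
            )
    out.n_skipped = skipped
    return out


def _vcf_depths(var, alt_index: int):
    """Extract (total depth, alt depth) for one ALT, preferring AD."""
    import numpy as np

    try:
        ad = var.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        ad = np.asarray(ad)[0]
        ad = ad[ad >= 0]
        if ad.size >= alt_index + 2:
            return int(ad.sum()), int(ad[alt_index + 1])
    # Varscan-style: FORMAT FREQ ("99.9%") with DP
    freq = None
    try:
        raw = var.format("FREQ")
        if raw is not None:
            text = raw[0]
            if isinstance(text, bytes):
                text = text.decode()
            freq = float(str(text).rstrip("%")) / 100.0
    except (KeyError, ValueError):
        freq = None
    dp = None
    try:
        dparr = var.format("DP")
        if dparr is not None:
            dp = int(np.asarray(dparr).ravel()[0])
    except KeyError:
        dp = None
    if dp is None:
        info_dp = var.INFO.get("DP")
        dp = int(info_dp) if info_dp is not None else None
    if freq is not None and dp:
        return dp, int(round(freq * dp))
    return None, None


def write_vcf(vs: VariantSet, path: str | Path, sample: str = "pool") -> None:
    """Write a VariantSet as a minimal single-sample VCFv4.2 file."""
    chroms = sorted({r.chrom for r in vs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsamap\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Quality-adjusted depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allele depths (ref, alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in vs.sorted():
            gt = "1/1" if r.zygosity == HOMOZYGOUS else "0/1"
            ref_count = r.total_qdepth - r.alt_count
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:DP:AD\t{gt}:{r.total_qdepth}:{ref_count},{r.alt_count}\n"
            )


# ---------------------------------------------------------------------------
# variant TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "total_qdepth", "alt_count",
    "freq", "zygosity", "is_indel", "indel_len",
]


def write_variants_tsv(vs: VariantSet, path: str | Path) -> None:
    rows = [
        {c: getattr(r, c) for c in _TSV_COLUMNS} for r in vs.sorted()
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> VariantSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    out = VariantSet()
    for row in df.itertuples(index=False):
        out.add(
            VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                total_qdepth=int(row.total_qdepth),
                alt_count=int(row.alt_count),
                freq=float(row.freq),
                zygosity=row.zygosity,
                is_indel=bool(row.is_indel),
                indel_len=int(row.indel_len),
            )
        )
    return out


# ---------------------------------------------------------------------------
# site-list panels
# ---------------------------------------------------------------------------

def read_site_panel(path: str | Path, label: str) -> SitePanel:
    """Read a chrom/pos/ref/alt TSV (header optional) into a SitePanel."""
    keys: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise PanelParseError(
                    f"{path}: line {lineno}: expected >=4 columns"
                )
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise PanelParseError(
                    f"{path}: line {lineno}: non-integer position {pos_s!r}"
                ) from None
            keys.add((chrom, pos, ref.upper(), alt.upper()))
    panel = SitePanel(label=label, keys=keys)
    logger.info("panel %s: loaded %d sites from %s", label, len(panel), path)
    return panel


def write_site_panel(panel: SitePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(panel.keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def panel_from_variants(vs: VariantSet, label: str) -> SitePanel:
    return SitePanel(label=label, keys=vs.keys())


# ---------------------------------------------------------------------------
# genome sequences, chromosome tables, gene models
# ---------------------------------------------------------------------------

def read_genome(path: str | Path):
    """Open a FASTA for random access (pyfaidx, raw uppercase strings)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom] start..end, 1-based inclusive.

    Accepts either a pyfaidx Fasta or a plain {chrom: sequence} dict.
    """
    seq = genome[chrom][start - 1 : end]
    return str(seq).upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length table."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, length = line.split()[:2]
            out[chrom] = int(length)
    return out


def write_chrom_lengths(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_gene_models(path: str | Path) -> list:
    """Parse GFF3 gene/mRNA/exon/CDS features into GeneModel objects."""
    import gffutils

    from .effects import GeneModel

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons:
            exons = list(cds)
        if not exons:
            continue
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


# ---------------------------------------------------------------------------
# per-bin TSV and BED export
# ---------------------------------------------------------------------------

def write_bins_tsv(tracks, path: str | Path) -> None:
    """Write BinTracks as chrom, bin_start (1-based), bin_end, count rows."""
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\tbin_end\tcount\n")
        for track in tracks:
            for i, count in enumerate(track.counts):
                start = i * track.bin_size + 1
                end = min((i + 1) * track.bin_size, track.chrom_length)
                fh.write(f"{track.chrom}\t{start}\t{end}\t{int(count)}\n")


def write_bed(intervals, path: str | Path) -> None:
    """Export mapping intervals as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = "secondary" if iv.secondary else "primary"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")
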