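"""Pooled-F2 simulator for BSA-Seq (outcross) and MutMap (backcross) designs.

The generator emulates the two crossing schemes used for EMS mutant
mapping in maize:

* ``bsa_outcross`` — a mutagenized line carrying EMS lesions (and its
  background's natural polymorphisms relative to the reference) is
  crossed to the reference background; F2 individuals homozygous for the
  causal lesion form the mutant pool.
* ``mutmap_backcross`` — the mutant is backcrossed to its unmutagenized
  parent, so only mutagenesis-induced SNPs segregate while the parental
  background's polymorphisms relative to the reference are fixed in every
  individual; wild-type sibling and parent pools are also emitted so the
  background-subtraction path can be exercised end to end.

Meiosis uses a Poisson crossover model with no interference and a uniform
genetic map, so the recombination fraction between two loci d Morgans
apart follows Haldane's map function r(d) = (1 - e^(-2d)) / 2, and the
expected mutant-pool allele frequency at distance d from the causal locus
is 1 - r(d).  Pooled sequencing draws a Poisson read depth per site, each
read sampling one of the pool's 2n chromosomes, with a per-base error
rate and a realistic base-quality mix (98% of bases at Phred >= 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import variant_io
from .filtering import FilterConfig, apply_filters
from .mapping import bin_variants, call_interval
from .panels import subtract_panels
from .variant_io import VariantSet, make_variant, panel_from_variants

logger = logging.getLogger(__name__)

MODE_OUTCROSS = "bsa_outcross"
MODE_MUTMAP = "mutmap_backcross"

_BASES = "ACGT"
_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
_EMS = {"G": "A", "C": "T"}


def haldane_r(d: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction at genetic distance d Morgans (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float)))


@dataclass
class SimConfig:
    """Study conditions for one simulated mapping experiment.

    The default genome is a 10x scaled-down surrogate: two 100 Mbp
    chromosomes of 1 Morgan each, the causal lesion mid-arm on the first.
    Marker densities are scaled to keep per-bin counts of order ten —
    comparable to the filtered homozygous-EMS track that interval reading
    actually uses in real MutMap data — rather than to the full natural
    polymorphism density of a maize inbred cross.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000_000, "chr2": 100_000_000}
    )
    genetic_lengths: dict[str, float] = field(
        default_factory=lambda: {"chr1": 1.0, "chr2": 1.0}
    )
    mode: str = MODE_OUTCROSS
    causal: tuple[str, int] = ("chr1", 45_000_000)
    n_mutants: int = 50
    n_ems_snps: int = 1000
    ems_fraction_canonical: float = 0.98
    n_background_snps: int = 2000
    n_residual_het_snps: int = 0
    mean_coverage: float = 25.0
    base_error_rate: float = 0.002
    q20_fraction: float = 0.98
    seed: int = 0
    #: explicit (chrom, pos) EMS marker placement, overriding n_ems_snps
    ems_positions: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in (MODE_OUTCROSS, MODE_MUTMAP):
            raise ValueError(f"unknown mode {self.mode!r}")
        chrom, pos = self.causal
        if chrom not in self.chrom_lengths or not 1 <= pos <= self.chrom_lengths[chrom]:
            raise ValueError("causal locus outside the declared chromosomes")
        for p in (self.ems_fraction_canonical, self.base_error_rate, self.q20_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if set(self.genetic_lengths) != set(self.chrom_lengths):
            raise ValueError("genetic_lengths must cover the same chromosomes")


@dataclass
class SimTruth:
    """Ground truth for one simulated experiment."""

    causal_key: tuple
    mode: str
    seed: int
    #: per-variant chrom, pos, ref, alt, origin, d_morgans, expected_freq
    table: pd.DataFrame


@dataclass
class Population:
    """Simulated individuals of one mapping experiment, as allele matrices.

    Matrices are (n_variants, 2n) 0/1 arrays over chromosome copies; entry
    1 means the copy carries the variant (non-reference) allele.
    """

    cfg: SimConfig
    variants: pd.DataFrame
    mutant_matrix: np.ndarray
    sibling_matrix: np.ndarray | None = None

    def pool_frequency(self, pool: str = "mutant") -> np.ndarray:
        """Per-variant allele frequency over the pool's 2n chromosomes."""
        if pool == "mutant":
            return self.mutant_matrix.mean(axis=1)
        if pool == "wt_sibling":
            if self.sibling_matrix is None:
                raise ValueError("no wild-type sibling pool was simulated")
            return self.sibling_matrix.mean(axis=1)
        if pool == "parent":
            origin = self.variants["origin"].to_numpy()
            freq = np.zeros(len(self.variants))
            if self.cfg.mode == MODE_MUTMAP:
                freq[origin == "background"] = 1.0
            freq[origin == "residual_het"] = 0.5
            return freq
        raise ValueError(f"unknown pool {pool!r}")


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def _draw_variant_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    taken = {cfg.causal}

    def place(n: int) -> list[tuple[str, int]]:
        out = []
        while len(out) < n:
            ci = rng.choice(len(chroms), p=weights)
            pos = int(rng.integers(1, int(lengths[ci]) + 1))
            key = (chroms[ci], pos)
            if key in taken:
                continue
            taken.add(key)
            out.append(key)
        return out

    rows = []

    def ems_alleles() -> tuple[str, str]:
        if rng.random() < cfg.ems_fraction_canonical:
            ref = "G" if rng.random() < 0.5 else "C"
            return ref, _EMS[ref]
        while True:
            ref = _BASES[rng.integers(4)]
            alt = _OTHER[ref][rng.integers(3)]
            if _EMS.get(ref) != alt:
                return ref, alt

    rows.append((*cfg.causal, "G", "A", "causal"))
    if cfg.ems_positions is not None:
        ems_sites = [p for p in cfg.ems_positions if tuple(p) != cfg.causal]
        for key in ems_sites:
            taken.add(tuple(key))
    else:
        ems_sites = place(cfg.n_ems_snps - 1 if cfg.n_ems_snps > 0 else 0)
    for chrom, pos in ems_sites:
        ref, alt = ems_alleles()
        rows.append((chrom, pos, ref, alt, "ems"))
    for chrom, pos in place(cfg.n_background_snps):
        ref = _BASES[rng.integers(4)]
        alt = _OTHER[ref][rng.integers(3)]
        rows.append((chrom, pos, ref, alt, "background"))
    for chrom, pos in place(cfg.n_residual_het_snps):
        ref = _BASES[rng.integers(4)]
        alt = _OTHER[ref][rng.integers(3)]
        rows.append((chrom, pos, ref, alt, "residual_het"))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "origin"])
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)

    causal_chrom, causal_pos = cfg.causal
    d = np.full(len(df), np.inf)
    on_causal = df["chrom"] == causal_chrom
    morgans_per_bp = (
        cfg.genetic_lengths[causal_chrom] / cfg.chrom_lengths[causal_chrom]
    )
    d[on_causal] = (
        np.abs(df.loc[on_causal, "pos"].to_numpy() - causal_pos) * morgans_per_bp
    )
    df["d_morgans"] = d

    # expected mutant-pool frequency of the non-reference allele
    segregating = 1.0 - haldane_r(np.where(np.isfinite(d), d, 0.0))
    segregating = np.where(np.isfinite(d), segregating, 0.5)
    expected = segregating.copy()
    origin = df["origin"].to_numpy()
    if cfg.mode == MODE_MUTMAP:
        expected[origin == "background"] = 1.0
    expected[origin == "residual_het"] = 0.5
    df["expected_freq"] = expected
    return df


class _Gamete:
    """Crossover breakpoints and starting phase for each chromosome."""

    __slots__ = ("breaks", "phase")

    def __init__(self, cfg: SimConfig, rng: np.random.Generator) -> None:
        self.breaks = {}
        self.phase = {}
        for chrom, phys in cfg.chrom_lengths.items():
            k = rng.poisson(cfg.genetic_lengths[chrom])
            self.breaks[chrom] = np.sort(rng.uniform(0.0, phys, k))
            self.phase[chrom] = int(rng.integers(2))

    def carries_mutant(self, chrom: str, pos) -> np.ndarray | bool:
        """Whether position(s) derive from the mutagenized haplotype."""
        crossings = np.searchsorted(self.breaks[chrom], pos)
        return (self.phase[chrom] + crossings) % 2 == 0


def simulate_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Population, SimTruth]:
    """Simulate the cross, select the mutant pool, and return ground truth.

    F1 individuals are heterozygous mutagenized/non-mutagenized at every
    EMS site in both designs; selfing them and selecting individuals
    homozygous for the mutagenized haplotype at the causal locus yields
    the mutant pool (drawn until ``n_mutants`` are found).  In MutMap
    mode an equally sized wild-type sibling pool is collected from the
    non-mutant segregants.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    variants = _draw_variant_table(cfg, rng)
    causal_chrom, causal_pos = cfg.causal

    mutant_gametes: list[_Gamete] = []
    sibling_gametes: list[_Gamete] = []
    n_sibs = cfg.n_mutants if cfg.mode == MODE_MUTMAP else 0
    guard = 0
    while len(mutant_gametes) < 2 * cfg.n_mutants or len(sibling_gametes) < 2 * n_sibs:
        guard += 1
        if guard > 400 * (cfg.n_mutants + n_sibs + 1):
            raise RuntimeError("causal locus failed to segregate; check the config")
        g1, g2 = _Gamete(cfg, rng), _Gamete(cfg, rng)
        hom = bool(g1.carries_mutant(causal_chrom, causal_pos)) and bool(
            g2.carries_mutant(causal_chrom, causal_pos)
        )
        if hom and len(mutant_gametes) < 2 * cfg.n_mutants:
            mutant_gametes += [g1, g2]
        elif not hom and len(sibling_gametes) < 2 * n_sibs:
            sibling_gametes += [g1, g2]

    mutant_matrix = _allele_matrix(cfg, variants, mutant_gametes, rng)
    sibling_matrix = (
        _allele_matrix(cfg, variants, sibling_gametes, rng) if n_sibs else None
    )
    pop = Population(
        cfg=cfg,
        variants=variants,
        mutant_matrix=mutant_matrix,
        sibling_matrix=sibling_matrix,
    )
    truth = SimTruth(
        causal_key=(
            causal_chrom,
            causal_pos,
            *variants.loc[
                (variants.chrom == causal_chrom) & (variants.pos == causal_pos),
                ["ref", "alt"],
            ].iloc[0],
        ),
        mode=cfg.mode,
        seed=cfg.seed,
        table=variants,
    )
    return pop, truth


def _allele_matrix(
    cfg: SimConfig,
    variants: pd.DataFrame,
    gametes: list[_Gamete],
    rng: np.random.Generator,
) -> np.ndarray:
    nv = len(variants)
    m = np.zeros((nv, len(gametes)), dtype=np.uint8)
    origin = variants["origin"].to_numpy()
    linked = np.isin(origin, ("ems", "causal"))
    if cfg.mode == MODE_OUTCROSS:
        linked |= origin == "background"
    else:
        m[origin == "background", :] = 1  # fixed in both parents
    residual = origin == "residual_het"
    if residual.any():
        m[residual, :] = rng.integers(0, 2, size=(int(residual.sum()), len(gametes)))

    by_chrom = variants.groupby("chrom", sort=False).indices
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        sel = idx[linked[idx]]
        if sel.size == 0:
            continue
        pos = variants["pos"].to_numpy()[sel]
        for j, g in enumerate(gametes):
            m[sel, j] = g.carries_mutant(chrom, pos)
    return m


# ---------------------------------------------------------------------------
# pooled read sampling
# ---------------------------------------------------------------------------

@dataclass
class PoolSample:
    """Per-read pooled sequencing draws over the simulated variant sites."""

    variants: pd.DataFrame
    depth: np.ndarray        # reads per site
    site_id: np.ndarray      # flat per-read arrays
    base_code: np.ndarray    # 0..3 -> ACGT
    qual: np.ndarray         # Phred
    forward: np.ndarray      # strand, for pileup rendering only

    def to_variant_set(
        self, min_base_quality: int = 20, hom_threshold: float = 0.99
    ) -> VariantSet:
        """Call per-site allele frequencies from the sampled reads.

        Vectorized equivalent of running ``compute_allele_frequency``
        over the written pileup: counts quality-passing bases per site,
        picks the most frequent non-reference base (ties A<C<G<T) and
        drops non-variant sites.
        """
        nv = len(self.variants)
        passing = self.qual >= min_base_quality
        counts = np.bincount(
            self.site_id[passing] * 4 + self.base_code[passing], minlength=nv * 4
        ).reshape(nv, 4)
        total_q = counts.sum(axis=1)
        ref_code = self.variants["ref_code"].to_numpy()
        nonref = counts.copy()
        nonref[np.arange(nv), ref_code] = -1
        alt_code = nonref.argmax(axis=1)  # argmax takes the first max: A<C<G<T
        alt_count = counts[np.arange(nv), alt_code]
        out = VariantSet()
        chroms = self.variants["chrom"].to_numpy()
        poss = self.variants["pos"].to_numpy()
        for i in np.flatnonzero(alt_count > 0):
            out.add(
                make_variant(
                    chroms[i],
                    int(poss[i]),
                    _BASES[ref_code[i]],
                    _BASES[alt_code[i]],
                    int(total_q[i]),
                    int(alt_count[i]),
                    hom_threshold=hom_threshold,
                )
            )
        return out

    def write_pileup(self, path) -> None:
        """Write the sampled reads as a 6-column samtools pileup file."""
        offsets = np.concatenate(([0], np.cumsum(self.depth)))
        chroms = self.variants["chrom"].to_numpy()
        poss = self.variants["pos"].to_numpy()
        ref_code = self.variants["ref_code"].to_numpy()
        with open(path, "w") as fh:
            for i in range(len(self.variants)):
                lo, hi = offsets[i], offsets[i + 1]
                if lo == hi:
                    continue  # unobserved site: samtools emits no line
                ref = ref_code[i]
                chars = []
                for b, fwd in zip(self.base_code[lo:hi], self.forward[lo:hi]):
                    if b == ref:
                        chars.append("." if fwd else ",")
                    else:
                        chars.append(_BASES[b] if fwd else _BASES[b].lower())
                quals = "".join(chr(q + 33) for q in self.qual[lo:hi])
                fh.write(
                    f"{chroms[i]}\t{poss[i]}\t{_BASES[ref]}\t{hi - lo}\t"
                    f"{''.join(chars)}\t{quals}\n"
                )

    def write_vcf(self, path, min_base_quality: int = 20,
                  hom_threshold: float = 0.99) -> None:
        variant_io.write_vcf(
            self.to_variant_set(min_base_quality, hom_threshold), path
        )


def sample_pool_reads(
    pop: Population,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    pool: str = "mutant",
) -> PoolSample:
    """Draw pooled short-read evidence over every simulated variant site.

    Depth is Poisson(mean_coverage) per site; each read samples the pool
    allele frequency, suffers a base-calling error with probability
    ``base_error_rate`` (to a uniformly chosen other base), and receives
    a Phred quality >= 20 with probability ``q20_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    q = pop.pool_frequency(pool)
    nv = len(q)
    depth = rng.poisson(cfg.mean_coverage, nv)
    total = int(depth.sum())
    site_id = np.repeat(np.arange(nv), depth)

    variants = pop.variants.copy()
    variants["ref_code"] = [_BASES.index(b) for b in variants["ref"]]
    variants["alt_code"] = [_BASES.index(b) for b in variants["alt"]]

    is_alt = rng.random(total) < q[site_id]
    base = np.where(
        is_alt,
        variants["alt_code"].to_numpy()[site_id],
        variants["ref_code"].to_numpy()[site_id],
    )
    err = rng.random(total) < cfg.base_error_rate
    shift = rng.integers(1, 4, total)
    base = np.where(err, (base + shift) % 4, base).astype(np.int64)
    hi = rng.random(total) < cfg.q20_fraction
    qual = np.where(hi, rng.integers(20, 41, total), rng.integers(2, 20, total))
    forward = rng.random(total) < 0.5
    return PoolSample(
        variants=variants,
        depth=depth,
        site_id=site_id,
        base_code=base,
        qual=qual.astype(np.int64),
        forward=forward,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline on simulated data
# ---------------------------------------------------------------------------

def run_end_to_end(
    cfg: SimConfig,
    filter_cfg: FilterConfig | None = None,
    predicate: str = "homozygous",
    bin_size: int = 1_000_000,
    k_mad: float = 5.0,
) -> dict:
    """Simulate, filter, subtract (MutMap), bin and call the interval.

    Returns a report with the called primary interval, whether it
    contains the causal position, its width, and per-stage tallies.
    """
    fc = filter_cfg or FilterConfig()
    rng = np.random.default_rng(cfg.seed)
    pop, truth = simulate_population(cfg, rng)
    mutant_reads = sample_pool_reads(pop, cfg, rng)
    vs = mutant_reads.to_variant_set(fc.min_base_quality, fc.hom_threshold)
    vs_map, filter_tallies = apply_filters(vs, fc, "mapping")

    subtraction_tallies: dict[str, int] = {}
    if cfg.mode == MODE_MUTMAP:
        panels = []
        for pool in ("parent", "wt_sibling"):
            reads = sample_pool_reads(pop, cfg, rng, pool=pool)
            pool_vs = reads.to_variant_set(fc.min_base_quality, fc.hom_threshold)
            hom_vs, _ = apply_filters(pool_vs, fc, "candidate")
            panels.append(panel_from_variants(hom_vs, pool))
        vs_map, subtraction_tallies = subtract_panels(vs_map, panels)

    tracks = bin_variants(vs_map, cfg.chrom_lengths, bin_size, predicate)
    intervals = call_interval(tracks, k_mad)
    primary = next((iv for iv in intervals if not iv.secondary), None)

    causal_chrom, causal_pos = cfg.causal
    return {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "causal": cfg.causal,
        "n_variants_called": len(vs),
        "n_variants_mapped": len(vs_map),
        "filter_tallies": filter_tallies,
        "subtraction_tallies": subtraction_tallies,
        "intervals": intervals,
        "interval": (primary.chrom, primary.start, primary.end) if primary else None,
        "contains_causal": bool(
            primary is not None and primary.contains(causal_chrom, causal_pos)
        ),
        "width_bp": primary.width if primary else None,
        "truth": truth,
    }


def write_outputs(cfg: SimConfig, outdir) -> dict:
    """Simulate one experiment and write pileup/VCF/panel/truth files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    pop, truth = simulate_population(cfg, rng)

    written = {}
    mutant = sample_pool_reads(pop, cfg, rng)
    mutant.write_pileup(outdir / "mutant.pileup")
    mutant.write_vcf(outdir / "mutant.vcf")
    written["mutant_pileup"] = outdir / "mutant.pileup"
    written["mutant_vcf"] = outdir / "mutant.vcf"
    if cfg.mode == MODE_MUTMAP:
        for pool in ("parent", "wt_sibling"):
            reads = sample_pool_reads(pop, cfg, rng, pool=pool)
            reads.write_pileup(outdir / f"{pool}.pileup")
            hom_vs, _ = apply_filters(
                reads.to_variant_set(), FilterConfig(), "candidate"
            )
            variant_io.write_site_panel(
                panel_from_variants(hom_vs, pool), outdir / f"{pool}_panel.tsv"
            )
            written[f"{pool}_pileup"] = outdir / f"{pool}.pileup"
            written[f"{pool}_panel"] = outdir / f"{pool}_panel.tsv"
    truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    variant_io.write_chrom_lengths(cfg.chrom_lengths, outdir / "genome.txt")
    written["truth"] = outdir / "truth.tsv"
    written["genome"] = outdir / "genome.txt"
    return written
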