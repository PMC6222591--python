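"""Config-driven pipeline: filter -> subtract -> bin -> interval -> candidates.

One YAML config names the inputs and thresholds; every threshold defaults
to the pipeline's standard value (base quality 20, depth 8, mapping cap
100, homozygosity 0.99, 1 Mbp bins, indels >= 15 bp, 100-150 bp flanks).
Outputs: bins.tsv, intervals.txt (+ intervals.bed), candidates.tsv,
markers.tsv and a run log with per-stage record tallies.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import effects, markers, variant_io
from .filtering import FilterConfig, apply_filters, compute_allele_frequency
from .mapping import bin_variants, call_interval
from .panels import subtract_panels

logger = logging.getLogger(__name__)

DEFAULTS = {
    "min_base_quality": 20,
    "min_depth": 8,
    "max_depth_for_mapping": 100,
    "hom_threshold": 0.99,
    "ems_only": True,
    "bin_size": 1_000_000,
    "predicate": "homozygous",
    "k_mad": 5.0,
    "key_mode": "allele",
    "min_indel_len": 15,
    "flank_min": 100,
    "flank_max": 150,
}


def load_variants_from_pileup(path, cfg: FilterConfig) -> variant_io.VariantSet:
    vs = variant_io.VariantSet()
    for rec in variant_io.read_pileup(path):
        v = compute_allele_frequency(
            rec, cfg.min_base_quality, cfg.hom_threshold
        )
        if v is not None:
            vs.add(v)
    return vs


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full mapping + candidate workflow from a config dict.

    Recognized keys: ``pileup`` or ``variants`` (mutant-pool evidence),
    ``vcf`` (candidate/indel calls; defaults to the pileup-derived set),
    ``panels`` (site-list TSVs to subtract), ``genome_lengths`` (two-column
    chrom/length table), ``gff`` + ``fasta`` (consequence calling and
    marker design) plus the threshold keys in ``DEFAULTS``.  Missing
    inputs for a stage skip that stage; a missing file fails fast naming
    the stage.
    """
    conf = {**DEFAULTS, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    fc = FilterConfig(
        min_base_quality=int(conf["min_base_quality"]),
        min_depth=int(conf["min_depth"]),
        max_depth_for_mapping=int(conf["max_depth_for_mapping"]),
        hom_threshold=float(conf["hom_threshold"]),
        ems_only=bool(conf["ems_only"]),
    )

    # --- load evidence -----------------------------------------------------
    if conf.get("pileup"):
        _require(conf["pileup"], "filter")
        vs = load_variants_from_pileup(conf["pileup"], fc)
    elif conf.get("variants"):
        _require(conf["variants"], "filter")
        vs = variant_io.read_variants_tsv(conf["variants"])
    else:
        raise ValueError("filter stage: config needs 'pileup' or 'variants'")
    report["stages"]["load"] = {"records": len(vs)}

    panels = [
        variant_io.read_site_panel(p, label=Path(p).stem)
        for p in conf.get("panels", [])
    ]

    # --- mapping track ------------------------------------------------------
    vs_map, filter_tallies = apply_filters(vs, fc, "mapping")
    if panels:
        vs_map, sub_tallies = subtract_panels(vs_map, panels, conf["key_mode"])
    else:
        sub_tallies = {}
    report["stages"]["mapping_filter"] = {
        "records": len(vs_map),
        "dropped": filter_tallies,
        "subtracted": sub_tallies,
    }

    _require(conf.get("genome_lengths"), "map")
    chrom_lengths = variant_io.read_chrom_lengths(conf["genome_lengths"])
    tracks = bin_variants(
        vs_map, chrom_lengths, int(conf["bin_size"]), conf["predicate"]
    )
    variant_io.write_bins_tsv(tracks, outdir / "bins.tsv")
    intervals = call_interval(tracks, float(conf["k_mad"]))
    primary = next((iv for iv in intervals if not iv.secondary), None)
    with open(outdir / "intervals.txt", "w") as fh:
        for iv in intervals:
            kind = "secondary" if iv.secondary else "primary"
            fh.write(
                f"{kind}\t{iv.chrom}:{iv.start}-{iv.end}\t"
                f"peak={iv.peak_count}\tbackground={iv.background_level}\n"
            )
    if intervals:
        variant_io.write_bed(intervals, outdir / "intervals.bed")
    report["stages"]["interval"] = {
        "primary": (primary.chrom, primary.start, primary.end) if primary else None,
        "n_secondary": sum(iv.secondary for iv in intervals),
    }

    # --- candidate track ----------------------------------------------------
    cand_source = (
        variant_io.read_vcf(conf["vcf"], fc.hom_threshold) if conf.get("vcf") else vs
    )
    vs_cand, cand_tallies = apply_filters(cand_source, fc, "candidate")
    if panels:
        vs_cand, _ = subtract_panels(vs_cand, panels, conf["key_mode"])
    report["stages"]["candidate_filter"] = {
        "records": len(vs_cand),
        "dropped": cand_tallies,
    }

    candidates_path = outdir / "candidates.tsv"
    if primary is not None and conf.get("gff") and conf.get("fasta"):
        models = variant_io.read_gene_models(conf["gff"])
        genome = variant_io.read_genome(conf["fasta"])
        calls = []
        for rec in vs_cand.sorted():
            if rec.is_indel or not primary.contains(rec.chrom, rec.pos):
                continue
            calls.extend(effects.annotate_variant(rec, models, genome))
        table = effects.triage_candidates(calls, primary)
        table.to_csv(candidates_path, sep="\t", index=False)
        report["stages"]["candidates"] = {"records": len(table)}
    else:
        # no annotation inputs: emit the filtered candidate variants as-is
        in_interval = variant_io.VariantSet(
            r for r in vs_cand
            if primary is None or primary.contains(r.chrom, r.pos)
        )
        variant_io.write_variants_tsv(in_interval, candidates_path)
        report["stages"]["candidates"] = {"records": len(in_interval)}

    # --- indel markers ------------------------------------------------------
    if primary is not None and conf.get("fasta"):
        genome = variant_io.read_genome(conf["fasta"])
        # indel evidence comes from the VCF path (pileup SNV calls carry none)
        indel_source = cand_source
        designed = markers.design_markers(
            indel_source,
            primary,
            genome,
            min_indel_len=int(conf["min_indel_len"]),
            flank_min=int(conf["flank_min"]),
            flank_max=int(conf["flank_max"]),
        )
        with open(outdir / "markers.tsv", "w") as fh:
            fh.write(
                "chrom\tpos\tindel_len\tleft_window\tright_window\t"
                "wt_product\tmut_product\n"
            )
            for mk in designed:
                fh.write(
                    f"{mk.chrom}\t{mk.pos}\t{mk.indel_len}\t"
                    f"{mk.left_primer_window[0]}-{mk.left_primer_window[1]}\t"
                    f"{mk.right_primer_window[0]}-{mk.right_primer_window[1]}\t"
                    f"{mk.wt_product}\t{mk.mut_product}\n"
                )
        report["stages"]["markers"] = {"records": len(designed)}

    with open(outdir / "run.log", "w") as fh:
        for stage, info in report["stages"].items():
            fh.write(f"{stage}\t{info}\n")
    return report


def _require(path, stage: str) -> None:
    if path is None:
        raise ValueError(f"{stage} stage: required input missing from config")
    if not Path(path).exists():
        raise FileNotFoundError(f"{stage} stage: input {path} does not exist")
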