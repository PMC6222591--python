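"""Pooled-F2 simulator: determinism, EMS spectrum, Haldane frequency law,
read-sampling round trips and the end-to-end mapping pipeline."""

import numpy as np
import pytest

from bsamap.filtering import compute_allele_frequency, is_canonical_ems
from bsamap.simulate import (
    SimConfig,
    haldane_r,
    run_end_to_end,
    sample_pool_reads,
    simulate_population,
    write_outputs,
)
from bsamap.variant_io import read_pileup, read_site_panel, read_vcf


def small_config(**kw):
    base = dict(
        chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
        genetic_lengths={"chr1": 0.5, "chr2": 0.5},
        causal=("chr1", 5_000_000),
        n_mutants=10,
        n_ems_snps=60,
        n_background_snps=150,
        seed=7,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_causal_must_lie_on_a_declared_chromosome(self):
        with pytest.raises(ValueError):
            small_config(causal=("chr9", 5))
        with pytest.raises(ValueError):
            small_config(causal=("chr1", 99_000_000))

    def test_probabilities_and_coverage_checked(self):
        with pytest.raises(ValueError):
            small_config(ems_fraction_canonical=1.5)
        with pytest.raises(ValueError):
            small_config(mean_coverage=0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            small_config(mode="f1_selfing")


class TestPopulation:
    def test_causal_fixed_and_unlinked_near_half_in_mutant_pool(self):
        cfg = small_config(n_mutants=50)
        pop, truth = simulate_population(cfg)
        t = truth.table
        causal_i = t.index[(t.chrom == "chr1") & (t.pos == 5_000_000)][0]
        assert pop.mutant_matrix[causal_i].mean() == 1.0
        assert t.loc[causal_i, "expected_freq"] == 1.0
        unlinked = t.index[t.chrom == "chr2"]
        assert t.loc[unlinked, "expected_freq"].eq(0.5).all()
        assert abs(pop.mutant_matrix[unlinked].mean() - 0.5) < 0.1

    def test_ems_spectrum_fraction_within_two_se(self):
        cfg = small_config(n_ems_snps=400, n_background_snps=0, n_mutants=2)
        _, truth = simulate_population(cfg)
        ems = truth.table[truth.table.origin.isin(["ems", "causal"])]
        frac = np.mean([is_canonical_ems(r, a) for r, a in zip(ems.ref, ems.alt)])
        se = np.sqrt(0.98 * 0.02 / len(ems))
        assert abs(frac - 0.98) <= 2 * se + 1e-9

    def test_pool_frequency_follows_haldane_law(self):
        """Mean pooled frequency at map distance d matches 1 - r(d)
        within 3 binomial standard errors (2n chromosomes)."""
        causal = 5_000_000
        d_targets = [0.0, 0.05, 0.1, 0.25]
        # 0.5 Morgan over 10 Mbp -> 1 Mbp per 0.05 Morgans
        positions = [("chr1", causal + int(d * 20_000_000)) for d in d_targets]
        positions.append(("chr2", 5_000_000))
        cfg = small_config(
            n_mutants=200, ems_positions=positions, n_background_snps=0,
            seed=11,
        )
        pop, truth = simulate_population(cfg)
        t = truth.table
        for (chrom, pos), d in zip(positions, d_targets + [None]):
            expected = 0.5 if d is None else float(1 - haldane_r(d))
            i = t.index[(t.chrom == chrom) & (t.pos == pos)][0]
            assert t.loc[i, "expected_freq"] == pytest.approx(expected)
            emp = pop.mutant_matrix[i].mean()
            se = np.sqrt(expected * (1 - expected) / 400)
            assert abs(emp - expected) <= 3 * se + 1e-12

    def test_mutmap_background_fixed_in_every_individual(self):
        cfg = small_config(mode="mutmap_backcross", n_mutants=8)
        pop, truth = simulate_population(cfg)
        bg = truth.table.index[truth.table.origin == "background"]
        assert pop.mutant_matrix[bg].all()
        assert pop.sibling_matrix[bg].all()
        assert pop.pool_frequency("parent")[bg].min() == 1.0

    def test_wt_siblings_not_homozygous_at_causal(self):
        cfg = small_config(mode="mutmap_backcross", n_mutants=12)
        pop, truth = simulate_population(cfg)
        t = truth.table
        causal_i = t.index[(t.chrom == "chr1") & (t.pos == 5_000_000)][0]
        assert pop.sibling_matrix[causal_i].mean() < 1.0


class TestReadSampling:
    def test_seed_determinism_is_byte_identical(self, tmp_path):
        cfg = small_config()
        for d in ("a", "b"):
            write_outputs(cfg, tmp_path / d)
        assert (tmp_path / "a/mutant.pileup").read_bytes() == (
            tmp_path / "b/mutant.pileup"
        ).read_bytes()
        assert (tmp_path / "a/mutant.vcf").read_bytes() == (
            tmp_path / "b/mutant.vcf"
        ).read_bytes()

    def test_mean_depth_matches_poisson_target(self):
        cfg = small_config(n_background_snps=10_000, n_ems_snps=10, n_mutants=4)
        pop, _ = simulate_population(cfg)
        sample = sample_pool_reads(pop, cfg)
        assert abs(sample.depth.mean() - 25.0) / 25.0 < 0.05

    def test_written_pileup_reproduces_alt_counts_exactly_at_zero_error(
        self, tmp_path
    ):
        cfg = small_config(base_error_rate=0.0, q20_fraction=1.0)
        pop, _ = simulate_population(cfg)
        sample = sample_pool_reads(pop, cfg)
        vs = sample.to_variant_set()
        path = tmp_path / "pool.pileup"
        sample.write_pileup(path)
        reread = {}
        for rec in read_pileup(path):
            v = compute_allele_frequency(rec)
            if v is not None:
                reread[v.key] = (v.alt_count, v.total_qdepth)
        assert set(reread) == set(vs.keys())
        for rec in vs:
            assert reread[rec.key] == (rec.alt_count, rec.total_qdepth)

    def test_causal_site_reads_are_all_alt_at_zero_error(self):
        cfg = small_config(base_error_rate=0.0, q20_fraction=1.0)
        pop, truth = simulate_population(cfg)
        sample = sample_pool_reads(pop, cfg)
        vs = sample.to_variant_set()
        rec = vs.get(truth.causal_key)
        assert rec is not None
        assert rec.freq == 1.0 and rec.zygosity == "homozygous"

    def test_vcf_output_readable_and_keyed_like_variant_set(self, tmp_path):
        cfg = small_config(base_error_rate=0.0, q20_fraction=1.0)
        out = write_outputs(cfg, tmp_path)
        vs = read_vcf(out["mutant_vcf"])
        assert len(vs) > 0
        pileup_keys = set()
        for rec in read_pileup(out["mutant_pileup"]):
            v = compute_allele_frequency(rec)
            if v is not None:
                pileup_keys.add(v.key)
        assert vs.keys() == pileup_keys


class TestEndToEnd:
    def test_outcross_interval_contains_causal(self):
        rep = run_end_to_end(SimConfig(seed=1))
        assert rep["contains_causal"]
        chrom, start, end = rep["interval"]
        assert chrom == "chr1" and start <= 45_000_000 <= end

    def test_mutmap_subtraction_reveals_ems_peak(self):
        rep = run_end_to_end(SimConfig(seed=2, mode="mutmap_backcross"))
        assert rep["contains_causal"]
        # the parental panel removed the fixed background SNPs
        assert rep["subtraction_tallies"]["parent"] > 1000

    def test_mutmap_outputs_include_panels(self, tmp_path):
        cfg = small_config(mode="mutmap_backcross", n_mutants=6)
        out = write_outputs(cfg, tmp_path)
        parent = read_site_panel(out["parent_panel"], "parent")
        assert len(parent) > 0
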