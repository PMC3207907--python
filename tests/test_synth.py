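"""Synthetic dataset generator: determinism, recovery, and background rates."""

import filecmp

import numpy as np
import pytest

from motiflink import run_scan_from_files
from motiflink.alignments import is_perfectly_conserved
from motiflink.motifs import scan_sequence
from motiflink.synth import (SyntheticConfig, expected_background_pairs,
                             generate_dataset, generate_locus,
                             motif_match_probability)


def noiseless_config(**kw):
    base = dict(n_genes=4, n_hc=2, n_pc=2, locus_length=1500,
                per_species_substitution_rate=0.0,
                per_species_indel_rate=0.0, seed=11)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"plant_probability": 1.5},
        {"per_species_substitution_rate": -0.1},
        {"gc_content": 2.0},
        {"n_genes": 3, "n_hc": 2, "n_pc": 2},
        {"locus_length": 100},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            noiseless_config(**kw)


class TestGenerateLocus:
    def test_planted_pair_recovered_exactly_without_noise(self, rng):
        cfg = noiseless_config()
        loc = generate_locus(cfg, 0, rng, plant_probability=1.0)
        t = loc.truth
        assert t.planted
        sox = [h for h in scan_sequence(loc.ref_seq, cfg.sox9, loc.chrom)
               if h.start == t.sox9_start and h.strand == t.sox9_strand]
        gli = [h for h in scan_sequence(loc.ref_seq, cfg.gli, loc.chrom)
               if h.start == t.gli_start and h.strand == t.gli_strand]
        assert sox and gli
        assert is_perfectly_conserved(loc.block, t.sox9_start,
                                      t.sox9_start + len(cfg.sox9), "human")

    def test_unplanted_locus(self, rng):
        loc = generate_locus(noiseless_config(), 1, rng, plant_probability=0.0)
        assert not loc.truth.planted
        assert loc.truth.sox9_start == -1

    def test_planted_pair_lies_in_nonexonic_space(self, rng):
        for i in range(10):
            loc = generate_locus(noiseless_config(), i, rng,
                                 plant_probability=1.0)
            t, g = loc.truth, loc.gene
            for s in (t.sox9_start, t.gli_start):
                for es, ee in g.exons:
                    assert not (es < s + 9 and s < ee)

    def test_total_divergence_destroys_conservation(self, rng):
        cfg = noiseless_config(per_species_substitution_rate=1.0,
                               protect_planted=False)
        loc = generate_locus(cfg, 0, rng, plant_probability=1.0)
        t = loc.truth
        assert not is_perfectly_conserved(loc.block, t.sox9_start,
                                          t.sox9_start + len(cfg.sox9), "human")

    def test_noise_recorded_in_truth(self, rng):
        cfg = noiseless_config(per_species_substitution_rate=0.2,
                               per_species_indel_rate=0.05)
        loc = generate_locus(cfg, 0, rng, plant_probability=0.0)
        assert loc.truth.n_substitutions > 0
        assert loc.truth.n_indels > 0


class TestGenerateDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = noiseless_config(per_species_substitution_rate=0.1,
                               per_species_indel_rate=0.02, seed=42)
        p1 = generate_dataset(cfg, str(tmp_path / "a"))
        p2 = generate_dataset(cfg, str(tmp_path / "b"))
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seeds_differ(self, tmp_path):
        pa = generate_dataset(noiseless_config(seed=1), str(tmp_path / "a"))
        pb = generate_dataset(noiseless_config(seed=2), str(tmp_path / "b"))
        assert not filecmp.cmp(pa["genome"], pb["genome"], shallow=False)

    def test_empty_dataset_valid(self, tmp_path):
        cfg = noiseless_config(n_genes=0, n_hc=0, n_pc=0)
        paths = generate_dataset(cfg, str(tmp_path / "e"))
        res = run_scan_from_files(paths["genome"], paths["maf"],
                                  paths["annotation"], paths["chrom_sizes"])
        assert res.pairs == [] and res.calls.calls == {}

    def test_gene_sets_have_configured_sizes(self, noiseless_dataset):
        cfg, paths = noiseless_dataset
        hc = open(paths["genes_hc"]).read().split()
        pc = open(paths["genes_pc"]).read().split()
        assert (len(hc), len(pc)) == (cfg.n_hc, cfg.n_pc)
        assert set(hc).isdisjoint(pc)

    def test_truth_header_records_seed(self, noiseless_dataset):
        cfg, paths = noiseless_dataset
        first = open(paths["truth"]).readline()
        assert first.strip() == f"# seed={cfg.seed}"


class TestPipelineRecovery:
    def test_full_sensitivity_on_noiseless_data(self, noiseless_dataset):
        """Every planted pair is recovered at its exact coordinates."""
        cfg, paths = noiseless_dataset
        res = run_scan_from_files(paths["genome"], paths["maf"],
                                  paths["annotation"], paths["chrom_sizes"])
        truth = [l.split("\t") for l in open(paths["truth"]).read().splitlines()[2:]]
        planted = [t for t in truth if t[2] == "True"]
        assert planted  # f_hi=1 guarantees plants
        found = {(p.chrom, p.sox9.start, p.sox9.strand,
                  p.gli.start, p.gli.strand, p.spacing) for p in res.pairs}
        for t in planted:
            key = (t[1], int(t[3]), t[4], int(t[5]), t[6], int(t[7]))
            assert key in found

    def test_pc_like_genes_negative_when_f_lo_zero(self, noiseless_dataset):
        cfg, paths = noiseless_dataset
        res = run_scan_from_files(paths["genome"], paths["maf"],
                                  paths["annotation"], paths["chrom_sizes"])
        pc = open(paths["genes_pc"]).read().split()
        # PC-like genes were planted at f=0; any positive is a background
        # coincidence, which at these motif lengths is very unlikely
        k, _ = res.calls.count_positive(pc)
        assert k == 0


class TestAnalyticBackground:
    def test_match_probability_uniform_base_composition(self):
        cfg = noiseless_config()
        # SOX9 WWCAAWG: (1/2)^3 (1/4)^4 per strand
        assert motif_match_probability(cfg.sox9, 0.5) == \
            pytest.approx(2 * (0.5 ** 3) * (0.25 ** 4))
        assert motif_match_probability(cfg.gli, 0.5) == \
            pytest.approx(2 * 0.25 ** 9)

    def test_background_rate_matches_analytic_expectation(self, tmp_path):
        """With f=0, realized pair count sits within 3 SE of the analytic rate."""
        n_loci, L = 300, 2000
        cfg = SyntheticConfig(n_genes=n_loci, n_hc=0, n_pc=0, locus_length=L,
                              plant_probability=0.0,
                              per_species_substitution_rate=0.0,
                              per_species_indel_rate=0.0, seed=33)
        paths = generate_dataset(cfg, str(tmp_path / "bg"))
        res = run_scan_from_files(paths["genome"], paths["maf"],
                                  paths["annotation"], paths["chrom_sizes"])
        observed = len(res.pairs)

        from motiflink.regions import read_annotation, read_chrom_sizes, build_region_mask
        genes = read_annotation(paths["annotation"], "bed12")
        mask = build_region_mask(genes, read_chrom_sizes(paths["chrom_sizes"]))
        expected = sum(
            expected_background_pairs(mask.noncoding(g.chrom), cfg.sox9,
                                      cfg.gli, 100, cfg.gc_content)
            for g in genes)
        # counts are approximately Poisson across loci
        assert abs(observed - expected) <= 3 * np.sqrt(expected)
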