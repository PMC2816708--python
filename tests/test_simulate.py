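"""Generators: determinism, planted-truth consistency, sampling laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eboxlink import (
    PositionalModel,
    ValidationError,
    gen_expression,
    gen_genome_and_tss,
    gen_pathways,
    gen_target_catalog,
    plant_motifs,
    scan_consensus,
)
from eboxlink.pathways import write_gmt
from eboxlink.promoters import extract_promoters
from tests.conftest import make_promoter


class TestGenome:
    def test_empty_gene_set_still_emits_genome(self):
        genome, tss = gen_genome_and_tss(0, chrom_len=10_000, seed=0)
        assert len(genome["chr1"]) == 10_000
        assert tss.empty

    def test_seeded_rerun_identical(self):
        a = gen_genome_and_tss(50, chrom_len=500_000, seed=1)
        b = gen_genome_and_tss(50, chrom_len=500_000, seed=1)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])
        assert len(a[1]) == 50

    def test_base_frequencies_law_of_large_numbers(self):
        genome, _ = gen_genome_and_tss(0, chrom_len=4_000_000, seed=2)
        seq = genome["chr1"]
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=0.005)

    def test_non_normalized_bg_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            gen_genome_and_tss(5, bg_freqs=(0.5, 0.5, 0.5, 0.5), seed=0)

    def test_capacity_error(self):
        with pytest.raises(ValidationError, match="cannot place"):
            gen_genome_and_tss(10_000, chrom_len=12_000, seed=0)

    def test_every_gene_admits_wide_window(self):
        genome, tss = gen_genome_and_tss(40, chrom_len=100_000, seed=3)
        proms = extract_promoters(genome, tss, 3000, 500, clip=False)
        assert len(proms) == 40
        assert all(not p.clipped for p in proms)


def random_promoters(n, seed, up=400, down=100):
    rng = np.random.default_rng(seed)
    return [
        make_promoter("".join("ACGT"[b] for b in rng.integers(0, 4, up + down)),
                      gene_id=f"g{i:03d}", window_up=up, window_down=down, offset=-up)
        for i in range(n)
    ]


class TestPlantMotifs:
    def test_rate_zero_changes_nothing(self):
        proms = random_promoters(10, 0)
        out, truth = plant_motifs(proms, "CACGTG", foreground_rate=0.0, seed=0)
        assert out == proms
        assert truth.planted_motif_positions == {}

    def test_fixed_offset_planted_equals_found(self):
        proms = random_promoters(20, 1)
        out, truth = plant_motifs(
            proms, "CACGTG", foreground_rate=1.0,
            positional_model=PositionalModel("fixed", peak_offset=-50), seed=1,
        )
        for p in out:
            offsets = {h.offset for h in scan_consensus(p, "CACGTG")}
            assert -50 in offsets
        assert all(v[0][0] == -50 for v in truth.planted_motif_positions.values())

    def test_truth_positions_inside_windows(self):
        proms = random_promoters(50, 2)
        out, truth = plant_motifs(proms, "CACGTG", foreground_rate=0.5, seed=2)
        by_gene = {p.gene_id: p for p in out}
        assert len(truth.planted_motif_positions) == 25
        for gene, planted in truth.planted_motif_positions.items():
            p = by_gene[gene]
            for offset, strand in planted:
                i = offset - p.tss_offset_of_first_base
                assert 0 <= i <= len(p.seq) - 6
                window = p.seq[i : i + 6]
                assert window == "CACGTG"  # palindromic: both strands identical

    def test_tss_peaked_mean_recovered(self):
        proms = random_promoters(500, 7)
        _, truth = plant_motifs(
            proms, "CACGTG", foreground_rate=1.0,
            positional_model=PositionalModel("tss_peaked", peak_offset=-50, spread=30),
            seed=7,
        )
        offsets = [off for v in truth.planted_motif_positions.values() for off, _ in v]
        assert np.mean(offsets) == pytest.approx(-50, abs=5)

    def test_out_of_window_model_fails_after_retries(self):
        proms = random_promoters(3, 3, up=100, down=20)
        with pytest.raises(ValidationError, match="offset"):
            plant_motifs(proms, "CACGTG", foreground_rate=1.0,
                         positional_model=PositionalModel("fixed", peak_offset=-5000),
                         seed=3)


class TestExpression:
    def test_no_noise_no_de_means_identical(self):
        df, _ = gen_expression([f"g{i}" for i in range(30)], noise_sd=0.0,
                               de_fraction=0.0, seed=0)
        ctrl = df.filter(like="control").mean(axis=1)
        trt = df.filter(like="treated").mean(axis=1)
        assert np.allclose(ctrl, trt)

    def test_planted_shift_gives_exact_fold_change(self):
        genes = [f"g{i}" for i in range(10)]
        df, truth = gen_expression(genes, noise_sd=0.0, de_fraction=0.1,
                                   lfc_magnitude=1.0, seed=1)
        (gene,) = truth.de_genes
        lfc = truth.de_genes[gene]
        diff = df.loc[gene].filter(like="treated").mean() - df.loc[gene].filter(like="control").mean()
        assert diff == pytest.approx(lfc)
        assert 2.0 ** abs(diff) == pytest.approx(2.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError, match="n_reps"):
            gen_expression(["g1"], n_reps=1, seed=0)

    def test_truth_genes_exist_in_universe(self):
        genes = [f"g{i}" for i in range(200)]
        df, truth = gen_expression(genes, de_fraction=0.1, seed=2)
        assert set(truth.de_genes) <= set(genes)
        assert len(truth.de_genes) == 20


class TestTargetCatalog:
    def test_null_overlap_within_3sd_of_hypergeometric(self):
        universe = [f"g{i}" for i in range(2000)]
        responsive = universe[:200]
        catalog, truth = gen_target_catalog(universe, (400,), responsive,
                                            enrichment_factor=1.0, seed=4)
        n, K, k = 2000, 200, 400
        mean = k * K / n
        sd = np.sqrt(stats.hypergeom(n, K, k).var())
        assert abs(len(truth.overlap_genes) - mean) <= 3 * sd

    def test_zero_enrichment_zero_overlap(self):
        universe = [f"g{i}" for i in range(500)]
        responsive = universe[:50]
        _, truth = gen_target_catalog(universe, (100,), responsive,
                                      enrichment_factor=0.0, seed=5)
        assert truth.overlap_genes == []

    def test_documented_cluster_sizes_disjoint(self):
        universe = [f"g{i}" for i in range(6000)]
        catalog, _ = gen_target_catalog(universe, (1712, 1643, 616, 178, 30), seed=6)
        sizes = [len(m) for _, m in catalog.clusters]
        assert sizes == [1712, 1643, 616, 178, 30]
        union = set()
        for _, m in catalog.clusters:
            assert not union & m
            union |= m

    def test_oversized_clusters_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            gen_target_catalog([f"g{i}" for i in range(10)], (8, 8), seed=0)

    def test_infeasible_enrichment_rejected(self):
        universe = [f"g{i}" for i in range(100)]
        with pytest.raises(ValidationError, match="infeasible"):
            gen_target_catalog(universe, (90,), universe[:1],
                               enrichment_factor=1e6, seed=0)


class TestPathwayGen:
    def test_zero_size_rejected(self):
        with pytest.raises(ValidationError, match=">= 1"):
            gen_pathways([f"g{i}" for i in range(50)], size_range=(0, 5), seed=0)

    def test_seeded_rerun_identical_gmt_text(self, tmp_path):
        universe = [f"g{i}" for i in range(200)]
        texts = []
        for run in range(2):
            pws, _ = gen_pathways(universe, n_pathways=10, size_range=(5, 20), seed=8)
            dest = tmp_path / f"run{run}.gmt"
            write_gmt(pws, dest)
            texts.append(dest.read_text())
        assert texts[0] == texts[1]

    def test_enriched_pathways_recorded_in_truth(self):
        universe = [f"g{i}" for i in range(300)]
        sig = universe[:30]
        pws, truth = gen_pathways(universe, n_pathways=8, size_range=(10, 30),
                                  enriched_pathway_count=2, sig_set=sig, seed=9)
        assert len(truth.enriched_pathways) == 2
        assert {p.pathway_id for p in pws} >= set(truth.enriched_pathways)
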