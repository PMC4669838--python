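"""Generator correctness: determinism, invariants, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from mbdseq.core import CAPTURED
from mbdseq.dmr_analysis import chi_square_proportions
from mbdseq.expression_qpcr import analyze_folds
from mbdseq.synthetic_data import (
    GenomeSpec,
    LineageConfig,
    PackingError,
    build_genome,
    build_truth_table,
    capture_probability,
    draw_landscapes,
    simulate_mbd_library,
    simulate_qpcr,
)


class TestBuildGenome:
    def test_counts_and_invariants(self, small_genome):
        g = small_genome
        assert len(g.genes) == 40
        assert len(g.cgis) == 25
        sizes = g.chrom_sizes
        for gene in g.genes:
            assert 0 <= gene.tx_start < gene.tx_end <= sizes[gene.chrom]
            assert gene.tx_start <= gene.cds_start <= gene.cds_end <= gene.tx_end
            # exon blocks sorted, non-overlapping, inside transcript
            prev = gene.tx_start
            for s, e in zip(gene.exon_starts, gene.exon_ends):
                assert prev <= s < e <= gene.tx_end
                prev = e

    def test_genes_do_not_overlap(self, small_genome):
        by_chrom = {}
        for gene in small_genome.genes:
            by_chrom.setdefault(gene.chrom, []).append((gene.tx_start, gene.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_deterministic(self):
        spec = GenomeSpec(
            chromosomes=(("chr1", 1_000_000),), n_genes=50, n_cgis=30, seed=7
        )
        assert build_genome(spec) == build_genome(spec)

    def test_infeasible_packing(self):
        spec = GenomeSpec(chromosomes=(("chr1", 10_000),), n_genes=500, n_cgis=0)
        with pytest.raises(PackingError):
            build_genome(spec)


class TestDrawLandscapes:
    def test_full_retention_is_identity(self, small_genome):
        cfg = LineageConfig(
            retention_dex=1.0, n_regions=60, region_width=500, seed=5, depth=1000
        )
        ls = draw_landscapes(small_genome, cfg)
        p1 = ls["dex_P1"].methylated_regions
        d3 = ls["dex_D3"].methylated_regions
        key = ["chrom", "start", "end"]
        assert sorted(map(tuple, p1[key].to_numpy().tolist())) == sorted(
            map(tuple, d3[key].to_numpy().tolist())
        )

    def test_zero_hypo_fraction_is_null_effect(self, small_genome):
        cfg = LineageConfig(
            hypo_fraction=0.0, gain_fraction=0.0, n_regions=60, region_width=500,
            seed=5, depth=1000,
        )
        ls = draw_landscapes(small_genome, cfg)
        a = ls["control_P1"].regions[["chrom", "start", "end", "methylated"]]
        b = ls["dex_P1"].regions[["chrom", "start", "end", "methylated"]]
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("retention", [0.0, 0.36, 0.63, 1.0])
    def test_retention_within_exact_binomial_interval(self, small_genome, retention):
        cfg = LineageConfig(
            retention_dex=retention, hypo_fraction=0.0, gain_fraction=0.0,
            n_regions=1000, region_width=200, region_min_gap=200, seed=17, depth=1000,
        )
        ls = draw_landscapes(small_genome, cfg)
        d3 = ls["dex_D3"].regions
        n = 1000
        k = int(d3["retained"].sum())
        lo = binom.ppf(0.005, n, retention)
        hi = binom.ppf(0.995, n, retention)
        assert lo <= k <= hi

    def test_net_hypomethylation_and_gains(self, small_genome):
        cfg = LineageConfig(n_regions=200, region_width=500, seed=2, depth=1000)
        ls = draw_landscapes(small_genome, cfg)
        n_control = ls["control_P1"].regions["methylated"].sum()
        n_dex = ls["dex_P1"].regions["methylated"].sum()
        assert n_dex < n_control

    def test_truth_table_lists_every_methylated_region_once(self, small_genome):
        cfg = LineageConfig(n_regions=100, region_width=500, seed=2, depth=1000)
        ls = draw_landscapes(small_genome, cfg)
        truth = build_truth_table(ls)
        expected = sum(len(v.regions) for v in ls.values())
        assert len(truth) == expected
        # one row per (sample, region id)
        assert not truth.duplicated(subset=["sample", "region_id"]).any()
        assert set(truth["condition"]) == {"control", "dex"}
        assert set(truth["stage"]) == {"P1", "D3"}


class TestSimulateLibrary:
    def _one_region_landscape(self, small_genome, level=1.0):
        from mbdseq.core import MethylationLandscape

        regions = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [500_000],
                "end": [501_000],
                "methylated": [True],
                "level": [level],
            }
        )
        return MethylationLandscape("control_P1", "control", "P1", regions)

    def test_conservation_and_determinism(self, small_genome):
        cfg = LineageConfig(depth=20_000, seed=9, n_regions=50, region_width=500)
        ls = draw_landscapes(small_genome, cfg)["control_P1"]
        r1 = simulate_mbd_library(ls, small_genome, cfg)
        r2 = simulate_mbd_library(ls, small_genome, cfg)
        assert len(r1) == cfg.depth
        pd.testing.assert_frame_equal(r1, r2)
        assert (r1["end"] - r1["start"] == cfg.fragment_length).all()

    def test_enriched_region_coverage_ratio(self, small_genome):
        # analytic oracle: capture prob inside = min(1, base*enr*level),
        # outside = base, so the coverage ratio equals min(1, b*e)/b >= 10
        cfg = LineageConfig(
            depth=100_000, enrichment=20.0, base_capture_rate=0.05, seed=4
        )
        ls = self._one_region_landscape(small_genome)
        reads = simulate_mbd_library(ls, small_genome, cfg)
        cap = reads[reads["fraction"] == CAPTURED]
        mids = ((cap["start"] + cap["end"]) // 2).to_numpy()
        on_chr1 = (cap["chrom"] == "chr1").to_numpy()
        inside = on_chr1 & (mids >= 500_000) & (mids < 501_000)
        mean_in = inside.sum() / 1_000
        mean_out = (~inside).sum() / (small_genome.total_bp - 1_000)
        assert mean_in / mean_out >= 10

    def test_unmethylated_landscape_gives_symmetric_fractions(self, small_genome):
        from mbdseq.core import MethylationLandscape

        empty = MethylationLandscape(
            "control_P1", "control", "P1",
            pd.DataFrame(columns=["chrom", "start", "end", "methylated", "level"]),
        )
        cfg = LineageConfig(depth=50_000, seed=8)
        reads = simulate_mbd_library(empty, small_genome, cfg)
        # spatial distribution of captured vs supernatant must agree:
        # two-sample proportion test on a fixed 100 kb window
        mids = ((reads["start"] + reads["end"]) // 2).to_numpy()
        in_window = (reads["chrom"] == "chr1").to_numpy() & (mids < 100_000)
        cap = (reads["fraction"] == CAPTURED).to_numpy()
        _, p = chi_square_proportions(
            int((in_window & cap).sum()), int(cap.sum()),
            int((in_window & ~cap).sum()), int((~cap).sum()),
        )
        assert p > 0.01

    def test_capture_probability_truncates_at_one(self):
        cfg = LineageConfig(enrichment=100.0, base_capture_rate=0.05)
        p = capture_probability(np.array([0.0, 0.1, 1.0]), cfg)
        assert p[0] == pytest.approx(0.05)
        assert p[2] == 1.0
        assert np.all((p >= 0) & (p <= 1))


class TestSimulateQpcr:
    def test_noiseless_fold_two_is_one_cycle(self):
        table = simulate_qpcr(
            {"geneA": {"control": 1.0, "dex": 2.0}}, replicates=3, noise_sd=0.0, seed=1
        )
        a = table[(table["gene"] == "geneA") & (table["group"] == "control")]["ct"]
        b = table[(table["gene"] == "geneA") & (table["group"] == "dex")]["ct"]
        assert np.allclose(a.to_numpy() - b.to_numpy(), 1.0)

    def test_null_design_recovers_unit_folds(self):
        design = {g: {"control": 1.0, "dex": 1.0} for g in ["g1", "g2"]}
        table = simulate_qpcr(design, replicates=6, noise_sd=0.05, seed=3)
        folds = analyze_folds(table, treated="dex", control="control")
        for r in folds.values():
            assert r.fold == pytest.approx(1.0, abs=0.15)

    def test_knockdown_fold_recovered(self):
        # Tet3-knockdown-like design: 0.46-fold at realistic noise
        est = []
        for seed in range(25):
            table = simulate_qpcr(
                {"Tet3": {"control": 1.0, "kd": 0.46}},
                replicates=6, noise_sd=0.2, seed=seed,
            )
            est.append(analyze_folds(table, "kd", "control")["Tet3"].fold)
        assert np.mean(est) == pytest.approx(0.46, abs=0.1)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_qpcr({"g": {"dex": 0.0}}, replicates=3)
        with pytest.raises(ValueError, match="replicates"):
            simulate_qpcr({"g": {"dex": 1.0}}, replicates=2)
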