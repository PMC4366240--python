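import numpy as np
import pytest
from scipy import stats

from p53targets.enrichment import count_bin_reads
from p53targets.intervals import GenomicInterval, overlaps
from p53targets.simulate import (
    SimulationConfig,
    plant_motif_sequences,
    plant_truth,
    simulate_chip,
    simulate_expression,
    simulate_genome,
)


def small_cfg(**kw):
    base = dict(n_genes=100, n_bound_genes=20, n_responsive_genes=20,
                n_target_genes=12, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateGenome:
    def test_seeded_determinism(self):
        a = simulate_genome(small_cfg())
        b = simulate_genome(small_cfg())
        assert [g.tss for g in a.genes] == [g.tss for g in b.genes]
        assert [(c.start, c.end) for c in a.cgis] == [(c.start, c.end) for c in b.cgis]

    def test_cgi_fraction_boundaries(self):
        assert simulate_genome(small_cfg(cgi_promoter_fraction=0.0)).cgis == []
        full = simulate_genome(small_cfg(n_genes=50, cgi_promoter_fraction=1.0,
                                         n_bound_genes=10, n_responsive_genes=10,
                                         n_target_genes=5))
        assert len(full.cgis) == 50
        for g, c in zip(full.genes, sorted(full.cgis, key=lambda x: x.start)):
            window = GenomicInterval(g.chrom, g.tss - 500, g.tss + 500)
            assert overlaps(window, c)

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(small_cfg(gene_spacing=50_000))

    def test_alternating_strands_and_bounds(self):
        g = simulate_genome(small_cfg())
        assert {gene.strand for gene in g.genes} == {"+", "-"}
        size = g.chrom_sizes["chrS"]
        assert all(0 <= min(x.tss, x.tes) and max(x.tss, x.tes) < size for x in g.genes)


class TestPlantTruth:
    def test_exact_counts_and_flags(self):
        cfg = small_cfg()
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        t = truth.table
        assert int(t["bound"].sum()) == cfg.n_bound_genes
        assert int(t["responsive"].sum()) == cfg.n_responsive_genes
        assert int(t["is_target"].sum()) == cfg.n_target_genes
        assert ((t["direction"] != "none") == t["responsive"]).all()

    def test_no_bound_boundary(self):
        cfg = small_cfg(n_bound_genes=0, n_responsive_genes=5, n_target_genes=0)
        truth = plant_truth(simulate_genome(cfg), cfg)
        assert not truth.table["bound"].any()

    def test_seeded_determinism(self):
        cfg = small_cfg()
        genome = simulate_genome(cfg)
        a, b = plant_truth(genome, cfg), plant_truth(genome, cfg)
        assert a.table.equals(b.table)

    def test_cgi_share_of_targets_matches_odds_sampler(self):
        """With CGI fraction 0.5 and 3:1 odds, targets should be ~75% CGI."""
        shares = []
        for seed in range(200):
            cfg = small_cfg(seed=seed, n_genes=120, n_bound_genes=30,
                            n_responsive_genes=30, n_target_genes=20)
            genome = simulate_genome(cfg)
            truth = plant_truth(genome, cfg)
            tgt = truth.table[truth.table["is_target"]]
            shares.append((tgt["promoter_class"] == "CGI").mean())
        mean_share = float(np.mean(shares))
        # expectation 0.75 under the weighted sampler; allow 4 SE of the
        # 200-replicate mean (binomial-ish se ~ sqrt(0.75*0.25/20)/sqrt(200))
        assert abs(mean_share - 0.75) < 0.03


class TestSimulateChip:
    def test_read_recount_roundtrip_exact(self):
        cfg = small_cfg()
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        _, reads, table = simulate_chip(genome, truth, cfg)
        recounted = count_bin_reads(reads, genome, samples=table.samples)
        assert recounted.counts.equals(table.counts)

    def test_dropout_one_leaves_no_replicated_bound_peaks(self):
        cfg = small_cfg(peak_dropout_prob=1.0)
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        peaks, _, _ = simulate_chip(genome, truth, cfg)
        for name, plist in peaks.items():
            if name.startswith("Grow"):
                continue
            # only decoys remain; no bound-gene peak appears at all
            bound_tss = {genome.gene(g).tss for g in truth.bound}
            for p in plist:
                mid = p.interval.midpoint
                assert all(abs(mid - t) > 5000 for t in bound_tss)

    def test_input_counts_match_nb_background_mean(self):
        cfg = small_cfg(n_genes=2000, n_bound_genes=100, n_responsive_genes=100,
                        n_target_genes=50)
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        _, _, table = simulate_chip(genome, truth, cfg)
        inputs = table.counts[table.columns_for("input")].to_numpy(dtype=float)
        mu = cfg.chip_mean_background
        var = mu + cfg.nb_dispersion * mu**2
        se = np.sqrt(var / inputs.size)
        assert abs(inputs.mean() - mu) < 3 * se

    def test_fold_one_null_distributions_indistinguishable(self):
        cfg = small_cfg(n_genes=2000, n_bound_genes=400, n_responsive_genes=100,
                        n_target_genes=50, chip_fold_enrichment=1.0)
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        _, _, table = simulate_chip(genome, truth, cfg)
        col = table.counts["chip_RIS_rep1"].to_numpy(dtype=float)
        bound = truth.table["bound"].to_numpy()
        ks = stats.ks_2samp(col[bound], col[~bound])
        assert ks.pvalue > 0.01

    def test_determinism(self):
        cfg = small_cfg()
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        p1, r1, t1 = simulate_chip(genome, truth, cfg)
        p2, r2, t2 = simulate_chip(genome, truth, cfg)
        assert t1.counts.equals(t2.counts)
        assert all(np.array_equal(r1[k], r2[k]) for k in r1)
        assert {k: [(p.interval.start, p.interval.end) for p in v] for k, v in p1.items()} == \
               {k: [(p.interval.start, p.interval.end) for p in v] for k, v in p2.items()}


class TestSimulateExpression:
    def test_effect_size_and_sign(self):
        cfg = small_cfg(n_genes=2000, n_bound_genes=200, n_responsive_genes=200,
                        n_target_genes=100, expr_effect=1.0)
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        vec, sh = simulate_expression(genome, truth, cfg)
        gene_of = {g.probe_ids[0]: g.gene_id for g in genome.genes}
        diffs = sh.mean(axis=1) - vec.mean(axis=1)
        dirs = truth.table["direction"]
        induced = [p for p in vec.index if dirs[gene_of[p]] == "induced"]
        repressed = [p for p in vec.index if dirs[gene_of[p]] == "repressed"]
        k = cfg.n_expr_replicates
        se = cfg.expr_sd * np.sqrt(2.0 / k) / np.sqrt(len(induced))
        assert abs(diffs[induced].mean() + cfg.expr_effect) < 4 * se
        assert diffs[repressed].mean() > 0.5

    def test_null_effect_gives_uniform_pvalues(self):
        cfg = small_cfg(n_genes=2000, n_bound_genes=200, n_responsive_genes=500,
                        n_target_genes=100, expr_effect=0.0)
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        vec, sh = simulate_expression(genome, truth, cfg)
        gene_of = {g.probe_ids[0]: g.gene_id for g in genome.genes}
        resp = [p for p in vec.index if truth.table["responsive"][gene_of[p]]]
        pvals = stats.ttest_ind(sh.loc[resp], vec.loc[resp], axis=1).pvalue
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_determinism(self):
        cfg = small_cfg()
        genome = simulate_genome(cfg)
        truth = plant_truth(genome, cfg)
        v1, s1 = simulate_expression(genome, truth, cfg)
        v2, s2 = simulate_expression(genome, truth, cfg)
        assert v1.equals(v2) and s1.equals(s2)


class TestMotifPlanting:
    def test_planted_motif_present_at_offsets(self):
        seqs = plant_motif_sequences(5, 100, "GGGCATGTCC", offsets=[40], seed=3)
        assert all(s[40:50] == "GGGCATGTCC" for s in seqs)

    def test_seeded_determinism(self):
        a = plant_motif_sequences(3, 80, "ACGTACGT", None, seed=9)
        b = plant_motif_sequences(3, 80, "ACGTACGT", None, seed=9)
        assert a == b


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"cgi_promoter_fraction": 1.5},
            {"peak_dropout_prob": -0.1},
            {"nb_dispersion": 0.0},
            {"n_bound_genes": 101},
            {"n_target_genes": 50},
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)
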