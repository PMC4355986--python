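import numpy as np
import pandas as pd
import pytest

import methclust as mc
from methclust.synthetic import (
    SimulationConfig,
    expected_reads_per_sample,
    simulate_annotation,
    simulate_clinical,
    simulate_cohort,
    simulate_conservation_track,
    simulate_expression,
    simulate_methylation_matrix,
    simulate_reads,
)

SMALL = dict(n_genes=16, n_clusters=2, genes_per_cluster=4,
             n_intragenic_cgis=4, n_intergenic_cgis=4, background_slots=5,
             n_tumor=6, n_normal=4)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(dmr_effect=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(censoring_fraction=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=4, n_clusters=2, genes_per_cluster=4)

    def test_json_round_trip(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        assert SimulationConfig.from_json(cfg.to_json()) == cfg


class TestAnnotation:
    def test_same_seed_identical_outputs(self):
        a = simulate_annotation(SimulationConfig(seed=5, **SMALL))
        b = simulate_annotation(SimulationConfig(seed=5, **SMALL))
        assert a.genome == b.genome
        assert a.genes == b.genes
        assert a.cgis == b.cgis

    def test_clusters_are_consecutive_on_one_chromosome(self):
        ann = simulate_annotation(SimulationConfig(seed=5, **SMALL))
        by_cluster = {}
        for g in ann.genes:
            if g.cluster_id:
                by_cluster.setdefault(g.cluster_id, []).append(g)
        assert len(by_cluster) == 2
        all_sorted = sorted(ann.genes, key=lambda g: (g.chrom, g.tss))
        for genes in by_cluster.values():
            assert len(genes) == 4
            assert len({g.chrom for g in genes}) == 1
            # cluster members occupy consecutive positions genome-wide
            idx = sorted(all_sorted.index(g) for g in genes)
            assert idx == list(range(idx[0], idx[0] + 4))

    def test_p_cgi_one_gives_every_promoter_a_cgi(self):
        from methclust import dmr as D

        ann = simulate_annotation(SimulationConfig(seed=5, p_cgi=1.0, **SMALL))
        regions = D.classify_regions(ann.genes, ann.cgis)
        assert not any(r.region_class == D.NONCGI_PROMOTER for r in regions)

    def test_planted_windows_lie_inside_annotated_windows(self):
        ann = simulate_annotation(SimulationConfig(seed=5, **SMALL))
        centers = {(c, ctr) for c, ctr, _ in ann.truth.window_centers}
        for p in ann.truth.planted_regions:
            mid = (p.interval.start + p.interval.end) // 2
            assert (p.interval.chrom, mid) in centers
            assert p.direction == "hyper" and p.tumor_rate > p.normal_rate

    def test_analysis_windows_disjoint(self):
        ann = simulate_annotation(SimulationConfig(seed=5, **SMALL))
        spans = sorted(
            (c, ctr - 4000, ctr + 4000) for c, ctr, _ in ann.truth.window_centers
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 <= s2

    def test_gc_content_controls_sequence_composition(self):
        ann = simulate_annotation(SimulationConfig(seed=5, gc_content=0.8, **SMALL))
        seq = ann.genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.8, abs=0.01)


class TestReads:
    def test_same_seed_identical_reads(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        ann = simulate_annotation(cfg)
        sample = mc.SampleRecord("tumor_001", "tumor")
        r1 = simulate_reads(cfg, ann.truth, sample, ann.chrom_lengths, 0)
        r2 = simulate_reads(cfg, ann.truth, sample, ann.chrom_lengths, 0)
        assert r1 == r2

    def test_null_effect_equalizes_expected_rates(self):
        cfg = SimulationConfig(seed=9, dmr_effect=1.0, **SMALL)
        ann = simulate_annotation(cfg)
        assert expected_reads_per_sample(cfg, ann.chrom_lengths, ann.truth,
                                         tumor=True) == pytest.approx(
            expected_reads_per_sample(cfg, ann.chrom_lengths, ann.truth,
                                      tumor=False)
        )

    def test_total_reads_conserved_within_five_sd(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        ann = simulate_annotation(cfg)
        sample = mc.SampleRecord("normal_001", "normal")
        reads = simulate_reads(cfg, ann.truth, sample, ann.chrom_lengths, 3)
        mean = expected_reads_per_sample(cfg, ann.chrom_lengths, ann.truth)
        assert abs(len(reads) - mean) <= 5 * np.sqrt(mean)

    def test_planted_bins_threefold_in_tumor_on_average(self, default_cohort):
        """Law-of-large-numbers check on the default cohort's read layer."""
        cohort = default_cohort
        cfg = cohort.config
        tumor_reads = [cohort.reads[s.sample_id] for s in cohort.samples
                       if s.group == "tumor"]
        normal_reads = [cohort.reads[s.sample_id] for s in cohort.samples
                        if s.group == "normal"]

        def planted_mean(read_sets):
            from methclust.quantify import bin_counts

            totals = []
            for reads in read_sets:
                counts, _ = bin_counts(reads, cohort.annotation.chrom_lengths)
                per_bin = []
                for p in cohort.truth.planted_regions:
                    lo = p.interval.start // 100
                    hi = p.interval.end // 100
                    per_bin.append(counts[p.interval.chrom][lo:hi])
                totals.append(np.concatenate(per_bin).mean())
            return np.mean(totals), np.concatenate(per_bin).size

        t_mean, n_bins = planted_mean(tumor_reads)
        n_mean, _ = planted_mean(normal_reads)
        assert n_bins >= 1000
        ratio = t_mean / n_mean
        # 3 SE tolerance on the ratio via Poisson error propagation
        se = ratio * np.sqrt(1 / (t_mean * n_bins * 20) + 1 / (n_mean * n_bins * 10))
        assert abs(ratio - cfg.dmr_effect) <= max(3 * se, 0.05)


class TestClinical:
    def test_censoring_zero_gives_all_events(self):
        cfg = SimulationConfig(seed=4, censoring_fraction=0.0, **SMALL)
        ann = simulate_annotation(cfg)
        records = simulate_clinical(cfg, ann.truth)
        tumors = [r for r in records if r.group == "tumor"]
        assert tumors and all(r.os_event == 1 for r in tumors)

    def test_censoring_fraction_approximately_achieved(self):
        cfg = SimulationConfig(seed=4, n_tumor=2000, censoring_fraction=0.3,
                               **{k: v for k, v in SMALL.items() if k != "n_tumor"})
        ann = simulate_annotation(cfg)
        records = simulate_clinical(cfg, ann.truth)
        events = np.array([r.os_event for r in records if r.group == "tumor"])
        assert 1 - events.mean() == pytest.approx(0.3, abs=0.05)

    def test_null_hazard_gives_uniform_logrank(self):
        from lifelines.statistics import logrank_test

        pvals = []
        for seed in range(8):
            cfg = SimulationConfig(seed=100 + seed, true_log_hr=0.0, n_tumor=100,
                                   **{k: v for k, v in SMALL.items()
                                      if k != "n_tumor"})
            ann = simulate_annotation(cfg)
            recs = [r for r in simulate_clinical(cfg, ann.truth)
                    if r.group == "tumor"]
            risk = np.array([ann.truth.patient_risk_group[r.sample_id]
                             for r in recs])
            t = np.array([r.os_time for r in recs])
            e = np.array([r.os_event for r in recs])
            if risk.sum() in (0, len(risk)):
                continue
            pvals.append(logrank_test(t[risk == 1], t[risk == 0],
                                      e[risk == 1], e[risk == 0]).p_value)
        # under the null, p-values spread out rather than pile near 0
        assert min(pvals) > 1e-4 and max(pvals) > 0.2


class TestExpression:
    def test_fixed_seed_identical_matrix(self):
        cfg = SimulationConfig(seed=6, **SMALL)
        cohort_a = simulate_cohort(cfg, with_reads=False)
        cohort_b = simulate_cohort(cfg, with_reads=False)
        pd.testing.assert_frame_equal(cohort_a.expression, cohort_b.expression)

    def test_zero_coupling_gives_near_zero_correlation(self):
        cfg = SimulationConfig(seed=6, expr_coupling_gamma=0.0, n_tumor=150,
                               **{k: v for k, v in SMALL.items() if k != "n_tumor"})
        cohort = simulate_cohort(cfg, with_reads=False)
        ids = [s.sample_id for s in cohort.samples if s.group == "tumor"]
        rs = []
        for gene in list(cohort.expression.index)[:10]:
            m = cohort.methylation.loc[ids, gene]
            e = np.log2(cohort.expression.loc[gene, ids].astype(float))
            rs.append(np.corrcoef(m, e)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_strong_coupling_low_noise_approaches_minus_one(self):
        cfg = SimulationConfig(seed=6, expr_coupling_gamma=5.0, noise_sd=1e-4,
                               **SMALL)
        cohort = simulate_cohort(cfg, with_reads=False)
        ids = [s.sample_id for s in cohort.samples]
        gene = cohort.expression.index[0]
        m = cohort.methylation.loc[ids, gene]
        e = np.log2(cohort.expression.loc[gene, ids].astype(float))
        assert np.corrcoef(m, e)[0, 1] == pytest.approx(-1.0, abs=1e-3)

    def test_rpkm_nonnegative(self):
        cohort = simulate_cohort(SimulationConfig(seed=6, **SMALL),
                                 with_reads=False)
        assert (cohort.expression.to_numpy() >= 0).all()


def test_conservation_track_values_in_unit_interval():
    cfg = SimulationConfig(seed=2, **SMALL)
    ann = simulate_annotation(cfg)
    track = simulate_conservation_track(cfg, ann)
    scores = np.array([iv.score for iv in track])
    assert ((scores >= 0) & (scores <= 1)).all()
    assert len(track) == sum(ann.chrom_lengths.values()) // 50
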