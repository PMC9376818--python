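import numpy as np
import pytest

from embryoz import simulate as sim
from embryoz.promoter_signal import count_cpg


class TestConfig:
    def test_bad_proportions_rejected(self):
        with pytest.raises(sim.ConfigurationError):
            sim.SimulationConfig(type_proportions={"Double": 0.5, "Single": 0.2, "No": 0.2})

    def test_genome_too_small_rejected(self):
        with pytest.raises(sim.ConfigurationError, match="too small"):
            sim.SimulationConfig(n_genes=100, chrom_length=100_000)

    def test_negative_rate_rejected(self):
        with pytest.raises(sim.ConfigurationError):
            sim.SimulationConfig(depth=-1)


class TestAnnotation:
    def test_reproducible(self):
        cfg = sim.SimulationConfig(n_genes=10, seed=1)
        genes_a, _ = sim.simulate_annotation(cfg, with_sequence=False)
        genes_b, _ = sim.simulate_annotation(cfg, with_sequence=False)
        assert genes_a == genes_b
        assert len(genes_a) == 10

    def test_zero_genes(self):
        cfg = sim.SimulationConfig(n_genes=0, chrom_length=50_000)
        genes, seq = sim.simulate_annotation(cfg)
        assert genes == [] and len(seq) == 50_000

    def test_sequence_bytes_identical(self):
        cfg = sim.SimulationConfig(n_genes=5, seed=9)
        truth = sim.plant_truth(cfg)
        _, seq_a = sim.simulate_annotation(cfg, truth)
        _, seq_b = sim.simulate_annotation(cfg, truth)
        assert seq_a == seq_b

    def test_wide_windows_inside_chromosome(self):
        cfg = sim.SimulationConfig(n_genes=50, seed=2)
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        for g in genes:
            assert g.tss - 5000 >= 0
            assert g.tss + 5000 <= cfg.chrom_length

    def test_cpg_density_tracks_architecture(self, small_dataset):
        ds = small_dataset
        arch = {t.gene_id: t.architecture for t in ds.truth}
        by_class = {"Double": [], "No": []}
        for g in ds.genes:
            if arch[g.gene_id] in by_class:
                by_class[arch[g.gene_id]].append(
                    count_cpg(ds.sequence[g.tss - 1000 : g.tss + 1000])
                )
        assert np.mean(by_class["Double"]) > 2 * np.mean(by_class["No"])


class TestH2az:
    def test_double_gene_flanking_maxima(self):
        """At high depth a Double promoter shows both nucleosome windows
        well above the TSS trough."""
        cfg = sim.SimulationConfig(n_genes=40, seed=5, depth=200)
        truth = [
            sim.SyntheticTruth(f"g{i + 1:05d}", "Double", "biallelic", 0.5,
                               "K4only", "active", "s")
            for i in range(40)
        ]
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        track, _, _ = sim.simulate_h2az(genes, truth, cfg)
        ok = 0
        for g in genes:
            sign = 1 if g.strand == "+" else -1
            minus = track.values[g.tss - sign * 500 : g.tss - sign * 100 : sign].mean()
            plus = track.values[g.tss + sign * 100 : g.tss + sign * 500 : sign].mean()
            tss = track.values[g.tss - 20 : g.tss + 20].mean()
            ok += minus > 2 * tss and plus > 2 * tss
        assert ok >= 38  # allow rare fluctuation

    def test_single_gene_window_ordering(self):
        cfg = sim.SimulationConfig(n_genes=30, seed=11, depth=500)
        truth = [
            sim.SyntheticTruth(f"g{i + 1:05d}", "Single", "biallelic", 0.5,
                               "K4only", "active", "s")
            for i in range(30)
        ]
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        track, _, _ = sim.simulate_h2az(genes, truth, cfg)
        for g in genes:
            sign = 1 if g.strand == "+" else -1
            minus = track.values[g.tss - sign * 500 : g.tss - sign * 100 : sign].mean()
            plus = track.values[g.tss + sign * 100 : g.tss + sign * 500 : sign].mean()
            tss = track.values[g.tss - 20 : g.tss + 20].mean()
            assert minus < tss < plus

    def test_zero_depth_zero_background_all_zero(self):
        cfg = sim.SimulationConfig(n_genes=5, seed=1, depth=0, background_rate=0)
        truth = sim.plant_truth(cfg)
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        track, _, _ = sim.simulate_h2az(genes, truth, cfg)
        assert track.values.sum() == 0

    def test_peaks_are_enriched_promoters(self, small_dataset):
        ds = small_dataset
        arch = {t.gene_id: t.architecture for t in ds.truth}
        assert all(arch[p.name] != "No" for p in ds.peaks)
        assert len(ds.peaks) == sum(a != "No" for a in arch.values())

    def test_determinism(self):
        cfg = sim.SimulationConfig(n_genes=20, seed=4)
        truth = sim.plant_truth(cfg)
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        t1, _, f1 = sim.simulate_h2az(genes, truth, cfg)
        t2, _, f2 = sim.simulate_h2az(genes, truth, cfg)
        np.testing.assert_array_equal(t1.values, t2.values)
        assert f1.equals(f2)


class TestAlleleCounts:
    def make(self, n_peaks, allelic_class, fraction, seed=0, **kwargs):
        cfg = sim.SimulationConfig(
            n_genes=n_peaks, seed=seed,
            allelic_class_proportions={allelic_class: 1.0,
                                       **{c: 0.0 for c in sim.ALLELIC_CLASSES
                                          if c != allelic_class}},
            paternal_fraction={**{c: 0.5 for c in sim.ALLELIC_CLASSES},
                               allelic_class: fraction},
            **kwargs,
        )
        truth = sim.plant_truth(cfg)
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        peaks = sim.truth_peaks(genes, truth)
        return sim.simulate_allele_counts(peaks, truth, cfg)

    def test_pure_paternal(self):
        counts = self.make(20, "biased_pat", 1.0)
        assert (counts["maternal"] == 0).all()

    def test_zero_trackable_probability(self):
        counts = self.make(20, "biallelic", 0.5, snp_trackable_probability=0.0)
        assert ((counts["paternal"] + counts["maternal"]) == 0).all()

    def test_law_of_large_numbers_biallelic(self):
        counts = self.make(600, "biallelic", 0.5, seed=2)
        totals = counts["paternal"] + counts["maternal"]
        ratio = counts["paternal"].sum() / totals.sum()
        se = 0.5 / np.sqrt(totals.sum())
        assert abs(ratio - 0.5) <= 3 * se

    def test_calibration_per_class(self, default_dataset):
        """Empirical paternal fraction per planted class within 3 SE."""
        ds = default_dataset
        merged = ds.allele_counts
        for cls, planted in ds.config.paternal_fraction.items():
            sub = merged[merged["true_class"] == cls]
            if sub.empty:
                continue
            total = (sub["paternal"] + sub["maternal"]).sum()
            ratio = sub["paternal"].sum() / total
            se = np.sqrt(planted * (1 - planted) / total)
            assert abs(ratio - planted) <= 3 * se + 1e-9, cls


class TestMarksExpression:
    def test_unmarked_gene_background_only(self):
        cfg = sim.SimulationConfig(n_genes=20, seed=6, background_rate=0.0)
        truth = [
            sim.SyntheticTruth(f"g{i + 1:05d}", "No", "biallelic", 0.5,
                               "Unmarked", "inactive", "s")
            for i in range(20)
        ]
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        k4, k27, _ = sim.simulate_marks_expression(genes, truth, cfg)
        assert k4.values.sum() == 0 and k27.values.sum() == 0

    def test_inactive_fpkm_below_threshold(self):
        cfg = sim.SimulationConfig(
            n_genes=1000, seed=8,
            type_proportions={"Double": 0.0, "Single": 0.0, "No": 1.0},
        )
        truth = [
            sim.SyntheticTruth(t.gene_id, t.architecture, t.allelic_class,
                               t.paternal_fraction, t.mark_state, "inactive", t.stage)
            for t in sim.plant_truth(cfg)
        ]
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        _, _, fpkm = sim.simulate_marks_expression(genes, truth, cfg)
        assert (fpkm["fpkm"] < 0.1).mean() >= 0.99

    def test_bivalent_gene_both_marks_enriched(self):
        from embryoz.promoter_signal import promoter_rpkm, promoter_window

        cfg = sim.SimulationConfig(n_genes=30, seed=12, depth=200)
        truth = [
            sim.SyntheticTruth(f"g{i + 1:05d}", "Single", "biallelic", 0.5,
                               "Bivalent", "intermediate", "s")
            for i in range(30)
        ]
        genes, _ = sim.simulate_annotation(cfg, with_sequence=False)
        k4, k27, _ = sim.simulate_marks_expression(genes, truth, cfg)
        for g in genes[:10]:
            w = promoter_window(g, chrom_length=len(k4))
            assert promoter_rpkm(k4, w) > 1
            assert promoter_rpkm(k27, w) > 1


class TestStageSeries:
    def test_stages_and_determinism(self):
        cfg = sim.SimulationConfig(n_genes=50, seed=3)
        a = sim.simulate_stage_series(cfg)
        b = sim.simulate_stage_series(cfg)
        assert list(a) == ["2cell", "8cell", "morula", "blastocyst"]
        assert a == b

    def test_persistence_extremes(self):
        cfg = sim.SimulationConfig(n_genes=100, seed=3)
        frozen = sim.simulate_stage_series(cfg, persistence=1.0)
        archs = [[t.architecture for t in stage] for stage in frozen.values()]
        assert all(a == archs[0] for a in archs)


class TestFullDataset:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = sim.SimulationConfig(n_genes=30, seed=13)
        for sub in ("a", "b"):
            ds = sim.simulate_dataset(cfg, with_sequence=True)
            sim.write_dataset(ds, tmp_path / sub)
        for name in ("genes.tsv", "genome.fa", "h2az.bedgraph", "peaks.bed",
                     "allele_counts.tsv", "fpkm.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name
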