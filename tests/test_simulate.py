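"""Synthetic-data generator: determinism, construction contracts, recovery."""

import numpy as np
import pandas as pd
import pytest

from chipdyn import simulate as sim
from chipdyn.exceptions import DesignError, PlacementError
from chipdyn.simulate import GroundTruth, SampleDesign, SimConfig
from chipdyn.stats import naive_de

SMALL = dict(n_chromosomes=1, chrom_length=100_000, n_genes=30, n_origins=6,
             n_db_genes=5, n_deg=8)


def small_config(**kw):
    return SimConfig(**{**SMALL, **kw, "seed": kw.get("seed", 7)})


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SimConfig(fraction_early=0.5, fraction_late=0.5, fraction_inactive=0.5)

    def test_degenerate_fractions_all_early(self):
        cfg = small_config(fraction_early=1.0, fraction_late=0.0,
                           fraction_inactive=0.0)
        _, origins, _ = sim.generate_annotation(cfg)
        assert (origins["true_type"] == "early").all()

    def test_infeasible_density_raises(self):
        with pytest.raises(PlacementError):
            sim.generate_annotation(SimConfig(n_chromosomes=1, chrom_length=50_000,
                                              n_genes=500, seed=0))


class TestAnnotation:
    def test_counts_bounds_and_strand_balance(self):
        cfg = small_config()
        genes, origins, blacklist = sim.generate_annotation(cfg)
        assert len(genes) == 30 and len(origins) == 6
        assert genes["tss"].between(0, cfg.chrom_length - 1).all()
        assert origins["center"].between(0, cfg.chrom_length - 1).all()
        n_plus = (genes["strand"] == "+").sum()
        assert 10 <= n_plus <= 20
        assert (blacklist["end"] > blacklist["start"]).all()

    def test_determinism_same_seed(self):
        a = sim.generate_annotation(small_config())
        b = sim.generate_annotation(small_config())
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_different_seed_differs(self):
        a, _, _ = sim.generate_annotation(small_config(seed=1))
        b, _, _ = sim.generate_annotation(small_config(seed=2))
        assert not a["tss"].equals(b["tss"])

    def test_promoter_windows_disjoint(self):
        genes, _, _ = sim.generate_annotation(small_config())
        iv = []
        for _, g in genes.iterrows():
            s = g["tss"] - 500 if g["strand"] == "+" else g["tss"]
            iv.append((max(s, 0), max(s, 0) + 500))
        iv.sort()
        assert all(iv[i][1] <= iv[i + 1][0] for i in range(len(iv) - 1))


class TestChipTracks:
    def design(self, timepoints=("G1", "HU45")):
        return [SampleDesign("WT", t, a, 1) for t in timepoints
                for a in ("IP", "input")]

    def test_track_shapes_and_determinism(self):
        cfg = small_config()
        genes, origins, _ = sim.generate_annotation(cfg)
        truth = sim.generate_truth(cfg, genes, origins)
        t1 = sim.simulate_chip_tracks(genes, origins, truth, self.design(), cfg)
        t2 = sim.simulate_chip_tracks(genes, origins, truth, self.design(), cfg)
        for name in t1:
            assert t1[name]["chr1"].size == cfg.chrom_length // cfg.bin_width
            np.testing.assert_array_equal(t1[name]["chr1"], t2[name]["chr1"])

    def test_missing_input_pairing_rejected(self):
        cfg = small_config()
        genes, origins, _ = sim.generate_annotation(cfg)
        truth = sim.generate_truth(cfg, genes, origins)
        with pytest.raises(DesignError, match="no matched input"):
            sim.simulate_chip_tracks(genes, origins, truth,
                                     [SampleDesign("WT", "G1", "IP", 1)], cfg)

    def test_zero_depth_zero_tracks(self):
        cfg = small_config(depth=0.0)
        genes, origins, _ = sim.generate_annotation(cfg)
        truth = sim.generate_truth(cfg, genes, origins)
        tracks = sim.simulate_chip_tracks(genes, origins, truth, self.design(), cfg)
        for t in tracks.values():
            assert t.total() == 0.0

    def test_null_effect_means_equal_across_timepoints(self):
        """With db_effect 0 (and no global drift) expected promoter coverage
        is identical in G1 and HU45; check via Monte-Carlo over seeds."""
        genes = origins = truth = None
        diffs = []
        for seed in range(50):
            cfg = small_config(seed=seed, db_effect=0.0, hu_global_log2=0.0,
                               fork_amplitude=0.0, nb_dispersion=0.0)
            if genes is None:
                genes, origins, _ = sim.generate_annotation(cfg)
            truth = sim.generate_truth(cfg, genes, origins)
            tracks = sim.simulate_chip_tracks(genes, origins, truth,
                                              self.design(), cfg)
            g1 = tracks["WT_G1_IP_rep1"]["chr1"]
            hu = tracks["WT_HU45_IP_rep1"]["chr1"]
            diffs.append(hu.mean() - g1.mean())
        # mean difference ~ N(0, sigma/sqrt(50*nbins)); generous 3-sigma band
        assert abs(np.mean(diffs)) < 0.3

    def test_planted_db_gene_shifts_in_planted_direction(self):
        """A planted gene's promoter coverage moves with its planted sign
        between G1 and HU45 in expectation (Monte-Carlo over 50 seeds)."""
        deltas = []
        for seed in range(50):
            cfg = small_config(seed=seed, hu_global_log2=0.0, fork_amplitude=0.0)
            genes, origins, _ = sim.generate_annotation(cfg)
            truth = sim.generate_truth(cfg, genes, origins)
            gene, sign = sorted(truth.db_genes.items())[0]
            row = genes.set_index("gene_id").loc[gene]
            start = row["tss"] - 500 if row["strand"] == "+" else row["tss"]
            tracks = sim.simulate_chip_tracks(genes, origins, truth,
                                              self.design(), cfg)
            g1 = tracks["WT_G1_IP_rep1"].interval_mean("chr1", start, start + 500)
            hu = tracks["WT_HU45_IP_rep1"].interval_mean("chr1", start, start + 500)
            deltas.append(np.sign(sign) * (hu - g1))
        assert np.mean(deltas) > 0


class TestEduTracks:
    def setup_method(self):
        self.cfg = small_config(fraction_early=0.5, fraction_late=0.5,
                                fraction_inactive=0.0)
        self.genes, self.origins, _ = sim.generate_annotation(self.cfg)
        self.truth = sim.generate_truth(self.cfg, self.genes, self.origins)

    def origin_of_type(self, kind):
        for oid, t in sorted(self.truth.origin_types.items()):
            if t == kind:
                return self.origins.set_index("origin_id").loc[oid]
        pytest.skip(f"no {kind} origin drawn")

    def window_mean(self, track, origin):
        return track.interval_mean(origin["chrom"], origin["center"] - 2500,
                                   origin["center"] + 2500)

    def test_g1_all_background(self):
        track = sim.simulate_edu_track(self.origins, self.truth, "WT", "G1",
                                       self.cfg, noise=False)
        assert np.all(track["chr1"] == self.cfg.edu_background)

    def test_wt_late_origin_stays_at_background(self):
        late = self.origin_of_type("late")
        track = sim.simulate_edu_track(self.origins, self.truth, "WT", "HU45",
                                       self.cfg, noise=False)
        assert self.window_mean(track, late) <= self.cfg.edu_background + 1e-9

    def test_mutant_late_origin_fires(self):
        late = self.origin_of_type("late")
        means = []
        for seed in range(50):
            cfg = small_config(seed=self.cfg.seed, fraction_early=0.5,
                               fraction_late=0.5, fraction_inactive=0.0)
            track = sim.simulate_edu_track(self.origins, self.truth, "rad53-kd",
                                           "HU90", cfg, replicate=seed)
            means.append(self.window_mean(track, late))
        assert np.mean(means) > 2.0  # plateau 4 >> threshold 2

    def test_unknown_genotype_rejected(self):
        with pytest.raises(DesignError):
            sim.simulate_edu_track(self.origins, self.truth, "nonsense", "HU45",
                                   self.cfg)


class TestRnaCounts:
    def design(self):
        return [SampleDesign("WT", t, "RNA", r) for t in ("G1", "HU45")
                for r in (1, 2, 3)]

    def test_determinism(self):
        cfg = small_config()
        genes, origins, _ = sim.generate_annotation(cfg)
        truth = sim.generate_truth(cfg, genes, origins)
        a = sim.simulate_rna_counts(genes, truth, self.design(), cfg)
        b = sim.simulate_rna_counts(genes, truth, self.design(), cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_null_config_equal_expected_counts(self):
        cfg = small_config(deg_log2fc=0.0, ho_down_bias=0.0, cd_down_bias=0.0,
                           nb_dispersion=0.0, conflict_log2fc=0.0)
        genes, origins, _ = sim.generate_annotation(cfg)
        truth = sim.generate_truth(cfg, genes, origins)
        counts = sim.simulate_rna_counts(genes, truth, self.design(), cfg)
        g1 = counts[[c for c in counts if "_G1_" in c]].mean(axis=1)
        hu = counts[[c for c in counts if "_HU45_" in c]].mean(axis=1)
        # equal means up to sampling noise across 30 genes x 3 reps
        assert abs((hu - g1).mean()) < 0.05 * g1.mean()

    def test_surrogate_recovers_planted_log2fc(self):
        """Planted log2FC 2 estimated within +-0.3 at depth >= 200, 3 reps."""
        errors = []
        for seed in range(5):
            cfg = small_config(seed=seed, n_genes=30, deg_log2fc=2.0,
                               rna_mean=300.0)
            genes, origins, _ = sim.generate_annotation(cfg)
            truth = sim.generate_truth(cfg, genes, origins)
            counts = sim.simulate_rna_counts(genes, truth, self.design(), cfg)
            condition = {c: ("G1" if "_G1_" in c else "HU45") for c in counts}
            de = naive_de(counts, condition, "G1", "HU45", lfc_threshold=1.0)
            planted_up = [g for g, v in truth.deg.items()
                          if v > 0 and g in de.index]
            errors.extend(de.loc[planted_up, "log2fc"] - 2.0)
        assert np.median(np.abs(errors)) < 0.3


def test_end_to_end_determinism_byte_identical(tmp_path):
    """Same config -> byte-identical written outputs."""
    from chipdyn import io as cio
    paths = []
    for run in ("a", "b"):
        cfg = small_config()
        genes, origins, _ = sim.generate_annotation(cfg)
        truth = sim.generate_truth(cfg, genes, origins)
        tracks = sim.simulate_chip_tracks(
            genes, origins, truth,
            [SampleDesign("WT", "G1", "IP", 1), SampleDesign("WT", "G1", "input", 1)],
            cfg)
        p = tmp_path / f"{run}.bedgraph"
        cio.write_bedgraph(tracks["WT_G1_IP_rep1"], p)
        g = tmp_path / f"{run}_genes.tsv"
        cio.write_gene_table(genes, g)
        paths.append((p.read_bytes(), g.read_bytes()))
    assert paths[0] == paths[1]
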