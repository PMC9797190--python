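"""Promoter windows, scores, empirical significance, Gini, peak annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chipdyn.exceptions import DegenerateInputError
from chipdyn.genome import BinnedTrack, GenomeLayout
from chipdyn.promoter import (annotate_peaks, empirical_promoter_p, lorenz_gini,
                              promoter_scores, promoter_window)


def gini_pairwise_oracle(values):
    """Independent oracle: relative mean absolute difference / 2."""
    x = np.asarray(values, float)
    n = x.size
    diff = np.abs(x[:, None] - x[None, :]).sum()
    return diff / (2 * n * n * x.mean())


class TestPromoterWindow:
    @pytest.mark.parametrize("strand,tss,up,down,expected", [
        ("+", 10_000, 500, 0, (9_500, 10_000)),
        ("-", 10_000, 500, 50, (9_950, 10_500)),
        ("+", 10_000, 500, 50, (9_500, 10_050)),
        ("-", 10_000, 500, 0, (10_000, 10_500)),
    ])
    def test_strand_mirroring(self, strand, tss, up, down, expected):
        layout = GenomeLayout({"chr1": 20_000})
        w = promoter_window("chr1", tss, strand, layout, up, down)
        assert (w.start, w.end) == expected and not w.clipped

    def test_edge_clip_flagged(self):
        layout = GenomeLayout({"chr1": 20_000})
        w = promoter_window("chr1", 100, "+", layout, upstream=500)
        assert (w.start, w.end) == (0, 100) and w.clipped


class TestPromoterScores:
    def test_constant_track_scores_constant(self, constant_track, toy_genes):
        s = promoter_scores(constant_track, toy_genes)
        np.testing.assert_allclose(s.to_numpy(), 1.0)

    def test_sparse_window_mean(self, tiny_layout):
        # + gene, TSS 2000: window [1500, 2000) covers bins 60..79
        data = {c: np.zeros(tiny_layout.n_bins(c)) for c in tiny_layout.chroms}
        data["chr1"][60] = 2.0
        data["chr1"][61] = 2.0
        track = BinnedTrack(tiny_layout, data, "log2fc")
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [2000], "strand": ["+"]})
        assert promoter_scores(track, genes).iloc[0] == pytest.approx(0.2)

    def test_clipped_window_width_normalized(self, constant_track):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [100], "strand": ["+"]})
        track = constant_track
        for c in track.layout.chroms:
            track.data[c][:] = 3.0
        assert promoter_scores(track, genes).iloc[0] == pytest.approx(3.0)

    def test_translation_invariance(self, tiny_layout):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=tiny_layout.n_bins("chr1"))
        data = {c: np.zeros(tiny_layout.n_bins(c)) for c in tiny_layout.chroms}
        data["chr1"] = vals
        track = BinnedTrack(tiny_layout, data, "log2fc")
        shift_bins = 40
        shifted = {c: v.copy() for c, v in data.items()}
        shifted["chr1"] = np.roll(vals, shift_bins)
        track2 = BinnedTrack(tiny_layout, shifted, "log2fc")
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [2000], "strand": ["+"]})
        moved = genes.assign(tss=genes["tss"] + shift_bins * 25)
        assert promoter_scores(track, genes).iloc[0] == \
            pytest.approx(promoter_scores(track2, moved).iloc[0])


class TestEmpiricalP:
    def test_p_bounds(self, tiny_layout):
        # strong spike at one promoter -> p = 1/(1+n_null)
        data = {c: np.zeros(tiny_layout.n_bins(c)) for c in tiny_layout.chroms}
        data["chr1"][60:80] = 100.0
        track = BinnedTrack(tiny_layout, data, "log2fc")
        genes = pd.DataFrame({"gene_id": ["hot", "cold"], "chrom": ["chr1"] * 2,
                              "tss": [2000, 6000], "strand": ["+", "+"]})
        p, n_sig = empirical_promoter_p(track, genes, n_null=999, seed=1)
        assert p["hot"] == pytest.approx(1 / 1000)
        # a window at the global minimum can never beat the null
        assert p["cold"] == pytest.approx(1.0, abs=0.05)
        assert n_sig >= 1

    def test_determinism_in_seed(self, constant_track, toy_genes):
        p1, _ = empirical_promoter_p(constant_track, toy_genes, n_null=200, seed=9)
        p2, _ = empirical_promoter_p(constant_track, toy_genes, n_null=200, seed=9)
        pd.testing.assert_series_equal(p1, p2)

    def test_small_n_null_rejected(self, constant_track, toy_genes):
        with pytest.raises(ValueError):
            empirical_promoter_p(constant_track, toy_genes, n_null=10, seed=0)


class TestLorenzGini:
    @pytest.mark.parametrize("values,expected", [
        ([5, 5, 5, 5], 0.0),
        ([0, 0, 0, 1], 0.75),
        ([1, 1, 2], 1 / 6),
    ])
    def test_known_values_match_pairwise_oracle(self, values, expected):
        res = lorenz_gini(values)
        assert res.gini == pytest.approx(expected)
        assert res.gini == pytest.approx(gini_pairwise_oracle(values))

    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                    min_size=2, max_size=60).filter(lambda v: sum(v) > 0))
    def test_oracle_equivalence_and_bounds(self, values):
        res = lorenz_gini(values)
        n = len(values)
        assert res.gini == pytest.approx(gini_pairwise_oracle(values), abs=1e-9)
        assert -1e-12 <= res.gini <= (n - 1) / n + 1e-12

    @given(st.lists(st.floats(min_value=0.0, max_value=100, allow_nan=False),
                    min_size=2, max_size=30).filter(lambda v: sum(v) > 0),
           st.floats(min_value=0.01, max_value=50))
    def test_scale_invariance(self, values, k):
        assert lorenz_gini(values).gini == \
            pytest.approx(lorenz_gini([v * k for v in values]).gini, abs=1e-9)

    def test_lorenz_curve_monotone_convex(self):
        res = lorenz_gini([3, 1, 4, 1, 5, 9, 2, 6])
        y = res.curve[:, 1]
        assert np.all(np.diff(y) >= 0)
        assert np.all(np.diff(y, 2) >= -1e-12)  # convex for sorted input
        assert res.curve[0, 1] == 0.0 and res.curve[-1, 1] == pytest.approx(1.0)

    def test_concentration_increases_gini(self):
        broad = lorenz_gini(np.full(100, 1.0) + np.linspace(0, 0.5, 100)).gini
        concentrated = lorenz_gini(np.r_[np.full(95, 0.05), np.full(5, 20.0)]).gini
        assert concentrated > broad + 0.3

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            lorenz_gini([0.0, 0.0])


class TestAnnotatePeaks:
    def test_categories_and_fraction(self, tiny_layout, toy_genes):
        peaks = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [1600, 9000, 2600],
            "end": [1700, 9100, 2700],
            "name": ["p1", "p2", "p3"],
        })
        # p1 hits gA promoter [1500, 2050); p3 hits gC promoter [2500, 3050)
        annotated, frac = annotate_peaks(peaks, toy_genes, tiny_layout)
        assert annotated["category"].tolist() == ["promoter", "other", "promoter"]
        assert frac == pytest.approx(2 / 3)

    def test_promoter_precedence_over_gene_body(self, tiny_layout, toy_genes):
        # spans both gA's promoter and its gene body
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [1900], "end": [2500],
                              "name": ["p"]})
        annotated, _ = annotate_peaks(peaks, toy_genes, tiny_layout)
        assert annotated["category"].iloc[0] == "promoter"

    def test_gene_body_category(self, tiny_layout, toy_genes):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [2800], "end": [2900],
                              "name": ["p"]})
        annotated, _ = annotate_peaks(peaks, toy_genes, tiny_layout)
        assert annotated["category"].iloc[0] == "gene body"

    def test_empty_peaks_rejected(self, tiny_layout, toy_genes):
        with pytest.raises(DegenerateInputError):
            annotate_peaks(pd.DataFrame(columns=["chrom", "start", "end"]),
                           toy_genes, tiny_layout)
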