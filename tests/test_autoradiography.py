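"""Halo geometry, conversion regression, histograms, and paired tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from piezolab.autoradiography import (
    ConversionFit,
    bin_width,
    build_histogram,
    cell_uptake,
    fit_conversion,
    halo_volume,
    highly_active_fraction,
    paired_histograms,
    taxon_paired_test,
    uptake_from_area,
)
from piezolab.synthetic import SyntheticConfig, gen_paired_community


class TestHaloVolume:
    def test_unit_radius(self):
        assert halo_volume(math.pi, "hemisphere") == pytest.approx(2 * math.pi / 3)
        assert halo_volume(math.pi, "sphere") == pytest.approx(4 * math.pi / 3)

    def test_zero_and_negative(self):
        assert halo_volume(0.0) == 0.0
        with pytest.raises(ValueError):
            halo_volume(-1.0)
        with pytest.raises(ValueError):
            halo_volume(1.0, "cube")


class TestConversionFit:
    def test_single_pair_reproduces_published_slope(self):
        fit = fit_conversion([(1.0, 9.72e7)])
        assert fit.slope == pytest.approx(9.72e7)

    def test_noiseless_line_exact(self):
        x = np.array([0.05, 0.1, 0.2, 0.4])
        fit = fit_conversion(list(zip(x, 9.72e7 * x)))
        assert fit.slope == pytest.approx(9.72e7, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_conversion([(0.0, 1.0), (0.0, 2.0)])


class TestCellUptake:
    FIT = ConversionFit(slope=9.72e7, r2=1.0, n=1)

    def test_hand_computed_value(self):
        # 40.5 µm³ over 10 h at the published slope → 1.00 amol cell⁻¹ d⁻¹
        assert cell_uptake(40.5, 10.0, self.FIT) == pytest.approx(1.00, abs=5e-3)

    def test_zero_volume(self):
        assert cell_uptake(0.0, 10.0, self.FIT) == 0.0

    @given(v=st.floats(0.1, 1e3), scale=st.floats(1.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_scaling(self, v, scale):
        base = cell_uptake(v, 10.0, self.FIT)
        assert cell_uptake(scale * v, 10.0, self.FIT) == pytest.approx(scale * base, rel=1e-9)
        assert cell_uptake(v, scale * 10.0, self.FIT) == pytest.approx(base / scale, rel=1e-9)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            cell_uptake(1.0, 0.0, self.FIT)

    def test_geometry_constant_cancels(self):
        """Refit with sphere instead of hemisphere → identical uptakes."""
        rng = np.random.default_rng(9)
        areas = rng.uniform(1.0, 50.0, 20)
        bulk = rng.uniform(0.05, 0.5, 10)
        for_conv = rng.uniform(1.0, 50.0, 10)
        uptakes = {}
        for geom in ("hemisphere", "sphere"):
            pairs = [(b, sum(halo_volume(a, geom) for a in for_conv) * b) for b in bulk]
            fit = fit_conversion(pairs)
            uptakes[geom] = [uptake_from_area(a, 10.0, fit, geom) for a in areas]
        assert uptakes["hemisphere"] == pytest.approx(uptakes["sphere"], rel=1e-9)

    def test_zero_noise_roundtrip_recovers_latent_uptake(self):
        cfg = SyntheticConfig(seed=1, n_active_cells=200, halo_noise_cv=0.0)
        cells, truth = gen_paired_community(cfg, 1)
        fit = ConversionFit(slope=cfg.conversion_slope, r2=1.0, n=1)
        lookup = dict(zip(truth.pool_index, truth.u_insitu_amol_d))
        insitu = cells[cells.condition == "in_situ"].reset_index(drop=True)
        recovered = [
            uptake_from_area(a, d, fit, cfg.geometry)
            for a, d in zip(insitu.halo_area_um2, insitu.duration_h)
        ]
        sampled = truth[truth.sampled_insitu].u_insitu_amol_d.to_numpy()
        assert np.sort(recovered) == pytest.approx(np.sort(sampled), rel=1e-9)


class TestHistogram:
    def test_all_equal_single_occupied_bin(self):
        h = build_histogram([0.25] * 7)
        assert h.counts.sum() == 7
        assert (h.counts > 0).sum() == 1

    def test_edge_value_falls_in_right_bin(self):
        # log10(u) exactly on an edge: anchor at -1.02 with h=0.17 → edge at -0.85
        h = build_histogram([10**-0.9, 10**-0.85], width=0.17)
        assert h.counts.tolist() == [1, 1]

    def test_counts_conserved_on_shared_grid(self):
        rng = np.random.default_rng(4)
        a, b = 10 ** rng.normal(-1.3, 0.5, 500), 10 ** rng.normal(-0.5, 0.5, 300)
        ha, hb = paired_histograms(a, b)
        assert ha.n_active == 500 and hb.n_active == 300
        assert ha.counts.sum() == 500 and hb.counts.sum() == 300
        assert np.allclose(ha.edges, hb.edges)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_histogram([])
        with pytest.raises(ValueError):
            build_histogram([0.1, -0.2])
        with pytest.raises(ValueError):
            build_histogram([0.1], width=0.0)


class TestBinWidth:
    def test_fixed_default(self):
        assert bin_width([1, 2, 3], method="fixed") == 0.17

    def test_scott_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 4000)
        expected = 3.49 * np.std(x, ddof=1) * 4000 ** (-1 / 3)
        assert bin_width(x, "scott") == pytest.approx(expected)

    def test_freedman_diaconis_closed_form(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 1000)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        assert bin_width(x, "freedman_diaconis") == pytest.approx(2 * iqr * 1000 ** (-1 / 3))

    def test_shimazaki_approaches_gaussian_optimum(self):
        """Cost-minimizing width converges to the MISE-optimal Gaussian width
        (Scott's 3.49·σ·n^(−1/3)) for a large normal sample."""
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20000)
        h = bin_width(x, "shimazaki")
        scott = bin_width(x, "scott")
        assert 0.5 * scott < h < 2.0 * scott

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            bin_width([1.0], "scott")


class TestHighlyActive:
    def test_strict_threshold(self):
        count, frac = highly_active_fraction([0.4, 0.5, 0.6])
        assert count == 1 and frac == pytest.approx(1 / 3)

    def test_all_below(self):
        assert highly_active_fraction([0.1, 0.2])[0] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            highly_active_fraction([])


class TestTaxonPairedTest:
    def test_degenerate_identical_pairs(self):
        res = taxon_paired_test([1, 2, 3, 4], [1, 2, 3, 4], taxon="SAR202")
        assert res.degenerate and res.test_used == "degenerate"
        assert math.isnan(res.p_value)

    def test_normal_shift_selects_paired_t(self):
        rng = np.random.default_rng(8)
        x = rng.normal(1.0, 0.2, 18)
        res = taxon_paired_test(x, x + 0.5 + rng.normal(0, 0.2, 18), taxon="Bacteroidetes",
                                sidedness="greater")
        assert res.test_used == "paired_t"
        assert res.p_value < 0.01

    def test_heavy_tailed_shift_selects_wilcoxon(self):
        rng = np.random.default_rng(12)
        x = rng.normal(1.0, 0.1, 20)
        diffs = rng.standard_cauchy(20) * 0.05 + 0.3
        res = taxon_paired_test(x, x + diffs, taxon="SAR406")
        assert res.test_used == "wilcoxon_signed_rank"

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            taxon_paired_test([1, 2], [2, 3])
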