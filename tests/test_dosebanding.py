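"""Dose-band tables, band assignment, and the reclassification Monte Carlo."""

import numpy as np
import pytest

from ibsa.dosebanding import (
    DoseBandTable,
    SimulationConfig,
    analytic_reclassification,
    assign_band,
    bundled_table_path,
    default_band_table,
    dose_delta_summary,
    load_band_table,
    simulate_reclassification,
)
from ibsa.errors import InvalidBandTableError


def _random_table(rng, n_bands):
    edges = np.sort(rng.uniform(1.0, 2.8, n_bands + 1))
    while np.any(np.diff(edges) < 0.05):
        edges = np.sort(rng.uniform(1.0, 2.8, n_bands + 1))
    return DoseBandTable(edges[:-1], edges[1:],
                         1000.0 + 150.0 * np.arange(n_bands))


class TestTable:
    def test_bundled_table_loads(self):
        t = load_band_table(bundled_table_path())
        assert t.n_bands == 8
        assert (t.bsa_min, t.bsa_max) == (1.2, 2.5)
        d = default_band_table()
        np.testing.assert_allclose(t.lows, d.lows, atol=1e-9)
        np.testing.assert_allclose(t.doses_mg, d.doses_mg)

    def test_gap_rejected(self):
        with pytest.raises(InvalidBandTableError):
            DoseBandTable([1.2, 1.51], [1.5, 1.8], [100, 200])

    def test_descending_doses_rejected(self):
        with pytest.raises(InvalidBandTableError):
            DoseBandTable([1.2, 1.5], [1.5, 1.8], [200, 100])

    def test_single_band_valid(self):
        t = DoseBandTable([1.2], [2.5], [1000])
        assert t.n_bands == 1


class TestAssignBand:
    def test_interior_boundary_goes_to_upper_band(self):
        t = default_band_table()
        b = float(t.lows[3])
        assert assign_band(t, b) == 3
        assert assign_band(t, b - 1e-9) == 2

    def test_clamping(self):
        t = default_band_table()
        assert assign_band(t, 0.9) == 0
        assert assign_band(t, 2.5) == t.n_bands - 1
        assert assign_band(t, 3.5) == t.n_bands - 1

    def test_occupancy_matches_bruteforce(self):
        t = default_band_table()
        grid = np.linspace(1.2, 2.5, 1000, endpoint=False)
        vec = np.bincount(assign_band(t, grid), minlength=t.n_bands)
        brute = np.zeros(t.n_bands, int)
        for v in grid:  # brute-force scan over bands
            for k in range(t.n_bands):
                if t.lows[k] <= v < t.highs[k] or (k == t.n_bands - 1
                                                   and v >= t.highs[k]):
                    brute[k] += 1
                    break
        assert np.array_equal(vec, brute)
        widths = t.highs - t.lows
        expected = 1000 * widths / widths.sum()
        assert np.all(np.abs(vec - expected) <= 1.0)


class TestSimulation:
    def test_zero_sigma_zero_rate(self):
        r = simulate_reclassification(SimulationConfig(n_samples=10_000,
                                                       sigma_pct=0.0))
        assert r.reclassification_rate == 0.0

    def test_single_band_always_zero(self):
        t = DoseBandTable([1.2], [2.5], [1000])
        r = simulate_reclassification(SimulationConfig(n_samples=10_000,
                                                       sigma_pct=8.0), t)
        assert r.reclassification_rate == 0.0

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_samples=50_000, seed=11)
        a = simulate_reclassification(cfg)
        b = simulate_reclassification(cfg)
        assert a.reclassification_rate == b.reclassification_rate
        assert a.shift_histogram == b.shift_histogram

    def test_histogram_sums_to_one(self):
        r = simulate_reclassification(SimulationConfig(n_samples=100_000))
        assert sum(r.shift_histogram.values()) == pytest.approx(1.0, abs=1e-12)
        assert r.reclassification_rate == pytest.approx(
            1.0 - r.shift_histogram[0], abs=1e-12)
        assert r.mc_standard_error == pytest.approx(
            np.sqrt(r.reclassification_rate * (1 - r.reclassification_rate)
                    / 100_000))

    def test_rate_monotone_in_sigma_common_seed(self):
        rates = [simulate_reclassification(
            SimulationConfig(n_samples=200_000, sigma_pct=s, seed=5)
        ).reclassification_rate for s in (1, 2, 3, 4, 5)]
        assert rates == sorted(rates)

    def test_two_band_shift_fraction_reported(self):
        r = simulate_reclassification(SimulationConfig(n_samples=500_000))
        two_plus = sum(v for k, v in r.shift_histogram.items() if k >= 2)
        assert 0.0 < two_plus < 0.05
        d = dose_delta_summary(default_band_table(), r)
        assert d["two_band_shift_fraction"] == pytest.approx(two_plus)

    def test_large_sigma_approaches_occupancy_limit(self):
        """As σ→∞ the perturbed value clamps to the outer bands; the rate
        tends to the probability of leaving your own band entirely."""
        r8 = simulate_reclassification(
            SimulationConfig(n_samples=200_000, sigma_pct=500.0))
        assert r8.reclassification_rate > 0.5


class TestAnalyticOracle:
    def test_zero_sigma(self):
        assert analytic_reclassification(default_band_table(), 0.0) == 0.0

    def test_matches_monte_carlo_default_table(self):
        cfgs = [SimulationConfig(n_samples=400_000, seed=s) for s in range(10)]
        rates = [simulate_reclassification(c).reclassification_rate
                 for c in cfgs]
        mc = float(np.mean(rates))
        se = float(np.std(rates, ddof=1) / np.sqrt(len(rates)))
        analytic = analytic_reclassification(default_band_table(), 4.11)
        assert abs(mc - analytic) < 3 * max(se, 1e-4)

    def test_two_equal_bands_small_sigma(self):
        """Only the midpoint boundary matters; cross-checked against a large
        Monte Carlo."""
        t = DoseBandTable([1.2, 1.85], [1.85, 2.5], [1000, 1150])
        analytic = analytic_reclassification(t, 2.0)
        r = simulate_reclassification(
            SimulationConfig(n_samples=2_000_000, sigma_pct=2.0, seed=3), t)
        assert abs(r.reclassification_rate - analytic) < 3 * r.mc_standard_error


class TestDoseSummary:
    def test_default_table(self):
        d = dose_delta_summary(default_band_table())
        assert d["step_mg"] == 150.0
        assert d["range_mg"] == 1050.0
        assert d["step_over_range_pct"] == pytest.approx(100 * 150 / 1050)
        assert d["step_over_range_pct"] > 10.0

    def test_two_band_ratio(self):
        t = DoseBandTable([1.2, 1.85], [1.85, 2.5], [1000, 1150])
        d = dose_delta_summary(t)
        assert (d["step_mg"], d["range_mg"]) == (150.0, 150.0)
        assert d["step_over_range_pct"] == pytest.approx(100.0)

    def test_equal_doses_rejected(self):
        t = DoseBandTable([1.2, 1.85], [1.85, 2.5], [1000, 1000])
        with pytest.raises(InvalidBandTableError):
            dose_delta_summary(t)

    def test_single_band_rejected(self):
        with pytest.raises(InvalidBandTableError):
            dose_delta_summary(DoseBandTable([1.2], [2.5], [1000]))


def test_random_tables_oracle_agreement(rng):
    for n_bands in (3, 5, 8):
        t = _random_table(rng, n_bands)
        cfg = SimulationConfig(n_samples=300_000, sigma_pct=4.11, seed=17,
                               bsa_min=t.bsa_min, bsa_max=t.bsa_max)
        r = simulate_reclassification(cfg, t)
        a = analytic_reclassification(t, 4.11, t.bsa_min, t.bsa_max)
        assert abs(r.reclassification_rate - a) < 3 * r.mc_standard_error
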