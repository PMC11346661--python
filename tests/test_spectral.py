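"""Spectral index, interpolation and correlogram-scan tests."""

import numpy as np
import pandas as pd
import pytest

from ripescan import Spectrum, compute_sri_catalog, correlogram_scan, reflectance_at, rsi, top_pairs
from ripescan.spectral import RSI_CATALOG_PAIRS


def tiny_spectrum(values, start=600, step=2):
    wl = np.arange(start, start + step * len(values), step, dtype=float)
    return Spectrum(wl, np.asarray(values, dtype=float))


class TestReflectanceLookup:
    def test_exact_grid_hit(self):
        sp = tiny_spectrum([0.10, 0.12, 0.14], start=660)
        assert reflectance_at(sp, 660) == 0.10

    def test_midpoint_interpolation(self):
        sp = tiny_spectrum([0.10, 0.12], start=676)
        assert reflectance_at(sp, 677) == pytest.approx(0.11)

    def test_out_of_range_rejected(self):
        sp = tiny_spectrum([0.1, 0.2], start=302)
        with pytest.raises(ValueError, match="outside spectral coverage"):
            reflectance_at(sp, 301)

    def test_nearest_mode(self):
        sp = tiny_spectrum([0.10, 0.30], start=660)
        assert reflectance_at(sp, 660.4, mode="nearest") == 0.10
        assert reflectance_at(sp, 661.6, mode="nearest") == 0.30

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([660.0, 660.0]), np.array([0.1, 0.2]))


class TestRatioIndex:
    def test_identity_and_direct_division(self, flat_spectrum):
        assert rsi(flat_spectrum, 700, 700) == 1.0
        wl = np.array([660.0, 780.0])
        sp = Spectrum(wl, np.array([0.1, 0.5]))
        assert rsi(sp, 780, 660) == pytest.approx(5.0)

    def test_reciprocal_pair(self, flat_spectrum):
        sp = flat_spectrum
        assert rsi(sp, 730, 650) * rsi(sp, 650, 730) == pytest.approx(1.0)

    def test_nonpositive_denominator_is_nan(self):
        sp = Spectrum(np.array([650.0, 730.0]), np.array([0.0, 0.5]))
        # construction clamps nothing here; zero denominators yield NaN
        assert np.isnan(rsi(sp, 730, 650))


class TestCatalog:
    def test_flat_limit(self, flat_spectrum):
        out = compute_sri_catalog(flat_spectrum)
        for lam1, lam2 in RSI_CATALOG_PAIRS:
            assert out[f"RSI_{lam1},{lam2}"] == pytest.approx(1.0)
        assert out["NDVI"] == pytest.approx(0.0)
        assert out["NAI"] == pytest.approx(0.0)
        assert out["PRMI"] == pytest.approx(0.0)
        assert out["GI"] == pytest.approx(1.0)

    def test_ndvi_hand_value(self):
        wl = np.arange(302.0, 1150.0, 2.0)
        refl = np.full(wl.size, 0.1)
        refl[wl >= 720] = 0.5
        out = compute_sri_catalog(Spectrum(wl, refl))
        # (0.5 - 0.1) / (0.5 + 0.1)
        assert out["NDVI"] == pytest.approx(0.6667, abs=1e-4)

    def test_normalized_difference_bounded(self, mandarin_cohort):
        traits, spectra, _ = mandarin_cohort
        wl = np.asarray([float(c) for c in spectra.columns])
        for i in range(0, len(spectra), 17):
            out = compute_sri_catalog(Spectrum(wl, spectra.iloc[i].to_numpy()))
            for name in ("NDVI", "NAI"):
                assert -1 <= out[name] <= 1

    def test_unripe_vs_overripe_red_edge_ratio(self, mandarin_cohort):
        traits, spectra, _ = mandarin_cohort
        from ripescan import sri_table

        cat = sri_table(spectra)
        by_stage = cat["RSI_730,650"].groupby(traits["stage"]).mean()
        assert by_stage["unripe"] > by_stage["overripe"]


class TestCorrelogramScan:
    def test_perfect_linear_fit_entry(self, rng):
        wl = np.arange(560.0, 760.0, 20.0)
        n = 12
        refl = rng.uniform(0.2, 0.8, (n, wl.size))
        spectra = pd.DataFrame(refl, columns=wl)
        i1, i2 = int(np.where(wl == 700)[0][0]), int(np.where(wl == 600)[0][0])
        trait = pd.Series(refl[:, i1] / refl[:, i2], name="t")
        res = correlogram_scan(spectra, trait)
        assert res.r2_grid[i1, i2] == pytest.approx(1.0)
        assert top_pairs(res, 1)[0][:2] == (700.0, 600.0)

    def test_matches_per_pair_ols_oracle(self, rng):
        wl = np.arange(400.0, 400.0 + 2 * 20, 2.0)
        n = 10
        refl = rng.uniform(0.1, 1.0, (n, wl.size))
        spectra = pd.DataFrame(refl, columns=wl)
        trait = pd.Series(rng.normal(size=n), name="y")
        res = correlogram_scan(spectra, trait)
        y = trait.to_numpy()
        for i in range(len(wl)):
            for j in range(len(wl)):
                if i == j:
                    assert np.isnan(res.r2_grid[i, j])
                    continue
                x = refl[:, i] / refl[:, j]
                # naive OLS: R2 = 1 - SSres/SStot from an explicit fit
                slope, intercept = np.polyfit(x, y, 1)
                ssres = np.sum((y - slope * x - intercept) ** 2)
                sstot = np.sum((y - y.mean()) ** 2)
                assert res.r2_grid[i, j] == pytest.approx(1 - ssres / sstot, abs=1e-10)

    def test_grid_is_not_symmetrized(self, rng):
        wl = np.array([500.0, 600.0, 700.0])
        refl = rng.uniform(0.1, 1.0, (15, 3))
        spectra = pd.DataFrame(refl, columns=wl)
        trait = pd.Series(refl[:, 2] / refl[:, 0] + rng.normal(0, 0.3, 15), name="y")
        res = correlogram_scan(spectra, trait)
        assert res.r2_grid[2, 0] != pytest.approx(res.r2_grid[0, 2], abs=1e-6)

    def test_r2_invariant_to_trait_rescaling(self, rng):
        wl = np.arange(500.0, 540.0, 2.0)
        refl = rng.uniform(0.1, 1.0, (12, wl.size))
        spectra = pd.DataFrame(refl, columns=wl)
        trait = pd.Series(rng.normal(size=12), name="y")
        a = correlogram_scan(spectra, trait)
        b = correlogram_scan(spectra, trait * 10 + 3)
        np.testing.assert_allclose(a.r2_grid, b.r2_grid, atol=1e-12)

    def test_grid_values_in_unit_interval(self, mandarin_cohort):
        traits, spectra, _ = mandarin_cohort
        res = correlogram_scan(spectra, traits["TSS"], lambda_step=32)
        finite = res.r2_grid[np.isfinite(res.r2_grid)]
        assert finite.size > 0
        assert np.all((finite >= 0) & (finite <= 1 + 1e-12))

    def test_constant_trait_rejected(self, rng):
        spectra = pd.DataFrame(rng.uniform(0.1, 1, (5, 4)), columns=[500.0, 502.0, 504.0, 506.0])
        with pytest.raises(ValueError, match="constant"):
            correlogram_scan(spectra, pd.Series(np.ones(5), name="c"))

    def test_bad_lambda_step_rejected(self, rng):
        spectra = pd.DataFrame(rng.uniform(0.1, 1, (5, 4)), columns=[500.0, 502.0, 504.0, 506.0])
        with pytest.raises(ValueError, match="multiple"):
            correlogram_scan(spectra, pd.Series(rng.normal(size=5), name="y"), lambda_step=3)


class TestTopPairs:
    def test_single_finite_entry(self):
        from ripescan.spectral import CorrelogramResult

        grid = np.full((3, 3), np.nan)
        grid[0, 1] = 0.5
        res = CorrelogramResult("t", np.array([500.0, 502.0, 504.0]), grid, 5)
        assert top_pairs(res, 3) == [(500.0, 502.0, 0.5)]

    def test_matches_sort_oracle(self, rng):
        from ripescan.spectral import CorrelogramResult

        wl = np.arange(500.0, 520.0, 2.0)
        grid = rng.uniform(0, 1, (10, 10))
        np.fill_diagonal(grid, np.nan)
        res = CorrelogramResult("t", wl, grid, 8)
        got = top_pairs(res, 5)
        entries = [
            (wl[i], wl[j], grid[i, j])
            for i in range(10) for j in range(10) if i != j
        ]
        entries.sort(key=lambda e: (-e[2], abs(e[0] - e[1]), e[0], e[1]))
        assert got == entries[:5]

    def test_tie_break_prefers_close_bands(self):
        from ripescan.spectral import CorrelogramResult

        wl = np.array([500.0, 510.0, 540.0])
        grid = np.full((3, 3), np.nan)
        grid[0, 2] = 0.9  # |500-540| = 40
        grid[0, 1] = 0.9  # |500-510| = 10 -> wins the tie
        res = CorrelogramResult("t", wl, grid, 5)
        assert top_pairs(res, 1)[0][:2] == (500.0, 510.0)
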