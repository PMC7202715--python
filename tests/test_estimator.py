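"""Multi-distance EAC estimator: selection, neighbourhoods, slope fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eacmap as em
from eacmap.eac_estimator import distance_stratified_eac, eac_channel_map, neighborhood
from eacmap.errors import EmptySelectionError, UnderdeterminedFitError
from tests.conftest import make_snr_table


def normal_equations_slope(r, y):
    """Independent brute-force OLS through the normal equations."""
    X = np.column_stack([np.ones(len(r)), r])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]


def snr_from_montage(montage, mu_eff_fn, amplitude=1e6):
    """Noise-free SNR table: SNR^2 equals the expected counts (shot-noise law)."""
    ch = montage.channels
    r = ch["distance_mm"].to_numpy()
    mids = ch[["mid_x_mm", "mid_y_mm", "mid_z_mm"]].to_numpy()
    wl = ch["wavelength_nm"].to_numpy()
    mu = np.array([mu_eff_fn(m, w) for m, w in zip(mids, wl)])
    counts = em.forward_intensity(mu, r, amplitude) * montage.channel_gains()
    df = ch[["channel_id", "wavelength_nm", "distance_mm",
             "mid_x_mm", "mid_y_mm", "mid_z_mm"]].copy()
    df["snr"] = np.sqrt(counts)
    df["y"] = np.log(counts * r**2)
    df["low_light"] = False
    df["motion"] = False
    df["rejected"] = False
    return df


class TestSelectChannels:
    def test_boundaries_inclusive(self):
        t = make_snr_table([15.0, 20.0, 35.0, 50.0, 55.0])
        out = em.select_channels(t, 20.0, 50.0)
        assert sorted(out["distance_mm"]) == [20.0, 35.0, 50.0]

    def test_all_flagged_empty_selection(self):
        t = make_snr_table([25.0, 30.0, 35.0])
        t["rejected"] = True
        with pytest.raises(EmptySelectionError):
            em.select_channels(t, 20.0, 50.0)

    def test_matches_brute_force_filter(self, small_montage):
        t = snr_from_montage(small_montage, lambda m, w: 0.2)
        out = em.select_channels(t, 20.0, 50.0)
        r = t["distance_mm"].to_numpy()
        assert len(out) == int(((r >= 20.0) & (r <= 50.0)).sum())


class TestNeighborhood:
    def test_radius_zero_is_singleton(self, small_montage):
        t = snr_from_montage(small_montage, lambda m, w: 0.2)
        nb = neighborhood(t.iloc[0], t, radius_mm=0.0)
        assert list(nb["channel_id"]) == [t["channel_id"].iloc[0]]

    def test_huge_radius_is_all_same_wavelength(self, small_montage):
        t = snr_from_montage(small_montage, lambda m, w: 0.2)
        target = t.iloc[0]
        nb = neighborhood(target, t, radius_mm=1e4)
        expect = (t["wavelength_nm"] == target["wavelength_nm"]).sum()
        assert len(nb) == expect

    def test_matches_exhaustive_distance_computation(self, small_montage):
        t = snr_from_montage(small_montage, lambda m, w: 0.2)
        target = t.iloc[5]
        nb = neighborhood(target, t, radius_mm=30.0)
        mids = t[["mid_x_mm", "mid_y_mm", "mid_z_mm"]].to_numpy()
        tm = mids[5]
        expected = {
            t["channel_id"].iloc[i]
            for i in range(len(t))
            if t["wavelength_nm"].iloc[i] == target["wavelength_nm"]
            and np.linalg.norm(mids[i] - tm) <= 30.0 + 1e-12
        }
        assert set(nb["channel_id"]) == expected


class TestFitEAC:
    def test_exact_synthetic_line(self):
        r = np.array([20.0, 30.0, 40.0, 50.0])
        t = make_snr_table(r, y=10.0 - 0.19 * r)
        fit = em.fit_eac(t, min_channels=4)
        assert fit.mu_eff == pytest.approx(0.19, abs=1e-12)
        assert fit.k == pytest.approx(10.0, abs=1e-12)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-12)

    def test_underdetermined_distance_spread(self):
        t = make_snr_table([30.0] * 6, y=np.arange(6.0))
        with pytest.raises(UnderdeterminedFitError):
            em.fit_eac(t)

    def test_too_few_samples(self):
        t = make_snr_table([20.0, 50.0])
        with pytest.raises(UnderdeterminedFitError):
            em.fit_eac(t)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        r = rng.uniform(20.0, 50.0, n)
        r[0], r[1] = 20.0, 49.0  # guarantee span
        y = rng.normal(5.0 - 0.2 * r, 0.3)
        fit = em.fit_eac(make_snr_table(r, y=y))
        slope, intercept = normal_equations_slope(r, y)
        assert fit.mu_eff == pytest.approx(-slope, abs=1e-10)
        assert fit.k == pytest.approx(intercept, abs=1e-10)

    def test_gain_invariance(self, small_montage):
        """Gains are distance-independent: a common rescaling shifts k exactly
        by the log gain product and leaves mu_eff untouched; boosting a single
        optode only adds intercept-like noise."""
        base = snr_from_montage(small_montage, lambda m, w: 0.19)
        f0 = em.global_eac(base)[830.0]
        assert f0.mu_eff == pytest.approx(0.19, abs=1e-9)

        scaled = small_montage.with_gains(np.full(len(small_montage.optodes), 7.0))
        f_scaled = em.global_eac(snr_from_montage(scaled, lambda m, w: 0.19))[830.0]
        assert f_scaled.mu_eff == pytest.approx(f0.mu_eff, abs=1e-12)
        assert f_scaled.k - f0.k == pytest.approx(np.log(49.0), abs=1e-9)

        gains = np.ones(len(small_montage.optodes))
        gains[::5] = 10.0
        pert = small_montage.with_gains(gains)
        f1 = em.global_eac(snr_from_montage(pert, lambda m, w: 0.19))[830.0]
        assert f1.mu_eff == pytest.approx(0.19, abs=0.02)


class TestGlobalAndMaps:
    def test_noise_free_recovery_to_1e9(self, small_montage):
        truth = {690.0: 0.21, 830.0: 0.18}
        t = snr_from_montage(small_montage, lambda m, w: truth[w])
        fits = em.global_eac(t)
        for wl, fit in fits.items():
            assert fit.mu_eff == pytest.approx(truth[wl], abs=1e-9)

    def test_channel_map_homogeneous_noise_free(self, dense_montage):
        t = snr_from_montage(dense_montage, lambda m, w: 0.2)
        cmap = eac_channel_map(t, radius_mm=30.0)
        good = cmap[cmap["reason"] == ""]
        assert len(good) > 0.8 * len(cmap)
        np.testing.assert_allclose(good["mu_eff"], 0.2, atol=1e-9)

    def test_channel_map_huge_radius_equals_global(self, dense_montage):
        t = snr_from_montage(dense_montage, lambda m, w: 0.2)
        fits = em.global_eac(t)
        cmap = eac_channel_map(t, radius_mm=1e4)
        for wl in (690.0, 830.0):
            vals = cmap.loc[cmap["wavelength_nm"] == wl, "mu_eff"]
            np.testing.assert_allclose(vals, fits[wl].mu_eff, atol=1e-12)

    def test_two_region_contrast_recovered(self, dense_montage):
        """Left/right hemispheres with different true mu_eff: the map recovers
        the contrast with the correct sign and ~magnitude."""
        def mu_fn(mid, wl):
            return 0.22 if mid[1] > 0 else 0.18

        t = snr_from_montage(dense_montage, mu_fn)
        cmap = eac_channel_map(t, radius_mm=25.0)
        good = cmap[cmap["reason"] == ""]
        left = good[good["mid_y_mm"] > 15]["mu_eff"].mean()
        right = good[good["mid_y_mm"] < -15]["mu_eff"].mean()
        assert left - right == pytest.approx(0.04, rel=0.10)

    def test_monotone_in_absorption(self, small_montage):
        mus = []
        for mua in (0.010, 0.014, 0.020):
            mu = em.mu_eff_from_coefficients(mua, 0.8)
            t = snr_from_montage(small_montage, lambda m, w: mu)
            mus.append(em.global_eac(t)[830.0].mu_eff)
        assert mus[0] < mus[1] < mus[2]

    def test_subset_invariance(self, small_montage):
        t = snr_from_montage(small_montage, lambda m, w: 0.2)
        rng = np.random.default_rng(9)
        half = rng.choice(len(t), len(t) // 2, replace=False)
        fit_half = em.global_eac(t.iloc[half])[830.0]
        fit_full = em.global_eac(t)[830.0]
        assert fit_half.mu_eff == pytest.approx(fit_full.mu_eff, abs=1e-9)


class TestStratified:
    def test_homogeneous_bins_agree(self, small_montage):
        t = snr_from_montage(small_montage, lambda m, w: 0.2)
        out = distance_stratified_eac(t)
        fitted = out[out["reason"] == ""]
        assert len(fitted) >= 6
        np.testing.assert_allclose(fitted["mu_eff"], 0.2, atol=1e-9)

    def test_depth_dependent_field_recovered_per_bin(self, small_montage):
        """mu_eff as a function of channel distance (depth proxy): each bin
        recovers roughly its own value."""
        ch = small_montage.channels
        r = ch["distance_mm"].to_numpy()
        # piecewise-constant in distance, matching the default bins
        mu_of_r = np.select([r < 25, r < 35, r < 45], [0.16, 0.19, 0.22], 0.25)
        counts = em.forward_intensity(mu_of_r, r, 1e8)
        t = ch[["channel_id", "wavelength_nm", "distance_mm",
                "mid_x_mm", "mid_y_mm", "mid_z_mm"]].copy()
        t["snr"] = np.sqrt(counts)
        t["y"] = np.log(counts * r**2)
        t["low_light"] = t["motion"] = t["rejected"] = False
        out = distance_stratified_eac(t)
        out = out[(out["wavelength_nm"] == 830.0) & (out["reason"] == "")]
        expected = {(15.0, 25.0): 0.16, (25.0, 35.0): 0.19,
                    (35.0, 45.0): 0.22, (45.0, 55.0): 0.25}
        for _, row in out.iterrows():
            truth = expected[(row["d_min_mm"], row["d_max_mm"])]
            assert row["mu_eff"] == pytest.approx(truth, rel=0.10)

    def test_sparse_bin_marked_underdetermined(self):
        t = make_snr_table([21.0, 26.0, 28.0, 30.0, 32.0, 34.0], y=np.zeros(6))
        out = distance_stratified_eac(t, bins=((15.0, 25.0), (25.0, 35.0)))
        first = out[(out["d_min_mm"] == 15.0)].iloc[0]
        assert first["reason"] == "underdetermined"
        assert np.isnan(first["mu_eff"])


class TestRecoveryAtScale:
    def test_cohort_recovery_regression(self, pipeline_result):
        """Estimated global EAC regressed on truth: slope ~1, R^2 high."""
        tb = pipeline_result.table
        for wl in (690, 830):
            x = tb[f"eac_{wl}_global_truth"].to_numpy()
            y = tb[f"eac_{wl}"].to_numpy()
            slope = np.polyfit(x, y, 1)[0]
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            assert 0.95 <= slope <= 1.05
            assert r2 > 0.98
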