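"""Composite scoring, correlations, paired tests, mediation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eacmap as em
from eacmap.errors import DegenerateTestError, UndefinedCorrelationError


class TestCompositeScores:
    def test_single_standardized_test_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 30)
        df = pd.DataFrame({"t1": v})
        out = em.composite_scores(df, {"t1": "performance"}, {"t1": +1})
        z = (v - v.mean()) / np.std(v, ddof=1)
        np.testing.assert_allclose(out["performance"], z, atol=1e-12)

    def test_timed_test_orientation(self):
        """One SD faster than average on a timed test contributes +1."""
        times = np.array([30.0, 40.0, 50.0])  # SD = 10
        df = pd.DataFrame({"trail_a": times})
        out = em.composite_scores(df, {"trail_a": "performance"}, {"trail_a": -1})
        assert out["performance"].iloc[0] == pytest.approx(+1.0, abs=1e-12)
        assert out["performance"].iloc[2] == pytest.approx(-1.0, abs=1e-12)

    def test_three_subject_hand_arithmetic(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [6.0, 4.0, 2.0]})
        out = em.composite_scores(df, {"a": "d", "b": "d"}, {"a": +1, "b": +1})
        za = (df.a - 2.0) / 1.0
        zb = (df.b - 4.0) / 2.0
        np.testing.assert_allclose(out["d"], (za + zb) / 2.0, atol=1e-12)

    def test_zero_variance_test_excluded(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            out = em.composite_scores(df, {"a": "d", "flat": "d"}, {"a": 1, "flat": 1})
        za = (df.a - 2.0) / 1.0
        np.testing.assert_allclose(out["d"], za, atol=1e-12)


class TestCorrelate:
    def test_fisher_z_value(self):
        """atanh(0.85) = 1.25615 at 5 decimals (series oracle)."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        # construct exact r = 0.85 via two-variable mixing
        rng = np.random.default_rng(1)
        n = 2000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / np.std(a)
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize exactly
        b /= np.std(b)
        y = 0.85 * a + math.sqrt(1 - 0.85**2) * b
        res = em.correlate(a, y)
        assert res.r == pytest.approx(0.85, abs=1e-9)
        assert res.z == pytest.approx(1.25615, abs=1e-5)

    def test_se_of_z_is_inverse_sqrt_n_minus_3(self):
        rng = np.random.default_rng(2)
        res = em.correlate(rng.normal(0, 1, 48), rng.normal(0, 1, 48))
        assert res.se_z == pytest.approx(45 ** -0.5, abs=1e-12)
        assert res.se_z == pytest.approx(0.14907, abs=1e-5)

    def test_perfect_correlation_flagged_infinite_z(self):
        x = np.arange(10.0)
        res = em.correlate(x, 2 * x + 1)
        assert res.r == 1.0
        assert math.isinf(res.z) and res.z_infinite

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            em.correlate(np.ones(10), np.arange(10.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        res = em.correlate(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        assert res.r == pytest.approx(r_oracle, abs=1e-10)


class TestPartialCorrelate:
    def test_identity_with_independent_covariate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        z = rng.normal(0, 1, 50)
        res = em.partial_correlate(x, x, z)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_from_correlation_triplet(self):
        """r_xy=0.6, r_xz=r_yz=0.5 -> partial r = 0.35/0.75 = 0.46667."""
        rng = np.random.default_rng(4)
        n = 6000
        g = rng.standard_normal((n, 3))
        # exact orthonormalization, then mix to the target correlation matrix
        q, _ = np.linalg.qr(g - g.mean(axis=0))
        q /= q.std(axis=0, ddof=0)
        target = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.5], [0.5, 0.5, 1.0]])
        L = np.linalg.cholesky(target)
        xyz = q @ L.T
        res = em.partial_correlate(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        expected = (0.6 - 0.25) / (1 - 0.25)
        assert res.r == pytest.approx(expected, abs=1e-9)

    def test_collinear_with_covariate_rejected(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, 30)
        with pytest.raises(UndefinedCorrelationError):
            em.partial_correlate(rng.normal(0, 1, 30), 2 * z + 3, z)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_closed_form_on_gaussian_data(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(0, 1, (3, 40))
        res = em.partial_correlate(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        oracle = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert res.r == pytest.approx(oracle, abs=1e-10)


class TestPairedT:
    def test_identical_pairs_degenerate(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateTestError):
            em.paired_t(x, x)

    def test_hand_computed_five_pairs(self):
        """differences {1,2,0,1,1}: t = mean / (SD/sqrt(5))."""
        y = np.zeros(5)
        x = np.array([1.0, 2.0, 0.0, 1.0, 1.0])
        t, df, p = em.paired_t(x, y)
        d = x
        expected_t = d.mean() / (np.std(d, ddof=1) / math.sqrt(5))
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert df == 4

    def test_strong_effect_tiny_p(self):
        rng = np.random.default_rng(6)
        x = 1.0 + rng.normal(0, 1e-6, 4)
        t, df, p = em.paired_t(x, np.zeros(4))
        assert t > 1e4 and p < 1e-8


class TestMediate:
    def test_generative_chain_is_full_mediation(self):
        rng = np.random.default_rng(7)
        n = 1000
        x = rng.standard_normal(n)
        m = -0.7 * x + rng.normal(0, math.sqrt(1 - 0.49), n)
        y = 0.5 * m + rng.normal(0, 0.5, n)
        res = em.mediate(x, m, y)
        assert res.classification == "full"
        assert abs(res.sobel) > 1.96

    def test_broken_first_stage_not_assessable(self):
        rng = np.random.default_rng(8)
        n = 1000
        x = rng.standard_normal(n)
        m = rng.standard_normal(n)  # independent of x
        y = 0.5 * m + rng.normal(0, 0.5, n)
        assert em.mediate(x, m, y).classification == "not-assessable"

    def test_sobel_statistic_formula(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.standard_normal(n)
        m = 0.6 * x + rng.normal(0, 0.8, n)
        y = 0.5 * m + 0.2 * x + rng.normal(0, 0.7, n)
        res = em.mediate(x, m, y)
        expected = res.a * res.b / math.sqrt(
            res.b**2 * res.se_a**2 + res.a**2 * res.se_b**2)
        assert res.sobel == pytest.approx(expected, abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        n = 300
        x = rng.standard_normal(n)
        m = -0.6 * x + rng.normal(0, 0.8, n)
        y = 0.5 * m + rng.normal(0, 0.7, n)
        a = em.mediate(x, m, y)
        b = em.mediate(3.0 * x - 7.0, -2.0 * m + 1.0, 0.5 * y + 4.0)
        assert a.classification == b.classification
        assert abs(a.sobel) == pytest.approx(abs(b.sobel), abs=1e-9)

    def test_type_i_control_on_independent_variables(self):
        """x, m, y mutually independent: full/partial classifications rare."""
        rng = np.random.default_rng(11)
        false_hits = 0
        n_rep = 500
        for _ in range(n_rep):
            x, m, y = rng.standard_normal((3, 48))
            cls = em.mediate(x, m, y).classification
            false_hits += cls in ("full", "partial")
        assert false_hits / n_rep <= 0.07

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(50)
        with pytest.raises(np.linalg.LinAlgError):
            em.mediate(x, x, rng.standard_normal(50))


class TestBattery:
    def test_age_driven_covariate_partials_to_zero(self, latent_cohort_2000):
        """A covariate that is f(age) + noise has ~zero age-partialed
        correlation with the components."""
        tr = latent_cohort_2000.truth.copy()
        pca = em.wavelength_pca(tr[["eac_690_true", "eac_830_true"]].to_numpy())
        tr["eac1"], tr["eac2"] = pca.scores[:, 0], pca.scores[:, 1]
        rng = np.random.default_rng(13)
        tr["pure_age"] = 2.0 * tr["age"] + rng.normal(0, 10.0, len(tr))
        out = em.association_battery(tr, covariates=["pure_age"])
        row = out.iloc[0]
        assert abs(row["r_eac1_age"]) < 0.1
        assert abs(row["r_eac2_age"]) < 0.1

    def test_thickness_positive_significant(self, latent_cohort_2000):
        tr = latent_cohort_2000.truth.copy()
        pca = em.wavelength_pca(tr[["eac_690_true", "eac_830_true"]].to_numpy())
        tr["eac1"], tr["eac2"] = pca.scores[:, 0], pca.scores[:, 1]
        out = em.association_battery(tr, covariates=["thickness_mm"])
        row = out.iloc[0]
        assert row["r_eac1"] > 0 and row["sig05_eac1"]

    def test_duplicated_covariates_identical_rows(self, latent_cohort_48):
        tr = latent_cohort_48.truth.copy()
        pca = em.wavelength_pca(tr[["eac_690_true", "eac_830_true"]].to_numpy())
        tr["eac1"], tr["eac2"] = pca.scores[:, 0], pca.scores[:, 1]
        tr["crf_copy"] = tr["crf"]
        out = em.association_battery(tr, covariates=["crf", "crf_copy"])
        a = out.iloc[0].drop("variable")
        b = out.iloc[1].drop("variable")
        assert (a == b).all()
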