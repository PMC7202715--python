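"""Cohort statistics: composite scoring, (partial) correlations, paired tests
and Baron-Kenny mediation with the Sobel test.

Conventions follow the cross-sectional aging-cohort analysis this package
implements: Fisher z with standard error ``(N - 3)^(-1/2)``, two-sided
p-values from the t distribution, no multiple-comparison correction, sex
coded 1 = M / 2 = F, significance tiers at p < 0.05 and p < 0.10.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, UndefinedCorrelationError


@dataclass(frozen=True)
class AssociationResult:
    """A Pearson correlation with its Fisher-z transform and p-value."""

    r: float
    n: int
    z: float          # atanh(r); +/-inf (flagged) at |r| = 1
    se_z: float       # (n - 3)^(-1/2)
    p: float
    z_infinite: bool = False


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def correlate(x, y) -> AssociationResult:
    """Pearson r with Fisher z, SE(z) = (n-3)^(-1/2), and a t-based p-value."""
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 finite pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    infinite = abs(r) >= 1.0 - 1e-12
    if infinite:
        r = math.copysign(1.0, r)
        z = math.inf * np.sign(r)
        p = 0.0
    else:
        z = math.atanh(r)
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return AssociationResult(r=r, n=n, z=z, se_z=(n - 3) ** -0.5, p=float(p),
                             z_infinite=bool(infinite))


def _residualize(v: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlate(x, y, covariate) -> AssociationResult:
    """Correlation of x and y after regressing the covariate out of both.

    One degree of freedom is consumed by the covariate: the p-value uses
    df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[ok], y[ok], c[ok]
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 finite triplets, got {n}")
    if np.std(c) == 0:
        raise UndefinedCorrelationError("covariate has zero variance")
    rx = _residualize(x, c)
    ry = _residualize(y, c)
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)) or np.std(ry) < 1e-12 * max(1.0, np.std(y)):
        raise UndefinedCorrelationError("x or y is collinear with the covariate")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    infinite = abs(r) >= 1.0 - 1e-12
    df = n - 3
    if infinite:
        r = math.copysign(1.0, r)
        z = math.inf * np.sign(r)
        p = 0.0
    else:
        z = math.atanh(r)
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=df)
    return AssociationResult(r=r, n=n, z=z, se_z=(n - 3) ** -0.5, p=float(p),
                             z_infinite=bool(infinite))


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test on the differences; returns (t, df, p)."""
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise DegenerateTestError("zero-variance differences")
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return t, df, p


# ---------------------------------------------------------------------------
# composite cognitive scoring

def composite_scores(tests: pd.DataFrame, domain_map: dict[str, str],
                     orientation: dict[str, int]) -> pd.DataFrame:
    """Equal-weight composite domain scores from raw test scores.

    Each test column is standardized across subjects (sample SD), multiplied
    by its orientation sign (timed tests get -1 so that positive always means
    better than average), and oriented z-scores are averaged within a domain.
    Tests with zero variance are excluded with a warning.
    """
    domains: dict[str, list[np.ndarray]] = {}
    for test, domain in domain_map.items():
        if test not in tests.columns:
            raise KeyError(f"test column {test!r} missing")
        v = tests[test].to_numpy(dtype=float)
        sd = np.std(v, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"test {test!r} has zero variance; excluded")
            continue
        z = (v - v.mean()) / sd * orientation.get(test, 1)
        domains.setdefault(domain, []).append(z)
    out = {}
    for domain, zs in domains.items():
        out[domain] = np.mean(np.stack(zs), axis=0)
    result = pd.DataFrame(out)
    if "subject_id" in tests.columns:
        result.insert(0, "subject_id", tests["subject_id"].to_numpy())
    return result


# ---------------------------------------------------------------------------
# mediation

@dataclass
class MediationResult:
    """Baron-Kenny three-step mediation with Sobel test.

    Path a: X -> M; path b: M -> Y given X; c: total X -> Y; c' (beta1):
    direct X -> Y given M; beta2: mediator effect.  Coefficients are
    standardized when ``standardize=True`` (the default).
    """

    a: float
    se_a: float
    p_a: float
    b: float
    se_b: float
    p_b: float
    c_total: float
    p_c: float
    beta1: float          # direct effect of X controlling M
    p_beta1: float
    beta2: float          # effect of M controlling X
    p_beta2: float
    sobel: float
    sobel_p: float        # normal-referenced
    sobel_p_t: float      # t-referenced, df = n - 3
    n: int
    classification: str   # full | partial | none | not-assessable


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS with intercept: returns (beta, se, p) for the slope columns."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        raise np.linalg.LinAlgError("singular regression design (collinear predictors)")
    resid = y - Xd @ beta
    dof = n - Xd.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return beta[1:], se[1:], p[1:]


def mediate(x, m, y, alpha: float = 0.05, standardize: bool = True) -> MediationResult:
    """Baron-Kenny mediation of the X -> Y association by M.

    Step 1 regresses Y on X (total effect c); step 2 regresses M on X
    (path a).  If either is non-significant at ``alpha`` the mediation is
    ``not-assessable``.  Step 3 regresses Y on X and M jointly, giving the
    direct effect beta1 and the mediator effect beta2 (= path b).
    Classification: ``full`` when beta1 is non-significant and beta2
    significant; ``partial`` when beta1 remains significant but attenuated
    (|beta1| < |c|) and the Sobel test is significant; ``none`` otherwise.
    Sobel statistic: ``a*b / sqrt(b^2 se_a^2 + a^2 se_b^2)``.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[ok], m[ok], y[ok]
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 complete cases for mediation")
    if standardize:
        def z(v):
            sd = np.std(v, ddof=1)
            if sd == 0:
                raise DegenerateTestError("zero-variance variable in mediation")
            return (v - v.mean()) / sd
        x, m, y = z(x), z(m), z(y)

    (c_tot,), _, (p_c,) = _ols(y, x[:, None])
    (a,), (se_a,), (p_a,) = _ols(m, x[:, None])
    (b1, b2), (_, se_b2), (p_b1, p_b2) = _ols(y, np.column_stack([x, m]))

    denom = math.sqrt(b2**2 * se_a**2 + a**2 * se_b2**2)
    sobel = a * b2 / denom if denom > 0 else math.nan
    sobel_p = 2.0 * stats.norm.sf(abs(sobel)) if math.isfinite(sobel) else math.nan
    sobel_p_t = (2.0 * stats.t.sf(abs(sobel), df=n - 3)
                 if math.isfinite(sobel) else math.nan)

    if p_c >= alpha or p_a >= alpha:
        classification = "not-assessable"
    elif p_b1 >= alpha and p_b2 < alpha:
        classification = "full"
    elif p_b1 < alpha and abs(b1) < abs(c_tot) and sobel_p < alpha:
        classification = "partial"
    else:
        classification = "none"

    return MediationResult(
        a=float(a), se_a=float(se_a), p_a=float(p_a),
        b=float(b2), se_b=float(se_b2), p_b=float(p_b2),
        c_total=float(c_tot), p_c=float(p_c),
        beta1=float(b1), p_beta1=float(p_b1),
        beta2=float(b2), p_beta2=float(p_b2),
        sobel=float(sobel), sobel_p=float(sobel_p), sobel_p_t=float(sobel_p_t),
        n=n, classification=classification,
    )


# ---------------------------------------------------------------------------
# the full association battery

DEFAULT_BATTERY_COVARIATES = [
    "age", "crf", "sex", "education_yrs", "hr", "hrv", "prefx",
    "thickness_mm", "wmsa", "performance_score", "verbal_score",
]


def association_battery(cohort: pd.DataFrame,
                        covariates: list[str] | None = None,
                        eac1_col: str = "eac1", eac2_col: str = "eac2",
                        age_col: str = "age") -> pd.DataFrame:
    """Correlations of every covariate with EAC1, EAC2 and age, plus the
    age-partialed EAC1/EAC2 columns.

    Returns one row per covariate with columns ``r_<target>``, ``p_<target>``
    and significance-tier flags (``sig05_<target>``, ``sig10_<target>``) for
    targets eac1, eac2, age, eac1_age (age partialed) and eac2_age.  No
    multiple-comparison correction is applied.
    """
    covariates = covariates or [c for c in DEFAULT_BATTERY_COVARIATES if c in cohort.columns]
    rows = []
    for cov in covariates:
        v = cohort[cov].to_numpy(dtype=float)
        rec: dict[str, object] = {"variable": cov}
        targets = {
            "eac1": lambda: correlate(v, cohort[eac1_col]),
            "eac2": lambda: correlate(v, cohort[eac2_col]),
            "age": lambda: correlate(v, cohort[age_col]),
            "eac1_age": lambda: partial_correlate(v, cohort[eac1_col], cohort[age_col]),
            "eac2_age": lambda: partial_correlate(v, cohort[eac2_col], cohort[age_col]),
        }
        for name, fn in targets.items():
            if cov == age_col and name in ("age", "eac1_age", "eac2_age"):
                rec[f"r_{name}"] = np.nan
                rec[f"p_{name}"] = np.nan
                rec[f"sig05_{name}"] = False
                rec[f"sig10_{name}"] = False
                continue
            res = fn()
            rec[f"r_{name}"] = res.r
            rec[f"p_{name}"] = res.p
            rec[f"sig05_{name}"] = res.p < 0.05
            rec[f"sig10_{name}"] = res.p < 0.10
        rows.append(rec)
    return pd.DataFrame(rows)
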