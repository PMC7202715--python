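"""Dual-wavelength oxygenation inversion and EAC wavelength-space PCA.

Tissue Oxygenation Index (TOI): assuming a power-law spectral dependence of
reduced scattering, ``mu_s'(lambda) = mu_s'(830) * (lambda/830)^(-b)``, the
measured EAC at each wavelength is inverted exactly for the absorption
coefficient, the two absorptions are unmixed into oxy-/deoxy-hemoglobin
concentrations through the packaged extinction coefficients, and
``TOI = C_HbO / (C_HbO + C_HbR)``.  The TOI is, to first order, a function of
the ratio of the EACs at the two wavelengths.

Wavelength PCA: the 2x2 covariance of the per-subject (EAC690, EAC830) pairs
is eigendecomposed into two orthogonal latent variables — EAC1 (both loadings
positive: the anatomical, CSF/atrophy-related average) and EAC2 (opposite-sign
loadings: the oxygenation-related difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromophores import unmixing_matrix
from .diffusion import mu_eff_from_coefficients, mua_from_mu_eff
from .errors import EacmapError, UndefinedCorrelationError

WAVELENGTHS = (690.0, 830.0)


class UndefinedTOIError(EacmapError):
    """Total inferred hemoglobin is zero; the oxygenation ratio is undefined."""


class DegenerateDecompositionError(EacmapError):
    """Zero covariance: the wavelength space has no variance to decompose."""


@dataclass
class TOIResult:
    """Oxygenation inversion output for one EAC pair."""

    toi: float
    mu_a: dict[float, float]          # inferred absorption, mm^-1
    mu_s_prime: dict[float, float]    # assumed scattering, mm^-1
    b: float                          # scattering power-law exponent
    c_hbo_um: float
    c_hbr_um: float
    nonphysical: bool                 # a concentration was clamped at 0


def toi_from_eac(eac_690: float, eac_830: float,
                 musp_830: float = 0.72, b: float = 1.0,
                 mode: str = "exact") -> TOIResult:
    """Tissue Oxygenation Index from the EAC pair.

    Parameters
    ----------
    eac_690, eac_830
        Measured effective attenuation coefficients, mm^-1 (> 0).
    musp_830
        Assumed reduced scattering at 830 nm, mm^-1 (default 0.72, a standard
        adult-head value).
    b
        Scattering power-law exponent (default 1).
    mode
        ``exact``: invert ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))`` for mu_a
        (positive root).  ``ratio``: use the diffusive approximation
        ``mu_a ~= EAC^2 / (3 mu_s')`` — under it the TOI depends on the EAC
        pair only through their ratio (for fixed b and reference scattering).
    """
    if eac_690 <= 0 or eac_830 <= 0:
        raise ValueError("EAC values must be positive")
    if musp_830 <= 0:
        raise ValueError("reference mu_s' must be positive")
    musp = {690.0: musp_830 * (690.0 / 830.0) ** (-b), 830.0: musp_830}
    eac = {690.0: float(eac_690), 830.0: float(eac_830)}
    if mode == "exact":
        mua = {wl: mua_from_mu_eff(eac[wl], musp[wl]) for wl in WAVELENGTHS}
    elif mode == "ratio":
        mua = {wl: eac[wl] ** 2 / (3.0 * musp[wl]) for wl in WAVELENGTHS}
    else:
        raise ValueError(f"mode must be 'exact' or 'ratio', got {mode!r}")

    ext = unmixing_matrix(WAVELENGTHS)
    if abs(np.linalg.det(ext)) < 1e-18:
        raise EacmapError("singular extinction system")
    conc = np.linalg.solve(ext, np.array([mua[wl] for wl in WAVELENGTHS]))
    nonphysical = bool(np.any(conc < 0))
    conc = np.maximum(conc, 0.0)
    total = conc.sum()
    if total == 0:
        raise UndefinedTOIError("inferred total hemoglobin is zero")
    return TOIResult(
        toi=float(conc[0] / total), mu_a=mua, mu_s_prime=musp, b=b,
        c_hbo_um=float(conc[0]), c_hbr_um=float(conc[1]), nonphysical=nonphysical,
    )


def forward_eac_pair(so2: float, total_hb_um: float,
                     musp_830: float = 0.72, b: float = 1.0) -> tuple[float, float]:
    """Forward counterpart of :func:`toi_from_eac` under the same scattering model.

    Useful for round-trip checks: generating an EAC pair here and inverting it
    with matching ``musp_830``/``b`` recovers ``so2`` exactly.
    """
    from .chromophores import derive_mua

    musp = {690.0: musp_830 * (690.0 / 830.0) ** (-b), 830.0: musp_830}
    return tuple(
        mu_eff_from_coefficients(derive_mua(so2, total_hb_um, wl), musp[wl])
        for wl in WAVELENGTHS
    )


# ---------------------------------------------------------------------------
# wavelength-space PCA

@dataclass
class PCAResult:
    """Eigendecomposition of the 2-wavelength EAC covariance."""

    eigenvalues: np.ndarray        # descending, length 2
    variance_fractions: np.ndarray
    loadings: np.ndarray           # rows = components, columns = (690, 830)
    scores: np.ndarray             # (n, 2): EAC1, EAC2 per subject
    mean: np.ndarray               # per-wavelength mean of the input pairs


def wavelength_pca(pairs: np.ndarray) -> PCAResult:
    """PCA of per-subject (EAC690, EAC830) pairs on the covariance matrix.

    Covariance (not correlation) PCA keeps the two same-unit variables on
    their natural scale.  Sign conventions: PC1 loadings both positive (the
    anatomical average component); PC2 has a positive 690 nm loading and a
    negative 830 nm loading (the oxygenation difference component).
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = np.cov(xc, rowvar=False, ddof=1)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise DegenerateDecompositionError("zero or non-finite covariance")
    evals, evecs = np.linalg.eigh(cov)          # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    loadings = evecs[:, order].T                # rows = components
    # sign conventions
    if loadings[0].sum() < 0:
        loadings[0] = -loadings[0]
    if loadings[1, 0] < 0:
        loadings[1] = -loadings[1]
    scores = xc @ loadings.T
    total = evals.sum()
    return PCAResult(
        eigenvalues=evals, variance_fractions=evals / total,
        loadings=loadings, scores=scores, mean=mean,
    )


def pca_from_summary(sd_690: float, sd_830: float, r: float) -> PCAResult:
    """PCA of a covariance assembled from printed summary statistics.

    Builds the 2x2 covariance from the two SDs and the cross-wavelength
    correlation and decomposes it analytically (scores are empty).
    """
    cov = np.array([[sd_690**2, r * sd_690 * sd_830],
                    [r * sd_690 * sd_830, sd_830**2]])
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    loadings = evecs[:, order].T
    if loadings[0].sum() < 0:
        loadings[0] = -loadings[0]
    if loadings[1, 0] < 0:
        loadings[1] = -loadings[1]
    return PCAResult(evals, evals / evals.sum(), loadings,
                     scores=np.empty((0, 2)), mean=np.zeros(2))


def pixelwise_components(maps_690, maps_830, pca: PCAResult):
    """Apply cohort-level PC loadings pixel-by-pixel to per-subject map pairs.

    Pixels are centred by the cohort pixel mean per wavelength, then projected
    on the (global) loadings.  Returns ``(eac1_maps, eac2_maps)`` — lists of
    :class:`~eacmap.topomap.GridMap`, one per subject.
    """
    from .topomap import GridMap

    if len(maps_690) != len(maps_830):
        raise ValueError("need one map pair per subject")
    for a, b_ in zip(maps_690, maps_830):
        if not a.same_grid(b_):
            from .errors import AlignmentError
            raise AlignmentError("map pairs do not share a common grid")
    import warnings as _warnings

    s690 = np.stack([m.values for m in maps_690])
    s830 = np.stack([m.values for m in maps_830])
    valid = np.logical_and.reduce([m.valid for m in maps_690 + maps_830])
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        c690 = s690 - np.nanmean(s690, axis=0)
        c830 = s830 - np.nanmean(s830, axis=0)
    n = maps_690[0].grid_n
    no_extrap = np.zeros_like(valid)
    eac1 = [GridMap(pca.loadings[0, 0] * a + pca.loadings[0, 1] * b_, valid, no_extrap, n)
            for a, b_ in zip(c690, c830)]
    eac2 = [GridMap(pca.loadings[1, 0] * a + pca.loadings[1, 1] * b_, valid, no_extrap, n)
            for a, b_ in zip(c690, c830)]
    return eac1, eac2


def pixelwise_correlation(maps, covariate) -> "np.ndarray":
    """Across-subject correlation of a per-subject pixel map stack with a covariate.

    Returns an array shaped like one map (NaN outside the jointly valid mask);
    this is the local-component correlation-map analysis (e.g. local EAC1 vs
    age or working-memory score).
    """
    cov = np.asarray(covariate, dtype=float)
    stack = np.stack([m.values for m in maps])
    if len(cov) != stack.shape[0]:
        raise ValueError("one covariate value per subject required")
    valid = np.logical_and.reduce([m.valid for m in maps])
    xs = stack - stack.mean(axis=0)
    ys = cov - cov.mean()
    denom = np.sqrt((xs**2).sum(axis=0) * (ys**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs * ys[:, None, None]).sum(axis=0) / denom
    r[~valid] = np.nan
    if np.all(~np.isfinite(r[valid])):
        raise UndefinedCorrelationError("no pixel with finite correlation")
    return r
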