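"""Synthetic cohort generator.

Generates latent subjects whose optical properties are tied to age, cortical
atrophy and tissue oxygenation, so that a simulated cohort reproduces the
study conditions the estimator is meant to face: uniform age stratification
over 18-78 with balanced sex per decade, cohort EAC means/SDs per wavelength,
the inter-wavelength EAC correlation, the EAC(690) > EAC(830) offset, and the
age-thickness-oxygenation correlation structure.

Mechanistically each subject carries
  * an anatomical scale factor (log-normal) partially driven by cortical
    thickness — the thinner the cortex, the thicker the clear sub-arachnoid
    CSF layer and the lower the whole-head EAC;
  * hemoglobin absorption derived from latent oxygen saturation (SO2) and
    total hemoglobin through packaged extinction coefficients;
  * reduced scattering drawn log-normally around literature head values
    (0.83 mm^-1 at 690 nm, 0.72 mm^-1 at 830 nm) with a wavelength-specific
    component sized by the calibration solver.

Dispersion calibration is closed-form in log space; mean calibration is a
deterministic fixed-point iteration on an internal Monte-Carlo sample (its
seed is a package constant, independent of the user's master seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .chromophores import derive_mua
from .diffusion import mu_eff_from_coefficients
from .errors import CalibrationError
from .montage import FIT_WINDOW_MM, Montage, generate_montage

_INTERNAL_CALIBRATION_SEED = 0x0EAC
_INTERNAL_CALIBRATION_N = 16384

#: population SD of an age uniform on [18, 78]
AGE_MEAN = 48.0
AGE_SD = 60.0 / math.sqrt(12.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    The calibration targets default to the cohort summary statistics of the
    human study the generator emulates; sampling/noise parameters default to
    the recording conditions of that study (39.0625 Hz sampling, shot-noise
    dominated counts, sub-10 Hz physiological oscillations).
    """

    n_subjects: int = 48
    master_seed: int = 0
    # recording
    sampling_rate_hz: float = 39.0625
    block_duration_s: float = 30.0
    n_blocks: int = 1
    photon_budget: float = 2e5       # expected counts/sample at the 20 mm reference channel
    cardiac_amplitude: float = 0.02  # fractional modulation
    respiratory_amplitude: float = 0.01
    drift_amplitude: float = 0.005
    cardiac_freq_hz: float = 1.1
    respiratory_freq_hz: float = 0.25
    drift_freq_hz: float = 0.02
    # montage: four consecutive helmet placements per subject, each with
    # 64 paired-source positions and 24 detectors (384 channels per montage,
    # 1536 per session)
    n_montages: int = 4
    n_source_pairs: int = 64
    n_detectors: int = 24
    head_radius_mm: float = 90.0
    gain_sigma: float = 0.5
    # age range
    age_min: float = 18.0
    age_max: float = 78.0
    # cohort calibration targets
    eac_mean_690: float = 0.192
    eac_mean_830: float = 0.170
    eac_sd_690: float = 0.040
    eac_sd_830: float = 0.036
    eac_cross_r: float = 0.85
    age_thickness_r: float = -0.65
    age_so2_r: float = -0.31
    # latent physiology
    so2_mean: float = 0.65
    so2_sd: float = 0.04
    total_hb_um: float = 70.0
    total_hb_log_sd: float = 0.08
    musp_base_690: float = 0.83
    musp_base_830: float = 0.72
    musp_common_log_sd: float = 0.05
    thickness_mean_mm: float = 2.5
    thickness_sd_mm: float = 0.15
    thickness_eac_coupling: float = 0.17   # d ln(EAC) per SD of cortical thickness
    # topographic relief on mu_eff (dorsal/occipital high), ln-amplitude per SD
    relief_amplitude: float = 0.10
    noise_scale: float = 1.0   # 0 silences all latent Gaussian noise (degenerate checks)

    def __post_init__(self):
        if self.sampling_rate_hz <= 20.0:
            raise ValueError("sampling rate must exceed 20 Hz so the >10 Hz band exists")
        if self.photon_budget <= 0:
            raise ValueError("photon budget must be positive")
        if not 0.0 < self.so2_mean < 1.0:
            raise ValueError("mean SO2 must lie strictly inside (0, 1)")

    def eac_mean(self, wl: float) -> float:
        return self.eac_mean_690 if wl == 690.0 else self.eac_mean_830

    def eac_sd(self, wl: float) -> float:
        return self.eac_sd_690 if wl == 690.0 else self.eac_sd_830

    def musp_base(self, wl: float) -> float:
        return self.musp_base_690 if wl == 690.0 else self.musp_base_830


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering at one wavelength, mm^-1."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self):
        if not 0.0 < self.mu_a < self.mu_s_prime:
            raise ValueError("require 0 < mu_a < mu_s' (diffusive regime)")

    @property
    def mu_eff(self) -> float:
        return mu_eff_from_coefficients(self.mu_a, self.mu_s_prime, mode="exact")


@dataclass
class LatentSubject:
    """Ground-truth latent state of one simulated participant."""

    subject_id: str
    age: float
    sex: int                     # 1 = M, 2 = F
    thickness_mm: float
    cortical_volume: float       # normalized units
    wmsa: float                  # log voxels
    so2: float
    total_hb_um: float
    crf: float                   # METs
    hr: float                    # bpm
    hrv: float                   # ms
    prefx: float
    education_yrs: float
    performance_score: float
    verbal_score: float
    optical: dict[float, OpticalProperties]

    @property
    def eac(self) -> dict[float, float]:
        return {wl: props.mu_eff for wl, props in self.optical.items()}


# ---------------------------------------------------------------------------
# topographic relief

_RELIEF_WEIGHT_VERTEX = 1.0
_RELIEF_WEIGHT_POSTERIOR = 0.6


def _relief_raw(unit_xyz: np.ndarray) -> np.ndarray:
    """Un-normalized relief pattern on the unit sphere: dorsal + occipital high.

    +z is the vertex, +x anterior.
    """
    nz = unit_xyz[..., 2]
    nx = unit_xyz[..., 0]
    return _RELIEF_WEIGHT_VERTEX * nz + _RELIEF_WEIGHT_POSTERIOR * (-nx)


@lru_cache(maxsize=1)
def _relief_norm(theta_max_deg: float = 100.0) -> tuple[float, float]:
    """Area-weighted mean/SD of the raw relief over the cap (deterministic grid)."""
    theta = np.linspace(0.0, math.radians(theta_max_deg), 400)
    phi = np.linspace(0.0, 2.0 * math.pi, 800, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    xyz = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1)
    p = _relief_raw(xyz)
    w = np.sin(tt)
    mean = float(np.sum(p * w) / np.sum(w))
    sd = float(np.sqrt(np.sum((p - mean) ** 2 * w) / np.sum(w)))
    return mean, sd


def relief_log_factor(points_mm: np.ndarray, amplitude: float) -> np.ndarray:
    """ln-modulation of the local mu_eff field at 3D points (any radius).

    The pattern is normalized to zero mean / unit SD over the optode cap, then
    scaled by ``amplitude``; ``amplitude=0`` gives a homogeneous head.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    norms = np.linalg.norm(pts, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    unit = pts / norms[:, None]
    mean, sd = _relief_norm()
    return amplitude * (_relief_raw(unit) - mean) / sd


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class CohortCalibration:
    """Solved generator parameters for a given :class:`SimulationConfig`."""

    anat_free_log_sd: float
    musp_specific_log_sd_690: float
    musp_specific_log_sd_830: float
    hb_scale: float
    musp_scale_690: float
    musp_scale_830: float

    def musp_specific(self, wl: float) -> float:
        return self.musp_specific_log_sd_690 if wl == 690.0 else self.musp_specific_log_sd_830

    def musp_scale(self, wl: float) -> float:
        return self.musp_scale_690 if wl == 690.0 else self.musp_scale_830


def _so2_slopes(config: SimulationConfig) -> dict[float, float]:
    """d ln(EAC_wl) / d SO2 at the configured latent means (finite difference)."""
    out = {}
    h = 1e-4
    for wl in (690.0, 830.0):
        musp = config.musp_base(wl)
        e_hi = mu_eff_from_coefficients(
            derive_mua(config.so2_mean + h, config.total_hb_um, wl), musp)
        e_lo = mu_eff_from_coefficients(
            derive_mua(config.so2_mean - h, config.total_hb_um, wl), musp)
        out[wl] = (math.log(e_hi) - math.log(e_lo)) / (2 * h)
    return out


def _eac_sample(config: SimulationConfig, cal: CohortCalibration, z: np.ndarray,
                ages: np.ndarray) -> dict[float, np.ndarray]:
    """Vectorized latent EAC pair for standard-normal draws ``z`` (n, 6).

    Columns of ``z``: thickness noise, SO2 noise, tHb noise, free anatomical
    noise, common scattering noise, then one wavelength-specific scattering
    column per wavelength (6 and 7 here, z has width 7).
    """
    c = config
    s = c.noise_scale
    age_z = (ages - AGE_MEAN) / AGE_SD
    r_at, r_as = c.age_thickness_r, c.age_so2_r
    th_z = r_at * age_z + math.sqrt(1.0 - r_at**2) * s * z[:, 0]
    so2 = np.clip(c.so2_mean + c.so2_sd * (r_as * age_z + math.sqrt(1.0 - r_as**2) * s * z[:, 1]),
                  0.02, 0.98)
    gamma = c.thickness_eac_coupling
    sig_free = cal.anat_free_log_sd
    anat = gamma * th_z + sig_free * s * z[:, 3] - 0.5 * (gamma**2 + (s * sig_free)**2)
    thb = c.total_hb_um * cal.hb_scale * np.exp(
        anat + c.total_hb_log_sd * s * z[:, 2] - 0.5 * (s * c.total_hb_log_sd)**2)
    out = {}
    for wi, wl in enumerate((690.0, 830.0)):
        sig_w = cal.musp_specific(wl)
        musp = (c.musp_base(wl) * cal.musp_scale(wl)
                * np.exp(anat + c.musp_common_log_sd * s * z[:, 4]
                         + sig_w * s * z[:, 5 + wi]
                         - 0.5 * ((s * c.musp_common_log_sd)**2 + (s * sig_w)**2)))
        mua = derive_mua(so2, thb, wl)
        out[wl] = mu_eff_from_coefficients(mua, musp)
    return out


def calibrate(config: SimulationConfig) -> CohortCalibration:
    """Solve generator dispersions and scales for the configured cohort targets.

    Dispersions: a log-space variance allocation matches the per-wavelength
    EAC coefficient of variation and the inter-wavelength correlation, after
    accounting for the (analytically known) SO2, total-hemoglobin and common
    scattering contributions.  Raises :class:`CalibrationError` when the
    targets are infeasible (e.g. a requested cross-wavelength correlation too
    high for the requested SDs, or dispersion targets that would require
    negative variance).

    Scales: a fixed-point iteration on an internal, deterministically seeded
    Monte-Carlo sample adjusts the total-hemoglobin and per-wavelength
    scattering scales until the cohort-expected EAC means hit the targets.
    """
    c = config
    slopes = _so2_slopes(c)
    v = {wl: math.log1p((c.eac_sd(wl) / c.eac_mean(wl)) ** 2) for wl in (690.0, 830.0)}
    cov_target = c.eac_cross_r * math.sqrt(v[690.0] * v[830.0])
    cov_so2 = slopes[690.0] * slopes[830.0] * c.so2_sd**2
    common = cov_target - cov_so2
    anat_var = common - 0.25 * c.total_hb_log_sd**2 - 0.25 * c.musp_common_log_sd**2
    gamma2 = c.thickness_eac_coupling**2
    if anat_var < gamma2:
        raise CalibrationError(
            "cross-wavelength correlation target infeasible: shared variance "
            f"{anat_var:.4g} below the squared thickness coupling {gamma2:.4g}"
        )
    sig_free = math.sqrt(anat_var - gamma2)
    sig_spec = {}
    for wl in (690.0, 830.0):
        w = v[wl] - common - (slopes[wl] * c.so2_sd) ** 2
        if w < 0:
            raise CalibrationError(
                f"EAC SD target at {wl:g} nm infeasible given the correlation target "
                f"(wavelength-specific variance {w:.4g} < 0)"
            )
        sig_spec[wl] = 2.0 * math.sqrt(w)

    cal = CohortCalibration(sig_free, sig_spec[690.0], sig_spec[830.0], 1.0, 1.0, 1.0)
    rng = np.random.default_rng(_INTERNAL_CALIBRATION_SEED)
    z = rng.standard_normal((_INTERNAL_CALIBRATION_N, 7))
    ages = rng.uniform(c.age_min, c.age_max, _INTERNAL_CALIBRATION_N)
    for _ in range(8):
        eac = _eac_sample(c, cal, z, ages)
        rho = {wl: c.eac_mean(wl) / float(np.mean(eac[wl])) for wl in (690.0, 830.0)}
        g = math.sqrt(rho[690.0] * rho[830.0])
        cal = replace(
            cal,
            hb_scale=cal.hb_scale * g,
            musp_scale_690=cal.musp_scale_690 * g * (rho[690.0] / g) ** 2,
            musp_scale_830=cal.musp_scale_830 * g * (rho[830.0] / g) ** 2,
        )
        if max(abs(rho[690.0] - 1), abs(rho[830.0] - 1)) < 1e-10:
            break
    mua_check = derive_mua(c.so2_mean, c.total_hb_um * cal.hb_scale, 690.0)
    if mua_check <= 0:
        raise CalibrationError("calibrated absorption is non-positive")
    return cal


@lru_cache(maxsize=8)
def _cached_calibration(config: SimulationConfig) -> CohortCalibration:
    return calibrate(config)


# ---------------------------------------------------------------------------
# subject sampling

# age loadings for the accessory covariates (typical aging-cohort structure)
_COV_AGE_R = {
    "cortical_volume": -0.81,
    "wmsa": 0.552,
    "crf": -0.741,
    "hr": -0.144,
    "hrv": -0.635,
    "prefx": -0.409,
    "education_yrs": 0.492,
    "verbal_score": 0.430,
}


def sample_subject(
    age: float,
    config: SimulationConfig,
    seed: int,
    sex: int | None = None,
    subject_id: str | None = None,
) -> LatentSubject:
    """Draw one latent subject at the given age under the calibrated model."""
    c = config
    if not c.age_min <= age <= c.age_max:
        raise ValueError(f"age {age} outside [{c.age_min}, {c.age_max}]")
    cal = _cached_calibration(c)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(7)
    e = rng.standard_normal(10)  # accessory covariate noises
    if sex is None:
        sex = int(rng.integers(1, 3))
    s = c.noise_scale
    age_arr = np.asarray([age], dtype=float)
    eac = _eac_sample(c, cal, z[None, :], age_arr)  # reuses exactly the latent pathway

    age_z = (age - AGE_MEAN) / AGE_SD
    r_at, r_as = c.age_thickness_r, c.age_so2_r
    th_z = r_at * age_z + math.sqrt(1 - r_at**2) * s * z[0]
    thickness = c.thickness_mean_mm + c.thickness_sd_mm * th_z
    so2 = float(np.clip(
        c.so2_mean + c.so2_sd * (r_as * age_z + math.sqrt(1 - r_as**2) * s * z[1]),
        0.02, 0.98))
    gamma, sig_free = c.thickness_eac_coupling, cal.anat_free_log_sd
    anat = gamma * th_z + sig_free * s * z[3] - 0.5 * (gamma**2 + (s * sig_free)**2)
    thb = c.total_hb_um * cal.hb_scale * math.exp(
        anat + c.total_hb_log_sd * s * z[2] - 0.5 * (s * c.total_hb_log_sd)**2)

    optical = {}
    for wi, wl in enumerate((690.0, 830.0)):
        sig_w = cal.musp_specific(wl)
        musp = (c.musp_base(wl) * cal.musp_scale(wl)
                * math.exp(anat + c.musp_common_log_sd * s * z[4] + sig_w * s * z[5 + wi]
                           - 0.5 * ((s * c.musp_common_log_sd)**2 + (s * sig_w)**2)))
        optical[wl] = OpticalProperties(derive_mua(so2, thb, wl), musp)
        assert abs(optical[wl].mu_eff - eac[wl][0]) < 1e-12

    def cov(r_age: float, extra: float = 0.0, extra_noise: float = 0.0, idx: int = 0) -> float:
        resid = 1.0 - r_age**2 - extra**2
        resid = math.sqrt(max(resid, 0.0))
        return r_age * age_z + extra * extra_noise + resid * s * e[idx]

    vol_z = -0.81 * age_z + 0.3336 * s * z[0] + 0.482 * s * e[0]
    perf_z = 0.7246 * th_z + 0.689 * s * e[8]
    subj = LatentSubject(
        subject_id=subject_id or f"sub-{seed:010d}",
        age=float(age),
        sex=sex,
        thickness_mm=float(thickness),
        cortical_volume=float(1.0 + 0.10 * vol_z),
        wmsa=float(7.0 + 0.8 * cov(_COV_AGE_R["wmsa"], idx=1)),
        so2=so2,
        total_hb_um=float(thb),
        crf=float(10.0 + 2.2 * cov(_COV_AGE_R["crf"], 0.2, s * z[1], idx=2)),
        hr=float(66.0 + 8.0 * cov(_COV_AGE_R["hr"], idx=3)),
        hrv=float(max(5.0, 50.0 + 15.0 * cov(_COV_AGE_R["hrv"], 0.3, s * z[1], idx=4))),
        prefx=float(cov(_COV_AGE_R["prefx"], 0.3, s * z[0], idx=5)),
        education_yrs=float(16.0 + 2.5 * cov(_COV_AGE_R["education_yrs"], idx=6)),
        performance_score=float(perf_z),
        verbal_score=float(cov(_COV_AGE_R["verbal_score"], idx=9)),
        optical=optical,
    )
    return subj


# ---------------------------------------------------------------------------
# cohort

def stratified_ages(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Ages stratified uniformly over decade bins with balanced sex per bin.

    Bins partition [age_min, age_max] into 10-year intervals.  Subjects are
    distributed as evenly as possible over bins (remainders to the youngest
    bins, deterministically); sexes alternate within each bin (remainder male).
    """
    c = config
    n_bins = max(1, int(round((c.age_max - c.age_min) / 10.0)))
    edges = np.linspace(c.age_min, c.age_max, n_bins + 1)
    base, extra = divmod(c.n_subjects, n_bins)
    ages, sexes = [], []
    for b in range(n_bins):
        n_b = base + (1 if b < extra else 0)
        lo, hi = edges[b], edges[b + 1]
        ages.extend(rng.uniform(lo, hi, n_b))
        sexes.extend([1 if k % 2 == 0 else 2 for k in range(n_b)])
    return np.asarray(ages), np.asarray(sexes, dtype=int)


@dataclass
class Cohort:
    """A generated cohort: ground truth plus lazily simulated raw data.

    ``truth`` is the ground-truth table (one row per subject).  The session
    geometry (one or more consecutive helmet placements, shared across
    subjects) is in ``geometries``; each subject gets fresh per-optode gains
    for every placement.  Channel time series are simulated on demand through
    :meth:`simulate_timeseries` from per-subject child seeds, so two cohorts
    with the same master seed produce identical artifacts without holding
    every recording in memory at once.
    """

    config: SimulationConfig
    subjects: list[LatentSubject]
    geometries: list[Montage]            # shared geometry, unit gains
    subject_gains: list[list[np.ndarray]]  # [subject][montage] optode gains
    timeseries_seeds: list[int]
    truth: pd.DataFrame

    @property
    def geometry(self) -> Montage:
        return self.geometries[0]

    def montage_for(self, i: int, montage: int = 0) -> Montage:
        return self.geometries[montage].with_gains(self.subject_gains[i][montage])

    def simulate_timeseries(self, i: int, montage: int = 0, block: int = 0):
        from .timeseries import simulate_timeseries  # local import avoids a cycle
        seed = (self.timeseries_seeds[i]
                + 7919 * block + 104729 * montage) % (2**31)
        return simulate_timeseries(
            self.subjects[i], self.montage_for(i, montage), self.config, seed)

    def __len__(self) -> int:
        return len(self.subjects)


def _global_relief_factor(geometries: list[Montage], amplitude: float) -> float:
    """Leverage-weighted relief factor over the session's fit-window channels.

    Under an inhomogeneous mu_eff field the expected multi-distance slope over
    channels c is ``sum_c w_c mu_c / sum_c w_c`` with OLS leverage weights
    ``w_c = (r_c - r_bar) r_c``; the ground-truth table stores
    ``base_mu_eff * this factor`` as the estimand of the global fit.
    """
    lo, hi = FIT_WINDOW_MM
    parts = []
    for g in geometries:
        ch = g.channels
        sel = ch[(ch["wavelength_nm"] == 690.0) & ch["distance_mm"].between(lo, hi)]
        parts.append(sel)
    sel = pd.concat(parts, ignore_index=True)
    r = sel["distance_mm"].to_numpy()
    w = (r - r.mean()) * r
    mids = sel[["mid_x_mm", "mid_y_mm", "mid_z_mm"]].to_numpy()
    rel = np.exp(relief_log_factor(mids, amplitude))
    return float(np.sum(w * rel) / np.sum(w))


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort (ground truth; raw data lazily).

    All randomness flows from ``config.master_seed`` through spawned child
    sequences: montage geometry/gains, subject latents and per-subject time
    series each get their own stream, so identical configs give identical
    cohorts.
    """
    c = config
    if c.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    root = np.random.SeedSequence(c.master_seed)
    ss_montage, ss_ages, ss_subjects, ss_gains, ss_ts = root.spawn(5)

    montage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_montage.spawn(c.n_montages)]
    geometries = [
        generate_montage(c.n_source_pairs, c.n_detectors, c.head_radius_mm,
                         seed=montage_seeds[m], gain_sigma=0.0, label=f"M{m}")
        for m in range(c.n_montages)
    ]
    ages, sexes = stratified_ages(c, np.random.default_rng(ss_ages))
    subj_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_subjects.spawn(c.n_subjects)]
    ts_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_ts.spawn(c.n_subjects)]
    gain_rng = np.random.default_rng(ss_gains)

    subjects, gains = [], []
    for i in range(c.n_subjects):
        subjects.append(sample_subject(
            float(ages[i]), c, subj_seeds[i], sex=int(sexes[i]), subject_id=f"sub-{i:03d}"))
        per_montage = []
        for g in geometries:
            if c.gain_sigma > 0:
                per_montage.append(
                    np.exp(c.gain_sigma * gain_rng.standard_normal(len(g.optodes))))
            else:
                per_montage.append(np.ones(len(g.optodes)))
        gains.append(per_montage)

    relief_factor = _global_relief_factor(geometries, c.relief_amplitude)
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
            "thickness_mm": s.thickness_mm, "cortical_volume": s.cortical_volume,
            "wmsa": s.wmsa, "so2": s.so2, "total_hb_um": s.total_hb_um,
            "crf": s.crf, "hr": s.hr, "hrv": s.hrv, "prefx": s.prefx,
            "education_yrs": s.education_yrs,
            "performance_score": s.performance_score, "verbal_score": s.verbal_score,
            "mua_690": s.optical[690.0].mu_a, "musp_690": s.optical[690.0].mu_s_prime,
            "mua_830": s.optical[830.0].mu_a, "musp_830": s.optical[830.0].mu_s_prime,
            "eac_690_true": s.optical[690.0].mu_eff,
            "eac_830_true": s.optical[830.0].mu_eff,
            "eac_690_global_truth": s.optical[690.0].mu_eff * relief_factor,
            "eac_830_global_truth": s.optical[830.0].mu_eff * relief_factor,
        })
    truth = pd.DataFrame(rows)
    return Cohort(c, subjects, geometries, gains, ts_seeds, truth)


# ---------------------------------------------------------------------------
# raw neuropsychological test scores (for the composite-scoring stage)

#: test -> (domain, orientation); -1 marks timed tests where lower is better
TEST_BATTERY = {
    "ravens": ("performance", +1),
    "forward_digit_span": ("performance", +1),
    "backward_digit_span": ("performance", +1),
    "ospan": ("performance", +1),
    "trail_a_s": ("performance", -1),
    "trail_b_s": ("performance", -1),
    "trail_b_minus_a_s": ("performance", -1),
    "shipley_vocabulary": ("verbal", +1),
    "verbal_fluency": ("verbal", +1),
}

_TEST_SCALES = {
    "ravens": (50.0, 8.0), "forward_digit_span": (9.0, 2.0),
    "backward_digit_span": (7.0, 2.0), "ospan": (40.0, 12.0),
    "trail_a_s": (30.0, 9.0), "trail_b_s": (70.0, 25.0),
    "trail_b_minus_a_s": (40.0, 20.0),
    "shipley_vocabulary": (32.0, 4.0), "verbal_fluency": (42.0, 11.0),
}


def generate_test_scores(truth: pd.DataFrame, seed: int, reliability: float = 0.75) -> pd.DataFrame:
    """Raw test scores consistent with the cohort's latent domain scores.

    Each test loads on its domain latent with the given reliability; timed
    tests are emitted on a seconds scale where *larger is worse*.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    out = {"subject_id": truth["subject_id"].to_numpy()}
    lat = {"performance": truth["performance_score"].to_numpy(),
           "verbal": truth["verbal_score"].to_numpy()}
    for test, (domain, orient) in TEST_BATTERY.items():
        mean, sd = _TEST_SCALES[test]
        z = reliability * lat[domain] + math.sqrt(1 - reliability**2) * rng.standard_normal(n)
        out[test] = mean + sd * orient * z
    return pd.DataFrame(out)
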