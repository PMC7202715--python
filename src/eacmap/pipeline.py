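"""End-to-end cohort analysis: simulate -> preprocess -> estimate -> map ->
oxygenation/PCA -> association battery and mediation.

``run_pipeline`` is the one-call driver used by the examples and the
acceptance script; each stage is also usable on its own.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_stats import MediationResult, association_battery, mediate, paired_t
from .cohort import Cohort, SimulationConfig, generate_cohort
from .eac_estimator import (
    DEFAULT_NEIGHBORHOOD_RADIUS_MM,
    eac_channel_map,
    global_eac,
)
from .preprocess import average_snr_tables, preprocess_block
from .spectral_oxygenation import pixelwise_components, toi_from_eac, wavelength_pca
from .topomap import (
    GridMap,
    group_maps,
    interpolate_map,
    map_correlation,
    project_to_disk,
    split_half_reliability,
)

WAVELENGTHS = (690.0, 830.0)


@dataclass
class PipelineResult:
    """Everything the cohort analysis produces."""

    config: SimulationConfig
    cohort: Cohort
    table: pd.DataFrame                      # truth + estimates + TOI + PC scores
    subject_maps: dict[float, list[GridMap]]  # per wavelength, one map per subject
    mean_maps: dict[float, GridMap]
    se_pct_maps: dict[float, GridMap]
    split_half_r: dict[float, float]
    cross_wavelength_r: float
    pca: object
    eac1_maps: list[GridMap] = field(default_factory=list)
    eac2_maps: list[GridMap] = field(default_factory=list)
    battery: pd.DataFrame | None = None
    mediation_thickness: MediationResult | None = None
    mediation_toi: MediationResult | None = None
    delta_eac_t: tuple[float, int, float] | None = None
    timings_s: dict[str, float] = field(default_factory=dict)


def estimate_subject(cohort: Cohort, i: int,
                     radius_mm: float = DEFAULT_NEIGHBORHOOD_RADIUS_MM,
                     spike_z: float = 5.0, cutoff_hz: float = 10.0):
    """Simulate, preprocess and estimate one subject.

    Returns ``(global fits per wavelength, channel map DataFrame, snr table)``.
    """
    per_montage = []
    for m in range(cohort.config.n_montages):
        tables = []
        for b in range(cohort.config.n_blocks):
            ts = cohort.simulate_timeseries(i, montage=m, block=b)
            tables.append(preprocess_block(ts, spike_z=spike_z, cutoff_hz=cutoff_hz))
        per_montage.append(average_snr_tables(tables))
    snr = pd.concat(per_montage, ignore_index=True)
    fits = global_eac(snr)
    cmap = eac_channel_map(snr, radius_mm=radius_mm)
    return fits, cmap, snr


def run_pipeline(config: SimulationConfig, grid_n: int = 64,
                 radius_mm: float = DEFAULT_NEIGHBORHOOD_RADIUS_MM,
                 split_seed: int = 0) -> PipelineResult:
    """Run the full analysis on a synthetic cohort defined by ``config``."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    cohort = generate_cohort(config)
    timings["generate"] = time.perf_counter() - t0

    # --- per-subject estimation -------------------------------------------
    t0 = time.perf_counter()
    table = cohort.truth.copy()
    est = {wl: np.empty(len(cohort)) for wl in WAVELENGTHS}
    maps: dict[float, list[GridMap]] = {wl: [] for wl in WAVELENGTHS}
    for i in range(len(cohort)):
        fits, cmap, _ = estimate_subject(cohort, i, radius_mm=radius_mm)
        for wl in WAVELENGTHS:
            est[wl][i] = fits[wl].mu_eff
            sub = cmap[cmap["wavelength_nm"] == wl]
            proj = project_to_disk(sub[["mid_x_mm", "mid_y_mm", "mid_z_mm"]].to_numpy())
            maps[wl].append(interpolate_map(proj, sub["mu_eff"].to_numpy(), grid_n))
    for wl in WAVELENGTHS:
        table[f"eac_{int(wl)}"] = est[wl]
    timings["estimate"] = time.perf_counter() - t0

    # --- maps --------------------------------------------------------------
    t0 = time.perf_counter()
    mean_maps, se_maps, split_r = {}, {}, {}
    decade = ((table["age"] - config.age_min) // 10).astype(int)
    strata = list(zip(decade, table["sex"]))
    # coarsen for small cohorts where (decade, sex) cells are all singletons
    if max(strata.count(s) for s in set(strata)) < 2:
        strata = list(decade)
        if max(strata.count(s) for s in set(strata)) < 2:
            strata = [0] * len(table)
    for wl in WAVELENGTHS:
        mean_maps[wl], se_maps[wl] = group_maps(maps[wl])
        split_r[wl] = split_half_reliability(maps[wl], strata, seed=split_seed)
    cross_r = map_correlation(mean_maps[690.0], mean_maps[830.0])
    timings["maps"] = time.perf_counter() - t0

    # --- oxygenation and wavelength PCA ------------------------------------
    t0 = time.perf_counter()
    toi = np.array([
        toi_from_eac(table["eac_690"].iat[i], table["eac_830"].iat[i]).toi
        for i in range(len(table))
    ])
    table["toi"] = toi
    pca = wavelength_pca(table[["eac_690", "eac_830"]].to_numpy())
    table["eac1"] = pca.scores[:, 0]
    table["eac2"] = pca.scores[:, 1]
    eac1_maps, eac2_maps = pixelwise_components(maps[690.0], maps[830.0], pca)
    timings["spectral"] = time.perf_counter() - t0

    # --- statistics ---------------------------------------------------------
    t0 = time.perf_counter()
    battery = association_battery(table)
    med_th = mediate(table["age"], table["thickness_mm"], table["eac1"])
    med_toi = mediate(table["age"], table["toi"], table["eac2"])
    delta_t = paired_t(table["eac_690"], table["eac_830"])
    timings["stats"] = time.perf_counter() - t0

    return PipelineResult(
        config=config, cohort=cohort, table=table,
        subject_maps=maps, mean_maps=mean_maps, se_pct_maps=se_maps,
        split_half_r=split_r, cross_wavelength_r=cross_r,
        pca=pca, eac1_maps=eac1_maps, eac2_maps=eac2_maps,
        battery=battery, mediation_thickness=med_th, mediation_toi=med_toi,
        delta_eac_t=delta_t, timings_s=timings,
    )
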