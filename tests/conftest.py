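"""Shared fixtures.

Everything is generated programmatically; the heavier cohort artifacts are
session-scoped so simulation cost is paid once.
"""

import numpy as np
import pandas as pd
import pytest

import eacmap as em


@pytest.fixture(scope="session")
def small_montage():
    """A modest but estimator-usable cap montage with unit gains."""
    return em.generate_montage(24, 16, head_radius_mm=90.0, seed=11, gain_sigma=0.0)


@pytest.fixture(scope="session")
def dense_montage():
    """Study-density placement (64 source pairs, 24 detectors), unit gains."""
    return em.generate_montage(64, 24, head_radius_mm=90.0, seed=11, gain_sigma=0.0)


@pytest.fixture(scope="session")
def latent_cohort_2000():
    """Large latent-only cohort for calibration checks (no time series)."""
    cfg = em.SimulationConfig(n_subjects=2000, master_seed=101,
                              n_montages=1, n_source_pairs=24, n_detectors=16)
    return em.generate_cohort(cfg)


@pytest.fixture(scope="session")
def latent_cohort_48():
    cfg = em.SimulationConfig(n_subjects=48, master_seed=7,
                              n_montages=1, n_source_pairs=24, n_detectors=16)
    return em.generate_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full end-to-end run on the default 48-subject cohort (shared).

    This is the heavyweight artifact behind the estimator-accuracy, map
    reliability and end-to-end checks; it is built once per session.
    """
    import time

    t0 = time.perf_counter()
    res = em.run_pipeline(em.SimulationConfig(master_seed=2), split_seed=2)
    res.wall_time_s = time.perf_counter() - t0
    return res


def make_snr_table(distances, y=None, wavelength=830.0, mids=None, **flags):
    """Hand-built SNR sample table for estimator tests."""
    distances = np.asarray(distances, dtype=float)
    n = len(distances)
    if y is None:
        y = np.zeros(n)
    if mids is None:
        mids = np.column_stack([distances, np.zeros(n), np.zeros(n)])
    df = pd.DataFrame({
        "channel_id": [f"ch{i}" for i in range(n)],
        "wavelength_nm": wavelength,
        "distance_mm": distances,
        "mid_x_mm": mids[:, 0], "mid_y_mm": mids[:, 1], "mid_z_mm": mids[:, 2],
        "snr": np.exp(np.asarray(y) / 2) / distances,
        "y": np.asarray(y, dtype=float),
        "low_light": False, "motion": False, "rejected": False,
    })
    for k, v in flags.items():
        df[k] = v
    return df


@pytest.fixture()
def snr_table_factory():
    return make_snr_table
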