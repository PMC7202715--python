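"""File I/O: TSV tables, SNIRF raw data, JSON configs.

Raw channel data can be written either as SNIRF (the standard HDF5-based
container for shared near-infrared spectroscopy data; continuous-wave
intensity, one file per subject) or as long-format plain TSV.  Montages,
ground truth, SNR tables and cohort tables are TSV; configs round-trip as
JSON including the packaged extinction coefficients for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .chromophores import EXTINCTION
from .cohort import SimulationConfig
from .montage import Montage
from .timeseries import ChannelTimeSeries

SNIRF_FORMAT_VERSION = "1.0"


# ---------------------------------------------------------------------------
# TSV

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_montage_tsv(montage: Montage, path) -> None:
    write_tsv(montage.optodes, path)


def write_timeseries_tsv(ts: ChannelTimeSeries, path) -> None:
    """Long format: time_s, channel_id, intensity."""
    t = np.arange(ts.n_samples) / ts.rate_hz
    ids = ts.channels["channel_id"].to_numpy()
    df = pd.DataFrame({
        "time_s": np.repeat(t[None, :], len(ids), axis=0).ravel(),
        "channel_id": np.repeat(ids, ts.n_samples),
        "intensity": ts.samples.ravel(),
    })
    write_tsv(df, path)


def read_timeseries_tsv(path, channels: pd.DataFrame, rate_hz: float) -> ChannelTimeSeries:
    df = read_tsv(path)
    ids = channels["channel_id"].to_numpy()
    n = df["time_s"].nunique()
    samples = np.empty((len(ids), n))
    grouped = {k: g for k, g in df.groupby("channel_id")}
    for i, cid in enumerate(ids):
        g = grouped[cid].sort_values("time_s")
        samples[i] = g["intensity"].to_numpy()
    return ChannelTimeSeries(channels.copy(), samples, rate_hz)


# ---------------------------------------------------------------------------
# config JSON

def write_config_json(config: SimulationConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["_provenance"] = {
        "extinction_mm_per_uM": {str(int(wl)): {"HbO2": e[0], "HbR": e[1]}
                                 for wl, e in EXTINCTION.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_config_json(path) -> SimulationConfig:
    payload = json.loads(Path(path).read_text())
    payload.pop("_provenance", None)
    return SimulationConfig(**payload)


# ---------------------------------------------------------------------------
# SNIRF

def write_snirf(ts: ChannelTimeSeries, montage: Montage, path) -> None:
    """Write one subject's continuous-wave intensity block as SNIRF v1.0.

    Layout: /nirs/data1 with dataTimeSeries (time x channels), per-channel
    measurementList entries (1-based source/detector/wavelength indices), and
    /nirs/probe with 3D source/detector positions and the wavelength table.
    Source positions are the paired-fibre locations, so both wavelengths share
    a source index.
    """
    opt = montage.optodes
    src_mask = opt["kind"].str.startswith("source_690").to_numpy()
    det_mask = (opt["kind"] == "detector").to_numpy()
    src_pos = opt.loc[src_mask, ["x_mm", "y_mm", "z_mm"]].to_numpy()
    det_pos = opt.loc[det_mask, ["x_mm", "y_mm", "z_mm"]].to_numpy()
    det_index_of_optode = {o: j + 1 for j, o in enumerate(np.nonzero(det_mask)[0])}

    wavelengths = sorted(ts.channels["wavelength_nm"].unique())
    t = np.arange(ts.n_samples) / ts.rate_hz
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=SNIRF_FORMAT_VERSION)
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=ts.samples.T)
        data.create_dataset("time", data=t)
        ch = ts.channels
        n_wl = ch["wavelength_nm"].nunique()
        for k in range(len(ch)):
            ml = data.create_group(f"measurementList{k + 1}")
            # source optodes are interleaved per wavelength: pair index
            ml.create_dataset("sourceIndex", data=int(ch["source_optode"].iat[k] // n_wl + 1))
            ml.create_dataset("detectorIndex",
                              data=det_index_of_optode[int(ch["detector_optode"].iat[k])])
            wl = float(ch["wavelength_nm"].iat[k])
            ml.create_dataset("wavelengthIndex", data=wavelengths.index(wl) + 1)
            ml.create_dataset("dataType", data=1)        # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, dtype=float))
        probe.create_dataset("sourcePos3D", data=src_pos)
        probe.create_dataset("detectorPos3D", data=det_pos)
        meta = nirs.create_group("metaDataTags")
        for tag, val in [("SubjectID", "synthetic"), ("MeasurementDate", "unknown"),
                         ("MeasurementTime", "unknown"), ("LengthUnit", "mm"),
                         ("TimeUnit", "s"), ("FrequencyUnit", "Hz")]:
            meta.create_dataset(tag, data=val)


def read_snirf(path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict]:
    """Read a SNIRF file: (samples channels x time, time vector, measurement
    table with 1-based indices, probe dict)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"]).T
        time = np.asarray(data["time"])
        rows = []
        k = 1
        while f"measurementList{k}" in data:
            ml = data[f"measurementList{k}"]
            rows.append({
                "sourceIndex": int(ml["sourceIndex"][()]),
                "detectorIndex": int(ml["detectorIndex"][()]),
                "wavelengthIndex": int(ml["wavelengthIndex"][()]),
            })
            k += 1
        probe = {
            "wavelengths": np.asarray(nirs["probe"]["wavelengths"]),
            "sourcePos3D": np.asarray(nirs["probe"]["sourcePos3D"]),
            "detectorPos3D": np.asarray(nirs["probe"]["detectorPos3D"]),
        }
    return series, time, pd.DataFrame(rows), probe
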