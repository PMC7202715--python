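"""From raw intensity to SNR samples, and pulse-derived heart metrics.

The processing order is fixed: normalize (divide by the block mean), movement
correction (robust-z spike interpolation), high-pass above 10 Hz (zero-phase
Butterworth), then SNR.  The SNR of a channel is defined through the variance
of the normalized, filtered signal, ``SNR^2 = 1 / var(i(t)/i_avg)``; with
shot-noise-dominated counts ``SNR^2`` is proportional to the detected light,
so ``y = ln(SNR^2 r^2)`` decays linearly with source-detector distance with
slope ``-mu_eff``.  The high-pass removes the sub-10 Hz physiological band
(cardiac, respiratory, slow drift) whose variance is not shot noise; it also
scales the white shot-noise variance by a fixed band fraction, which shifts
the intercept ``k`` identically for every channel and leaves the slope —
hence the EAC — untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import (
    InvalidChannelError,
    NoPulseError,
    ParameterError,
    UndefinedSNRError,
)
from .timeseries import ChannelTimeSeries

SNR_COLUMNS = ["channel_id", "wavelength_nm", "distance_mm",
               "mid_x_mm", "mid_y_mm", "mid_z_mm", "snr", "y",
               "low_light", "motion", "rejected"]


def normalize_block(ts: ChannelTimeSeries) -> ChannelTimeSeries:
    """Divide each channel by its block-mean intensity (output mean exactly 1).

    A single-channel series with non-positive mean or non-finite samples
    raises :class:`InvalidChannelError`; in a multi-channel block such
    channels are flagged ``rejected`` instead so one bad channel never aborts
    a cohort run.
    """
    i_avg = ts.i_avg
    finite = np.isfinite(ts.samples).all(axis=1)
    bad = (i_avg <= 0) | ~np.isfinite(i_avg) | ~finite
    if bad.all():
        raise InvalidChannelError("no channel has a positive, finite block mean")
    denom = np.where(bad, 1.0, i_avg)
    out = ts.copy_with(ts.samples / denom[:, None], normalized=True, i_avg_raw=i_avg)
    out.channels.loc[bad, "rejected"] = True
    return out


def movement_correct(ts: ChannelTimeSeries, spike_z: float = 5.0,
                     window_s: float = 1.0, motion_frac: float = 0.10,
                     reject_frac: float = 0.50) -> ChannelTimeSeries:
    """Replace samples deviating from a running median by > ``spike_z`` robust SDs.

    The scale is the MAD (x1.4826) of the residuals with an epsilon floor, so
    constant channels produce no spurious flags.  Spikes are replaced by
    linear interpolation of neighbouring good samples.  Channels with more
    than 10% replaced are flagged ``motion``; more than 50% replaced marks the
    channel ``rejected``.
    """
    if not ts.normalized:
        raise InvalidChannelError("movement correction expects a normalized block")
    x = ts.samples
    k = max(3, int(round(window_s * ts.rate_hz)) | 1)
    med = ndimage.median_filter(x, size=(1, k), mode="nearest")
    resid = x - med
    mad = 1.4826 * np.median(np.abs(resid), axis=1)
    # floor at the shot-noise SD (1/sqrt(mean counts) in normalized units):
    # on dim channels the discrete counts collapse the MAD and every photon
    # would otherwise register as a spike
    if ts.i_avg_raw is not None:
        shot_sd = 1.0 / np.sqrt(np.maximum(ts.i_avg_raw, 1e-300))
        scale = np.maximum(mad, shot_sd)
    else:
        scale = mad
    scale = np.maximum(scale, 1e-12)
    spikes = np.abs(resid) > spike_z * scale[:, None]

    out = x.copy()
    idx = np.arange(x.shape[1])
    frac = spikes.mean(axis=1)
    for c in np.nonzero(spikes.any(axis=1))[0]:
        good = ~spikes[c]
        if good.sum() >= 2:
            out[c, spikes[c]] = np.interp(idx[spikes[c]], idx[good], x[c, good])
    res = ts.copy_with(out)
    res.channels["replaced_frac"] = frac
    res.channels.loc[frac > motion_frac, "motion"] = True
    res.channels.loc[frac > reject_frac, "rejected"] = True
    return res


def highpass(ts: ChannelTimeSeries, cutoff_hz: float = 10.0, order: int = 4) -> ChannelTimeSeries:
    """Zero-phase Butterworth high-pass (applied forward and backward)."""
    nyq = ts.rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ParameterError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=ts.rate_hz, output="sos")
    return ts.copy_with(signal.sosfiltfilt(sos, ts.samples, axis=1), filtered=True)


def highpass_response(f_hz, cutoff_hz: float = 10.0, order: int = 4,
                      rate_hz: float = 39.0625) -> np.ndarray:
    """Analytic amplitude response of the zero-phase high-pass at ``f_hz``.

    Useful as an oracle: zero-phase application squares the single-pass
    magnitude response.
    """
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(f_hz, dtype=float)), fs=rate_hz)
    return np.abs(h) ** 2


def compute_snr(ts: ChannelTimeSeries) -> pd.DataFrame:
    """Per-channel SNR and ``y = ln(SNR^2 r^2)`` from the processed block.

    ``SNR^2 = 1 / var(samples)`` on the normalized (and typically filtered)
    series.  Zero variance on a single-channel input raises
    :class:`UndefinedSNRError`; in a block it marks the channel rejected.
    Returns the SNR table consumed by :mod:`eacmap.eac_estimator`.
    """
    if not ts.normalized:
        raise InvalidChannelError("SNR is defined on the normalized block")
    var = ts.samples.var(axis=1)
    bad = (var <= 0) | ~np.isfinite(var)
    if bad.all():
        raise UndefinedSNRError("variance is zero or non-finite for every channel")
    ch = ts.channels
    snr = np.where(bad, np.nan, 1.0 / np.sqrt(np.where(bad, 1.0, var)))
    r = ch["distance_mm"].to_numpy()
    with np.errstate(invalid="ignore"):
        y = np.log(snr**2 * r**2)
    out = ch[["channel_id", "wavelength_nm", "distance_mm",
              "mid_x_mm", "mid_y_mm", "mid_z_mm"]].copy()
    out["snr"] = snr
    out["y"] = y
    out["low_light"] = ch["low_light"].to_numpy()
    out["motion"] = ch["motion"].to_numpy()
    out["rejected"] = ch["rejected"].to_numpy() | bad
    return out.reset_index(drop=True)


def preprocess_block(ts: ChannelTimeSeries, spike_z: float = 5.0,
                     cutoff_hz: float = 10.0) -> pd.DataFrame:
    """The fixed pipeline: normalize -> movement-correct -> high-pass -> SNR."""
    return compute_snr(highpass(movement_correct(normalize_block(ts), spike_z), cutoff_hz))


def average_snr_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-channel SNR samples across recording blocks (in y, log domain)."""
    if len(tables) == 1:
        return tables[0]
    cat = pd.concat(tables, ignore_index=True)
    keys = ["channel_id", "wavelength_nm", "distance_mm",
            "mid_x_mm", "mid_y_mm", "mid_z_mm"]
    agg = cat.groupby(keys, as_index=False).agg(
        y=("y", "mean"),
        low_light=("low_light", "any"),
        motion=("motion", "any"),
        rejected=("rejected", "any"),
    )
    agg["snr"] = np.sqrt(np.exp(agg["y"]) / agg["distance_mm"] ** 2)
    return agg[SNR_COLUMNS]


# ---------------------------------------------------------------------------
# heart rate / heart-rate variability from the optical pulse

@dataclass(frozen=True)
class PulseMetrics:
    """Heart rate (bpm), heart-rate variability (SD of inter-beat intervals, ms)."""

    hr_bpm: float
    hrv_ms: float
    n_beats: int


def _refine_extremum(x: np.ndarray, i: int) -> float:
    """Sub-sample parabolic refinement of a local extremum index."""
    if 0 < i < len(x) - 1:
        denom = x[i - 1] - 2 * x[i] + x[i + 1]
        if denom != 0:
            return i + 0.5 * (x[i - 1] - x[i + 1]) / denom
    return float(i)


def compute_hr_hrv(ts: ChannelTimeSeries, band_hz: tuple[float, float] = (0.5, 2.5),
                   refractory_s: float = 0.33) -> PulseMetrics:
    """Heart rate and HRV from the optical pulse.

    The normalized series is averaged across all accepted channels, band-passed
    to the cardiac band, and diastolic troughs are detected by local-minimum
    search with a refractory period; inter-beat intervals are the lags between
    consecutive troughs (sub-sample refined).  HR is the inverse of the mean
    interval; HRV is the SD of the intervals in ms.
    """
    if ts.duration_s < 30.0:
        raise ParameterError("need at least 30 s of data for pulse metrics")
    if not ts.normalized:
        ts = normalize_block(ts)
    acc = ts.accepted
    if not acc.any():
        raise NoPulseError("no accepted channels")
    mean_sig = ts.samples[acc].mean(axis=0)
    lo, hi = band_hz
    nyq = ts.rate_hz / 2
    if not 0 < lo < hi < nyq:
        raise ParameterError("cardiac band must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=ts.rate_hz, output="sos")
    pulse = signal.sosfiltfilt(sos, mean_sig)
    if np.std(pulse) < 1e-10:  # normalized units: numerically flat
        raise NoPulseError("flat signal: no cardiac modulation")

    # dominant cardiac frequency sets the trough spacing: harmonics of the
    # pulse waveform (e.g. the dicrotic notch) produce shallower secondary
    # minima between beats that a fixed refractory period alone would count
    freqs, pxx = signal.periodogram(pulse, fs=ts.rate_hz)
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any() or np.all(pxx[band] == 0):
        raise NoPulseError("no spectral power in the cardiac band")
    f_dom = float(freqs[band][np.argmax(pxx[band])])
    spacing_s = max(refractory_s, 0.7 / f_dom)
    min_dist = max(1, int(round(spacing_s * ts.rate_hz)))
    prominence = 0.25 * np.std(pulse)
    troughs, _ = signal.find_peaks(-pulse, distance=min_dist, prominence=prominence)
    if len(troughs) < 3:
        raise NoPulseError(f"only {len(troughs)} diastolic troughs detected")
    times = np.array([_refine_extremum(-pulse, int(i)) for i in troughs]) / ts.rate_hz
    ibi_ms = np.diff(times) * 1000.0
    if len(ibi_ms) < 2:
        raise NoPulseError("fewer than 2 inter-beat intervals")
    return PulseMetrics(
        hr_bpm=60000.0 / float(np.mean(ibi_ms)),
        hrv_ms=float(np.std(ibi_ms, ddof=1)),
        n_beats=len(troughs),
    )
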