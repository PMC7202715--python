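"""Multi-distance EAC estimation.

Every estimate is the ordinary-least-squares slope of ``y = ln(SNR^2 r^2)``
on source-detector distance ``r`` over some channel subset: the whole
accepted set (global EAC), a 30 mm neighbourhood around each channel
(topographic EAC), or a source-detector-distance bin (depth-stratified EAC).
``mu_eff = -slope``; the intercept ``k`` absorbs source power, detector
efficiency and coupling and is reported for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import mu_eff_from_coefficients  # re-exported: part of this module's surface
from .errors import EmptySelectionError, UnderdeterminedFitError

__all__ = [
    "EACFit", "select_channels", "neighborhood", "fit_eac", "eac_channel_map",
    "global_eac", "distance_stratified_eac", "mu_eff_from_coefficients",
    "DEFAULT_FIT_WINDOW_MM", "DEFAULT_NEIGHBORHOOD_RADIUS_MM", "DEFAULT_DISTANCE_BINS_MM",
]

DEFAULT_FIT_WINDOW_MM = (20.0, 50.0)
DEFAULT_NEIGHBORHOOD_RADIUS_MM = 30.0
DEFAULT_DISTANCE_BINS_MM = ((15.0, 25.0), (25.0, 35.0), (35.0, 45.0), (45.0, 55.0))
MIN_FIT_CHANNELS = 5
MIN_DISTANCE_SPAN_MM = 10.0

# low-light is informational (dim channels remain valid shot-noise samples and
# excluding them would censor low-gain channels preferentially at long
# distances, tilting the slope); motion/rejected mark invalid data
_FLAG_COLS = ("motion", "rejected")


@dataclass
class EACFit:
    """One multi-distance slope fit."""

    mu_eff: float            # mm^-1
    k: float                 # intercept, absorbs gains/source power
    n_channels_used: int
    resid_sd: float
    distance_range_mm: tuple[float, float]
    wavelength_nm: float | None = None
    residuals: np.ndarray | None = None  # exposed for Gaussianity diagnostics


def _accepted_mask(samples: pd.DataFrame) -> np.ndarray:
    mask = np.ones(len(samples), dtype=bool)
    for col in _FLAG_COLS:
        if col in samples.columns:
            mask &= ~samples[col].to_numpy().astype(bool)
    mask &= np.isfinite(samples["y"].to_numpy())
    return mask


def select_channels(samples: pd.DataFrame, d_min: float = DEFAULT_FIT_WINDOW_MM[0],
                    d_max: float = DEFAULT_FIT_WINDOW_MM[1]) -> pd.DataFrame:
    """Retain unflagged SNR samples with ``d_min <= r <= d_max`` (inclusive)."""
    if not d_min < d_max:
        raise ValueError("d_min must be smaller than d_max")
    r = samples["distance_mm"].to_numpy()
    keep = (r >= d_min) & (r <= d_max) & _accepted_mask(samples)
    out = samples.loc[keep]
    if out.empty:
        raise EmptySelectionError(
            f"no acceptable channels with distance in [{d_min}, {d_max}] mm")
    return out.reset_index(drop=True)


def neighborhood(target: pd.Series | str, samples: pd.DataFrame,
                 radius_mm: float = DEFAULT_NEIGHBORHOOD_RADIUS_MM) -> pd.DataFrame:
    """Same-wavelength samples whose channel midpoint lies within ``radius_mm``.

    ``target`` is a row of the SNR table (or a channel_id present in it); the
    target itself is always included.  Membership is by Euclidean (chord)
    distance between channel midpoints, inclusive at the boundary.
    """
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if isinstance(target, str):
        rows = samples.loc[samples["channel_id"] == target]
        if rows.empty:
            raise KeyError(f"channel {target!r} not in the sample table")
        target = rows.iloc[0]
    same_wl = samples["wavelength_nm"].to_numpy() == target["wavelength_nm"]
    mids = samples[["mid_x_mm", "mid_y_mm", "mid_z_mm"]].to_numpy()
    t_mid = np.array([target["mid_x_mm"], target["mid_y_mm"], target["mid_z_mm"]])
    dist = np.linalg.norm(mids - t_mid, axis=1)
    keep = same_wl & (dist <= radius_mm + 1e-12)
    keep |= samples["channel_id"].to_numpy() == target["channel_id"]
    return samples.loc[keep].reset_index(drop=True)


def _ols_slope(r: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    r_mean, y_mean = r.mean(), y.mean()
    dr = r - r_mean
    slope = float(np.dot(dr, y - y_mean) / np.dot(dr, dr))
    intercept = float(y_mean - slope * r_mean)
    resid = y - (intercept + slope * r)
    return slope, intercept, resid


def fit_eac(samples: pd.DataFrame, min_channels: int = MIN_FIT_CHANNELS,
            min_span_mm: float = MIN_DISTANCE_SPAN_MM) -> EACFit:
    """OLS of ``y`` on ``r`` over the given samples; ``mu_eff = -slope``.

    Raises :class:`UnderdeterminedFitError` below ``min_channels`` samples or
    when the distances span less than ``min_span_mm``.
    """
    keep = _accepted_mask(samples)
    r = samples["distance_mm"].to_numpy()[keep]
    y = samples["y"].to_numpy()[keep]
    if len(r) < min_channels:
        raise UnderdeterminedFitError(f"{len(r)} samples < minimum fit size {min_channels}")
    span = float(r.max() - r.min())
    if span < min_span_mm:
        raise UnderdeterminedFitError(
            f"distance span {span:.1f} mm < required {min_span_mm} mm")
    slope, intercept, resid = _ols_slope(r, y)
    wl = samples["wavelength_nm"].to_numpy()[keep] if "wavelength_nm" in samples else None
    wavelength = float(wl[0]) if wl is not None and np.all(wl == wl[0]) else None
    resid_sd = float(np.std(resid, ddof=2)) if len(r) > 2 else 0.0
    return EACFit(
        mu_eff=-slope, k=intercept, n_channels_used=int(len(r)),
        resid_sd=resid_sd, distance_range_mm=(float(r.min()), float(r.max())),
        wavelength_nm=wavelength, residuals=resid,
    )


def global_eac(samples: pd.DataFrame, d_min: float = DEFAULT_FIT_WINDOW_MM[0],
               d_max: float = DEFAULT_FIT_WINDOW_MM[1]) -> dict[float, EACFit]:
    """One fit per wavelength over all acceptable channels in the fit window.

    Equivalent to a neighbourhood radius much larger than the head.
    """
    sel = select_channels(samples, d_min, d_max)
    out = {}
    for wl, group in sel.groupby("wavelength_nm"):
        out[float(wl)] = fit_eac(group)
    return out


def eac_channel_map(samples: pd.DataFrame,
                    radius_mm: float = DEFAULT_NEIGHBORHOOD_RADIUS_MM,
                    d_min: float = DEFAULT_FIT_WINDOW_MM[0],
                    d_max: float = DEFAULT_FIT_WINDOW_MM[1]) -> pd.DataFrame:
    """Per-channel EAC from the neighbourhood fit.

    Returns one row per accepted channel with columns ``mu_eff``, ``k``,
    ``n_used``, ``resid_sd`` and ``reason`` — underdetermined neighbourhoods
    yield NaN with a reason code instead of raising, so a cohort run never
    aborts on one bad channel.
    """
    sel = select_channels(samples, d_min, d_max)
    mids = sel[["mid_x_mm", "mid_y_mm", "mid_z_mm"]].to_numpy()
    r = sel["distance_mm"].to_numpy()
    y = sel["y"].to_numpy()
    wl = sel["wavelength_nm"].to_numpy()

    rows = []
    for w in np.unique(wl):
        iw = np.nonzero(wl == w)[0]
        m = mids[iw]
        # pairwise midpoint distances within this wavelength
        d2 = np.sum((m[:, None, :] - m[None, :, :]) ** 2, axis=2)
        within = d2 <= (radius_mm + 1e-12) ** 2
        for local_i, gi in enumerate(iw):
            nb = iw[within[local_i]]
            rr, yy = r[nb], y[nb]
            rec = {
                "channel_id": sel["channel_id"].iat[gi],
                "wavelength_nm": float(w),
                "distance_mm": float(r[gi]),
                "mid_x_mm": mids[gi, 0], "mid_y_mm": mids[gi, 1], "mid_z_mm": mids[gi, 2],
                "mu_eff": np.nan, "k": np.nan, "n_used": len(nb),
                "resid_sd": np.nan, "reason": "",
            }
            if len(rr) < MIN_FIT_CHANNELS or rr.max() - rr.min() < MIN_DISTANCE_SPAN_MM:
                rec["reason"] = "underdetermined"
            else:
                slope, intercept, resid = _ols_slope(rr, yy)
                rec.update(mu_eff=-slope, k=intercept,
                           resid_sd=float(np.std(resid, ddof=2)))
            rows.append(rec)
    return pd.DataFrame(rows)


def distance_stratified_eac(samples: pd.DataFrame,
                            bins: tuple[tuple[float, float], ...] = DEFAULT_DISTANCE_BINS_MM,
                            min_span_mm: float = 5.0) -> pd.DataFrame:
    """Independent EAC fit per source-detector-distance bin and wavelength.

    The default bins are the four 10 mm intervals 15-25, 25-35, 35-45,
    45-55 mm (deliberately wider than the 20-50 mm global window).  Because a
    10 mm bin cannot span 10 mm of distance internally, the minimum-span guard
    is relaxed to ``min_span_mm`` (default 5 mm) within a bin.  Bins with an
    underdetermined fit return NaN with a reason code.
    """
    keep = _accepted_mask(samples)
    sel = samples.loc[keep]
    rows = []
    for wl, group in sel.groupby("wavelength_nm"):
        r = group["distance_mm"].to_numpy()
        y = group["y"].to_numpy()
        for lo, hi in bins:
            m = (r >= lo) & (r <= hi)
            rec = {"wavelength_nm": float(wl), "d_min_mm": lo, "d_max_mm": hi,
                   "mu_eff": np.nan, "k": np.nan, "n_used": int(m.sum()),
                   "resid_sd": np.nan, "reason": ""}
            if m.sum() < MIN_FIT_CHANNELS or (m.any() and r[m].max() - r[m].min() < min_span_mm):
                rec["reason"] = "underdetermined"
            else:
                slope, intercept, resid = _ols_slope(r[m], y[m])
                rec.update(mu_eff=-slope, k=intercept,
                           resid_sd=float(np.std(resid, ddof=2)))
            rows.append(rec)
    return pd.DataFrame(rows)
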