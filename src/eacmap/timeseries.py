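"""Channel intensity time-series container and shot-noise simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import LatentSubject, SimulationConfig, relief_log_factor
from .diffusion import forward_intensity
from .montage import Montage

#: Poisson means are clamped here; above it shot noise is numerically negligible
#: anyway (relative variance < 1e-12) and the sampler stays stable.
_LAM_CLAMP = 1e12


@dataclass
class ChannelTimeSeries:
    """A block of raw (or processed) intensity samples for a set of channels.

    ``channels`` carries the montage metadata plus per-channel flag columns
    (``low_light``, ``motion``, ``rejected``); ``samples`` is an
    ``(n_channels, n_samples)`` array at fixed sampling rate.
    """

    channels: pd.DataFrame
    samples: np.ndarray
    rate_hz: float
    normalized: bool = False
    filtered: bool = False
    i_avg_raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[None, :]
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel table and sample array are inconsistent")
        for col in ("low_light", "motion", "rejected"):
            if col not in self.channels.columns:
                self.channels = self.channels.copy()
                self.channels[col] = False

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def i_avg(self) -> np.ndarray:
        """Mean intensity per channel over the block."""
        return self.samples.mean(axis=1)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def accepted(self) -> np.ndarray:
        return ~self.channels["rejected"].to_numpy()

    def copy_with(self, samples: np.ndarray, **kw) -> "ChannelTimeSeries":
        out = ChannelTimeSeries(
            self.channels.copy(), samples, self.rate_hz,
            normalized=kw.pop("normalized", self.normalized),
            filtered=kw.pop("filtered", self.filtered),
            i_avg_raw=kw.pop("i_avg_raw", self.i_avg_raw),
        )
        return out


def physiological_modulation(t: np.ndarray, config: SimulationConfig,
                             phases: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Multiplicative sub-10 Hz modulation: cardiac + respiratory + slow drift."""
    c = config
    m = (1.0
         + c.cardiac_amplitude * np.sin(2 * np.pi * c.cardiac_freq_hz * t + phases[0])
         + c.respiratory_amplitude * np.sin(2 * np.pi * c.respiratory_freq_hz * t + phases[1])
         + c.drift_amplitude * np.sin(2 * np.pi * c.drift_freq_hz * t + phases[2]))
    return m


def expected_channel_counts(subject: LatentSubject, montage: Montage,
                            config: SimulationConfig) -> np.ndarray:
    """Baseline expected counts per sample for every channel of the montage.

    The source amplitude per wavelength is set so that a gain-1 channel at the
    20 mm reference distance with the subject's base mu_eff would receive
    ``config.photon_budget`` counts per sample; a smooth topographic relief
    (amplitude ``config.relief_amplitude``) modulates the local mu_eff at each
    channel's midpoint.
    """
    ch = montage.channels
    r = ch["distance_mm"].to_numpy()
    wl = ch["wavelength_nm"].to_numpy()
    mids = ch[["mid_x_mm", "mid_y_mm", "mid_z_mm"]].to_numpy()
    log_relief = relief_log_factor(mids, config.relief_amplitude)
    gains = montage.channel_gains()

    counts = np.empty(len(ch))
    for w in np.unique(wl):
        sel = wl == w
        mu_base = subject.optical[float(w)].mu_eff
        amplitude = config.photon_budget * 20.0**2 * np.exp(mu_base * 20.0)
        mu_local = mu_base * np.exp(log_relief[sel])
        counts[sel] = forward_intensity(mu_local, r[sel], amplitude) * gains[sel]
    return counts


def simulate_timeseries(subject: LatentSubject, montage: Montage,
                        config: SimulationConfig, seed: int) -> ChannelTimeSeries:
    """Simulate one recording block for all channels of a montage.

    Each sample is Poisson around the channel baseline modulated by global
    physiological sinusoids (cardiac, respiratory, drift — all well below
    10 Hz).  Channels whose expected count drops below 1 per sample are kept
    but flagged ``low_light``.  Fixed seed => bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n = int(round(config.sampling_rate_hz * config.block_duration_s))
    t = np.arange(n) / config.sampling_rate_hz
    phases = tuple(rng.uniform(0, 2 * np.pi, 3))
    mod = physiological_modulation(t, config, phases)

    base = expected_channel_counts(subject, montage, config)
    lam = np.clip(base[:, None] * mod[None, :], 0.0, _LAM_CLAMP)
    samples = rng.poisson(lam).astype(float)

    channels = montage.channels.copy()
    channels["gain_product"] = montage.channel_gains()
    channels["low_light"] = base < 1.0
    channels["motion"] = False
    channels["rejected"] = False
    return ChannelTimeSeries(channels, samples, config.sampling_rate_hz)
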