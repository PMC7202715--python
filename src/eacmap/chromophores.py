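"""Hemoglobin extinction coefficients and the absorption forward model.

Molar extinction coefficients for oxy- and deoxy-hemoglobin are taken from the
standard Prahl/Cope compilation at the two laser-diode wavelengths used by
dual-wavelength CW-NIRS oximeters (690 and 830 nm, one on each side of the
hemoglobin isosbestic point near 800 nm).  Values are stored in
mm^-1 uM^-1 so that ``mu_a = ln(10) * eps * C`` with concentrations in uM
yields an absorption coefficient in mm^-1.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import UnsupportedWavelengthError

# Prahl/Cope compilation, molar extinction in cm^-1 / M; 1 cm^-1/M = 1e-7 mm^-1/uM.
_EXTINCTION_CM_PER_M = {
    # wavelength nm: (epsilon_HbO2, epsilon_HbR)
    690.0: (276.0, 2051.96),
    830.0: (974.0, 693.04),
}

#: molar extinction, mm^-1 uM^-1, keyed by wavelength in nm
EXTINCTION = {
    wl: (eps_o * 1e-7, eps_r * 1e-7) for wl, (eps_o, eps_r) in _EXTINCTION_CM_PER_M.items()
}

LN10 = math.log(10.0)


def extinction(wavelength_nm: float) -> tuple[float, float]:
    """Return ``(eps_HbO2, eps_HbR)`` in mm^-1 uM^-1 at a supported wavelength."""
    try:
        return EXTINCTION[float(wavelength_nm)]
    except KeyError:
        raise UnsupportedWavelengthError(
            f"no extinction data for {wavelength_nm} nm; supported: "
            f"{sorted(EXTINCTION)}"
        ) from None


def derive_mua(so2, total_hb_um, wavelength_nm: float, background: float = 0.0):
    """Absorption coefficient of hemoglobin-dominated tissue, mm^-1.

    Parameters
    ----------
    so2
        Tissue oxygen saturation, fraction in [0, 1].
    total_hb_um
        Total hemoglobin concentration (HbO2 + HbR), uM.
    wavelength_nm
        690 or 830.
    background
        Fixed wavelength-independent offset (water/lipid background), mm^-1.
        Defaults to 0.

    Notes
    -----
    ``mu_a = ln(10) * (eps_HbO * SO2 + eps_HbR * (1 - SO2)) * tHb + background``.
    This is the forward counterpart of the two-wavelength oxygenation
    inversion in :mod:`eacmap.spectral_oxygenation`.
    """
    so2 = np.asarray(so2, dtype=float)
    total_hb_um = np.asarray(total_hb_um, dtype=float)
    if np.any(so2 < 0.0) or np.any(so2 > 1.0):
        raise ValueError("SO2 must lie in [0, 1]")
    if np.any(total_hb_um < 0.0):
        raise ValueError("total hemoglobin must be non-negative")
    eps_o, eps_r = extinction(wavelength_nm)
    mua = LN10 * (eps_o * so2 + eps_r * (1.0 - so2)) * total_hb_um + background
    if mua.ndim == 0:
        return float(mua)
    return mua


def unmixing_matrix(wavelengths=(690.0, 830.0)) -> np.ndarray:
    """ln(10)-scaled extinction matrix mapping (C_HbO, C_HbR) in uM to mu_a in mm^-1."""
    rows = [extinction(wl) for wl in wavelengths]
    return LN10 * np.asarray(rows, dtype=float)
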