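"""Semi-infinite CW diffusion forward model.

In a semi-infinite homogeneous diffusive medium with zero boundary conditions,
the continuous-wave reflectance a distance ``r`` from a point source decays as
``exp(-mu_eff * r) / r**2``, where ``mu_eff`` is the effective attenuation
coefficient (EAC).  Consequently ``ln(I * r**2)`` is exactly linear in ``r``
with slope ``-mu_eff`` — the relationship the multi-distance estimator in
:mod:`eacmap.eac_estimator` inverts.
"""

from __future__ import annotations

import numpy as np


def mu_eff_from_coefficients(mu_a, mu_s_prime, mode: str = "exact"):
    """Effective attenuation coefficient from absorption and reduced scattering.

    ``exact``        : sqrt(3 * mu_a * (mu_a + mu_s'))
    ``approximate``  : sqrt(3 * mu_a * mu_s')   (valid when mu_a << mu_s')

    All coefficients in mm^-1.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_a < 0.0):
        raise ValueError("mu_a must be non-negative")
    if np.any(mu_s_prime < 0.0):
        raise ValueError("mu_s' must be non-negative")
    if mode == "exact":
        out = np.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))
    elif mode == "approximate":
        out = np.sqrt(3.0 * mu_a * mu_s_prime)
    else:
        raise ValueError(f"mode must be 'exact' or 'approximate', got {mode!r}")
    if out.ndim == 0:
        return float(out)
    return out


def mua_from_mu_eff(mu_eff, mu_s_prime):
    """Invert ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))`` for mu_a (positive root).

    Solves ``3 mu_a^2 + 3 mu_a mu_s' - mu_eff^2 = 0``.
    """
    mu_eff = np.asarray(mu_eff, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_eff < 0.0) or np.any(mu_s_prime <= 0.0):
        raise ValueError("require mu_eff >= 0 and mu_s' > 0")
    out = (-3.0 * mu_s_prime + np.sqrt(9.0 * mu_s_prime**2 + 12.0 * mu_eff**2)) / 6.0
    if out.ndim == 0:
        return float(out)
    return out


def forward_intensity(mu_eff, r_mm, amplitude):
    """Expected detected counts ``amplitude * exp(-mu_eff * r) / r**2``.

    Parameters
    ----------
    mu_eff
        Effective attenuation coefficient, mm^-1 (>= 0).
    r_mm
        Source-detector distance, mm (> 0).
    amplitude
        Source amplitude in expected counts at unit geometry (> 0).
    """
    mu_eff = np.asarray(mu_eff, dtype=float)
    r = np.asarray(r_mm, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("source-detector distance must be positive")
    if np.any(mu_eff < 0.0):
        raise ValueError("mu_eff must be non-negative")
    if np.any(amplitude <= 0.0):
        raise ValueError("amplitude must be positive")
    out = amplitude * np.exp(-mu_eff * r) / r**2
    if out.ndim == 0:
        return float(out)
    return out
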