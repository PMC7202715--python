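"""Forward model and the multi-distance EAC estimator on noise-free channels.

Builds a small cap montage, generates exact shot-noise-law SNR samples for a
homogeneous head, and recovers the effective attenuation coefficient from the
slope of ln(SNR^2 r^2) versus source-detector distance.
"""

import numpy as np

import eacmap as em

# the classic closed form: mu_eff = sqrt(3 mu_a (mu_a + mu_s'))
mu_a, musp = 0.0144, 0.830
print(f"mu_a = {mu_a} mm^-1, mu_s' = {musp} mm^-1")
print(f"  exact EAC       = {em.mu_eff_from_coefficients(mu_a, musp):.4f} mm^-1")
print(f"  approximate EAC = {em.mu_eff_from_coefficients(mu_a, musp, 'approximate'):.4f} mm^-1")
print("  (the approximate form drops mu_a against mu_s'; both are printed in mm^-1)")

montage = em.generate_montage(64, 24, head_radius_mm=90.0, seed=1, gain_sigma=0.0)
truth = {690.0: 0.192, 830.0: 0.170}

ch = montage.channels
r = ch["distance_mm"].to_numpy()
mu = np.array([truth[w] for w in ch["wavelength_nm"]])
counts = em.forward_intensity(mu, r, 1e6)  # expected counts per sample
snr = ch[["channel_id", "wavelength_nm", "distance_mm",
          "mid_x_mm", "mid_y_mm", "mid_z_mm"]].copy()
snr["snr"] = np.sqrt(counts)               # shot-noise law: SNR^2 = counts
snr["y"] = np.log(counts * r**2)
snr["low_light"] = snr["motion"] = snr["rejected"] = False

fits = em.global_eac(snr)                   # 20-50 mm window, one fit per wavelength
print(f"\nmontage: {len(ch)} channels ({montage.n_channels(690.0)} per wavelength)")
for wl, fit in fits.items():
    print(f"  {wl:.0f} nm: mu_eff = {fit.mu_eff:.6f} mm^-1 "
          f"(truth {truth[wl]}), k = {fit.k:.3f}, n = {fit.n_channels_used}")
print("noise-free channels recover the decay rate to numerical precision;")
print("the intercept k absorbs source power, detector efficiency and coupling.")
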