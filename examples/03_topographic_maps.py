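"""Per-channel EAC maps projected onto the circular head template.

Runs neighbourhood-based estimation for one subject, flattens channel
midpoints with the azimuthal-equidistant projection and interpolates a
64 x 64 disk raster; then prints where the head is most and least opaque.
"""

import numpy as np

import eacmap as em

cfg = em.SimulationConfig(n_subjects=2, master_seed=3)
cohort = em.generate_cohort(cfg)
fits, cmap, snr = em.estimate_subject(cohort, 0)

sub = cmap[(cmap["wavelength_nm"] == 830.0) & (cmap["reason"] == "")]
print(f"channel map at 830 nm: {len(sub)} channels with a neighbourhood fit "
      f"(30 mm radius, median {int(sub['n_used'].median())} channels per fit)")

proj = em.project_to_disk(sub[["mid_x_mm", "mid_y_mm", "mid_z_mm"]].to_numpy())
gm = em.interpolate_map(proj, sub["mu_eff"].to_numpy(), grid_n=64)
vals = gm.values[gm.valid]
print(f"interpolated disk map: {int(gm.valid.sum())} valid pixels")
print(f"  EAC range {vals.min():.3f} - {vals.max():.3f} mm^-1 "
      f"({100 * (vals.max() - vals.min()) / vals.mean():.0f}% spread)")

# dorsal (disk centre) vs frontal rim (anterior = +x half of the rim)
xs = np.linspace(-1, 1, 64)
gx, gy = np.meshgrid(xs, xs, indexing="xy")
rho = np.hypot(gx, gy)
centre = gm.valid & (rho < 0.4)
front = gm.valid & (rho > 0.75) & (gx > 0.3)
print(f"  dorsal mean {np.nanmean(gm.values[centre]):.3f} mm^-1 vs "
      f"frontal rim {np.nanmean(gm.values[front]):.3f} mm^-1")
print("dorsal/occipital regions are more opaque than frontal/lateral ones,")
print("the topography the generator's relief encodes and the map recovers.")
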