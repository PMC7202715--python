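"""Simulate one subject's raw optical recording and preprocess it to SNR.

Shows the generator's noise structure (Poisson shot noise plus sub-10 Hz
physiological modulations) and the fixed preprocessing order:
normalize -> movement-correct -> high-pass (10 Hz) -> SNR.
"""

import numpy as np

import eacmap as em

cfg = em.SimulationConfig(n_subjects=2, master_seed=7)
cohort = em.generate_cohort(cfg)
subject = cohort.subjects[0]
print(f"subject {subject.subject_id}: age {subject.age:.1f} y, "
      f"SO2 {subject.so2:.2f}, thickness {subject.thickness_mm:.2f} mm")
print(f"  true EAC: 690 nm {subject.optical[690.0].mu_eff:.4f} mm^-1, "
      f"830 nm {subject.optical[830.0].mu_eff:.4f} mm^-1")

ts = cohort.simulate_timeseries(0)  # first helmet placement, one 30 s block
print(f"\nraw block: {ts.samples.shape[0]} channels x {ts.n_samples} samples "
      f"at {ts.rate_hz:.4f} Hz")
print(f"  low-light channels (< 1 expected count/sample): "
      f"{int(ts.channels['low_light'].sum())}")

snr = em.preprocess_block(ts)
ok = snr[~snr["rejected"]]
print(f"\nSNR table: {len(ok)} usable channels")
window = ok[ok["distance_mm"].between(20, 50)]
print(f"  in the 20-50 mm fit window: {len(window)}")
print("  example rows (y = ln(SNR^2 r^2) decays linearly with distance):")
for _, row in window.sort_values("distance_mm").iloc[[0, len(window) // 2, -1]].iterrows():
    print(f"    r = {row.distance_mm:5.1f} mm   SNR = {row.snr:8.1f}   y = {row.y:6.2f}")

fits = em.global_eac(snr)
for wl in (690.0, 830.0):
    est, tru = fits[wl].mu_eff, subject.optical[wl].mu_eff
    print(f"  {wl:.0f} nm: estimated mu_eff {est:.4f} mm^-1 "
          f"({100 * abs(est - tru) / tru:.1f}% from the homogeneous-base truth)")
print("the estimate tracks the generator's opacity despite order-of-magnitude")
print("optode gain heterogeneity, because gains are distance-independent;")
print("the full session pools four helmet placements, tightening this further.")
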