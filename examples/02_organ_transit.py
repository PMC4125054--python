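"""Within-organ transit: Brownian first passage in LN sphere and spleen disc.

The LN sphere radius is calibrated so that a 60 µm²/min random walk from
the center takes 13.5 h on average to reach the absorbing surface; the
spleen cross-section's absorbing aperture is calibrated to a 6 h mean.
Both distributions show an initial lag (no immediate egress), unlike an
exponential dwell model.
"""

import numpy as np

from tcellsim import geometry

ln = geometry.default_ln_sphere()
print(f"LN sphere: radius {ln.radius:.0f} µm, motility {ln.motility:.0f} µm²/min")
print(f"  analytic mean transit: {geometry.ln_mean_transit(ln):.2f} h")

rng = np.random.default_rng(2)
series = geometry.sample_ln_transit(ln, rng, size=50_000)
print(f"  eigen-series sampler : {np.mean(series):.2f} h mean, "
      f"1st percentile {np.percentile(series, 1):.2f} h (egress lag)")

walks = geometry.sample_ln_transit_brownian(ln, rng, n=2000, dt=0.1)
print(f"  explicit Brownian oracle (2000 walks): {np.mean(walks):.2f} h mean")

spleen = geometry.default_spleen_section()
print(f"\nSpleen disc: radius {spleen.radius:.0f} µm, "
      f"aperture {spleen.aperture_angle:.3f} rad (calibrated)")
transits = geometry.simulate_spleen_transits(spleen, 2000, rng, dt=0.1)
print(f"  simulated mean transit: {np.mean(transits):.2f} h, "
      f"P(exit < 0.5 h) = {np.mean(transits < 0.5):.3f}")

print(
    "\nThe two means (13.5 h LN, 6 h spleen) match classic physiological dwell"
    "\ntimes; the near-zero early-exit probabilities are the 'lag time' that"
    "\ndistinguishes spatial first passage from exponential egress."
)
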