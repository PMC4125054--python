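"""Signal integration vs probabilistic priming: retention-time laws.

Both models share a mean phase-I duration of 8 h at one cognate DC
encounter per hour, but signal integration (8 required contacts) produces a
switch-like retention curve while probabilistic priming (1/8 success per
contact) retains gradually from the start.
"""

import numpy as np

from tcellsim import PrimingParams, RetentionLaw, retention_cdf, sample_retention_time

si = PrimingParams.signal_integration(required_contacts=8, contact_rate=1.0)
pp = PrimingParams.probabilistic(success_prob=1 / 8, contact_rate=1.0)

rng = np.random.default_rng(1)
for name, params in [("signal integration", si), ("probabilistic priming", pp)]:
    law = RetentionLaw(params)
    draws = sample_retention_time(params, rng, size=50_000)
    print(
        f"{name:22s} mean {law.mean:.2f} h (MC {np.mean(draws):.2f} h), "
        f"sd {np.sqrt(law.variance):.2f} h"
    )

print("\nretained fraction by time post LN entry:")
print("  t(h)   signal-int   probabilistic")
for t in (1, 2, 4, 6, 8, 12, 16):
    print(f"  {t:4d}   {retention_cdf(t, si):10.3f}   {retention_cdf(t, pp):12.3f}")

print(
    "\nEqual means, different shapes: probabilistic priming retains more cells"
    "\nearly (gradual) while signal integration overtakes it after ~8 h"
    "\n(switch-like), and its spread is sqrt(8) times smaller."
)
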