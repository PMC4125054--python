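"""Capture times: how fast circulating cognate cells are caught in dLNs.

For an infection affecting 25% of LN spheres with signal-integration
priming (one encounter per hour), the expected capture time is computed in
closed form for fixed LN transit times, minimized over the transit time,
and compared against stochastic (first-passage) transit.
"""

import numpy as np

from tcellsim import (
    CaptureScenario,
    PrimingParams,
    TransitMode,
    capture_time_mc,
    expected_capture_time,
    optimal_transit_time,
)
from tcellsim.capture import benefit_risk_matrix

si8 = PrimingParams.signal_integration(8.0, 1.0)
print("deterministic LN transit, f = 0.25, 8 required contacts:")
for t_det in (6.0, 12.0, 24.0):
    scen = CaptureScenario(0.25, si8, TransitMode.deterministic(t_det))
    sol = expected_capture_time(scen)
    print(f"  T_det = {t_det:4.0f} h → E[capture] = {sol.expected_capture/24:.1f} d "
          f"(P per dLN visit {sol.retention_prob:.3f}, "
          f"{sol.expected_failed_visits:.1f} failed LN visits)")

for n in (2.0, 8.0):
    topt = optimal_transit_time(0.25, PrimingParams.signal_integration(n, 1.0))
    print(f"optimal fixed transit for {n:.0f} contacts: {topt:.1f} h")

scen_st = CaptureScenario(0.25, si8, TransitMode.stochastic())
mc = capture_time_mc(scen_st, 800, np.random.default_rng(6))
print(f"stochastic transit (13.5 h mean dwell): {np.mean(mc)/24:.1f} d mean capture")

print("\nbenefit/risk of tuning the transit time (fold vs stochastic transit):")
m = benefit_risk_matrix([2], [2, 10], 0.25)
print(m.round(2).to_string())
print(
    "\nTransit tuned for a 2-contact antigen detects it faster than stochastic"
    "\ntransit (ratio < 1) but is dozens of times slower on a 10-contact dose:"
    "\nstochastic LN transit is the robust strategy."
)
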