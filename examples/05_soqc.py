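"""Self-organized quasi-criticality via homeostatic weight scaling.

Starts a network far from criticality (mean weight 0.5 mV, five times the
critical value) and lets the local rule

    <W> <- <W> * (1 - gamma * (2*#spikes - N) / N)

act once per refractory period: windows in which more than half the
neurons fire shrink the weights, quiet windows inflate them.  The weight
trajectory hovers around the closed-form critical weight without ever
being told its value.
"""

import numpy as np

import lifcrit as lc

cfg = lc.SoqcConfig(
    params=lc.soqc_params(threshold=10.0, ri=2.0),
    gamma=0.1,
    initial_mean_weight=0.5,
    n_updates=2000,
    seed=1,
)
traj = lc.run_soqc(cfg)

print("update     <W> (mV)")
for u in range(0, 2001, 250):
    print(f"{u:>6} {traj.mean_weights[u]:>12.4f}")

print(f"\nclosed-form W_crit    = {traj.w_critical:.4f} mV")
print(f"settled weight        = {traj.settled_weight:.4f} mV (median of trailing 25%)")
print(f"final relative error  = {traj.final_relative_error:.3f}")
print(
    "\nThe rule needs no knowledge of the critical point, yet the dynamics "
    "settle within a\nfew percent of it: a minimal model of self-organized "
    "quasi-criticality."
)
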