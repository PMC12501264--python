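"""Spike-count phase transition across the critical weight.

Sweeps the mean synaptic weight across the closed-form critical value and
reports the median total spike count per run.  The count jumps by more than
an order of magnitude between the subcritical and supercritical sides —
the signature of the order/disorder transition.
"""

import lifcrit as lc

params = lc.methods_params()
wc = lc.critical_weight(params)
grid = [0.7 * wc, 0.9 * wc, 1.0 * wc, 1.1 * wc, 1.3 * wc]

res = lc.sweep(params, "spike_count", grid, n_reps=4, seed=0, n_steps=10_000)

print(f"W_crit = {wc:.4f} mV; T = 10000 steps (1 s), medians over 4 replicates\n")
print(f"{'W/W_crit':>9} {'median spike count':>19}")
for w, m in zip(res.weight_grid, res.medians):
    print(f"{w / wc:>9.2f} {m:>19.0f}")

max_count = params.n_neurons * 10_000 // (params.refractory_steps + 1)
print(f"\nrefractory-limited maximum: {max_count} spikes")
print(
    "Supercritical counts approach that ceiling while subcritical activity "
    "stays one to two\norders of magnitude below it."
)
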