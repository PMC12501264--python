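"""Closed-form critical point of a LIF reservoir.

Builds the reference configuration (1000 neurons, 5 mV threshold, 1 ms
refractory period, one 1 mV external kick somewhere in the network every
0.01 ms, 10% connectivity, leak 0.01/ms), checks the three validity
conditions of the mean-field analysis, and prints the critical mean
synaptic weight and critical mean inter-spike interval.
"""

import lifcrit as lc

params = lc.methods_params()
report = lc.check_validity(params)

print("validity conditions:")
print(f"  alpha*tau_ref            = {report.leak_refractory_value:g}  (< 0.5: {report.cond_leak_refractory})")
print(f"  theta*tau*N/(RI*tau_ref) = {report.drive_ratio_value:g}  (>= 2: {report.cond_drive_ratio})")
print(f"  theta*tau*N*alpha/RI     = {report.leak_drive_value:g}  (< 1: {report.cond_leak_drive})")

cp = lc.critical_point(params)
print(f"\ncritical mean weight W_crit = {cp.w_critical:.4f} mV")
print(f"critical mean ISI           = {cp.isi_critical:.2f} ms")
print(
    "\nInitializing synaptic weights at W_crit places the reservoir at the "
    "order/disorder transition:\nbelow it activity is sparse and prone to "
    "extinction, above it firing saturates at the\nrefractory-period limit."
)
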