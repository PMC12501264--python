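"""Numba-compiled inner loops: LIF stepping and LZW dictionary growth."""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import Dict


@njit(cache=True)
def lif_steps(
    indptr,
    indices,
    data,
    ri_per_neuron,
    theta,
    decay,
    n_ref_steps,
    n_events,
    n_steps,
    seed,
    buffer_refractory,
    poisson_events,
    events_lambda,
    v,
    refr,
    prev_spiked,
    record,
):
    """Advance the LIF network ``n_steps`` steps, recording spikes.

    Per step: (1) potentials decay by ``decay``; (2) ``n_events`` external
    kicks land on uniformly chosen neurons; (3) spikes of the previous step
    arrive through the weight matrix (CSC arrays: column j lists the
    targets of presynaptic neuron j); (4) non-refractory neurons at or
    above threshold fire, reset to 0 and stay refractory for
    ``n_ref_steps`` subsequent steps.

    With ``buffer_refractory`` true (the default model), refractory neurons
    keep integrating inputs — they just cannot fire until the refractory
    clock runs out.  With it false, refractory neurons discard all inputs
    and their potential stays clamped at 0.  State arrays ``v``, ``refr``,
    ``prev_spiked`` are updated in place so windowed callers can resume.
    """
    np.random.seed(seed)
    n = v.shape[0]
    for t in range(n_steps):
        for i in range(n):
            if buffer_refractory or refr[i] == 0:
                v[i] *= decay
        n_ev = n_events
        if poisson_events:
            n_ev = np.random.poisson(events_lambda)
        for _ in range(n_ev):
            tgt = np.random.randint(0, n)
            if buffer_refractory or refr[tgt] == 0:
                v[tgt] += ri_per_neuron[tgt]
        for j in range(n):
            if prev_spiked[j] == 1:
                for k in range(indptr[j], indptr[j + 1]):
                    i2 = indices[k]
                    if buffer_refractory or refr[i2] == 0:
                        v[i2] += data[k]
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                prev_spiked[i] = 0
            elif v[i] >= theta:
                record[i, t] = 1
                v[i] = 0.0
                refr[i] = n_ref_steps
                prev_spiked[i] = 1
            else:
                prev_spiked[i] = 0
    return 0


@njit(cache=True)
def lzw_added_patterns(bits):
    """Number of entries LZW adds to a dictionary seeded with {"0", "1"}.

    Phrases are encoded as integer codes; the pair (prefix code, next bit)
    maps to the key ``(code << 1) | bit``, which is unique per pair.
    """
    n = bits.shape[0]
    if n == 0:
        return -1
    table = Dict.empty(types.int64, types.int64)
    w = np.int64(bits[0])
    next_code = np.int64(2)
    added = 0
    for i in range(1, n):
        b = np.int64(bits[i])
        key = (w << 1) | b
        if key in table:
            w = table[key]
        else:
            table[key] = next_code
            next_code += 1
            added += 1
            w = b
    return added
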