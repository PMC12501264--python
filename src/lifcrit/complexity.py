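"""Lempel-Ziv-Welch complexity of binary spike trains.

The complexity of a raster is the number of new patterns the LZW compressor
adds to its dictionary (seeded with the single symbols "0" and "1") while
encoding the concatenation of all neurons' time series.  A random
Bernoulli(0.5) string of the same length acts as the empirical ceiling: the
normalized complexity divides by the mean dictionary growth over ``n_null``
such strings, so values near 1 mean near-maximal information density and
values near 0 mean highly compressible (ordered or silent) activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._kernels import lzw_added_patterns
from .simulator import SpikeRaster

__all__ = ["ComplexityResult", "lzw_complexity", "raster_complexity"]

DEFAULT_N_NULL = 8


@dataclass(frozen=True)
class ComplexityResult:
    dictionary_length: int
    normalized: float
    sequence_length: int


def _as_bits(bits) -> np.ndarray:
    arr = np.asarray(bits)
    if arr.dtype.kind in "US":  # allow "0101" strings for convenience
        arr = np.frombuffer(str(bits).encode(), np.uint8) - ord("0")
    arr = np.ascontiguousarray(arr, np.uint8)
    if arr.size == 0:
        raise ValueError("empty sequence has no LZW complexity")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("sequence must be binary")
    return arr


def lzw_complexity(bits) -> int:
    """Number of patterns LZW adds while encoding a binary sequence.

    Accepts a 0/1 array or a "0101..."-style string.  The two single-symbol
    seed entries are not counted.
    """
    return int(lzw_added_patterns(_as_bits(bits)))


@lru_cache(maxsize=32)
def _null_complexity(length: int, n_null: int, seed: int) -> tuple[float, float]:
    """Mean and std of LZW complexity over Bernoulli(0.5) strings."""
    rng = np.random.default_rng(seed)
    vals = [
        lzw_added_patterns(rng.integers(0, 2, size=length, dtype=np.uint8))
        for _ in range(n_null)
    ]
    return float(np.mean(vals)), float(np.std(vals))


def raster_complexity(
    raster: SpikeRaster,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    time_major: bool = False,
) -> ComplexityResult:
    """Normalized LZW complexity of a spike raster.

    Rows of S are concatenated in neuron-index order (neuron 0's full time
    series, then neuron 1's, ...) into one N*T bitstring; ``time_major=True``
    concatenates columns instead (sensitivity analysis).  ``normalized`` is
    the dictionary growth divided by its mean over ``n_null`` seeded
    Bernoulli(0.5) strings of equal length.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    s = raster.spikes.T if time_major else raster.spikes
    bits = np.ascontiguousarray(s.reshape(-1), np.uint8)
    if bits.size == 0:
        raise ValueError("empty raster")
    raw = int(lzw_added_patterns(bits))
    null_mean, _ = _null_complexity(bits.size, n_null, seed)
    return ComplexityResult(
        dictionary_length=raw,
        normalized=raw / null_mean,
        sequence_length=int(bits.size),
    )
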