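"""Fixed 64-bit integer hash used for k-mer sketching.

The sketch layer needs a deterministic, well-mixing 64-bit hash over 2-bit
encoded k-mers. We use the splitmix64 finalizer (Steele, Lea & Flood 2014),
which is invertible (no collisions on 64-bit inputs) and passes standard
avalanche tests. Implemented over numpy uint64 arrays; unsigned arithmetic
wraps, which is exactly the intended modular behaviour.
"""

from __future__ import annotations

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Apply the splitmix64 finalizer elementwise to a uint64 array."""
    z = x.astype(np.uint64, copy=True)
    z += _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))
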