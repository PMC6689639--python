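"""Uniform sampling without replacement with a fixed draw protocol.

All d-subset samples in the model (death, birth, grant applicants) go
through this partial Fisher–Yates shuffle driven by a single vector of
``d`` uniforms. Keeping the draw protocol fixed and minimal lets the
compiled engine kernel replay exactly the same random stream as the
pure-numpy stage functions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_without_replacement"]


def sample_without_replacement(
    n: int, d: int, rng: np.random.Generator
) -> np.ndarray:
    """A uniformly random ``d``-subset of ``range(n)``, in random order.

    Consumes exactly one ``rng.random(d)`` vector.
    """
    u = rng.random(d)
    pool = np.arange(n)
    for i in range(d):
        j = i + int(u[i] * (n - i))
        pool[i], pool[j] = pool[j], pool[i]
    return pool[:d]
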