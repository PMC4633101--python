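"""Reference series with known properties, used to validate the estimators.

The Hénon map is the standard low-dimensional chaotic benchmark (correlation
dimension ~ 1.2); a Gaussian AR(2) process realises the linear-stochastic
null hypothesis the surrogate test must retain.
"""

from __future__ import annotations

import numpy as np


def henon_series(n: int, seed: int = 0, a: float = 1.4, b: float = 0.3,
                 discard: int = 1000) -> np.ndarray:
    """x-series of the Hénon map; the seed perturbs the initial condition."""
    rng = np.random.default_rng(seed)
    x, y = 0.1 + 0.01 * rng.random(), 0.1
    out = np.empty(n + discard)
    for i in range(n + discard):
        x, y = 1.0 - a * x * x + y, b * x
        out[i] = x
    return out[discard:]


def ar2_series(n: int, seed: int = 0, phi1: float = 0.6, phi2: float = -0.3,
               discard: int = 500) -> np.ndarray:
    """Stationary Gaussian AR(2): x_t = phi1 x_{t-1} + phi2 x_{t-2} + e_t."""
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n + discard)
    x = np.zeros(n + discard)
    for t in range(2, n + discard):
        x[t] = phi1 * x[t - 1] + phi2 * x[t - 2] + e[t]
    return x[discard:]
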