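"""Statistical functionals used to summarize descriptor sequences.

Every hand-crafted descriptor sequence (per frame, per transition or per
voiced segment) is reduced to four numbers: mean, standard deviation,
skewness and Fisher kurtosis (normal distribution -> 0).  Degenerate
sequences (zero variance or fewer than two values) get skewness and
kurtosis of 0 by convention so feature vectors stay finite.
"""

from __future__ import annotations

import numpy as np

FUNCTIONAL_NAMES = ("mean", "std", "skew", "kurt")

__all__ = ["FUNCTIONAL_NAMES", "functionals"]


def functionals(values: np.ndarray) -> np.ndarray:
    """Return (mean, std, skewness, Fisher kurtosis) of a 1-D sequence."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        return np.zeros(4)
    mean = float(x.mean())
    std = float(x.std())
    if x.size < 2 or std < 1e-12:
        return np.array([mean, 0.0, 0.0, 0.0])
    z = (x - mean) / std
    skew = float(np.mean(z**3))
    kurt = float(np.mean(z**4) - 3.0)
    return np.array([mean, std, skew, kurt])
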