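"""Target standardization fit on training data only."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Standardizer:
    """Affine map y -> (y - mean) / sd with its exact inverse.

    Fitted on training targets only; the same constants are applied to any
    later predictions so callers always see the original yield units.
    """

    mean: float
    sd: float

    @classmethod
    def fit(cls, train_y) -> "Standardizer":
        y = np.asarray(train_y, dtype=np.float64).ravel()
        if y.size < 2 or np.unique(y).size < 2:
            raise ValueError("standardization requires >= 2 distinct training values")
        return cls(mean=float(y.mean()), sd=float(y.std()))

    def transform(self, y):
        return (np.asarray(y, dtype=np.float64) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=np.float64) * self.sd + self.mean

    def inverse_variance(self, v):
        return np.asarray(v, dtype=np.float64) * self.sd**2


def standardizer(train_y):
    """Return ``(transform, inverse)`` closures fitted on ``train_y``.

    The transform maps the training targets to zero mean and unit variance;
    ``inverse`` undoes it exactly.  Raises on constant input.
    """
    s = Standardizer.fit(train_y)
    return s.transform, s.inverse
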