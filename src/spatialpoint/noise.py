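"""Angular shot-noise families.

Within a trial cell, shots are modelled as the model-predicted direction
plus an independent angular deviation.  Two circular families are supported
and always named in outputs, since results can depend on the choice:

* ``wrapped_gaussian`` — a normal deviate in degrees, wrapped to (−180, 180].
  Its log-density is evaluated with the nearest-image normal term only,
  which is accurate to well below 1e-6 for spreads up to ~30°.
* ``von_mises`` — the circular exponential family with concentration κ;
  κ is derived from the requested spread as κ = 1/σ² (σ in radians).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import wrap_angle

__all__ = ["NoiseSpec", "NOISE_FAMILIES"]

NOISE_FAMILIES = ("wrapped_gaussian", "von_mises")


@dataclass(frozen=True)
class NoiseSpec:
    """Family and spread of the within-cell angular shot noise."""

    family: str = "wrapped_gaussian"
    sd_deg: float = 8.0

    def __post_init__(self):
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; have {NOISE_FAMILIES}")
        if not self.sd_deg > 0:
            raise ValueError("noise spread must be positive")

    @property
    def kappa(self) -> float:
        """Von Mises concentration matched to the requested spread."""
        return 1.0 / math.radians(self.sd_deg) ** 2

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        """Angular deviations in degrees, wrapped to (−180, 180]."""
        if self.family == "wrapped_gaussian":
            dev = rng.normal(0.0, self.sd_deg, size=size)
        else:
            dev = np.degrees(rng.vonmises(0.0, self.kappa, size=size))
        return wrap_angle(dev)

    def logpdf(self, dev_deg) -> np.ndarray:
        """Log density (per degree) of wrapped angular deviations."""
        d = wrap_angle(np.asarray(dev_deg, dtype=float))
        if self.family == "wrapped_gaussian":
            return -0.5 * (d / self.sd_deg) ** 2 - math.log(self.sd_deg * math.sqrt(2.0 * math.pi))
        return stats.vonmises.logpdf(np.radians(d), self.kappa) + math.log(math.pi / 180.0)
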