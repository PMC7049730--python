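"""Noise models for the synthetic-data generators.

A :class:`NoiseSpec` names one of four error models and carries its scale.
``gaussian_constant`` adds homoscedastic Gaussian noise of absolute standard
deviation ``sigma``; ``gaussian_proportional`` adds Gaussian noise whose
standard deviation is ``sigma`` times the local signal magnitude (the usual
shot-to-shot model for normalised optical traces); ``poisson`` treats the
signal as expected counts and draws Poisson variates; ``none`` returns the
noiseless model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSpec", "NOISE_KINDS"]

NOISE_KINDS = ("none", "gaussian_constant", "gaussian_proportional", "poisson")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model specification.

    Parameters
    ----------
    kind : str
        One of ``none``, ``gaussian_constant``, ``gaussian_proportional``,
        ``poisson``.
    sigma : float
        Noise scale. Absolute units for ``gaussian_constant``, fraction of
        the signal for ``gaussian_proportional``; ignored for ``poisson``
        and ``none``.
    """

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}")
        if self.sigma < 0:
            raise ValueError("noise sigma must be nonnegative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Return a noisy copy of *values* drawn with *rng*."""
        values = np.asarray(values, dtype=float)
        if self.kind == "none":
            return values.copy()
        if self.kind == "gaussian_constant":
            return values + rng.normal(0.0, self.sigma, size=values.shape)
        if self.kind == "gaussian_proportional":
            return values + rng.normal(0.0, 1.0, size=values.shape) * self.sigma * np.abs(values)
        # poisson: signal interpreted as expected counts
        if np.any(values < 0):
            raise ValueError("poisson noise requires a nonnegative signal")
        return rng.poisson(values).astype(float)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "sigma": self.sigma}
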