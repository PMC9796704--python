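"""Parameter containers shared by the simulator and the sampler."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .kernel import DispersalParams, ExtinctionParams

__all__ = ["DetectionParams", "ModelIndicators", "SPOMParameters"]


@dataclass
class DetectionParams:
    """Year-specific detection probabilities as logit-normal random effects.

    logit p_t ~ Normal(mu_p, sigma_p); ``p_t`` holds realized values when
    known (simulation truth) or sampled values (posterior draws).
    """

    mu_p: float = 0.0
    sigma_p: float = 1.0
    p_t: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.sigma_p < 0:
            raise ValueError("sigma_p must be non-negative")
        if self.p_t is not None:
            self.p_t = np.asarray(self.p_t, dtype=float)
            if np.any((self.p_t <= 0) | (self.p_t >= 1)):
                raise ValueError("p_t must lie in (0, 1)")

    def realize(self, T: int, rng: np.random.Generator) -> np.ndarray:
        """Draw p_t for T years from the logit-normal hyper distribution."""
        return expit(rng.normal(self.mu_p, self.sigma_p, size=T))


@dataclass
class ModelIndicators:
    """Binary model-structure indicators for Gibbs variable selection.

    ``I_z`` switches demographic (occupancy) weighting on, ``I_D`` switches
    year-varying dispersal random effects on; (I_z, I_D) maps onto the
    UI/UV/DI/DV model taxonomy.
    """

    I_z: int = 0
    I_D: int = 0

    def __post_init__(self):
        if self.I_z not in (0, 1) or self.I_D not in (0, 1):
            raise ValueError("indicators must be 0 or 1")

    @property
    def label(self) -> str:
        return {(0, 0): "UI", (0, 1): "UV", (1, 0): "DI", (1, 1): "DV"}[
            (self.I_z, self.I_D)
        ]


@dataclass
class SPOMParameters:
    """All model unknowns of the dynamic occupancy SPOM."""

    psi1: float
    extinction: ExtinctionParams
    dispersal: DispersalParams
    detection: DetectionParams = field(default_factory=DetectionParams)
    indicators: Optional[ModelIndicators] = None

    def __post_init__(self):
        if not 0 <= self.psi1 <= 1:
            raise ValueError("psi1 must lie in [0, 1]")
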