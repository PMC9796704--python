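"""Deterministic model core: connectivity, colonization, extinction.

The four model variants cross two binary assumptions:

* **occupancy weighting** — connectivity sums over occupied source
  patches only (demographic weighting, models DI/DV) or treats every
  patch as a source (structural assumption z ≡ 1, models UI/UV);
* **time-varying dispersal** — the kernel scale α (km⁻¹) and effective
  dispersal rate β are year-specific random effects (UV/DV) or static
  (UI/DI).

Connectivity of patch i is the incidence-function aggregate

    S_i = β · Σ_{j≠i} A_j z_j exp(−α d_ij),

with source-patch weighting A_j z_j (each source contributes its own
length, switched off when it is empty).  Colonization is
γ = 1 − exp(−S), extinction is logit⁻¹(δ0 + δ1 A_i), and occupancy
evolves as a patch-level Markov chain:
ψ = γ if the patch was empty, 1 − ε if it was occupied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "ALL_ONES",
    "ModelSpec",
    "DispersalParams",
    "ExtinctionParams",
    "connectivity_vector",
    "colonization_prob",
    "extinction_prob",
    "transition_prob",
]

#: Sentinel occupancy vector: the structural assumption z ≡ 1 (models UI/UV).
ALL_ONES = "all_ones"

_LABELS = {(False, False): "UI", (False, True): "UV", (True, False): "DI", (True, True): "DV"}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four connectivity formulations.

    ``weighted`` toggles demographic (occupancy) weighting, ``time_varying``
    toggles year-specific dispersal random effects.  The label is the
    standard two-letter code: U/D for unweighted/demographically weighted,
    I/V for time-invariant/time-varying.
    """

    weighted: bool = False
    time_varying: bool = False

    @property
    def label(self) -> str:
        return _LABELS[(self.weighted, self.time_varying)]

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        label = label.upper()
        for flags, lab in _LABELS.items():
            if lab == label:
                return cls(weighted=flags[0], time_varying=flags[1])
        raise ValueError(f"unknown model label {label!r}; expected UI/UV/DI/DV")


@dataclass
class DispersalParams:
    """Dispersal kernel scale α (km⁻¹) and effective dispersal rate β.

    For time-varying models ``alpha_t``/``beta_t`` hold one value per
    transition year (into years 2..T); ``sigma_alpha``/``sigma_beta`` are
    the random-effect SDs of the log-scale deviates.
    """

    alpha: float
    beta: float
    alpha_t: Optional[np.ndarray] = None
    beta_t: Optional[np.ndarray] = None
    sigma_alpha: float = 0.0
    sigma_beta: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.sigma_alpha < 0 or self.sigma_beta < 0:
            raise ValueError("random-effect SDs must be non-negative")
        for name in ("alpha_t", "beta_t"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v <= 0) and name == "alpha_t":
                    raise ValueError("alpha_t must be positive")
                if np.any(v < 0):
                    raise ValueError(f"{name} must be non-negative")
                object.__setattr__(self, name, v)

    def for_transition(self, t: int, time_varying: bool) -> tuple:
        """(α, β) driving colonization into transition year ``t`` (0-based)."""
        if not time_varying or self.alpha_t is None:
            return self.alpha, self.beta
        return float(self.alpha_t[t]), float(self.beta_t[t])


@dataclass
class ExtinctionParams:
    """Logit-linear extinction model: logit ε_i = δ0 + δ1 A_i."""

    delta0: float
    delta1: float

    def __post_init__(self):
        if not (np.isfinite(self.delta0) and np.isfinite(self.delta1)):
            raise ValueError("extinction parameters must be finite")


def connectivity_vector(
    network,
    occupancy: Union[np.ndarray, str],
    alpha: float,
    beta: float,
    *,
    receiver_weighting: bool = False,
) -> np.ndarray:
    """Per-patch connectivity S_i = β Σ_{j≠i} A_j z_j exp(−α d_ij).

    ``occupancy`` is a length-n 0/1 vector, or the :data:`ALL_ONES`
    sentinel for the structural assumption (every patch a source).

    ``receiver_weighting=True`` evaluates the literal receiving-patch
    variant β Σ_{j≠i} A_i z_i exp(−α d_ij) instead; it exists purely for
    comparison with the standard source-patch form and is never the
    default.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    n = network.n
    if isinstance(occupancy, str):
        if occupancy != ALL_ONES:
            raise ValueError(f"unknown occupancy sentinel {occupancy!r}")
        z = np.ones(n)
    else:
        z = np.asarray(occupancy, dtype=float)
        if z.shape != (n,):
            raise ValueError(f"occupancy must have length {n}")
    K = np.exp(-alpha * network.dist)
    np.fill_diagonal(K, 0.0)  # self-contribution excluded
    if receiver_weighting:
        return beta * network.length * z * K.sum(axis=1)
    return beta * (K @ (network.length * z))


def colonization_prob(S):
    """Colonization probability γ = 1 − exp(−S); asymptotic in connectivity."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("connectivity must be non-negative")
    out = -np.expm1(-S)
    return float(out) if out.ndim == 0 else out


def extinction_prob(A, params: ExtinctionParams):
    """Extinction probability ε = logit⁻¹(δ0 + δ1 A) for patch length A (km)."""
    out = expit(params.delta0 + params.delta1 * np.asarray(A, dtype=float))
    return float(out) if out.ndim == 0 else out


def transition_prob(z_prev, gamma, epsilon):
    """Markov occupancy probability: ψ = γ if empty before, 1 − ε if occupied."""
    z_prev = np.asarray(z_prev)
    if not np.all((z_prev == 0) | (z_prev == 1)):
        raise ValueError("previous state must be 0/1")
    gamma = np.asarray(gamma, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    if np.any((gamma < 0) | (gamma > 1)) or np.any((epsilon < 0) | (epsilon > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = (1 - z_prev) * gamma + z_prev * (1 - epsilon)
    return float(out) if out.ndim == 0 else out
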