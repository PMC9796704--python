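"""Bayesian fitting of the four dynamic-connectivity occupancy models.

The sampler is Metropolis-within-Gibbs: latent occupancy states are drawn
from their exact full conditionals (detection-forced states clamped to 1),
continuous parameters move by adaptive random-walk Metropolis on
transformed scales (log for α, β and the SDs, logit for detection, identity
for the extinction regression; ψ1 and μ_p are conjugate), and year-specific
dispersal parameters are log-scale random effects.  Model selection over
the two connectivity assumptions uses Gibbs variable selection with
pseudo-priors fitted to a pilot run of the full (DV) model.

Priors (all configurable via :class:`PriorConfig`) default to vague
choices: ψ1 ~ U(0,1); δ0, δ1 ~ N(0, 10²); α, β, σ_α, σ_β, σ_p ~ U(0, 5);
μ_p ~ N(0, 1.65²); indicators ~ Bernoulli(0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _sampler
from .kernel import (
    ALL_ONES,
    DispersalParams,
    ExtinctionParams,
    ModelSpec,
    colonization_prob,
    connectivity_vector,
    extinction_prob,
)
from .network import DetectionHistory, OccupancyState, PatchNetwork
from .params import DetectionParams, ModelIndicators, SPOMParameters

__all__ = [
    "PriorConfig",
    "MCMCConfig",
    "PosteriorSamples",
    "detection_loglik",
    "z_full_conditional",
    "fit_mcmc",
    "fit_gvs",
    "rhat",
]

_SCALAR_COLS = [
    "psi1",
    "delta0",
    "delta1",
    "alpha",
    "beta",
    "sigma_alpha",
    "sigma_beta",
    "mu_p",
    "sigma_p",
    "I_z",
    "I_D",
    "loglik",
]


@dataclass
class PriorConfig:
    """Hyperparameters of the (vague) default priors."""

    delta_sd: float = 10.0
    alpha_hi: float = 5.0
    beta_hi: float = 5.0
    sigma_hi: float = 5.0
    mup_sd: float = 1.65
    sigp_hi: float = 5.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.delta_sd,
                self.alpha_hi,
                self.beta_hi,
                self.sigma_hi,
                self.mup_sd,
                self.sigp_hi,
            ]
        )


@dataclass
class MCMCConfig:
    """Chain layout and sampler options.

    Defaults are deliberately modest; production fits of an Assynt-sized
    problem used three chains of 1e5 iterations with half discarded.
    ``pilot_iter``/``pilot_burn`` control the short full-model run used to
    fit Gibbs-variable-selection pseudo-priors.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 10
    seed: int = 0
    priors: PriorConfig = field(default_factory=PriorConfig)
    pilot_iter: int = 4_000
    pilot_burn: int = 2_000

    def __post_init__(self):
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("invalid chain layout")

    def chain_seed(self, chain: int) -> int:
        return int((self.seed + 99991 * (chain + 1)) % 2_147_483_647)


class PosteriorSamples:
    """Saved MCMC draws plus latent-state samples and run metadata.

    ``draws`` is a tidy DataFrame (one row per saved iteration, a ``chain``
    column, one column per scalar parameter); ``z_draws`` is an
    (n_saved_total, n_patches, T) int8 array aligned with the rows of
    ``draws``.
    """

    def __init__(self, draws: pd.DataFrame, z_draws=None, meta=None):
        self.draws = draws
        self.z_draws = z_draws
        self.meta = meta or {}

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def param_names(self):
        return [c for c in self.draws.columns if c != "chain"]

    def per_chain(self, name: str) -> np.ndarray:
        """(n_chains, n_per_chain) matrix of one parameter's draws."""
        g = [v.to_numpy() for _, v in self.draws.groupby("chain")[name]]
        return np.vstack(g)

    def summary(self, params=None) -> pd.DataFrame:
        """Posterior mean, sd and 2.5/50/97.5 percentiles per parameter."""
        params = params or self.param_names()
        rows = []
        for name in params:
            v = self.draws[name].to_numpy()
            rows.append(
                {
                    "param": name,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                    "q2.5": np.percentile(v, 2.5),
                    "q50": np.percentile(v, 50),
                    "q97.5": np.percentile(v, 97.5),
                }
            )
        out = pd.DataFrame(rows).set_index("param")
        if self.draws["chain"].nunique() >= 2:
            out["rhat"] = [
                rhat(self.per_chain(name)) if self.draws[name].std() > 0 else np.nan
                for name in params
            ]
        return out

    def model_probabilities(self) -> pd.DataFrame:
        """Joint posterior mass over the four connectivity formulations."""
        iz = self.draws["I_z"].to_numpy().astype(int)
        idd = self.draws["I_D"].to_numpy().astype(int)
        labels = {(0, 0): "UI", (0, 1): "UV", (1, 0): "DI", (1, 1): "DV"}
        rows = []
        for (a, b), lab in labels.items():
            rows.append(
                {
                    "model": lab,
                    "I_z": a,
                    "I_D": b,
                    "probability": float(np.mean((iz == a) & (idd == b))),
                }
            )
        return pd.DataFrame(rows).set_index("model")

    def indicator_probabilities(self) -> dict:
        return {
            "pr_I_z": float(self.draws["I_z"].mean()),
            "pr_I_D": float(self.draws["I_D"].mean()),
        }

    def mean_params(self, years=None) -> SPOMParameters:
        """Posterior-mean point estimates packed as :class:`SPOMParameters`."""
        m = self.draws.mean(numeric_only=True)
        alpha_t = beta_t = None
        at = [c for c in self.draws.columns if c.startswith("alpha_t_")]
        bt = [c for c in self.draws.columns if c.startswith("beta_t_")]
        if at:
            alpha_t = m[at].to_numpy()
            beta_t = m[bt].to_numpy()
        pt = [c for c in self.draws.columns if c.startswith("p_t_")]
        return SPOMParameters(
            psi1=float(m["psi1"]),
            extinction=ExtinctionParams(float(m["delta0"]), float(m["delta1"])),
            dispersal=DispersalParams(
                alpha=float(m["alpha"]),
                beta=float(m["beta"]),
                alpha_t=alpha_t,
                beta_t=beta_t,
                sigma_alpha=float(m["sigma_alpha"]),
                sigma_beta=float(m["sigma_beta"]),
            ),
            detection=DetectionParams(
                mu_p=float(m["mu_p"]),
                sigma_p=float(m["sigma_p"]),
                p_t=m[pt].to_numpy() if pt else None,
            ),
        )

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)

    def write_z_draws(self, network: PatchNetwork, years, path) -> None:
        """Latent-state draws as CSV, one row per draw, patch:year columns."""
        n, T = self.z_draws.shape[1:]
        cols = [f"{pid}:{yr}" for pid in network.patch_id for yr in years]
        pd.DataFrame(self.z_draws.reshape(-1, n * T), columns=cols).to_csv(
            path, index=False
        )


def detection_loglik(y_it, z_it, p_t) -> float:
    """Log-likelihood of one patch-year's visit outcomes given z.

    No false positives: an unoccupied patch-year has likelihood 1 for all-
    zero records and 0 (−inf) if any visit recorded a detection.  Missing
    visits contribute nothing.
    """
    y = np.asarray(y_it, dtype=float)
    y = y[~np.isnan(y)]
    if z_it == 0:
        return 0.0 if not np.any(y == 1) else -np.inf
    if len(y) and not 0 < p_t < 1:
        raise ValueError("p_t must lie in (0, 1)")
    return float(np.sum(y * np.log(p_t) + (1 - y) * np.log1p(-p_t)))


def z_full_conditional(
    i: int,
    t: int,
    state: OccupancyState,
    params: SPOMParameters,
    model: ModelSpec,
    data: DetectionHistory,
    network: PatchNetwork,
) -> float:
    """Pr(z_{i,t} = 1 | every other state, parameters, data).

    Reference (vectorised numpy) evaluation of the same full conditional
    the compiled sampler uses: the patch's detection record, its own
    incoming transition (ψ1 in the first year), and — through connectivity —
    the outgoing transition of every patch in the next year.  A detection
    forces the probability to exactly 1.
    """
    z = state.z.copy()
    n, T = z.shape
    if not (0 <= i < n and 0 <= t < T):
        raise IndexError("patch/year index out of range")
    y_it = data.y[i, t]
    if np.nansum(y_it) > 0:
        return 1.0
    p_t = params.detection.p_t
    eps = extinction_prob(network.length, params.extinction)
    logw = np.zeros(2)
    for a in (0, 1):
        z[i, t] = a
        w = detection_loglik(y_it, a, p_t[t])
        if t == 0:
            w += np.log(params.psi1) if a == 1 else np.log1p(-params.psi1)
        else:
            w += _transition_logprob(z, t - 1, t, i, params, model, network, eps)
        if t < T - 1:
            ks = range(n) if model.weighted else [i]
            for k in ks:
                w += _transition_logprob(z, t, t + 1, k, params, model, network, eps)
        logw[a] = w
    z[i, t] = state.z[i, t]
    m = logw.max()
    w0, w1 = np.exp(logw - m)
    return float(w1 / (w0 + w1))


def _transition_logprob(z, r, t_next, k, params, model, network, eps):
    """log Pr(z_{k,t_next} | z_{·,r}) under the chosen connectivity model."""
    if z[k, r] == 1:
        psi = 1.0 - eps[k]
    else:
        a, b = params.dispersal.for_transition(r, model.time_varying)
        occ = z[:, r] if model.weighted else ALL_ONES
        S = connectivity_vector(network, occ, a, b)
        psi = colonization_prob(S[k])
    psi = min(max(psi, 1e-300), 1 - 1e-16)
    return np.log(psi) if z[k, t_next] == 1 else np.log1p(-psi)


# ---------------------------------------------------------------------------
# fitting


def _pack_data(data: DetectionHistory, network: PatchNetwork):
    if data.n != network.n:
        raise ValueError("detection history and network disagree on patch count")
    ysum = np.ascontiguousarray(data.detections.astype(np.int64))
    J = np.ascontiguousarray(data.visits.astype(np.int64))
    forced = np.ascontiguousarray((ysum > 0).astype(np.int8))
    A = np.ascontiguousarray(network.length)
    D = np.ascontiguousarray(network.dist)
    return A, D, ysum, J, forced


def _columns(years):
    years = list(years)
    return (
        _SCALAR_COLS
        + [f"p_t_{y}" for y in years]
        + [f"alpha_t_{y}" for y in years[1:]]
        + [f"beta_t_{y}" for y in years[1:]]
    )


def _run_chains(data, network, config, weighted, time_varying, gvs, pseudo):
    A, D, ysum, J, forced = _pack_data(data, network)
    R = data.T - 1
    if pseudo is None:
        pseudo = (
            np.zeros(R), np.ones(R), np.zeros(R), np.ones(R),
            np.zeros(2), np.ones(2),
        )
    # occupancy fraction for the joint (I_z, beta) branch-switch proposal:
    # weighted connectivity sums are roughly this fraction of structural ones
    naive = (ysum > 0).astype(float)
    surveyed = J > 0
    rho = float(naive[surveyed].mean()) if surveyed.any() else 0.5
    rho = min(max(rho, 0.05), 0.95)
    frames, zs, accs = [], [], []
    for c in range(config.n_chains):
        draws, z_draws, acc = _sampler.run_chain(
            A,
            D,
            ysum,
            J,
            forced,
            int(weighted),
            int(time_varying),
            int(gvs),
            *pseudo,
            rho,
            config.priors.as_array(),
            config.n_iter,
            config.n_burnin,
            config.thin,
            config.chain_seed(c),
        )
        df = pd.DataFrame(draws, columns=_columns(data.years))
        df.insert(0, "chain", c)
        frames.append(df)
        zs.append(z_draws)
        accs.append(acc)
    meta = {
        "acceptance": np.mean(accs, axis=0),
        "n_chains": config.n_chains,
        "n_iter": config.n_iter,
        "n_burnin": config.n_burnin,
        "thin": config.thin,
        "seed": config.seed,
    }
    return PosteriorSamples(
        pd.concat(frames, ignore_index=True), np.concatenate(zs), meta
    )


def fit_mcmc(
    data: DetectionHistory,
    network: PatchNetwork,
    model: ModelSpec,
    config: MCMCConfig,
) -> PosteriorSamples:
    """Fit one of the four connectivity formulations by MCMC."""
    post = _run_chains(
        data, network, config, model.weighted, model.time_varying, gvs=False,
        pseudo=None,
    )
    post.meta["model"] = model.label
    return post


def fit_pseudo_priors(pilot: PosteriorSamples):
    """Normal pseudo-priors for the deactivated dispersal block.

    Moments of the pilot posterior of each log-scale deviate
    (log α_t − log α, log β_t − log β) and of the log random-effect SDs,
    with floored spreads so a degenerate pilot cannot produce a point-mass
    pseudo-prior.
    """
    d = pilot.draws
    at = [c for c in d.columns if c.startswith("alpha_t_")]
    bt = [c for c in d.columns if c.startswith("beta_t_")]
    ea = np.log(d[at].to_numpy()) - np.log(d[["alpha"]].to_numpy())
    eb = np.log(d[bt].to_numpy()) - np.log(d[["beta"]].to_numpy())
    ls = np.log(d[["sigma_alpha", "sigma_beta"]].to_numpy())
    floor = 0.05
    return (
        ea.mean(axis=0),
        np.maximum(ea.std(axis=0, ddof=1), floor),
        eb.mean(axis=0),
        np.maximum(eb.std(axis=0, ddof=1), floor),
        ls.mean(axis=0),
        np.maximum(ls.std(axis=0, ddof=1), floor),
    )


def fit_gvs(
    data: DetectionHistory,
    network: PatchNetwork,
    config: MCMCConfig,
    pilot: Optional[PosteriorSamples] = None,
) -> PosteriorSamples:
    """Joint fit with Gibbs variable selection over (I_z, I_D).

    A short pilot run of the full DV model supplies Normal pseudo-priors
    for the year-specific dispersal deviates; pass ``pilot`` to reuse an
    existing run.  The returned samples carry indicator draws; use
    :meth:`PosteriorSamples.model_probabilities` for the 4-cell table.
    """
    if pilot is None:
        from dataclasses import replace

        pilot_cfg = replace(
            config,
            n_iter=config.pilot_iter,
            n_burnin=config.pilot_burn,
            n_chains=1,
            seed=config.seed + 1,
        )
        pilot = fit_mcmc(
            data, network, ModelSpec(weighted=True, time_varying=True), pilot_cfg
        )
    pseudo = fit_pseudo_priors(pilot)
    post = _run_chains(
        data, network, config, weighted=1, time_varying=1, gvs=True, pseudo=pseudo
    )
    post.meta["model"] = "GVS"
    post.meta["pseudo_priors"] = pseudo
    return post


def rhat(chains) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    Each chain is split in half; R-hat compares between- and within-chain
    variance of the resulting 2m sequences.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains")
    if chains.shape[1] < 4:
        raise ValueError("need at least four draws per chain")
    half = chains.shape[1] // 2
    split = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    m, n = split.shape
    means = split.mean(axis=1)
    B = n * means.var(ddof=1)
    W = split.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))
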