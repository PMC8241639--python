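"""Bayesian binomial logistic models for factorial germination trials.

For experiment 1 (full 2x2 factorial of heat H and smoke S) the linear
predictor for dish *i* is

    eta_i = b0 + b1*H_i + b2*S_i + b3*H_i*S_i,        G_i ~ Binomial(V_i, pi_i)

with pi_i = expit(eta_i); experiment 2 (combined cue only) uses
eta_i = b0 + b1*HS_i.  Coefficients get wide Normal(0, 10^2) priors by
default; cells with 0% or 100% germination make the likelihood flat in one
direction (complete separation), in which case weakly informative
Student-t(3, 0, 2.5) priors keep the posterior proper and well behaved.
Extra-binomial dish-to-dish variation is absorbed by an observation-level
(per-dish) normal random effect on the logit scale with standard deviation
sigma (a binomial GLMM).

Sampling is adaptive random-walk Metropolis-within-Gibbs, vectorised across
independent chains: a full-covariance block update for the coefficients,
element-wise updates for the dish effects (conditionally independent given
the coefficients and sigma), and a scalar update for log sigma.  Proposal
scales and the coefficient proposal covariance adapt during burn-in only,
so the retained chains are draws from a fixed, valid Markov kernel.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .io import (
    TREATMENTS_EXP1,
    TREATMENTS_EXP2,
    GerminationObservation,
    ValidationError,
)

__all__ = [
    "ModelSpec",
    "SamplerConfig",
    "PosteriorDraws",
    "build_design",
    "detect_separation",
    "fit_model",
    "fit_overdispersed",
    "derive_treatment_probabilities",
    "treatment_probabilities",
    "effect_draws",
    "rhat",
    "ess",
    "posterior_predictive_check",
]

PARAM_NAMES = {
    1: ("beta0", "beta_H", "beta_S", "beta_HxS"),
    2: ("beta0", "beta_HS"),
}

# treatment -> coefficient combination, rows align with PARAM_NAMES
_TREATMENT_CODING = {
    1: {"C": (1, 0, 0, 0), "H": (1, 1, 0, 0), "S": (1, 0, 1, 0), "HS": (1, 1, 1, 1)},
    2: {"C": (1, 0), "HS": (1, 1)},
}


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: experiment layout, prior family, random effect."""

    experiment: int = 1
    prior_family: str = "flat-normal"  # or "student_t"
    student_t_params: tuple[float, float, float] = (3.0, 0.0, 2.5)  # df, loc, scale
    normal_scale: float = 10.0
    overdispersed: bool = False
    sigma_prior_scale: float = 2.0  # half-normal scale for the dish-effect SD

    def __post_init__(self):
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.prior_family not in ("flat-normal", "student_t"):
            raise ValueError(f"unknown prior family {self.prior_family!r}")

    @property
    def n_coefficients(self) -> int:
        return 4 if self.experiment == 1 else 2

    @property
    def param_names(self) -> tuple[str, ...]:
        names = PARAM_NAMES[self.experiment]
        return names + ("sigma",) if self.overdispersed else names


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC protocol.  Defaults follow the reference protocol: five chains of
    80,000 iterations, 50,000 burn-in, thinning 10, i.e. 15,000 retained
    draws.  Smaller configurations are routinely adequate for these models."""

    chains: int = 5
    iterations: int = 80_000
    burn_in: int = 50_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning

    @property
    def retained(self) -> int:
        return self.chains * self.retained_per_chain

    def scaled(self, factor: float) -> "SamplerConfig":
        """Same protocol with iteration counts divided by ``factor``."""
        return SamplerConfig(
            chains=self.chains,
            iterations=max(2, int(self.iterations / factor)),
            burn_in=int(self.burn_in / factor),
            thinning=self.thinning,
            seed=self.seed,
        )


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus derived treatment probabilities and
    convergence diagnostics for one species-level model fit."""

    spec: ModelSpec
    config: SamplerConfig
    param_names: tuple[str, ...]
    beta: np.ndarray                 # (chains, kept, p) logit-scale coefficients
    treatments: tuple[str, ...]
    pi: np.ndarray                   # (chains, kept, T) germination probabilities
    design: np.ndarray               # (n_obs, p)
    germinated: np.ndarray           # (n_obs,)
    viable: np.ndarray               # (n_obs,)
    sigma: np.ndarray | None = None  # (chains, kept) dish-effect SD
    eps: np.ndarray | None = None    # (chains, kept, n_obs) dish effects
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    bayesian_p: float | None = None
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    @property
    def pi_flat(self) -> np.ndarray:
        return self.pi.reshape(-1, self.pi.shape[-1])

    @property
    def sigma_flat(self) -> np.ndarray | None:
        return None if self.sigma is None else self.sigma.reshape(-1)

    def pi_for(self, treatment: str) -> np.ndarray:
        try:
            j = self.treatments.index(treatment)
        except ValueError:
            raise KeyError(
                f"treatment {treatment!r} not in this fit (has {self.treatments})"
            ) from None
        return self.pi_flat[:, j]

    def to_frame(self):
        """Flat (chain, draw, parameter, value) table of the coefficient draws."""
        import pandas as pd

        C, K, P = self.beta.shape
        recs = []
        for c in range(C):
            for jp, name in enumerate(self.param_names[:P]):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "draw": np.arange(K),
                            "parameter": name,
                            "value": self.beta[c, :, jp],
                        }
                    )
                )
            if self.sigma is not None:
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "draw": np.arange(K),
                            "parameter": "sigma",
                            "value": self.sigma[c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    obs: Sequence[GerminationObservation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, tuple[str, ...]]:
    """Indicator-coded design matrix and count vectors for one species.

    Returns ``(X, G, V, experiment, row_treatments)``.  Experiment 1 rows are
    (1, H, S, H*S); experiment 2 rows are (1, HS).
    """
    if not obs:
        raise ValidationError(["no observations"])
    exps = {o.experiment for o in obs}
    if len(exps) > 1:
        raise ValidationError([f"mixed experiment codes {sorted(exps)}"])
    exp = exps.pop()
    coding = _TREATMENT_CODING[exp]
    rows, G, V, trts = [], [], [], []
    for o in obs:
        if o.treatment not in coding:
            raise ValidationError(
                [f"treatment {o.treatment!r} invalid for experiment {exp}"]
            )
        rows.append(coding[o.treatment])
        G.append(o.germinated)
        V.append(o.viable)
        trts.append(o.treatment)
    return (
        np.asarray(rows, dtype=float),
        np.asarray(G, dtype=float),
        np.asarray(V, dtype=float),
        exp,
        tuple(trts),
    )


def detect_separation(
    G: np.ndarray, V: np.ndarray, row_treatments: Sequence[str]
) -> list[str]:
    """Treatment cells whose pooled counts sit on the boundary (0% or 100%)."""
    G = np.asarray(G)
    V = np.asarray(V)
    out = []
    for t in dict.fromkeys(row_treatments):  # preserve order, unique
        m = np.array([rt == t for rt in row_treatments])
        g, v = G[m].sum(), V[m].sum()
        if v > 0 and (g == 0 or g == v):
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _log_prior_beta(beta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    if spec.prior_family == "flat-normal":
        return -0.5 * np.sum((beta / spec.normal_scale) ** 2, axis=-1)
    df, loc, scale = spec.student_t_params
    z = (beta - loc) / scale
    return np.sum(-(df + 1.0) / 2.0 * np.log1p(z * z / df), axis=-1)


def _loglik_obs(eta: np.ndarray, G: np.ndarray, V: np.ndarray) -> np.ndarray:
    # binomial log-likelihood up to a constant, per observation
    return G * eta - V * np.logaddexp(0.0, eta)


def fit_model(
    design: np.ndarray,
    counts: tuple[np.ndarray, np.ndarray],
    spec: ModelSpec,
    config: SamplerConfig,
    row_treatments: Sequence[str] | None = None,
    compute_ppc: bool = True,
) -> PosteriorDraws:
    """Fit the binomial logistic model by MCMC and return retained draws.

    ``counts`` is ``(G, V)`` aligned with the rows of ``design``.  The result
    carries split R-hat and effective sample size per coefficient, a
    posterior-predictive dispersion p-value, and warnings (never a silent
    failure) when chains have not converged or when separated data are fit
    under the wide-normal prior.
    """
    X = np.asarray(design, dtype=float)
    G = np.asarray(counts[0], dtype=float)
    V = np.asarray(counts[1], dtype=float)
    if np.any(G < 0) or np.any(G > V):
        raise ValidationError(["counts must satisfy 0 <= G <= V"])
    n, p = X.shape
    if p != spec.n_coefficients:
        raise ValidationError(
            [f"design has {p} columns but experiment {spec.experiment} "
             f"expects {spec.n_coefficients}"]
        )

    rng = np.random.default_rng(config.seed)
    C = config.chains
    over = spec.overdispersed

    # start near the empirical logits, jittered per chain
    emp = np.log((G + 0.5) / (V - G + 0.5))
    b0, *_ = np.linalg.lstsq(X, emp, rcond=None)
    b0 = np.clip(b0, -8, 8)
    beta = b0[None, :] + 0.3 * rng.standard_normal((C, p))
    eps = 0.1 * rng.standard_normal((C, n)) if over else np.zeros((C, n))
    u = np.log(0.5) + 0.2 * rng.standard_normal(C) if over else np.zeros(C)

    eta = beta @ X.T + (eps if over else 0.0)
    ll_obs = _loglik_obs(eta, G, V)
    lp_beta = _log_prior_beta(beta, spec)

    ls_b = np.full(C, np.log(2.38 / np.sqrt(p)) - 1.0)
    ls_e = np.full(C, np.log(0.5))
    ls_u = np.full(C, np.log(0.5))
    L = np.broadcast_to(np.eye(p), (C, p, p)).copy()

    kept = config.retained_per_chain
    out_beta = np.empty((C, kept, p))
    out_sigma = np.empty((C, kept)) if over else None
    out_eps = np.empty((C, kept, n)) if over else None

    hist = np.empty((config.burn_in, C, p)) if config.burn_in else None
    k = 0
    for t in range(config.iterations):
        adapting = t < config.burn_in
        gamma = min(0.1, 2.0 / (t + 10) ** 0.6)

        # --- coefficient block
        z = rng.standard_normal((C, p))
        step = np.einsum("cij,cj->ci", L, z) * np.exp(ls_b)[:, None]
        beta_p = beta + step
        eta_p = eta + step @ X.T
        ll_obs_p = _loglik_obs(eta_p, G, V)
        lp_p = _log_prior_beta(beta_p, spec)
        log_acc = ll_obs_p.sum(1) + lp_p - ll_obs.sum(1) - lp_beta
        acc = np.log(rng.random(C)) < log_acc
        beta[acc] = beta_p[acc]
        eta[acc] = eta_p[acc]
        ll_obs[acc] = ll_obs_p[acc]
        lp_beta[acc] = lp_p[acc]
        if adapting:
            ls_b += gamma * (acc.astype(float) - 0.28)
            hist[t] = beta
            if t >= 400 and t % 250 == 0:
                lo = t // 2
                for c in range(C):
                    cov = np.cov(hist[lo:t, c].T).reshape(p, p)
                    L[c] = np.linalg.cholesky(cov + 1e-8 * np.eye(p))

        if over:
            sig2 = np.exp(2 * u)[:, None]
            # --- dish effects, element-wise (conditionally independent)
            ze = rng.standard_normal((C, n))
            eps_p = eps + np.exp(ls_e)[:, None] * ze
            eta_p = eta + (eps_p - eps)
            ll_obs_p = _loglik_obs(eta_p, G, V)
            d = (ll_obs_p - ll_obs) - (eps_p**2 - eps**2) / (2 * sig2)
            m = np.log(rng.random((C, n))) < d
            eps = np.where(m, eps_p, eps)
            eta = np.where(m, eta_p, eta)
            ll_obs = np.where(m, ll_obs_p, ll_obs)
            if adapting:
                ls_e += gamma * (m.mean(1) - 0.44)

            # --- log sigma, scalar random walk
            S = np.sum(eps**2, axis=1)
            up = u + np.exp(ls_u) * rng.standard_normal(C)

            def _lp_u(uu):
                s2 = np.exp(2 * uu)
                return (
                    -n * uu
                    - S / (2 * s2)
                    - 0.5 * (np.exp(uu) / spec.sigma_prior_scale) ** 2
                    + uu  # Jacobian of sigma -> log sigma
                )

            accu = np.log(rng.random(C)) < _lp_u(up) - _lp_u(u)
            u = np.where(accu, up, u)
            if adapting:
                ls_u += gamma * (accu.astype(float) - 0.44)

        if t >= config.burn_in and (t - config.burn_in) % config.thinning == 0:
            if k < kept:
                out_beta[:, k] = beta
                if over:
                    out_sigma[:, k] = np.exp(u)
                    out_eps[:, k] = eps
                k += 1

    # derived per-treatment germination probabilities (GLMM: at eps = 0,
    # i.e. the median dish)
    pi, treatments = derive_treatment_probabilities(out_beta, spec.experiment)

    result = PosteriorDraws(
        spec=spec,
        config=config,
        param_names=spec.param_names,
        beta=out_beta,
        treatments=tuple(treatments),
        pi=pi,
        design=X,
        germinated=G,
        viable=V,
        sigma=out_sigma,
        eps=out_eps,
    )

    # diagnostics
    names = PARAM_NAMES[spec.experiment]
    for jp, name in enumerate(names):
        chains_x = out_beta[:, :, jp]
        result.rhat[name] = rhat(chains_x) if C >= 2 else float("nan")
        result.ess[name] = ess(chains_x)
    if over:
        result.rhat["sigma"] = rhat(out_sigma) if C >= 2 else float("nan")
        result.ess["sigma"] = ess(out_sigma)
    finite = [v for v in result.rhat.values() if np.isfinite(v)]
    result.converged = bool(finite) and max(finite) < 1.1
    if not result.converged:
        result.warnings.append(
            "chains not converged (max R-hat "
            f"{max(finite) if finite else float('nan'):.3f} >= 1.1); "
            "increase iterations or thinning"
        )

    separated = detect_separation(G, V, row_treatments or _rows_to_treatments(X, spec))
    if separated and spec.prior_family == "flat-normal":
        result.warnings.append(
            "complete separation in treatment(s) "
            f"{', '.join(separated)} under the wide-normal prior; "
            "refit with Student-t priors recommended"
        )

    if compute_ppc:
        result.bayesian_p = posterior_predictive_check(result, seed=config.seed + 1)[0]
    return result


def _rows_to_treatments(X: np.ndarray, spec: ModelSpec) -> list[str]:
    coding = _TREATMENT_CODING[spec.experiment]
    inv = {tuple(v): k for k, v in coding.items()}
    return [inv.get(tuple(int(x) for x in row), "?") for row in X]


def fit_overdispersed(
    design: np.ndarray,
    counts: tuple[np.ndarray, np.ndarray],
    spec: ModelSpec,
    config: SamplerConfig,
    **kw,
) -> PosteriorDraws:
    """GLMM variant of :func:`fit_model`: adds the per-dish random effect."""
    spec = ModelSpec(
        experiment=spec.experiment,
        prior_family=spec.prior_family,
        student_t_params=spec.student_t_params,
        normal_scale=spec.normal_scale,
        overdispersed=True,
        sigma_prior_scale=spec.sigma_prior_scale,
    )
    return fit_model(design, counts, spec, config, **kw)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def derive_treatment_probabilities(
    beta_draws: np.ndarray, experiment: int
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Map coefficient draws to per-treatment germination probabilities.

    For experiment 1: pi_C = expit(b0), pi_H = expit(b0 + b1),
    pi_S = expit(b0 + b2), pi_HS = expit(b0 + b1 + b2 + b3); experiment 2:
    pi_C = expit(b0), pi_HS = expit(b0 + b1).  ``beta_draws`` may carry any
    leading shape; the last axis indexes coefficients.
    """
    treatments = TREATMENTS_EXP1 if experiment == 1 else TREATMENTS_EXP2
    A = np.asarray([_TREATMENT_CODING[experiment][t] for t in treatments])
    return expit(np.asarray(beta_draws) @ A.T), tuple(treatments)


def treatment_probabilities(
    draws: PosteriorDraws, percent: bool = False
) -> dict[str, np.ndarray]:
    """Per-treatment germination-probability draws keyed by treatment."""
    scale = 100.0 if percent else 1.0
    return {t: scale * draws.pi_for(t) for t in draws.treatments}


_CONTRASTS_EXP1 = ("H-C", "S-C", "HS-C", "HS-S", "interaction")
_CONTRASTS_EXP2 = ("HS-C",)


def effect_draws(
    draws: PosteriorDraws, names: Sequence[str] | None = None
) -> dict[str, np.ndarray]:
    """Treatment-effect draws in percentage points of germination.

    Experiment 1 exposes H-C, S-C, HS-C, HS-S and the interaction
    pi_HS - pi_H - pi_S + pi_C; experiment 2 exposes HS-C only.  Requesting a
    contrast the experiment does not support raises ``KeyError``.
    """
    avail = _CONTRASTS_EXP1 if draws.spec.experiment == 1 else _CONTRASTS_EXP2
    if names is None:
        names = avail
    pct = {t: 100.0 * draws.pi_for(t) for t in draws.treatments}
    out = {}
    for name in names:
        if name not in avail:
            raise KeyError(
                f"contrast {name!r} unavailable for experiment "
                f"{draws.spec.experiment} (available: {avail})"
            )
        if name == "interaction":
            out[name] = pct["HS"] - pct["H"] - pct["S"] + pct["C"]
        else:
            a, b = name.split("-")
            out[name] = pct[a] - pct[b]
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def rhat(chains: np.ndarray, split: bool = True) -> float:
    """Gelman–Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  With ``split=True`` (default)
    each chain is halved first, which also flags within-chain drift.
    Values below 1.1 indicate convergence.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat needs a (chains, draws) array with >= 2 chains")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = x.shape
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def ess(chains: np.ndarray) -> float:
    """Effective sample size, autocorrelation-adjusted across chains.

    Uses FFT autocovariances averaged over chains and Geyer's initial
    monotone positive-pair truncation.  For independent draws the result is
    close to the total draw count.
    """
    x = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = x.shape
    if n < 4:
        return float(m * n)
    # per-chain autocovariance via FFT
    xc = x - x.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)

    W = x.var(axis=1, ddof=1).mean()
    if m >= 2:
        B = n * x.mean(axis=1).var(ddof=1)
        var_plus = (n - 1) / n * W + B / n
    else:
        var_plus = (n - 1) / n * W
    if var_plus == 0:
        return float(m * n)
    rho = 1.0 - (W - mean_acov) / var_plus  # rho[0] ~ 1

    # Geyer initial monotone positive sequence over lag pairs
    tau = 0.0
    prev = np.inf
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += pair
    tau = 1.0 + 2.0 * tau
    return float(m * n / max(tau, 1e-12))


# ---------------------------------------------------------------------------
# posterior predictive check
# ---------------------------------------------------------------------------

def posterior_predictive_check(
    draws: PosteriorDraws,
    seed: int = 0,
    max_draws: int = 2000,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Bayesian p-value from a dispersion discrepancy.

    For each retained draw the dish-level probabilities are formed (including
    the dish random effect when present), replicate counts are simulated from
    the fitted binomial model, and the discrepancy T = sum of squared Pearson
    residuals is compared between observed and replicate data:
    p = Pr(T_rep >= T_obs).  p near 0 flags overdispersion; p in (0.05, 0.95)
    is consistent with the model.  Returns ``(p, T_obs, T_rep)``.
    """
    rng = np.random.default_rng(seed)
    beta = draws.beta_flat
    N = beta.shape[0]
    idx = (
        np.arange(N)
        if N <= max_draws
        else rng.choice(N, size=max_draws, replace=False)
    )
    X, G, V = draws.design, draws.germinated, draws.viable
    eta = beta[idx] @ X.T
    if draws.eps is not None:
        eta = eta + draws.eps.reshape(-1, draws.eps.shape[-1])[idx]
    p_dish = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    mu = V * p_dish
    var = V * p_dish * (1 - p_dish)
    T_obs = np.sum((G - mu) ** 2 / var, axis=1)
    G_rep = rng.binomial(V.astype(int), p_dish)
    T_rep = np.sum((G_rep - mu) ** 2 / var, axis=1)
    p = float(np.mean(T_rep >= T_obs))
    return p, T_obs, T_rep
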