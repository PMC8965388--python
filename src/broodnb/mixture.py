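"""Length-based Bayesian Gaussian mixture cohort inference.

Two K-selection procedures are provided: the overfitted-mixture cutoff rule
(fit a deliberately large K and count components whose weight survives a
small cutoff, per MCMC draw) and a birth-death MCMC in which the number of
components itself moves.  A consensus rule picks the working K and a final
fixed-K fit yields individual assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


@dataclass
class MCMCSettings:
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5


@dataclass
class MixturePriors:
    """Weakly-informative, range-anchored priors.

    Component variances get sigma^2 ~ InvGamma(var_shape, beta) with a
    Gamma(hyper_g, hyper_h) hyperprior on beta, so the variance scale adapts
    to the within-component spread instead of being pinned to the overall
    sample variance (which would favour one wide component).
    """

    mean_loc: float
    mean_scale: float          # prior sd of component means (sample range)
    var_shape: float = 2.5
    var_scale: float = 1.0     # initial beta
    dirichlet: float = 1.0
    hyper_g: float = 0.2
    hyper_h: float | None = None   # None disables the beta hyperprior

    @classmethod
    def from_data(cls, x: np.ndarray) -> "MixturePriors":
        rng_width = float(np.ptp(x)) or 1.0
        return cls(mean_loc=float(np.mean(x)), mean_scale=rng_width,
                   var_scale=(1.5 * float(np.var(x))) or 1.0,
                   hyper_h=10.0 / rng_width**2)


@dataclass
class MixtureFit:
    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    responsibilities: np.ndarray   # (n, K), rows sum to 1
    n_draws: int
    burn_in: int
    weight_draws: np.ndarray | None = None  # (draws, K) retained weight samples

    @property
    def labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


@dataclass
class KPosterior:
    method: str                    # "overfitted_cutoff" | "bd_mcmc"
    probs: np.ndarray              # index k-1 -> P(K = k)
    diagnostics: dict = field(default_factory=dict)

    @property
    def mode(self) -> int:
        return int(np.argmax(self.probs)) + 1

    @property
    def mode_prob(self) -> float:
        return float(self.probs.max())


def _validate_lengths(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("lengths must be finite")
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    return x


def _gibbs_sweep(x, z, w, mu, var, priors, rng, beta=None):
    n = len(x)
    K = len(w)
    if beta is None:
        beta = priors.var_scale
    # assignments
    logd = (np.log(np.maximum(w, 1e-300))[None, :]
            + norm.logpdf(x[:, None], mu[None, :], np.sqrt(var)[None, :]))
    logd -= logd.max(axis=1, keepdims=True)
    probs = np.exp(logd)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    z = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    counts = np.bincount(z, minlength=K)
    # weights
    w = rng.dirichlet(priors.dirichlet + counts)
    # means and variances
    for k in range(K):
        xk = x[z == k]
        nk = len(xk)
        prec = 1.0 / priors.mean_scale**2 + nk / var[k]
        m = (priors.mean_loc / priors.mean_scale**2
             + xk.sum() / var[k]) / prec
        mu[k] = rng.normal(m, np.sqrt(1.0 / prec))
        sse = ((xk - mu[k]) ** 2).sum()
        var[k] = 1.0 / rng.gamma(priors.var_shape + nk / 2.0,
                                 1.0 / (beta + sse / 2.0))
    if priors.hyper_h is not None:
        beta = rng.gamma(priors.hyper_g + K * priors.var_shape,
                         1.0 / (priors.hyper_h + (1.0 / var).sum()))
    return z, w, mu, var, beta


def fit_mixture_fixed_k(lengths, K: int, priors: MixturePriors | None = None,
                        mcmc: MCMCSettings | None = None, seed: int = 0,
                        keep_weight_draws: bool = False,
                        n_chains: int = 1) -> MixtureFit:
    """Gibbs sampler for a K-component univariate normal mixture.

    Label switching is resolved by sorting components by mean within each
    retained draw before averaging; reported responsibilities are evaluated
    at the posterior-mean parameters.  With ``n_chains`` > 1, independent
    chains are run from overdispersed starts and the chain with the highest
    mean retained-data log-likelihood is kept (guards against the sticky
    one-wide-component mode of overfitted mixtures).
    """
    x = _validate_lengths(lengths)
    n = len(x)
    if K > n:
        raise ValueError(f"K={K} exceeds sample size n={n}")
    mc = mcmc or MCMCSettings()
    pri = priors or MixturePriors.from_data(x)

    best = None
    for chain in range(max(n_chains, 1)):
        rng = np.random.default_rng(seed + 1000 * chain)
        # init: spread means over the data quantiles and bin points by rank,
        # which avoids starting inside the collapsed mode
        mu = np.quantile(x, (np.arange(K) + 0.5) / K)
        var = np.full(K, np.var(x) / max(K, 1) + 1e-6)
        w = np.full(K, 1.0 / K)
        if chain == 0:
            z = np.minimum((x.argsort().argsort() * K) // n, K - 1)
        else:
            z = rng.integers(0, K, size=n)

        kept_w, kept_mu, kept_var = [], [], []
        ll_sum = 0.0
        beta = None
        for it in range(mc.n_iter):
            z, w, mu, var, beta = _gibbs_sweep(x, z, w, mu, var, pri, rng,
                                               beta)
            if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
                order = np.argsort(mu)
                kept_w.append(w[order])
                kept_mu.append(mu[order])
                kept_var.append(var[order])
                ll_sum += _mixture_loglik(x, w, mu, var)
        mean_ll = ll_sum / max(len(kept_w), 1)
        if best is None or mean_ll > best[0]:
            best = (mean_ll, kept_w, kept_mu, kept_var)

    _, kept_w, kept_mu, kept_var = best
    W = np.array(kept_w)
    MU = np.array(kept_mu)
    V = np.array(kept_var)
    w_hat, mu_hat, sd_hat = W.mean(0), MU.mean(0), np.sqrt(V.mean(0))

    logd = (np.log(np.maximum(w_hat, 1e-300))[None, :]
            + norm.logpdf(x[:, None], mu_hat[None, :], sd_hat[None, :]))
    logd -= logd.max(axis=1, keepdims=True)
    resp = np.exp(logd)
    resp /= resp.sum(axis=1, keepdims=True)

    return MixtureFit(K=K, weights=w_hat, means=mu_hat, sds=sd_hat,
                      responsibilities=resp, n_draws=len(W),
                      burn_in=mc.burn_in,
                      weight_draws=W if keep_weight_draws else None)


def posterior_k_overfitted(lengths, K_max: int = 10, cutoff: float = 0.035,
                           mcmc: MCMCSettings | None = None,
                           sparsity: float = 0.01,
                           seed: int = 0) -> KPosterior:
    """Overfitted-mixture K selection: fit K_max components and, per retained
    draw, count components whose weight is at least ``cutoff``.

    ``sparsity`` is the Dirichlet concentration of the overfitted fit; it
    must be well below 1 so that superfluous components empty out.
    """
    if K_max < 2:
        raise ValueError("K_max must be >= 2")
    if not (0.01 <= cutoff <= 0.05) and cutoff != 0.0:
        warnings.warn(f"cutoff {cutoff} outside the recommended [0.01, 0.05] "
                      "band", stacklevel=2)
    x = _validate_lengths(lengths)
    K_fit = min(K_max, len(x))
    # superfluous-component weights only shrink under a sparse Dirichlet
    pri = MixturePriors.from_data(x)
    pri.dirichlet = sparsity
    fit = fit_mixture_fixed_k(x, K_fit, priors=pri, mcmc=mcmc, seed=seed,
                              keep_weight_draws=True, n_chains=3)
    surviving = (fit.weight_draws >= cutoff).sum(axis=1)
    surviving = np.clip(surviving, 1, K_max)
    probs = np.bincount(surviving, minlength=K_max + 1)[1:K_max + 1]
    probs = probs / probs.sum()
    return KPosterior(method="overfitted_cutoff", probs=probs,
                      diagnostics={"K_fit": K_fit, "cutoff": cutoff,
                                   "n_draws": fit.n_draws})


def _mixture_loglik(x, w, mu, var):
    d = w[None, :] * norm.pdf(x[:, None], mu[None, :],
                              np.sqrt(var)[None, :])
    return float(np.log(np.maximum(d.sum(axis=1), 1e-300)).sum())


def posterior_k_bdmcmc(lengths, K_max: int = 10, birth_rate: float = 1.0,
                       mcmc: MCMCSettings | None = None,
                       seed: int = 0) -> KPosterior:
    """Birth-death MCMC over the number of mixture components.

    Births add a component drawn from the prior with a Beta(1, K) weight at
    constant rate; each component dies at a rate proportional to the
    likelihood ratio of the model without it.  Between jump phases the
    component parameters are refreshed by a Gibbs sweep.  The K trajectory
    is histogrammed into a posterior.
    """
    if K_max < 2:
        raise ValueError("K_max must be >= 2")
    x = _validate_lengths(lengths)
    mc = mcmc or MCMCSettings()
    pri = MixturePriors.from_data(x)
    rng = np.random.default_rng(seed)

    K = 1
    mu = np.array([float(np.mean(x))])
    var = np.array([float(np.var(x)) + 1e-6])
    w = np.array([1.0])
    z = np.zeros(len(x), dtype=int)

    ks = []
    max_jumps = 20
    beta = None
    for it in range(mc.n_iter):
        # birth-death phase over one unit of virtual time
        t = 0.0
        for _ in range(max_jumps):
            dens = norm.pdf(x[:, None], mu[None, :], np.sqrt(var)[None, :])
            mix = np.maximum(dens @ w, 1e-300)
            ll_full = np.log(mix).sum()
            death = np.zeros(K)
            if K > 1:
                for j in range(K):
                    mix_wo = np.maximum(
                        (mix - dens[:, j] * w[j]) / max(1.0 - w[j], 1e-12),
                        1e-300)
                    ll_wo = np.log(mix_wo).sum()
                    death[j] = birth_rate * np.exp(
                        np.clip(ll_wo - ll_full, -700, 700))
            birth = birth_rate if K < K_max else 0.0
            total = birth + death.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= 1.0:
                break
            if rng.random() < birth / total:
                w_new = rng.beta(1, K)
                w = np.append(w * (1.0 - w_new), w_new)
                mu = np.append(mu, rng.normal(pri.mean_loc, pri.mean_scale))
                b = pri.var_scale if beta is None else beta
                var = np.append(var, 1.0 / rng.gamma(pri.var_shape, 1.0 / b))
                K += 1
            else:
                j = rng.choice(K, p=death / death.sum())
                w = np.delete(w, j) / max(1.0 - w[j], 1e-12)
                mu = np.delete(mu, j)
                var = np.delete(var, j)
                K -= 1
        z, w, mu, var, beta = _gibbs_sweep(x, z, w, mu, var, pri, rng, beta)
        K = len(w)
        if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0:
            ks.append(K)

    ks = np.array(ks)
    probs = np.bincount(np.clip(ks, 1, K_max), minlength=K_max + 1)[1:]
    probs = probs / probs.sum()
    diagnostics = {"n_draws": len(ks), "stuck": bool(len(np.unique(ks)) == 1)}
    return KPosterior(method="bd_mcmc", probs=probs, diagnostics=diagnostics)


def select_k_and_assign(lengths, kp1: KPosterior, kp2: KPosterior,
                        mcmc: MCMCSettings | None = None, seed: int = 0
                        ) -> tuple[MixtureFit, np.ndarray, int]:
    """Consensus K rule and final fixed-K assignment.

    K* is the shared posterior mode if both selectors agree; otherwise the
    mode with the larger posterior probability.  An exact probability tie
    falls back to the smaller K (parsimony).  Returns the final fit, the
    argmax-responsibility labels, and K*.
    """
    if len(kp1.probs) != len(kp2.probs):
        raise ValueError("K posteriors cover different ranges")
    if kp1.mode == kp2.mode:
        k_star = kp1.mode
    elif kp1.mode_prob > kp2.mode_prob:
        k_star = kp1.mode
    elif kp2.mode_prob > kp1.mode_prob:
        k_star = kp2.mode
    else:
        k_star = min(kp1.mode, kp2.mode)
        warnings.warn("exact posterior-probability tie; choosing smaller K",
                      stacklevel=2)
    fit = fit_mixture_fixed_k(lengths, k_star, mcmc=mcmc, seed=seed)
    return fit, fit.labels, k_star
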