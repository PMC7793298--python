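"""Bayesian multinomial phylogenetic regression for trophic guilds.

Guild membership of species *i* is modeled with a reference-category
multinomial logit,

    Pr(guild k) = exp(mu_k) / sum_j exp(mu_j),   mu_1 = 0,
    mu_k = beta0_k + beta1_k * ln(sizemax_i) + gamma_{i,k}   (k = 2..K),

where the per-category phylogenetic random effect gamma_{.,k} has a
zero-mean Gaussian prior with covariance sigma_k^2 * C, C being the
Brownian-motion correlation implied by the tree. Priors are weakly
informative: Normal(0, 5) on intercepts and slopes, Half-Normal(0, 2.5)
on each sigma_k.

Posterior draws come from a Hamiltonian Monte Carlo sampler with
dual-averaging step-size adaptation and a non-centered parameterization
(gamma = sigma * L z with C = L L'); convergence is summarized by
split-R-hat. Unobserved species are predicted by combining posterior
draws of the fixed effects with the Brownian conditional expectation of
gamma at the new tip given the training tips, repeated over draws and
(optionally) over a set of alternative trees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import logsumexp

from ._phylo import PhyloArrays, prune_to
from .phylo_signal import DiscreteTrait

logger = logging.getLogger(__name__)

__all__ = [
    "GuildModel",
    "phylo_covariance",
    "guild_probability",
    "negentropy",
    "total_sd",
    "fit",
    "fitted_probabilities",
    "extrapolate",
    "loo_cv",
    "extrapolation_pool",
]

_PRIOR_BETA_SD = 5.0
_PRIOR_SIGMA_SD = 2.5
_RHAT_LIMIT = 1.05


# ----------------------------------------------------------------------
# Elementary pieces
# ----------------------------------------------------------------------

def phylo_covariance(tree: dendropy.Tree | PhyloArrays) -> pd.DataFrame:
    """Unit-diagonal Brownian correlation matrix among the tree's tips."""
    arr = tree if isinstance(tree, PhyloArrays) else PhyloArrays.from_dendropy(tree)
    C = arr.brownian_correlation()
    return pd.DataFrame(C, index=arr.labels, columns=arr.labels)


def guild_probability(mu: np.ndarray) -> np.ndarray:
    """Softmax over the K linear predictors (mu[..., 0] must be 0)."""
    mu = np.asarray(mu, dtype=float)
    z = mu - logsumexp(mu, axis=-1, keepdims=True)
    return np.exp(z)


def negentropy(p: np.ndarray) -> float | np.ndarray:
    """Certainty of an assignment: 1 - H(p)/ln(K), in [0, 1]."""
    p = np.asarray(p, dtype=float)
    k = p.shape[-1]
    q = np.where(p > 0, p, 1.0)  # 0*log 0 := 0
    h = -(p * np.log(q)).sum(axis=-1) / np.log(k)
    out = 1.0 - h
    return float(out) if out.ndim == 0 else out


def total_sd(sds: np.ndarray) -> float:
    """Square root of the quadratic sum of per-category SDs."""
    sds = np.asarray(sds, dtype=float)
    if (sds < 0).any():
        raise ValueError("standard deviations must be non-negative")
    return float(np.sqrt((sds ** 2).sum()))


# ----------------------------------------------------------------------
# Model container
# ----------------------------------------------------------------------

@dataclass
class GuildModel:
    """Posterior draws of the multinomial phylogenetic regression."""

    k: int
    species: list[str]
    guilds: np.ndarray              # training categories in 1..K
    log_size: np.ndarray            # raw ln(sizemax)
    log_size_center: float
    corr: pd.DataFrame              # Brownian correlation among species
    beta0: np.ndarray               # (draws, K-1)
    beta1: np.ndarray               # (draws, K-1)
    sigma: np.ndarray               # (draws, K-1)
    gamma: np.ndarray               # (draws, n, K-1)
    rhat: dict[str, float] = field(default_factory=dict)
    accept_rate: float = float("nan")
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[0]

    def linear_predictor(self, idx: np.ndarray | slice = slice(None)) -> np.ndarray:
        """mu for training species: (draws, n, K) with mu[..., 0] = 0."""
        x = self.log_size - self.log_size_center
        mu = (self.beta0[idx, None, :] + self.beta1[idx, None, :] * x[None, :, None]
              + self.gamma[idx])
        zeros = np.zeros(mu.shape[:-1] + (1,))
        return np.concatenate([zeros, mu], axis=-1)


# ----------------------------------------------------------------------
# HMC machinery
# ----------------------------------------------------------------------

class _Posterior:
    """Log posterior and gradient in the unconstrained parameterization.

    theta = [b0, b1, nu, z.ravel()]; all components have standard
    normal priors. beta = 5*b, sigma = 2.5*|nu| (folded normal),
    gamma[:, k] = sigma_k * (L @ z[:, k]).
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, L: np.ndarray, k: int):
        self.y = y  # 0-based categories
        self.x = x  # centered ln size
        self.L = L
        self.k = k
        self.n = y.size
        self.km1 = k - 1
        self.dim = 3 * self.km1 + self.n * self.km1
        self.onehot = np.zeros((self.n, k))
        self._rows = np.arange(self.n)
        self.onehot[self._rows, y] = 1.0

    def unpack(self, theta: np.ndarray):
        km1, n = self.km1, self.n
        b0 = theta[:km1]
        b1 = theta[km1:2 * km1]
        nu = theta[2 * km1:3 * km1]
        z = theta[3 * km1:].reshape(n, km1)
        return b0, b1, nu, z

    def constrained(self, theta: np.ndarray):
        b0, b1, nu, z = self.unpack(theta)
        beta0 = _PRIOR_BETA_SD * b0
        beta1 = _PRIOR_BETA_SD * b1
        sigma = _PRIOR_SIGMA_SD * np.abs(nu)
        Lz = self.L @ z
        gamma = Lz * sigma[None, :]
        return beta0, beta1, sigma, gamma, Lz, nu

    def _mu(self, beta0, beta1, gamma):
        mu = beta0[None, :] + beta1[None, :] * self.x[:, None] + gamma
        return np.concatenate([np.zeros((self.n, 1)), mu], axis=1)

    def logp_grad(self, theta: np.ndarray):
        beta0, beta1, sigma, gamma, Lz, nu = self.constrained(theta)
        mu = self._mu(beta0, beta1, gamma)
        mx = mu.max(axis=1)
        P = np.exp(mu - mx[:, None])
        Z = P.sum(axis=1)
        lse = mx + np.log(Z)
        ll = float(mu[self._rows, self.y].sum() - lse.sum())
        logp = ll - 0.5 * float(theta @ theta)
        P /= Z[:, None]
        E = (self.onehot - P)[:, 1:]  # (n, K-1)
        b0, b1, _, z = self.unpack(theta)
        g_b0 = _PRIOR_BETA_SD * E.sum(axis=0) - b0
        g_b1 = _PRIOR_BETA_SD * (self.x @ E) - b1
        g_nu = _PRIOR_SIGMA_SD * np.sign(nu) * np.einsum("ik,ik->k", Lz, E) - nu
        g_z = (self.L.T @ E) * sigma[None, :] - z
        grad = np.concatenate([g_b0, g_b1, g_nu, g_z.ravel()])
        return logp, grad


def _hmc_chain(post: _Posterior, iterations: int, warmup: int, seed: int,
               leapfrog: int = 15, target_accept: float = 0.8,
               thin: int = 1):
    """One HMC chain: dual-averaging step size + diagonal mass adaptation.

    The inverse mass (per-coordinate posterior variance) is estimated
    from the middle of the warmup window; step-size adaptation restarts
    afterwards, as in the standard windowed scheme.
    """
    rng = np.random.default_rng(seed)
    theta = 0.1 * rng.standard_normal(post.dim)
    logp, grad = post.logp_grad(theta)
    inv_mass = np.ones(post.dim)
    sqrt_inv = np.ones(post.dim)
    # dual averaging (Nesterov) step-size adaptation
    eps = 0.1
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    da_iter = 0
    gamma_da, t0, kappa = 0.05, 10.0, 0.75
    win_lo, win_hi = int(0.25 * warmup), int(0.75 * warmup)
    win_samples: list[np.ndarray] = []
    draws = []
    n_accept = 0
    for it in range(iterations):
        p0 = rng.standard_normal(post.dim) / sqrt_inv
        steps = int(rng.integers(max(1, int(0.8 * leapfrog)),
                                 int(1.2 * leapfrog) + 1))
        th, p, gr = theta.copy(), p0.copy(), grad.copy()
        p = p + 0.5 * eps * gr
        for s in range(steps):
            th = th + eps * (inv_mass * p)
            lp_new, gr = post.logp_grad(th)
            if s < steps - 1:
                p = p + eps * gr
        p = p + 0.5 * eps * gr
        h0 = logp - 0.5 * float((inv_mass * p0) @ p0)
        h1 = lp_new - 0.5 * float((inv_mass * p) @ p)
        log_alpha = min(0.0, h1 - h0) if np.isfinite(h1) else -np.inf
        accept_prob = np.exp(log_alpha)
        if np.log(rng.random()) < log_alpha:
            theta, logp = th, lp_new
            grad = gr
            n_accept += 1
        if it < warmup:
            if win_lo <= it < win_hi:
                win_samples.append(theta.copy())
            da_iter += 1
            w = 1.0 / (da_iter + t0)
            h_bar = (1 - w) * h_bar + w * (target_accept - accept_prob)
            log_eps = mu_da - np.sqrt(da_iter) / gamma_da * h_bar
            eta = da_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it == win_hi - 1 and len(win_samples) >= 20:
                var = np.var(np.asarray(win_samples), axis=0)
                inv_mass = np.clip(var, 1e-3, 1e3)
                sqrt_inv = np.sqrt(inv_mass)
                # restart step-size adaptation under the new metric
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar)) if da_iter else eps
        elif (it - warmup) % thin == 0:
            draws.append(theta.copy())
    return np.array(draws), n_accept / iterations


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chain, n_draw) scalar parameter."""
    try:
        import arviz as az
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(az.rhat(az.convert_to_dataset(chains[:, :, None]))
                         .to_array().values.max())
    except Exception:  # pragma: no cover - arviz always present in practice
        half = chains.shape[1] // 2
        segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
        m, n = segs.shape
        means = segs.mean(axis=1)
        W = segs.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        var = (n - 1) / n * W + B / n
        return float(np.sqrt(var / W))


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

def fit(trait: DiscreteTrait, attrs: pd.DataFrame, tree: dendropy.Tree,
        chains: int = 3, iterations: int = 6000, warmup: int = 1000,
        seed: int = 0, leapfrog: int = 15, thin: int = 1) -> GuildModel:
    """Sample the posterior of the guild model.

    ``iterations`` counts total HMC iterations per chain including the
    ``warmup`` adaptation phase (post-warmup draws are retained, thinned
    by ``thin``). Species are the intersection of the trait table, the
    attribute table and the tree tips; the tree is pruned accordingly.
    """
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    species = sorted(set(trait.states) & set(attrs.index) & tips)
    if not species:
        raise ValueError("no species shared by trait, attributes and tree")
    if len(species) < len(trait.states):
        logger.info("model restricted to %d species common to all inputs",
                    len(species))
    k = trait.k
    if k < 2:
        raise ValueError("need at least 2 guild categories")
    y = np.array([trait.states[sp] - 1 for sp in species])
    log_size = np.log(attrs.loc[species, "max_size_cm"].to_numpy(float))
    center = float(log_size.mean())
    pruned = prune_to(tree, species)
    corr = phylo_covariance(pruned).loc[species, species]
    L = cholesky(corr.values + 1e-10 * np.eye(len(species)), lower=True)

    post = _Posterior(y=y, x=log_size - center, L=L, k=k)
    seeds = np.random.SeedSequence(seed).generate_state(chains) % (2**31)
    chain_draws, accepts = [], []
    for s in seeds:
        d, acc = _hmc_chain(post, iterations, warmup, int(s),
                            leapfrog=leapfrog, thin=thin)
        chain_draws.append(d)
        accepts.append(acc)
    n_keep = min(d.shape[0] for d in chain_draws)
    stacked = np.stack([d[:n_keep] for d in chain_draws])  # (chain, draw, dim)

    km1 = k - 1
    rhat: dict[str, float] = {}
    if chains >= 2 and n_keep >= 4:
        for name, sl in (("beta0", slice(0, km1)),
                         ("beta1", slice(km1, 2 * km1)),
                         ("sigma", slice(2 * km1, 3 * km1))):
            rhat[name] = max(_split_rhat(stacked[:, :, j])
                             for j in range(sl.start, sl.stop))
        # spot-check a handful of latent effects
        z_cols = np.linspace(3 * km1, stacked.shape[2] - 1, num=min(10, post.n),
                             dtype=int)
        rhat["gamma"] = max(_split_rhat(stacked[:, :, j]) for j in z_cols)
        worst = max(rhat.values())
        if worst > _RHAT_LIMIT:
            warnings.warn(
                f"sampler may not have converged: max split-R-hat {worst:.3f} "
                f"(limit {_RHAT_LIMIT}); diagnostics: {rhat}", stacklevel=2)

    flat = stacked.reshape(-1, stacked.shape[2])
    b0 = flat[:, :km1] * _PRIOR_BETA_SD
    b1 = flat[:, km1:2 * km1] * _PRIOR_BETA_SD
    sg = np.abs(flat[:, 2 * km1:3 * km1]) * _PRIOR_SIGMA_SD
    z = flat[:, 3 * km1:].reshape(-1, post.n, km1)
    gamma = np.einsum("ij,djk->dik", L, z) * sg[:, None, :]
    return GuildModel(
        k=k, species=species, guilds=y + 1, log_size=log_size,
        log_size_center=center, corr=corr,
        beta0=b0, beta1=b1, sigma=sg, gamma=gamma,
        rhat=rhat, accept_rate=float(np.mean(accepts)), seed=seed,
    )


# ----------------------------------------------------------------------
# Predictions
# ----------------------------------------------------------------------

def _summarize(probs_sum, probs_sqsum, neg_sum, neg_sqsum, n, species, k):
    mean = probs_sum / n
    var = np.maximum(probs_sqsum / n - mean ** 2, 0.0)
    sd = np.sqrt(var)
    neg_mean = neg_sum / n
    neg_sd = np.sqrt(np.maximum(neg_sqsum / n - neg_mean ** 2, 0.0))
    data = {}
    for j in range(k):
        data[f"p{j + 1}_mean"] = mean[:, j]
        data[f"p{j + 1}_sd"] = sd[:, j]
    df = pd.DataFrame(data, index=species)
    df["total_sd"] = np.sqrt((sd ** 2).sum(axis=1))
    df["negentropy_mean"] = neg_mean
    df["negentropy_sd"] = neg_sd
    df["guild"] = mean.argmax(axis=1) + 1
    return df


def fitted_probabilities(model: GuildModel, chunk: int = 500) -> pd.DataFrame:
    """Posterior guild probabilities for the training species.

    Per-draw softmax probabilities are averaged over draws; negentropy
    is computed per draw and summarized; the assigned guild is the
    argmax of the mean probabilities.
    """
    n, k = len(model.species), model.k
    s_sum = np.zeros((n, k))
    s_sq = np.zeros((n, k))
    g_sum = np.zeros(n)
    g_sq = np.zeros(n)
    for start in range(0, model.n_draws, chunk):
        idx = slice(start, min(start + chunk, model.n_draws))
        p = guild_probability(model.linear_predictor(idx))
        s_sum += p.sum(axis=0)
        s_sq += (p ** 2).sum(axis=0)
        neg = negentropy(p)
        g_sum += neg.sum(axis=0)
        g_sq += (neg ** 2).sum(axis=0)
    return _summarize(s_sum, s_sq, g_sum, g_sq, model.n_draws,
                      model.species, k)


def _conditional_weights(tree: dendropy.Tree, train: list[str],
                         new: list[str]) -> np.ndarray:
    """Brownian conditional-mean weights of new tips given training tips."""
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(new) - tips)
    if missing:
        raise ValueError(f"new species missing from a tree: {missing[:5]}")
    sub = prune_to(tree, list(train) + list(new))
    C = phylo_covariance(sub)
    Ctt = C.loc[train, train].values
    Cnt = C.loc[new, train].values
    fac = cho_factor(Ctt + 1e-10 * np.eye(len(train)), lower=True)
    return cho_solve(fac, Cnt.T).T  # (n_new, n_train)


def extrapolate(model: GuildModel, trees: list[dendropy.Tree] | dendropy.Tree,
                new_species: pd.DataFrame, n_draws: int = 2000,
                seed: int = 0) -> pd.DataFrame:
    """Predict guild probabilities for species not in the training set.

    Per draw, one tree and one posterior draw are sampled; the
    phylogenetic effect at each new tip is its Brownian conditional
    mean given that draw's training-tip effects (the ancestral estimate
    at the tip's attachment point), combined with the draw's intercepts
    and size slopes through the softmax link. Mean and SD per guild are
    reported over draws.
    """
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    new = [sp for sp in new_species.index if sp not in model.species]
    if not new:
        raise ValueError("no new species to extrapolate")
    weights = [_conditional_weights(t, model.species, new) for t in trees]
    x_new = np.log(new_species.loc[new, "max_size_cm"].to_numpy(float))
    x_new = x_new - model.log_size_center

    rng = np.random.default_rng(seed)
    total = model.n_draws
    if n_draws >= total and len(trees) == 1:
        draw_idx = np.arange(total)  # use every posterior draw once
    else:
        draw_idx = rng.integers(0, total, size=n_draws)
    tree_idx = rng.integers(0, len(trees), size=draw_idx.size)

    m, k = len(new), model.k
    s_sum = np.zeros((m, k))
    s_sq = np.zeros((m, k))
    g_sum = np.zeros(m)
    g_sq = np.zeros(m)
    for t in range(len(trees)):
        sel = draw_idx[tree_idx == t]
        if sel.size == 0:
            continue
        gam = np.einsum("mn,dnk->dmk", weights[t], model.gamma[sel])
        mu = (model.beta0[sel, None, :] + model.beta1[sel, None, :]
              * x_new[None, :, None] + gam)
        mu = np.concatenate([np.zeros(mu.shape[:-1] + (1,)), mu], axis=-1)
        p = guild_probability(mu)
        s_sum += p.sum(axis=0)
        s_sq += (p ** 2).sum(axis=0)
        neg = negentropy(p)
        g_sum += neg.sum(axis=0)
        g_sq += (neg ** 2).sum(axis=0)
    return _summarize(s_sum, s_sq, g_sum, g_sq, draw_idx.size, new, k)


def loo_cv(trait: DiscreteTrait, attrs: pd.DataFrame,
           trees: list[dendropy.Tree] | dendropy.Tree,
           chains: int = 1, iterations: int = 600, warmup: int = 250,
           n_draws: int = 200, seed: int = 0,
           leapfrog: int = 12) -> dict:
    """Leave-one-out cross-validation of the extrapolation pipeline.

    Each species in turn is withheld, the model refitted on the rest
    (with a reduced sampling schedule -- an approximation of the full
    budget), and the held-out species predicted by extrapolation. The
    default schedule is the fast mode; pass the full schedule for an
    exact replication.
    """
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    base_tree = trees[0]
    tips = {lf.taxon.label for lf in base_tree.leaf_node_iter()}
    species = sorted(set(trait.states) & set(attrs.index) & tips)
    k = trait.k
    counts = pd.Series([trait.states[sp] for sp in species]).value_counts()
    if (counts < 2).any():
        warnings.warn("some guilds have < 2 species; their LOO folds "
                      "cannot be predicted from same-guild relatives",
                      stacklevel=2)
    seeds = np.random.SeedSequence(seed).generate_state(len(species)) % (2**31)
    records = []
    for fold, sp in enumerate(species):
        held_trait = DiscreteTrait({s: v for s, v in trait.states.items()
                                    if s != sp})
        if held_trait.k < k:
            logger.warning("fold %s: guild disappears without it; skipped", sp)
            continue
        sub_attrs = attrs.drop(index=sp)
        sub_tree = prune_to(base_tree, [s for s in species if s != sp])
        m = fit(held_trait, sub_attrs, sub_tree, chains=chains,
                iterations=iterations, warmup=warmup,
                seed=int(seeds[fold]), leapfrog=leapfrog)
        pred = extrapolate(m, trees, attrs.loc[[sp]], n_draws=n_draws,
                           seed=int(seeds[fold]))
        records.append({"species": sp, "true": trait.states[sp],
                        "predicted": int(pred["guild"].iloc[0])})
    res = pd.DataFrame(records)
    acc = float((res["true"] == res["predicted"]).mean())
    confusion = pd.crosstab(res["true"], res["predicted"]).reindex(
        index=range(1, k + 1), columns=range(1, k + 1), fill_value=0)
    return {"accuracy": acc, "confusion": confusion, "predictions": res}


def extrapolation_pool(species_table: pd.DataFrame, min_size_cm: float = 3.0,
                       include_families: tuple[str, ...] = ()) -> pd.DataFrame:
    """Filter a species table to the extrapolation target pool.

    Keeps species from families with more than one representative in
    the table (plus explicitly included families) whose maximum length
    exceeds ``min_size_cm``.
    """
    fam_counts = species_table["family"].value_counts()
    ok_family = species_table["family"].map(fam_counts).gt(1) | \
        species_table["family"].isin(include_families)
    ok_size = species_table["max_size_cm"] > min_size_cm
    return species_table[ok_family & ok_size].copy()
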