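"""Spike-and-slab shrinkage of log hazard-ratio estimates.

One genetic exposure at a time, the observed log HRs across the disease
panel are modelled as draws from a mixture of a point mass at zero (the
spike) and a 50:50 mixture of normals centred at +-mu (the slab), with the
exposure-specific non-null proportion p_e given a Beta(alpha, beta) prior:

    p_e      ~ Beta(alpha, beta)
    pi_{e,d} ~ Bernoulli(0.5)                         (slab sign)
    b_{e,d}  ~ Bernoulli(p_e) [(1-pi) N(mu, s^2) + pi N(-mu, s^2)]

The measurement model links the Cox estimate to the latent effect as
beta_hat ~ N(b, se^2); integrating b out of the slab analytically gives
marginal component likelihoods N(0, se^2), N(+-mu, s^2 + se^2). A collapsed
Gibbs sampler alternates component labels and p_e; posterior null
probabilities above the threshold (default 10%, strict) mark an estimate
for discarding. An exact 3^d enumeration oracle is provided for small d.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp
from scipy.stats import norm

_LABELS = ("null", "slab_plus", "slab_minus")


@dataclass(frozen=True)
class ShrinkagePrior:
    """Hyperparameters of the spike-and-slab prior and the retention rule.

    Defaults give a prior non-null proportion of alpha/(alpha+beta) = 0.05,
    i.e. 4 expected non-null effects across an 80-disease panel, with slab
    components centred at hazard ratios exp(+-0.3) ~= 1.35 and 0.74.
    """

    alpha: float = 1.0
    beta: float = 19.0
    mu: float = 0.3
    sigma: float = 0.1
    null_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be positive")
        if not 0 < self.null_threshold < 1:
            raise ValueError("null_threshold must lie in (0, 1)")

    @property
    def prior_inclusion(self) -> float:
        """Prior mean of p_e."""
        return self.alpha / (self.alpha + self.beta)

    def expected_nonnull(self, n_diseases: int) -> float:
        """Prior expected number of non-null effects over a disease panel."""
        return n_diseases * self.prior_inclusion


@dataclass
class ShrinkageResult:
    """Posterior null probabilities and retention flags for one or more exposures."""

    table: pd.DataFrame  # columns: exposure_id, disease_id, null_prob, retained
    p_mean: dict = field(default_factory=dict)  # exposure_id -> posterior mean of p_e
    threshold: float = 0.10

    def null_probs(self, exposure_id) -> pd.Series:
        sub = self.table[self.table["exposure_id"] == exposure_id]
        return sub.set_index("disease_id")["null_prob"]


def _component_log_likelihoods(log_hr, se, prior):
    """Per-estimate log density under null / slab+ / slab- (b integrated out).

    Returns an array of shape (..., 3). The 1/2 sign-mixing weight is folded
    into the slab columns so label probabilities are (1-p)*L0, p*L+, p*L-.
    """
    log_hr = np.asarray(log_hr, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    slab_sd = np.sqrt(prior.sigma**2 + se**2)
    l0 = norm.logpdf(log_hr, 0.0, se)
    lp = norm.logpdf(log_hr, prior.mu, slab_sd) + np.log(0.5)
    lm = norm.logpdf(log_hr, -prior.mu, slab_sd) + np.log(0.5)
    return np.stack([l0, lp, lm], axis=-1)


def gibbs_null_probabilities(
    log_hr: np.ndarray,
    se: np.ndarray,
    prior: ShrinkagePrior,
    n_iter: int = 10_000,
    burn_in: int = 1_000,
    seed: int = 0,
):
    """Batched collapsed Gibbs over independent exposures.

    ``log_hr`` and ``se`` have shape (n_exposures, n_diseases); each row is
    one exposure's chain, run in lockstep. Labels are conditionally
    independent given p_e, and p_e | labels is conjugate Beta, so a sweep
    is two vectorized draws.

    Returns (null_prob, p_mean): shapes (E, D) and (E,).
    """
    log_hr = np.atleast_2d(np.asarray(log_hr, dtype=float))
    se = np.atleast_2d(np.asarray(se, dtype=float))
    if log_hr.shape != se.shape:
        raise ValueError("log_hr and se shapes differ")
    if n_iter <= burn_in or burn_in < 0:
        raise ValueError("need n_iter > burn_in >= 0")
    n_exp, n_dis = log_hr.shape
    rng = np.random.default_rng(seed)

    ll = _component_log_likelihoods(log_hr, se, prior)  # (E, D, 3)

    p = np.full(n_exp, prior.prior_inclusion)
    # initial labels from the prior
    labels = (rng.random((n_exp, n_dis)) < p[:, None]).astype(np.int64)
    labels *= rng.integers(1, 3, size=(n_exp, n_dis))

    null_count = np.zeros((n_exp, n_dis))
    p_sum = np.zeros(n_exp)
    kept = 0
    logw = np.empty_like(ll)
    for it in range(n_iter):
        logw[..., 0] = ll[..., 0] + np.log1p(-p)[:, None]
        logp = np.log(p)[:, None]
        logw[..., 1] = ll[..., 1] + logp
        logw[..., 2] = ll[..., 2] + logp
        # normalized cumulative probabilities, sampled by inverse CDF
        logw -= logw.max(axis=-1, keepdims=True)
        w = np.exp(logw)
        w_cum = np.cumsum(w, axis=-1)
        u = rng.random((n_exp, n_dis, 1)) * w_cum[..., -1:]
        labels = (u > w_cum).sum(axis=-1)

        k = (labels > 0).sum(axis=1)
        p = rng.beta(prior.alpha + k, prior.beta + n_dis - k)

        if it >= burn_in:
            null_count += labels == 0
            p_sum += p
            kept += 1

    return null_count / kept, p_sum / kept


def retain_rule(null_prob, threshold: float):
    """Estimates are discarded only when the null probability is strictly
    over the threshold; a value exactly at the threshold is retained."""
    return np.asarray(null_prob) <= threshold


def collapsed_gibbs(
    estimates,
    prior: ShrinkagePrior,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    seed: int = 0,
    exposure_id="exposure",
    disease_ids=None,
) -> ShrinkageResult:
    """Collapsed Gibbs posterior null probabilities for one exposure.

    ``estimates`` is a sequence of (log_hr, se) pairs, one per disease.
    Default iteration counts give 10,000 post burn-in sweeps.
    """
    arr = np.asarray(list(estimates), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("estimates must be (log_hr, se) pairs")
    log_hr, se = arr[:, 0], arr[:, 1]
    null_prob, p_mean = gibbs_null_probabilities(
        log_hr[None, :], se[None, :], prior, n_iter=n_iter, burn_in=burn_in, seed=seed
    )
    null_prob = null_prob[0]
    if disease_ids is None:
        disease_ids = [f"d{i}" for i in range(len(log_hr))]
    table = pd.DataFrame(
        {
            "exposure_id": exposure_id,
            "disease_id": list(disease_ids),
            "null_prob": null_prob,
            "retained": retain_rule(null_prob, prior.null_threshold),
        }
    )
    return ShrinkageResult(table=table, p_mean={exposure_id: p_mean[0]}, threshold=prior.null_threshold)


def exact_posterior_null(estimates, prior: ShrinkagePrior, max_dim: int = 12) -> np.ndarray:
    """Exact marginal posterior null probabilities by 3^d enumeration.

    Each configuration of labels (null / slab+ / slab-) over the d diseases
    carries weight

        B(alpha + k, beta + d - k) / B(alpha, beta) * (1/2)^k * prod_j L_j

    where k is the non-null count and L_j the component likelihood of
    disease j's estimate. Marginals follow by summing normalized weights.
    Only feasible for small d; larger problems must use the Gibbs sampler.
    """
    arr = np.asarray(list(estimates), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("estimates must be (log_hr, se) pairs")
    d = arr.shape[0]
    if d > max_dim:
        raise ValueError(f"d={d} too large for 3^d enumeration; use collapsed_gibbs")
    ll = _component_log_likelihoods(arr[:, 0], arr[:, 1], prior)  # (d, 3), 1/2 folded in

    log_weights = []
    configs = list(itertools.product(range(3), repeat=d))
    for cfg in configs:
        k = sum(1 for c in cfg if c > 0)
        lw = betaln(prior.alpha + k, prior.beta + d - k) - betaln(prior.alpha, prior.beta)
        lw += sum(ll[j, c] for j, c in enumerate(cfg))
        log_weights.append(lw)
    log_weights = np.array(log_weights)
    log_total = logsumexp(log_weights)

    null_prob = np.empty(d)
    for j in range(d):
        mask = np.array([cfg[j] == 0 for cfg in configs])
        null_prob[j] = np.exp(logsumexp(log_weights[mask]) - log_total)
    return null_prob


def exact_marginals(estimates, prior: ShrinkagePrior, max_dim: int = 12) -> np.ndarray:
    """Exact (d, 3) marginal label probabilities, same enumeration as above."""
    arr = np.asarray(list(estimates), dtype=float)
    d = arr.shape[0]
    if d > max_dim:
        raise ValueError(f"d={d} too large for 3^d enumeration")
    ll = _component_log_likelihoods(arr[:, 0], arr[:, 1], prior)
    configs = list(itertools.product(range(3), repeat=d))
    log_weights = np.array(
        [
            betaln(prior.alpha + sum(c > 0 for c in cfg), prior.beta + d - sum(c > 0 for c in cfg))
            - betaln(prior.alpha, prior.beta)
            + sum(ll[j, c] for j, c in enumerate(cfg))
            for cfg in configs
        ]
    )
    log_total = logsumexp(log_weights)
    out = np.empty((d, 3))
    for j in range(d):
        for c in range(3):
            mask = np.array([cfg[j] == c for cfg in configs])
            out[j, c] = np.exp(logsumexp(log_weights[mask]) - log_total)
    return out


def shrink_estimate_set(
    estimates: pd.DataFrame,
    prior: ShrinkagePrior,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    seed: int = 0,
) -> ShrinkageResult:
    """Run the collapsed Gibbs chain for every exposure in an estimate table.

    ``estimates`` needs columns (exposure_id, disease_id, log_hr, se). One
    independent chain per exposure, seeded ``seed + exposure index`` for
    reproducibility. Exposures with differing disease panels are run on
    their own available diseases.
    """
    frames = []
    p_means = {}
    for i, (eid, sub) in enumerate(estimates.groupby("exposure_id", sort=True)):
        res = collapsed_gibbs(
            list(zip(sub["log_hr"], sub["se"])),
            prior,
            n_iter=n_iter,
            burn_in=burn_in,
            seed=seed + i,
            exposure_id=eid,
            disease_ids=list(sub["disease_id"]),
        )
        frames.append(res.table)
        p_means.update(res.p_mean)
    table = pd.concat(frames, ignore_index=True)
    return ShrinkageResult(table=table, p_mean=p_means, threshold=prior.null_threshold)


def filter_by_null_probability(result: ShrinkageResult, estimates: pd.DataFrame):
    """Split an estimate table into retained and discarded halves.

    Retained pairs carry their original (unshrunk) Cox point estimates and
    SEs downstream; discarded pairs are returned separately because the
    correlation-matrix stage consumes exactly those.
    """
    keys = ["exposure_id", "disease_id"]
    flags = result.table[keys + ["retained"]]
    merged = estimates.merge(flags, on=keys, how="left", validate="one_to_one")
    if merged["retained"].isna().any():
        missing = merged.loc[merged["retained"].isna(), keys].head()
        raise KeyError(f"estimates without shrinkage results, e.g.\n{missing}")
    retained = merged[merged["retained"]].drop(columns="retained").reset_index(drop=True)
    discarded = merged[~merged["retained"]].drop(columns="retained").reset_index(drop=True)
    return retained, discarded
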