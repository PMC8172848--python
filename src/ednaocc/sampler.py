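"""MCMC machinery for the two-stage occupancy model.

Latent-state data augmentation: per site an occupancy indicator z, per
sample an eDNA-capture indicator a.  The sampler alternates

1. a | z, theta, p, y   (Bernoulli full conditional, vectorised),
2. z | a, psi, theta    (Bernoulli full conditional; y is conditionally
   independent of z given a),
3. the probability parameters — conjugate Beta full conditionals in the
   covariate-free case, adaptive random-walk Metropolis on logit-scale
   coefficient blocks when probabilities are functions of covariates.

The identifiable orientation theta11 > theta10 and p11 > p10 is enforced
by rejection (redraw for Beta updates, proposal rejection for Metropolis),
preventing the true/false signal modes from label-switching.  Sites with a
confirmed presence have z pinned to 1 throughout.

Per stored draw the per-site occupancy probability is Rao-Blackwellised:
P(z_i = 1 | y_i, current parameters), marginalising the sample states.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, logit

from .data import DetectionDataset
from .params import PARAM_NAMES, MCMCConfig, PriorSpec

__all__ = [
    "occupancy_full_conditional",
    "sample_state_full_conditional",
    "run_mcmc",
]

_ORIENTED_PAIRS = (("theta11", "theta10"), ("p11", "p10"))
_MAX_REJECT = 1000


# --------------------------------------------------------------------------
# full conditionals (exposed for exact checks against direct Bayes rule)
# --------------------------------------------------------------------------
def occupancy_full_conditional(psi, theta11, theta10, a, site_index, n_sites):
    """P(z_i = 1 | a, psi, theta) for every site.

    ``psi``, ``theta11``, ``theta10`` may be scalars or per-site arrays;
    ``a`` is the per-sample capture indicator.
    """
    a = np.asarray(a, dtype=bool)
    site_index = np.asarray(site_index, dtype=np.intp)
    th11 = np.broadcast_to(np.asarray(theta11, dtype=float), (n_sites,))
    th10 = np.broadcast_to(np.asarray(theta10, dtype=float), (n_sites,))
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n_sites,))
    with np.errstate(divide="ignore"):
        c1 = np.where(a, np.log(th11[site_index]), np.log1p(-th11[site_index]))
        c0 = np.where(a, np.log(th10[site_index]), np.log1p(-th10[site_index]))
        s1 = np.bincount(site_index, weights=c1, minlength=n_sites)
        s0 = np.bincount(site_index, weights=c0, minlength=n_sites)
        lo = np.log(psi) - np.log1p(-psi)
    return expit(lo + s1 - s0)


def sample_state_full_conditional(z, theta11, theta10, p11, p10, k, y, site_index):
    """P(a_j = 1 | z, theta, p, y) for every sample.

    Probability parameters may be scalars or per-site arrays.
    """
    site_index = np.asarray(site_index, dtype=np.intp)
    z = np.asarray(z, dtype=bool)
    n_sites = z.size
    k = np.asarray(k, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)

    def per_site(v):
        return np.broadcast_to(np.asarray(v, dtype=float), (n_sites,))[site_index]

    theta = np.where(z[site_index], per_site(theta11), per_site(theta10))
    q11, q10 = per_site(p11), per_site(p10)
    with np.errstate(divide="ignore", invalid="ignore"):
        la1 = np.log(theta) + y * np.log(q11) + (k - y) * np.log1p(-q11)
        la0 = np.log1p(-theta) + y * np.log(q10) + (k - y) * np.log1p(-q10)
        # 0 * log 0 -> 0 for degenerate probabilities
        la1 = np.where((y == 0) & (q11 == 0), np.log(theta), la1)
        la1 = np.where((y == k) & (q11 == 1), np.log(theta), la1)
        la0 = np.where((y == 0) & (q10 == 0), np.log1p(-theta), la0)
        la0 = np.where((y == k) & (q10 == 1), np.log1p(-theta), la0)
    with np.errstate(invalid="ignore"):
        pa = expit(la1 - la0)
    # both branches impossible cannot occur for valid data; guard anyway
    return np.where(np.isnan(pa), 0.5, pa)


def _rao_blackwell_site_occupancy(psi, theta11, theta10, p11, p10, data, log_binom):
    """P(z_i = 1 | y_i, params), marginalising a (per-site arrays allowed)."""
    si, k, y = data.site_index, data.k, data.y
    S = data.n_sites

    def per_site(v):
        return np.broadcast_to(np.asarray(v, dtype=float), (S,))[si]

    def mixture(theta):
        q11, q10 = per_site(p11), per_site(p10)
        with np.errstate(divide="ignore", invalid="ignore"):
            la = np.log(theta) + log_binom + y * np.log(q11) + (k - y) * np.log1p(-q11)
            lb = np.log1p(-theta) + log_binom + y * np.log(q10) + (k - y) * np.log1p(-q10)
            la = np.where((y == 0) & (q11 == 0), np.log(theta) + log_binom, la)
            lb = np.where((y == 0) & (q10 == 0), np.log1p(-theta) + log_binom, lb)
        return np.logaddexp(la, lb)

    f1 = mixture(per_site(theta11))
    f0 = mixture(per_site(theta10))
    s1 = np.bincount(si, weights=f1, minlength=S)
    s0 = np.bincount(si, weights=f0, minlength=S)
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (S,))
    with np.errstate(divide="ignore"):
        lo = np.log(psi) - np.log1p(-psi)
    pz = expit(lo + s1 - s0)
    pz = np.where(data.confirmed, 1.0, pz)
    return pz


# --------------------------------------------------------------------------
# covariate-free chain: conjugate Gibbs
# --------------------------------------------------------------------------
def _init_latent(data: DetectionDataset):
    a = data.y > (data.k // 4)
    z = np.zeros(data.n_sites, dtype=bool)
    np.logical_or.at(z, data.site_index, a)
    z |= data.confirmed
    return z, a


def _draw_oriented_beta(rng, a_hi, b_hi, a_lo, b_lo, prev_hi, prev_lo):
    """Draw (hi, lo) from independent Betas truncated to hi > lo."""
    for _ in range(_MAX_REJECT):
        hi = rng.beta(a_hi, b_hi)
        lo = rng.beta(a_lo, b_lo)
        if hi > lo:
            return hi, lo
    return prev_hi, prev_lo


def _run_chain_conjugate(data, priors: PriorSpec, mcmc: MCMCConfig, rng, constrained):
    k, y, si = data.k, data.y, data.site_index
    S, N = data.n_sites, data.n_samples
    log_binom = gammaln(k + 1) - gammaln(y + 1) - gammaln(k - y + 1)

    z, a = _init_latent(data)
    psi, th11, th10, p11, p10 = 0.5, 0.8, 0.02, 0.8, 0.02
    if constrained:
        th10 = p10 = 0.0
        a = a | (y > 0)
        np.logical_or.at(z, si, a)

    pri = {name: priors.beta_prior(name) for name in PARAM_NAMES}
    n_stored = mcmc.n_stored
    draws = {name: np.empty(n_stored) for name in PARAM_NAMES}
    site_occ = np.empty((n_stored, S))

    total = mcmc.n_burnin + mcmc.n_iterations
    stored = 0
    for it in range(total):
        # --- a | z, theta, p, y
        pa = sample_state_full_conditional(z, th11, th10, p11, p10, k, y, si)
        a = rng.random(N) < pa
        if constrained:
            a[y > 0] = True  # p10 = 0 makes amplification without eDNA impossible

        # --- z | a, psi, theta
        pz = occupancy_full_conditional(psi, th11, th10, a, si, S)
        z = rng.random(S) < pz
        z |= data.confirmed
        if constrained:
            np.logical_or.at(z, si, a)  # theta10 = 0: any captured sample pins z = 1

        # --- conjugate parameter updates
        nz = int(z.sum())
        psi = rng.beta(pri["psi"].a + nz, pri["psi"].b + S - nz)

        z_s = z[si]
        n11, m1 = int(a[z_s].sum()), int(z_s.sum())
        y1, k1 = int(y[a].sum()), int(k[a].sum())
        if constrained:
            th11 = rng.beta(pri["theta11"].a + n11, pri["theta11"].b + m1 - n11)
            p11 = rng.beta(pri["p11"].a + y1, pri["p11"].b + k1 - y1)
        else:
            n10, m0 = int(a[~z_s].sum()), N - m1
            y0, k0 = int(y[~a].sum()), int(k[~a].sum())
            th11, th10 = _draw_oriented_beta(
                rng,
                pri["theta11"].a + n11, pri["theta11"].b + m1 - n11,
                pri["theta10"].a + n10, pri["theta10"].b + m0 - n10,
                th11, th10,
            )
            p11, p10 = _draw_oriented_beta(
                rng,
                pri["p11"].a + y1, pri["p11"].b + k1 - y1,
                pri["p10"].a + y0, pri["p10"].b + k0 - y0,
                p11, p10,
            )

        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thinning == mcmc.thinning - 1:
            for name, v in zip(PARAM_NAMES, (psi, th11, th10, p11, p10)):
                draws[name][stored] = v
            site_occ[stored] = _rao_blackwell_site_occupancy(
                psi, th11, th10, p11, p10, data, log_binom
            )
            stored += 1

    return draws, site_occ


# --------------------------------------------------------------------------
# covariate chain: RWM-within-Gibbs on logit-scale coefficient blocks
# --------------------------------------------------------------------------
def _bernoulli_loglik(eta, x):
    return float(np.sum(x * eta - np.logaddexp(0.0, eta)))


def _binomial_loglik(eta, y, k):
    return float(np.sum(y * eta - k * np.logaddexp(0.0, eta)))


class _CoefBlock:
    """One coefficient vector with its prior and an adaptive RW proposal."""

    def __init__(self, name, design, prior_mean, prior_sd, init):
        self.name = name
        self.X = design  # (rows, d)
        self.mean = prior_mean
        self.sd = prior_sd
        self.beta = init.copy()
        self.log_step = np.log(0.1)
        self.n_adapt = 0

    def log_prior(self, beta):
        return float(-0.5 * np.sum(((beta - self.mean) / self.sd) ** 2))

    def propose(self, rng):
        d = self.beta.size
        return self.beta + np.exp(self.log_step) * rng.standard_normal(d)

    def adapt(self, accept_prob, target=0.3):
        self.n_adapt += 1
        self.log_step += (accept_prob - target) / self.n_adapt**0.6


def _make_design(covariates, names):
    cols = [np.ones(len(covariates))]
    cols += [np.asarray(covariates[c], dtype=float) for c in names]
    return np.column_stack(cols)


def _run_chain_covariate(data, priors, mcmc, rng, constrained, design_spec):
    """design_spec: mapping param name -> tuple of covariate column names."""
    k, y, si = data.k, data.y, data.site_index
    S, N = data.n_sites, data.n_samples
    log_binom = gammaln(k + 1) - gammaln(y + 1) - gammaln(k - y + 1)
    cov = data.covariates

    active = list(PARAM_NAMES)
    if constrained:
        active = ["psi", "theta11", "p11"]

    blocks: dict[str, _CoefBlock] = {}
    for name in active:
        names = tuple(design_spec.get(name, ()))
        X = _make_design(cov, names) if names else np.ones((S, 1))
        means, sds = priors.coefficient_priors(name, len(names))
        init = np.concatenate([[priors.intercept_prior(name).mean], np.zeros(len(names))])
        blocks[name] = _CoefBlock(name, X, means, sds, init)

    def prob(name):
        if name not in blocks:  # constrained false-positive rates
            return np.zeros(S)
        b = blocks[name]
        return expit(b.X @ b.beta)

    z, a = _init_latent(data)
    if constrained:
        a = a | (y > 0)
        np.logical_or.at(z, si, a)

    def block_loglik(name, beta, z, a):
        b = blocks[name]
        if name == "psi":
            return _bernoulli_loglik(b.X @ beta, z)
        if name in ("theta11", "theta10"):
            rows = z[si] if name == "theta11" else ~z[si]
            eta = (b.X @ beta)[si][rows]
            return _bernoulli_loglik(eta, a[rows])
        rows = a if name == "p11" else ~a
        eta = (b.X @ beta)[si][rows]
        return _binomial_loglik(eta, y[rows], k[rows])

    def orientation_ok(name, beta):
        # compare baseline (intercept) probabilities of each oriented pair
        for hi, lo in _ORIENTED_PAIRS:
            if constrained:
                continue
            b_hi = beta[0] if name == hi else blocks[hi].beta[0]
            b_lo = beta[0] if name == lo else blocks[lo].beta[0]
            if name in (hi, lo) and b_hi <= b_lo:
                return False
        return True

    n_stored = mcmc.n_stored
    coef_names = [
        f"beta_{name}_{label}"
        for name in active
        for label in ("intercept", *design_spec.get(name, ()))
    ]
    draws = {name: np.empty(n_stored) for name in PARAM_NAMES}
    coef_draws = {c: np.empty(n_stored) for c in coef_names}
    site_occ = np.empty((n_stored, S))

    total = mcmc.n_burnin + mcmc.n_iterations
    stored = 0
    for it in range(total):
        psi_i = prob("psi")
        th11_i, th10_i = prob("theta11"), prob("theta10")
        p11_i, p10_i = prob("p11"), prob("p10")

        pa = sample_state_full_conditional(z, th11_i, th10_i, p11_i, p10_i, k, y, si)
        a = rng.random(N) < pa
        if constrained:
            a[y > 0] = True

        pz = occupancy_full_conditional(psi_i, th11_i, th10_i, a, si, S)
        z = rng.random(S) < pz
        z |= data.confirmed
        if constrained:
            np.logical_or.at(z, si, a)

        for name in active:
            b = blocks[name]
            proposal = b.propose(rng)
            if not orientation_ok(name, proposal):
                accept_prob = 0.0
            else:
                log_alpha = (
                    block_loglik(name, proposal, z, a)
                    - block_loglik(name, b.beta, z, a)
                    + b.log_prior(proposal)
                    - b.log_prior(b.beta)
                )
                accept_prob = float(np.exp(min(0.0, log_alpha)))
                if rng.random() < accept_prob:
                    b.beta = proposal
            if it < mcmc.n_burnin:
                b.adapt(accept_prob)

        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thinning == mcmc.thinning - 1:
            for name in PARAM_NAMES:
                draws[name][stored] = (
                    expit(blocks[name].beta[0]) if name in blocks else 0.0
                )
            for name in active:
                b = blocks[name]
                for j, label in enumerate(("intercept", *design_spec.get(name, ()))):
                    coef_draws[f"beta_{name}_{label}"][stored] = b.beta[j]
            site_occ[stored] = _rao_blackwell_site_occupancy(
                prob("psi"), prob("theta11"), prob("theta10"),
                prob("p11"), prob("p10"), data, log_binom,
            )
            stored += 1

    draws.update(coef_draws)
    return draws, site_occ


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------
def run_mcmc(
    data: DetectionDataset,
    priors: PriorSpec,
    mcmc: MCMCConfig,
    constrained: bool = False,
    design_spec=None,
):
    """Run ``mcmc.n_chains`` chains; return stacked draws and site posteriors.

    Returns
    -------
    draws : dict[str, ndarray]
        Each value has shape ``(n_chains, n_stored)``; keys are the five
        probability names (baseline scale) plus coefficient names when a
        covariate design is used.
    site_occ : ndarray, shape (n_chains, n_stored, S)
        Rao-Blackwellised per-site occupancy probabilities per stored draw.
    """
    root = np.random.SeedSequence(mcmc.seed)
    chain_draws, chain_occ = [], []
    for child in root.spawn(mcmc.n_chains):
        rng = np.random.default_rng(child)
        if design_spec:
            d, occ = _run_chain_covariate(data, priors, mcmc, rng, constrained, design_spec)
        else:
            d, occ = _run_chain_conjugate(data, priors, mcmc, rng, constrained)
        chain_draws.append(d)
        chain_occ.append(occ)
    keys = chain_draws[0].keys()
    draws = {key: np.stack([c[key] for c in chain_draws]) for key in keys}
    site_occ = np.stack(chain_occ)
    return draws, site_occ
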