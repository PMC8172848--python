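"""Exact marginal likelihood of the two-stage occupancy model and derived
quantities.

A site is occupied with probability ``psi``.  Each of its M water samples
captures target eDNA with probability ``theta11`` if the site is occupied
and ``theta10`` if not.  Each of the K qPCR replicates run on a sample
amplifies with probability ``p11`` if the sample is eDNA-positive and
``p10`` if not.  Marginalising the latent sample states gives, per sample,

    f_z(y) = theta_z1 * Binom(y; K, p11) + (1 - theta_z1) * Binom(y; K, p10)

with ``theta_11`` for occupied and ``theta_10`` for unoccupied sites, and
the site marginal likelihood

    P(y_1..y_M) = (1 - psi) * prod_j f_0(y_j) + psi * prod_j f_1(y_j).
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .data import DetectionDataset
from .params import ModelParams

__all__ = [
    "site_marginal_likelihood",
    "site_log_likelihood_parts",
    "dataset_log_likelihood",
    "site_occupancy_given_data",
    "conditional_absence_probability",
    "posterior_absence_curve",
    "naive_occupancy",
    "replicate_count_spectrum",
]


def _as_ky(samples) -> tuple[np.ndarray, np.ndarray]:
    arr = np.atleast_2d(np.asarray(samples, dtype=np.int64))
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("samples must be a non-empty sequence of (K, y) pairs")
    k, y = arr[:, 0], arr[:, 1]
    if np.any(k < 1):
        raise ValueError("K must be >= 1 for every sample")
    if np.any((y < 0) | (y > k)):
        raise ValueError("need 0 <= y <= K for every sample")
    return k, y


def _sample_log_mixture(theta: float, k, y, p11: float, p10: float) -> np.ndarray:
    """log[ theta * B(y;K,p11) + (1-theta) * B(y;K,p10) ], elementwise."""
    with np.errstate(divide="ignore"):
        la = np.log(theta) + binom.logpmf(y, k, p11)
        lb = np.log1p(-theta) + binom.logpmf(y, k, p10)
    return logsumexp(np.stack([la, lb]), axis=0)


def site_log_likelihood_parts(params: ModelParams, samples) -> tuple[float, float]:
    """The two addends of the site marginal likelihood, in log space.

    Returns ``(log P(z=0, y), log P(z=1, y))`` where ``y`` is the tuple of
    positive-replicate counts across the site's samples.
    """
    k, y = _as_ky(samples)
    with np.errstate(divide="ignore"):
        log_absent = np.log1p(-params.psi) + float(
            _sample_log_mixture(params.theta10, k, y, params.p11, params.p10).sum()
        )
        log_present = np.log(params.psi) if params.psi > 0 else -np.inf
    log_present = log_present + float(
        _sample_log_mixture(params.theta11, k, y, params.p11, params.p10).sum()
    )
    return log_absent, log_present


def site_marginal_likelihood(params: ModelParams, samples) -> float:
    """P(y_1..y_M) for one site, marginalised over both latent stages.

    ``samples`` is a sequence of ``(K, y)`` pairs.  The value is returned on
    the probability scale; use :func:`dataset_log_likelihood` for products
    over many sites.
    """
    la, lp = site_log_likelihood_parts(params, samples)
    return float(np.exp(logsumexp([la, lp])))


def dataset_log_likelihood(params: ModelParams, dataset: DetectionDataset) -> float:
    """Log-likelihood of a full dataset (sum of site log marginals)."""
    with np.errstate(divide="ignore"):
        f0 = _sample_log_mixture(params.theta10, dataset.k, dataset.y, params.p11, params.p10)
        f1 = _sample_log_mixture(params.theta11, dataset.k, dataset.y, params.p11, params.p10)
        s0 = np.bincount(dataset.site_index, weights=f0, minlength=dataset.n_sites)
        s1 = np.bincount(dataset.site_index, weights=f1, minlength=dataset.n_sites)
        l0 = np.log1p(-params.psi) + s0
        l1 = (np.log(params.psi) if params.psi > 0 else -np.inf) + s1
    return float(logsumexp(np.stack([l0, l1]), axis=0).sum())


def site_occupancy_given_data(params: ModelParams, samples) -> float:
    """P(z = 1 | y_1..y_M) for one site under fixed parameters."""
    la, lp = site_log_likelihood_parts(params, samples)
    denom = logsumexp([la, lp])
    if np.isneginf(denom):
        raise ValueError("data has probability zero under these parameters")
    return float(np.exp(lp - denom))


def conditional_absence_probability(params: ModelParams, x: int, k: int) -> float:
    """P(species absent | x of K qPCR replicates amplified), single sample.

    This is the baseline-site quantity: with identifiable orientation
    (``theta11 > theta10``, ``p11 > p10``) it is non-increasing in ``x`` —
    the more replicates amplify, the less tenable absence becomes.
    """
    if not 0 <= x <= k:
        raise ValueError(f"need 0 <= x <= K (got x={x}, K={k})")
    return 1.0 - site_occupancy_given_data(params, [(k, x)])


def posterior_absence_curve(draws, k: int, x=None) -> np.ndarray:
    """Posterior-averaged conditional absence probabilities.

    ``draws`` is a DataFrame (or mapping of arrays) with columns
    ``psi, theta11, theta10, p11, p10``; the curve averages the plug-in
    Bayes ratio over the posterior draws, the default reading of a
    "posterior conditional probability".  ``x`` defaults to ``0..K``.
    """
    xs = np.arange(k + 1) if x is None else np.atleast_1d(np.asarray(x, dtype=np.int64))
    if np.any((xs < 0) | (xs > k)):
        raise ValueError("need 0 <= x <= K")
    psi = np.asarray(draws["psi"], dtype=float)
    th11 = np.asarray(draws["theta11"], dtype=float)
    th10 = np.asarray(draws["theta10"], dtype=float)
    p11 = np.asarray(draws["p11"], dtype=float)
    p10 = np.asarray(draws["p10"], dtype=float)
    out = np.empty(xs.size, dtype=float)
    for i, xv in enumerate(xs):
        f1 = th11 * binom.pmf(xv, k, p11) + (1 - th11) * binom.pmf(xv, k, p10)
        f0 = th10 * binom.pmf(xv, k, p11) + (1 - th10) * binom.pmf(xv, k, p10)
        out[i] = np.mean((1 - psi) * f0 / ((1 - psi) * f0 + psi * f1))
    return out if x is None or np.ndim(x) else float(out[0])


def naive_occupancy(dataset: DetectionDataset, threshold: int = 1) -> float:
    """Fraction of sites with >= 1 sample reaching ``threshold`` positives.

    The error-free summary practitioners quote ("naive occupancy"): a site
    counts as occupied if any of its samples had at least ``threshold``
    amplifying replicates.  Non-increasing in ``threshold``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return float(np.mean(dataset.max_y_per_site() >= threshold))


def replicate_count_spectrum(dataset: DetectionDataset) -> dict[int, int]:
    """Frequency table of positive-replicate counts y across all samples.

    With a shared K the keys run over the observed values of ``y``; the
    counts sum to the total number of samples.  Real eDNA data typically
    shows a bimodal spectrum (mass at 0/low counts and at y = K).
    """
    return dict(sorted(Counter(dataset.y.tolist()).items()))
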