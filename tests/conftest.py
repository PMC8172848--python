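"""Shared fixtures and independent oracles.

The brute-force functions here enumerate every latent configuration
explicitly with Python scalars — deliberately naive, and independent of the
vectorised log-space implementations they check.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ednaocc import DetectionDataset, ModelParams

#: the simulation study's generating values
PAPER_PARAMS = ModelParams(psi=0.1, theta11=0.85, theta10=0.01, p11=0.9, p10=0.01)

#: full-model posterior means from the newt case study (baseline site)
TABLE1_PARAMS = ModelParams(psi=0.26, theta11=0.77, theta10=0.02, p11=0.84, p10=0.02)


@pytest.fixture
def paper_params():
    return PAPER_PARAMS


@pytest.fixture
def table1_params():
    return TABLE1_PARAMS


# ---------------------------------------------------------------- oracles
def binom_pmf(y, k, p):
    """Binomial pmf with the 0^0 = 1 convention, in plain Python."""
    return math.comb(k, y) * p**y * (1.0 - p) ** (k - y)


def brute_force_site_likelihood(params: ModelParams, samples) -> float:
    """P(y_1..y_M) by exhaustive enumeration over (z, a_1..a_M)."""
    total = 0.0
    M = len(samples)
    for z in (0, 1):
        pz = params.psi if z else 1.0 - params.psi
        theta = params.theta11 if z else params.theta10
        for a_vec in itertools.product((0, 1), repeat=M):
            term = pz
            for a, (k, y) in zip(a_vec, samples):
                term *= theta if a else 1.0 - theta
                p = params.p11 if a else params.p10
                term *= binom_pmf(y, k, p)
            total += term
    return total


def brute_force_occupancy_given_data(params: ModelParams, samples) -> float:
    """P(z = 1 | y) by enumerating the two addends of the marginal."""
    joint = {}
    for z in (0, 1):
        pz = params.psi if z else 1.0 - params.psi
        theta = params.theta11 if z else params.theta10
        total = pz
        for k, y in samples:
            total *= theta * binom_pmf(y, k, params.p11) + (1.0 - theta) * binom_pmf(
                y, k, params.p10
            )
        joint[z] = total
    return joint[1] / (joint[0] + joint[1])


def random_oriented_params(rng) -> ModelParams:
    """A random parameter draw respecting the identifiable orientation."""
    psi = rng.uniform(0.01, 0.99)
    lo, hi = sorted(rng.uniform(0.0, 1.0, size=2))
    plo, phi = sorted(rng.uniform(0.0, 1.0, size=2))
    return ModelParams(psi=psi, theta11=hi, theta10=lo, p11=phi, p10=plo)


# ---------------------------------------------------------------- datasets
def make_dataset(site_records, covariates=None) -> DetectionDataset:
    """Build a dataset from [(site_id, confirmed, [(K, y), ...]), ...]."""
    site_ids, site_index, sample_ids, ks, ys, confirmed = [], [], [], [], [], []
    for i, (sid, conf, samples) in enumerate(site_records):
        site_ids.append(sid)
        confirmed.append(conf)
        for j, (k, y) in enumerate(samples):
            site_index.append(i)
            sample_ids.append(f"s{j + 1}")
            ks.append(k)
            ys.append(y)
    return DetectionDataset(
        site_ids=np.array(site_ids),
        site_index=np.array(site_index),
        sample_ids=np.array(sample_ids),
        k=np.array(ks),
        y=np.array(ys),
        confirmed=np.array(confirmed),
        covariates=None if covariates is None else pd.DataFrame(covariates),
    )


@pytest.fixture
def toy_dataset():
    """4 sites, max y per site = (0, 1, 2, 3) at K = 4."""
    return make_dataset(
        [
            ("A", False, [(4, 0), (4, 0)]),
            ("B", False, [(4, 1), (4, 0)]),
            ("C", False, [(4, 2), (4, 1)]),
            ("D", False, [(4, 3), (4, 3)]),
        ]
    )
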