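"""Synthetic eDNA survey data with the two-stage error structure.

Generates datasets matching the structure of the simulation study: S
independent sites, M water samples per site, K qPCR replicates per sample;
Bernoulli occupancy, Bernoulli per-sample eDNA capture conditional on
occupancy, Binomial replicate amplification conditional on the sample
state.  One standard-normal continuous covariate and one Bernoulli(0.5)
binary covariate per site can be attached (as generated, their effects are
zero unless covariate-scale parameters are supplied — in the study they
exist purely to restore identifiability at M = 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DetectionDataset, write_detection_csv
from .params import CovariateModelParams, ModelParams

__all__ = ["SimulationConfig", "simulate_dataset", "simulate_grid", "cell_seed"]

#: default names for the two identifiability covariates
COVARIATE_NAMES = ("cov_continuous", "cov_binary")


class IdentifiabilityWarning(UserWarning):
    """Raised for configurations where true/false positive rates may not be
    separable from the data alone (e.g. M = 1 with no covariates)."""


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated survey design.

    Parameters
    ----------
    S, M, K
        Number of sites, water samples per site, qPCR replicates per sample.
    params
        Generating probabilities, either constant (:class:`ModelParams`) or
        covariate-dependent (:class:`CovariateModelParams`).
    include_covariates
        Attach the continuous + binary site covariates.
    seed
        Seed for the dataset's private random generator.
    """

    S: int
    M: int
    K: int
    params: ModelParams | CovariateModelParams = field(
        default_factory=lambda: ModelParams(0.1, 0.85, 0.01, 0.9, 0.01)
    )
    include_covariates: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("S", "M", "K"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.M == 1 and not self.include_covariates:
            warnings.warn(
                "M = 1 with no covariates and no confirmed presences is not "
                "identifiable without informative priors",
                IdentifiabilityWarning,
                stacklevel=3,
            )


def _site_probabilities(config: SimulationConfig, covariates: pd.DataFrame | None):
    """Per-site psi/theta/p arrays (length S each)."""
    S = config.S
    if isinstance(config.params, CovariateModelParams):
        if covariates is None:
            covariates = pd.DataFrame(index=range(S))
        return {
            name: np.broadcast_to(config.params.probability(name, covariates), (S,))
            for name in ("psi", "theta11", "theta10", "p11", "p10")
        }
    p = config.params
    return {
        name: np.full(S, getattr(p, name)) for name in ("psi", "theta11", "theta10", "p11", "p10")
    }


def simulate_dataset(config: SimulationConfig, return_latent: bool = False):
    """Draw one dataset from the two-stage generative model.

    Per site i: z_i ~ Bern(psi_i); per sample j of site i:
    a_ij ~ Bern(theta11_i) if z_i = 1 else Bern(theta10_i);
    y_ij ~ Binom(K, p11_i) if a_ij = 1 else Binom(K, p10_i).
    The same seed always yields the identical dataset.

    With ``return_latent=True`` also returns the latent site occupancy ``z``
    and per-sample capture states ``a`` (useful for calibration checks; real
    surveys never observe them).
    """
    rng = np.random.default_rng(config.seed)
    S, M, K = config.S, config.M, config.K

    covariates = None
    if config.include_covariates:
        covariates = pd.DataFrame(
            {
                COVARIATE_NAMES[0]: rng.standard_normal(S),
                COVARIATE_NAMES[1]: rng.binomial(1, 0.5, size=S).astype(float),
            }
        )

    probs = _site_probabilities(config, covariates)
    z = rng.random(S) < probs["psi"]

    site_index = np.repeat(np.arange(S, dtype=np.intp), M)
    theta = np.where(z, probs["theta11"], probs["theta10"])[site_index]
    a = rng.random(S * M) < theta
    p_amp = np.where(a, probs["p11"][site_index], probs["p10"][site_index])
    y = rng.binomial(K, p_amp)

    dataset = DetectionDataset(
        site_ids=np.array([f"site_{i:05d}" for i in range(S)]),
        site_index=site_index,
        sample_ids=np.array([f"s{j % M + 1}" for j in range(S * M)]),
        k=np.full(S * M, K, dtype=np.int64),
        y=y,
        confirmed=np.zeros(S, dtype=bool),
        covariates=covariates,
    )
    if return_latent:
        return dataset, z, a
    return dataset


def cell_seed(base_seed: int, S: int, M: int, K: int, repeat: int) -> int:
    """Deterministic, order-independent seed for one (S, M, K, repeat) cell."""
    ss = np.random.SeedSequence([int(base_seed), int(S), int(M), int(K), int(repeat)])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_grid(
    S_list,
    M_list,
    K_list,
    repeats: int,
    params: ModelParams | CovariateModelParams,
    base_seed: int,
    include_covariates: bool = True,
) -> dict[tuple[int, int, int, int], DetectionDataset]:
    """Simulate the full (S, M, K) x repeats design grid.

    Returns a dict keyed by ``(S, M, K, repeat)``.  Seeds derive from
    ``base_seed`` and the cell key only, so any subset of cells can be
    regenerated independently and in any order.
    """
    if not (len(S_list) and len(M_list) and len(K_list)):
        raise ValueError("grid lists must be non-empty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    out = {}
    for S in S_list:
        for M in M_list:
            for K in K_list:
                for r in range(repeats):
                    cfg = SimulationConfig(
                        S=S,
                        M=M,
                        K=K,
                        params=params,
                        include_covariates=include_covariates,
                        seed=cell_seed(base_seed, S, M, K, r),
                    )
                    out[(S, M, K, r)] = simulate_dataset(cfg)
    return out


def write_simulation(dataset: DetectionDataset, config: SimulationConfig, out_dir) -> None:
    """Write a dataset plus a sidecar JSON recording its configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_detection_csv(dataset, out_dir / "detections.csv")
    params = config.params
    sidecar = {
        "S": config.S,
        "M": config.M,
        "K": config.K,
        "seed": config.seed,
        "include_covariates": config.include_covariates,
        "params": params.as_dict() if isinstance(params, ModelParams) else {
            f"beta_{n}": list(params.coefficients(n))
            for n in ("psi", "theta11", "theta10", "p11", "p10")
        },
    }
    (out_dir / "simulation_config.json").write_text(json.dumps(sidecar, indent=2))
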