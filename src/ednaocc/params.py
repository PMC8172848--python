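"""Parameter containers for the two-stage occupancy model.

The model has five probabilities:

========  ===========================================================
``psi``      probability a site is occupied
``theta11``  stage-1 true positive: a water sample captures target
             eDNA given the site is occupied
``theta10``  stage-1 false positive: a sample "captures" signal given
             the site is unoccupied
``p11``      stage-2 true positive: a single qPCR replicate amplifies
             given the sample is eDNA-positive
``p10``      stage-2 false positive: a replicate amplifies given the
             sample is eDNA-negative
========  ===========================================================

Complements (``theta01 = 1 - theta11`` etc.) are never stored; they are
always computed on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

#: canonical ordering of the five model probabilities
PARAM_NAMES: tuple[str, ...] = ("psi", "theta11", "theta10", "p11", "p10")


@dataclass(frozen=True)
class ModelParams:
    """The five probabilities of the two-stage occupancy model.

    All values must lie in ``[0, 1]``.  The identifiable orientation
    ``theta11 >= theta10`` and ``p11 >= p10`` is required (equality is
    permitted so that degenerate limits, e.g. the no-information case
    ``theta11 == theta10``, remain expressible; the MCMC sampler enforces
    the strict orientation by rejection).
    """

    psi: float
    theta11: float
    theta10: float
    p11: float
    p10: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        if self.theta11 < self.theta10:
            raise ValueError(
                f"identifiable orientation requires theta11 >= theta10 "
                f"(got {self.theta11} < {self.theta10})"
            )
        if self.p11 < self.p10:
            raise ValueError(
                f"identifiable orientation requires p11 >= p10 "
                f"(got {self.p11} < {self.p10})"
            )

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParams":
        return cls(**{name: float(d[name]) for name in PARAM_NAMES})

    def constrained(self) -> "ModelParams":
        """Return a copy with both false-positive probabilities fixed to 0."""
        return replace(self, theta10=0.0, p10=0.0)


#: generating values used throughout the simulation study
DEFAULT_SIMULATION_PARAMS = ModelParams(
    psi=0.1, theta11=0.85, theta10=0.01, p11=0.9, p10=0.01
)


@dataclass(frozen=True)
class CovariateModelParams:
    """Logit-scale regression coefficients for the five probabilities.

    Each coefficient vector starts with an intercept followed by one entry
    per covariate named in ``design[param]``.  With every covariate at 0
    (continuous covariates centred, categorical at baseline) the implied
    probabilities define the *baseline site*.

    Parameters
    ----------
    beta_psi, beta_theta11, beta_theta10, beta_p11, beta_p10
        Coefficient vectors, intercept first.
    design
        Mapping from parameter name to the tuple of covariate names entering
        its linear predictor.  Parameters absent from the mapping get an
        intercept-only design.
    """

    beta_psi: tuple[float, ...]
    beta_theta11: tuple[float, ...]
    beta_theta10: tuple[float, ...]
    beta_p11: tuple[float, ...]
    beta_p10: tuple[float, ...]
    design: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "design", dict(self.design))
        for name in PARAM_NAMES:
            beta = np.asarray(self.coefficients(name), dtype=float)
            if beta.ndim != 1 or beta.size < 1:
                raise ValueError(f"beta_{name} must be a non-empty 1-d vector")
            if not np.all(np.isfinite(beta)):
                raise ValueError(f"beta_{name} contains non-finite values")
            expected = 1 + len(self.design.get(name, ()))
            if beta.size != expected:
                raise ValueError(
                    f"beta_{name} has {beta.size} entries but the design implies "
                    f"{expected} (intercept + covariates {self.design.get(name, ())})"
                )

    def coefficients(self, name: str) -> tuple[float, ...]:
        return getattr(self, f"beta_{name}")

    def linear_predictor(self, name: str, covariates) -> np.ndarray:
        """Evaluate ``X @ beta`` for parameter ``name`` on a covariate table."""
        beta = np.asarray(self.coefficients(name), dtype=float)
        cols = self.design.get(name, ())
        eta = np.full(len(covariates), beta[0], dtype=float)
        for b, col in zip(beta[1:], cols):
            eta += b * np.asarray(covariates[col], dtype=float)
        return eta

    def probability(self, name: str, covariates) -> np.ndarray:
        return expit(self.linear_predictor(name, covariates))

    def baseline(self) -> ModelParams:
        """Probabilities at the baseline site (all covariates zero)."""
        return ModelParams(
            **{name: float(expit(self.coefficients(name)[0])) for name in PARAM_NAMES}
        )

    @classmethod
    def from_probabilities(
        cls, params: ModelParams, design: Mapping[str, Sequence[str]] | None = None
    ) -> "CovariateModelParams":
        """Intercept-only coefficients reproducing constant probabilities.

        Covariate slots named in ``design`` are filled with zero effects
        (decoy covariates, as in the simulation study).
        """
        design = {k: tuple(v) for k, v in (design or {}).items()}
        kwargs = {}
        for name in PARAM_NAMES:
            p = getattr(params, name)
            intercept = float(logit(min(max(p, 1e-12), 1 - 1e-12)))
            kwargs[f"beta_{name}"] = (intercept,) + (0.0,) * len(design.get(name, ()))
        return cls(design=design, **kwargs)


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior on a probability."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta hyperparameters must be strictly positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class NormalPrior:
    """Normal(mean, sd^2) prior on a logit-scale coefficient."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("Normal prior scale must be strictly positive")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the occupancy model.

    Defaults follow the informative-prior identifiability device: flat
    Beta(1, 1) on ``psi``, ``theta11`` and ``p11`` but Beta(1, 19)
    (mean 0.05) on the false-positive probabilities ``theta10`` and
    ``p10``, concentrating them near zero.  On the logit scale the
    intercept priors mirror the same asymmetry and covariate slopes get
    Normal(0, 1.5^2).
    """

    psi: BetaPrior = BetaPrior(1.0, 1.0)
    theta11: BetaPrior = BetaPrior(1.0, 1.0)
    theta10: BetaPrior = BetaPrior(1.0, 19.0)
    p11: BetaPrior = BetaPrior(1.0, 1.0)
    p10: BetaPrior = BetaPrior(1.0, 19.0)
    slope: NormalPrior = NormalPrior(0.0, 1.5)
    intercept_tp: NormalPrior = NormalPrior(0.0, 1.5)
    intercept_fp: NormalPrior = NormalPrior(float(logit(0.05)), 1.0)

    def beta_prior(self, name: str) -> BetaPrior:
        return getattr(self, name)

    def intercept_prior(self, name: str) -> NormalPrior:
        return self.intercept_fp if name in ("theta10", "p10") else self.intercept_tp

    def coefficient_priors(self, name: str, n_covariates: int) -> tuple[np.ndarray, np.ndarray]:
        """(means, sds) for intercept + ``n_covariates`` slopes of ``name``."""
        inter = self.intercept_prior(name)
        means = np.array([inter.mean] + [self.slope.mean] * n_covariates)
        sds = np.array([inter.sd] + [self.slope.sd] * n_covariates)
        return means, sds


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC run settings.

    Defaults mirror the study's short runs (1 chain, 1000 burn-in, 2000
    iterations, thinning 10); for final inference longer chains are
    recommended.
    """

    n_burnin: int = 1000
    n_iterations: int = 2000
    thinning: int = 10
    n_chains: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_burnin", "n_iterations", "thinning", "n_chains"):
            if getattr(self, name) < 1 and name != "n_burnin":
                raise ValueError(f"{name} must be positive")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be non-negative")
        if self.n_iterations % self.thinning:
            raise ValueError("n_iterations must be a multiple of thinning")

    @property
    def n_stored(self) -> int:
        """Stored draws per chain."""
        return self.n_iterations // self.thinning
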