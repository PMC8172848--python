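"""Scikit-learn style estimators for Bayesian two-stage occupancy modelling.

:class:`MultiScaleOccupancyModel` is the user-facing estimator.  Fitting
runs the latent-state MCMC sampler; fitted attributes follow the sklearn
trailing-underscore convention and the full posterior is available as a
:class:`PosteriorResult`.  The no-false-positive variant (theta10 = p10
fixed to 0, the classical multi-scale occupancy model) is obtained with
``false_positives=False``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import DetectionDataset
from .params import PARAM_NAMES, MCMCConfig, PriorSpec
from .sampler import run_mcmc
from .simulate import IdentifiabilityWarning

__all__ = [
    "PosteriorResult",
    "ModelComparison",
    "MultiScaleOccupancyModel",
    "fit_full_model",
    "fit_no_false_positive_model",
    "site_occupancy_posteriors",
    "compare_models",
]


@dataclass
class PosteriorResult:
    """Posterior summaries and draws from one fitted occupancy model.

    Attributes
    ----------
    draws : DataFrame
        One row per stored draw (chains concatenated), one column per
        parameter: the five probabilities on the baseline scale plus any
        logit-scale coefficients.
    summary : DataFrame
        Indexed by parameter: posterior mean, 95% credible interval bounds
        (2.5% / 97.5% quantiles), effective sample size and split R-hat.
    site_occupancy : DataFrame
        Per site: posterior mean occupancy probability and its 95% interval.
    model_variant : str
        ``"full"`` or ``"no_false_positives"``.
    """

    draws: pd.DataFrame
    summary: pd.DataFrame
    site_occupancy: pd.DataFrame
    model_variant: str
    n_chains: int
    n_stored: int

    def pci_width(self, name: str) -> float:
        """Width of the 95% posterior credible interval for ``name``."""
        row = self.summary.loc[name]
        return float(row["pci_upper"] - row["pci_lower"])

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(out_dir / "posterior_draws.csv", index=False)
        self.site_occupancy.to_csv(out_dir / "site_occupancy.csv", index=False)
        payload = {
            "model_variant": self.model_variant,
            "n_chains": self.n_chains,
            "n_stored": self.n_stored,
            "parameters": {
                name: {col: float(row[col]) for col in self.summary.columns}
                for name, row in self.summary.iterrows()
            },
        }
        (out_dir / "summary.json").write_text(json.dumps(payload, indent=2))


def _summarise(stacked: dict[str, np.ndarray]) -> pd.DataFrame:
    import logging

    # arviz instantiates its logger directly, bypassing the getLogger registry
    az_logger = getattr(az, "_log", logging.getLogger("arviz"))
    level = az_logger.level
    az_logger.setLevel(logging.ERROR)  # single short chains trip shape warnings
    try:
        rows = _summarise_rows(stacked)
    finally:
        az_logger.setLevel(level)
    return pd.DataFrame.from_dict(rows, orient="index")


def _summarise_rows(stacked: dict[str, np.ndarray]) -> dict:
    rows = {}
    for name, chains in stacked.items():
        flat = chains.reshape(-1)
        idata = az.convert_to_dataset({name: chains})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(idata)[name])
            rhat = (
                float(az.rhat(idata)[name])
                if chains.shape[0] * chains.shape[1] > 3
                else np.nan
            )
        rows[name] = {
            "mean": float(flat.mean()),
            "pci_lower": float(np.quantile(flat, 0.025)),
            "pci_upper": float(np.quantile(flat, 0.975)),
            "ess": ess,
            "rhat": rhat,
        }
    return rows


class MultiScaleOccupancyModel(BaseEstimator):
    """Bayesian multi-scale occupancy model for eDNA qPCR surveys.

    Parameters
    ----------
    false_positives : bool, default True
        Model false positive error at both stages (the full model).  If
        False, theta10 and p10 are fixed to 0 — the classical no-false-
        positive multi-scale model, in which any amplification implies
        eDNA capture and any capture implies occupancy.
    covariates : None, "all", or sequence of str
        Covariate columns entering every linear predictor on the logit
        scale.  ``None`` fits constant probabilities with conjugate Gibbs
        updates; ``"all"`` uses every covariate in the dataset.
    priors : PriorSpec, optional
        Defaults to informative priors concentrating false-positive
        probabilities near zero (the identifiability device).
    n_burnin, n_iterations, thinning, n_chains
        MCMC settings; defaults mirror the short study runs (1000 burn-in,
        2000 iterations, thinning 10, one chain).
    random_state : int, optional
        Seed for all sampler randomness.

    Attributes
    ----------
    result_ : PosteriorResult
    draws_ : DataFrame of posterior draws.
    summary_ : DataFrame of posterior summaries.
    site_occupancy_ : DataFrame of per-site occupancy posteriors.
    psi_, theta11_, theta10_, p11_, p10_ : float
        Posterior means on the baseline probability scale.
    """

    def __init__(
        self,
        false_positives: bool = True,
        covariates=None,
        priors: PriorSpec | None = None,
        n_burnin: int = 1000,
        n_iterations: int = 2000,
        thinning: int = 10,
        n_chains: int = 1,
        random_state: int | None = None,
    ):
        self.false_positives = false_positives
        self.covariates = covariates
        self.priors = priors
        self.n_burnin = n_burnin
        self.n_iterations = n_iterations
        self.thinning = thinning
        self.n_chains = n_chains
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _coerce(self, X) -> DetectionDataset:
        if isinstance(X, DetectionDataset):
            return X
        if isinstance(X, pd.DataFrame):
            return DetectionDataset.from_frame(X)
        raise TypeError("X must be a DetectionDataset or a long-format DataFrame")

    def _design_spec(self, data: DetectionDataset):
        if self.covariates is None:
            return None
        names = data.covariate_names if self.covariates == "all" else tuple(self.covariates)
        missing = [c for c in names if c not in data.covariate_names]
        if missing:
            raise ValueError(f"covariates not in dataset: {missing}")
        if not names:
            return None
        return {name: names for name in PARAM_NAMES}

    def fit(self, X, y=None):
        """Run the MCMC sampler on a detection dataset.

        ``X`` is a :class:`DetectionDataset` or a long-format DataFrame;
        ``y`` is ignored (the response lives inside ``X``).
        """
        data = self._coerce(X)
        design_spec = self._design_spec(data)
        if (
            self.false_positives
            and np.all(data.samples_per_site() == 1)
            and design_spec is None
            and not data.confirmed.any()
        ):
            warnings.warn(
                "single-sample design with no covariates and no confirmed "
                "presences: error rates are identified only through the "
                "informative priors",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        mcmc = MCMCConfig(
            n_burnin=self.n_burnin,
            n_iterations=self.n_iterations,
            thinning=self.thinning,
            n_chains=self.n_chains,
            seed=self.random_state,
        )
        priors = self.priors or PriorSpec()
        draws, site_occ = run_mcmc(
            data, priors, mcmc,
            constrained=not self.false_positives,
            design_spec=design_spec,
        )
        summary = _summarise(draws)
        flat_occ = site_occ.reshape(-1, data.n_sites)
        site_df = pd.DataFrame(
            {
                "site_id": data.site_ids,
                "mean": flat_occ.mean(axis=0),
                "pci_lower": np.quantile(flat_occ, 0.025, axis=0),
                "pci_upper": np.quantile(flat_occ, 0.975, axis=0),
            }
        )
        self.result_ = PosteriorResult(
            draws=pd.DataFrame({k: v.reshape(-1) for k, v in draws.items()}),
            summary=summary,
            site_occupancy=site_df,
            model_variant="full" if self.false_positives else "no_false_positives",
            n_chains=mcmc.n_chains,
            n_stored=mcmc.n_stored,
        )
        self.draws_ = self.result_.draws
        self.summary_ = summary
        self.site_occupancy_ = site_df
        self._site_occ_draws_ = flat_occ
        for name in PARAM_NAMES:
            setattr(self, f"{name}_", float(summary.loc[name, "mean"]))
        self.n_sites_ = data.n_sites
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        """Posterior mean occupancy probability per site.

        With ``X=None`` the training sites are returned.  Passing a new
        dataset scores it against the stored parameter draws (posterior
        mean of P(z=1 | y, params) over draws); this requires the same
        covariate design.
        """
        if not hasattr(self, "result_"):
            raise AttributeError("model is not fitted")
        if X is None:
            return self.site_occupancy_["mean"].to_numpy()
        from .sampler import _rao_blackwell_site_occupancy
        from scipy.special import expit, gammaln

        data = self._coerce(X)
        log_binom = gammaln(data.k + 1) - gammaln(data.y + 1) - gammaln(data.k - data.y + 1)
        design_spec = self._design_spec(data)
        acc = np.zeros(data.n_sites)
        draws = self.draws_
        for i in range(len(draws)):
            row = draws.iloc[i]
            if design_spec is None:
                probs = {name: float(row[name]) for name in PARAM_NAMES}
            else:
                probs = {}
                for name in PARAM_NAMES:
                    key = f"beta_{name}_intercept"
                    if key not in draws.columns:
                        probs[name] = 0.0
                        continue
                    eta = np.full(data.n_sites, row[key])
                    for c in design_spec[name]:
                        eta += row[f"beta_{name}_{c}"] * data.covariates[c].to_numpy()
                    probs[name] = expit(eta)
            acc += _rao_blackwell_site_occupancy(
                probs["psi"], probs["theta11"], probs["theta10"],
                probs["p11"], probs["p10"], data, log_binom,
            )
        return acc / len(draws)

    def predict(self, X=None, threshold: float = 0.5) -> np.ndarray:
        """Binary occupancy call per site at a posterior-probability threshold."""
        return (self.predict_proba(X) >= threshold).astype(int)


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------
def _fit(dataset, priors, mcmc, covariates, false_positives) -> PosteriorResult:
    mcmc = mcmc or MCMCConfig()
    model = MultiScaleOccupancyModel(
        false_positives=false_positives,
        covariates=covariates,
        priors=priors,
        n_burnin=mcmc.n_burnin,
        n_iterations=mcmc.n_iterations,
        thinning=mcmc.thinning,
        n_chains=mcmc.n_chains,
        random_state=mcmc.seed,
    )
    return model.fit(dataset).result_


def fit_full_model(
    dataset, priors: PriorSpec | None = None, mcmc: MCMCConfig | None = None, covariates=None
) -> PosteriorResult:
    """Fit the two-stage occupancy model with false positives at both stages."""
    return _fit(dataset, priors, mcmc, covariates, false_positives=True)


def fit_no_false_positive_model(
    dataset, priors: PriorSpec | None = None, mcmc: MCMCConfig | None = None, covariates=None
) -> PosteriorResult:
    """Fit the constrained model with theta10 = p10 = 0."""
    return _fit(dataset, priors, mcmc, covariates, false_positives=False)


def site_occupancy_posteriors(result: PosteriorResult) -> pd.DataFrame:
    """Per-site posterior mean occupancy probabilities with 95% intervals."""
    return result.site_occupancy.copy()


@dataclass
class ModelComparison:
    """Side-by-side comparison of the full and no-false-positive fits.

    Fractions are over sites: where the constrained model's posterior mean
    occupancy exceeds the full model's, where its interval is wider, and
    where the two intervals overlap.
    """

    frac_constrained_higher: float
    frac_constrained_wider: float
    frac_pci_overlap: float
    psi_summary_full: dict
    psi_summary_constrained: dict

    def as_dict(self) -> dict:
        return {
            "frac_constrained_higher": self.frac_constrained_higher,
            "frac_constrained_wider": self.frac_constrained_wider,
            "frac_pci_overlap": self.frac_pci_overlap,
            "psi_full": self.psi_summary_full,
            "psi_constrained": self.psi_summary_constrained,
        }


def compare_models(full: PosteriorResult, constrained: PosteriorResult) -> ModelComparison:
    """Compare fits of the two model variants on the same dataset."""
    f, c = full.site_occupancy, constrained.site_occupancy
    if len(f) != len(c) or not (f["site_id"].to_numpy() == c["site_id"].to_numpy()).all():
        raise ValueError("results were not fitted on the same site set")
    higher = c["mean"].to_numpy() > f["mean"].to_numpy()
    width_f = (f["pci_upper"] - f["pci_lower"]).to_numpy()
    width_c = (c["pci_upper"] - c["pci_lower"]).to_numpy()
    overlap = (c["pci_lower"].to_numpy() <= f["pci_upper"].to_numpy()) & (
        f["pci_lower"].to_numpy() <= c["pci_upper"].to_numpy()
    )

    def psi_row(res):
        row = res.summary.loc["psi"]
        return {key: float(row[key]) for key in ("mean", "pci_lower", "pci_upper")}

    return ModelComparison(
        frac_constrained_higher=float(higher.mean()),
        frac_constrained_wider=float((width_c > width_f).mean()),
        frac_pci_overlap=float(overlap.mean()),
        psi_summary_full=psi_row(full),
        psi_summary_constrained=psi_row(constrained),
    )
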