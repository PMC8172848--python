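"""Detection data container and CSV dialect.

The on-disk format is a long-format CSV, one row per field sample:
``site_id, sample_id, k_replicates, y_positive, confirmed_present`` plus
any number of site-level covariate columns.  An optional ``inconclusive``
column (0/1) marks samples to be dropped on read (degradation / PCR
inhibition screening happens upstream of the model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("site_id", "sample_id", "k_replicates", "y_positive")
RESERVED_COLUMNS = REQUIRED_COLUMNS + ("confirmed_present", "inconclusive")


@dataclass
class DetectionDataset:
    """Sites x samples table of positive qPCR replicate counts.

    Attributes
    ----------
    site_ids : (S,) array
        Unique site identifiers, in first-appearance order.
    site_index : (N,) int array
        Maps each sample row to its site (index into ``site_ids``).
    sample_ids : (N,) array
        Sample identifiers, unique within a site.
    k : (N,) int array
        Number of qPCR replicates run on each sample.
    y : (N,) int array
        Number of replicates that amplified, ``0 <= y <= k``.
    confirmed : (S,) bool array
        True where the species was directly observed at the site; such
        sites have their latent occupancy fixed to 1 during inference.
    covariates : DataFrame or None
        Site-level covariates, one row per site in ``site_ids`` order.
    """

    site_ids: np.ndarray
    site_index: np.ndarray
    sample_ids: np.ndarray
    k: np.ndarray
    y: np.ndarray
    confirmed: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids)
        self.site_index = np.asarray(self.site_index, dtype=np.intp)
        self.sample_ids = np.asarray(self.sample_ids)
        self.k = np.asarray(self.k, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.confirmed = np.asarray(self.confirmed, dtype=bool)
        S, N = len(self.site_ids), len(self.site_index)
        if N == 0 or S == 0:
            raise ValueError("dataset must contain at least one site and one sample")
        if len(np.unique(self.site_ids)) != S:
            raise ValueError("site_ids must be unique")
        if not (len(self.sample_ids) == len(self.k) == len(self.y) == N):
            raise ValueError("sample arrays must share one length")
        if self.confirmed.shape != (S,):
            raise ValueError("confirmed must have one entry per site")
        if self.site_index.min() < 0 or self.site_index.max() >= S:
            raise ValueError("site_index out of range")
        if np.any(self.k < 1):
            raise ValueError("every sample needs k_replicates >= 1")
        bad = (self.y < 0) | (self.y > self.k)
        if np.any(bad):
            rows = np.flatnonzero(bad)[:5].tolist()
            raise ValueError(f"y_positive outside [0, k_replicates] at sample rows {rows}")
        if len(np.unique(self.site_index)) != S:
            missing = set(range(S)) - set(self.site_index.tolist())
            ids = [self.site_ids[i] for i in sorted(missing)][:5]
            raise ValueError(f"every site needs >= 1 sample; none for {ids}")
        if self.covariates is not None:
            if len(self.covariates) != S:
                raise ValueError("covariates must have one row per site")
            self.covariates = self.covariates.reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return () if self.covariates is None else tuple(self.covariates.columns)

    def samples_per_site(self) -> np.ndarray:
        return np.bincount(self.site_index, minlength=self.n_sites)

    def max_y_per_site(self) -> np.ndarray:
        out = np.zeros(self.n_sites, dtype=np.int64)
        np.maximum.at(out, self.site_index, self.y)
        return out

    def site_samples(self, i: int) -> list[tuple[int, int]]:
        """``(K, y)`` pairs for site ``i`` (by position)."""
        mask = self.site_index == i
        return list(zip(self.k[mask].tolist(), self.y[mask].tolist()))

    # ------------------------------------------------------------- conversion
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "site_id": self.site_ids[self.site_index],
                "sample_id": self.sample_ids,
                "k_replicates": self.k,
                "y_positive": self.y,
                "confirmed_present": self.confirmed[self.site_index].astype(int),
            }
        )
        if self.covariates is not None:
            for col in self.covariates.columns:
                df[col] = self.covariates[col].to_numpy()[self.site_index]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariate_columns=None) -> "DetectionDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        dup = df.duplicated(subset=["site_id", "sample_id"])
        if dup.any():
            rows = df.index[dup][:5].tolist()
            raise ValueError(f"duplicate (site_id, sample_id) keys at rows {rows}")
        site_ids = pd.unique(df["site_id"].to_numpy())  # first-appearance order
        id_to_idx = {sid: i for i, sid in enumerate(site_ids)}
        site_index = df["site_id"].map(id_to_idx).to_numpy(dtype=np.intp)

        S = len(site_ids)
        confirmed = np.zeros(S, dtype=bool)
        if "confirmed_present" in df.columns:
            flags = df["confirmed_present"].to_numpy().astype(bool)
            np.logical_or.at(confirmed, site_index, flags)

        if covariate_columns is None:
            covariate_columns = [c for c in df.columns if c not in RESERVED_COLUMNS]
        cov = None
        if covariate_columns:
            _, first_row = np.unique(site_index, return_index=True)
            cov = df.iloc[first_row][list(covariate_columns)].reset_index(drop=True)
            cov = cov.astype(float)

        return cls(
            site_ids=site_ids,
            site_index=site_index,
            sample_ids=df["sample_id"].to_numpy(),
            k=df["k_replicates"].to_numpy(),
            y=df["y_positive"].to_numpy(),
            confirmed=confirmed,
            covariates=cov,
        )

    def with_covariates(self, covariates: pd.DataFrame | None) -> "DetectionDataset":
        return replace(self, covariates=covariates)


def read_detection_csv(
    path, covariate_columns=None, drop_inconclusive: bool = True
) -> DetectionDataset:
    """Read the long-format detection CSV.

    Rows with a truthy ``inconclusive`` flag are dropped (with a logged
    count) before validation, mirroring the screening of degraded or
    PCR-inhibited samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if drop_inconclusive and "inconclusive" in df.columns:
        n_before = len(df)
        df = df[~df["inconclusive"].astype(bool)].drop(columns=["inconclusive"])
        n_dropped = n_before - len(df)
        if n_dropped:
            logger.info("dropped %d inconclusive sample(s) from %s", n_dropped, path)
        if df.empty:
            raise ValueError(f"{path}: all samples flagged inconclusive")
    bad = df["y_positive"] > df["k_replicates"]
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"{path}: y_positive > k_replicates at row {row} "
            f"(site {df.loc[row, 'site_id']}, sample {df.loc[row, 'sample_id']})"
        )
    return DetectionDataset.from_frame(df, covariate_columns=covariate_columns)


def write_detection_csv(dataset: DetectionDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CovariateScaling:
    """Per-covariate centring/scaling record for back-transformation."""

    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)


def is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def standardise_covariates(
    dataset: DetectionDataset,
) -> tuple[DetectionDataset, CovariateScaling]:
    """Standardise continuous covariates to mean 0, sample SD 1.

    Binary (0/1) covariates are left untouched.  The sample SD (ddof=1)
    convention is used and recorded in the returned scaling so effects can
    be mapped back to the original units.  Constant continuous covariates
    raise, naming the column.
    """
    if dataset.covariates is None:
        return dataset, CovariateScaling()
    cov = dataset.covariates.copy()
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    for col in cov.columns:
        values = cov[col].to_numpy(dtype=float)
        if is_binary(values):
            continue
        if np.unique(values).size < 2:
            raise ValueError(f"covariate {col!r} is constant; cannot standardise")
        mu = float(values.mean())
        sd = float(values.std(ddof=1))
        cov[col] = (values - mu) / sd
        center[col], scale[col] = mu, sd
    return dataset.with_covariates(cov), CovariateScaling(center=center, scale=scale)
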