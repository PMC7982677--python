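"""Environmental covariates and the environmental kinship Omega = WW'/q.

Hourly weather series per environment are aligned to each environment's
planting date (planting day = day 0), laid out on a day x hour x covariate
grid, flattened to one row per environment of the covariate matrix W, and
turned into the environment relationship matrix Omega = W W' / q used by the
reaction-norm interaction terms.

With the defaults (8 covariates, 131 days, 24 hours) a complete environment
contributes 24 x 8 x 131 = 25,152 covariate cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import Kernel

__all__ = [
    "COVARIATES",
    "EnvCovariateMatrix",
    "OmegaKernel",
    "align_to_planting",
    "build_W",
    "omega",
]

#: canonical hourly weather covariates, in column order
COVARIATES = (
    "temp_c",
    "dewpoint_c",
    "rh_pct",
    "rain_mm",
    "wind_ms",
    "wind_dir_deg",
    "gust_ms",
    "solar_wm2",
)

DEFAULT_N_DAYS = 131


@dataclass
class EnvCovariateMatrix:
    """Environments x q covariate matrix with standardization metadata.

    Columns are laid out in (covariate, day, hour) order. ``q`` is the number
    of retained (non-constant) columns; when ``standardized`` each retained
    column has mean 0 and SD 1 across environments.
    """

    W: np.ndarray
    env_ids: list[str]
    columns: list[str]
    standardized: bool
    col_means: np.ndarray
    col_sds: np.ndarray
    n_constant_dropped: int = 0
    n_all_missing_dropped: int = 0

    @property
    def q(self) -> int:
        return self.W.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.env_ids, columns=self.columns)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class OmegaKernel(Kernel):
    """Environment relationship matrix Omega = WW'/q with provenance."""

    q: int = 0
    standardized: bool = True


def align_to_planting(
    series: pd.DataFrame,
    planting_date,
    n_days: int = DEFAULT_N_DAYS,
    covariates: tuple[str, ...] = COVARIATES,
    completeness_threshold: float = 0.9,
    env_id: str = "?",
) -> np.ndarray:
    """Align one environment's hourly weather to its planting date.

    Returns an ``(n_days, 24, n_cov)`` float grid indexed by day since
    planting (day 0 = planting day), hour of day, covariate; hours absent
    from the series are NaN. Raises if overall coverage falls below
    ``completeness_threshold``.
    """
    if not 0 <= completeness_threshold <= 1:
        raise ValueError("completeness_threshold must be in [0, 1]")
    missing_cols = [c for c in covariates if c not in series.columns]
    if missing_cols:
        raise ValueError(f"weather series for {env_id} lacks columns {missing_cols}")
    ts = pd.to_datetime(series["timestamp"])
    start = pd.Timestamp(planting_date).normalize()
    hours_since = ((ts - start) / pd.Timedelta(hours=1)).round().astype(int)
    grid = np.full((n_days, 24, len(covariates)), np.nan)
    in_window = (hours_since >= 0) & (hours_since < n_days * 24)
    sel = series.loc[in_window.to_numpy(), list(covariates)].to_numpy(dtype=float)
    hrs = hours_since.to_numpy()[in_window.to_numpy()]
    grid[hrs // 24, hrs % 24, :] = sel
    coverage = 1.0 - np.isnan(grid).mean()
    if coverage < completeness_threshold:
        raise ValueError(
            f"environment {env_id}: weather coverage {coverage:.1%} below "
            f"threshold {completeness_threshold:.0%} over {n_days} days from planting"
        )
    return grid


def flatten_grid(grid: np.ndarray, covariates: tuple[str, ...] = COVARIATES) -> np.ndarray:
    """Flatten a (day, hour, covariate) grid in (covariate, day, hour) order."""
    return np.transpose(grid, (2, 0, 1)).reshape(-1)


def grid_column_labels(n_days: int, covariates: tuple[str, ...] = COVARIATES) -> list[str]:
    return [
        f"{cov}_d{day}_h{hour}"
        for cov in covariates
        for day in range(n_days)
        for hour in range(24)
    ]


def build_W(
    grids: dict[str, np.ndarray],
    standardize: bool = True,
    covariates: tuple[str, ...] = COVARIATES,
) -> EnvCovariateMatrix:
    """Stack per-environment grids into the environments x q matrix W.

    Missing cells are imputed with the column mean across environments;
    columns missing in every environment, and columns constant across
    environments, are dropped (with a warning for the former). When
    ``standardize`` is on the retained columns are centered and scaled to
    unit SD across environments.
    """
    if len(grids) < 2:
        raise ValueError("need at least two environments to build W")
    env_ids = list(grids)
    shapes = {g.shape for g in grids.values()}
    if len(shapes) != 1:
        raise ValueError(f"environment grids have differing shapes: {shapes}")
    n_days = next(iter(shapes))[0]
    W = np.vstack([flatten_grid(grids[e], covariates) for e in env_ids])
    labels = np.array(grid_column_labels(n_days, covariates))

    all_missing = np.isnan(W).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} covariate columns missing in every "
            "environment; dropped"
        )
    W = W[:, ~all_missing]
    labels = labels[~all_missing]

    col_mean = np.nanmean(W, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(W))
    W[nan_r, nan_c] = col_mean[nan_c]

    sds = W.std(axis=0, ddof=0)
    constant = sds == 0
    W = W[:, ~constant]
    labels = labels[~constant]
    means = W.mean(axis=0)
    sds = W.std(axis=0, ddof=0)
    if W.shape[1] == 0:
        raise ValueError("no informative covariate columns remain")
    if standardize:
        W = (W - means) / sds
    return EnvCovariateMatrix(
        W=W,
        env_ids=env_ids,
        columns=[str(l) for l in labels],
        standardized=standardize,
        col_means=means,
        col_sds=sds,
        n_constant_dropped=int(constant.sum()),
        n_all_missing_dropped=int(all_missing.sum()),
    )


def omega(W: EnvCovariateMatrix, name: str = "Omega") -> OmegaKernel:
    """Environmental kinship Omega = WW'/q over the retained columns."""
    if W.q < 1:
        raise ValueError("W has no columns; cannot build Omega")
    M = (W.W @ W.W.T) / W.q
    return OmegaKernel(
        name=name,
        level="environment",
        matrix=M,
        ids=list(W.env_ids),
        q=W.q,
        standardized=W.standardized,
    )
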