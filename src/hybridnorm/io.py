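"""Reading, validating and quality-controlling the four pipeline inputs.

The on-disk dialects are deliberately plain:

* markers — TSV/CSV, rows = inbred ids, columns = locus ids, cells 0/1/2
  (or A/C/G/T diploid calls when ``recode=True``), missing as ``NA``;
* pedigree — CSV with columns ``hybrid,parent1,parent2``;
* phenotypes — CSV with columns ``hybrid,env,year,yield_kg_ha``;
* weather — a directory with one ``<env>.csv`` hourly series per environment
  (``timestamp`` plus the eight covariate columns) and a companion
  ``planting.csv`` with columns ``env,planting_date``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enviro import COVARIATES
from .kernels import HybridSet, MarkerMatrix, code_major_allele

__all__ = [
    "PhenoTable",
    "DatasetBundle",
    "SchemaError",
    "ReferentialError",
    "read_dataset",
    "write_dataset",
    "qc_filter",
]

PHENO_COLUMNS = ["hybrid", "env", "year", "yield_kg_ha"]


class SchemaError(ValueError):
    """An input table lacks a required column or has a malformed cell."""


class ReferentialError(ValueError):
    """A table references an id that is absent from its counterpart table."""


@dataclass
class PhenoTable:
    """Phenotype records: one grain-yield observation per (hybrid, environment).

    The environment is a location-by-year combination and is the unit of the
    analysis; ``year`` is carried as metadata only.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"phenotype table missing columns: {missing}")
        self.df = self.df[PHENO_COLUMNS].reset_index(drop=True)
        y = self.df["yield_kg_ha"].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype yields must be finite")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def env_ids(self) -> list[str]:
        return sorted(self.df["env"].unique())

    @property
    def hybrid_ids(self) -> list[str]:
        return sorted(self.df["hybrid"].unique())

    @property
    def y(self) -> np.ndarray:
        return self.df["yield_kg_ha"].to_numpy(dtype=float)

    def cells(self) -> list[tuple[str, str]]:
        return list(zip(self.df["hybrid"], self.df["env"]))

    def env_groups(self) -> dict[str, np.ndarray]:
        return {e: g.index.to_numpy() for e, g in self.df.groupby("env")}


@dataclass
class DatasetBundle:
    """All four validated inputs for one analysis.

    Invariants: every parent referenced by ``hybrids`` has a marker row; every
    environment in ``pheno`` has a weather series and a planting date.
    """

    markers: MarkerMatrix
    hybrids: HybridSet
    pheno: PhenoTable
    weather: dict[str, pd.DataFrame]
    planting: dict[str, pd.Timestamp]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        marker_ids = set(self.markers.ids)
        bad_parents = sorted(
            {p for _, p1, p2 in self.hybrids.hybrids for p in (p1, p2)} - marker_ids
        )
        if bad_parents:
            raise ReferentialError(f"parents without marker rows: {bad_parents}")
        known_hybrids = set(self.hybrids.ids)
        bad_hyb = sorted(set(self.pheno.df["hybrid"]) - known_hybrids)
        if bad_hyb:
            raise ReferentialError(f"phenotype rows reference unknown hybrids: {bad_hyb}")
        bad_env = sorted(set(self.pheno.df["env"]) - set(self.weather))
        if bad_env:
            raise ReferentialError(
                f"phenotype rows reference environments without weather: {bad_env}"
            )
        bad_plant = sorted(set(self.weather) - set(self.planting))
        if bad_plant:
            raise ReferentialError(f"environments without planting date: {bad_plant}")

    @property
    def env_ids(self) -> list[str]:
        return sorted(self.weather)

    def summary(self) -> dict:
        return {
            "n_hybrids": len(self.hybrids),
            "n_parent1": len(self.hybrids.parent1_ids),
            "n_parent2": len(self.hybrids.parent2_ids),
            "n_inbreds": len(self.markers.ids),
            "n_loci": self.markers.n_loci,
            "n_environments": len(self.env_ids),
            "n_records": self.pheno.n,
        }


def _read_table(path, name: str, columns: list[str], sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table at {path} missing columns: {missing}")
    return df


def read_dataset(
    marker_path,
    pedigree_path,
    pheno_path,
    weather_dir,
    recode: bool = False,
) -> DatasetBundle:
    """Read and cross-validate the four pipeline inputs.

    ``recode=True`` triggers major-allele recoding of letter genotype calls;
    numeric tables are taken as 0/1/2 major-allele counts either way (missing
    cells are imputed to the rounded locus mean in both cases).
    """
    marker_path = Path(marker_path)
    sep = "\t" if marker_path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(marker_path, sep=sep, index_col=0, dtype=str)
    markers = code_major_allele(raw)

    ped = _read_table(pedigree_path, "pedigree", ["hybrid", "parent1", "parent2"])
    hybrids = HybridSet(
        [tuple(map(str, r)) for r in ped[["hybrid", "parent1", "parent2"]].itertuples(index=False)]
    )

    pheno_df = _read_table(pheno_path, "phenotype", PHENO_COLUMNS)
    pheno = PhenoTable(pheno_df)

    weather_dir = Path(weather_dir)
    meta = _read_table(weather_dir / "planting.csv", "planting metadata",
                       ["env", "planting_date"])
    planting = {str(r.env): pd.Timestamp(r.planting_date) for r in meta.itertuples()}
    weather: dict[str, pd.DataFrame] = {}
    for env in planting:
        f = weather_dir / f"{env}.csv"
        if not f.exists():
            raise ReferentialError(f"no weather series for environment {env} at {f}")
        w = _read_table(f, f"weather[{env}]", ["timestamp", *COVARIATES])
        weather[env] = w

    bundle = DatasetBundle(markers, hybrids, pheno, weather, planting)
    s = bundle.summary()
    warnings.warn(
        f"loaded dataset: {s['n_hybrids']} hybrids, {s['n_inbreds']} inbreds, "
        f"{s['n_environments']} environments, {s['n_records']} records",
        stacklevel=2,
    )
    return bundle


def write_dataset(bundle: DatasetBundle, outdir) -> dict[str, Path]:
    """Write a bundle back to the on-disk dialects (inverse of read_dataset)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": outdir / "markers.csv",
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "weather": outdir / "weather",
    }
    bundle.markers.to_frame().to_csv(paths["markers"])
    pd.DataFrame(bundle.hybrids.hybrids, columns=["hybrid", "parent1", "parent2"]).to_csv(
        paths["pedigree"], index=False
    )
    bundle.pheno.df.to_csv(paths["phenotypes"], index=False)
    wdir = paths["weather"]
    wdir.mkdir(exist_ok=True)
    pd.DataFrame(
        {"env": list(bundle.planting), "planting_date": [d.date() for d in bundle.planting.values()]}
    ).to_csv(wdir / "planting.csv", index=False)
    for env, series in bundle.weather.items():
        series.to_csv(wdir / f"{env}.csv", index=False)
    return paths


def qc_filter(pheno: PhenoTable, n_sd: float = 3.0) -> tuple[PhenoTable, pd.DataFrame]:
    """Per-environment outlier filter: drop records outside mean +/- n_sd * SD.

    The mean and sample SD (n-1 denominator) are computed within each
    environment over all its records, including the candidate record; the
    interval is closed, so boundary values are kept. A single pass is made.
    Environments with a single record are kept untouched with a warning, and
    environments left with fewer than 3 records are flagged with a warning.

    Returns the filtered table and a report of the removed records.
    """
    df = pheno.df
    keep = np.ones(len(df), dtype=bool)
    for env, g in df.groupby("env"):
        y = g["yield_kg_ha"].to_numpy(dtype=float)
        if len(y) < 2:
            warnings.warn(f"environment {env} has a single record; QC skipped")
            continue
        m, sd = y.mean(), y.std(ddof=1)
        out = (y < m - n_sd * sd) | (y > m + n_sd * sd)
        keep[g.index.to_numpy()[out]] = False
    removed = df.loc[~keep].copy()
    kept = PhenoTable(df.loc[keep].reset_index(drop=True))
    small = [e for e, g in kept.df.groupby("env") if len(g) < 3]
    if small:
        warnings.warn(f"environments with fewer than 3 records after QC: {small}")
    return kept, removed
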