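"""Synthetic multi-environment hybrid trial generator.

Emulates the statistical structure of a two-pool maize hybrid testing
program: many parent-1 inbreds crossed to a handful of heavily reused
testers (parent 2), a sparse hybrid x environment incidence, hourly weather
with between-environment structure, and grain-yield phenotypes drawn from
the full combining-ability reaction-norm decomposition (environment, GCA,
SCA, their interactions with the environment identity and with the
weather-based environmental kinship, plus iid residual).

Defaults are desk-scale: 300 hybrids from 60 + 8 parents, 500 loci, 10
environments, 30% of cells observed. The default variance fractions and the
phenotype scale (mean 9065.5 kg/ha, SD 2979.2 kg/ha) echo the partitions
reported for large public maize hybrid trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enviro import COVARIATES, build_W, align_to_planting, omega as build_omega, OmegaKernel
from .io import DatasetBundle, PhenoTable
from .kernels import HybridSet, MarkerMatrix, grm
from .model import MODEL_TERMS, build_terms, _eigendecompose

__all__ = [
    "DEFAULT_FRACTIONS",
    "SimTruth",
    "simulate_genotypes",
    "simulate_design",
    "simulate_weather",
    "simulate_phenotypes",
    "simulate_dataset",
]

#: default generating variance fractions for the full (M5) decomposition
DEFAULT_FRACTIONS: dict[str, float] = {
    "E": 0.572,
    "G_P1": 0.027,
    "G_P2": 0.028,
    "G_P1xP2": 0.045,
    "G_P1xE": 0.024,
    "G_P2xE": 0.007,
    "G_P1xP2xE": 0.001,
    "G_P1xW": 0.019,
    "G_P2xW": 0.040,
    "G_P1xP2xW": 0.027,
    "residual": 0.211,
}

DEFAULT_MU = 9065.5
DEFAULT_TOTAL_SD = 2979.2


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    fractions: dict[str, float]           # normalized generating fractions
    sigma2: dict[str, float]              # generating variances per term
    effects: dict[str, np.ndarray]        # realized effect vector per term (per record)
    mu: float
    seed: int
    params: dict = field(default_factory=dict)

    def realized_shares(self) -> dict[str, float]:
        """Sample-variance share of each realized component (residual incl.)."""
        var = {t: float(np.var(v)) for t, v in self.effects.items()}
        total = sum(var.values())
        return {t: v / total for t, v in var.items()}


def simulate_genotypes(
    n_p1: int = 60,
    n_p2: int = 8,
    m: int = 500,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    het_rate: float = 0.0,
) -> tuple[MarkerMatrix, list[str], list[str]]:
    """Draw inbred genotypes for the two parental pools.

    Per locus an allele frequency is drawn uniformly from ``maf_range`` and
    inbreds are homozygous (0 or 2 copies) at that frequency; ``het_rate``
    adds residual heterozygosity. Loci monomorphic across all inbreds are
    redrawn. Returns the marker matrix plus the parent-1 and parent-2 id
    lists (parent 1 first in row order).
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 1):
        raise ValueError(f"infeasible maf_range {maf_range}")
    if n_p1 < 2 or n_p2 < 2 or m < 10:
        raise ValueError("need n_p1 >= 2, n_p2 >= 2, m >= 10")
    rng = np.random.default_rng(seed)
    n = n_p1 + n_p2
    X = np.empty((n, m), dtype=np.int64)
    for j in range(m):
        for _ in range(100):
            f = rng.uniform(lo, hi)
            col = 2 * (rng.random(n) < f).astype(np.int64)
            if het_rate > 0:
                het = rng.random(n) < het_rate
                col[het] = 1
            if len(np.unique(col)) > 1:
                break
        X[:, j] = col
    p1_ids = [f"P1_{i:03d}" for i in range(n_p1)]
    p2_ids = [f"T{i:02d}" for i in range(n_p2)]
    loci = [f"L{j:04d}" for j in range(m)]
    return MarkerMatrix(X, p1_ids + p2_ids, loci), p1_ids, p2_ids


def simulate_design(
    p1_ids: list[str],
    p2_ids: list[str],
    n_hybrids: int = 300,
    n_env: int = 10,
    obs_fraction: float = 0.3,
    seed: int = 0,
    min_hybrids_per_env: int = 30,
) -> tuple[HybridSet, list[tuple[str, str]], dict[str, int]]:
    """Draw the pedigree and the sparse hybrid x environment incidence.

    Parent-1 inbreds are used nearly uniquely (cycled) while testers
    (parent 2) are reused heavily; hybrids are distinct (parent1, parent2)
    pairs. Observed cells are sampled per environment so every environment
    gets at least ``min_hybrids_per_env`` hybrids (capped at the hybrid
    count) and every hybrid at least one environment. Returns the hybrids,
    the observed cells, and an env -> year map (metadata).
    """
    if n_hybrids > len(p1_ids) * len(p2_ids):
        raise ValueError("n_hybrids exceeds the number of distinct parent pairs")
    if not 0 < obs_fraction <= 1:
        raise ValueError("obs_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    seen = set()
    p1_cycle = list(p1_ids)
    rng.shuffle(p1_cycle)
    i = 0
    while len(pairs) < n_hybrids:
        p1 = p1_cycle[i % len(p1_cycle)]
        p2 = p2_ids[rng.integers(len(p2_ids))]
        i += 1
        if (p1, p2) not in seen:
            seen.add((p1, p2))
            pairs.append((p1, p2))
    hybrids = HybridSet(
        [(f"H{k:04d}", p1, p2) for k, (p1, p2) in enumerate(pairs)]
    )
    env_ids = [f"E{j:02d}" for j in range(n_env)]
    env_year = {e: 2014 + (j % 2) for j, e in enumerate(env_ids)}

    per_env = int(round(obs_fraction * n_hybrids))
    per_env = max(per_env, min(min_hybrids_per_env, n_hybrids))
    per_env = min(per_env, n_hybrids)
    hyb_ids = hybrids.ids
    cells: list[tuple[str, str]] = []
    covered: set[str] = set()
    for e in env_ids:
        chosen = rng.choice(hyb_ids, size=per_env, replace=False)
        cells.extend((h, e) for h in chosen)
        covered.update(chosen)
    planned = len(cells) / (n_hybrids * n_env)
    tol = 0.02 + 0.5 / n_hybrids  # rounding granularity at small sizes
    if abs(planned - obs_fraction) > tol and per_env == int(round(obs_fraction * n_hybrids)):
        raise ValueError(
            f"planned observed fraction {planned:.3f} deviates from target "
            f"{obs_fraction:.3f} by more than 2 points"
        )
    for h in hyb_ids:  # every hybrid observed at least once (may add cells)
        if h not in covered:
            cells.append((h, env_ids[rng.integers(n_env)]))
    return hybrids, cells, env_year


# per-covariate generators: (base level, env shift SD, seasonal amplitude,
# diurnal amplitude, AR(1) noise SD, lower clip, upper clip)
_WEATHER_PARAMS = {
    "temp_c": (22.0, 3.0, 6.0, 5.0, 1.5, -20.0, 55.0),
    "dewpoint_c": (14.0, 2.5, 4.0, 1.5, 1.2, -25.0, 35.0),
    "rh_pct": (65.0, 8.0, 10.0, 12.0, 5.0, 0.0, 100.0),
    "wind_ms": (3.0, 0.8, 0.5, 1.0, 0.8, 0.0, 40.0),
    "wind_dir_deg": (180.0, 40.0, 20.0, 10.0, 25.0, 0.0, 360.0),
    "gust_ms": (5.0, 1.2, 0.5, 1.5, 1.2, 0.0, 60.0),
    "solar_wm2": (0.0, 60.0, 80.0, 400.0, 40.0, 0.0, 1400.0),
}


def simulate_weather(
    n_env: int,
    n_days: int = 131,
    seed: int = 0,
    env_ids: list[str] | None = None,
    start_year: int = 2014,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.Timestamp]]:
    """Generate hourly weather series with between-environment structure.

    Each covariate is an environment-level mean shift plus a seasonal trend,
    a diurnal sinusoid, and AR(1) noise; rain is zero-inflated. Planting
    dates are staggered around early May. Between-environment variance is
    strictly positive for every covariate by construction.
    """
    if n_env < 2:
        raise ValueError("need at least 2 environments")
    rng = np.random.default_rng(seed)
    env_ids = env_ids or [f"E{j:02d}" for j in range(n_env)]
    n_hours = n_days * 24
    hours = np.arange(n_hours)
    day = hours / 24.0
    hod = hours % 24
    weather: dict[str, pd.DataFrame] = {}
    planting: dict[str, pd.Timestamp] = {}
    for j, e in enumerate(env_ids):
        plant = pd.Timestamp(f"{start_year + (j % 2)}-05-01") + pd.Timedelta(
            days=int(rng.integers(0, 15))
        )
        planting[e] = plant
        ts = plant + pd.to_timedelta(hours, unit="h")
        data = {"timestamp": ts}
        for cov, (base, env_sd, seas, diur, ar_sd, lo, hi) in _WEATHER_PARAMS.items():
            shift = rng.normal(0.0, env_sd)
            seasonal = seas * np.sin(np.pi * day / max(n_days, 1))
            diurnal = diur * np.sin(2 * np.pi * (hod - 6) / 24.0)
            noise = np.empty(n_hours)
            noise[0] = rng.normal(0, ar_sd)
            eps = rng.normal(0, ar_sd, n_hours)
            for t in range(1, n_hours):
                noise[t] = 0.8 * noise[t - 1] + 0.6 * eps[t]
            vals = base + shift + seasonal + diurnal + noise
            if cov == "solar_wm2":
                vals = np.maximum(vals, 0.0) * (diurnal > 0)
            data[cov] = np.clip(vals, lo, hi)
        # zero-inflated hourly rain with an environment-level wetness shift
        wet = min(max(0.05 + rng.normal(0, 0.02), 0.005), 0.5)
        rain = np.where(rng.random(n_hours) < wet, rng.exponential(1.5, n_hours), 0.0)
        data["rain_mm"] = rain
        weather[e] = pd.DataFrame(data)[["timestamp", *COVARIATES]]
    return weather, planting


def simulate_phenotypes(
    markers: MarkerMatrix,
    p1_ids: list[str],
    p2_ids: list[str],
    hybrids: HybridSet,
    cells: list[tuple[str, str]],
    omega_kernel: OmegaKernel,
    env_year: dict[str, int],
    fractions: dict[str, float] | None = None,
    mu: float = DEFAULT_MU,
    total_sd: float = DEFAULT_TOTAL_SD,
    seed: int = 0,
    center_grm: bool = True,
) -> tuple[PhenoTable, SimTruth]:
    """Draw phenotypes from the full reaction-norm variance decomposition.

    Each term's effect vector is drawn N(0, K sigma2_t) in the eigenbasis of
    its observation-level kernel (rescaled to mean diagonal 1, so that
    sigma2_t = fraction_t * total variance gives each term its target
    expected share); the phenotype is mu + sum of terms + residual.
    """
    fractions = dict(fractions or DEFAULT_FRACTIONS)
    bad = set(fractions) - set(MODEL_TERMS["M5"]) - {"residual"}
    if bad:
        raise ValueError(f"unknown variance-fraction terms: {bad}")
    if any(v < 0 for v in fractions.values()):
        raise ValueError("variance fractions must be nonnegative")
    total_frac = sum(fractions.values())
    if total_frac <= 0:
        raise ValueError("variance fractions must not all be zero")
    fractions = {t: v / total_frac for t, v in fractions.items()}

    rng = np.random.default_rng(seed)
    total_var = total_sd**2
    # a minimal bundle-like container for build_terms: phenotype rows are the
    # observed cells with placeholder yields
    df = pd.DataFrame(
        {
            "hybrid": [h for h, _ in cells],
            "env": [e for _, e in cells],
            "year": [env_year[e] for _, e in cells],
            "yield_kg_ha": 0.0,
        }
    )
    pheno = PhenoTable(df)

    class _Shim:
        pass

    shim = _Shim()
    shim.hybrids = hybrids
    shim.pheno = pheno
    shim.env_ids = sorted(env_year)
    kernels = {
        "G_P1": grm(markers.subset(p1_ids), center=center_grm, level="parent1"),
        "G_P2": grm(markers.subset(p2_ids), center=center_grm, level="parent2"),
    }
    spec = build_terms("M5", shim, kernels, omega=omega_kernel, cells=cells, rescale=True)

    effects: dict[str, np.ndarray] = {}
    sigma2: dict[str, float] = {}
    n = len(cells)
    for term in spec.terms:
        s2 = fractions.get(term.name, 0.0) * total_var
        sigma2[term.name] = s2
        if s2 == 0:
            effects[term.name] = np.zeros(n)
            continue
        d, U = _eigendecompose(spec.obs_kernel(term.name).matrix)
        z = rng.standard_normal(d.size)
        effects[term.name] = U @ (np.sqrt(d * s2) * z)
    sigma2["residual"] = fractions.get("residual", 0.0) * total_var
    effects["residual"] = rng.normal(0.0, np.sqrt(sigma2["residual"]), n)

    y = mu + sum(effects.values())
    pheno = PhenoTable(df.assign(yield_kg_ha=y))
    truth = SimTruth(
        fractions=fractions,
        sigma2=sigma2,
        effects=effects,
        mu=mu,
        seed=seed,
        params={"n_records": n, "total_sd": total_sd},
    )
    return pheno, truth


def simulate_dataset(
    seed: int = 0,
    n_p1: int = 60,
    n_p2: int = 8,
    m: int = 500,
    n_hybrids: int = 300,
    n_env: int = 10,
    obs_fraction: float = 0.3,
    n_days: int = 131,
    fractions: dict[str, float] | None = None,
    mu: float = DEFAULT_MU,
    total_sd: float = DEFAULT_TOTAL_SD,
    standardize_ecs: bool = True,
    center_grm: bool = True,
    misspecified_window: tuple[int, int] | None = None,
    min_hybrids_per_env: int = 30,
) -> tuple[DatasetBundle, SimTruth]:
    """End-to-end generator: genotypes, design, weather, phenotypes.

    The GxW effects are generated from the same full-window environmental
    kinship later available to the fitting side (well-specified case). With
    ``misspecified_window=(d0, d1)`` they are instead generated from a hidden
    kinship restricted to days d0..d1-1 (a phenology window) while the
    returned weather remains full-window, so a naive fit is misspecified.
    """
    rng = np.random.default_rng(seed)
    s_geno, s_design, s_weather, s_pheno = rng.integers(0, 2**31 - 1, size=4)
    markers, p1_ids, p2_ids = simulate_genotypes(n_p1, n_p2, m, seed=int(s_geno))
    hybrids, cells, env_year = simulate_design(
        p1_ids, p2_ids, n_hybrids, n_env, obs_fraction, seed=int(s_design),
        min_hybrids_per_env=min_hybrids_per_env,
    )
    env_ids = sorted(env_year)
    weather, planting = simulate_weather(
        n_env, n_days=n_days, seed=int(s_weather), env_ids=env_ids
    )
    grids = {
        e: align_to_planting(weather[e], planting[e], n_days=n_days) for e in env_ids
    }
    if misspecified_window is not None:
        d0, d1 = misspecified_window
        gen_grids = {e: g[d0:d1] for e, g in grids.items()}
    else:
        gen_grids = grids
    W = build_W(gen_grids, standardize=standardize_ecs)
    om = build_omega(W)
    pheno, truth = simulate_phenotypes(
        markers, p1_ids, p2_ids, hybrids, cells, om, env_year,
        fractions=fractions, mu=mu, total_sd=total_sd, seed=int(s_pheno),
        center_grm=center_grm,
    )
    truth.params.update(
        n_p1=n_p1, n_p2=n_p2, m=m, n_hybrids=n_hybrids, n_env=n_env,
        obs_fraction=obs_fraction, n_days=n_days, seed=seed,
        misspecified_window=misspecified_window,
    )
    bundle = DatasetBundle(markers, hybrids, pheno, weather, planting)
    return bundle, truth
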