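"""The four hybrid-prediction cross-validation schemes.

* ``CV2`` — incomplete field trials: records split into k folds stratified
  by environment, so test hybrids are tested elsewhere and environments stay
  observed;
* ``CV1`` — untested hybrids in observed environments: hybrids split into k
  folds, all records of held-out hybrids masked;
* ``CV0``  — tested hybrids in unobserved environments: leave one
  environment out;
* ``CV00`` — untested hybrids in unobserved environments: for each
  environment and each hybrid fold, the environment is masked entirely and
  the fold's hybrids are masked everywhere; the test set is that fold's
  hybrids in that environment.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enviro import OmegaKernel
from .io import DatasetBundle, PhenoTable
from .kernels import HybridSet, Kernel
from .model import SamplerConfig, build_terms, fit, predict_cells

__all__ = ["SCHEMES", "FoldAssignment", "make_folds", "run_scheme"]

SCHEMES = ("CV2", "CV1", "CV0", "CV00")

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Train/test record-index pairs for one scheme on one phenotype table."""

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    params: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)


def _hybrid_folds(hybrid_ids: list[str], k: int, rng: np.random.Generator) -> list[set]:
    order = list(hybrid_ids)
    rng.shuffle(order)
    return [set(chunk) for chunk in np.array_split(np.array(order, dtype=object), k)]


def make_folds(
    scheme: str,
    pheno: PhenoTable,
    hybrids: HybridSet,
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Construct the train/test masks of one scheme.

    A pure function of (scheme, record set, k, seed). ``k`` is the number of
    record folds (CV2) or hybrid folds (CV1, CV00); CV0 always has one fold
    per environment.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    df = pheno.df
    n = len(df)
    all_idx = np.arange(n)
    envs = pheno.env_ids
    if scheme in ("CV0", "CV00") and len(envs) < 2:
        raise ValueError(f"{scheme} needs at least 2 environments")
    if scheme in ("CV1", "CV2", "CV00") and k < 2:
        raise ValueError(f"{scheme} needs k >= 2 folds")
    rng = np.random.default_rng(seed)
    rec_hyb = df["hybrid"].to_numpy()
    rec_env = df["env"].to_numpy()
    folds: list[tuple[np.ndarray, np.ndarray]] = []

    if scheme == "CV2":
        # deal each hybrid's records round-robin across folds (random order,
        # random offset): every test hybrid with >= 2 records stays tested
        # elsewhere, and environments remain represented in every training set
        labels = np.empty(n, dtype=int)
        for h in pheno.hybrid_ids:
            idx = rng.permutation(all_idx[rec_hyb == h])
            labels[idx] = (np.arange(len(idx)) + rng.integers(k)) % k
        for f in range(k):
            test = all_idx[labels == f]
            folds.append((all_idx[labels != f], test))
    elif scheme == "CV1":
        groups = _hybrid_folds(pheno.hybrid_ids, k, rng)
        for grp in groups:
            mask = np.isin(rec_hyb, list(grp))
            folds.append((all_idx[~mask], all_idx[mask]))
    elif scheme == "CV0":
        for e in envs:
            mask = rec_env == e
            folds.append((all_idx[~mask], all_idx[mask]))
    else:  # CV00
        groups = _hybrid_folds(pheno.hybrid_ids, k, rng)
        for e in envs:
            in_env = rec_env == e
            for grp in groups:
                in_grp = np.isin(rec_hyb, list(grp))
                test = all_idx[in_env & in_grp]
                train = all_idx[~in_env & ~in_grp]
                if len(test) == 0:
                    continue
                folds.append((train, test))
    return FoldAssignment(scheme, folds, seed, {"k": k})


def run_scheme(
    model_id: str,
    scheme: str,
    bundle: DatasetBundle,
    kernels: dict[str, Kernel],
    omega: OmegaKernel | None = None,
    k: int = 5,
    seed: int = 0,
    sampler: SamplerConfig | None = None,
    rescale: bool = True,
    min_train: int = 10,
) -> pd.DataFrame:
    """Fit/predict every fold of a scheme; returns the prediction table.

    Columns: ``hybrid, env, fold, observed, predicted``. Each masked cell
    appears exactly once for CV2/CV1/CV0 and once per (environment,
    hybrid-fold) pair for CV00. Folds with fewer than ``min_train`` training
    records are skipped with a warning.
    """
    sampler = sampler or SamplerConfig()
    assignment = make_folds(scheme, bundle.pheno, bundle.hybrids, k=k, seed=seed)
    df = bundle.pheno.df
    y = bundle.pheno.y
    cells = bundle.pheno.cells()
    out = []
    for fold_id, (train, test) in enumerate(assignment):
        if len(train) < min_train:
            warnings.warn(
                f"{scheme} fold {fold_id}: only {len(train)} training records; skipped"
            )
            continue
        t0 = time.perf_counter()
        train_cells = [cells[i] for i in train]
        test_cells = [cells[i] for i in test]
        spec = build_terms(model_id, bundle, kernels, omega=omega,
                           cells=train_cells, rescale=rescale)
        fold_sampler = SamplerConfig(
            n_iter=sampler.n_iter, burn_in=sampler.burn_in, thin=sampler.thin,
            prior_df=sampler.prior_df, prior_var_share=sampler.prior_var_share,
            seed=sampler.seed + 1000 * fold_id,
        )
        res = fit(spec, y[train], fold_sampler)
        pred = predict_cells(res, test_cells)
        logger.info(
            "%s %s fold=%d n_train=%d n_test=%d runtime=%.2fs",
            model_id, scheme, fold_id, len(train), len(test),
            time.perf_counter() - t0,
        )
        out.append(pd.DataFrame({
            "hybrid": df["hybrid"].to_numpy()[test],
            "env": df["env"].to_numpy()[test],
            "fold": fold_id,
            "observed": y[test],
            "predicted": pred,
        }))
    if not out:
        raise ValueError(f"no usable folds for scheme {scheme}")
    return pd.concat(out, ignore_index=True)
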