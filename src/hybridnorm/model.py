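"""Multi-kernel Gaussian mixed models for hybrid reaction-norm prediction.

Five nested models are supported, each a sum of zero-mean Gaussian random
terms with known covariance kernels plus an intercept and iid residual:

* ``M1`` — environment main effect + GCA of parent 1 and parent 2;
* ``M2`` — M1 + SCA (Hadamard product of the parental GRMs);
* ``M3`` — M2 + GCAxE and SCAxE reaction-norm interactions with the
  environment identity structure;
* ``M4`` — M2 + GCAxW and SCAxW interactions with the environmental kinship
  Omega built from weather covariates;
* ``M5`` — M3 + M4 combined (both interaction families).

Every term's observation-level covariance factorizes into entity-level
kernels gathered onto observations (e.g. Z_g G Z_g' o Z_E Omega Z_E'); the
factorization is kept so that cross-covariances to unobserved cells — in
particular unobserved environments, which contribute through Omega but not
through the environment identity — come for free at prediction time.

Inference is Bayesian kernel regression via Gibbs sampling: each term's
effect vector is sampled in its kernel eigenbasis (diagonal full
conditionals), variances from scaled-inverse-chi-square full conditionals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .enviro import OmegaKernel
from .io import DatasetBundle
from .kernels import HybridSet, Kernel

__all__ = [
    "MODEL_IDS",
    "MODEL_TERMS",
    "SamplerConfig",
    "ModelTerm",
    "ModelSpec",
    "FitResult",
    "VariancePartition",
    "build_terms",
    "fit",
    "variance_partition",
    "predict_cells",
]

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5")

# term -> factor recipe: (kernel key, cell selector); 'I_E' is the
# environment identity, 'Omega' the weather-derived environmental kinship
_TERM_FACTORS: dict[str, tuple[tuple[str, str], ...]] = {
    "E": (("I_E", "env"),),
    "G_P1": (("G_P1", "parent1"),),
    "G_P2": (("G_P2", "parent2"),),
    "G_P1xP2": (("G_P1", "parent1"), ("G_P2", "parent2")),
    "G_P1xE": (("G_P1", "parent1"), ("I_E", "env")),
    "G_P2xE": (("G_P2", "parent2"), ("I_E", "env")),
    "G_P1xP2xE": (("G_P1", "parent1"), ("G_P2", "parent2"), ("I_E", "env")),
    "G_P1xW": (("G_P1", "parent1"), ("Omega", "env")),
    "G_P2xW": (("G_P2", "parent2"), ("Omega", "env")),
    "G_P1xP2xW": (("G_P1", "parent1"), ("G_P2", "parent2"), ("Omega", "env")),
}

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M1": ("E", "G_P1", "G_P2"),
    "M2": ("E", "G_P1", "G_P2", "G_P1xP2"),
    "M3": ("E", "G_P1", "G_P2", "G_P1xP2", "G_P1xE", "G_P2xE", "G_P1xP2xE"),
    "M4": ("E", "G_P1", "G_P2", "G_P1xP2", "G_P1xW", "G_P2xW", "G_P1xP2xW"),
    "M5": (
        "E", "G_P1", "G_P2", "G_P1xP2",
        "G_P1xE", "G_P2xE", "G_P1xP2xE",
        "G_P1xW", "G_P2xW", "G_P1xP2xW",
    ),
}


@dataclass
class SamplerConfig:
    """Gibbs sampler settings.

    ``n_iter`` total iterations, of which the first ``burn_in`` are
    discarded and every ``thin``-th of the rest is kept. The
    scaled-inverse-chi-square priors use ``prior_df`` degrees of freedom with
    total prior scale ``prior_var_share * var(y)`` split equally among the
    random terms (the residual gets the same share whole).
    """

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    prior_df: float = 5.0
    prior_var_share: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class ModelTerm:
    """One random term: a product of entity-level kernel factors.

    ``factors`` is a tuple of (entity Kernel, selector) pairs where the
    selector maps an observation cell (hybrid, env) to the kernel's entity:
    ``parent1`` / ``parent2`` via the pedigree, ``env`` directly. ``scale``
    is the divisor that brings the training-cell kernel to mean diagonal 1.
    """

    name: str
    factors: tuple[tuple[Kernel, str], ...]
    hybrids: HybridSet
    scale: float = 1.0

    def _indices(self, cells: list[tuple[str, str]], kernel: Kernel, selector: str) -> np.ndarray:
        pos = {g: i for i, g in enumerate(kernel.ids)}
        try:
            if selector == "env":
                return np.array([pos[e] for _, e in cells], dtype=int)
            if selector == "parent1":
                return np.array([pos[self.hybrids.parents(h)[0]] for h, _ in cells], dtype=int)
            if selector == "parent2":
                return np.array([pos[self.hybrids.parents(h)[1]] for h, _ in cells], dtype=int)
        except KeyError as e:
            raise KeyError(
                f"term {self.name}: cell references entity absent from "
                f"kernel '{kernel.name}': {e}"
            ) from None
        raise ValueError(f"unknown selector {selector!r}")

    def cov(self, cells_a: list[tuple[str, str]], cells_b: list[tuple[str, str]]) -> np.ndarray:
        """Covariance block between two cell lists under this term."""
        M = np.ones((len(cells_a), len(cells_b)))
        for kernel, selector in self.factors:
            ia = self._indices(cells_a, kernel, selector)
            ib = self._indices(cells_b, kernel, selector)
            M *= kernel.matrix[np.ix_(ia, ib)]
        return M / self.scale

    def obs_kernel(self, cells: list[tuple[str, str]]) -> Kernel:
        M = self.cov(cells, cells)
        ids = [f"{h}:{e}" for h, e in cells]
        return Kernel(self.name, "observation", (M + M.T) / 2.0, ids)


@dataclass
class ModelSpec:
    """A model id, its training cells, and the ordered random terms."""

    model_id: str
    cells: list[tuple[str, str]]
    terms: list[ModelTerm]
    intercept: bool = True
    _obs_kernels: dict[str, Kernel] = field(default_factory=dict, repr=False)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def obs_kernel(self, name: str) -> Kernel:
        """Observation-level kernel of one term on the training cells (cached)."""
        if name not in self._obs_kernels:
            term = next(t for t in self.terms if t.name == name)
            self._obs_kernels[name] = term.obs_kernel(self.cells)
        return self._obs_kernels[name]


def build_terms(
    model_id: str,
    bundle: DatasetBundle,
    kernels: dict[str, Kernel],
    omega: OmegaKernel | None = None,
    cells: list[tuple[str, str]] | None = None,
    rescale: bool = True,
) -> ModelSpec:
    """Assemble the random terms of one model for a set of training cells.

    ``kernels`` must provide entity-level ``G_P1`` and ``G_P2`` GRMs; the
    environment identity kernel is built over all environments of the bundle.
    ``omega`` is required for M4/M5. With ``rescale`` (default) each term is
    scaled so its training-cell kernel has mean diagonal 1, making variance
    components comparable across terms.
    """
    if model_id not in MODEL_TERMS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    needs_omega = any(
        key == "Omega" for t in MODEL_TERMS[model_id] for key, _ in _TERM_FACTORS[t]
    )
    if needs_omega and omega is None:
        raise ValueError(f"model {model_id} requires the environmental kinship Omega")
    if cells is None:
        cells = bundle.pheno.cells()
    env_ids = bundle.env_ids
    base: dict[str, Kernel] = {
        "G_P1": kernels["G_P1"],
        "G_P2": kernels["G_P2"],
        "I_E": Kernel("I_E", "environment", np.eye(len(env_ids)), env_ids),
    }
    if omega is not None:
        base["Omega"] = omega
    terms: list[ModelTerm] = []
    for tname in MODEL_TERMS[model_id]:
        factors = tuple((base[key], sel) for key, sel in _TERM_FACTORS[tname])
        term = ModelTerm(tname, factors, bundle.hybrids)
        if rescale:
            d = float(np.mean(np.diag(term.cov(cells, cells))))
            if d > 0:
                term.scale = d
        terms.append(term)
    return ModelSpec(model_id, list(cells), terms)


@dataclass
class FitResult:
    """Posterior summaries of one Gibbs fit on one training mask."""

    model_id: str
    mu: float
    varcomps: dict[str, float]          # term name -> posterior-mean variance
    effects: dict[str, np.ndarray]      # term name -> posterior-mean effect per obs
    fitted: np.ndarray
    cells: list[tuple[str, str]]
    terms: list[ModelTerm]
    pred_weights: dict[str, np.ndarray]  # term name -> K_train^+ @ effect
    kernel_mean_diag: dict[str, float]
    diagnostics: dict

    def to_dict(self) -> dict:
        """JSON-serializable summary (variances, mu, diagnostics, effects)."""
        return {
            "model_id": self.model_id,
            "mu": self.mu,
            "varcomps": {k: float(v) for k, v in self.varcomps.items()},
            "effects": {k: v.tolist() for k, v in self.effects.items()},
            "diagnostics": self.diagnostics,
        }


@dataclass
class VariancePartition:
    """Percent of total variance per model component (residual included)."""

    model_id: str
    percentages: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"variance percentages sum to {total}, not 100")


def _eigendecompose(K: np.ndarray, rtol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = scipy.linalg.eigh((K + K.T) / 2.0)
    top = max(vals[-1], 0.0)
    keep = vals > max(top * rtol, 0.0)
    return vals[keep], vecs[:, keep]


def _split_chain_rhat(x: np.ndarray) -> float:
    """Potential scale reduction factor on one chain split in half."""
    n = len(x) // 2
    if n < 2:
        return 1.0
    halves = np.stack([x[:n], x[len(x) - n:]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (w * n)))


def fit(spec: ModelSpec, y: np.ndarray, config: SamplerConfig | None = None) -> FitResult:
    """Gibbs-sample the multi-kernel model and return posterior means.

    Each term's effect vector is parameterized in the eigenbasis of its
    observation-level kernel (rank-truncated), giving diagonal Gaussian full
    conditionals; variances are sampled from scaled-inverse-chi-square full
    conditionals. Deterministic given ``config.seed``.
    """
    config = config or SamplerConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 training observations, got {n}")
    if n != len(spec.cells):
        raise ValueError("y length does not match training cells")
    rng = np.random.default_rng(config.seed)

    names = spec.term_names
    eig = {t: _eigendecompose(spec.obs_kernel(t).matrix) for t in names}
    mean_diag = {t: float(np.mean(np.diag(spec.obs_kernel(t).matrix))) for t in names}

    vary = float(np.var(y))
    var_floor = max(vary, 1.0) * 1e-12
    df0 = config.prior_df
    s0_terms = max(config.prior_var_share * vary / max(len(names), 1), var_floor)
    s0_e = max(config.prior_var_share * vary, var_floor)

    mu = float(np.mean(y))
    g = {t: np.zeros(n) for t in names}
    a = {t: np.zeros(eig[t][0].shape[0]) for t in names}
    a_mean = {t: np.zeros(eig[t][0].shape[0]) for t in names}
    sigma2 = {t: s0_terms for t in names}
    ss_cond = {t: 0.0 for t in names}
    sigma2_e = max(s0_e, var_floor)

    n_kept = 0
    mu_sum = 0.0
    sig_sum = {t: 0.0 for t in names}
    sig_e_sum = 0.0
    a_sum = {t: np.zeros_like(a[t]) for t in names}
    sigma_e_chain = []

    resid = y - mu  # residual excluding nothing (all g are zero initially)
    for it in range(config.n_iter):
        # intercept (flat prior)
        resid += mu
        mu = float(rng.normal(resid.mean(), np.sqrt(sigma2_e / n)))
        resid -= mu
        # term effects in their eigenbases
        for t in names:
            d, U = eig[t]
            if d.size == 0:
                continue
            resid += g[t]
            h = U.T @ resid
            prec = 1.0 / sigma2_e + 1.0 / (d * sigma2[t])
            mean = h / sigma2_e / prec
            a_mean[t] = mean
            a[t] = mean + rng.standard_normal(d.size) / np.sqrt(prec)
            g[t] = U @ a[t]
            resid -= g[t]
            ss = float(np.sum(a[t] ** 2 / d))
            sigma2[t] = max(
                (df0 * s0_terms + ss) / rng.chisquare(df0 + d.size), var_floor
            )
            ss_cond[t] = ss
        ss_e = float(resid @ resid)
        sigma2_e = max((df0 * s0_e + ss_e) / rng.chisquare(df0 + n), var_floor)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            n_kept += 1
            mu_sum += mu
            # Rao-Blackwellized variance accumulation: the conditional
            # posterior mean given the current effects, not the draw
            sig_e_sum += (df0 * s0_e + ss_e) / (df0 + n - 2)
            sigma_e_chain.append(sigma2_e)
            for t in names:
                rank = eig[t][0].size
                sig_sum[t] += (df0 * s0_terms + ss_cond[t]) / (df0 + rank - 2)
                a_sum[t] += a_mean[t]

    mu_bar = mu_sum / n_kept
    effects = {}
    pred_weights = {}
    for t in names:
        d, U = eig[t]
        a_bar = a_sum[t] / n_kept
        effects[t] = U @ a_bar
        pred_weights[t] = U @ (a_bar / d) if d.size else np.zeros(n)
    fitted = mu_bar + sum(effects[t] for t in names)
    varcomps = {t: sig_sum[t] / n_kept for t in names}
    varcomps["residual"] = sig_e_sum / n_kept

    rhat = _split_chain_rhat(np.asarray(sigma_e_chain))
    diagnostics = {
        "n_iter": config.n_iter,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "n_kept": n_kept,
        "seed": config.seed,
        "rhat_sigma2_e": rhat,
    }
    if rhat > 1.2:
        warnings.warn(
            f"residual-variance chain may not have converged (Rhat={rhat:.2f})"
        )
    return FitResult(
        model_id=spec.model_id,
        mu=mu_bar,
        varcomps=varcomps,
        effects=effects,
        fitted=np.asarray(fitted),
        cells=list(spec.cells),
        terms=list(spec.terms),
        pred_weights=pred_weights,
        kernel_mean_diag=mean_diag,
        diagnostics=diagnostics,
    )


def variance_partition(fit_result: FitResult) -> VariancePartition:
    """Percent of total variance per component, residual included.

    Each variance is weighted by the mean diagonal of its observation-level
    kernel (1 after the default rescaling; the residual kernel is the
    identity), so terms with unequal kernel scales partition comparably.
    """
    weights = dict(fit_result.kernel_mean_diag)
    weights["residual"] = 1.0
    contrib = {t: fit_result.varcomps[t] * weights[t] for t in fit_result.varcomps}
    total = sum(contrib.values())
    pct = {t: 100.0 * v / total for t, v in contrib.items()}
    return VariancePartition(fit_result.model_id, pct)


def predict_cells(
    fit_result: FitResult, cells: list[tuple[str, str]]
) -> np.ndarray:
    """Predict phenotypes for arbitrary (hybrid, env) cells.

    Each term contributes its Gaussian conditional mean
    K(new, train) K(train, train)^+ g_train, computed in the training
    eigenbasis. Terms gated by the environment identity contribute exactly 0
    for environments absent from training; terms carrying Omega contribute
    through the weather-based environmental similarities.
    """
    pred = np.full(len(cells), fit_result.mu)
    for term in fit_result.terms:
        Knt = term.cov(cells, fit_result.cells)
        pred += Knt @ fit_result.pred_weights[term.name]
    return pred
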