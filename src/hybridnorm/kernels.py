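"""Genomic covariance structures for hybrid prediction.

Builds the marker coding, genomic relationship matrices (GRMs) for the two
parental pools, the specific-combining-ability (SCA) Hadamard kernel among
hybrids, and the observation-level expansions and Hadamard interactions used
by the reaction-norm mixed models.

All covariance matrices are carried as :class:`Kernel` objects which enforce
symmetry and positive semi-definiteness (to numerical tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "HybridSet",
    "Kernel",
    "code_major_allele",
    "grm",
    "sca_kernel",
    "expand_to_observations",
    "interaction_kernel",
    "incidence_matrix",
]

#: relative tolerance on the smallest eigenvalue of a kernel
PSD_RTOL = 1e-8
#: absolute tolerance on symmetry
SYM_ATOL = 1e-10

_MISSING_TOKENS = {"NA", "NN", "--", "", "nan"}


@dataclass
class MarkerMatrix:
    """Inbred genotypes coded as counts (0/1/2) of the major allele.

    Parameters
    ----------
    values
        ``(n_inbreds, n_loci)`` integer array with entries in {0, 1, 2}.
    ids
        Inbred line identifiers (rows).
    loci
        Locus identifiers (columns).
    """

    values: np.ndarray
    ids: list[str]
    loci: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.ids = list(self.ids)
        self.loci = list(self.loci)
        if self.values.ndim != 2:
            raise ValueError("marker values must be 2-D")
        if self.values.shape != (len(self.ids), len(self.loci)):
            raise ValueError("marker shape does not match id/locus labels")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate inbred ids")
        bad = ~np.isin(self.values, (0, 1, 2))
        if bad.any():
            raise ValueError("marker entries must be 0, 1 or 2 after coding")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, ids: list[str]) -> "MarkerMatrix":
        """Row-subset (and reorder) to the given inbred ids."""
        pos = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"unknown inbred ids: {missing}")
        idx = [pos[g] for g in ids]
        return MarkerMatrix(self.values[idx], list(ids), self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.loci)


@dataclass
class HybridSet:
    """Pedigree of single-cross hybrids: hybrid -> (parent 1, parent 2).

    The parent-1 / parent-2 role assignment is fixed per hybrid; incidence
    matrices onto observations are produced on demand from a list of
    observation-level hybrid (or environment) labels.
    """

    hybrids: list[tuple[str, str, str]]  # (hybrid_id, parent1_id, parent2_id)

    def __post_init__(self) -> None:
        ids = [h for h, _, _ in self.hybrids]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate hybrid ids")
        self._index = {h: (p1, p2) for h, p1, p2 in self.hybrids}

    @property
    def ids(self) -> list[str]:
        return [h for h, _, _ in self.hybrids]

    @property
    def parent1_ids(self) -> list[str]:
        return sorted({p1 for _, p1, _ in self.hybrids})

    @property
    def parent2_ids(self) -> list[str]:
        return sorted({p2 for _, _, p2 in self.hybrids})

    def parents(self, hybrid_id: str) -> tuple[str, str]:
        try:
            return self._index[hybrid_id]
        except KeyError:
            raise KeyError(f"unknown hybrid id: {hybrid_id}") from None

    def __len__(self) -> int:
        return len(self.hybrids)

    def __contains__(self, hybrid_id: str) -> bool:
        return hybrid_id in self._index


@dataclass
class Kernel:
    """A named symmetric PSD covariance matrix with row labels.

    ``level`` records the entity the rows refer to: one of ``parent1``,
    ``parent2``, ``hybrid``, ``environment`` or ``observation``.
    """

    name: str
    level: str
    matrix: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"kernel '{self.name}' matrix must be square")
        if self.ids and len(self.ids) != m.shape[0]:
            raise ValueError(f"kernel '{self.name}': ids do not match matrix size")
        if self.ids and len(set(self.ids)) != len(self.ids):
            raise ValueError(f"kernel '{self.name}': duplicate ids")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def validate(self) -> None:
        """Raise if the matrix is asymmetric or indefinite beyond tolerance."""
        m = self.matrix
        if not np.all(np.abs(m - m.T) <= SYM_ATOL):
            raise ValueError(f"kernel '{self.name}' is not symmetric")
        ev = np.linalg.eigvalsh((m + m.T) / 2.0)
        lo, hi = ev[0], max(ev[-1], 0.0)
        if lo < -PSD_RTOL * max(hi, 1.0):
            raise ValueError(
                f"kernel '{self.name}' is not PSD: min eig {lo:.3e}, max {hi:.3e}"
            )

    def rescaled(self) -> "Kernel":
        """Return a copy scaled to mean diagonal 1 (no-op on a zero kernel)."""
        d = float(np.mean(np.diag(self.matrix)))
        if d <= 0:
            return Kernel(self.name, self.level, self.matrix.copy(), list(self.ids))
        return Kernel(self.name, self.level, self.matrix / d, list(self.ids))

    def to_csv(self, path) -> None:
        ids = self.ids or [str(i) for i in range(self.n)]
        pd.DataFrame(self.matrix, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, name: str = "kernel", level: str = "observation") -> "Kernel":
        df = pd.read_csv(path, index_col=0)
        return cls(name, level, df.to_numpy(dtype=float), [str(c) for c in df.columns])


def _major_allele_counts(column: pd.Series) -> tuple[np.ndarray, bool]:
    """Code one locus of diploid string calls (e.g. 'AA', 'AC') as major-allele
    counts; returns (float array with NaN for missing, ok flag)."""
    alleles: dict[str, int] = {}
    calls = []
    for raw in column:
        s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
        if s in _MISSING_TOKENS:
            calls.append(None)
            continue
        if len(s) == 1:  # haploid-style call, count twice (inbred homozygote)
            s = s + s
        if len(s) != 2:
            return np.empty(0), False
        calls.append(s)
        for a in s:
            alleles[a] = alleles.get(a, 0) + 1
    if len(alleles) > 2 or not alleles:
        return np.empty(0), False
    total = sum(alleles.values())
    # major = allele with frequency >= 0.5; exact tie -> lexicographically smaller
    best = sorted(alleles.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    out = np.full(len(calls), np.nan)
    for i, c in enumerate(calls):
        if c is not None:
            out[i] = sum(1 for a in c if a == best)
    return out, True


def code_major_allele(raw_calls: pd.DataFrame) -> MarkerMatrix:
    """Code raw biallelic genotype calls as counts of the major allele.

    Accepts either numeric 0/1/2 columns (missing as NaN/"NA") or diploid
    string calls ("AA", "AC", ...). Per locus the allele with frequency
    >= 0.5 is "major"; at an exact 0.5 tie the lexicographically smaller
    allele wins. Loci with more than two alleles are dropped with a warning.
    Missing calls are imputed to the rounded locus mean count.

    Parameters
    ----------
    raw_calls
        DataFrame indexed by inbred id, one column per locus.
    """
    cols: list[np.ndarray] = []
    kept: list[str] = []
    dropped: list[str] = []
    for locus in raw_calls.columns:
        col = raw_calls[locus]
        cleaned = col.replace(list(_MISSING_TOKENS), np.nan)
        numeric = pd.to_numeric(cleaned, errors="coerce")
        if numeric.notna().sum() == cleaned.notna().sum() and numeric.notna().any():
            vals = numeric.to_numpy(dtype=float)
            if not np.all(np.isin(vals[~np.isnan(vals)], (0, 1, 2))):
                dropped.append(str(locus))
                continue
            counts = vals
        else:
            counts, ok = _major_allele_counts(col)
            if not ok:
                dropped.append(str(locus))
                continue
        if np.all(np.isnan(counts)):
            dropped.append(str(locus))
            continue
        mean = float(np.nanmean(counts))
        counts = np.where(np.isnan(counts), int(round(mean)), counts)
        cols.append(counts.astype(np.int64))
        kept.append(str(locus))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} loci (multi-allelic, invalid or all missing): "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    if not kept:
        raise ValueError("no usable loci after coding")
    values = np.column_stack(cols)
    return MarkerMatrix(values, [str(i) for i in raw_calls.index], kept)


def grm(X: MarkerMatrix, center: bool = False, level: str = "parent1",
        name: str | None = None) -> Kernel:
    """Genomic relationship matrix G = X*X*'/p.

    By default the raw 0/1/2 counts enter the cross-product; with
    ``center=True`` columns are mean-centered first (the VanRaden-style
    construction). ``p`` is the number of loci.
    """
    if X.n_loci == 0:
        raise ValueError("cannot build a GRM from zero loci")
    M = X.values.astype(float)
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    G = (M @ M.T) / X.n_loci
    return Kernel(name or f"G_{level}", level, G, list(X.ids))


def sca_kernel(G1: Kernel, G2: Kernel, hybrids: HybridSet,
               name: str = "G_P1xP2") -> Kernel:
    """Specific-combining-ability kernel among hybrids.

    Entry (j, j') = G1[p1_j, p1_j'] * G2[p2_j, p2_j'] — the Hadamard (Schur)
    product of the parental GRMs gathered onto hybrid pairs; PSD by the Schur
    product theorem.
    """
    i1 = {g: i for i, g in enumerate(G1.ids)}
    i2 = {g: i for i, g in enumerate(G2.ids)}
    try:
        idx1 = np.array([i1[p1] for _, p1, _ in hybrids.hybrids])
        idx2 = np.array([i2[p2] for _, _, p2 in hybrids.hybrids])
    except KeyError as e:
        raise KeyError(f"hybrid references parent absent from kernel ids: {e}") from None
    M = G1.matrix[np.ix_(idx1, idx1)] * G2.matrix[np.ix_(idx2, idx2)]
    return Kernel(name, "hybrid", M, hybrids.ids)


def incidence_matrix(labels: list[str], entity_ids: list[str]) -> np.ndarray:
    """0/1 incidence matrix Z (observations x entities), one unit per row."""
    pos = {g: i for i, g in enumerate(entity_ids)}
    missing = sorted({l for l in labels if l not in pos})
    if missing:
        raise KeyError(f"labels not among entity ids: {missing}")
    Z = np.zeros((len(labels), len(entity_ids)))
    Z[np.arange(len(labels)), [pos[l] for l in labels]] = 1.0
    return Z


def expand_to_observations(K: Kernel, Z: np.ndarray,
                           obs_ids: list[str] | None = None) -> Kernel:
    """Observation-level expansion Z K Z' of an entity-level kernel.

    ``Z`` must be a 0/1 incidence matrix with exactly one unit entry per row;
    the product is then a pure gather: entry (i, i') = K[entity(i), entity(i')].
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != K.n:
        raise ValueError(
            f"incidence shape {Z.shape} incompatible with kernel '{K.name}' (n={K.n})"
        )
    rows_ok = np.all(Z.sum(axis=1) == 1) and np.all((Z == 0) | (Z == 1))
    if not rows_ok:
        raise ValueError("incidence matrix must have exactly one unit entry per row")
    idx = Z.argmax(axis=1)
    M = K.matrix[np.ix_(idx, idx)]
    ids = obs_ids or [f"obs{i}" for i in range(Z.shape[0])]
    return Kernel(K.name, "observation", M, ids)


def interaction_kernel(*kernels: Kernel, name: str | None = None) -> Kernel:
    """Hadamard (cell-by-cell) product of two or more observation-level kernels.

    All factors must share the same observation ordering; PSD is preserved by
    the Schur product theorem.
    """
    if len(kernels) < 2:
        raise ValueError("need at least two kernels to interact")
    first = kernels[0]
    for k in kernels[1:]:
        if k.n != first.n:
            raise ValueError("observation counts differ between interaction factors")
        if first.ids and k.ids and k.ids != first.ids:
            raise ValueError(
                f"observation ordering mismatch between '{first.name}' and '{k.name}'"
            )
    M = first.matrix.copy()
    for k in kernels[1:]:
        M *= k.matrix
    return Kernel(name or "x".join(k.name for k in kernels), "observation",
                  M, list(first.ids))
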