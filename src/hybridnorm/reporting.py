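"""Run bookkeeping and summary tables.

Collects evaluation summaries and variance partitions across (model, scheme,
seed) runs and renders two canonical tables: a model x scheme matrix of
weighted average correlations with 95% CIs, and a model x component matrix
of variance percentages; plus per-environment head-to-head counts between
model pairs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import EvalSummary
from .model import MODEL_TERMS, VariancePartition

__all__ = ["RunLedger", "tabulate", "head_to_head", "config_hash"]


def config_hash(config) -> str:
    """Stable short hash of a configuration (dataclass or mapping)."""
    if hasattr(config, "__dataclass_fields__"):
        payload = {k: repr(getattr(config, k)) for k in config.__dataclass_fields__}
    else:
        payload = {k: repr(v) for k, v in dict(config).items()}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunLedger:
    """Entries keyed by (model_id, scheme, seed); duplicate keys rejected."""

    entries: dict = field(default_factory=dict)

    def add(
        self,
        model_id: str,
        scheme: str,
        seed: int,
        evaluation: EvalSummary,
        partition: VariancePartition | None = None,
        config=None,
    ) -> None:
        key = (model_id, scheme, seed)
        if key in self.entries:
            raise KeyError(f"duplicate ledger entry {key}")
        self.entries[key] = {
            "evaluation": evaluation,
            "partition": partition,
            "config_hash": config_hash(config) if config is not None else "",
        }

    def __len__(self) -> int:
        return len(self.entries)


def tabulate(ledger: RunLedger) -> dict[str, pd.DataFrame]:
    """Render the ledger as summary tables (pure function, idempotent).

    Returns a dict with a ``correlations`` model x scheme table of
    "r [lo, hi]" strings (multi-seed entries aggregated as mean with
    across-seed SD), a ``variance`` model x component percentage table, and
    a ``per_env`` long table of per-environment correlations.
    """
    if not ledger.entries:
        raise ValueError("empty ledger")
    models = sorted({m for m, _, _ in ledger.entries})
    schemes = []
    for _, s, _ in ledger.entries:  # keep first-seen scheme order
        if s not in schemes:
            schemes.append(s)

    corr = pd.DataFrame(index=models, columns=schemes, dtype=object)
    per_env_rows = []
    for m in models:
        for s in schemes:
            runs = [
                v for (mm, ss, _), v in ledger.entries.items() if mm == m and ss == s
            ]
            if not runs:
                continue  # scheme not run for this model: omitted, not zero-filled
            r = np.array([x["evaluation"].r_phi for x in runs])
            if len(runs) == 1:
                lo, hi = runs[0]["evaluation"].ci95
                corr.loc[m, s] = f"{r[0]:.2f} [{lo:.2f}, {hi:.2f}]"
            else:
                corr.loc[m, s] = f"{r.mean():.2f} (SD {r.std(ddof=1):.2f}, n={len(r)})"
            for x in runs:
                d = x["evaluation"].per_env.copy()
                d["model"], d["scheme"] = m, s
                per_env_rows.append(d)
    corr = corr.dropna(axis=1, how="all")

    var_rows = {}
    all_terms = list(MODEL_TERMS["M5"]) + ["residual"]
    for m in models:
        parts = [
            v["partition"].percentages
            for (mm, _, _), v in ledger.entries.items()
            if mm == m and v["partition"] is not None
        ]
        if parts:
            agg = {
                t: float(np.mean([p[t] for p in parts])) for t in all_terms
                if all(t in p for p in parts)
            }
            var_rows[m] = agg
    variance = pd.DataFrame.from_dict(var_rows, orient="index")

    per_env = (
        pd.concat(per_env_rows, ignore_index=True)
        if per_env_rows
        else pd.DataFrame(columns=["env", "r", "n", "model", "scheme"])
    )
    return {"correlations": corr, "variance": variance, "per_env": per_env}


def head_to_head(ledger: RunLedger, model_a: str, model_b: str, scheme: str) -> dict:
    """Count environments where ``model_a`` beats ``model_b`` under a scheme.

    Uses per-environment correlations averaged across seeds; returns e.g.
    ``{"a_wins": 29, "n_env": 30, ...}`` for "29 out of the 30 environments"
    style statements.
    """
    def _mean_per_env(model):
        runs = [
            v["evaluation"].per_env
            for (m, s, _), v in ledger.entries.items()
            if m == model and s == scheme
        ]
        if not runs:
            raise KeyError(f"no entries for ({model}, {scheme})")
        return pd.concat(runs).groupby("env")["r"].mean()

    ra, rb = _mean_per_env(model_a), _mean_per_env(model_b)
    common = ra.index.intersection(rb.index)
    wins = int((ra[common] > rb[common]).sum())
    return {
        "model_a": model_a,
        "model_b": model_b,
        "scheme": scheme,
        "a_wins": wins,
        "b_wins": int((rb[common] > ra[common]).sum()),
        "n_env": int(len(common)),
    }


def write_markdown(tables: dict[str, pd.DataFrame], path) -> None:
    with open(path, "w") as fh:
        for name, df in tables.items():
            fh.write(f"## {name}\n\n")
            fh.write(df.to_string())
            fh.write("\n\n")
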