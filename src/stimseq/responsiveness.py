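"""Threshold-based responsiveness classification over expression tables.

The classification rules operate on per-feature tables carrying FPKM per
condition, a signed fold change, and a BH-adjusted q-value. The signed
fold-change convention reports an x-fold reduction as ``-x`` (never a value
in (-1, 1)), so "|fold| < 2" is the non-differential band.

All thresholds are applied as strict inequalities exactly as printed in
their defaults (q < 0.05, fold > 2, FPKM > 1 for genes; FPKM > 0.5,
fold > 1.6 for eRNAs); boundary values are excluded.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 0.1


class SchemaError(ValueError):
    """An expression table is missing required columns or feature universe."""


def _require_columns(table: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"expression table missing required columns {missing}")


def fold_induction(
    fpkm_before, fpkm_after, pseudocount: float = DEFAULT_PSEUDOCOUNT
):
    """Fold ratio of expression after vs before stimulation.

    ``(fpkm_after + pseudocount) / (fpkm_before + pseudocount)``; the
    pseudocount (> 0) keeps zero-FPKM features finite and is inert on
    expressed features.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    before = np.asarray(fpkm_before, dtype=float)
    after = np.asarray(fpkm_after, dtype=float)
    if (before < 0).any() or (after < 0).any():
        raise ValueError("FPKM values must be >= 0")
    out = (after + pseudocount) / (before + pseudocount)
    return float(out) if out.ndim == 0 else out


def _ranked_calls(
    table: pd.DataFrame,
    responsive_mask: pd.Series,
    before_col: str,
    after_col: str,
    pseudocount: float,
) -> pd.DataFrame:
    calls = table.loc[responsive_mask, ["feature_id", before_col, after_col, "fold_change", "q_value"]].copy()
    calls["fold_induction"] = fold_induction(calls[before_col], calls[after_col], pseudocount)
    # descending fold induction; ties broken lexicographically for determinism
    calls = calls.sort_values(
        ["fold_induction", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    calls["rank"] = np.arange(1, len(calls) + 1)
    return calls


def call_responsive_genes(
    table: pd.DataFrame,
    before: str,
    after: str,
    min_fold: float = 2.0,
    max_q: float = 0.05,
    min_fpkm: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Stimulus-responsive genes: q < max_q, fold change > min_fold, post-stimulation FPKM > min_fpkm.

    Returns the responsive subset ranked by descending fold induction
    (columns ``feature_id, fold_induction, rank, ...``).
    """
    if table.empty:
        raise SchemaError("expression table is empty")
    before_col, after_col = f"fpkm_{before}", f"fpkm_{after}"
    _require_columns(table, ["feature_id", "fold_change", "q_value", before_col, after_col])
    mask = (
        (table["fold_change"] > min_fold)
        & (table["q_value"] < max_q)
        & (table[after_col] > min_fpkm)
    )
    return _ranked_calls(table, mask, before_col, after_col, pseudocount)


def call_responsive_ernas(
    table: pd.DataFrame,
    before: str,
    after: str,
    min_fold: float = 1.6,
    max_q: float = 0.05,
    min_fpkm: float = 0.5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Stimulus-responsive eRNA loci (relaxed thresholds: FPKM > 0.5, fold > 1.6)."""
    return call_responsive_genes(
        table, before, after, min_fold=min_fold, max_q=max_q, min_fpkm=min_fpkm,
        pseudocount=pseudocount,
    )


def call_inhibitor_responsive(
    tables: Mapping[str, pd.DataFrame],
    fpkm_col: str,
    min_fold_reduction: float = 2.0,
    max_q: float = 0.05,
    min_fpkm: float = 1.0,
) -> set[str]:
    """Features reduced >= min_fold_reduction in *every* inhibitor arm.

    Each table is one inhibitor treatment; a feature qualifies per table
    when its signed fold change is <= -min_fold_reduction, q < max_q, and
    FPKM > min_fpkm, and overall when it qualifies in all tables.
    """
    if len(tables) < 2:
        raise SchemaError("need at least two inhibitor tables to intersect")
    universes = []
    qualified: list[set[str]] = []
    for name, table in tables.items():
        _require_columns(table, ["feature_id", "fold_change", "q_value", fpkm_col])
        universes.append(set(table["feature_id"]))
        mask = (
            (table["fold_change"] <= -min_fold_reduction)
            & (table["q_value"] < max_q)
            & (table[fpkm_col] > min_fpkm)
        )
        qualified.append(set(table.loc[mask, "feature_id"]))
    shared = set.intersection(*universes)
    if not shared:
        raise SchemaError("inhibitor tables have disjoint feature universes")
    return set.intersection(*qualified) & shared


def control_gene_pool(
    tables: Mapping[str, pd.DataFrame],
    fpkm_col: str,
    max_fold: float = 2.0,
    min_q: float = 0.05,
    min_fpkm: float = 1.0,
) -> list[str]:
    """Genes not differentially expressed in any condition (control-eligible).

    Eligibility in every table: q > min_q, |signed fold change| < max_fold,
    FPKM > min_fpkm.
    """
    eligible: set[str] | None = None
    for table in tables.values():
        _require_columns(table, ["feature_id", "fold_change", "q_value", fpkm_col])
        mask = (
            (table["q_value"] > min_q)
            & (table["fold_change"].abs() < max_fold)
            & (table[fpkm_col] > min_fpkm)
        )
        ids = set(table.loc[mask, "feature_id"])
        eligible = ids if eligible is None else (eligible & ids)
    return sorted(eligible or set())


def select_control_genes(
    tables: Mapping[str, pd.DataFrame],
    n: int,
    seed: int,
    fpkm_col: str,
    **pool_kwargs,
) -> set[str]:
    """Uniform sample of n control genes from the non-differential pool.

    Deterministic under ``seed``; raises with the pool size when the pool
    is too small.
    """
    pool = control_gene_pool(tables, fpkm_col, **pool_kwargs)
    if len(pool) < n:
        raise ValueError(
            f"control-gene pool has only {len(pool)} eligible genes, need {n}"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=n, replace=False))


def classify_affected(
    responsive: pd.DataFrame,
    control_table: pd.DataFrame,
    perturbed_table: pd.DataFrame,
    before: str,
    after: str,
    perturbed_after: str | None = None,
    top_fraction: float = 0.30,
    reduction_factor: float = 0.50,
    tier2_min_q: float = 0.05,
    tier2_max_fold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Tiered rule for genes whose stimulus response a perturbation blunts.

    ``responsive`` must already be ranked by descending control-arm fold
    induction (output of :func:`call_responsive_genes`). The top
    ``ceil(top_fraction * n)`` genes are called affected when their
    perturbed-arm fold induction drops to <= ``reduction_factor`` times the
    control-arm fold induction; the remaining genes are called affected
    when they lose differential status in the perturbed arm
    (q > tier2_min_q and fold change < tier2_max_fold after stimulation).

    Returns feature_id, affected flag, and the rule that fired
    (``top-tier-reduction`` / ``lost-significance``).
    """
    if "rank" not in responsive.columns or "fold_induction" not in responsive.columns:
        raise ValueError("responsive set must be ranked (columns 'rank', 'fold_induction')")
    ranks = np.sort(responsive["rank"].to_numpy())
    if len(ranks) and not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
        raise ValueError("responsive ranks must be a permutation of 1..n")
    before_col, after_col = f"fpkm_{before}", f"fpkm_{after}"
    pert_after_col = f"fpkm_{perturbed_after}" if perturbed_after else after_col
    _require_columns(control_table, ["feature_id", before_col, after_col])
    _require_columns(perturbed_table, ["feature_id", before_col, pert_after_col, "fold_change", "q_value"])

    ctrl = control_table.set_index("feature_id")
    pert = perturbed_table.set_index("feature_id")
    n_top = math.ceil(top_fraction * len(responsive))
    rows = []
    for row in responsive.itertuples(index=False):
        fid = row.feature_id
        ctrl_fi = fold_induction(ctrl.at[fid, before_col], ctrl.at[fid, after_col], pseudocount)
        pert_fi = fold_induction(pert.at[fid, before_col], pert.at[fid, pert_after_col], pseudocount)
        if row.rank <= n_top:
            affected = pert_fi <= reduction_factor * ctrl_fi
            rule = "top-tier-reduction" if affected else ""
        else:
            affected = (
                pert.at[fid, "q_value"] > tier2_min_q
                and pert.at[fid, "fold_change"] < tier2_max_fold
            )
            rule = "lost-significance" if affected else ""
        rows.append((fid, int(row.rank), bool(affected), rule))
    return pd.DataFrame(rows, columns=["feature_id", "rank", "affected", "rule"])


def classify_affected_reduction(
    control_table: pd.DataFrame,
    perturbed_table: pd.DataFrame,
    fpkm_col: str,
    min_reduction: float = 0.40,
    inclusive: bool = True,
    features: Sequence[str] | None = None,
) -> set[str]:
    """Expression-level reduction rule (knockdown criterion).

    A feature is affected when its perturbed expression falls to at most
    ``(1 - min_reduction)`` of the control level — i.e. at least a 40%
    reduction at the default. The boundary is inclusive by default
    (exactly 40% down counts), configurable via ``inclusive``.
    """
    _require_columns(control_table, ["feature_id", fpkm_col])
    _require_columns(perturbed_table, ["feature_id", fpkm_col])
    ctrl = control_table.set_index("feature_id")[fpkm_col]
    pert = perturbed_table.set_index("feature_id")[fpkm_col]
    ids = list(features) if features is not None else [f for f in ctrl.index if f in pert.index]
    threshold = {True: np.less_equal, False: np.less}[inclusive]
    return {
        fid for fid in ids
        if threshold(pert[fid], (1.0 - min_reduction) * ctrl[fid])
    }
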