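"""Differential comparison of communication networks between two conditions.

Both conditions must be profiled over the same cell-type label set (paired
samples, time courses). Edges are matched by the identity key
(sender, ligand, receptor, receiver) -- presence/absence, not weight -- and
partitioned into shared / reference-only / target-only sets. Summary
networks are compared entrywise by signed difference and log2 fold change,
with entries flagged when one condition has twofold or more the weight of
the other.

Zero handling for fold changes: log2 ratios substitute a floor epsilon for
zero weights (by default half the smallest positive weight in either
network), so exclusive entries get a large-magnitude but finite, documented
value; they are additionally listed as exclusive rather than hidden inside
the matrix. Entries zero in both conditions have fold change 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edge_extraction import EDGE_KEY, EdgeTable
from .expression_io import CellAnnotation, CellTypeProfile

_MERGE_SUFFIXES = ("_ref", "_target")


@dataclass
class DeltaEdgeTable:
    """Edge partition between two conditions.

    ``shared`` carries both conditions' weights (suffixes ``_ref`` and
    ``_target``); ``only_ref`` / ``only_target`` are plain edge tables.
    """

    shared: pd.DataFrame
    only_ref: pd.DataFrame
    only_target: pd.DataFrame

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_only_ref(self) -> int:
        return len(self.only_ref)

    @property
    def n_only_target(self) -> int:
        return len(self.only_target)


@dataclass
class DeltaNetwork:
    """Entrywise comparison of two same-scheme summary networks."""

    weight_ref: pd.DataFrame
    weight_target: pd.DataFrame
    fold_change: pd.DataFrame  # log2(target / ref), zeros floored at epsilon
    abs_difference: pd.DataFrame  # target - ref
    flags: pd.DataFrame  # "", "up_in_ref", "up_in_target"
    scheme: str = ""
    epsilon: float = 0.0
    population_fraction_ref: pd.Series | None = None
    population_fraction_target: pd.Series | None = None


def match_edge_tables(ref: EdgeTable, target: EdgeTable) -> DeltaEdgeTable:
    """Partition two edge tables by exact (sender, ligand, receptor, receiver) key."""
    ref_types = set(ref.edges["sender"]) | set(ref.edges["receiver"])
    target_types = set(target.edges["sender"]) | set(target.edges["receiver"])
    if ref_types != target_types:
        raise ValueError(
            "cell-type label sets differ between conditions "
            f"(only-ref: {sorted(ref_types - target_types)}, "
            f"only-target: {sorted(target_types - ref_types)}); "
            "relabel so both conditions share the same cell types"
        )
    merged = ref.edges.merge(
        target.edges, on=EDGE_KEY, how="outer", suffixes=_MERGE_SUFFIXES, indicator=True
    )
    ref_cols = EDGE_KEY + [c for c in merged.columns if c.endswith("_ref")]
    target_cols = EDGE_KEY + [c for c in merged.columns if c.endswith("_target")]

    shared = merged.loc[merged["_merge"] == "both"].drop(columns="_merge")
    only_ref = (
        merged.loc[merged["_merge"] == "left_only", ref_cols]
        .rename(columns=lambda c: c.removesuffix("_ref"))
        .reset_index(drop=True)
    )
    only_target = (
        merged.loc[merged["_merge"] == "right_only", target_cols]
        .rename(columns=lambda c: c.removesuffix("_target"))
        .reset_index(drop=True)
    )
    return DeltaEdgeTable(
        shared=shared.reset_index(drop=True), only_ref=only_ref, only_target=only_target
    )


def _log2_ratio(target: np.ndarray, ref: np.ndarray, eps: float) -> np.ndarray:
    t = np.where(target > 0, target, eps)
    r = np.where(ref > 0, ref, eps)
    fc = np.log2(t / r)
    fc[(target == 0) & (ref == 0)] = 0.0
    return fc


def delta_summary(
    ref_net,
    target_net,
    mode: str = "fold_change",
    ann_ref: CellAnnotation | None = None,
    ann_target: CellAnnotation | None = None,
) -> DeltaNetwork:
    """Entrywise delta of two summary networks (same cell types, same scheme).

    ``mode`` selects which quantification drives the flags' magnitude but
    both fold change and signed difference are always populated. An entry is
    flagged ``up_in_ref`` when the reference weight is at least twice the
    target weight and ``up_in_target`` for the converse.
    """
    if mode not in ("fold_change", "difference"):
        raise ValueError(f"unknown mode {mode!r}")
    if ref_net.scheme != target_net.scheme:
        raise ValueError(
            f"scheme mismatch: {ref_net.scheme!r} vs {target_net.scheme!r}"
        )
    if list(ref_net.cell_types) != list(target_net.cell_types):
        raise ValueError("cell-type label sets differ between summary networks")

    w_ref = ref_net.adjacency.astype(float)
    w_tgt = target_net.adjacency.astype(float)
    positive = np.concatenate(
        [w_ref.values[w_ref.values > 0], w_tgt.values[w_tgt.values > 0]]
    )
    eps = float(positive.min()) / 2.0 if positive.size else 1.0

    fc = pd.DataFrame(
        _log2_ratio(w_tgt.values, w_ref.values, eps),
        index=w_ref.index,
        columns=w_ref.columns,
    )
    diff = w_tgt - w_ref

    rvals, tvals = w_ref.values, w_tgt.values
    flags = np.full(rvals.shape, "", dtype=object)
    up_ref = (rvals >= 2 * tvals) & (rvals > 0)
    up_tgt = (tvals >= 2 * rvals) & (tvals > 0)
    flags[up_ref] = "up_in_ref"
    flags[up_tgt] = "up_in_target"
    flags_df = pd.DataFrame(flags, index=w_ref.index, columns=w_ref.columns)

    def _popfrac(ann: CellAnnotation | None) -> pd.Series | None:
        if ann is None:
            return None
        counts = pd.Series(list(ann.mapping.values())).value_counts()
        return (counts / counts.sum()).reindex(w_ref.index).fillna(0.0)

    return DeltaNetwork(
        weight_ref=w_ref,
        weight_target=w_tgt,
        fold_change=fc,
        abs_difference=diff,
        flags=flags_df,
        scheme=ref_net.scheme,
        epsilon=eps,
        population_fraction_ref=_popfrac(ann_ref),
        population_fraction_target=_popfrac(ann_target),
    )


def edge_class_involvement(
    delta: DeltaEdgeTable, focus_types: set[str]
) -> dict[str, tuple[int, float]]:
    """Count and fraction of exclusive edges touching any focus cell type.

    An edge is "involved" when its sender OR receiver is in ``focus_types``
    -- e.g. how many of the edges exclusive to the aged condition involve
    signalling to or from lymphocytes.
    """
    if not focus_types:
        raise ValueError("empty focus set")
    out: dict[str, tuple[int, float]] = {}
    for name, frame in (("only_ref", delta.only_ref), ("only_target", delta.only_target)):
        if frame.empty:
            out[name] = (0, float("nan"))
            continue
        touched = frame["sender"].isin(focus_types) | frame["receiver"].isin(focus_types)
        out[name] = (int(touched.sum()), float(touched.mean()))
    return out


def per_gene_fold_changes(
    ref_profile: CellTypeProfile,
    target_profile: CellTypeProfile,
    cell_type: str,
    genes: list[str],
    epsilon: float = 1e-3,
) -> pd.Series:
    """log2 fold change of mean expression per gene within one cell type.

    Zero means are floored at ``epsilon`` (expression units) before taking
    the ratio; genes absent from a profile count as mean 0. Positive values
    are up in the target condition.
    """
    from .lr_database import normalise_symbol

    def _mean(profile: CellTypeProfile, gene: str) -> float:
        lookup = {normalise_symbol(g): g for g in profile.genes}
        row = lookup.get(normalise_symbol(gene))
        if row is None:
            return 0.0
        return float(profile.mean_expr.loc[row, cell_type])

    values = {}
    for g in genes:
        r = max(_mean(ref_profile, g), epsilon)
        t = max(_mean(target_profile, g), epsilon)
        values[g] = float(np.log2(t / r))
    return pd.Series(values, name="log2_fold_change")
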