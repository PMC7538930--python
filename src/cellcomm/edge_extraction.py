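"""Ligand-receptor edges between ordered cell-type pairs, with three weights.

An edge asserts that a *sender* cell type expresses a ligand whose cognate
receptor is expressed by a *receiver* cell type (sender may equal receiver:
autocrine). Each edge carries three weights:

* mean-expression weight -- mean ligand expression in the sender times mean
  receptor expression in the receiver; emphasises highly expressed pairs.
* specificity weight -- the product of ligand and receptor specificities,
  each being the type's mean expression divided by the sum of mean
  expressions across ALL cell types in the dataset. Ranges over [0, 1]; a
  weight of 1 means ligand and receptor are each expressed in exactly one
  cell type. The denominators are taken over every cell type, including
  those failing detection filters: specificity is a dataset-local quantity.
* total-expression weight -- summed ligand expression in the sender times
  summed receptor expression in the receiver; acknowledges cell-type
  abundance (500 cells at mean 10 CPM contribute 5000, outweighing 10 cells
  at mean 80 CPM contributing 800).

A gene silent in every cell type has specificity 0 by convention (not NaN).

Per-cell co-detection is the single-cell refinement of autocrine signalling:
a ligand and its receptor counted only when both exceed the expression
threshold in the *same individual cell*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import (
    CellAnnotation,
    CellTypeProfile,
    ExpressionMatrix,
    FilterSettings,
)
from .lr_database import PairDatabase, normalise_symbol

EDGE_KEY = ["sender", "ligand", "receptor", "receiver"]

EDGE_COLUMNS = EDGE_KEY + [
    "ligand_mean",
    "ligand_total",
    "ligand_detection",
    "ligand_specificity",
    "receptor_mean",
    "receptor_total",
    "receptor_detection",
    "receptor_specificity",
    "mean_weight",
    "specificity_weight",
    "total_weight",
]


@dataclass
class EdgeTable:
    """One row per (sender, ligand, receptor, receiver); see EDGE_COLUMNS."""

    edges: pd.DataFrame
    settings: FilterSettings = field(default_factory=FilterSettings)
    database_id: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.edges.empty:
            self.edges = pd.DataFrame(columns=EDGE_COLUMNS)
        missing = set(EDGE_COLUMNS) - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns {sorted(missing)}")
        if self.edges.duplicated(subset=EDGE_KEY).any():
            raise ValueError("duplicate (sender, ligand, receptor, receiver) rows")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.edges["sender"]) | set(self.edges["receiver"]))

    def keys(self) -> set[tuple[str, str, str, str]]:
        return set(map(tuple, self.edges[EDGE_KEY].itertuples(index=False, name=None)))


class _ProfileView:
    """Case-insensitive gene lookup over a CellTypeProfile, with zero fallback."""

    def __init__(self, profile: CellTypeProfile):
        self.profile = profile
        self._row = {normalise_symbol(g): g for g in profile.genes}
        self.types = list(profile.cell_types)
        n = len(self.types)
        self._zero = pd.Series(0.0, index=self.types)

    def _vec(self, frame: pd.DataFrame, gene: str) -> pd.Series:
        row = self._row.get(normalise_symbol(gene))
        if row is None:
            return self._zero
        return frame.loc[row]

    def mean(self, gene: str) -> pd.Series:
        return self._vec(self.profile.mean_expr, gene)

    def total(self, gene: str) -> pd.Series:
        return self._vec(self.profile.total_expr, gene)

    def detection(self, gene: str) -> pd.Series:
        return self._vec(self.profile.detection_fraction, gene)

    def specificity(self, gene: str) -> pd.Series:
        """mean / (sum of means across all cell types); 0/0 -> 0."""
        means = self.mean(gene)
        denom = float(means.sum())
        if denom <= 0:
            return self._zero
        return means / denom


def _check_type(view: _ProfileView, cell_type: str) -> None:
    if cell_type not in view.types:
        raise KeyError(f"unknown cell type {cell_type!r}")


def specificity_weight(
    profile: CellTypeProfile, ligand: str, receptor: str, sender: str, receiver: str
) -> float:
    """Ligand specificity in sender x receptor specificity in receiver."""
    view = _ProfileView(profile)
    _check_type(view, sender)
    _check_type(view, receiver)
    return float(view.specificity(ligand)[sender] * view.specificity(receptor)[receiver])


def mean_expression_weight(
    profile: CellTypeProfile, ligand: str, receptor: str, sender: str, receiver: str
) -> float:
    """Mean ligand expression in sender x mean receptor expression in receiver."""
    view = _ProfileView(profile)
    _check_type(view, sender)
    _check_type(view, receiver)
    return float(view.mean(ligand)[sender] * view.mean(receptor)[receiver])


def total_expression_weight(
    profile: CellTypeProfile, ligand: str, receptor: str, sender: str, receiver: str
) -> float:
    """Summed ligand expression in sender x summed receptor expression in receiver."""
    view = _ProfileView(profile)
    _check_type(view, sender)
    _check_type(view, receiver)
    return float(view.total(ligand)[sender] * view.total(receptor)[receiver])


def _passes(view: _ProfileView, gene: str, f: FilterSettings) -> pd.Series:
    """Boolean per cell type: gene counts as expressed under the filters."""
    det_ok = f.detection_passes(view.detection(gene))
    expr_ok = view.mean(gene) >= f.expression_threshold
    return det_ok & expr_ok


def extract_edges(
    profile: CellTypeProfile,
    db: PairDatabase,
    f: FilterSettings | None = None,
    database_id: str = "",
    dataset_id: str = "",
) -> EdgeTable:
    """All edges surviving the detection/expression filters.

    One edge per database pair and ordered (sender, receiver) cell-type pair
    (autocrine sender == receiver included) where the ligand passes the
    filters in the sender AND the receptor passes them in the receiver. The
    filters apply to each endpoint independently; the specificity threshold
    is a summary-network filter and is not applied here.
    """
    f = f or FilterSettings()
    if len(db) == 0:
        raise ValueError("empty pair database")
    if not profile.cell_types:
        raise ValueError("empty cell-type profile")

    view = _ProfileView(profile)
    types = view.types
    rows: list[dict] = []
    for pair in db.pairs:
        lig, rec = pair.ligand_symbol, pair.receptor_symbol
        lig_ok = _passes(view, lig, f)
        if not lig_ok.any():
            continue
        rec_ok = _passes(view, rec, f)
        if not rec_ok.any():
            continue
        lig_mean, lig_total = view.mean(lig), view.total(lig)
        lig_det, lig_spec = view.detection(lig), view.specificity(lig)
        rec_mean, rec_total = view.mean(rec), view.total(rec)
        rec_det, rec_spec = view.detection(rec), view.specificity(rec)
        senders = [t for t in types if lig_ok[t]]
        receivers = [t for t in types if rec_ok[t]]
        for s, r in itertools.product(senders, receivers):
            rows.append(
                {
                    "sender": s,
                    "ligand": lig,
                    "receptor": rec,
                    "receiver": r,
                    "ligand_mean": lig_mean[s],
                    "ligand_total": lig_total[s],
                    "ligand_detection": lig_det[s],
                    "ligand_specificity": lig_spec[s],
                    "receptor_mean": rec_mean[r],
                    "receptor_total": rec_total[r],
                    "receptor_detection": rec_det[r],
                    "receptor_specificity": rec_spec[r],
                    "mean_weight": lig_mean[s] * rec_mean[r],
                    "specificity_weight": lig_spec[s] * rec_spec[r],
                    "total_weight": lig_total[s] * rec_total[r],
                }
            )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return EdgeTable(edges=edges, settings=f, database_id=database_id, dataset_id=dataset_id)


def filter_edges(table: EdgeTable, f: FilterSettings) -> pd.DataFrame:
    """Rows of ``table`` surviving detection, expression and specificity thresholds."""
    e = table.edges
    if e.empty:
        return e
    keep = (
        f.detection_passes(e["ligand_detection"].to_numpy())
        & f.detection_passes(e["receptor_detection"].to_numpy())
        & (e["ligand_mean"].to_numpy() >= f.expression_threshold)
        & (e["receptor_mean"].to_numpy() >= f.expression_threshold)
        & (e["specificity_weight"].to_numpy() >= f.specificity_threshold)
    )
    return e.loc[keep]


@dataclass(frozen=True)
class CoDetectionRecord:
    """A ligand-receptor pair co-detected within single cells of one type."""

    cell_type: str
    ligand: str
    receptor: str
    co_detection_fraction: float


def codetect_pairs_per_cell(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    db: PairDatabase,
    expr_threshold: float = 10.0,
    codetect_fraction: float = 0.20,
) -> list[CoDetectionRecord]:
    """Pairs whose ligand AND receptor exceed ``expr_threshold`` in the same cell.

    For each cell type, a pair is reported when the fraction of that type's
    cells co-expressing both genes above the threshold is at least
    ``codetect_fraction``. This separates true self-signalling potential from
    cell-type-level autocrine calls, where ligand and receptor may sit in
    different cells of the same type.
    """
    ann.validate_against(m)
    norm_to_row = {normalise_symbol(g): g for g in m.gene_ids}
    records: list[CoDetectionRecord] = []
    for cell_type in ann.cell_types:
        cells = ann.cells_of(cell_type)
        block = m.values[cells]
        above = block.to_numpy(dtype=float) > expr_threshold
        row_index = {g: i for i, g in enumerate(block.index)}
        for pair in db.pairs:
            lig_row = norm_to_row.get(normalise_symbol(pair.ligand_symbol))
            rec_row = norm_to_row.get(normalise_symbol(pair.receptor_symbol))
            if lig_row is None or rec_row is None:
                continue
            both = above[row_index[lig_row]] & above[row_index[rec_row]]
            frac = float(both.mean())
            if frac >= codetect_fraction:
                records.append(
                    CoDetectionRecord(
                        cell_type, pair.ligand_symbol, pair.receptor_symbol, frac
                    )
                )
    return records


def codetection_counts(records: list[CoDetectionRecord]) -> pd.Series:
    """Number of co-detected pairs per cell type (for median-per-type summaries)."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.cell_type] = counts.get(r.cell_type, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def write_edge_table(table: EdgeTable, path) -> None:
    """Tab-delimited edge file; weights rounded to 6 significant digits."""
    out = table.edges.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: float(f"{x:.6g}"))
    out.to_csv(path, sep="\t", index=False)


def read_edge_table(path, settings: FilterSettings | None = None) -> EdgeTable:
    df = pd.read_csv(path, sep="\t")
    for col in EDGE_KEY:
        df[col] = df[col].astype(str)
    return EdgeTable(edges=df, settings=settings or FilterSettings())
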