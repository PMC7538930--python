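"""Expression matrices, cell annotations, CPM normalisation, per-type summaries.

The expression matrix is genes x cells, tab-delimited text with a gene-symbol
first column and a header row of cell identifiers (gzip accepted). The
annotation file maps each cell to a cell-type / cluster label
(``Cell<TAB>Annotation``).

Per cell type, three summaries are computed for each gene of interest:

* mean expression (``mean_expr``, in the matrix's expression units),
* total expression (``total_expr`` = sum over the type's cells), and
* detection fraction (share of the type's cells with value strictly > 0).

These are the quantities all edge weights are built from. A gene listed in
the pair database but absent from the matrix is treated as unexpressed
(mean 0, total 0, detection 0), not as an error: cross-species projections
and targeted panels routinely lack genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lr_database import normalise_symbol

logger = logging.getLogger("cellcomm")

CPM_SCALE = 1_000_000.0


@dataclass
class FilterSettings:
    """Thresholds deciding when a ligand/receptor counts as expressed.

    detection_threshold: minimum fraction of a cell type's cells in which the
        gene is detected (default 0.20, the common single-cell convention).
        Compared with >= by default; ``strict_detection`` switches to >.
    expression_threshold: minimum mean expression, in the matrix's units
        (e.g. CPM). Default 0 (no expression filter).
    specificity_threshold: minimum per-edge specificity weight, applied when
        hard-filtering summary networks. Default 0.
    """

    detection_threshold: float = 0.20
    expression_threshold: float = 0.0
    specificity_threshold: float = 0.0
    strict_detection: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_threshold <= 1.0:
            raise ValueError("detection_threshold must be in [0, 1]")
        if self.expression_threshold < 0:
            raise ValueError("expression_threshold must be >= 0")
        if not 0.0 <= self.specificity_threshold <= 1.0:
            raise ValueError("specificity_threshold must be in [0, 1]")

    def detection_passes(self, fraction: np.ndarray | float) -> np.ndarray | bool:
        if self.strict_detection:
            return fraction > self.detection_threshold
        return fraction >= self.detection_threshold


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression values."""

    values: pd.DataFrame  # index: gene symbols, columns: cell ids
    scale: str = "raw_counts"  # raw_counts | cpm | other_normalised

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate cell ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class CellAnnotation:
    """Mapping cell id -> cell-type label."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty annotation")

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def cells_of(self, cell_type: str) -> list[str]:
        return [c for c, t in self.mapping.items() if t == cell_type]

    def validate_against(self, m: ExpressionMatrix) -> None:
        unknown = set(self.mapping) - set(m.cell_ids)
        if unknown:
            raise ValueError(
                f"annotation references cells absent from the matrix: {sorted(unknown)[:5]}"
            )


@dataclass
class CellTypeProfile:
    """Per (gene, cell type) summaries over genes of interest.

    All three frames are genes x cell types with identical index/columns;
    ``n_cells`` maps cell type -> cell count.
    """

    mean_expr: pd.DataFrame
    total_expr: pd.DataFrame
    detection_fraction: pd.DataFrame
    n_cells: pd.Series
    scale: str = "cpm"

    def __post_init__(self) -> None:
        for frame in (self.total_expr, self.detection_fraction):
            if not frame.index.equals(self.mean_expr.index) or not frame.columns.equals(
                self.mean_expr.columns
            ):
                raise ValueError("profile frames must share index and columns")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_expr.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.mean_expr.index)


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x cells tab-delimited matrix.

    Duplicate gene rows are collapsed by summing (with a warning); negative
    entries are rejected; ragged rows raise a format error from the parser.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values") from exc
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    df.index = df.index.map(str)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicated gene rows by sum", path, n_dup)
        df = df.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(values=df, scale="raw_counts")


def load_annotation(path: str | Path) -> CellAnnotation:
    """Read a two-column ``Cell<TAB>Annotation`` table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs two columns (cell, cell type)")
    cells = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1].astype(str)
    if cells.duplicated().any():
        raise ValueError(f"{path}: duplicated cell ids in annotation")
    return CellAnnotation(dict(zip(cells, labels)))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="Gene")


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"Cell": list(ann.mapping), "Annotation": list(ann.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def normalise_cpm(m: ExpressionMatrix, allow_renormalise: bool = False) -> ExpressionMatrix:
    """Counts-per-million: rescale each cell so its values sum to 1e6.

    Library size is a whole-transcriptome property, so the column sum is
    taken over ALL genes in the matrix, not only ligands/receptors. Calling
    on an already-CPM matrix is an error unless ``allow_renormalise`` (then a
    no-op up to the rescaling, which is idempotent).
    """
    if m.scale == "cpm" and not allow_renormalise:
        raise ValueError("matrix is already CPM-scaled (pass allow_renormalise=True to force)")
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"cells with zero total counts: {list(zero.index)[:5]}")
    scaled = m.values.div(colsums, axis=1) * CPM_SCALE
    return ExpressionMatrix(values=scaled, scale="cpm")


def summarise_by_cell_type(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    genes_of_interest: set[str] | None = None,
) -> CellTypeProfile:
    """Mean, total and detection fraction per (gene, cell type).

    ``genes_of_interest`` is normally the union of ligand and receptor
    symbols in the active pair database; matching against matrix rows is
    case-insensitive, and database genes missing from the matrix appear in
    the profile as all-zero rows (logged). Detection counts strictly
    positive values.
    """
    ann.validate_against(m)

    if genes_of_interest is None:
        wanted = list(m.gene_ids)
        sub = m.values
        missing: list[str] = []
    else:
        norm_to_row = {normalise_symbol(g): g for g in m.gene_ids}
        wanted, rows, missing = [], [], []
        seen_norm: set[str] = set()
        for g in sorted(genes_of_interest):
            norm = normalise_symbol(g)
            if norm in seen_norm:  # same gene under two casings
                continue
            seen_norm.add(norm)
            row = norm_to_row.get(norm)
            if row is None:
                missing.append(g)
            else:
                rows.append(row)
            wanted.append(g)
        sub = m.values.loc[rows]
        if missing:
            logger.info(
                "%d database genes absent from matrix (treated as unexpressed): %s%s",
                len(missing), missing[:5], "..." if len(missing) > 5 else "",
            )

    types = ann.cell_types
    mean = pd.DataFrame(0.0, index=wanted, columns=types)
    total = pd.DataFrame(0.0, index=wanted, columns=types)
    det = pd.DataFrame(0.0, index=wanted, columns=types)
    n_cells = pd.Series(0, index=types, dtype=int)

    present = [g for g in wanted if g not in set(missing)] if genes_of_interest else wanted
    # map profile gene label -> matrix row values
    if genes_of_interest is not None:
        norm_to_row = {normalise_symbol(g): g for g in m.gene_ids}
        row_of = {g: norm_to_row[normalise_symbol(g)] for g in present}
    else:
        row_of = {g: g for g in present}

    for t in types:
        cells = ann.cells_of(t)
        n_cells[t] = len(cells)
        block = m.values.loc[[row_of[g] for g in present], cells]
        vals = block.to_numpy(dtype=float)
        mean.loc[present, t] = vals.mean(axis=1)
        total.loc[present, t] = vals.sum(axis=1)
        det.loc[present, t] = (vals > 0).mean(axis=1)

    return CellTypeProfile(
        mean_expr=mean,
        total_expr=total,
        detection_fraction=det,
        n_cells=n_cells,
        scale=m.scale,
    )
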