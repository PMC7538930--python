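"""Synthetic single-cell fixtures with planted communication structure.

Generates sparse non-negative count matrices with cell-type structure, a
matching annotation, a pair database, an organ map, and a ground-truth
manifest, so the whole pipeline is testable without real accessions.

Count model: per-gene base means are drawn log-normally around
``baseline_mean``; counts are negative-binomial (gamma-Poisson) with
dispersion ``dispersion`` and then zeroed independently with probability
``dropout_rate`` -- the minimal model giving realistic sparsity and
controllable detection fractions. No claim of biological co-expression
structure is made beyond what is explicitly planted.

Planting:

* a planted edge (sender, ligand, receptor, receiver, effect_size) makes the
  ligand *exclusive* to the sender and the receptor exclusive to the
  receiver, expressed at ``effect_size x baseline_mean`` with detection
  forced above the default 20% threshold. Exclusivity pins the edge's
  specificity weight to exactly 1, the cleanest recoverable signal.
* a planted co-detection (cell_type, (ligand, receptor), target_fraction)
  forces both genes above threshold in exactly that fraction of the type's
  cells (and nowhere else), so per-cell co-detection is exact by
  construction.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import CellAnnotation, ExpressionMatrix, FilterSettings
from .lr_database import LigandLocation, LigandReceptorPair, PairDatabase
from .network_analysis import OrganMap

_LOCATION_CYCLE = (
    LigandLocation.SECRETED,
    LigandLocation.PLASMA_MEMBRANE,
    LigandLocation.BOTH,
)

# fraction of a planted (gene, cell type)'s cells forced to nonzero counts
_PLANT_DETECTION = 0.9


@dataclass
class FixtureConfig:
    n_cell_types: int = 6
    cells_per_type: int | tuple[int, int] = 50
    n_genes: int = 200
    n_pairs: int = 30
    baseline_mean: float = 5.0
    dispersion: float = 0.5
    dropout_rate: float = 0.3
    planted_edges: list[tuple[str, str, str, str, float]] = field(default_factory=list)
    planted_codetection: list[tuple[str, tuple[str, str], float]] = field(
        default_factory=list
    )
    types_per_organ: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.n_pairs * 2 > self.n_genes:
            raise ValueError("gene universe too small for n_pairs ligands+receptors")
        if self.n_cell_types < 1 or self.n_genes < 1:
            raise ValueError("need at least one cell type and one gene")


def ligand_name(i: int) -> str:
    return f"LIG{i + 1:03d}"


def receptor_name(i: int) -> str:
    return f"REC{i + 1:03d}"


def cell_type_name(i: int) -> str:
    return f"CT{i + 1:02d}"


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2 (gamma-Poisson)."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def _plant_home_types(cfg: FixtureConfig) -> dict[str, str]:
    """Each planted-exclusive gene's home cell type; conflicting plants error."""
    homes: dict[str, str] = {}
    for sender, ligand, receptor, receiver, _effect in cfg.planted_edges:
        for gene, home in ((ligand, sender), (receptor, receiver)):
            if homes.get(gene, home) != home:
                raise ValueError(
                    f"contradictory plant: gene {gene} exclusive in both "
                    f"{homes[gene]} and {home}"
                )
            homes[gene] = home
    return homes


def generate_fixture(
    cfg: FixtureConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, PairDatabase, OrganMap, dict]:
    """Build (raw-count matrix, annotation, pair database, organ map, manifest)."""
    rng = np.random.default_rng(cfg.seed)

    types = [cell_type_name(i) for i in range(cfg.n_cell_types)]
    if isinstance(cfg.cells_per_type, tuple):
        lo, hi = cfg.cells_per_type
        n_cells_per_type = {t: int(rng.integers(lo, hi + 1)) for t in types}
    else:
        n_cells_per_type = {t: int(cfg.cells_per_type) for t in types}

    cells: list[str] = []
    labels: list[str] = []
    for t in types:
        for j in range(n_cells_per_type[t]):
            cells.append(f"{t}_c{j + 1:04d}")
            labels.append(t)
    annotation = CellAnnotation(dict(zip(cells, labels)))

    organs = OrganMap(
        {t: f"ORG{i // cfg.types_per_organ + 1:02d}" for i, t in enumerate(types)}
    )

    ligands = [ligand_name(i) for i in range(cfg.n_pairs)]
    receptors = [receptor_name(i) for i in range(cfg.n_pairs)]
    n_background = cfg.n_genes - 2 * cfg.n_pairs
    background = [f"BG{i + 1:04d}" for i in range(n_background)]
    genes = ligands + receptors + background

    pairs = [
        LigandReceptorPair(
            ligands[i],
            receptors[i],
            _LOCATION_CYCLE[i % len(_LOCATION_CYCLE)],
            (f"PMID:{1000 + i}",),
            "synthetic",
        )
        for i in range(cfg.n_pairs)
    ]
    db = PairDatabase(pairs, species_taxon="synthetic")

    plant_homes = _plant_home_types(cfg)
    unknown_types = ({s for s, *_ in cfg.planted_edges}
                     | {e[3] for e in cfg.planted_edges}
                     | {ct for ct, _, _ in cfg.planted_codetection}) - set(types)
    if unknown_types:
        raise ValueError(f"planted cell types not in fixture: {sorted(unknown_types)}")
    codetect_genes = {g for _, pair, _ in cfg.planted_codetection for g in pair}
    overlap = codetect_genes & set(plant_homes)
    if overlap:
        raise ValueError(
            f"genes planted both as exclusive edge and co-detection: {sorted(overlap)}"
        )

    # background base means, log-normal around baseline_mean
    base_mean = np.exp(
        rng.normal(math.log(cfg.baseline_mean), 0.5, size=len(genes))
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    # planted-exclusive and co-detection genes carry no background expression
    for g in set(plant_homes) | codetect_genes:
        base_mean[gene_index[g]] = 0.0

    values = np.zeros((len(genes), len(cells)), dtype=np.int64)
    col_of_type = {
        t: np.array([i for i, lab in enumerate(labels) if lab == t]) for t in types
    }
    for gi in range(len(genes)):
        if base_mean[gi] <= 0:
            continue
        counts = _nb_counts(rng, base_mean[gi], cfg.dispersion, len(cells))
        values[gi] = counts
    if 0.0 < cfg.dropout_rate:
        keep = rng.random(values.shape) >= cfg.dropout_rate
        values = values * keep

    # plant exclusive ligand/receptor expression
    for gene, home in plant_homes.items():
        effect = max(
            e[4]
            for e in cfg.planted_edges
            if gene in (e[1], e[2]) and home in (e[0], e[3])
        )
        cols = col_of_type[home]
        counts = _nb_counts(rng, effect * cfg.baseline_mean, cfg.dispersion, len(cols))
        n_force = math.ceil(_PLANT_DETECTION * len(cols))
        counts[:n_force] = np.maximum(counts[:n_force], 1)
        values[gene_index[gene], cols] = counts

    # plant per-cell co-detection at an exact fraction
    high = max(1, int(round(10 * cfg.baseline_mean)))
    for cell_type, (lig, rec), frac in cfg.planted_codetection:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("co-detection fraction must be in [0, 1]")
        cols = col_of_type[cell_type]
        k = int(round(frac * len(cols)))
        for g in (lig, rec):
            values[gene_index[g], cols[:k]] = high

    # a cell with zero total counts cannot be CPM-normalised; give it one count
    zero_cols = np.flatnonzero(values.sum(axis=0) == 0)
    if zero_cols.size and n_background:
        values[gene_index[background[0]], zero_cols] = 1

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=cells), scale="raw_counts"
    )
    manifest = {
        "config": cfg,
        "cell_types": types,
        "n_cells_per_type": n_cells_per_type,
        "planted_edges": list(cfg.planted_edges),
        "planted_codetection": list(cfg.planted_codetection),
        "pair_keys": [(p.ligand_symbol, p.receptor_symbol) for p in pairs],
    }
    return matrix, annotation, db, organs, manifest


def fixture_truth_report(
    manifest: dict,
    settings: FilterSettings | None = None,
    expr_threshold: float = 10.0,
    codetect_fraction: float = 0.20,
) -> dict:
    """Assertable expectations implied by the manifest at stated thresholds.

    * ``expected_edges``: the (sender, ligand, receptor, receiver) keys every
      planted edge must produce (exclusive plants produce exactly these keys
      for their pairs at the default detection threshold).
    * ``expected_codetected`` / ``expected_not_codetected``: co-detection
      plants partitioned by whether their planted fraction reaches the
      reporting threshold.
    """
    settings = settings or FilterSettings()
    expected_edges = {
        (sender, ligand, receptor, receiver)
        for sender, ligand, receptor, receiver, _ in manifest["planted_edges"]
    }
    codetected, absent = set(), set()
    for cell_type, (lig, rec), frac in manifest["planted_codetection"]:
        n = manifest["n_cells_per_type"][cell_type]
        realised = round(frac * n) / n
        if realised >= codetect_fraction:
            codetected.add((cell_type, lig, rec))
        else:
            absent.add((cell_type, lig, rec))
    return {
        "expected_edges": expected_edges,
        "planted_pairs": {
            (ligand, receptor) for _, ligand, receptor, _, _ in manifest["planted_edges"]
        },
        "expected_codetected": codetected,
        "expected_not_codetected": absent,
        "settings": settings,
    }
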