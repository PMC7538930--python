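import numpy as np
import pandas as pd
import pytest

from cellcomm import (
    CellAnnotation,
    ExpressionMatrix,
    FilterSettings,
    FixtureConfig,
    LigandReceptorPair,
    PairDatabase,
    generate_fixture,
    normalise_cpm,
    summarise_by_cell_type,
)


def make_matrix(data: dict[str, list[float]], cells: list[str], scale="cpm") -> ExpressionMatrix:
    """Matrix from {gene: per-cell values}."""
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(data, orient="index", columns=cells, dtype=float),
        scale=scale,
    )


def make_annotation(assignment: dict[str, list[str]]) -> CellAnnotation:
    """Annotation from {cell_type: [cell ids]}."""
    return CellAnnotation({c: t for t, cs in assignment.items() for c in cs})


def make_db(pairs: list[tuple[str, str]], locations=None) -> PairDatabase:
    locations = locations or ["both"] * len(pairs)
    return PairDatabase(
        [LigandReceptorPair(l, r, loc) for (l, r), loc in zip(pairs, locations)]
    )


@pytest.fixture
def exclusive_profile():
    """Ligand only in A, receptor only in B, 2 cells per type."""
    m = make_matrix(
        {"LIG": [5, 7, 0, 0], "REC": [0, 0, 3, 9], "HK": [1, 1, 1, 1]},
        cells=["a1", "a2", "b1", "b2"],
    )
    ann = make_annotation({"A": ["a1", "a2"], "B": ["b1", "b2"]})
    return summarise_by_cell_type(m, ann, {"LIG", "REC"})


@pytest.fixture
def random_fixture():
    """A mid-size seeded synthetic dataset, CPM-normalised, with its db."""
    cfg = FixtureConfig(
        n_cell_types=5, cells_per_type=40, n_genes=120, n_pairs=20,
        dropout_rate=0.4, seed=7,
    )
    matrix, ann, db, organs, manifest = generate_fixture(cfg)
    cpm = normalise_cpm(matrix)
    profile = summarise_by_cell_type(cpm, ann, db.gene_universe())
    return {
        "matrix": cpm, "raw": matrix, "annotation": ann, "db": db,
        "organs": organs, "manifest": manifest, "profile": profile,
    }
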