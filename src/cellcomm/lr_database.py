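"""Ligand-receptor pair databases: loading, filtering, ortholog projection.

A pair database is the prior knowledge driving all downstream network
inference: each row asserts that a ligand gene product binds a receptor gene
product, with the ligand annotated as secreted, plasma-membrane bound, or
both. Two on-disk dialects are supported:

* ``connectomedb`` -- the curated-database layout: delimited text with
  ligand, receptor, ligand-location, literature-evidence and source columns.
  An optional companion sheet of excluded pairs (pair + reason for removal)
  is parsed but kept strictly outside the database.
* ``two_column_user`` -- a minimal user list: header row then
  ``Ligand<TAB>Receptor``. Location defaults to ``both``.

Gene symbols are compared case-insensitively after whitespace trimming (human
symbols are conventionally uppercase, mouse capitalised); the original casing
is preserved for output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cellcomm")

HUMAN_TAXON = "9606"


class LigandLocation(str, Enum):
    SECRETED = "secreted"
    PLASMA_MEMBRANE = "plasma_membrane"
    BOTH = "both"


_LOCATION_ALIASES = {
    "secreted": LigandLocation.SECRETED,
    "secreted ligand": LigandLocation.SECRETED,
    "plasma membrane": LigandLocation.PLASMA_MEMBRANE,
    "plasma_membrane": LigandLocation.PLASMA_MEMBRANE,
    "plasma membrane ligand": LigandLocation.PLASMA_MEMBRANE,
    "membrane": LigandLocation.PLASMA_MEMBRANE,
    "both": LigandLocation.BOTH,
    "secreted and plasma membrane": LigandLocation.BOTH,
}


def normalise_symbol(symbol: str) -> str:
    """Canonical form used for all symbol comparisons: trimmed, upper-cased."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class LigandReceptorPair:
    """One curated ligand-receptor interaction."""

    ligand_symbol: str
    receptor_symbol: str
    ligand_location: LigandLocation = LigandLocation.BOTH
    evidence_ids: tuple[str, ...] = ()
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_symbol or not self.receptor_symbol:
            raise ValueError("ligand and receptor symbols must be non-empty")
        if not isinstance(self.ligand_location, LigandLocation):
            object.__setattr__(
                self, "ligand_location", LigandLocation(self.ligand_location)
            )

    @property
    def key(self) -> tuple[str, str]:
        return (normalise_symbol(self.ligand_symbol), normalise_symbol(self.receptor_symbol))


@dataclass
class PairDatabase:
    """A deduplicated set of ligand-receptor pairs for one species."""

    pairs: list[LigandReceptorPair] = field(default_factory=list)
    species_taxon: str = HUMAN_TAXON

    def __post_init__(self) -> None:
        keys = [p.key for p in self.pairs]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (ligand, receptor) pairs in PairDatabase")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def ligand_symbols(self) -> list[str]:
        return [p.ligand_symbol for p in self.pairs]

    @property
    def receptor_symbols(self) -> list[str]:
        return [p.receptor_symbol for p in self.pairs]

    def gene_universe(self) -> set[str]:
        """All ligand and receptor symbols (original casing)."""
        genes: set[str] = set()
        for p in self.pairs:
            genes.add(p.ligand_symbol)
            genes.add(p.receptor_symbol)
        return genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Ligand": [p.ligand_symbol for p in self.pairs],
                "Receptor": [p.receptor_symbol for p in self.pairs],
                "Ligand location": [p.ligand_location.value for p in self.pairs],
                "Evidence": [";".join(p.evidence_ids) for p in self.pairs],
                "Source": [p.source_tag for p in self.pairs],
            }
        )


@dataclass
class HomologyTable:
    """HomoloGene-style ortholog groups: rows of (group id, taxon id, symbol)."""

    rows: pd.DataFrame  # columns: group_id, taxon_id, symbol

    def __post_init__(self) -> None:
        required = {"group_id", "taxon_id", "symbol"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"HomologyTable needs columns {sorted(required)}")
        self.rows = self.rows.astype(str)
        self.rows["norm_symbol"] = self.rows["symbol"].map(normalise_symbol)

    def taxa(self) -> set[str]:
        return set(self.rows["taxon_id"])

    def groups_for(self, taxon: str, symbol: str) -> set[str]:
        sub = self.rows
        mask = (sub["taxon_id"] == str(taxon)) & (
            sub["norm_symbol"] == normalise_symbol(symbol)
        )
        return set(sub.loc[mask, "group_id"])

    def symbols_in(self, taxon: str, groups: set[str]) -> list[str]:
        sub = self.rows
        mask = (sub["taxon_id"] == str(taxon)) & sub["group_id"].isin(groups)
        return sorted(set(sub.loc[mask, "symbol"]))


def load_homology_table(path: str | Path) -> HomologyTable:
    """Read a three-column tab-delimited (group, taxon, symbol) table."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: homology table needs 3 columns (group, taxon, symbol)")
    df = df.iloc[:, :3]
    df.columns = ["group_id", "taxon_id", "symbol"]
    return HomologyTable(df)


class PairFormatError(ValueError):
    """Raised when a pair file does not match the declared dialect."""


def _find_column(columns: list[str], candidates: tuple[str, ...]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    # substring fallback ("Ligand gene symbol" etc.)
    for cand in candidates:
        for low, orig in lowered.items():
            if cand in low:
                return orig
    return None


def _parse_location(raw: object) -> LigandLocation:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return LigandLocation.BOTH
    text = str(raw).strip().lower().replace("-", " ")
    if not text or text == "nan":
        return LigandLocation.BOTH
    if text in _LOCATION_ALIASES:
        return _LOCATION_ALIASES[text]
    raise PairFormatError(f"unrecognised ligand location {raw!r}")


def load_pair_database(
    path: str | Path,
    dialect: str = "connectomedb",
    species_taxon: str = HUMAN_TAXON,
) -> PairDatabase:
    """Load a ligand-receptor pair file into a deduplicated :class:`PairDatabase`.

    Duplicated (ligand, receptor) rows are merged -- evidence unioned, first
    location kept -- with a warning, since merged multi-source tables
    legitimately repeat pairs. Rows in a connectomedb-dialect file flagged as
    excluded never enter the database.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise PairFormatError(f"{path}: no pair rows")

    cols = list(df.columns)
    lig_col = _find_column(cols, ("ligand", "ligand symbol", "ligand gene symbol"))
    rec_col = _find_column(cols, ("receptor", "receptor symbol", "receptor gene symbol"))
    if lig_col is None or rec_col is None:
        raise PairFormatError(
            f"{path}: could not identify ligand and receptor columns in {cols}"
        )

    if dialect == "two_column_user":
        loc_col = ev_col = src_col = None
    elif dialect == "connectomedb":
        loc_col = _find_column(cols, ("ligand location", "location"))
        ev_col = _find_column(cols, ("pubmed", "evidence", "pmid"))
        src_col = _find_column(cols, ("source",))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    excl_col = _find_column(cols, ("excluded", "exclusion reason"))

    merged: dict[tuple[str, str], LigandReceptorPair] = {}
    n_rows = 0
    n_dups = 0
    n_excluded = 0
    for _, row in df.iterrows():
        lig = str(row[lig_col]).strip()
        rec = str(row[rec_col]).strip()
        if not lig or not rec or lig.lower() == "nan" or rec.lower() == "nan":
            continue
        n_rows += 1
        if excl_col is not None:
            flag = str(row[excl_col]).strip()
            if flag and flag.lower() not in ("nan", "no", "false", "0", ""):
                n_excluded += 1
                continue
        loc = _parse_location(row[loc_col]) if loc_col else LigandLocation.BOTH
        evidence: tuple[str, ...] = ()
        if ev_col is not None:
            raw_ev = str(row[ev_col]).strip()
            if raw_ev and raw_ev.lower() != "nan":
                evidence = tuple(
                    e.strip() for e in raw_ev.replace(",", ";").split(";") if e.strip()
                )
        source = ""
        if src_col is not None:
            raw_src = str(row[src_col]).strip()
            if raw_src and raw_src.lower() != "nan":
                source = raw_src
        pair = LigandReceptorPair(lig, rec, loc, evidence, source)
        if pair.key in merged:
            n_dups += 1
            prev = merged[pair.key]
            ev_union = tuple(dict.fromkeys(prev.evidence_ids + pair.evidence_ids))
            merged[pair.key] = replace(prev, evidence_ids=ev_union)
        else:
            merged[pair.key] = pair

    if not merged:
        raise PairFormatError(f"{path}: no usable pair rows")
    if n_dups:
        logger.warning("%s: merged %d duplicated pair rows", path, n_dups)
    logger.info(
        "%s: parsed %d rows -> %d pairs (%d excluded, %d duplicates merged)",
        path, n_rows, len(merged), n_excluded, n_dups,
    )
    return PairDatabase(list(merged.values()), species_taxon=species_taxon)


def write_pair_database(db: PairDatabase, path: str | Path) -> None:
    """Serialise in the connectomedb dialect (tab-delimited)."""
    db.to_frame().to_csv(path, sep="\t", index=False)


def filter_by_location(db: PairDatabase, wanted: str | LigandLocation) -> PairDatabase:
    """Pairs whose ligand is ``wanted`` or ``both``.

    A 'both' ligand exists in secreted and membrane-bound forms, so it
    participates in either analysis.
    """
    wanted = LigandLocation(wanted)
    if wanted is LigandLocation.BOTH:
        raise ValueError("filter by 'secreted' or 'plasma_membrane'; 'both' is not a filter")
    kept = [
        p
        for p in db.pairs
        if p.ligand_location in (wanted, LigandLocation.BOTH)
    ]
    return PairDatabase(kept, species_taxon=db.species_taxon)


def map_orthologs(
    db: PairDatabase,
    target_taxon: str,
    table: HomologyTable,
    source_taxon: str = HUMAN_TAXON,
) -> PairDatabase:
    """Project a pair database into another species via ortholog groups.

    Each pair expands to every (ortholog-ligand x ortholog-receptor)
    combination in the target taxon; one-to-many orthologs therefore yield
    multiple projected pairs. Pairs with no ortholog for either partner are
    dropped and counted. Location and provenance carry over.
    """
    target_taxon = str(target_taxon)
    if target_taxon not in table.taxa():
        raise ValueError(f"taxon {target_taxon} absent from homology table")

    projected: dict[tuple[str, str], LigandReceptorPair] = {}
    n_dropped = 0
    for p in db.pairs:
        lig_groups = table.groups_for(source_taxon, p.ligand_symbol)
        rec_groups = table.groups_for(source_taxon, p.receptor_symbol)
        lig_orthos = table.symbols_in(target_taxon, lig_groups)
        rec_orthos = table.symbols_in(target_taxon, rec_groups)
        if not lig_orthos or not rec_orthos:
            n_dropped += 1
            continue
        for lo in lig_orthos:
            for ro in rec_orthos:
                new = LigandReceptorPair(
                    lo, ro, p.ligand_location, p.evidence_ids, p.source_tag
                )
                projected.setdefault(new.key, new)
    logger.info(
        "ortholog projection %s->%s: %d/%d pairs dropped (no ortholog)",
        source_taxon, target_taxon, n_dropped, len(db),
    )
    return PairDatabase(list(projected.values()), species_taxon=target_taxon)


def randomise_pairs(db: PairDatabase, n: int, seed: int) -> list[PairDatabase]:
    """Degree-preserving null databases: permute the receptor assignment.

    Each of the ``n`` returned databases keeps the multiset of ligand symbols
    and the multiset of receptor symbols, permuting which receptor each
    ligand is paired with uniformly at random. Randomised databases may
    recreate real pairs (that is allowed); permutations that would duplicate
    a (ligand, receptor) tuple -- possible when symbols repeat across pairs --
    are rejected and redrawn so every null database has exactly the input's
    pair count and degree multisets. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(db) < 2:
        raise ValueError("randomisation degenerate for <2 pairs")
    rng = np.random.default_rng(seed)
    lig_norm = [normalise_symbol(p.ligand_symbol) for p in db.pairs]
    rec_syms = [p.receptor_symbol for p in db.pairs]
    rec_norm = [normalise_symbol(r) for r in rec_syms]
    out: list[PairDatabase] = []
    for _ in range(n):
        for _attempt in range(10_000):
            perm = rng.permutation(len(db))
            keys = {(lig_norm[i], rec_norm[perm[i]]) for i in range(len(db))}
            if len(keys) == len(db):
                break
        else:  # pragma: no cover - requires pathological symbol repetition
            raise RuntimeError("could not draw a collision-free permutation")
        pairs = [
            LigandReceptorPair(
                p.ligand_symbol, rec_syms[perm[i]], p.ligand_location, (), "randomised"
            )
            for i, p in enumerate(db.pairs)
        ]
        out.append(PairDatabase(pairs, species_taxon=db.species_taxon))
    return out
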