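"""Organism-scale analyses of summary networks.

Three questions about the global structure of a communication network:

1. How much autocrine signalling potential does each cell type have -- what
   fraction of its expressed ligands have their cognate receptor expressed
   in the same cell type (and the reciprocal for receptors)?
2. Are autocrine / intra-organ / inter-organ summary edges more specific
   than expected? Each cell type's outgoing (or incoming) summary edges are
   ranked by weight (rank 1 = most specific, average ranks on ties), ranks
   are pooled by edge class, and the observed class means are compared with
   a degree-preserving null obtained by re-pairing ligands with receptors at
   random and rebuilding the network.
3. Do cell types cluster into communities by their communication profiles?
   Each type is represented by the concatenation of its outgoing row and
   incoming column of summary weights and clustered hierarchically
   (average linkage, correlation distance by default).

Note on rank direction: rank 1 is the highest weight, so "autocrine edges
rank higher" shows up as a numerically *smaller* mean rank. Ranks are pooled
raw across cell types (every type faces the same number of candidate
partners when built from one dataset); a warning is the caller's job if
edge-list lengths differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .edge_extraction import EdgeTable, extract_edges
from .expression_io import CellTypeProfile, FilterSettings
from .lr_database import PairDatabase, randomise_pairs
from .summary_network import SummaryNetwork, summed_weight_network

logger = logging.getLogger("cellcomm")

EDGE_CLASSES = ("autocrine", "intra_organ", "inter_organ")


@dataclass
class OrganMap:
    """Total mapping cell-type label -> organ label."""

    mapping: dict[str, str]

    def organ_of(self, cell_type: str) -> str:
        return self.mapping[cell_type]

    def validate_over(self, cell_types: list[str]) -> None:
        missing = set(cell_types) - set(self.mapping)
        if missing:
            raise ValueError(f"organ map missing cell types: {sorted(missing)}")


def load_organ_map(path) -> OrganMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: organ map needs two columns (cell type, organ)")
    return OrganMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def autocrine_fractions(edges: EdgeTable) -> pd.DataFrame:
    """Per cell type: fraction of its ligands with a same-type cognate receptor.

    A ligand counts as expressed by type T when T sends any edge using it;
    it counts as autocrine when some edge T -> T uses it. The receptor
    fraction is the mirror image. A type expressing no ligands (or no
    receptors) gets NaN for that fraction. Also reports the across-type
    means in a ``__mean__`` row.
    """
    e = edges.edges
    types = edges.cell_types
    rows = {}
    for t in types:
        ligands = set(e.loc[e["sender"] == t, "ligand"])
        receptors = set(e.loc[e["receiver"] == t, "receptor"])
        auto = e.loc[(e["sender"] == t) & (e["receiver"] == t)]
        auto_ligands = set(auto["ligand"])
        auto_receptors = set(auto["receptor"])
        lig_frac = len(auto_ligands) / len(ligands) if ligands else float("nan")
        rec_frac = len(auto_receptors) / len(receptors) if receptors else float("nan")
        rows[t] = {
            "n_ligands": len(ligands),
            "n_receptors": len(receptors),
            "ligand_fraction": lig_frac,
            "receptor_fraction": rec_frac,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    means = out[["ligand_fraction", "receptor_fraction"]].mean()
    out.loc["__mean__"] = {
        "n_ligands": np.nan,
        "n_receptors": np.nan,
        "ligand_fraction": means["ligand_fraction"],
        "receptor_fraction": means["receptor_fraction"],
    }
    return out


def classify_summary_edges(net: SummaryNetwork, organs: OrganMap) -> pd.DataFrame:
    """Class label per (sender, receiver): autocrine / intra_organ / inter_organ."""
    organs.validate_over(net.cell_types)
    types = net.cell_types
    labels = pd.DataFrame("", index=pd.Index(types), columns=pd.Index(types), dtype=object)
    for s in types:
        for r in types:
            if s == r:
                labels.loc[s, r] = "autocrine"
            elif organs.organ_of(s) == organs.organ_of(r):
                labels.loc[s, r] = "intra_organ"
            else:
                labels.loc[s, r] = "inter_organ"
    return labels


@dataclass
class RankDistribution:
    """Mean/sd/n of within-type edge ranks, pooled by edge class."""

    table: pd.DataFrame  # index: class, columns: mean_rank, sd, n
    direction: str
    scheme: str

    def mean_rank(self, edge_class: str) -> float:
        return float(self.table.loc[edge_class, "mean_rank"])


def _pooled_ranks(
    net: SummaryNetwork, labels: pd.DataFrame, direction: str
) -> dict[str, list[float]]:
    if direction not in ("outgoing", "incoming"):
        raise ValueError(f"direction must be 'outgoing' or 'incoming', got {direction!r}")
    pooled: dict[str, list[float]] = {c: [] for c in EDGE_CLASSES}
    for t in net.cell_types:
        if direction == "outgoing":
            weights = net.adjacency.loc[t]
            classes = labels.loc[t]
        else:
            weights = net.adjacency[t]
            classes = labels[t]
        # rank 1 = largest weight; ties share the average rank
        ranks = rankdata(-weights.to_numpy(dtype=float), method="average")
        for rank, cls in zip(ranks, classes):
            pooled[cls].append(float(rank))
    return pooled


def rank_distributions(
    net: SummaryNetwork, organs: OrganMap, direction: str = "outgoing"
) -> RankDistribution:
    """Rank each type's summary edges, pool ranks by class, summarise.

    Outgoing ranks a sender's row across receivers; incoming ranks a
    receiver's column across senders. All |types| candidate partners enter
    the ranking (zero-weight edges tie at the bottom).
    """
    labels = classify_summary_edges(net, organs)
    pooled = _pooled_ranks(net, labels, direction)
    rows = {}
    for cls in EDGE_CLASSES:
        arr = np.asarray(pooled[cls], dtype=float)
        rows[cls] = {
            "mean_rank": arr.mean() if arr.size else float("nan"),
            "sd": arr.std(ddof=0) if arr.size else float("nan"),
            "n": int(arr.size),
        }
    return RankDistribution(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        direction=direction,
        scheme=net.scheme,
    )


def permutation_rank_null(
    profile: CellTypeProfile,
    db: PairDatabase,
    organs: OrganMap,
    n_perm: int = 100,
    seed: int = 0,
    direction: str = "outgoing",
    settings: FilterSettings | None = None,
    scheme: str = "summed_specificity",
) -> pd.DataFrame:
    """Null distribution of class mean ranks under randomised ligand-receptor pairing.

    For each of ``n_perm`` degree-preserving randomisations of the pair
    database, edges are re-extracted, the summary network rebuilt, and the
    per-class mean ranks recomputed. Returns one row per class with the mean
    and sd of the per-permutation class mean ranks, plus ``n_perm``.
    Deterministic given ``seed``.
    """
    settings = settings or FilterSettings()
    null_dbs = randomise_pairs(db, n_perm, seed)
    per_perm: dict[str, list[float]] = {c: [] for c in EDGE_CLASSES}
    for null_db in null_dbs:
        edges = extract_edges(profile, null_db, settings)
        net = summed_weight_network(edges, scheme, cell_types=profile.cell_types)
        dist = rank_distributions(net, organs, direction)
        for cls in EDGE_CLASSES:
            per_perm[cls].append(dist.mean_rank(cls))
    rows = {}
    for cls in EDGE_CLASSES:
        arr = np.asarray(per_perm[cls], dtype=float)
        valid = arr[~np.isnan(arr)]
        rows[cls] = {
            "null_mean_rank": valid.mean() if valid.size else float("nan"),
            "null_sd": valid.std(ddof=1) if valid.size > 1 else float("nan"),
            "n_perm": int(valid.size),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cluster_cell_types(
    net: SummaryNetwork, metric: str = "correlation", method: str = "average"
) -> dict:
    """Hierarchical clustering of cell types by their communication vectors.

    Each type's feature vector is its outgoing row concatenated with its
    incoming column. Returns the scipy linkage matrix, the deterministic
    leaf order, and the feature matrix. Types with constant feature vectors
    make correlation distance undefined; a tiny jitter-free fallback maps
    those distances to the maximum (2.0).
    """
    types = net.cell_types
    if len(types) < 3:
        raise ValueError("clustering needs at least 3 cell types")
    features = np.hstack(
        [net.adjacency.to_numpy(dtype=float), net.adjacency.to_numpy(dtype=float).T]
    )
    dists = pdist(features, metric=metric)
    if metric == "correlation":
        dists = np.nan_to_num(dists, nan=2.0)
    link = linkage(dists, method=method)
    order = [types[i] for i in leaves_list(link)]
    return {"linkage": link, "leaf_order": order, "features": pd.DataFrame(features, index=types)}


def cut_clusters(link: np.ndarray, cell_types: list[str], k: int) -> dict[str, int]:
    """Flat cluster memberships from a linkage at ``k`` clusters."""
    from scipy.cluster.hierarchy import fcluster

    assignments = fcluster(link, t=k, criterion="maxclust")
    return dict(zip(cell_types, (int(a) for a in assignments)))
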