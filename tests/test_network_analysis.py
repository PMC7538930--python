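"""Autocrine fractions, edge-class rank distributions, permutation null, clustering."""

import numpy as np
import pandas as pd
import pytest

from cellcomm import (
    FilterSettings,
    FixtureConfig,
    OrganMap,
    SummaryNetwork,
    autocrine_fractions,
    classify_summary_edges,
    cluster_cell_types,
    cut_clusters,
    extract_edges,
    generate_fixture,
    normalise_cpm,
    permutation_rank_null,
    rank_distributions,
    summarise_by_cell_type,
    summed_weight_network,
)

from conftest import make_annotation, make_db, make_matrix


def _summary(entries, types, scheme="summed_specificity"):
    adj = pd.DataFrame(0.0, index=types, columns=types)
    for (s, r), w in entries.items():
        adj.loc[s, r] = w
    return SummaryNetwork(adjacency=adj, scheme=scheme)


@pytest.fixture(scope="module")
def autocrine_fixture():
    """Three planted exclusive autocrine loops plus background pairs."""
    cfg = FixtureConfig(
        n_cell_types=6, cells_per_type=40, n_genes=120, n_pairs=18, seed=42,
        dropout_rate=0.35,
        planted_edges=[
            ("CT01", "LIG001", "REC001", "CT01", 12.0),
            ("CT02", "LIG002", "REC002", "CT02", 12.0),
            ("CT03", "LIG003", "REC003", "CT03", 12.0),
        ],
    )
    m, ann, db, organs, manifest = generate_fixture(cfg)
    profile = summarise_by_cell_type(normalise_cpm(m), ann, db.gene_universe())
    return profile, db, organs


@pytest.fixture(scope="module")
def structureless_fixture():
    """No planted edges: ligand and receptor expression are independent."""
    cfg = FixtureConfig(
        n_cell_types=6, cells_per_type=40, n_genes=120, n_pairs=18, seed=43,
        dropout_rate=0.35,
    )
    m, ann, db, organs, manifest = generate_fixture(cfg)
    profile = summarise_by_cell_type(normalise_cpm(m), ann, db.gene_universe())
    return profile, db, organs


class TestAutocrineFractions:
    def test_half_of_ligands_have_same_type_receptor(self):
        # T expresses L1, L2, R1; U expresses R2. Pairs (L1,R1), (L2,R2).
        cells = ["t1", "t2", "u1", "u2"]
        m = make_matrix(
            {
                "L1": [5, 5, 0, 0], "L2": [5, 5, 0, 0],
                "R1": [5, 5, 0, 0], "R2": [0, 0, 5, 5],
            },
            cells=cells,
        )
        ann = make_annotation({"T": ["t1", "t2"], "U": ["u1", "u2"]})
        db = make_db([("L1", "R1"), ("L2", "R2")])
        prof = summarise_by_cell_type(m, ann, db.gene_universe())
        table = extract_edges(prof, db, FilterSettings())
        out = autocrine_fractions(table)
        assert out.loc["T", "ligand_fraction"] == pytest.approx(0.5)

    def test_no_cognate_partner_gives_zero(self):
        cells = ["t1", "t2", "u1", "u2"]
        m = make_matrix(
            {"L1": [5, 5, 0, 0], "R1": [0, 0, 5, 5]}, cells=cells
        )
        ann = make_annotation({"T": ["t1", "t2"], "U": ["u1", "u2"]})
        db = make_db([("L1", "R1")])
        prof = summarise_by_cell_type(m, ann, db.gene_universe())
        out = autocrine_fractions(extract_edges(prof, db, FilterSettings()))
        assert out.loc["T", "ligand_fraction"] == 0.0
        assert out.loc["U", "receptor_fraction"] == 0.0

    def test_matches_set_intersection_oracle(self, structureless_fixture):
        profile, db, _ = structureless_fixture
        table = extract_edges(profile, db, FilterSettings())
        out = autocrine_fractions(table)
        e = table.edges
        for t in table.cell_types:
            ligands = set(e.loc[e["sender"] == t, "ligand"])
            auto = set(e.loc[(e["sender"] == t) & (e["receiver"] == t), "ligand"])
            if ligands:
                assert out.loc[t, "ligand_fraction"] == pytest.approx(len(auto & ligands) / len(ligands))

    def test_fractions_within_unit_interval_and_mean_row_present(self, structureless_fixture):
        profile, db, _ = structureless_fixture
        out = autocrine_fractions(extract_edges(profile, db, FilterSettings()))
        vals = out[["ligand_fraction", "receptor_fraction"]].dropna()
        assert ((vals >= 0) & (vals <= 1)).all().all()
        assert "__mean__" in out.index

    def test_invariant_to_edge_row_order(self, structureless_fixture):
        from cellcomm import EdgeTable

        profile, db, _ = structureless_fixture
        table = extract_edges(profile, db, FilterSettings())
        shuffled = EdgeTable(
            edges=table.edges.sample(frac=1.0, random_state=9).reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            autocrine_fractions(table), autocrine_fractions(shuffled)
        )


class TestClassification:
    def test_three_way_classification(self):
        net = _summary({}, ["A", "B", "C"])
        organs = OrganMap({"A": "org1", "B": "org1", "C": "org2"})
        labels = classify_summary_edges(net, organs)
        assert labels.loc["A", "A"] == "autocrine"
        assert labels.loc["A", "B"] == "intra_organ"
        assert labels.loc["A", "C"] == "inter_organ"

    def test_partial_organ_map_is_error(self):
        net = _summary({}, ["A", "B"])
        with pytest.raises(ValueError):
            classify_summary_edges(net, OrganMap({"A": "org1"}))


class TestRankDistributions:
    def test_autocrine_row_maximum_gives_mean_rank_one(self):
        types = ["A", "B", "C"]
        entries = {}
        for s in types:
            for r in types:
                entries[(s, r)] = 9.0 if s == r else 1.0
        net = _summary(entries, types)
        organs = OrganMap({t: "org1" for t in types})
        dist = rank_distributions(net, organs, "outgoing")
        assert dist.mean_rank("autocrine") == pytest.approx(1.0)

    def test_all_equal_weights_share_average_rank(self):
        types = ["A", "B", "C", "D"]
        net = _summary({(s, r): 2.0 for s in types for r in types}, types)
        organs = OrganMap({"A": "o1", "B": "o1", "C": "o2", "D": "o2"})
        dist = rank_distributions(net, organs, "outgoing")
        expected = (len(types) + 1) / 2
        for cls in ("autocrine", "intra_organ", "inter_organ"):
            assert dist.mean_rank(cls) == pytest.approx(expected)

    def test_matches_brute_force_sort_oracle(self):
        from oracles import oracle_ranks

        rng = np.random.default_rng(8)
        types = [f"T{i}" for i in range(8)]
        net = _summary(
            {(s, r): float(rng.integers(0, 6)) for s in types for r in types}, types
        )
        organs = OrganMap({t: f"o{i // 3}" for i, t in enumerate(types)})
        labels = classify_summary_edges(net, organs)
        for direction in ("outgoing", "incoming"):
            if direction == "outgoing":
                rows = [[float(net.adjacency.loc[s, r]) for r in types] for s in types]
                cls_rows = [[labels.loc[s, r] for r in types] for s in types]
            else:
                rows = [[float(net.adjacency.loc[s, r]) for s in types] for r in types]
                cls_rows = [[labels.loc[s, r] for s in types] for r in types]
            expected = oracle_ranks(rows, cls_rows)
            dist = rank_distributions(net, organs, direction)
            for cls, (mean, n) in expected.items():
                assert dist.mean_rank(cls) == pytest.approx(mean)
                assert dist.table.loc[cls, "n"] == n

    def test_class_ranks_partition_each_row(self):
        rng = np.random.default_rng(12)
        types = [f"T{i}" for i in range(6)]
        net = _summary({(s, r): rng.random() for s in types for r in types}, types)
        organs = OrganMap({t: f"o{i // 2}" for i, t in enumerate(types)})
        dist = rank_distributions(net, organs, "outgoing")
        total_n = int(dist.table["n"].sum())
        assert total_n == len(types) ** 2
        # with distinct weights, pooled rank sum per type is n(n+1)/2
        pooled_sum = float((dist.table["mean_rank"] * dist.table["n"]).sum())
        assert pooled_sum == pytest.approx(len(types) * len(types) * (len(types) + 1) / 2)


class TestPermutationNull:
    def test_planted_autocrine_beats_null(self, autocrine_fixture):
        profile, db, organs = autocrine_fixture
        table = extract_edges(profile, db, FilterSettings())
        net = summed_weight_network(table, "summed_specificity", cell_types=profile.cell_types)
        observed = rank_distributions(net, organs, "outgoing").mean_rank("autocrine")
        null = permutation_rank_null(profile, db, organs, n_perm=30, seed=5)
        assert observed < null.loc["autocrine", "null_mean_rank"]

    def test_structureless_fixture_matches_null(self, structureless_fixture):
        profile, db, organs = structureless_fixture
        table = extract_edges(profile, db, FilterSettings())
        net = summed_weight_network(table, "summed_specificity", cell_types=profile.cell_types)
        observed = rank_distributions(net, organs, "outgoing").mean_rank("autocrine")
        null = permutation_rank_null(profile, db, organs, n_perm=30, seed=6)
        gap = abs(observed - null.loc["autocrine", "null_mean_rank"])
        assert gap <= 4 * null.loc["autocrine", "null_sd"] + 1e-9

    def test_reproducible_given_seed(self, structureless_fixture):
        profile, db, organs = structureless_fixture
        a = permutation_rank_null(profile, db, organs, n_perm=2, seed=9)
        b = permutation_rank_null(profile, db, organs, n_perm=2, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestClustering:
    def test_identical_profiles_merge_first(self):
        types = ["A", "B", "C"]
        entries = {
            ("A", "C"): 5.0, ("B", "C"): 5.0,
            ("C", "A"): 1.0, ("C", "B"): 1.0, ("C", "C"): 3.0,
        }
        net = _summary(entries, types)
        out = cluster_cell_types(net)
        # A and B have identical rows and columns: first merge joins leaves 0 and 1
        first = out["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_block_structure_recovered_at_k2(self):
        rng = np.random.default_rng(21)
        types = [f"T{i}" for i in range(6)]
        entries = {}
        for i, s in enumerate(types):
            for j, r in enumerate(types):
                same_block = (i < 3) == (j < 3)
                entries[(s, r)] = (5.0 if same_block else 0.2) + rng.normal(0, 0.05)
        adj = pd.DataFrame(0.0, index=types, columns=types)
        for (s, r), w in entries.items():
            adj.loc[s, r] = max(w, 0.0)
        net = SummaryNetwork(adjacency=adj, scheme="summed_specificity")
        out = cluster_cell_types(net)
        clusters = cut_clusters(out["linkage"], types, 2)
        assert len({clusters[t] for t in types[:3]}) == 1
        assert len({clusters[t] for t in types[3:]}) == 1
        assert clusters[types[0]] != clusters[types[3]]

    def test_membership_invariant_to_type_order(self):
        rng = np.random.default_rng(22)
        types = [f"T{i}" for i in range(5)]
        adj = pd.DataFrame(rng.random((5, 5)), index=types, columns=types)
        net = SummaryNetwork(adjacency=adj, scheme="summed_specificity")
        out1 = cluster_cell_types(net)
        perm = types[::-1]
        net2 = SummaryNetwork(adjacency=adj.loc[perm, perm], scheme="summed_specificity")
        out2 = cluster_cell_types(net2)
        c1 = cut_clusters(out1["linkage"], net.cell_types, 2)
        c2 = cut_clusters(out2["linkage"], net2.cell_types, 2)
        partition1 = frozenset(frozenset(t for t in types if c1[t] == k) for k in set(c1.values()))
        partition2 = frozenset(frozenset(t for t in types if c2[t] == k) for k in set(c2.values()))
        assert partition1 == partition2

    def test_too_few_types_is_error(self):
        net = _summary({("A", "B"): 1.0}, ["A", "B"])
        with pytest.raises(ValueError):
            cluster_cell_types(net)
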