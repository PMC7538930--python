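"""Independent brute-force re-implementations used as test oracles.

Everything here recomputes quantities from the raw matrix and annotation with
plain Python loops, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math


def oracle_profile(matrix_df, ann_map, genes):
    """{(gene, type): (mean, total, detection)} from per-cell values."""
    types = sorted(set(ann_map.values()))
    cells_of = {t: [c for c, lab in ann_map.items() if lab == t] for t in types}
    out = {}
    matrix_genes = {g.upper(): g for g in matrix_df.index}
    for gene in genes:
        row = matrix_genes.get(gene.upper())
        for t in types:
            if row is None:
                out[(gene, t)] = (0.0, 0.0, 0.0)
                continue
            vals = [float(matrix_df.loc[row, c]) for c in cells_of[t]]
            mean = sum(vals) / len(vals)
            total = sum(vals)
            det = sum(1 for v in vals if v > 0) / len(vals)
            out[(gene, t)] = (mean, total, det)
    return out, types


def oracle_edges(matrix_df, ann_map, pairs, det_thr=0.20, expr_thr=0.0, strict=False):
    """{key: (mean_w, spec_w, total_w)} by exhaustive enumeration."""
    genes = sorted({g for p in pairs for g in p})
    prof, types = oracle_profile(matrix_df, ann_map, genes)

    def passes(gene, t):
        mean, _total, det = prof[(gene, t)]
        det_ok = det > det_thr if strict else det >= det_thr
        return det_ok and mean >= expr_thr

    def spec(gene, t):
        denom = sum(prof[(gene, u)][0] for u in types)
        if denom <= 0:
            return 0.0
        return prof[(gene, t)][0] / denom

    edges = {}
    for lig, rec in pairs:
        for s in types:
            if not passes(lig, s):
                continue
            for r in types:
                if not passes(rec, r):
                    continue
                mean_w = prof[(lig, s)][0] * prof[(rec, r)][0]
                spec_w = spec(lig, s) * spec(rec, r)
                total_w = prof[(lig, s)][1] * prof[(rec, r)][1]
                edges[(s, lig, rec, r)] = (mean_w, spec_w, total_w)
    return edges


def oracle_edge_count(edges, spec_thr=0.0):
    """{(sender, receiver): count} over edges surviving the specificity threshold."""
    counts = {}
    for (s, _lig, _rec, r), (_m, spec_w, _t) in edges.items():
        if spec_w >= spec_thr:
            counts[(s, r)] = counts.get((s, r), 0) + 1
    return counts


def oracle_summed(edges, which):
    """{(sender, receiver): sum of weights}; which in {'spec', 'mean'}."""
    idx = 1 if which == "spec" else 0
    sums = {}
    for (s, _lig, _rec, r), w in edges.items():
        sums[(s, r)] = sums.get((s, r), 0.0) + w[idx]
    return sums


def oracle_match(ref_keys, target_keys):
    ref_keys, target_keys = set(ref_keys), set(target_keys)
    return ref_keys & target_keys, ref_keys - target_keys, target_keys - ref_keys


def oracle_codetection(matrix_df, ann_map, pairs, expr_thr, codetect_fraction):
    """{(type, lig, rec): fraction} for pairs meeting the reporting threshold."""
    types = sorted(set(ann_map.values()))
    cells_of = {t: [c for c, lab in ann_map.items() if lab == t] for t in types}
    matrix_genes = {g.upper(): g for g in matrix_df.index}
    out = {}
    for t in types:
        for lig, rec in pairs:
            lrow, rrow = matrix_genes.get(lig.upper()), matrix_genes.get(rec.upper())
            if lrow is None or rrow is None:
                continue
            n_both = sum(
                1
                for c in cells_of[t]
                if matrix_df.loc[lrow, c] > expr_thr and matrix_df.loc[rrow, c] > expr_thr
            )
            frac = n_both / len(cells_of[t])
            if frac >= codetect_fraction:
                out[(t, lig, rec)] = frac
    return out


def oracle_union_find(edge_list):
    """Connected components by union-find over undirected node pairs."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for e in edge_list:
        union(e[0], e[1])
    comps = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return sorted(comps.values(), key=lambda c: (-len(c), min(c)))


def oracle_ranks(adjacency_rows, classes_rows):
    """Pooled per-class average ranks; adjacency_rows is a list of weight lists.

    rank 1 = largest; ties get the average of the positions they span.
    """
    pooled = {}
    for weights, classes in zip(adjacency_rows, classes_rows):
        order = sorted(range(len(weights)), key=lambda i: -weights[i])
        ranks = [0.0] * len(weights)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and math.isclose(
                weights[order[j + 1]], weights[order[i]], rel_tol=0, abs_tol=0
            ) and weights[order[j + 1]] == weights[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        for r, cls in zip(ranks, classes):
            pooled.setdefault(cls, []).append(r)
    return {
        cls: (sum(v) / len(v), len(v)) for cls, v in pooled.items()
    }
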