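# Methods

## Model and assumptions

`cellcomm` infers potential, not verified, communication: an edge asserts
only that a sender cell type expresses a ligand whose cognate receptor is
expressed by a receiver cell type, at mRNA level. The method assumes the
input clustering/annotation is trustworthy, that mRNA abundance is an
acceptable proxy for functional protein, and that pairs act independently —
heteromeric ligand or receptor complexes, co-receptor requirements and
binding kinetics are out of scope. Specificity weights are dataset-local:
they are normalised over the cell types present in the analysed matrix, so
the same pair can score differently in datasets with different cell-type
compositions.

## Quantities

For gene *g* and cell type *c* with *n_c* cells:

- `mean_g(c)` — mean expression over the type's cells (CPM unless the user
  supplies pre-normalised data);
- `sum_g(c) = mean_g(c) · n_c` — total expression;
- `det_g(c)` — fraction of cells with value strictly > 0.

Edge weights for pair (L, R) from sender *s* to receiver *r*:

- mean-expression weight: `mean_L(s) · mean_R(r)`;
- specificity weight:
  `[mean_L(s) / Σ_c mean_L(c)] · [mean_R(r) / Σ_c mean_R(c)]`;
- total-expression weight: `sum_L(s) · sum_R(r)`.

The specificity denominators run over **all** cell types in the dataset,
including types failing the detection filter — filtering decides which edges
are emitted, not what specificity means. A gene with zero mean everywhere
gets specificity 0 rather than NaN; such pairs never pass filters anyway and
the convention stops NaN propagation.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| `detection_threshold` | fraction of cells | 0.20 | common single-cell convention for "expressed" |
| `expression_threshold` | expression units (CPM) | 0 | off by default; a floor of ~10 CPM filters weak ligands/receptors |
| `specificity_threshold` | dimensionless [0,1] | 0 | hard filter for the edge-count summary only |
| co-detection `expr_threshold` | CPM | 10 | per-cell "expressed" needs a stronger criterion than nonzero |
| co-detection `codetect_fraction` | fraction of cells | 0.20 | mirrors the detection convention at single-cell level |

Boundary conventions: the detection comparison is inclusive (`det ≥ 0.20`
passes at exactly 20%); a `strict_detection` flag switches to `>` since
usage in the field varies and the difference is observable exactly at the
boundary. The mean-expression filter is inclusive (`mean ≥ threshold`);
per-cell co-detection is strict (`value > threshold`), consistent with
"detected" meaning strictly nonzero at threshold 0. Genes present in the
pair database but absent from the matrix are treated as unexpressed
(mean 0, detection 0), not as errors: cross-species projections and
targeted panels routinely lack genes. CPM normalisation divides by each
cell's total over **all** matrix genes, because library size is a
whole-transcriptome property.

## Database handling

Symbols are compared case-insensitively after trimming (human symbols are
uppercase, mouse capitalised); original casing is preserved in outputs.
Duplicate (ligand, receptor) rows merge with evidence unioned — merged
multi-source tables legitimately repeat pairs. Rows flagged as excluded in a
curated-layout file are parsed but never enter the database. A
"both"-location ligand participates in both the secreted and the
plasma-membrane analysis, since the annotation means the ligand exists in
both forms.

Ortholog projection expands one-to-many homology groups to **all**
(ligand-ortholog × receptor-ortholog) combinations rather than picking a
canonical hit: expansion is lossless and downstream thresholds remove
noise. Pairs with no ortholog for either partner are dropped and counted.

## Randomised-pair null

The null for rank enrichment permutes the receptor assignment over the
existing pair list, preserving the ligand and receptor degree multisets —
the conservative choice when only "randomly re-paired" is specified.
Permutations that would collide on an existing (ligand, receptor) key (possible
when symbols repeat across pairs) are rejected and redrawn, so every null
database has exactly the input's pair count; recreating a real pair is
allowed. For each null database the edges and the summed-specificity
network are rebuilt from scratch and the class mean ranks recomputed.

Rank conventions: within each cell type's outgoing row (or incoming
column), rank 1 is the highest weight, so enrichment of a class appears as
a numerically smaller mean rank; ties receive average ranks; all candidate
partners enter the ranking, with absent edges tied at zero weight. Ranks
are pooled raw (not percentile-normalised) across cell types — every type
faces the same number of candidate partners when built from one dataset.

## Delta networks

Edge identity between conditions is the (sender, ligand, receptor,
receiver) key only; weights do not enter identity, matching the
presence/absence meaning of "detected in both conditions". Both conditions
must share a cell-type label set (the comparison is meaningless otherwise,
and the mismatch error says to relabel).

Log2 fold changes substitute a floor ε for zero weights —
ε = half the smallest positive weight in either network — rather than
adding a pseudocount to every entry: substitution leaves ratios of two
positive weights exact (8 vs 2 is exactly −2) while keeping exclusive
entries finite and conspicuous; exclusive edges are additionally listed
separately. Entries zero in both conditions get fold change 0. An entry is
flagged `up_in_ref`/`up_in_target` at a twofold-or-more ratio. Per-gene
fold changes use the same zero-floor idea with ε = 0.001 expression units.

## Clustering

Cell types are represented by the concatenation of their outgoing row and
incoming column of summary weights and clustered with average linkage on
correlation distance (both exposed as options; the choice is conventional,
not prescribed). Constant feature vectors make correlation undefined; those
distances map to the maximum (2.0). Fewer than 3 cell types is an error.

## Synthetic fixtures

The generator emulates the features the pipeline is sensitive to: sparse
non-negative integer counts with cell-type structure (negative-binomial
with log-normal gene means around `baseline_mean` = 5 counts, dispersion
0.5, independent dropout at rate 0.3 — chosen as typical moderate-depth
single-cell sparsity), controllable detection fractions, and planted
signals. A planted edge makes its ligand and receptor exclusive to the
sender and receiver respectively at `effect_size ×` baseline expression
with detection forced to ≥ 90% of cells, pinning the edge's specificity at
exactly 1; a planted co-detection forces both genes above threshold in an
exact fraction of a type's cells. Cells left with zero totals (possible at
extreme dropout) receive a single count in one background gene so CPM
normalisation stays defined.

What the generator does **not** emulate: gene–gene correlation beyond the
plants, batch effects, ambient RNA, doublets, UMI saturation, or realistic
mean–variance relationships per cell type. Passing tests therefore
demonstrate algorithmic correctness (filters, weights, matching, ranking)
under controlled conditions, not robustness to real-data artefacts.

Default problem sizes in the test and acceptance workloads — 5–6 cell
types, 25–40 cells per type, 100–200 genes, 16–30 pairs, 20 fixture seeds,
100 permutations for the null — are small enough to enumerate exhaustively
with the brute-force oracles while leaving every code path exercised.

## Numerical choices and degenerate inputs

Weights are computed and stored in double precision; serialisation rounds
to 6 significant digits. Top-k ranking breaks ties lexicographically by
(sender, receiver) for determinism. Duplicate gene rows on load collapse by
sum (logged); negative values and ragged rows are rejected; an all-zero
cell is an error naming the cell at CPM time. Empty databases or profiles
are errors at edge extraction; an edge table that is empty after filtering
is valid and yields zero matrices.

## Known limitations

- Autocrine-fraction denominators are derived from the edge table, so a
  ligand whose receptor is expressed nowhere in the dataset does not enter
  the denominator; with a comprehensive pair database the effect is
  negligible, but on tiny gene panels the fractions can be optimistic.
- The permutation null re-extracts edges per permutation, which is exact
  but O(n_perm × pairs × types²); organism-scale atlases may want the
  profile cached (it already is) and fewer permutations while exploring.
- No statistical significance is attached to delta networks; without
  replicates a fold-change flag is descriptive, not inferential.
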