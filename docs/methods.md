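# Methods

This note documents the models, the parameters that matter, the synthetic
data the tests run on, and the numerical choices — the things a maintainer
or a careful user would want spelled out.

## Term distance and its normalization

The distance between two ontology terms is the minimum, over their common
ancestors, of the summed child-to-parent edge counts from each term up to
that ancestor, divided by the ontology-wide maximum `d_max`. Two points are
deliberate:

* **Routes go through common ancestors only.** A generic undirected
  shortest path could shortcut through a shared *descendant*; semantically
  that is a different statement (two specific phenotypes are not similar
  because some syndrome exhibits both), so it is excluded.
* **Each leg uses the shortest climb.** In a DAG a term can reach an
  ancestor along several parent chains; the minimum governs both legs.

`d_max` has two modes. `exact` maximizes the common-ancestor-path distance
over all pairs — quadratic, intended for test-sized ontologies, and the
mode every oracle test uses. `depth_bound` returns twice the maximum root
depth, an upper bound (each leg of any route climbs at most `depth` edges),
cheap enough for real HPO/GO; it is the default for loaded ontologies. The
mode is recorded in all serialized outputs, because absolute score values
are only comparable under the same normalization.

Edge policies: terms from disjoint components (multi-root OBO files) have
no common ancestor and get distance 1.0, preserving the [0, 1] codomain; a
single-term ontology has `d_max = 0` and the division is guarded; `alt_id`
accessions resolve to their canonical term; obsolete terms are dropped at
load and rejected in queries with a dedicated error rather than "unknown
id". Only *is a* edges are read; other relationship types in an OBO file
are ignored.

## Disease distances

The weighted phenotype distance is the symmetrized best-match average with
the matched pair's weights multiplied onto each term's contribution. The
formula binds the second weight to "the term attaining the minimum"; when
two candidate terms are exactly equidistant the tie is broken toward the
**larger** weight, so the weighting reflects the most clinically typical
match. This rule is deterministic and covered by a dedicated test.

Two properties are worth knowing. First, with all weights equal to 1 the
phenotype distance collapses to the plain unweighted two-way best-match
average — the same shape as the gene-side disease distance; the suite
asserts this identity on fixtures. Second, the weighted distance is **not a
metric**: small weights deflate distances, so a disease annotated with the
same terms at near-zero frequency sits "close" to everything and triangle
inequality fails. A test pins one violating example so the behavior
stays documented. Diseases whose every phenotype is weight-0 ("excluded"-only
annotations) would be distance-0 to everything; they are flagged and left
out of map construction by default.

On the gene side, the per-aspect distance between two genes' GO term sets
is the minimum cross-pair term distance (best match); an aspect missing on
either gene contributes the maximal value 1.0 to the three-aspect mean —
dropping the aspect silently would make distances incomparable across gene
pairs.

## Frequency weights

Orphanet-style frequency classes are mapped to the midpoint of each printed
band: Obligate 1.0, Very frequent 0.895, Frequent 0.545, Occasional 0.17,
Very rare 0.02, Excluded 0.0. Midpoints are the least-assumption numeric
reading of a categorical vocabulary; the table is an argument everywhere it
is consumed, and literal numeric fractions in input files pass through
unchanged, so users can probe how sensitive scores are to the mapping.

## Map construction

Classical (Torgerson) scaling: square the distances, double-center,
eigendecompose, scale the top eigenvectors by the square roots of their
eigenvalues. The disease distances are not Euclidean, so negative
eigenvalues are expected; they are clamped to zero and their relative mass
(`Σ|λ⁻| / Σ|λ|`) is reported as a map-quality diagnostic — on the synthetic
fixtures it sits around 0.02–0.05, i.e. the 2-D picture is faithful. Axis
signs are fixed (largest-magnitude coordinate positive per axis) so runs
are bit-reproducible; the embedding is otherwise defined up to rotation and
reflection, which is why tests compare recovered *distances*, never raw
coordinates.

Clustering runs k-means on the 2-D coordinates (matching the idea of
dividing the drawn map into regions). k is selected by bootstrap stability:
for each candidate k, B resamples (default 20) are re-clustered and each
original cluster's stability is the mean of its best Jaccard overlap with
the bootstrap clusters, computed on the unique resampled points. The
selected k is the largest candidate whose *least stable* cluster reaches
the threshold; if none does, the k with the highest mean stability is
returned and flagged as a fallback.

The stability threshold defaults to **0.85**. This sits at the conventional
"highly stable" mark for bootstrap Jaccard stability, and with a
largest-passing-k rule it cannot be much lower: an arbitrary k-means split
of homogeneous data already bootstraps at roughly 0.6–0.75, so a 0.6 bar
would wave through every over-segmentation. On planted three-cluster data
the correct k=3 solution scores a minimum stability of 1.00 while k=4..6
splits score 0.54–0.93; 0.85 separates these regimes. The threshold, B, the
k range and the number of k-means restarts are all configurable, and every
selection run returns the full (k, cluster, stability) table so the choice
can be audited.

## Search and ranking

The default search score is the **one-way** best-match average from query
to disease: each query term finds its closest disease term and the
distances are averaged over the query. One-way is the right default for
clinical use because queries are partial — a query that is a subset of the
disease's annotation scores exactly 0, whereas the symmetric score
penalizes the disease's unmatched annotation (a test pins this asymmetry).
The symmetric variant (`similarity_avg`, the disease distance with the
query as a unit-weight pseudo-disease) and the Jaccard term-overlap
baseline (reported as distance 1−J) are available under the same interface.

Disease-term frequency weights multiply the matched term's contribution in
interactive search by default, consistent with the disease-distance
convention; a flag disables this. The in silico benchmark *defaults to
unweighted* scoring: low-frequency-weighted diseases score near zero
against any query, and with weighting on, the method comparison measures
that deflation artifact instead of semantic robustness. Both behaviors are
implemented and flagged.

Ranks are tie-aware: 1 plus the number of strictly smaller scores, so a
target tied with others but beaten by none is rank 1. Result lists are
sorted by (score, disease id); the default 100-hit cap never splits a tie
group.

## Evaluation protocols

**Imprecise-phenotype benchmark.** Each target disease is represented by
its `terms_per_query` (default 4) highest-weight phenotypes, ties broken by
term id. At imprecision level L, a uniformly chosen subset of L query terms
is each replaced by a uniformly chosen *graph-adjacent* term — a parent or
child in the DAG, never the original term. Targets are sampled uniformly
among diseases with enough phenotypes, under a fixed seed. Because the
performance metric behind this kind of curve is ambiguous, the report emits
the rank-1 fraction, the top-10 fraction and the mean rank per level and
method; the suite asserts the method *ordering* (semantic ≥ term-matching
at every level ≥ 1, and term-matching degrading from level 0 to 4), not
absolute curve values. One adjacency subtlety: replacing a term by a child
moves its distance to any fixed target by at most one edge, but replacing
it by a parent can move it further on multi-parent DAGs (the parent may
lack the close common ancestor another parent provided); the property tests
assert exactly the bounds that hold.

**Case ranking.** A case is an HPO term list plus a diagnosed target
disease referenced by an external id (OMIM); targets resolve through the
knowledge base's cross-references. The harness reports each case's
tie-aware rank and score next to any reference columns in the case table,
plus mean/median/worst rank and mean ± sd score; unresolvable targets are
counted and excluded from summaries, never fatal. The packaged 20-case
table of published case reports carries the originally reported ranks and
scores for side-by-side comparison; reproducing those numbers requires the
2019-era HPO + Orphanet snapshot they were computed against, which cannot
be redistributed here.

## Synthetic data

The generator builds everything the loaders read, deterministically from a
seed, and returns a manifest holding the complete ground truth. Generated
ontologies grow as a single root with a few top-level branches ("sectors");
extra parents stay within a term's sector, loosely mimicking how ontology
cross-links concentrate within organ systems. Defaults — a 200-term
phenotype DAG, 120-term GO aspect DAGs, 60 diseases with 8 phenotype terms,
depth ≤ 8 — keep the full suite in seconds while leaving the DAGs deep
enough for non-trivial distances.

Planted clusters are a testing device: each cluster samples its diseases'
terms from one tight ball of one sector (the 2·`terms_per_disease` terms
nearest a cluster anchor in the path metric, with the tightest of several
candidate anchors kept), so within-cluster distances are small while
between-cluster routes must climb to the root. Two deliberate choices keep
the planted signal clean, and both say something about the method itself:
the ball is twice the per-disease draw because smaller pools make diseases
share entire annotation subsets — identical points that read as extra,
perfectly stable clusters — and planted diseases use a high-frequency
weight ladder (Obligate/Very frequent/Frequent at 0.4/0.4/0.2) because
"very rare" weights deflate the weighted distance toward zero and collect
those diseases into a spurious central blob. Unclustered fixtures keep the
full six-class ladder.

What the generator does **not** emulate: real HPO term-frequency and
annotation-size distributions, Orphanet prevalence marginals, the
correlation between phenotype and gene annotations of the same disease,
and ontology cross-links between distant branches. Passing tests therefore
demonstrate correctness of the computations and the qualitative behavior
of the methods under controlled conditions — not clinical performance on
real Orphanet data.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
oracle equivalence on 20 random DAGs of up to 50 terms and on 20-disease
knowledge bases (all-pairs, against independent brute-force
implementations kept free of package code); map recovery on 60 diseases in
3 planted clusters; the imprecision benchmark on 60 diseases × 5 levels ×
10 replicate seeds. Every stochastic step — generation, k-means,
bootstrap, query degradation — derives its seed from one master seed, and
reports record the seeds they ran under, so any number in any output can
be regenerated exactly.

## Known limitations

* Absolute similarity scores depend on `d_max`, and the published scores'
  normalization mode is unknowable; compare scores only within one
  configuration.
* The weighted disease distance is not a metric (by design, documented
  above); algorithms that assume metricity should use the unweighted
  variant.
* `exact` d_max is quadratic in ontology size; real HPO/GO runs use the
  `depth_bound` bound, which can only shrink normalized distances relative
  to `exact`.
* Cluster counts on real data depend on the snapshot and on the stability
  parameters; the published 17/18-cluster figures are not an assertable
  target and are not asserted.
* The all-pairs distance matrix is dense O(n²); at the few-thousand-disease
  scale this is desk-size, far beyond it this implementation is the wrong
  tool.
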