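# Methods

This note documents the models and procedures implemented in `fminer`,
the parameter choices that matter, and what the synthetic data generator
does and does not emulate.

## Standardization

Term matching is **exact after normalization**: trim, collapse internal
whitespace, full-width → half-width conversion (via NFKC), and case
folding for Latin text; CJK characters are compared as-is. No fuzzy or
edit-distance matching is attempted — approximate matches on herb
nomenclature are a curation decision, not one an algorithm should make
silently, and exact matching keeps every mapping auditable. Terms without
a lookup entry abort cleaning unless the caller opts into dropping them;
drops are logged with counts, and `make_lookup` produces the unmatched
report a curator works through.

Within a record, duplicate entries (two occurrences of the same herb or
symptom) collapse to one: prescriptions are modeled as sets. Formulas
left empty after cleaning are dropped by default (logged), since an empty
transaction carries no information for any downstream statistic.

Wide-matrix columns are ordered by descending total frequency with
alphabetical tie-break, making every exported matrix byte-reproducible.

## Attribute statistics

"Weighted" counts weight each herb by its occurrence count across
formulas; "unweighted" counts each distinct herb once. Occurrence count
(not dose) is the weight because doses are frequently absent from
prescription collections, and occurrence weighting is the only definition
under which both variants are well-defined on every dataset. Multi-valued
attributes (flavors, meridians) contribute to each category they carry,
so flavor/meridian counts sum to more than the number of herbs; nature is
single-valued and its unweighted column sums to the number of distinct
herbs with a known nature.

## Association rules

Mining is level-wise Apriori with prefix-join candidate generation and
downward-closure pruning. `max_len` defaults to 5 items per rule —
herbal transaction data are dense (10–20 items per transaction is
common), and unbounded itemset growth is exponential; 5 covers the core
combinations practitioners look for. Consequents are single items by
default (the convention of classic rule miners); multi-item consequents
are available by flag.

The lift filter is **strict** (lift > 1): a rule at exactly lift 1 shows
no positive association. Rule order is fixed (lift desc, support desc,
lexicographic) for reproducibility.

`explore_rules` evaluates every (min_support, min_confidence) pair of the
requested grid. Internally the rule set is mined once at the smallest
thresholds and filtered per cell — any rule satisfying a stricter cell
also satisfies the loosest one, so the per-cell results are identical to
independent mining, at a fraction of the cost. Cells whose rule set is
empty have undefined range statistics; they are dropped from the filtered
table (the companion full grid retains them for bubble-chart exports).

## Phi correlation

For binary columns the phi coefficient equals the Pearson correlation,
and the chi-square statistic with 1 df equals n·phi². P-values use that
identity **without** continuity correction (the identity only holds
without it); a Yates-corrected variant is available by flag. Zero-variance
columns (an item in every formula or none) have undefined phi; they are
reported as phi 0 with p 1 and flagged, rather than propagating NaN into
matrix exports. Stars mark p < 0.05 per cell. No multiple-testing
correction is applied — with hundreds of herb pairs the starred matrix is
exploratory, not confirmatory; treat stars as a screening aid.

## Hierarchical clustering

Items are clustered on their occurrence patterns across formulas, with
either binary Jaccard distance or 1 − phi. The agglomeration engine
implements the Lance–Williams recurrence with the seven classical
coefficient sets. Conventions follow R's `hclust`: `ward.D` applies
Ward's update to the dissimilarities as given; `ward.D2` squares them
first and reports square-rooted heights; `centroid` and `median` apply
the recurrence to the input as given (they are exact for squared
Euclidean input and heuristic otherwise, and may produce height
inversions). Ties are broken by merging the lexicographically smallest
eligible index pair, so results are deterministic. The test suite checks
all seven linkages against R's `hclust` on random matrices to 1e-10.

### Cluster-number voting

`k_selection` cuts one dendrogram (ward.D2 by default) at every k in the
requested range and lets a panel of internal validity indices vote; the
winner is the modal recommendation with ties broken toward the smallest k
(parsimony). The panel has 11 indices, all computable from the distance
matrix alone: silhouette, Calinski–Harabasz (distance-based pseudo-F),
Davies–Bouldin (medoid-based), Dunn, C-index, McClain–Rao, point-biserial,
Baker–Hubert gamma, G+, within-SS elbow (largest second difference), and
Xie–Beni (medoid-based). Indices that require the original feature
vectors (e.g. Ratkowsky–Lance) are excluded by design, since the input
contract is a dissimilarity matrix; centroid-based definitions are
evaluated at medoids for the same reason. An index that fails on every
candidate partition (degenerate geometry, e.g. coincident medoids) is
excluded from the tally with a warning, and the tally always sums to the
number of indices that voted.

## Formula similarity

`calc_jaccard`'s pair table keeps pairs with J **≥** threshold;
`similarity_network` edges require J **strictly >** threshold. The
asymmetry is deliberate: the pair table is a report (inclusive), the
network filter expresses "more similar than the cutoff". Degree
centrality is normalized by (n_nodes − 1) over the retained nodes, so it
lies in [0, 1]. A node's `frequency` attribute counts how many formulas
in the dataset share its exact composition. Isolated formulas are
excluded from the network.

Role weights for `wt_similarity` default to Monarch 4, Minister 3,
Assistant 2, Envoy 1, unassigned 1 — a simple strictly decreasing ranking
of the classical role hierarchy; the scheme is fully configurable and the
weighted-Jaccard functional form is this package's own definition. With
all weights equal it reduces exactly to the Jaccard coefficient (tested).
Dosage-aware similarity is out of scope.

## Synthetic data generator

`simulate` emulates the structure of clinical prescription corpora:

* **Zipf background** (exponent 1.0 by default): herb usage in real
  collections is heavy-tailed — a few harmonizing herbs appear in most
  formulas. Background herbs are drawn without replacement with
  probability proportional to 1/rank.
* **Planted motifs**: fixed herb combinations included wholesale with a
  per-formula probability — the "core combination" that association-rule
  and network analyses are supposed to recover.
* **Noise**: `synonym_noise_rate` replaces a standardized name with a
  variant from the packaged lookup (so cleaning can provably undo it);
  `duplicate_entry_rate` repeats entries within a record, emulating
  transcription duplicates.
* Formula sizes are uniform on a configurable range (default 8–15,
  typical of decoction prescriptions); defaults are 2000 formulas over an
  80-herb vocabulary.

Ground truth (true ingredient sets, motif placements, variant map) is
always returned; tests assert against it rather than re-deriving it.

What the generator does **not** emulate: correlated syndrome/symptom
structure, dose distributions beyond uniform placeholders, free-text or
OCR noise, and herb-herb dependencies beyond the planted motifs. Passing
tests therefore demonstrate correctness of the statistics and recovery of
planted combinatorial structure, not robustness to every artifact of real
clinical records.

The packaged fixtures (60 herbs with attributes, ~140 synonym pairs, 15
classical formulas) are a small synthetic stand-in for a curated
pharmacopoeia-derived reference; they emulate its shape, not its content.
The first 60 simulated-vocabulary herbs are fixture herbs (so simulated
data cleans against the packaged lookup); larger vocabularies are padded
with synthetic `HerbNNN` names that have no lookup entries.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems chosen to make exhaustive oracles feasible: brute-force rule
enumeration is limited to ≤ 10 items and ≤ 30 transactions per set (full
subset enumeration is exponential), linkage checks use ≤ 8-item
matrices, and the end-to-end simulation uses 2000 formulas over the
60-herb fixture vocabulary. The algorithms themselves have no such
limits; the rule-grid exploration mines once at the loosest thresholds,
so grids over large datasets cost one Apriori pass.

## Known limitations

* Exact-match standardization will not catch misspellings; the unmatched
  report is the intended workflow for those.
* Phi p-values are asymptotic; for very sparse herbs Fisher's exact test
  would be preferable (not implemented — the chi-square form preserves
  the n·phi² identity used throughout the field).
* `centroid`/`median` linkage on non-Euclidean dissimilarities is a
  heuristic (as in R) and can produce dendrogram inversions.
* The k-vote is only as good as its indices; on data without block
  structure the vote is typically scattered and should be read together
  with the dendrograms, not instead of them.
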