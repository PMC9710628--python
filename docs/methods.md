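# Methods

## Event model and identity

A reading-table row is one *extraction*: regulator entity, regulated entity,
interaction sign, source paper, evidence sentence. Rows are grouped into
distinct events keyed by (regulator key, regulated key, sign). The
interaction subtype (phosphorylation vs. transcription vs. amount change) is
not part of identity: every downstream computation uses only signed
influence structure, and folding subtypes keeps the occurrence count
`f_i` consistent with the graph semantics. Entity keys prefer the database
identifier when the reader grounded the entity (names vary across readers
and papers); otherwise the case-folded, whitespace-collapsed name. The same
rule is applied to model elements so overlap and evaluation compare like
with like. Activity- vs. amount-level events are likewise collapsed to sign
only.

`f_i` counts rows (occurrences), while the paper set of an event is a set:
two sentences in one paper raise `f_i` by two but contribute one paper to
every co-occurrence count. Co-occurrence is strictly per-paper.

The event set is assumed pre-filtered to candidate extensions. Events that
coincide with an existing model edge are flagged in the parse report but not
removed; deciding whether they corroborate or contradict the model is out of
scope.

## Scoring

Frequency class of an event: `FC_ia = floor(0.5 - log2(f_i / f_max))`, with
`f_max` the maximum occurrence count. Class 0 = most frequent; each class
doubles the rarity. The implementation computes the ratio in floating point;
at the class boundaries the ratio is an exact power of two and therefore
exactly representable, so the floor is exact (the tests verify against an
all-integer oracle). Pair frequency class applies the same algebra to the
shared-paper count with `f_max_pair`. The inverse-frequency pair weight is
`IF_pa = f_ij * (ln(N/f_i) + ln(N/f_j))` with `N` the total occurrence
count; it grows with co-occurrence and with the rarity of the pair's
members.

Filtering removes events with `FC_ia` above a threshold. The default
("auto") threshold is the unweighted mean of `FC_ia` over distinct events,
rounded half-up to an integer; the averaging population and rounding are our
choice, made once. An optional second rule keeps only neighbors of class-0
events (off by default — it is an additional criterion, not part of the core
procedure), and isolated survivors are retained by default since they can
still carry model-support signal as singleton clusters. Pair metrics are
recomputed on the filtered graph: `f_max_pair` can shrink when edges
disappear, and the pair classes are defined relative to the graph in force.
`N`, `f_max` and the node classes are properties of the event set, not of
the graph, and are not recomputed.

## Clustering

Louvain with modularity
`Q = (1/2m) Σ_{u,v} [w_uv − σ_u σ_v/(2m)] δ(c_u, c_v)` over ordered node
pairs. Implementation choices, all in service of determinism and testability:

- Node sweep order is the sorted node list shuffled by `node_order_seed`
  (default 0); repeated runs are identical.
- Equal-gain ties go to the lowest community label.
- A move must improve Q by more than 1e−12 to count; this prevents
  float-noise oscillation.
- Contraction stores intra-community weight as a self-loop contributing
  twice to the super-node degree, preserving Q across levels.
- Connected components never mix (no positive gain across components);
  labels are renumbered contiguously by each community's smallest member.
- The move gain is computed incrementally and equals the full modularity
  difference for first-phase moves; the test suite asserts this equality on
  random graphs and checks the final Q against exhaustive partition search
  on small fixtures.

Edge weights default to `IF_pa`. Clustering on `FC_pa` poses a semantic
trap: low class means strong support, but modularity rewards heavy edges, so
the weight used is `fc_pa_max − fc_pa + 1`. This inversion is our design
choice and is recorded in the partition object.

Cluster literature scores are arithmetic means of `FC_pa` and `IF_pa` over
intra-cluster edges (`P_l` of them). Edgeless clusters have undefined means
and can qualify for selection only through model support.

## Selection and extension

Interpreted clusters map events back to directed signed entity edges. Node
overlap `NO` is the percentage of cluster entities already in the model.
Return paths are enumerated by depth-first search over the union of all
interpreted-cluster edges, started at model nodes, emitting a path at every
model node reached; edges are traversed head-to-tail (regulator →
regulated), interior nodes may be model or new nodes, and only cluster edges
participate — baseline edges do not shortcut a path. The search is bounded
at 6 edges by default (simple-path enumeration is exponential; observed
extension paths are well within this) with a 10,000-path cap.

The selection rule: a cluster is chosen if (mean `FC_pa` is the global
minimum AND mean `IF_pa` is the global maximum — ties all qualify) OR
(`NO` > 50 AND the cluster lies on ≥ 1 return path). The min/max are taken
over all clusters with defined means, with no size floor. When a return path
touches both a selected and an unselected cluster, the unselected one is
merged in (to fixpoint); this is what stitches an upstream-regulator cluster
to a downstream-target cluster into one coherent extension. An optional
element-of-interest mode pre-selects pairs of clusters that regulate and are
regulated by a named entity when a return path connects them.

Extension appends each merged event to the model: unknown entities become
new elements named with an `_ext` suffix (registered under the entity's
canonical key, database id carried over), and the regulator is appended to
the target's positive or negative influence expression with the OR
separator. Influence expressions of existing elements are otherwise
preserved verbatim — the procedure extends structure, not update-function
logic, so a '!'-negated regulator inside a positive expression stays where
it was written. Extension is idempotent and never removes baseline content.

## Evaluation

Precision is computed over selected events (entities) that are not already
baseline content; recall's denominator is gold events (entities) present in
the extracted event set and absent from the baseline — content the method
could possibly have found. The entity rule mirrors the event rule. Sign is
part of event identity in matching; a sign-agnostic mode exists because
reader polarity is sometimes unreliable. When nothing was recoverable the
recall is vacuously 1.0 if anything was selected (nothing was missed) and
0.0 for an empty selection.

## Synthetic data

The generator emulates the shape of real extracted event sets: communities
of events co-occurring in a small pool of papers. Defaults — 3 communities,
15 events each, 5 papers each, cross-community occurrence rate 0.02,
per-event frequency uniform on [1, 6] — give a desk-scale set of ~45 events
and ~150 occurrences whose community structure is strong but not trivial
(the rarest events appear in a single paper). Entity labels are synthetic,
optionally mixed with baseline-model element names (`model_overlap_fraction`)
so node overlap and return paths are exercised.

Model pairs: the gold model is a random directed signed graph (20 nodes, 40
edges, ring backbone for weak connectivity); the baseline is derived by one
of three truncation schemes — removing all in-edges of randomly chosen key
players, breaking directed paths between node pairs via minimum edge cuts,
or deleting random edges. The end-to-end benchmark plants the removed edges
as the generated event set's community 0 at the top of the frequency law, so
the recoverable content is the best literature-supported community — the
regime the selection rule is designed for.

Not emulated: reader mis-grounding, synonymous entity labels, erroneous
events, or subtype ambiguity. Green tests on these fixtures certify the
pipeline machinery (grouping, scoring, clustering, selection, bookkeeping),
not robustness to reader noise.

## Problem sizes and numerical notes

Test and benchmark sizes (≤ 50 events, ≤ 10-node graphs for exhaustive
partition search, 200 random event sets for formula cross-checks) were
chosen so every oracle is exact and enumeration is feasible; they are small
by design. Degenerate inputs: an empty event set refuses to build a graph;
filtering that would empty the graph raises rather than returning nothing;
an edgeless graph clusters into singletons with a warning; modularity is
undefined (error) at zero total weight.

## Known limitations

- Canonical keys do not merge synonyms that share neither id nor folded
  name; near-duplicate events remain distinct nodes.
- The literature disjunct selects global double-winners only; in event sets
  where no cluster wins both rankings, selection rests entirely on model
  support.
- Return-path enumeration is exhaustive up to the length bound; on very
  dense interpreted clusters the path cap may truncate the listing (the
  selected-cluster set is insensitive to the cap in all tested regimes).
- Update-function logic (AND/OR nesting) for newly added regulators is not
  inferred; new regulators join the influence set as plain OR terms.
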