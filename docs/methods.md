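# Methods

## Model and conventions

All metrics operate on a simple directed graph: no self-loops, no parallel
edges.  The loader drops self-loops (logged) and collapses duplicate ordered
pairs keeping the last weight/timestamp, because every definition in the
package assumes their absence; node identifiers are opaque strings with no
contiguity assumption.  Comment lines starting with `#` or `%` are skipped,
covering the common public edge-list dialects.

**Bidirectional decomposition.**  A reciprocated edge is treated as two
unidirectional edges wherever triads or triangles are counted: an open triad
containing one bidirectional edge counts as two unidirectional triads, a
triangle with two bidirectional edges as four unidirectional triangles, and
so on.  The package enforces this uniformly by counting *instances*: a
triangle instance is one choice of a single directed edge in each of its
three node-pair slots, and a triangle with bidirectional edges is classified
per instance, never as a composite.  This makes all identities exact in
integer arithmetic:

- t_src + t_tgt = 2 t_d (each instance is seen from two end-node views);
- t_head + t_mid + t_end + t_cyc = t_d (each instance has exactly one
  pattern);
- OTE^{oo} + OTE^{oi} + OTE^{io} + OTE^{ii} = OTE^D;
- 2·OTC^D = d(d−1) − 2·d_bi.

**Undefined values.**  A coefficient with a zero denominator is undefined.
It is represented as `None` at node level (CSV writes `NA`), and mapped to
zero only inside averages — the averaging convention used for every
network-level mean in the package.  This also settles the network-summary
question of whether undefined nodes are excluded: they are not; they
contribute zeros.

**Average degree** is |E|/|V| (edges per node), not 2|E|/|V|; this is the
convention the summary statistics and signature tables use throughout.

## Numerators and denominators

The fast path (`netclosure/_counts.py`) computes, per node, all integer
counts from the node's neighbourhood and its neighbours' degrees — O(k²)
with k the node degree, hence O(|V|·k̄²) across a network — and the public
coefficient functions perform a single division at the end.  No floating
accumulation happens inside a coefficient, so fast-path values equal the
brute-force oracle ratios bit-for-bit; the test suite asserts equality of
the integer counts themselves on hundreds of random digraphs.

Two definitional choices deserve a note:

- **Source/target denominators.**  The source and target closure
  coefficients both divide by OTE^D(i) computed from the *neighbours'*
  degrees d_j, the same denominator as the directed closure coefficient.
  This is required for the identity E^src + E^tgt = 2 E^D, which the suite
  checks exactly; a variant using the focal node's own degree would break
  it.
- **Pattern denominators.**  The four closure-pattern denominators are sums
  of two of the four end-node open-triad type counts (e.g. e_head uses
  OTE^{oo} + OTE^{oi}: triads whose first edge leaves i, whichever way the
  second edge points, are the ones a head-pattern triangle can close).  The
  four clustering-pattern denominators are d_out(d_out−1) for head,
  d_in(d_in−1) for end and d_in·d_out − d_bi for the two mixed patterns.
  Oracle equivalence is the arbiter for all of them.

## Weighted and signed closure

Weights are normalised to [−1, 1] by the maximum absolute weight; the metric
functions refuse unnormalised input rather than silently producing
out-of-range values, and `normalize_weights` is idempotent.  Zero-weight
edges are dropped at construction (indistinguishable from absence in every
formula).  The closing edge is implicitly assigned the maximum weight 1, so
the denominator is a strength-based capacity.

On signed graphs the strength is s_i = Σ|w_i·| + Σ|w_·i|, and the
denominator factors (w_ij + w_ji) are likewise taken in magnitude,
|w_ij| + |w_ji|.  The numerator keeps raw signs.  This is the minimal
completion that keeps the denominator a positive capacity and the
coefficient inside [−1, 1]; with it, negating every weight negates every
defined coefficient exactly (the numerator is odd in the weights, the
denominator even), which the suite asserts.  With 0/1 weights both weighted
definitions reduce exactly to the binary ones.

## Link-prediction protocol

Edges are split 50/50: by timestamp when available (ties broken by input
order, a stable sort), uniformly at random otherwise, with random splits
repeated 10 times.  The old graph's nodes V* define the candidate set; the
positives are future edges with both endpoints in V*.  Candidates are all
ordered non-self pairs over V* not already present as old edges — self-pairs
are excluded even though the |V*|²−|E_old| accounting would retain them,
since a simple digraph cannot realise them and they only pad negatives.
Undefined E^src/E^tgt on the old graph contribute zero to CCI/ECCI.  DiAA
uses the natural logarithm (the convention of the original Adamic–Adar
index); every common neighbour u has |N(u)| ≥ 2, so the term is finite.

PR-AUC is non-interpolated average precision computed directly from the
descending-score ranking with stable tie order; it matches
scikit-learn's `average_precision_score` on tie-free scores (asserted).
On networks above 10,000 nodes, 3,000 connected nodes (degree ≥ 1 in the
old graph) are sampled per repeat and candidates restricted to pairs among
them.

## Classification harness

Network signatures feed a leave-one-out cross-validated classifier:
decision tree, random forest or gradient-boosted trees at library default
hyperparameters (none are tuned — the harness specifies the contract, not a
model search).  Because tree fits are stochastic, accuracy is averaged over
repeated seeded runs; feature importances are normalised impurity decreases,
averaged the same way, and a degenerate fit with no splits is assigned
uniform importances so scores always sum to one.  Every class must have at
least two members or LOOCV is refused.

## Synthetic data

The random model is directed G(n, p) with independent ordered-pair Bernoulli
edges — the setting of the E[E^D(i)] = p expectation, with reciprocity
arising only by chance.  Unsigned weights are uniform on (0, 1], signed
weights uniform on [−1, 1] excluding 0.  Motif fixtures provide the
feed-forward triangle, the 3-cycle, a bidirectional triad, all eight
labelled triangle direction patterns and all four end-node open-triad types.
What G(n, p) does *not* emulate: heavy-tailed degrees, degree–closure
correlation, community structure, and the systematic excess of transitive
over cyclic triangles seen in real food webs and trust networks.  Passing
tests on it therefore validate the *algebra* (identities, reductions,
oracle agreement, expectation) rather than any empirical claim about real
networks; real-network checks live in the dataset-gated acceptance tests.

## Problem sizes and numerical choices

The oracle is O(n²) per node by design (clarity over speed) and is exercised
on digraphs up to n = 40; the property suite covers 200 seeded graphs at
p ∈ {0.05, 0.2, 0.5}.  The expectation check uses G(300, p) with a
three-standard-error band estimated from the node sample.  Global
closure-vs-clustering equivalence is asserted to 1e−12 (pure float
round-off; the integer totals are identical).  All randomness — generators,
splits, classifier seeds — flows from explicit integer seeds via
`numpy.random.SeedSequence`, so every reported number is reproducible.

## Known limitations

- Weighted versions of the four patterns and of the source/target split are
  not defined (the weighted theory covers E^W and E^{W,D} only).
- The undirected weighted closure coefficient expects an undirected graph
  stored either symmetrically or with one orientation per edge; conflicting
  asymmetric weights are read from whichever orientation is present first.
- Exact reproduction of published per-dataset values can be sensitive to
  preprocessing (duplicate-edge and self-loop handling) that the original
  sources do not fully specify.
- The evaluation protocol scores all |V*|² − |E_old| candidate pairs;
  beyond ~10⁴ nodes use the built-in node sampling.
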