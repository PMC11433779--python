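# Methods

## The task and the cross-join reduction

Given a metabolite's structure (an MDL molfile) and a pathway defined as a
set of member metabolites, the package predicts the binary association
1{metabolite ∈ pathway}. All |M| metabolites are paired with all |P|
pathways, giving |M|·|P| entries; the entry feature row is the metabolite
feature block concatenated with the pathway feature block (metabolite
first — an arbitrary but fixed order recorded in the run manifest). The
reduction turns a many-pathway multi-label problem into one binary problem
with enough positives to train a single model, and accommodates new
pathways without retraining heads. Pathways come from a two-level
hierarchy: L2 categories and L3 individual pathways, every L3 belonging to
exactly one L2; L2 membership is the union of child-L3 memberships.

## Atom-color featurization

Molfiles (V2000) are parsed with a fixed-column parser; explicit hydrogens
are stripped and atoms re-indexed densely. Each remaining atom gets one
canonical color per radius r ∈ {0, 1, 2, 3}:

* r = 0: the element symbol, e.g. `C`;
* r ≥ 1: `element "(" sorted, comma-joined {order digit + neighbor's
  radius-(r−1) color} ")"`, e.g. the middle carbon of C–C–O is `C(1C,1O)`.

Sorting makes colors invariant to atom input order; because a radius-r
color embeds each neighbor's radius-(r−1) color (whose element prefix is
recoverable), colors refine monotonically — distinct color counts never
decrease with radius. Bond order (molfile codes 1–3, 4 = aromatic) is
encoded in the color because "neighborhood" without bond type would discard
information. The same textual key at different radii is a different
feature: the radius is the grouping key of the entry-wise normalization.
Counts at each radius sum to the number of non-hydrogen atoms.
Disconnected structures are colored per fragment and kept whole; charges
are parsed but do not enter colors; stereochemistry and implicit hydrogens
are ignored. Any injective canonicalization yields an equivalent feature
space, so feature *counts* from other implementations of neighborhood
coloring need not match ours.

## Feature matrices and normalization

Metabolite vectors are assembled over the union vocabulary (columns sorted
by (radius, key)); pathway vectors are element-wise sums of raw member
count vectors, assembled over their own separate vocabulary. Each row is
normalized entry-wise: features grouped by radius, each group divided by
its group sum (zero groups stay zero). The operation the field calls
"softmax by bond count" is this group-sum division, not an exponential
softmax; an exponential variant is available behind
`normalization.exponential` for comparison only. After normalization,
all-zero columns and exact duplicate columns are dropped (first column of
each duplicate group kept, provenance recorded). Dedup must follow
normalization: dropping columns first would change the radius-group sums.
With few rows the pathway matrix has many coinciding columns, which is why
pathway feature counts come out well below metabolite feature counts.
Optional feature-wise min–max scaling maps each column to [0, 1]
((x−min)/(max−min); constant columns → 0; out-of-fit values clipped). It
is fitted on the full assembled dataset by default; since every metabolite
row and every pathway row appears in the cross-join, this equals fitting
per block. A leakage-free `per_fold` variant refits on training entries
only inside each CV iteration.

## Model

A multi-layer perceptron: input width = metabolite width + pathway width,
`n_hidden_layers` (default 2) fully connected ReLU layers of `hidden_size`
(default 64), one sigmoid output, binary cross-entropy minimized by Adam
(learning rate 1e-3) in mini-batches (256). The backend is scikit-learn's
`MLPClassifier`, giving deterministic single-threaded training from a seed.
Scores ≥ `classification_threshold` (default 0.5, tunable) classify as 1 —
equality counts as positive, a fixed documented tie rule. Early stopping
(on a 5% validation slice) is available via `early_stop_patience` but off
by default: at desk scale the slice holds only a few dozen entries and
halts training long before convergence. A random-search tuner scores
sampled configs by MCC on one held-out stratified fold.

## Evaluation protocol

Repeated stratified 10-fold cross-validation: iteration i shuffles with
seed = base_seed + i, and only fold 0 of each iteration is consumed as the
10% test set (a jackknife-style hold-out). Stratification is on the binary
label alone — per-(pathway, label) strata would fail for 3-member pathways
against 10 folds. Per iteration we record entry-level accuracy, precision,
recall, F1 and MCC over the whole test fold, plus one TP/FP/TN/FN cell per
pathway (zero cell when a pathway drew no test entries, so cells per run =
iterations × pathways exactly). Two aggregations are kept strictly
separate: per-iteration metrics support a mean ± SD; per-pathway (and
per-level) *overall MCC* sums the cells across iterations first and
computes a single MCC from the summed matrix — small pathways rarely admit
a valid per-iteration MCC, and no SD exists for the summed statistic.
Degenerate MCC (any zero marginal) is 0 by convention. Iteration reports
are checkpointed as JSON, so interrupted runs resume at iteration
granularity.

Size analyses: pathway size is measured both as member count and as summed
non-hydrogen atoms over members. The correlation table reports Spearman on
raw sizes and Pearson on log10 sizes against overall MCC (constant input →
coefficient 0, p 1 by convention rather than NaN). The *evaluation*
size-threshold curve re-sums the already-computed cells of pathways at or
above each threshold — no retraining; threshold 0 reproduces the
all-pathway overall MCC exactly. The *training* filter experiment rebuilds
the dataset at thresholds (default 3, 5, 7, 10, 12, 20, 50, 100), retrains,
and scores only the N largest pathways (default 33, ranked by member count,
ties broken by pathway id) so thresholds are comparable.

## Synthetic universes

The generator emulates the statistical shape of a curated metabolic
knowledgebase: 2 L2 categories × 3 L3 pathways each by default; L3 sizes
`3 + floor(lognormal(μ=3.0, σ=0.5))` (minimum 3 members, heavy right
tail, ≈150 molecules in total); molecules are random labeled trees of 8–24
non-hydrogen atoms over {C, N, O, S, P} with random bond orders (mostly
single); a metabolite joins a second pathway with probability 0.05. The
learnable signal is a pathway-specific 3-atom scaffold motif grafted onto
each member with probability `scaffold_signal`: because pathway vectors are
member sums, a shared motif couples the two feature blocks — the mechanism
that makes the cross-join design predictive at all. Valence is not
enforced; the featurization consumes arbitrary labeled graphs. What
passing tests on these fixtures show is that the pipeline's machinery and
the size/transfer phenomena behave as designed — not that real
knowledgebase-scale performance is reproduced; real molecules share far
more substructure, real vocabularies are ~20× larger, and real pathway
sizes span hundreds of members.

## Known limitation: membership leakage through pathway sums

Pathway features are sums over *all* members, computed before entries are
split into CV folds. A held-out (m, p) pair with m ∈ p therefore satisfies
"every color of m occurs in p's block", while non-member pairs almost never
do when molecules carry near-unique radius-3 colors — as random-tree
molecules do. On a fixture whose membership is assigned independently of
structure (`scaffold_signal=0`) this coverage statistic separates members
from non-members perfectly, and the trained MLP partially exploits it
(mean test MCC ≈ 0.5 instead of the ≈ 0 a leakage-free protocol would
give). This is a property of the evaluation design itself — pathway
vectors would have to be recomputed from training-fold members only to
remove it — and should be kept in mind when interpreting absolute MCCs
from any cross-join protocol of this form. The package keeps the faithful
design and documents the effect; the no-signal fixture quantifies it.

## Problem sizes and numerical choices

Desk-scale defaults (≈150 molecules, 8 pathways, ≈1,100 entries, 3 CV
iterations) evaluate in seconds on one CPU; the reference-scale arithmetic
(5,683 × 184 = 1,045,672 entries) runs through the same lazy cross-join,
which assembles feature rows batch-wise and never materializes the dense
grid. Group sums are checked to 1e-9; MCC uses exact integer arithmetic
under the square root; content hashes (SHA-256 over ids, labels and
feature values) verify end-to-end determinism of reruns.
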