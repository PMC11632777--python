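# Methods

## The AABBA representation

`aabbatools` featurizes an attributed molecular graph — nodes carry atomic
property vectors, edges carry bond property vectors, and at most one node is
flagged as the metal center — into a fixed-length vector of Moreau–Broto-style
autocorrelations. An autocorrelation at depth *d* is a sum over element pairs
at graph distance *d* of an arithmetic combination of their property values:

* **AA** (atom–atom): pairs of atoms at shortest-path distance *d*; the
  classical autocorrelation descriptor.
* **BB** (bond–bond): pairs of bonds at line-graph distance *d* (bonds sharing
  an atom are at distance 1).
* **BA** (bond–atom): (bond, atom) pairs at distance
  `min(d(u, j), d(v, j))` over the bond's endpoints `u, v`; an endpoint atom
  is at depth 0.

Four pair operators are supported: product (the default autocorrelation,
label code `A`), deltametric (difference, `D`), ratiometric (ratio, `R`) and
summetric (sum, `S`). Each runs from either the **full** origin (all elements)
or the **metal-centered** origin (only the metal atom, or, for bonds, the
**super-bond** obtained by merging all metal–ligand bond property vectors by
sum (`BB`) or mean (`BBm`)).

**AABBA(I)** concatenates AA, BB/BBm and BA blocks over a property catalog
into one labeled vector. **AABBA(II)** first merges each edge's endpoint
atomic properties with its bond properties into a per-edge "atom-bond" vector
(variants II1–II5 differ in the electronegativity/polarity and geometry
components) and autocorrelates those vectors exactly as BB; the implementation
makes that literal — AABBA(II) is computed by substituting the merged vectors
for the bond table and calling the BB kernel, and a strict equality test pins
the identity.

The **maximal-dimensionality vector** runs every kernel × origin × operator at
depths 0–6. For *a* atomic and *b* bond properties its length is
`4·7·(2a + 3b + 2ab)` with a metal and `4·7·(a + b + ab)` without; redundancy
removal then drops columns that are constant across the dataset or exact
duplicates (after rounding to 12 significant digits) of an earlier column.

## Conventions and numerical choices

* **Pair counting.** Full-origin sums count each unordered pair once, with the
  element earlier in the stored (file) order on the origin side, plus one
  self-term per element at depth 0. For the symmetric operators the canonical
  order is irrelevant; for deltametric/ratiometric it preserves information
  that double-counting would cancel to zero. Feature vectors are therefore
  invariant under relabeling that preserves the stored order, and under
  arbitrary relabeling for symmetric operators (tested both ways).
* **Metal-centered bond depth.** Metal–ligand bonds form the depth-0
  super-bond; any other bond sits at its line-graph distance to the nearest
  metal–ligand bond, so the first shell of ligand-internal bonds is depth 1.
  (Anchoring that shell at depth 2 instead would leave depth 1 an always-empty
  bin for every graph, which wastes a dimension and contradicts the
  ligand-shell picture the metal-centered origin is meant to encode.)
* **Empty shells** contribute exactly 0.0; depths beyond the graph diameter
  are zeros, not missing values.
* **Ratiometric zero divisors** raise an error naming the feature by default;
  an opt-in `skip_zero_division` mode makes the offending term contribute 0.
  Silent skipping is not the default because it can mask a bad property table.
* **Label grammar.** `<prop>-<depth>_<origin∈{M,F}><op∈{A,D,R,S}>_<kernel>`
  with kernels `AA`, `BB`, `BBm` (averaged super-bond, rendered BB̅ in
  reports), `BA` (whose property field is `<bond>~<atom>`), `II1`–`II5` and
  `WG` (optional whole-graph extras: node/edge counts and property sums).
  Parsing and formatting are exact inverses; property names may not contain
  `-` or `~`.

## Regression harnesses

* **MLP**: two hidden layers of 128 ReLU units, Adam on the MSE loss,
  80:10:10 train/validation/test split repeated 10 times by default (a
  20:40:40 small-data mode is accepted). Features are z-scored with train-row
  statistics. Epoch budget 2000 with early stopping at patience 50 on the
  validation MSE; the validation monitor is a shuffled holdout of the pooled
  train+validation rows sized to the plan's validation share. Batch size
  `min(64, n_train/10)`. Early stopping is disabled for zero-variance targets
  (its R² score is undefined there).
* **GBM**: 1000 regression trees of maximum depth 5, learning rate 0.05, MSE
  loss, 5-fold cross-validation. Trees are fit on raw features (scale
  invariance). Feature relevance is the Friedman-MSE impurity importance
  averaged over folds and normalized to sum to 1; ranking ties are broken by
  original column order.
* **GP**: exact dense Gaussian-process regression with the product kernel
  `k(x,x') = σ²_lin⟨x,x'⟩ · σ²_rbf exp(−‖x−x'‖²/2λ²)` plus a fitted white
  noise term. The two variances enter only through their product, so the fit
  carries a single amplitude. Hyperparameters maximize the log marginal
  likelihood by multi-restart (default 3) L-BFGS on log-parameters; features
  are z-scored and the target is centered and scaled internally so amplitude
  and noise live near 1 in any units. Dense inference is refused beyond 5000
  rows.
* **Metrics**: MAE and the coefficient of determination
  `r² = 1 − SS_res/SS_tot` (not squared Pearson). A zero-variance target
  yields `r² = NaN` with a warning.

## Accumulated-relevance reduction

Features are ranked by descending GBM relevance; pruning at threshold *t*
keeps the smallest rank prefix whose cumulative relevance reaches *t*
(threshold 1.0 keeps everything, including zero-relevance features). The scan
retrains the chosen model (GP or MLP) at each threshold of a descending grid
(default 100%→10% in 2% steps), always including the full-dimensional
baseline, reusing one relevance table throughout (re-estimation per threshold
is deliberately not the default: the workflow estimates relevance once on the
full representation).

## Synthetic data: what it emulates and what it does not

The generator emulates only the *shape* of a mononuclear transition-metal
complex: a metal hub with 4–6 ligand subtrees, each a random tree of up to 3
extra atoms within depth 3 of the ligand root. Properties are i.i.d. draws —
a Z-like integer on [1, 80], a χ-like real on [0.7, 4.0], a radius-like real
on [0.3, 2.3] for atoms; distance-like [1.0, 3.0] and order-like [0.5, 3.0]
for bonds. All are positive so every ratiometric feature is defined. No
electronic structure, valence rules or geometric consistency are simulated;
passing tests therefore demonstrate correctness and recoverability of the
*featurization and modeling machinery*, not predictive accuracy on real
complexes.

The regression target is planted: `y = Σ_k w_k f_k + ε` with labeled
autocorrelation features `f_k` and Gaussian noise whose sd defaults to 10% of
the signal sd. The default recipe plants one atom–atom feature
(`Z-1_MA_AA`, weight 1) and one bond–atom feature (`BD~Z-1_MA_BA`, weight 5);
the weights were chosen so the two contribute comparable shares of the signal
variance under the default distributions (their natural scales differ by
roughly that factor).

The recovery benchmark poses the planted columns against independent
standard-normal distractors. Distractors are pure noise by design: the
question answered is whether the relevance estimator ranks generating
features above uninformative ones. Inside a full AABBA matrix the planted
features have algebraically related siblings (the same pairs under other
operators) that legitimately share tree-ensemble credit; that collinearity is
a documented property of impurity importances (a dedicated test shows
duplicated features splitting relevance), not a recovery failure, but it
means top-k recovery statements are made against noise distractors only.

All randomness flows from explicit integer seeds through named
`numpy.random` streams; identical configurations give byte-identical files.

## Problem sizes

Default end-to-end benchmark sizes, chosen as a desk-scale working set: 1000
graphs, 2 planted + 48 noise features for relevance recovery with the full
1000-tree ensemble; 480 further noise features for the reduction scan, whose
relevance table uses a 250-tree ensemble and whose GP scan uses 6 thresholds,
2 split repeats and 1 optimizer restart. The oracle cross-check runs 200
random graphs (≤ 10 nodes) over all operators and depths 0–4 at 1e-12
relative tolerance.

## Known limitations

* Exact dense GP only; no sparse/inducing-point approximations.
* Impurity-based relevance inherits the usual biases (split credit dilution
  among correlated features; preference for high-cardinality continuous
  features is moot here since all features are continuous).
* The redundancy filter removes only exact duplicates and constants;
  linearly dependent but non-identical columns are kept.
* Graphs must be connected; disconnected inputs are rejected rather than
  featurized per component.
* The shipped property catalogs and AABBA(II) recipes are documented
  assumptions intended for synthetic and user-supplied data, not a claim
  about any particular published property set.
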