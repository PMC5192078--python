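# Methods

## Annotation and phyletic patterns

Domain hits are read from HMMER3 per-domain tabular output (`domtblout`);
the family identifier is the query accession when present, else the query
name, and the score/E-value are the *full-sequence* columns — the
conservative convention for deciding family presence, since per-domain
statistics can split one genuine family hit into several weak ones. Hits
are kept when `bit_score ≥ 25` and `E ≤ 1e-2`. Both boundaries are
inclusive on the keep side: "above the threshold is discarded" fixes the
E-value convention and the bit-score convention is chosen symmetrically.
Per-family curated bit-score thresholds (as distributed with Pfam) are not
applied by default — they require the Pfam database — but a per-family
threshold table can be passed to `filter_hits` callers by pre-filtering.
Counts are collapsed to presence/absence; species with several sequenced
strains get the union of their strains' family sets (the pangenome union).

Phenotype labels are ternary (present / absent / unknown; strain-specific
annotations should be encoded as unknown by the data preparer). A
phenotype enters training only with ≥ 20 observed labels, of which ≥ 10
positive and ≥ 10 negative.

## Gain/loss posteriors

Characters (families and the phenotype) are modelled as independent
two-state continuous-time Markov chains along a rooted bifurcating tree
with branch lengths: gain rate `a` (0→1) and loss rate `b` (1→0) per unit
length, root state drawn from the chain's stationary distribution
(optionally fixed to absent). For every branch the posterior probability
that the parent endpoint is 0 and the child endpoint 1 (*gain*), or 1 and
0 (*loss*), given all leaf states, is computed exactly with the standard
inside/outside recursions, vectorised over characters. This is
deliberately a simple, exactly verifiable reconstruction — the package's
tests check it against exhaustive enumeration of all ancestral state
assignments on small trees. Gamma-distributed rate mixtures (as used by
dedicated gain/loss mappers) are out of scope; externally computed
posteriors can be imported via a tab-delimited table
(`branch_id, character_id, gain_prob, loss_prob`, absent pairs = 0), and
per-character rates default to maximum-likelihood point estimates on a
coarse one-dimensional grid (`gain = loss = ρ`,
ρ ∈ {0.05, 0.1, 0.2, 0.5, 1, 2}).

When a tree is pruned to the labelled taxa, chains of unary nodes collapse
and each surviving branch records the ordered root-ward chain of original
branches it absorbs. Posteriors computed on the full tree are transferred
to a pruned branch as the probability of at least one event along its
chain, `h_{n+1} = h_n + (1 − h_n)·g_{n+1} = 1 − Π(1 − g_i)`. (When the
reconstruction is instead re-run directly on the pruned tree — the default
during cross-validation — no transfer is needed.)

Gains and losses are merged per branch into a single change probability
`x = g + (1 − g)·l`: a family that is gained together with a phenotype is
assumed to be lost with it too, which halves the number of problems to
solve. Branches whose phenotype change probability lies in the uncertain
band `[r, t)` are discarded (defaults `r = 0.05`, `t = 0.5`; `r` plays the
role of an external mapper's reporting threshold, below which an event
probability is treated as a confident zero). Retained branches carry the
binary event label `y′ = [y ≥ t]`.

## Classifiers

`train_svm` fits the LIBLINEAR L1-regularised L2-loss primal
(`LinearSVC(penalty="l1", loss="squared_hinge", dual=False)`, tolerance
1e-4, max 10⁴ iterations, fixed random state). In `phypat+PGL` mode the
real-valued event rows are stacked beneath the binary leaf rows with unit
weight — no rescaling; the event probabilities already live in [0, 1],
the same range as the binary features.

Model selection and error estimation follow nested cross-validation.
Outer: stratified 10-fold over the labelled samples; per fold, an inner
cross-validation on the training fold scores every C in the grid
`{1e-3} ∪ {10^k·f : k ∈ {−2,−1,0}, f ∈ {0.1, 0.2, 0.5, 0.7, 1}}` (capped
at 1, i.e. 13 values) by pooled accuracy, and the best C (ties → smaller
C, i.e. stronger sparsity) trains the fold's model. The confusion matrix
is accumulated on observed leaf labels only — never on inferred events —
and in gain/loss-aware mode the ancestral reconstruction is recomputed for
every inner and outer training fold on the tree pruned to that fold's
taxa, so no test leaf can leak into the event rows. Because the
eligibility floor is 10 per class, an outer training fold can hold as few
as 9 members of a class; the inner split count therefore degrades to
`min(folds, smallest class count)`.

The deployed committee contains the five C values with the best pooled
cross-validated accuracy on the full labelled data (same tie-break), each
retrained on everything; members are stored sorted by score. This makes
the committee five *different* points on the regularisation path rather
than five near-copies of one model, which is what gives the majority vote
and the weak-call notion their meaning. Class weighting is not applied;
the eligibility filter bounds the imbalance.

Prediction aligns profiles to the committee's stored family universe by
id — families absent from a profile count as absent, unknown families are
ignored — and a committee votes `sign(wᵀx + b) > 0` per member. Consensus
between the two flavours is the intersection rule: positive only if both
are positive (a weak call is a minority vote, hence not a positive);
consequently consensus can only remove false positives, at the cost of
positive recall.

## Feature selection

A family is phenotype-associated when ≥ 3 of 5 members give it a strictly
positive weight (zero L1 weights are non-selections). Selected families
are ranked by the Pearson correlation (equivalently the phi coefficient)
of their presence column with the observed labels, computed on the leaf
data only — event rows are training devices, not observations. Constant
columns get r = 0 and are logged. Only majority-selected families are
ranked by default. Note that strongly correlated causal families share
their signal: an L1 committee keeps representatives of a redundant block,
so the selected set is best read as "families carrying independent
signal", not an exhaustive causal inventory.

## Evaluation

`Macroaccuracy` is the mean of the per-phenotype positive- and
negative-class recalls averaged over phenotypes; pooled `Accuracy` is the
printed `(RecallPos + RecallNeg)/2` over summed counts. The alternative
verbal reading — the raw fraction of correct assignments — is available as
`pooled_fraction_correct`. Weak calls count as negative predictions
throughout, since assignment is to the committee's majority class.
Phenotypes lacking a positive (negative) label are excluded from the
macro averages and logged; a `min_pos`/`min_neg` parameter (default 1,
preset 5 for small-label regimes) tightens this. Per-taxon reports pool
the confusion over a taxon's member species; taxa with fewer than 5
labelled species are flagged and skipped by default.

The incomplete-genome experiment deletes genes *in silico*: per replicate
and retention fraction f, each sample keeps a uniform random subset of
`round(f·k)` of its k present families, both committees re-predict, and
metrics are computed against the full-genome labels (10 replicates per
sampling point by default, seeded). Deletion operates at the
family-presence level — the observable consequence of deleting coding
sequences before annotation — which keeps the experiment independent of
any annotation tooling.

## Synthetic data

The generator emulates the training-data regime: a Yule tree (random leaf
splits) with Exp(1) branch lengths; a phenotype and `n_families` binary
characters evolved by exact per-branch transition sampling (no event-time
simulation), every sampled parent→child change recorded so inference can
be validated against the truth. Causal families copy the phenotype's
branch outcome with probability `phenotype_linkage` (0.9 by default) and
otherwise evolve independently; at linkage 1 their leaf patterns equal
the phenotype's exactly. Defaults — 200 leaves, 500 families, 10 causal,
gain = loss = 0.3 per unit length (a few expected state changes per
root-to-leaf path, giving mixed but phylogenetically clustered
characters), 5 % label noise — are the study conditions used throughout
the tests and the acceptance script; smaller sizes used in individual
analyses (e.g. 120 × 300 for the regime comparison, 120 × 150 for the
hold-out analyses) are stated where they occur and were chosen as the
smallest sizes at which the compared quantities are stable.

Two stress regimes: `clade_confounded` plants an identical block of
neutral families in a single clade (lineage-specific content that
correlates with clade-aligned phenotypes through ancestry alone);
`hgt_like` places ≥ 3 independent phenotype gains on disjoint mid-sized
clades with no losses — the horizontal-transfer-like situation in which
leaf-pattern-only models are most easily misled.

What the generator does **not** emulate: annotation noise (false/missed
domain hits beyond the decoy rows in fixture files), correlated evolution
among neutral families, rate variation across branches or characters
beyond the single-rate chain, unbalanced taxon sampling, and genuinely
unknown labels. Passing tests therefore demonstrate correctness of the
machinery and qualitative behaviour under controlled evolution, not
field performance on real genome corpora.

## Numerical notes and limitations

* Posterior inference is exact (to floating point) for any tree size;
  likelihoods are computed per character without log-space scaling, which
  is safe for the tree depths and rates used here but would underflow on
  trees several hundred times deeper.
* Internal node ids (`N1, N2, ...`) are assigned by deterministic
  post-order traversal, so branch ids — and hence posterior tables and
  event-row indices — are stable across runs.
* LinearSVC at the largest grid C occasionally stops at the iteration cap
  on event-augmented data; the returned model is still deterministic for
  a fixed seed, and such C values are penalised naturally by their
  cross-validation score.
* Ties in model selection are resolved toward stronger regularisation and
  then lexicographically, making committees reproducible.
* The input Newick is taken as rooted as written; no re-rooting is
  attempted. Posterior semantics depend on the root prior (stationary by
  default).
* Independent samples may be processed concurrently by callers; all
  outputs are byte-identical to serial execution since every random draw
  is owned by an explicit seeded generator.
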