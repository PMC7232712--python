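# Methods

This note records the model, the conventions the implementation commits
to, the parameters that matter, what the synthetic worlds do and do not
emulate, and the known limitations.

## Model and procedure

The drug network is an undirected weighted graph: nodes are the drugs of
the study universe, an edge joins two drugs whenever they share a
chemical–chemical interaction with a positive integrated evidence score
(integer, 1–999), and the edge weight is that score. Node order is
lexicographic everywhere, which fixes matrix indexing across runs.

For each side effect the drugs owning it form the seed set *SN*. The
restart vector `p_0` puts mass `1/|SN|` on every seed. The walk update is

    p_{t+1} = (1 − λ) M p_t + λ p_0,

with `M` the columnwise-normalized adjacency. The update is written in
the literature with a transpose on the normalized matrix; for a
symmetric weight matrix, literally transposing a column-normalized
matrix yields an operator that does not conserve probability mass. We
commit to the mass-conserving reading — the column-stochastic `M`
applied to `p` — which keeps `Σp = 1` on connected worlds and matches
the standard formulation of restart walks. On degree-heterogeneous
graphs the two readings genuinely differ; the conserved one is the one
whose fixed point is a probability distribution.

Iteration stops when the L1 change falls below θ. The stationary point
also solves `(I − (1−λ)M) p = λ p_0`; for λ > 0 and sub-stochastic `M`
the system matrix is non-singular, so a direct linear solve provides an
independent oracle and the preferred solver on small networks (dense
factorization below 2 000 nodes, with all side effects of one network
solved against a single factorization; sparse factorization above).
Non-convergence of the iterative solver within `max_iter` (default
10 000) is flagged on the result and warned, never silent. Note the stop
rule bounds the *step*, not the distance to the fixed point: at λ = 0.8
a step below θ guarantees roughly θ/4 accuracy, so tests that compare
the two solvers at 10⁻⁹ run the iteration with θ = 10⁻¹².

Isolated nodes keep all-zero transition columns (no self-loop
injection). Mass that steps onto an isolated node would be lost, but
mass can never *enter* an isolated node — only seeding one loses mass,
and that case is reported honestly through `Σp < 1`.

### Selection

Drugs with stationary probability `p ≤ ε` (inclusive: equality selects,
so ε = 0 selects exactly the drugs unreachable from every seed) are
paired with the side effect as candidate negatives; known positive pairs
are excluded explicitly even though the restart floor `λ/|SN|` already
keeps seeds far above any practical threshold. The union over side
effects is the negative dataset (NDS). `NDS(ε)` is nested and
non-decreasing in ε by construction.

Quality parts along a threshold grid ε₁ < … < ε_k follow the bracket
pattern part 1 = [0, ε₁], part 2 = (ε₁, ε₂), part i ≥ 3 = [ε_{i−1},
ε_i). The pattern is deliberately irregular (the second cell is open on
both sides, so a probability exactly at ε₂ belongs to part 3); we keep
it as the method's published convention, and close the final cell on the
right so that the largest admissible probability has a part.

The score-distribution diagnostic collects, for each selected pair
(d, s), the network weight between *d* and every owner of *s* (zero when
no edge), and bins the scores into `n_bins` equal-width right-closed
intervals over (0, 999], with zeros in a separate leading bin (or
dropped, in exclude-zeros mode). The exact bin boundaries are not
prescribed anywhere authoritative; equal width over the score scale is
our choice. Low-probability parts show all-zero score histograms — their
drugs have no direct links to carriers — and higher parts progressively
fill the upper bins, which is the visual argument for the quality
gradient.

### Threshold grids

On a full-scale interaction network the classic nine-point grid
(0, 5×10⁻⁷, 5×10⁻⁶, 1×10⁻⁵, 2×10⁻⁵, 3×10⁻⁵, 4×10⁻⁵, 5×10⁻⁵, 6×10⁻⁵)
is the default. Walk probabilities scale inversely with network and
seed-set size, so that grid is meaningless on a 300-drug world; for
simulated inputs the pipeline instead derives a grid from quantiles
(0.1, 0.3, 0.5, 0.75, 1.0) of the pooled non-positive pair
probabilities. The final quantile is 1.0 so that the top threshold
admits every candidate — the trend experiments need the full range from
"only unreachable drugs" to "everything".

### Features

Per pair and per association channel, the feature is the maximum
similarity between the pair's drug and any *other* owner of the side
effect. Fingerprint (Tanimoto over hashed substructure bit sets;
radius-2 circular fingerprints ≙ ECFP4 when computed from SMILES via the
optional rdkit plugin) and target-profile (direction cosine over 0/1
protein vectors) channels are computed natively. Structure
(maximum-common-subgraph), ATC-code and literature channels are defined
by external tools and prior work; they are consumed as precomputed
symmetric matrices. Missing entries and absent drugs are zero ("no
evidence"), both-empty fingerprints have Tanimoto 0, all-zero profiles
have cosine 0, and a sole-owner side effect yields feature 0 (curated
data guarantees several owners per side effect; the convention matters
only for degenerate inputs). Channels are used on their native scales;
the within-channel max is invariant to any strictly monotone rescaling.

### Comparator

The FIRE-style comparator scores a non-positive pair by the drug's
direct edge weights to the side effect's owners and selects zero-score
pairs. Only the zero/nonzero behaviour of the original score matters for
selection; we aggregate owners by max, which reproduces that behaviour
exactly and is order-independent. Zero walk probability implies no path,
hence no direct edge, hence a zero comparator score — the walk-based
selection at ε = 0 is always contained in the comparator's, while the
walk additionally grades the comparator's undifferentiated zero-score
mass by distance.

### Evaluation

Point metrics (SN/recall, FPR, SP, ACC, MCC, precision, F1) follow the
standard confusion-table formulas; any zero denominator yields 0 and the
measure is flagged. ROC and PR curves are computed at every distinct
score threshold; areas by the trapezoid rule (for ROC this equals the
tie-corrected Mann–Whitney statistic; the scikit-learn implementation
serves as a cross-check in the tests, not as the implementation). The PR
curve's zero-recall anchor reuses the first measured precision.

Cross-validation is stratified (not required by the protocol we mirror,
but it controls fold variance and guarantees both classes per fold) with
the fold assignment a pure function of labels, fold count and seed, so
classifier families are compared on identical splits. Pooled
out-of-fold scores are cut at 0.5 for the single-number metrics — the
cutting rule is not stated in the protocol we mirror; 0.5 on calibrated
probabilities is the neutral choice. Classifiers are scikit-learn's
random forest, SVC (with probability outputs) and multilayer perceptron
at library defaults plus a fixed seed; replicating another toolkit's
defaults is out of scope, and hyperparameter tuning is deliberately
absent. The balance experiments draw negatives without replacement at
1× or 2× the positive count (five repeats by default) or use all
negatives at once.

## Synthetic worlds

The generator plants the mechanism the method exploits. Drugs are split
into `n_communities` equal communities; edges appear with probability
`p_in` within and `p_out` between, weights uniform on {1..999}. Each
side effect is carried by one or two communities, and each drug of a
carrying community owns it with probability `carriage_prob` (side
effects with fewer than two owners are resampled). Every similarity
channel gives same-community pairs `similarity_signal` plus uniform
noise and cross-community pairs only noise on [0, `similarity_noise`].
Non-positive pairs carry ground truth: *latent positive* if the drug's
community carries the side effect, *true negative* otherwise.

Defaults — 300 drugs, 40 side effects, 6 communities, `p_in` 0.25,
`p_out` 0.01, `carriage_prob` 0.5, signal 0.6, noise 0.1 — are chosen so
that communities are internally connected (every carrying-community drug
is reachable from the seeds, making the ε = 0 selection *exactly* the
true negatives when `p_out` = 0), cross-community leakage is small but
present when `p_out` > 0, and roughly half the carrying drugs stay
latent, giving the trend experiments real label noise to detect. With
`p_out` > 0 the whole network is connected with overwhelming
probability, so the ε = 0 selection is empty there; purity statements on
cross-linked worlds therefore use the smallest positive grid threshold.

What the worlds do **not** emulate: the heavy-tailed degree and
owner-count distributions of real interaction and pharmacovigilance
data, correlated evidence channels (the five channels are sampled
independently here), score-dependent edge semantics, and any
drug-specific chemistry. Passing tests show the machinery is correct and
the selection mechanism behaves as designed when its premise (community
structure aligned with side-effect carriage) holds; they do not certify
performance numbers on real SIDER/STITCH snapshots, whose reproduction
requires those snapshots.

## Numerical and design choices

- Duplicate unordered interaction rows collapse to the maximum score
  (deterministic, conservative); self-pairs are dropped; scores outside
  1–999 are parse errors.
- Similarity matrices must be symmetric within 10⁻⁹; asymmetry is a
  consistency error rather than silently averaged.
- Column sums of the transition matrix are exact to 10⁻¹²; isolated
  columns are exactly zero.
- The direct solver refuses nothing in practice (the system is provably
  non-singular for λ > 0); a singular factorization would raise rather
  than return garbage.
- Pipeline runs fan one global seed out to stages by fixed offsets;
  reports are JSON with sorted keys, so identical seeds give bitwise
  identical reports.
- The pipeline's evaluated threshold defaults to the smallest grid value
  that selects at least one negative, and errors informatively when no
  grid value does.
- Problem sizes in the test suite and acceptance script (worlds of
  90–300 drugs, 5–10 fold cross-validation, 5–10 world replicates per
  trend statistic) are the package's desk-scale defaults: large enough
  for every qualitative claim to be stable across seeds, small enough to
  iterate on freely.

## Limitations

- The ε = 0 guarantee is graph-theoretic, not biological: it certifies
  "no evidence path", not "no side effect".
- Selection quality degrades exactly as designed when thresholds grow;
  there is no internal criterion for choosing ε beyond "small", matching
  the method's own recommendation.
- The three consumed channels are only as good as the matrices supplied;
  no attempt is made to validate their provenance beyond symmetry and
  non-negativity.
- Weka-default classifier behaviour is not replicated; conclusions about
  *relative* negative-set quality are robust to the classifier library,
  absolute metric values are not.
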