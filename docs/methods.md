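# Methods

This note documents the statistical model, the tunable parameters, the
synthetic data used for validation, and the numerical and design choices
made where more than one reasonable option existed.

## Model overview

The package scores every unordered pair of retained alignment columns with
one or both of two coupling metrics, fits an alignment-specific null to the
scores, and converts the scores to pair and site calls at a user-chosen
false discovery rate (FDR).

### Pre-processing

Four filters run in a fixed order; each is tracked in a `FilterReport` and
every retained column keeps its original index and reference residue
number.

1. *Sequence redundancy/relatedness.*  Sequences are scanned in file order
   (reference first).  A sequence is dropped if its identity to any
   already-kept sequence is above `max_id` (default 0.90) or below `min_id`
   (default 0.20).  Identity is computed over columns where neither
   sequence is gapped, so the statistic is stable in gappy alignments.
   This greedy rule is deterministic, keeps the reference unconditionally,
   and guarantees the post-hoc invariant that every kept pair lies in the
   identity band — the strongest reading of "delete highly similar and
   dissimilar sequences", which does not itself prescribe an algorithm.
2. *Conserved columns.*  A column is dropped when its most frequent residue
   exceeds `max_cons` (default 0.95) of its non-gap rows; gaps are not
   residues and are excluded from both numerator and denominator.
3. *Gapped columns.*  A column is dropped when its gap fraction exceeds
   `max_gap` (default 0.25) of all rows.
4. *Depth.*  Fewer than `min_depth` (default 125) remaining sequences
   flags the alignment (an error in strict mode).

Non-standard residue codes (B, Z, X, U, O, J, `*`) are mapped to gaps:
the pair-state space is fixed at 20 × 20 ordered amino-acid pairs
(alphabetical order, index `20·idx(a) + idx(b)`), and ambiguity codes
carry no usable pair information.  A consequence worth knowing: if the
*reference* sequence contains such a code, reference numbering counts only
its standard residues.

### Coupling metrics

With H_i, H_j the entropies (bits) of the two marginals of the empirical
400-state pair distribution and H_ij its joint entropy,

    U(i,j) = 2 (H_i + H_j − H_ij) / (H_i + H_j)  ∈ [0, 1].

Rows gapped at either column are excluded, and the marginals are computed
from the same row subset as the joint — this guarantees H_ij ≤ H_i + H_j
and hence U ≥ 0.  U := 0 when H_i + H_j = 0 (both columns constant on the
shared support); pairs with empty shared support also score 0.  No
pseudocounts are added anywhere.

UD(α) transforms the pair distribution p by D(α) = (1−α) I + α D, with D
the trained doubly stochastic matrix and α ∈ (0, 1] (default 1), and takes
the U-value of the transform, *with marginals recomputed from the
transformed joint* — the only reading consistent with "the U-value of the
transform"; re-using the raw column entropies in the denominator would not
be the U of any distribution.  The transform is implemented as
q = p + α(Dp − p), which makes D = I a bitwise no-op, so a UD run with the
identity matrix reproduces a U run exactly (a useful end-to-end
consistency check, exercised in the tests).

Because every doubly stochastic matrix is a mixture of permutations, the
transform can only increase entropy.  Pairs whose joint distribution
already matches the compensatory-exchange pattern stored in D lose little
mutual information under the map; pairs with an unrelated covariation
pattern are smoothed toward independence and scored down.  This is the
mechanism by which UD(α) upscales dissimilar compensatory mutations
relative to everything else.

### Training the compensatory-exchange matrix D

A pair of ordered residue pairs ((a_i, a_j), (a_k, a_l)) is a *formal
dissimilar compensatory mutation* iff BLOSUM62(a_i, a_k) < 0 and
BLOSUM62(a_j, a_l) < 0.  Training, given a corpus of MSAs and an FDR:

1. **Counting.**  For each MSA the U pipeline is run and its significant
   column pairs form the signal set; a seeded random draw of
   non-significant pairs (per MSA: the number of signal pairs, minimum 50)
   forms the null set.  For each column pair, every unordered pair of
   rows without gaps at the two columns contributes one count to both
   ordered entries of a 400×400 matrix (the block-substitution counting
   scheme lifted from single columns to column pairs), giving C_alt and
   C_null.  MSAs deeper than 300 rows are subsampled (seeded) per column
   pair for tractability; both matrices are symmetric by construction,
   diagonal counts included at the same factor 2 so that relative
   frequencies are unaffected.
2. **Relative-frequency filter.**  An off-diagonal entry of C_alt survives
   iff its relative frequency strictly exceeds its relative frequency in
   C_null; diagonal entries always survive.
3. **Dissimilarity mask.**  Surviving off-diagonal entries that are not
   formal dissimilar compensatory exchanges are zeroed; the result is
   normalized to a probability matrix P.
4. **Log-odds.**  S = log P(s,t) / (Pb(s)·Pb(t)), with Pb the first-index
   marginal of P (natural log; only the sign matters downstream).  Zero
   entries get −∞.
5. **Sinkhorn scaling.**  Negative entries of S are zeroed; zero diagonal
   entries are then set to 1 — an identity substitution is always
   admissible, and for a symmetric non-negative matrix a fully positive
   diagonal guarantees *total support* and therefore geometric convergence
   of the alternating row/column normalization (without it the iteration
   can stall on sparse patterns).  Iteration runs to a max row/column-sum
   deviation of 1e-8 (cap 10,000 sweeps, error on failure), and the result
   is symmetrized as (D + Dᵀ)/2 and re-validated.

Training is deterministic given the corpus and a seed.  The matrix is
persisted as plain text with a provenance header (alphabet, pair-index
convention, corpus hash, seed, FDR) and validated on load.  An optional
`iterations` parameter re-runs the significance scan with the UD(1) metric
of the previous matrix and retrains (default 1, i.e. the single standard
pass).  No pre-trained matrix ships with the package — a full-precision
400×400 text matrix is megabytes — so the out-of-box default is the
identity matrix and `cmf train` builds a real one from any corpus in
minutes.

### Significance model

Scores of one metric on one MSA are treated as an iid sample whose null
component is Beta(a, b).  The null mean is the sample mean of *all* pair
scores; the null variance is the sample variance of ν (default
min(1000, #pairs)) re-scored pairs in which the second column was randomly
permuted across rows — shuffling preserves both column compositions but
destroys any genuine row-wise association, so the shuffled scores are
draws from the no-coupling distribution.  Candidate pairs for shuffling
are taken from a score subinterval (default [0.2, 0.8]) when it is
populated, otherwise from all pairs (logged).  (a, b) follow by moments:
k = m(1−m)/v − 1, a = mk, b = (1−m)k; an infeasible variance
(v ≥ m(1−m)) is an error rather than a silent clamp.

P-values are p = 1 − F0(score).  The null fraction is estimated as
γ = #{p ∈ [λ1, λ2]} / (μ (λ2 − λ1)) with defaults λ1 = 0.25, λ2 = 0.70 —
a window in which the p-value distributions of both metrics are close to
uniform on real proteins — clipped to [1/μ, 1] to avoid a zero FDR
estimate.  The threshold τ is the largest *observed* p-value t ≤ λ1 with
γ·μ·t / #{p ≤ t} ≤ target FDR (candidates at observed p-values maximize
the discovery set without interpolation); τ = 0 means nothing is called.

Sites: the connectivity degree of site *i* is the number of significant
pairs containing it.  The degree threshold is the nearest-rank percentile
(default 90th; the ceil(q·n)-th order statistic — deterministic, no
interpolation) of the degrees of sites with degree ≥ 1; sites at or above
it are metric-significant (`strict` switches ≥ to >, both conventions
appearing in practice).  CMF-significant sites are the union over the two
metrics, reported in reference-residue coordinates with per-metric flags
and degrees.  Both metrics use the same seed for their null estimation, so
identical score tables yield identical calls.

## Synthetic data

The generator produces the three ingredients the detector must separate.

* **Background columns** use a consensus-mixture model: each column draws
  a consensus residue from a background frequency vector (default uniform;
  a BLOSUM62-diagonal-derived preset exists), and each ancestral sequence
  carries the consensus with probability 1 − `divergence` (default 0.40),
  otherwise an independent background draw.  Columns are mutually
  independent — the correct null — while sequences attain ~39% expected
  pairwise identity and therefore pass the 20–90% identity filter.  A
  fully iid-per-cell background would give ~5% pairwise identity and no
  alignment would survive pre-processing.
* **Coupled pairs** (i, j, ρ, state set): with probability ρ a row's two
  residues are a joint draw from the state set, else each follows its
  column's background process.  Default planted alphabets hold four pair
  states; a real coevolving pair admits several residue combinations, so
  its columns are entropy-matched to other non-conserved columns.  This
  matters statistically, not just cosmetically: planting low-entropy
  two-state "toggles" drags down the alignment-wide score mean that the
  single beta null is fitted to and visibly inflates the realized FDR — a
  model-mismatch sensitivity of the single-null design that users should
  keep in mind for real alignments with strong entropy heterogeneity.
* **Phylogenetic redundancy** is modelled by duplication: a fraction
  (default 0.15) of rows are copies of earlier rows with independent
  per-site point mutations (rate 0.12).  This is the minimal mechanism
  that produces correlated rows; a full tree simulator is out of scope.
  Gaps are injected uniformly (rate 0.01); the reference row stays
  gap-free so that every column has a reference residue number.

Everything is reproducible from a single integer seed; corpora of MSAs
with varied coupled-pair placements are generated from spawned seeds and
written with a ground-truth manifest.

What passing tests on this generator do *not* show: behaviour under real
tree-shaped phylogenies (duplication is a one-level caricature), under
realistic substitution processes (no WAG/LG rates), or under the column
entropy heterogeneity of real HSSP-style alignments.

### Benchmark corpora for the trained matrix

The training benchmark compares a matrix trained on a corpus whose planted
couplings exchange states by formal dissimilar compensatory mutations with
one trained on a control corpus whose couplings are uniformly
BLOSUM62-similar.  Both preset families are four-state alphabets built
from residue groups that are pairwise BLOSUM62-negative
({D,G,W,P}, {K,C,F,D}, {E,W,G,C}, {N,F,P,A}) or pairwise non-negative
({I,L,V,M}, {K,R,Q,E}, {D,E,N,Q}), so *every* within-set exchange has the
intended character (asserted in the tests).  A literally coupling-free
control cannot be trained — with nothing significant the training
correctly refuses to run — so similar couplings are the strongest
well-defined control: equal covariation signal, zero dissimilar content.
These corpora use ρ = 1 (deterministic compensatory coupling).  With
ρ < 1, background draws inside coupled columns seed rare pair states whose
substitution counts are singletons; a singleton's relative frequency can
essentially never be beaten by the null set in the phase-2 filter, and its
sparse row then receives a large share of Sinkhorn mass.  That noise is
unrelated to the property under test and, at desk-scale corpus sizes,
drowns it.  The same singleton/log-odds fragility is a genuine limitation
of the training procedure itself at small data scales (see below).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `fdr` | 0.01 | target false discovery rate for pair calls |
| `alpha` | 1.0 | weight of the trained matrix in D(α) |
| `min_id`, `max_id` | 0.20, 0.90 | pairwise identity band (inclusive) |
| `max_cons` | 0.95 | conservation cutoff (fraction of non-gap rows) |
| `max_gap` | 0.25 | column gap-fraction cutoff |
| `min_depth` | 125 | minimum sequences after filtering |
| `lambda1`, `lambda2` | 0.25, 0.70 | γ estimation window; τ ≤ λ1 |
| `nu` | 1000 | shuffled pairs for the null variance |
| `subinterval` | [0.2, 0.8] | score band for shuffle candidates |
| `percentile` | 90 | connectivity-degree site cutoff (nearest rank) |

## Problem sizes used in validation

The test suite and the acceptance script validate at desk scale: twenty
150-sequence × 120-column alignments with ten planted pairs for FDR and
power; eight seeds per coupling level for the monotonicity check; corpora
of four 150×120 MSAs per arm for training discrimination; 200
micro-alignments against the direct-summation oracle; 1000 random
400-state distributions for the majorization property.  These sizes give
Monte-Carlo error small enough for the assertions made and run in seconds
to a few minutes; they are of course far below the ~10³-MSA corpus scale
at which the matrix training is meant to operate.

## Known limitations

* The single beta null assumes exchangeable pair scores.  Strong column
  entropy heterogeneity shifts subpopulations of scores relative to the
  fitted null and can inflate the realized FDR beyond the nominal target
  (measured directly in the planted-toggle experiment described above).
* Phase 2's strict relative-frequency rule cannot veto singleton
  substitution counts, and phase 4's log-odds are largest precisely for
  rare events, so sparse training corpora put nontrivial Sinkhorn mass on
  chance transitions.  The effect shrinks as corpus size grows; treat
  matrices trained on a handful of MSAs as demonstrations only.
* The p-value machinery treats pair scores as iid although pairs sharing
  a column are correlated; no dependence correction is attempted.
* Average-product correction and other explicit background-noise metrics
  are deliberately out of scope; the FDR model is the noise-control
  mechanism here.
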