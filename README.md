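# cmf — Coupled Mutation Finder

Detection of **compensatory (coevolving) residue-site pairs and sites** in
protein multiple sequence alignments, with an MSA-specific false discovery
rate model.

When a substitution at one site of a protein is offset by a substitution at
another, the two alignment columns covary.  Such coupled, *non-conserved*
sites are often structurally or functionally important (contacts, allosteric
or binding-site shells, disease-associated positions), but the covariation
signal is buried in noise from shared ancestry ("phylogenetic noise"),
sparse data, and unrelated column pairs.  `cmf` separates the signal from
the noise with multiple-testing machinery rather than ad-hoc top-*k* cutoffs,
and adds a second metric that specifically amplifies *dissimilar*
compensatory exchanges.

## Method

For columns *i*, *j* of a filtered alignment, with column entropies
H<sub>i</sub>, H<sub>j</sub> and joint entropy H<sub>i,j</sub>:

* **U-metric** — normalized mutual information in [0, 1]:

      U(i,j) = 2 · (H_i + H_j − H_i,j) / (H_i + H_j)

* **UD(α)-metric** — the U-value of the pair distribution after the linear
  map D(α) = (1−α)·I + α·D, where D is a 400×400 **doubly stochastic
  matrix** over ordered amino-acid pair states trained so that its mass sits
  on *formal dissimilar compensatory* exchanges (both positional BLOSUM62
  scores negative).  A doubly stochastic map can only increase entropy, so
  pairs whose statistics do not match the trained compensatory pattern are
  penalized relative to pairs that do.  D is trained in five phases
  (substitution counting over significant vs. random column pairs, a
  relative-frequency filter, the dissimilarity mask, log-odds, Sinkhorn
  row/column normalization); see `docs/methods.md`.

* **Significance** — per metric, scores are referred to a beta null F0
  fitted by moments (mean of all scores; variance from column-shuffled
  pairs), p = 1 − F0(score).  The null fraction γ is estimated from the
  p-value histogram on [λ1, λ2] = [0.25, 0.70], and the threshold τ is the
  largest p ≤ λ1 with estimated FDR γ·μ·τ / #{p ≤ τ} at or below the
  target (a Storey–Tibshirani-style procedure).  A site is
  metric-significant when its **connectivity degree** (number of significant
  pairs containing it) reaches the 90th percentile of nonzero degrees; a
  site is **CMF-significant** when significant under U *or* UD(α).

Inputs are multiple-FASTA alignments.  Pre-processing enforces pairwise
sequence identity in [20%, 90%], removes >95%-conserved and >25%-gap
columns, and requires ≥125 remaining sequences.

## Worked example

Generate a synthetic alignment with 8 planted coupled column pairs, then
analyze it at FDR 1% (no trained matrix needed for a first run; `--dcm
identity` makes UD coincide with U):

```
$ cmf simulate --n-msas 1 --n-coupled 8 --seed 11 --out corpus
$ cmf run --msa corpus/msa000.fasta --fdr 0.01 --seed 11 --out reports
U: 8 significant pairs, 16 significant sites (tau=1.43e-58, gamma_hat=0.813)
UD: 8 significant pairs, 16 significant sites (tau=1.43e-58, gamma_hat=0.813)
CMF-significant sites: 16
reports written to reports
```

All 8 planted pairs (and nothing else) are recovered — compare
`reports/pairs_U.tsv` with the ground truth `corpus/truth.tsv`:

```
$ head -3 reports/pairs_U.tsv
col_i  col_j  ref_res_i  ref_res_j  score     p_value       metric
1      79     2          80         0.930747  2.24e-91      U
13     94     14         95         0.908171  5.99e-79      U
```

`score` is the U-value of the column pair, `p_value` its tail probability
under the fitted beta null, and coordinates are given both as original
alignment columns and as residue numbers of the ungapped reference
sequence.  `gamma_hat = 0.813` says ~81% of pairs look null; `tau` is the
p-value cutoff that keeps the estimated FDR ≤ 1%.  The 16 CMF-significant
sites in `reports/sites.tsv` are exactly the 16 planted columns, each with
its per-metric connectivity degree.

To use the dissimilarity-upscaling metric with a trained matrix:

```
cmf train --corpus corpus/ --fdr 0.01 --seed 1 --out dcm.tsv
cmf run --msa corpus/msa000.fasta --dcm dcm.tsv --fdr 0.01 --out reports2
```

The same pipeline is available as a library: `cmf.RunConfig` /
`cmf.run_cmf`, with every stage (`filter_alignment`, `all_pair_scores`,
`analyze`, `train_dcm`, ...) importable on its own.

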