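# Methods

## The model family

`codonbench` implements time-reversible continuous-time Markov models on
the 61 sense codons of the universal genetic code, in which an
instantaneous event changes exactly one nucleotide. For sense codons
*i → j* differing only at codon position *k*, exchanging nucleotides
*x → y*:

```
q_ij = rho_c(aa_i, aa_j) * theta_{xy} * pi_k(y)     (non-synonymous)
q_ij =          1        * theta_{xy} * pi_k(y)     (synonymous)
q_ij = 0                                            (> 1 position differs)
```

* **rho** — amino-acid exchangeabilities. The 75 unordered residue pairs
  reachable by a single nucleotide substitution are partitioned into K
  classes; all pairs in a class share one rate, measured relative to the
  synonymous baseline of 1, so each rho is a non-synonymous/synonymous
  rate ratio. K = 1 is the single-rate (SR) model and rho is the
  classical omega = dN/dS; K = 75 (one class per pair) is the codon
  general time-reversible (REV) model. Intermediate K with *random*
  pair-to-class assignment is the benchmarking device this package
  exists for. Assignments are over residue *pairs*, not residues, so no
  rate transitivity is imposed — the genetic code itself is
  non-transitive in one-step reachability.
* **theta** — symmetric mutational biases for the six unordered
  nucleotide pairs. A<->G is fixed at 1 for identifiability (the usual
  GTR-style convention); an HKY-like submodel (transitions fixed,
  single transversion bias) is available.
* **pi** — position-specific nucleotide frequencies (3 x 4, rows sum
  to 1; 9 free parameters). The stationary distribution is the product
  of positional frequencies restricted to sense codons and renormalised;
  this is the exact stationary law of the family (detailed balance
  pi_i q_ij = pi_j q_ji holds by construction and is verified by test,
  not assumed).

Q is rescaled so the stationary expected substitution rate is exactly 1,
making branch lengths expected substitutions per codon site and
comparable across models.

## Likelihood and fitting

The likelihood on a fixed unrooted tree is computed by Felsenstein
pruning over compressed site patterns, root term weighted by the
stationary distribution; reversibility makes the traversal root
irrelevant (tested to 1e-8). Gaps/ambiguous codons are missing data
(partial-likelihood vectors of ones). Per-node rescaling guards against
underflow. Transition matrices come from a symmetric-similarity
eigendecomposition of Q (`eigh`), cached per matrix so branch-length
optimisation reuses one decomposition.

Maximum-likelihood fitting alternates L-BFGS-B blocks — (1) all branch
lengths, (2) exchangeabilities + biases (+ frequencies when ML) — until
the per-cycle log-likelihood gain falls below a relative tolerance of
1e-8 (default; `FitOptions.tol`). Rate-like parameters are optimised in
log space inside [1e-6, 100]; frequencies via per-position logits.
Non-finite likelihood evaluations (reachable when a line search probes
an extreme corner of the frequency simplex) return a large penalty so
the search backtracks instead of stalling. Estimates at or effectively
at a bound (branch lengths below 1e-6 count as degenerate) are flagged
as boundary solutions; non-convergence within the cycle budget is
flagged, never silently ignored.

Initialisation: branch lengths from the input tree when present,
otherwise all edges at half the mean pairwise codon p-distance;
frequencies at observed positional proportions; all rates at 1.
Optional seeded random restarts jitter this start multiplicatively.
When a richer model is fitted after a nested one,
`warm_start_options` starts every class rate at the nested model's
common rate and reuses its branch lengths/biases/frequencies, which
guarantees the optimised log-likelihood can only improve on the nested
fit — the nesting chain SR ⊆ random-K ⊆ REV then holds numerically,
not just in expectation.

**Frequency policy.** By default positional frequencies are estimated
by ML (9 free parameters), matching the protocol under which the
reference analyses were run. A faster `freq_mode="observed"` plug-in
(frequencies fixed at alignment proportions) is available, but plug-in
frequencies are mildly misspecified on finite data and that misfit is
partially absorbable by a multi-rate alternative; in ensemble
benchmarking this visibly distorts the null distribution of the
likelihood-ratio statistic, so ML frequencies are the default and the
plug-in is documented as an approximation.

## Degrees of freedom and model size

Free parameters: (2n−3) branch lengths (when optimised) + 5 biases
(REV-like; 1 HKY-like) + 9 frequencies (ML mode; 0 observed) + the
number of *non-empty* rate classes. Independent uniform class draws can
leave classes empty; only occupied classes are estimable, and all
df/BIC accounting uses the effective count. The SR-vs-random-K LRT df
is therefore K_eff − 1.

## The benchmarking protocol

`run_random_ensemble` fits SR once, then `n_replicates` (default 100)
random K-class models with assignment seeds `base_seed + r`, each
warm-started from the SR optimum and fully re-optimised with the same
settings. Each replicate is compared to SR by a chi-square LRT at
`alpha` and at the Bonferroni-corrected `alpha / n_replicates`;
non-converged replicates are excluded from significance counts and from
the ensemble mean BIC, and tallied separately. BIC uses
n = codon sites, the dominant convention in phylogenetics.
`summarize` renders the two benchmark tables: per-K counts of random
models beating SR ("raw (Bonferroni)") and a BIC comparison with the
per-alignment minimum starred.

**Correlation across replicates.** All replicates of an ensemble share
one alignment, so their LR statistics are strongly positively
correlated: an alignment whose sampling noise mimics pair-level rate
heterogeneity lifts every random split at once, and on null
(SR-simulated) data the per-alignment mean statistic varies several-fold
around the chi-square(1) mean. Pooled across independent alignments the
statistic matches its chi-square reference closely; the calibration
test in the suite therefore pools 20 simulated alignments x 10 random
splits and checks both the QQ slope against chi-square(1) and the
pooled rejection fraction at alpha = 0.05. Single-alignment ensemble
counts should be read as estimates with extra-binomial variance — which
is also why on real alignments the fraction of significant random
models varies widely between data sets.

## The simulator

`simulate_alignment` draws root states from the stationary distribution
and propagates them edge by edge with exact transition probabilities
P(t) = exp(Qt); a single RNG stream seeded once is consumed node by
node in preorder (all sites of a node drawn together), making output
bit-reproducible. An optional Gillespie mode samples the embedded jump
chain per (edge, site) and logs each substitution with its synonymous
flag, so expected event flows stationary_i * q_ij * t are directly
checkable. `random_tree` grows an unrooted binary topology by uniform
random joining with exponential branch lengths.

What the simulator emulates: the exact generating process of the model
family on a fixed tree. What it does not: indels, site-to-site rate
variation, non-stationary composition, recombination, alignment error.
Passing recovery and calibration tests therefore demonstrates
correctness of inference *under the model*, not robustness of the model
on real data.

## Problem sizes and test-time choices

The suite exercises the statistical claims at desk scale: parameter
recovery uses 12-taxon, 1,000-codon alignments (20 replicates);
type-I-error and power ensembles use 50 random models on one
12-taxon, 1,000-codon alignment; the chi-square calibration pools 200
statistics from 20 six-taxon, 300-codon alignments; exhaustive-
summation oracles run on all topologies with up to 4 taxa. Default
simulation settings (mean branch length 0.1–0.12 expected substitutions
per codon site, omega-like rates between 0.05 and 10) sit in the range
typical of the protein-coding alignments this method targets.

## Known limitations

* No site-to-site rate variation (no gamma mixture or site classes),
  no branch-specific rates, no topology search.
* LRT calibration is asymptotic: at low information (few taxa, short
  alignments) the statistic is conservative, and on any single
  alignment ensemble counts carry extra-binomial variance (above).
* Empty classes are handled by effective-count accounting, but a
  random assignment with many empty classes is reported, not resampled.
* The ensemble protocol is a benchmark for model-comparison practice,
  not a biological inference: a "significant" random model says the SR
  baseline is weak, not that the random partition is meaningful.
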