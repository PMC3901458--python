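# Methods

## Model

A clonal family `Q` of immunoglobulin V-region sequences is assumed to
descend from one unmutated ancestor (UA) `α`, itself produced by V(D)J
recombination. Two stochastic stages define the posterior `P(α|Q) ∝
P(Q|α) P0(α)`.

**Rearrangement prior.** A rearrangement is parameterized by the chosen
gene segments (V and J; additionally D for heavy chains), a recombination
point per joining end, and the N-nucleotide sequences at each junction. The
assembled candidate is deterministic in these parameters: trimmed V, then
N1, (trimmed D, then N2,) then trimmed J. Conventions:

* Recombination points are stored as *trim counts* from the joining end:
  0 = intact germline end, positive k = k bases removed, negative k ≥ −4 =
  |k| P nucleotides appended (reverse complement of the terminal germline
  bases, the hairpin-opening footprint). The upper bound never removes the
  invariant V cysteine / J tryptophan-phenylalanine codon; D may be trimmed
  from both ends.
* Allele priors are locus-uniform: each locus carries equal mass, split
  equally among its alleles, so allele-rich loci are not overweighted. A
  TSV override can inject population allele frequencies.
* Trim priors are uniform over each segment's allowed range; N composition
  is i.i.d. `π_N` (uniform by default) with an improper-uniform length
  prior. Two operational caps make the improper prior computable:
  `n_max = 30` nt per junction (far above junction lengths seen in
  repertoires), and `d_trim_max = 10` nt per D end. The D cap reflects
  exonuclease biology — trimming rarely exceeds ~10 nt per end — and keeps
  meaningful prior mass off 1–3-nt D remnants that no method could assign.
  Hypothesis enumeration also requires at least one retained D base, since a
  fully erased D has no placement in the column model.

**Mutation likelihood.** Alignment columns evolve independently under
Jukes–Cantor along a rooted clonal tree, factored as `T = μ·T1` with `T1`
unit-mean-branch. Column likelihoods for each candidate root base come from
Felsenstein pruning, vectorized across columns; leaf gaps are missing data.
CDR3 columns (between the V cysteine codon and the J tryptophan codon,
mapped through the modal segment alignments) evolve at
`cdr3_multiplier = 2.0` times the branch rate, compensating the known
under-counting of junction mutations. μ is integrated over a discrete grid,
by default 25 log-spaced points on [0.001, 0.5] substitutions/site with a
uniform grid prior — the range brackets clonal mutation frequencies (a few
percent) with a wide margin on both sides.

## Alignment and hypothesis enumeration

Each (segment, trim) pair is aligned to the fixed query MSA by dynamic
programming under the likelihood-derived scheme: match score
`m(i,a) = log P(column_i | root base a)`; N score
`N_i = log Σ_x P(column_i|x) π_N(x)`; linear (non-affine) gap scores with a
per-site indel probability of 0.01. Two conventions matter:

* **Multi-query insertion score.** A gap in the ancestor must explain every
  observed base in that column, so the insertion score is the per-site
  penalty times the column's non-gap query count. For a single query this
  is the plain per-site penalty.
* **N-adjusted scores.** DP scores are stored minus the N score of the
  occupied columns. The full-hypothesis log likelihood then decomposes as
  `Σ_i N_i + adj(V) + adj(D) + adj(J)`, so each segment can independently
  take its maximum-score alignment (one per trim value) and the placements
  are only afterwards checked for consistency — the overlap indicator `f`
  is 1 iff V end < (D interval <) J start. V is anchored at the MSA 5' end
  and J at the 3' end, with free end gaps (default on) absorbing sequencing
  fragments that start inside V or end inside J; D floats between them.

Hypotheses are the consistent cross-products of per-role candidates, with
the columns between placements charged to N (length ≤ `n_max`). Per μ grid
point, the hypothesis posterior is normalized from the factorized scores;
hypotheses more than 20 nats below the mode are pruned (and at most 2000
kept) before position posteriors — both bounds configurable, with pruned
mass below e⁻²⁰ of the total. A grid point where every placement
combination is inconsistent carries zero posterior mass.

Per-position posteriors mix, over hypotheses and μ: a point mass at the
covering germline base for segment columns, and the likelihood-weighted
`π_N` posterior for N columns. The probable error at a position is one
minus the maximum posterior; its sum, the total probable error, estimates
the expected number of modal-UA mismatches. The modal gene segment per role
is the argmax of the marginal segment posterior.

## Iteration and tree estimation

The loop starts from a palm tree (root–stem–star), computes the posterior
integrating over μ, adds the modal UA as the root taxon, and re-estimates
the tree: neighbor joining on Jukes–Cantor distances with deterministic
lexicographic tie-breaking, re-rooted at the UA, then fixed-topology branch
lengths by L-BFGS-B on the pruning likelihood. Convergence is identical
rooted topology with no branch moving more than 1e-4 (max 20 iterations;
2–3 typical). A user-supplied newick tree bypasses estimation entirely, and
a pre-computed MSA can replace the built-in center-star aligner (clonal
sequences of equal length are used as given — SHM rarely creates indels).

**Flat-prior ablation.** With `flat_prior` the rearrangement model is
replaced by independent uniform base priors per column: the posterior is
simply the normalized column likelihood. In comparative studies the flat
model is evaluated on the tree estimated by the full model, since only the
prior is meant to change; letting the flat model re-fit its own tree
collapses the root-to-ancestor stem onto the observed consensus and
understates its error.

## Synthetic data

The simulator mirrors the inference model exactly: locus-uniform segments,
uniform trims (D capped at `d_trim_max` per end, ≥1 base retained), N
lengths uniform on [0, 8] (the realistic TdT range) with uniform
composition, and Jukes–Cantor point mutation (no indels) along a random
tree — by default a palm tree with exponential(1) branch lengths,
unit-normalized and scaled by the true rate; a birth-process topology is
available for harder cases. CDR3 columns use the doubled rate. Ground truth
(parameters, UA, tree, per-branch mutation events) is recorded and
replayable.

Because generator and model share the same structure, passing tests show
the inference machinery is correct and the posterior calibrated *under the
model's own assumptions*. They do not probe model misspecification present
in real repertoires: SHM hot/cold-spot motifs, selection, indels,
non-uniform trim and N-length distributions, or IMGT-scale libraries with
dozens of near-identical alleles. The bundled library is small (6 V / 4 D /
3 J heavy, with one two-allele V locus) and its segments are shorter than
real genes, so absolute probable-error magnitudes are not transferable to
real data; the calibration *relationship* is what the studies test.

## Validation studies and sizes

The studies in `igua.experiments` (run by the test suite and
`scripts/acceptance.py`) use an 8-point μ grid on [0.005, 0.3] and at most
6 outer iterations — a scaled-down configuration chosen so a full study
suite completes in minutes on one CPU:

* **Round trip** (5 clones, 5 leaves, μ=0): exact modal-UA recovery and
  segment posteriors ≥ 0.99, restricted to identifiable clones (retained
  D ≥ 6 nt, unique among the toy D segments).
* **Calibration** (20 clones, 10 leaves, μ=0.05): per-role recovery of the
  modal segment, and mean observed mismatches compared with the mean total
  probable error within twice the standard error of the observed mean.
  Mismatch counts are overdispersed — errors are correlated through shared
  stem mutations — so the sampling error of the mean is the comparison
  scale. A small upward residual (~0.5 nt) in mismatches is expected: the
  iterative algorithm plugs the modal UA in as the tree root, which biases
  the root-to-ancestor stem short wherever no germline-visible stem
  mutation remains, and junction columns inherit that optimism. Removing
  this bias would require integrating over trees, which is out of scope.
* **Subsample trend** (subsets of 1/3/9 sequences from 27-leaf clones, 10
  clones): mean total probable error is non-increasing in subsample size.
* **Prior ablation** (20 clones): the flat-prior model's total probable
  error exceeds the full model's on ≥ 80% of clones (observed: all).

## Numerical notes and edge cases

Pruning rescales partial likelihoods per column, tracking log scale
factors, so 100-sequence clones do not underflow. DP ties break toward
fewer gaps, then the 5'-most placement; the batched DP (one pass per
fragment length) and the single-candidate DP are verified equal. Identical
queries (total tree length ~0) skip tree re-estimation and report
convergence. Branch lengths are bounded to [1e-8, 5] during optimization.
JC distances cap the mismatch fraction at 0.74 to stay finite. All
randomness flows through explicit integer seeds; inference itself is
deterministic given inputs and configuration.

## Limitations

Single substitution rate (no per-site heterogeneity beyond the CDR3
factor); Jukes–Cantor only; one maximum-score alignment per segment rather
than a sum over alignments; the UA is the only ancestor inferred —
internal-node reconstruction is a separate problem; clonal membership is
assumed, not inferred; IUPAC ambiguity codes are rejected rather than
modeled.
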