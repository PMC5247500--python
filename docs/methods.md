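# Methods

`morphobench` implements a controlled simulation study of phylogenetic
inference from discrete phenotype (morphological) characters. Data of known
provenance are simulated on two fixed 32-taxon generating trees, calibrated
to empirical levels of homoplasy, and analysed with four inference methods;
accuracy is scored against the generating tree. This note documents the
models, the calibration, the numerical choices and the limitations.

## Generating trees

Two rooted binary trees on 32 taxa sit at the extremes of tree shape:

- **Symmetric** — the fully balanced tree; every leaf at depth 5. All edges
  have length 1, which makes the tree ultrametric with unit node spacing.
- **Asymmetric** — the fully pectinate (caterpillar) tree. By default it is
  ultrametric with unit node spacing: internal edges have length 1 and each
  terminal branch stretches to the present, so the leaf attached at height
  h carries a branch of length h (lengths 1, 1, 2, …, 30, 30). Deep
  divergences are therefore separated by short internal edges relative to
  long terminal branches.

The ultrametric convention for the caterpillar is a deliberate design
choice. A caterpillar with unit lengths on *every* edge is nearly trivial
to reconstruct (with 1000 calibrated characters, equal-weights parsimony
recovers it almost exactly) and shows no depth gradient in node recovery.
The ultrametric form produces the two phenomena this study design exists to
expose: substantially lower accuracy on the asymmetric tree than the
symmetric one, and node recovery that improves towards the tips. The
unit-length variant remains available (`ultrametric=False`,
`assign_branch_lengths`).

Branch lengths are expected substitutions per site before the
replicate-level rate multiplier (below) is applied.

## Character simulation

Characters evolve as nucleotides under HKY with continuous gamma rate
variation, then are recoded to discrete morphological states:

- transition/transversion ratio κ = 2; stationary frequencies
  π = (0.2, 0.2, 0.3, 0.3) in A,C,G,T order. The uneven π ensures the
  generating process is *not* an Mk model, so no analysis method matches
  the generator exactly.
- per replicate, the gamma shape α (with rate set equal to the shape, so
  per-character rates have mean 1) and the overall substitution rate μ are
  drawn i.i.d. Exponential(mean 1). μ rescales every branch length.
- per character, a rate r ~ Gamma(α, α); the transition matrix on an edge
  of length b is P(b·μ·r), computed from the eigendecomposition of the
  normalised HKY generator.
- recoding: 55% of columns (rounding half-up) become binary by
  purine/pyrimidine (R/Y) coding (A,G → 0; C,T → 1); the rest map
  A,C,G,T → 0,1,2,3. Because π_A+π_G = 0.5, binary characters are
  symmetric. Which columns become binary is uniform per replicate.

Matrix sizes are 100, 350 and 1000 characters. Everything is deterministic
given (tree, parameters, seed).

## Homoplasy calibration

Matrices are admitted by rejection sampling until the among-matrix
distribution of the ensemble consistency index, CI = Σ mᵢ / Σ sᵢ (minimum
conceivable changes over realised parsimony steps; invariant characters
excluded from both sums), matches a target histogram on [0.26, 1.0] in
0.05-wide bins (first bin [0.26, 0.30), last closed at 1.0). Draws outside
the range are discarded; per-bin quotas come from the largest-remainder
method.

Two choices matter here:

- **CI reference tree.** Candidate matrices are scored on the generating
  tree (`ci_tree="generating"`): cheap, deterministic, and — in our
  measurements — indistinguishable from the alternative in the resulting
  per-cell accuracy at 100 characters while clearly better calibrated at
  1000. The alternative `ci_tree="mp"` scores each candidate on its own
  heuristically found most-parsimonious tree (single random-addition start
  plus NNI, the addition guided on a ≤256-column subsample for wide
  matrices), which is how empirical CI values are reported; it is kept as
  an option because MP-tree CIs saturate at 1.0 for weak matrices, which
  biases the upper bins toward information-poor draws.
- **Target density.** The default is a triangular density peaking near
  CI = 0.6, a documented stand-in for the empirical distribution of CI in
  published morphological matrices; any `HomoplasyTarget` may be supplied.

Wide matrices can make individual extreme bins practically unreachable
(1000-character matrices jump from CI ≈ 0.85 to exactly 1.0). The sampler
is strict by default (quota histogram matched exactly, error on stall with
a per-bin shortfall report); the study runner enables a bounded fallback
(`reallocate_after`) that converts any still-unfilled quota into wildcard
slots after a fixed number of draws, recorded in the acceptance log.

## Inference methods

All methods return a single summary topology per replicate: the strict
majority-rule consensus (> 0.5) of their tree sample.

- **Equal-weights parsimony (EW).** Score = total Fitch steps. Search:
  greedy random-addition starting trees (10 starts) with greedy NNI
  hill-climbing; all distinct topologies tying the best score found (cap
  500) feed the consensus. SPR neighbourhoods are available and are used
  in the exhaustive-equivalence tests; on ≤7 taxa the search matches full
  enumeration over all (2n−5)!! topologies.
- **Implied-weights parsimony (IW).** Goloboff fit F = Σ k/(k+eᵢ) with
  eᵢ = sᵢ − mᵢ and concavity k = 2, maximised with the same search
  machinery (internally minimising Σ eᵢ/(eᵢ+k)).
- **Maximum likelihood, Mk+Γ.** Lewis's k-state symmetric model with
  per-character state count kc = max(observed states, 2) (states relabelled
  to 0..kc−1), uniform root frequencies, and 4 equal-probability discrete
  gamma categories (exact conditional bin means, renormalised to mean 1).
  Likelihoods by Felsenstein pruning with per-node rescaling. Search:
  parsimony starting tree; per-edge Brent optimisation of branch lengths
  from inside/outside partials (Jacobi-style passes with an
  accept-only-if-better guard), bounded shape optimisation, a joint polish
  along the (tree length, shape) ridge, and best-improvement NNI. ML output
  is one fully resolved tree; its "consensus" is itself. The Mkv variant
  (likelihood conditioned on characters being variable) is available for
  empirical matrices that exclude constant characters; the simulated data
  has no such ascertainment bias, so the study uses plain Mk.
- **Bayesian, Mk+Γ.** Metropolis–Hastings over topology (NNI and a
  fixed-length SPR variant, both symmetric proposals), branch lengths
  (multiplier moves, clamped to [1e-8, 1e4]) and the gamma shape. Priors:
  i.i.d. Exponential(10) on branch lengths, Exponential(1) on the shape,
  uniform on topologies. The shape is discretised onto a 121-point
  log-spaced grid on [0.02, 50] with prior mass ∝ density × cell width and
  a symmetric random-walk proposal; this keeps the whole chain inside one
  compiled kernel. Proposal mix 40/10/40/10 (NNI/SPR/branch/shape).
  Metropolis coupling (heated chains βᵢ = 1/(1+0.1·i), swap attempts every
  1000 generations) is available and enabled in the paper-scale preset.

The sampler state is a rooted binary tree with all 2n−2 branch lengths
free; since Mk is reversible the likelihood depends only on the unrooted
tree, and a uniform prior over rooted topologies induces a uniform prior
over unrooted ones (each unrooted topology has exactly 2n−3 rootings).
Validation includes prior-only runs (branch-length prior recovered, the
three quartet topologies uniform) and an NNI-only chain whose topology
frequencies match the normalised likelihoods of the three enumerated
quartet topologies.

## Scoring

- **Robinson–Foulds distance:** size of the symmetric difference of the
  non-trivial unrooted bipartition sets (maximum 2(n−3) = 58 at n = 32).
- **Resolution:** non-trivial splits present / (n−3).
- **Per-node accuracy:** for every internal node of the rooted generating
  tree, the percentage of replicate consensus trees containing its
  bipartition; a node counts as recovered only when the exact bipartition
  is present. Node depth is the edge count from the root.
- **Depth–accuracy association:** Spearman rank correlation (average ranks
  for ties) of recovery percentage against depth; positive values mean
  nodes nearer the tips are recovered more often.
- **Convergence:** average standard deviation of split frequencies between
  independent runs (threshold 0.05) and Gelman–Rubin potential scale
  reduction for the shape and tree length.

## Study scales

The full design is 2 shapes × 3 sizes × 1000 replicates = 6000 matrices,
with 1,000,000-generation Metropolis-coupled MCMC (4 chains, 2 runs, every
100th sample stored, 25% burn-in) — the `paper` preset, reported by the
dry-run counter. Desk-scale work uses the `desk` preset: 50 replicates per
cell and 100,000-generation single-run MCMC with a single cold chain. The
test-suite reproductions use 20–30 replicates per cell (8 for the
size-monotonicity cells, with 20,000-generation chains), sizes chosen so
the whole suite completes in minutes while Monte-Carlo error stays well
inside the asserted tolerances.

## Known limitations

- The generating trees' branch lengths are a convention (unit spacing,
  ultrametric caterpillar); empirical studies rarely justify a particular
  choice, and absolute per-cell accuracy is sensitive to it. In
  particular, 100-character matrices on the symmetric tree give mean
  Bayesian/EW RF distances a few units higher here than published
  comparisons that used unpublished branch lengths; the per-CI-bin floor
  of achievable accuracy makes this insensitive to any admissible
  homoplasy target.
- The homoplasy target density is a stand-in; supply an empirical
  `HomoplasyTarget` for calibrated work.
- The parsimony "tree sample" is the set of tied local optima from
  multi-start hill-climbing, not the complete set of most-parsimonious
  trees a branch-and-bound or ratchet search would return.
- The Bayesian shape parameter lives on a discrete grid; topology and
  branch-length inference are unaffected, but the alpha posterior has grid
  granularity (~4% spacing).
- Simulated matrices contain no missing data, no polymorphic codings and
  no character correlation; real morphological matrices have all three.
  Missing data (`?`/`-`) is accepted in user matrices and handled by the
  likelihood and parsimony engines, but is never generated.
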