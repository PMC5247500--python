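# morphobench

Benchmarking phylogenetic inference methods on simulated discrete
morphological characters.

Morphological (phenotype) data are the only way to place fossils — and most
of life's history — on the tree of life, but practitioners disagree about
how to analyse them: classic equal-weights parsimony, implied-weights
parsimony, or probabilistic inference under Lewis's Mk model in a
maximum-likelihood or Bayesian framework. Because the true tree is never
known for real data, the methods can only be compared on simulated
matrices whose generating tree is known. `morphobench` implements such a
study end to end, for method developers and empiricists who want to probe
when and why these methods disagree:

- **synthetic data** — binary/multistate character matrices (55:45 mix)
  simulated under HKY+Γ (κ = 2, π = [0.2, 0.2, 0.3, 0.3], per-replicate
  gamma shape and rate ~ Exponential(mean 1)) on fully symmetric and fully
  pectinate 32-taxon trees, then recoded to morphological states by R/Y
  coding (binary) and base-to-integer mapping (multistate);
- **homoplasy calibration** — rejection sampling until the among-matrix
  consistency index (CI) distribution matches a target histogram on
  [0.26, 1.0], emulating empirical levels of homoplasy;
- **four inference engines** — equal-weights parsimony (Fitch), implied
  weights (Goloboff fit `k/(k+e)`, k = 2), maximum-likelihood Mk+Γ, and
  Bayesian Mk+Γ by Metropolis–Hastings MCMC (optionally
  Metropolis-coupled), all returning majority-rule consensus trees;
- **scoring** — Robinson–Foulds distance to the generating tree,
  resolution, per-node recovery versus node depth, and Spearman
  depth–accuracy correlations.

The core quantities: a character's fit to a tree is its Fitch step count
`s` against the minimum conceivable `m` (observed states − 1); ensemble
CI = Σm/Σs. The Mk likelihood uses the k-state symmetric transition
probability `P_same(τ) = 1/k + (k−1)/k · e^{−kτ/(k−1)}` averaged over four
discrete gamma rate categories. See `docs/methods.md` for the full model
and design description.

## Worked example

```python
import numpy as np
from morphobench import (MCMCConfig, make_asymmetric_tree, run_mcmc,
                         rf_distance, resolution)
from morphobench.homoplasy import (bin_match_sampler, ci_matrix_generator,
                                   default_homoplasy_target)

tree = make_asymmetric_tree(32)                  # pectinate generating tree
gen = ci_matrix_generator(tree, n_characters=100)
matrices = bin_match_sampler(gen, default_homoplasy_target(), 3, seed=11)
for i, m in enumerate(matrices):
    sample = run_mcmc(m, MCMCConfig(n_generations=100_000, n_runs=1), seed=i)
    cons = sample.consensus()
    print(f"CI={m.ci:.2f}  RF={rf_distance(cons, tree)}  "
          f"resolution={resolution(cons):.2f}")
```

prints (one line per replicate matrix):

```
CI=0.59  RF=29  resolution=0.34
CI=0.61  RF=26  resolution=0.10
CI=0.70  RF=29  resolution=0.00
```

Each accepted matrix reports its consistency index, the Robinson–Foulds
distance between the Bayesian majority-rule consensus and the true tree
(0 = identical, 58 = maximal disagreement at 32 taxa), and the fraction of
the 29 possible internal splits the consensus resolves. On 100-character
pectinate-tree data all methods are far from the truth — the point the
benchmark is designed to quantify.

The same machinery runs from the shell:

```bash
morphobench simulate --shape asymmetric --n-characters 100 --n-matrices 5 --out data/
morphobench infer data/asymmetric_100_0000.nex --method bayes --out tree.nwk
morphobench evaluate tree.nwk data/asymmetric_generating.nwk
morphobench run-study --preset desk --out study_results/
```

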