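# divergrass

Diversification analyses for binary-trait phylogenies: did a derived
character state — the motivating case is C4 photosynthesis in grasses —
elevate lineage diversification?

The package implements, as a tested library with a thin CLI, the three
complementary analyses used to answer that question on large
time-calibrated trees:

1. **State-dependent birth–death (BiSSE) likelihoods.** A binary character
   (C3 = 0, C4 = 1) evolves on a tree whose speciation, extinction and
   transition rates depend on the state: parameters
   (λ₀, λ₁, μ₀, μ₁, q₀₁, q₁₀), all in events · lineage⁻¹ · My⁻¹. The
   likelihood integrates, backward in time along every branch,

       dE_i/dt = μ_i − (λ_i + μ_i + q_ij) E_i + q_ij E_j + λ_i E_i²
       dD_i/dt = −(λ_i + μ_i + q_ij) D_i + q_ij D_j + 2 λ_i E_i D_i

   combining daughter lineages at each node as
   D_i ← λ_i · D_i^left · D_i^right. Missing diversity enters either
   *proportionally* (tip initial conditions D_i = f·1[state = i],
   E_i = 1 − f for a global sampling fraction f) or as *unresolved clades*
   of known species richness, whose D is computed from the truncated
   master equation over joint lineage counts. A constrained model family
   (equal-diversification λ₀=λ₁, μ₀=μ₁; equal-speciation; equal-extinction;
   full) supports likelihood-ratio tests and AICc comparison, singly or
   across replicate tree sets.

2. **Stepwise rate-shift detection (MEDUSA-style).** A tree with
   terminally unresolved richness is modeled piecewise by birth–death
   regimes (r = λ − μ, ε = μ/λ). Resolved internal branches contribute the
   reconstructed-process density; each tip of richness n at stem age t
   contributes the clade-size probability with geometric parameter
   β(t) = (e^{rt} − 1)/(e^{rt} − ε). A greedy forward search adds one
   shift at a time wherever AICc improves by at least a threshold
   (presets 8.4547, 10.5 and 17).

3. **Sister-clade contrasts.** Under irreversible-gain parsimony, each
   maximal C4 clade whose sister is entirely C3 yields a directly
   comparable richness pair; log richness differences are tested with an
   exact Wilcoxon signed-rank test (null by enumeration up to n = 25,
   midranks for ties).

Supporting modules handle composite-tree assembly (root-age rescaling,
grafting calibrated subtrees over placeholder pairs, collapsing to genus
representatives with largest-remainder richness splitting) and seeded
simulation of every data-generating process the analyses assume.

## Worked example

Simulate a 300-tip tree under the package's standard study conditions
(C3 net rate 0.10, C4 net rate 0.20, relative extinction 0.5), then ask
whether the character state affects diversification:

    $ divergrass simulate bisse --seed 42 --tips 300 --out grass
    wrote grass.nwk (300 tips) and grass.tips.tsv

    $ divergrass bisse --tree grass.nwk --tips grass.tips.tsv \
          --models equal,full --seed 1 --json bisse.json

The JSON output contains, per model, the fitted rates and log-likelihood,
and the nested comparisons. For this seed:

    equal_diversification  k=4  lnL=-892.168  r0=0.1288  r1=0.1288
    full                   k=6  lnL=-887.035  r0=0.1418  r1=0.1328
    LRT: stat=10.266  df=2  p=0.0059

The likelihood-ratio test rejects equal diversification (p ≈ 0.006): the
two states demonstrably diversify under different dynamics. Note what the
rates say: on this single realization the *net*-rate point estimates are
nearly equal — the signal sits in the separate speciation and extinction
rates, and net-rate contrasts from one 300-tip tree are noisy (the methods
note quantifies this). Across replicate trees the simulated twofold C4
advantage is recovered in sign in ~90% of 500-tip datasets.

The sister-clade contrast on the same data:

    $ divergrass sisters --tree grass.nwk --tips grass.tips.tsv --json sis.json
    pairs: 33   W=73.5   p_greater=0.5595

Thirty-three C4 origins have entirely-C3 sisters here; with richness 1 per
tip (no assigned diversity) the contrast is weak on a single simulated
tree, as expected.

Shift detection on a tree with one planted fivefold rate acceleration:

    $ divergrass simulate shift --seed 7 --max-age 36 --shift-age 8 \
          --base-r 0.1 --shift-r 0.5 --out sh
    $ divergrass medusa --tree sh.nwk --threshold 10.5 --json shifts.json

finds exactly one shift on (or adjacent to) the planted branch in ≥ 80%
of such replicates, with ≤ 10% false positives on homogeneous trees.

## Layout

    src/divergrass/
      phylo_core.py       tree model, Newick/Nexus I/O, LTT, clade queries
      tree_assembly.py    rescaling, grafting, genus collapsing, richness
      bisse.py            state-dependent likelihoods, fits, comparisons
      _sse_core.py        numba ODE/pruning kernel
      medusa.py           piecewise birth-death + stepwise AICc search
      sister_contrasts.py sister pairs + exact signed-rank test
      synthetic_data.py   seeded simulators for all of the above
      cli.py              `divergrass` command-line entry points
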