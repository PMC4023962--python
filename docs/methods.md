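# Methods

This note documents the models, numerical choices and design decisions
behind `divergrass`, and what the synthetic-data tests do and do not show
about real data.

## Data model

Trees are rooted, ultrametric, time-calibrated in million years (My), with
node ages measured backward from the present (tips at age 0). A tree whose
tip depths spread more than `1e-6 × root age` is rejected unless the
caller asks for proportional terminal-branch adjustment; composite trees
assembled from separately calibrated pieces are constructed ultrametric,
so a violation indicates corrupted input rather than something to repair
silently. Polytomies are resolved arbitrarily with zero-length branches
(with a warning) because the SSE pruning pass is defined on bifurcations;
a zero-length resolution leaves the likelihood of any parameter set
unchanged relative to treating the polytomy as simultaneous branching.

Per-tip data are a table of `tip_label`, binary state (0 = C3, 1 = C4, NA
= unknown) and assigned species richness, plus a sampling mode. In
*proportional* mode every tip is one sampled species and a global
sampling fraction `f` (the study's values were 0.2973 for the whole
family and 0.2966 for the focal subclade) enters the tip initial
conditions. In *unresolved* mode a tip stands for a clade of known
richness attached at its stem, and `f` inside the clade is 1.

## State-dependent birth–death likelihood

The branch ODEs and node combination follow the standard two-state
speciation–extinction construction; all rates are per-lineage per-My.
Numerical choices:

- **Integrator.** An embedded Dormand–Prince 5(4) pair with adaptive step
  control, `rtol = 1e-8`, `atol = 1e-10`, compiled with numba. The
  correctness reference in the test suite is an independent fixed-step
  RK4 integrator at `h = 1e-4`, written separately in plain Python;
  agreement on random 10-tip trees is required to 1e-6 relative.
- **Underflow.** Whenever max(D₀, D₁) drops below 1e-50 during the
  pruning pass, D is renormalized and the discarded magnitude accumulated
  in a log-scale factor, so log-likelihoods remain finite on trees far
  larger than double precision would otherwise allow. This replaces the
  manual clade-merging workaround such analyses historically needed.
- **Root treatment.** Default is likelihood-weighted state mixing (each
  state weighted by its relative D at the root); flat, equilibrium
  (stationary distribution of the q's) and given-state options are flags,
  as is conditioning on the survival of both root lineages. The weighted
  default is symmetric and assumption-free, but note that on datasets
  where the two states' histories are nearly exchangeable it permits a
  mirror-image solution (the "C4-rooted" reading of a C3-rooted history);
  when the root state is known — as it is for simulated data and arguably
  for grasses — the given-state treatment is better specified and is what
  the calibration experiments use.

### Unresolved clades

D for a richness-n tip is the probability that one lineage in state i at
the stem produces exactly the observed count (and state tally, when
known) at present, obtained by exponentiating the truncated master
equation over joint counts (n₀, n₁) with n₀ + n₁ ≤ cap (sparse
`expm_multiply`). Default cap is `richness + 200` with a leak tolerance
of 1e-7. The leak check is deliberately conservative: probability mass
that crosses the cap essentially never returns to small counts, so the
computed P(n_obs) is far more accurate than the total leaked mass
suggests. For clades whose stem is deep enough that the *expected* size
e^{rt} approaches the cap, the check fires; callers can raise the cap or,
knowingly, loosen `mass_tol` — the consistency tests on deep-stem
fixtures do the latter and document it here. Reducing a richness-1,
known-state clade recovers the resolved-tip initial condition to 1e-6,
and the μ = q = 0 limit reproduces the Yule geometric closed form.

### Fitting and comparison

Constrained models are equality partitions of the six rates
(equal-diversification k=4, equal-speciation k=5, equal-extinction k=5,
full k=6). Optimization runs in log-rate space (bounds e⁻¹⁵…e³) with
L-BFGS-B from 5 deterministic starts: an unperturbed moment start (net
rate from ln(n_effective/2)/root-age at ε = 0.5; transition rates from
the Fitch parsimony change count over total branch length) plus seeded
lognormal perturbations (σ = 0.5). Nested pairs are compared by
2ΔlnL against χ² with df = Δk; AIC/AICc are reported alongside, AICc
with n = number of tips.

**What recovery simulations show.** Under the standard study conditions
(below), 20 fits on 500-tip trees recover the speciation rates with ~10%
median error and the sign of the C4 − C3 net-rate contrast in ~90% of
replicates, and the equal-diversification LRT holds its nominal 5% size
(rejections within the exact binomial interval over 200 null
simulations of 100 tips). Extinction rates are a different matter:
their median relative error is 30–65% at n = 500. This is a property of
the estimation problem, not of the optimizer — the fitted likelihood
exceeds the truth's on these datasets — and mirrors the well-documented
difficulty of estimating extinction from reconstructed phylogenies.
Conclusions that rest on μ̂ (or on q estimated from few transitions)
should be treated as qualitative at this scale.

## Piecewise birth–death with richness (shift detection)

Each regime is parameterized by (r, ε) with ε ∈ [0, 0.999]; λ = r/(1−ε).
A shift on a branch governs that branch and its entire subtree
(stem-inclusive); every branch maps to the nearest rootward shift. The
log-likelihood of a regime is

- one ln λ per internal node assigned to the regime (root included),
- a transport factor ln g(t_old) − ln g(t_young) per internal branch,
  with g(t) = e^{−rt}(1 − E(t))² and E the extinction probability, and
- per tip, the *unconditioned* clade-size probability
  (1 − E(t))·(1 − β)β^{n−1}, β = (e^{rt} − 1)/(e^{rt} − ε), t the stem age.

The public `richness_loglik` reports the survival-conditioned geometric
(the natural standalone quantity); inside the joint likelihood the
survival factor (1 − E) must be kept, otherwise extinction is
unpenalized and ε escapes to its upper bound — an error mode we verified
against `ape::birthdeath`, which the corrected likelihood matches
(r̂ 0.0895 vs 0.0908, ε̂ 0.514 vs 0.495 on the same 162-tip tree).
Richness-1 tips make the tip terms collapse into ordinary terminal-branch
transport factors, so the model reduces exactly to a resolved-tree
birth–death fit. Root-survival conditioning is on by default (flag).

Per-regime (r, logit ε) maximization uses Nelder–Mead from 3
deterministic starts around a Yule-style moment guess. The greedy forward
search scans every non-root branch, accepts the best AICc improvement if
it is at least the threshold (ties: older stem age, then clade label; a
single optimizer start during scanning, full refit on acceptance), with
AICc = −2lnL + 2k + 2k(k+1)/(n−k−1), k = 3·regimes − 1,
n = internal nodes + richness data. The thresholds are explicit
configuration with presets 8.4547 (the genus-level default from the tree
size formula of the original method, not re-derived here), 10.5
(conservative) and 17 (full-tree runs); the full-tree convention assigns
every sampled tip richness 1 rather than spreading unsampled diversity.

Power under the standard conditions: a planted fivefold net-rate shift
(subclade ≥ 50 tips, trees ~100–300 tips) is found on the true branch or
an immediate neighbor in ≥ 80% of replicates at threshold 10.5, with
≤ 10% false positives on homogeneous trees.

## Sister contrasts

A C4 origin is the MRCA of a maximal connected set of C4 tips
(irreversible-gain parsimony); pairs require an entirely C3 sister, with
unknown-state tips disqualifying a sister. Richness sums over clade tips.
The signed-rank test drops zero differences (n reduced), midranks ties,
and enumerates the exact null through the standard convolution over sign
assignments (ranks doubled to stay integral under midranks) for n ≤ 25,
switching to a normal approximation with continuity and tie corrections
above. P-values are invariant to the log base and to common scaling of
all richness values, and the exact path matches `scipy.stats.wilcoxon`
on tie-free data.

## Composite-tree assembly

`scale_to_root_age` multiplies every branch by target/current root age.
`graft` replaces a two-tip placeholder clade by a subtree rescaled to a
target crown age, reusing the placeholder's stem so all outside node ages
are untouched; grafts require an explicit manifest (attachment labels,
subtree, crown age) because composite-tree studies rarely record their
graft order. Genus collapsing keeps one representative per genus (the
lexicographically first tip by default — "most sequence data" is not
recoverable from a tree, and determinism matters more; the policy is
pluggable), splits mixed C3/C4 genera into the minimum number of
state-pure clades, divides genera above 190 species among
⌈size/190⌉ representatives, and spreads designated polyphyletic genera
evenly across their tips before block collapsing. All integer divisions
use largest remainder, so richness is conserved exactly — fractional
species would break the unresolved-clade likelihoods.

## Synthetic data: what it emulates, what it does not

The generators produce forward Gillespie simulations of the exact
processes the likelihoods assume: state-dependent birth–death with
character flips, piecewise constant-rate birth–death with one planted
regime shift, Bernoulli tip subsampling, genus-style monophyletic
collapsing, and age-jittered replicate tree sets standing in for a
posterior sample. Simulations start from a root split (two lineages;
single-lineage origin by flag) and condition on survival by seeded
rejection with a retry cap of 1000.

Standard study conditions, fixed once: λ = (0.20, 0.40),
μ = (0.10, 0.20), q = (0.04, 0.06), root state C3. The net rates 0.10 vs
0.20 mirror the C3/C4 contrast the motivating study estimated; ε = 0.5
reflects substantial relative extinction as inferred for grasses; the
transition rates are far above the study's MLEs (~0.007 and below)
because transitions must happen repeatedly on a ~30 My simulated tree to
be estimable at all, and because they keep the tip-state mix near the
roughly balanced proportion real grass trees show. Test tree sizes
(10–500 tips; 20 recovery replicates, 200 null LRT replicates, 50 power
replicates) are the package's standard simulation sizes.

Passing tests on these data show internal consistency: the likelihoods
match their generating processes, estimators are calibrated under the
model, and detection has the stated power against the planted
alternative. They do not establish robustness to what real phylogenies
add — calibration error, topological uncertainty beyond node-age jitter,
non-binary or mis-scored characters, diversity-dependent or time-varying
rates, or state-dependent sampling — and the estimator caveats above
(extinction rates, root-mode multimodality) apply with extra force there.

## Known limitations

- Extinction-rate and low-transition-rate estimates are imprecise at
  realistic tree sizes (quantified above); the LRT for state-dependent
  diversification is well calibrated regardless.
- The unresolved-clade master equation is quadratic in the cap; deep-stem,
  fast-growing clades need caps that make it expensive, which is why
  genus-level analyses should attach unresolved tips at shallow stems
  (the 190-species splitting rule exists for exactly this reason).
- The stepwise search is greedy: one shift per step, no removal step, so
  closely nested shifts can shadow each other.
- Wilcoxon p-values for n > 25 use the normal approximation (continuity
  and tie corrected), accurate to ~0.01 at the switchover.
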