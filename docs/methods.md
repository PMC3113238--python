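# Methods

## The model

A genome-scale metabolic reconstruction is reduced to an undirected,
unweighted bipartite graph: M metabolites, R reactions, and L links
(m, r) stating that metabolite m participates in reaction r. Substrates and
products are not distinguished and stoichiometry is discarded; everything
below operates on this topology alone.

### Hierarchical random graph over a bipartite network

The generative model places the M + R network nodes at the leaves of a
rooted binary tree (dendrogram). Each of the M + R − 1 internal nodes t
carries a connection probability ρ_t, and every metabolite–reaction pair
whose lowest common ancestor (LCA) is t is linked independently with
probability ρ_t. Writing E_t for the number of observed links whose LCA is
t and ε_t for the number of possible such links,

    ε_t = Lm_t · Rr_t + Lr_t · Rm_t ,

where Lm_t/Lr_t (Rm_t/Rr_t) count metabolite/reaction leaves in the left
(right) subtree of t — only cross-class pairs can be links, so an internal
node whose branches hold a single node class has ε_t = 0 and contributes
nothing. The log-likelihood of a dendrogram D is

    log L(D) = Σ_t [ E_t log ρ_t + (ε_t − E_t) log(1 − ρ_t) ] ,

with the 0·log 0 = 0 convention, and for a fixed topology it is maximized
by ρ_t = E_t / ε_t (the profile likelihood used throughout). The tree
distance of a pair is d_mr = 1 − ρ_t at its LCA.

### MCMC over tree space

Dendrogram space is explored by Metropolis–Hastings. A proposal picks a
non-root internal node t uniformly, one of its two child branches
uniformly, and exchanges it with t's sibling branch (the branch attached at
t's parent). The move is self-inverse and selected with equal probability
in both directions, so the kernel is symmetric; branch swaps connect all of
tree space, so the chain is ergodic and its stationary distribution is
proportional to L(D). Proposals that do not decrease the likelihood are
always accepted; otherwise acceptance has probability exp(Δ log L). Only
the two affected internal nodes change their (E_t, ε_t) bookkeeping, so a
step costs far less than a full recount.

After burn-in, dendrograms are sampled at fixed proposal-count intervals
and ρ at each pair's LCA is averaged into ρ_mr. Sampling is deliberately
scheduled in proposals, not accepted moves: sampling at acceptance events
draws from the jump chain of the sampler, which under-weights
high-likelihood states exactly in proportion to how rarely they are left.
On the 5-leaf path network, where all 105 dendrograms can be enumerated,
proposal-scheduled samples reproduce the exact likelihood-weighted ρ_mr
while acceptance-scheduled samples converge to visibly shifted values; the
test suite pins the correct behaviour.

Each sampled dendrogram satisfies Σ_t ε_t ρ_t = Σ_t E_t = L, so the
averaged matrix obeys Σ_mr ρ_mr = L identically — the raw hierarchical fit
is globally calibrated by construction.

### Degree-corrected connection probabilities (TDB)

Trees compress degree heterogeneity: a currency metabolite attached to
half of all reactions cannot be "close" to all of them simultaneously. The
Tree Distance Bipartite model therefore corrects the fitted distance with
the metabolite degree k_m:

    p_mr = 1 / (1 + d_mr / (μ k_m)) ,   μ = 1/R .

The form is monotone decreasing in the distance, non-decreasing in the
degree, and calibrated: a pair at maximal distance (d = 1) has
p = k_m/(k_m + R) ≈ μ k_m, and Σ_m k_m = L makes the expected link count
track L. Measured on fitted synthetic networks the ratio Σ p_mr / L stays
within a few percent of 1 across sizes and structures.

This calibration has a structural consequence worth stating: because far
pairs sit *at* the configuration-model baseline μ k_m rather than below
it, the degree-corrected model penalizes dispersed metabolite sets only
mildly. Relative scores (below) are therefore compressed toward 1 at small
network sizes; strong anticorrelation signals require the long distances
of full-scale networks.

### Reaction scores

A reaction is identified with its metabolite set ν. Under pair
independence, the probability that exactly ν occurs at reaction slot r is

    P(ν, r) = Π_{m∈ν} p_mr · Π_{m'∉ν} (1 − p_m'r) ,

and the absolute score is the expected number of co-occurrences over all R
reaction slots, n_ν = Σ_r P(ν, r) (the scored reaction's own slot
included). Scores span many orders of magnitude, so all products are
evaluated in log space and summed via the max-shift trick.

The null is the configuration model for bipartite networks (CMB):
degree-preserving, otherwise maximally random, with pair probability
p_mr = k_m k_r / L (clamped at 1, with a warning). Because reaction degrees
are nearly homogeneous, k_r ≈ ⟨k_r⟩ makes all R slot terms equal and the
null score closed-form:

    S_CMB(ν) = R · Π_{m∈ν} p_m · Π_{m'∉ν} (1 − p_m') ,
    p_m = min(1, k_m ⟨k_r⟩ / L) .

Since ⟨k_r⟩ R = L, p_m = μ k_m exactly. The relative score Σ =
S_TDB / S_CMB reads off tree-distance correlations: Σ > 1 means the
reaction's metabolites aggregate in the fitted metric relative to the
degree-preserving null, Σ < 1 that they avoid each other.

The common-neighbours (CN) baseline scores a pair (m, r) by
Σ_{m'∈ν(r), m'≠m} o_mm', where o_mm' counts reactions in which m and m'
co-occur — excluding co-occurrence contributed by r itself. Without that
leave-one-out every observed link would carry automatic self-support of
about k_r − 1 while absent pairs carry none, and the measure would grade
its own input rather than predict; with it, CN behaves like the weak local
baseline it is meant to be. CN feeds only rank-based validation, so its
normalization is irrelevant.

## Validation

Positives are observed links, negatives all M·R − L absent pairs (no
subsampling). The ROC curve sweeps the distinct predicted values as
thresholds; the AUC is computed by the Mann–Whitney rank formulation with
ties credited 1/2, which equals the trapezoidal ROC area exactly (both
routes are kept and compared in tests). The link-removal statistic removes
⌊fraction · L⌋ links uniformly at random, refits on the remainder
(isolated nodes are retained at degree 0), and measures the AUC of removed
links against never-present pairs; it runs repeatedly and reports the
spread. Calibration bins all pairs by predicted probability (equal-width
bins) and compares each bin's observed link fraction with its mean
prediction.

## Synthetic data

Two generators produce networks with the statistical structure the method
assumes, so every experiment runs without external data.

* **Degree-sequence (CMB) generator** — metabolite degrees from a discrete
  power law P(k) ∝ k^(−γ), default γ = 2.2 with natural cutoff; reaction
  degrees 1 + Binomial(12, 0.32), giving mode 5 and mean ≈ 4.8. Because a
  unit-minimum power law cannot reach the mean degree the reaction side
  implies, the metabolite sequence is rescaled multiplicatively (which
  preserves the log–log slope) before stub matching; the integer remainder
  is spread by unit increments. Stub matching avoids multi-edges; blocked
  terminal configurations are untangled by random degree-preserving edge
  swaps, with an error if a bounded number of attempts fails.
* **Planted hierarchy** — blocks of metabolites and reactions at the
  leaves of a block tree; each pair connects independently with the
  density at its blocks' LCA, optionally modulated by per-metabolite
  weights. The exact generating probability matrix is returned, providing
  ground truth for recovery and calibration tests.

### The scaled benchmark

`metabolic_benchmark()` combines the features of curated bacterial
reconstructions that the scoring models respond to, at roughly 1:10 scale
(defaults ~100 metabolites × ~150 reactions): eight currency metabolites
attaching to every reaction with graded probabilities 0.55–0.20 (the
atp/h2o/pi analogues; they produce hubs touching up to half of all
reactions), eight pathway blocks in a three-level hierarchy (densities
0.10 / 0.03 / 0.010 / 0.003) over the specific metabolites with mild
Pareto weights, and one planted twelve-metabolite reaction over rare,
anchored metabolites — the analogue of the largest and least probable
reaction in a reconstruction, kept the sole largest by trimming currency
links from any generated reaction that would tie it. The defaults land on
mean reaction degree ≈ 4.8–5.2 with mode near 5 and a heavy metabolite
degree tail.

What the benchmark does not emulate: compartment structure, reaction
reversibility, stoichiometry, and — importantly — full-scale sparsity. At
matched degree statistics a 10× smaller network is roughly 10× denser,
which systematically flattens score contrasts and makes local-overlap
baselines stronger than they are at genome scale. Passing tests on the
benchmark therefore demonstrate correct machinery and the right *ordering*
of models, not the published magnitudes to high precision.

## Numerical and scheduling choices

* Likelihood is computed and compared in log space; ties at Δ log L = 0
  are accepted.
* ε_t = 0 nodes store ρ_t as NaN; they are never the LCA of a
  metabolite–reaction pair, so no pair probability depends on them.
* Initial state: balanced tree over a uniformly shuffled leaf order.
* Defaults: burn-in 50·(M+R)² proposals, 10³ samples, sampling interval
  M + R proposals. Experiments in this repository use explicit scaled-down
  schedules (2·10⁶ burn-in proposals, 500 samples for the ~250-leaf
  benchmark; proportionally less for smaller fixtures), chosen so that the
  equilibrium diagnostic below is quiet and a full validation run
  completes in minutes.
* Equilibrium diagnostic: on the recorded burn-in trace, (a) a linear
  drift over the last window large relative to the residual fluctuation,
  or (b) a final-quarter mean more than `eq_tol` (default 3) standard
  deviations above the preceding quarter, raises a warning. Tree-space
  chains equilibrate slowly — on the benchmark the log-likelihood still
  creeps upward by ~2 standard deviations per quarter after 2·10⁶
  proposals — so the diagnostic flags clear under-burning, not certified
  stationarity; averaged pair probabilities are far less sensitive to the
  residual creep than the raw likelihood.
* Score-table ranks are descending with ties broken stably by reaction
  id; Σ is undefined (NaN, flagged) where S_CMB = 0.
* Reproducibility: every stochastic routine takes a seed or Generator;
  identical seeds give byte-identical outputs.

## Known limitations

* The relative-score compression at small scale discussed above: the
  calibrated degree correction bounds how far below 1 the relative score
  of a dispersed metabolite set can fall, so the extreme anticorrelation
  values reported for full-scale networks are not reproduced at benchmark
  size (the minimum-Σ identity check in the acceptance suite documents
  this honestly rather than loosening itself).
* MCMC cost grows roughly with (M+R)² per the default burn-in; the
  pure-Python sampler handles hundreds of leaves in minutes but is not
  sized for genome-scale fits in one sitting — those need hours, as
  expected for this class of model.
* CN leave-one-out, the Fermi-function body of the degree correction, and
  the analytic null's mean-degree substitution are the package's own
  resolutions of underdetermined details; each is pinned by tests at the
  level of the contracts stated here (monotonicity, calibration,
  rank-ordering), not by external reference values.
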