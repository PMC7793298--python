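# Methods

`trophoguild` implements a quantitative pipeline for defining consumer
trophic guilds from gut-content data and predicting both guild
membership and pairwise trophic interactions from phylogeny and body
size. This note documents the models, the numerical choices, and what
the synthetic-data experiments do and do not establish.

## Gut-content standardization

Raw records are one row per individual × prey item with the fraction of
gut volume (or frequency) that item represents. Standardization has
three steps:

1. **Crosswalk.** Heterogeneous raw prey labels are mapped onto 38
   canonical prey groups (mostly phylum/class; crustaceans at
   order/superorder; plus the non-taxonomic groups *detritus*,
   *inorganic* and *zooplankton*). A label may split across two groups
   with weights summing to 1 (the historical "Algae & Detritus" label is
   divided equally between *detritus* and *benthic autotroph*), or be
   discarded as non-informative. The packaged group list is a synthetic
   analog assembled from the prey taxa named in reef food-web work; user
   crosswalks may add labels but not groups.
2. **Sampling filter.** Species with fewer than 10 non-empty guts are
   dropped (configurable `min_guts`).
3. **Aggregation.** Each individual's proportions are renormalized to
   sum to 1 (discards make totals fall short of 1), then averaged with
   *equal weight per individual* within a consumer node — either a
   species or a species × location pair. Equal weighting per individual
   is the neutral choice where pooled-volume weighting is not
   defensible from the records; pooling across locations likewise
   weights individuals, not locations, equally. Row sums are exact to
   1e-9 after a final renormalization; raw inputs are validated to a
   1e-6 tolerance.

## Guilds as network modules

The diet matrix is a weighted bipartite network (consumers × prey
groups, weights = diet proportions, so rare or accidental prey carry
little weight by construction). Guilds are consumer-side modules that
maximize Barber's weighted bipartite modularity

    Q = (1/m) Σ_ij (W_ij − r_i c_j / m) · 1[g_i = h_j],

with m the total weight and r, c row/column strengths. The optimizer is
a label-propagation scheme in the LPAwb+ family: within a pass one
side's labels are fixed, so each node's best label is obtained from a
single matrix product; passes alternate until stable (synchronous
updates may 2-cycle, which is detected and cut off), followed by greedy
module merging and single-node hill climbing iterated to a fixpoint.
Restarts alternate three seeded initializations (singleton consumer
modules, coarse random consumer labels, random joint labels). Each run
is deterministic given its seed. On exhaustively enumerable networks
(≤10 nodes) the optimizer with 30 restarts attains the global maximum
in ≥95% of random instances (tested).

Because the first step is stochastic, the analysis runs the optimizer
500 times and keeps the **medoid** partition — the run minimizing the
summed variation of information (VI = H₁ + H₂ − 2I, natural log) to all
other runs, ties broken by run index. Identical partitions are grouped
before the O(n²) VI computation. Regional robustness is summarized as
the fraction of species sampled in more than one location whose
location-nodes fall in a single module; the pooled (global) network is
used for all downstream stages.

## Phylogenetic conservatism (δ)

δ measures how much the tree "knows" about the guild labels. Marginal
ancestral state probabilities are computed at every internal node under
an equal-rates Mk model — the transition probabilities have the closed
form P(same) = 1/K + (K−1)/K · exp(−qKt/(K−1)) where q is the total
leave rate — with q fitted by maximum likelihood (bounded search on
log q) and a uniform root prior. Each node's uncertainty is summarized
by a piecewise-linear entropy analog in [0, 1] (probabilities above 1/K
contribute (1−p)/(K−1), the rest contribute p; a point mass scores 0,
the uniform vector 1). The collection of node uncertainties is modeled
as a Beta(α, β) sample with Exponential(0.1) priors on both shape
parameters, and δ = β/α: strongly conserved traits give uncertainties
piled near 0, hence small α and large δ. By default δ is the posterior
mode (deterministic); a seeded Metropolis mode returns the posterior
mean of β/α instead. The linear uncertainty index and the exponential
regularization keep δ finite and stable when reconstructions are nearly
certain; the Shannon form with a raw maximum-likelihood Beta fit is far
noisier there.

δ's absolute scale depends on tree size, trait balance and the K level,
so significance always comes from a trait-shuffling null: the labels
are permuted across tips (rate refitted each time) and
p = (1 + #{δ_null ≥ δ_obs}) / (1 + n_shuffles). By exchangeability this
p-value is exactly calibrated, which the test suite confirms
empirically. Power is high for well-populated conserved guilds but
intrinsically limited for nearly monomorphic traits (a trait carried by
62 of 64 species looks conserved under any shuffle); the power
experiment therefore conditions the generator on every guild holding at
least a handful of species, which matches assemblages where every guild
is populated. Zero-length branches are clamped to 1e-8 with a warning.

## Bayesian multinomial phylogenetic regression

Guild membership is a reference-category multinomial logit:

    Pr(k) = exp(mu_k) / Σ_j exp(mu_j),  mu_1 = 0,
    mu_k = β0_k + β1_k · ln(sizemax) + γ_{·k},   k = 2..K,

with a per-category phylogenetic random effect γ_{·k} ~ N(0, σ_k² C).
C is the Brownian-motion correlation of the tree (shared root-to-MRCA
path normalized by depth; cov2cor scaling keeps a unit diagonal for
near-ultrametric trees, with a warning otherwise). Priors are weakly
informative — Normal(0, 5) on β0 and β1, Half-Normal(0, 2.5) on each
σ_k — and cross-category correlation of γ is not modeled. ln(sizemax)
is centered internally for sampler stability (β1 is unaffected;
predictions use the stored center).

The sampler is Hamiltonian Monte Carlo written directly in numpy: all
parameters live on the unconstrained standard-normal scale (β = 5b,
σ = 2.5|ν| via the folded-normal trick, non-centered γ = σ·L·z with
C = L Lᵀ), with analytic gradients, jittered leapfrog path lengths and
dual-averaging step-size adaptation (target acceptance 0.8) during
warmup. Default schedule: 3 chains × 6,000 iterations with 1,000
warmup. Convergence is summarized by split-R̂ (via arviz) on the fixed
effects, the scales, and a spot-checked subset of latent effects; R̂
above 1.05 triggers a warning, never a silent pass. Chains are seeded
from a split of the master seed, so fits are bit-reproducible. The σ
half-normal funnel is the slowest-mixing direction; parameter-recovery
experiments (K = 4, n = 150, 20 replicates) show ≥80% empirical
coverage of the 90% intervals for the size slopes even at reduced
schedules.

**Per-species summaries.** Per-draw softmax probabilities are averaged
over draws; the assigned guild is the argmax of the mean probabilities.
Certainty is reported as negentropy 1 − H(p)/ln K (entropy normalized
so the value lies in [0, 1]; the normalization constant is a package
choice since "entropy" alone does not fix a base) computed per draw and
summarized, and as the total SD √(Σ_k sd_k²).

**Extrapolation to unobserved species.** Per draw, one tree is sampled
from the supplied set (to propagate topological uncertainty) and one
posterior draw of (β0, β1, γ); the new tip's phylogenetic effect is the
Brownian conditional expectation E[γ_new | γ_train] = c′ C_train⁻¹
γ_train, i.e. the ancestral estimate at the tip's attachment point
under the model's zero-mean prior. This replaces the re-rooted
flat-root GLS estimate used by some R tools; the two coincide exactly
in the zero-length-branch limit, where the prediction collapses onto
the neighboring tip's fitted value (asserted to 1e-3 in tests). Default
2,000 draws; when a single tree is supplied and the draw budget covers
the posterior, every draw is used exactly once, making the mean
prediction deterministic.

**Leave-one-out cross-validation** refits the model without each
species and extrapolates to it. The default per-fold schedule (1 chain,
600 iterations, 250 warmup, 200 prediction draws) is a deliberate
approximation of the full budget — refitting 3×6,000 iterations per
fold is available but hundreds of times more expensive. Folds whose
guild would vanish from the training set are skipped with a log notice.
A helper applies the extrapolation-pool rule (families with more than
one representative plus declared exceptions; maximum length above
3 cm) to a user-supplied species table.

## Pairwise interaction prediction

Each (species, prey group) pair is a binary instance; the positive
label means the pooled diet proportion exceeds a presence threshold
(library default 0: any observed consumption counts). In the shipped
end-to-end analysis the threshold is 1% of the pooled diet: below that
level the synthetic generator's positives are single-gut trace items
that are random by construction, so they measure the noise model rather
than the predictor. The threshold is an explicit argument everywhere.
Features: phylogenetic eigenvector coordinates, ln(sizemax), and a
one-hot prey-group encoding in a single shared model (statistical
sharing across prey groups; a per-prey mode would fit 38 separate
models and is not the default).

Phylogenetic eigenvectors are the principal coordinates of the
Gower-centered patristic distance matrix, B = −½ J D J. For an additive
tree D decomposes exactly as d_ij = V_ii + V_jj − 2V_ij with V the
(PSD) Brownian path-length matrix, so B is positive semi-definite and
the squared Euclidean distances over all retained axes reproduce the
patristic distances (tested to 1e-6). Axes are ordered by eigenvalue;
by default the smallest set explaining 95% of positive-eigenvalue
variance is kept. Eigenvectors are computed once on the full supplied
tree so that training species and prediction targets share one
coordinate system.

The ensemble stacks three base learners — XGBoost, LightGBM (the two
gradient-boosting variants) and a random forest, 2,000 trees each by
default, otherwise library defaults — calibrated by stratified 10-fold
cross-validation. The logistic super-learner is fit strictly on
out-of-fold predictions, on the logit scale, so it can reproduce any
single base learner exactly; consequently the stacked out-of-fold
log-loss is never materially worse than the best base learner's.
Performance metrics: AUC via the tie-aware Mann-Whitney rank statistic
(checked against a brute-force pairwise oracle), and TSS = sensitivity
+ specificity − 1 at the threshold maximizing sensitivity +
specificity on *calibration* predictions — never on test labels.
Transferability is assessed by leave-one-region-out: fit on all but one
sampling region, evaluate on the held-out region with the
training-derived threshold. All learners run single-threaded with fixed
seeds, so fits are reproducible.

## Synthetic data generator

The generator mirrors the structure of a multi-region gut-content
synthesis and is the package's test bed:

- **Tree:** unit-depth Yule tree (pure birth, crown-group scaling).
- **Guilds:** equal-rates Mk evolution from a uniform root;
  the rate knob q is the *total* leave rate, so E[#changes] = q × total
  branch length. Optional conditioning keeps all guilds populated
  (`min_states`, `min_count`), emulating real assemblages; a zero-rate
  limit (`simulate_clade_guilds`) cuts the tree at its K−1 oldest
  splits for perfectly conserved, fully populated guilds.
- **Sizes:** ln(sizemax) = guild mean + Brownian deviation (defaults
  spread 8–80 cm across guilds, BM sd 0.4 over unit depth).
- **Diets:** a guild → species → individual Dirichlet hierarchy
  (concentrations 50 and 20 by default). Guild profiles concentrate 90%
  of mass on a guild-specific focal prey block (for K = 8 the blocks
  follow the prey taxa characteristic of sessile invertivores, HMD,
  corallivores, piscivores, micro- and macroinvertivores, crustacivores
  and planktivores) over a 10% uniform background, which yields the
  sparse "accidental prey" tail observed in real guts. Items below 1%
  of an individual gut are treated as unobserved and the gut is
  renormalized.
- **Regions:** six regions by default; each species has a home region
  and is shared into others with probability 0.16 (matching roughly one
  in six species sampled in multiple locations); shared species reuse
  their species-level profile unless regional noise is requested.
- **Experts:** each of 33 simulated classification schemes relabels
  each species with probability 0.115 according to a guild-specific
  confusion kernel (uniform by default). Pairwise agreement between two
  independent experts is (1−ε)² plus a small same-wrong-label term, so
  ε = 0.115 puts the median pairwise agreement near 78%.
- **Scale defaults** mirror the compiled-study design (615 species,
  8 guilds, 10–40 guts per species ≈ 23 on average); tests and the
  acceptance script run the same process at smaller sizes chosen so the
  whole analysis completes in minutes on one CPU (e.g. 120 species for
  the end-to-end run, 64 tips for signal/LOO experiments, 150 tips for
  parameter recovery).

A master seed is split (`numpy.random.SeedSequence`) into per-stage
streams, so one configuration and seed reproduce the entire dataset
bit-identically and any stage can be regenerated alone.

**What passing tests show — and don't.** The generator produces clean
Dirichlet mixtures on a correct tree with error-free species
identities. Real gut-content syntheses add observer bias, heterogeneous
prey resolution across sources, ontogenetic diet shifts, and tree
error; none of these are emulated, so the pipeline's measured accuracy
on synthetic data is an upper bound on what equally-sized real data
would give. What the tests do establish is internal correctness
(oracle agreement, metric axioms, calibration, coverage, limits) and
that each stage responds to its governing knob in the right direction
(lower Mk rate ⇒ higher δ, higher LOO accuracy, higher ensemble AUC).

## Numerical choices and degenerate inputs

- Proportion tolerances: 1e-6 on raw inputs, 1e-9 after normalization.
- Zero/negative branch lengths clamped to 1e-8 (warning).
- Node-uncertainty values clipped to [1e-6, 1 − 1e-6] before the Beta
  fit; correlation matrices get a 1e-10 diagonal jitter before Cholesky.
- Single-module modularity returns exactly 0.0 (the strength identity
  makes it so analytically; floating-point summation would not).
- Label-propagation ties break toward the smallest module id; medoid
  ties toward the lowest run index.
- Constant traits make δ undefined and raise; single-class interaction
  data refuse to fit; empty guts and sub-threshold species are dropped
  with log notices, never silently.
- Monte Carlo conventions: permutation p-values use (1 + #extreme) /
  (1 + n); seeds derived from a master seed stay below 2³¹.

## Known limitations

- The δ implementation is this package's construction of the
  entropy-of-ancestral-probabilities statistic; its absolute magnitude
  is not comparable across implementations (only the shuffle-null test
  is), and its power is inherently weak for near-monomorphic traits.
- The HMC sampler mixes slowly in the σ funnel at short schedules;
  split-R̂ warnings should be taken seriously for final analyses.
- LOO in fast mode underestimates posterior spread per fold; point
  predictions (argmax) are barely affected, which is what the accuracy
  summary uses.
- The extrapolation treats γ for new species as conditionally normal
  given training species; species attaching deep in the tree with few
  close relatives revert toward the prior mean (uniform-ish guild
  probabilities), which is the honest statement of ignorance.
- One shared ensemble with one-hot prey identity assumes prey-group
  effects shift, not reshape, the phylogenetic signal; a per-prey-group
  mode exists for the alternative.
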