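# trophoguild

Quantitative, reproducible delineation of consumer **trophic guilds**
from gut-content data, and prediction of guilds and pairwise trophic
interactions from **phylogeny and body size**.

Trait-based ecology leans heavily on expert-assigned trophic
categories, and experts disagree — independent reef-fish classification
schemes routinely differ on a fifth of species or more. `trophoguild`
replaces opinion with a pipeline grounded in empirical diet data:

1. **Standardize** individual-level gut-content records onto 38
   canonical prey groups and build a consumer × prey diet matrix
   (`core_data`), quantifying expert disagreement along the way
   (`expert_agreement`).
2. **Define guilds** as modules of the weighted bipartite diet network
   by maximizing Barber's modularity
   `Q = (1/m) Σᵢⱼ (Wᵢⱼ − rᵢcⱼ/m)·1[gᵢ = hⱼ]`
   over 500 seeded runs, keeping the variation-of-information medoid
   (`guild_network`).
3. **Measure phylogenetic conservatism** of the guilds with the δ
   statistic (entropy of marginal ancestral-state reconstructions,
   Beta-modeled) against a trait-shuffling null (`phylo_signal`).
4. **Model guild membership** with a Bayesian multinomial phylogenetic
   regression — `Pr(k) ∝ exp(β0ₖ + β1ₖ·ln sizemax + γ_phy,k)`, reference
   category `mu₁ = 0`, Brownian covariance on γ — sampled by
   Hamiltonian Monte Carlo, and **extrapolate** guild probabilities to
   species without diet data via Brownian conditional estimates of the
   phylogenetic effect, with negentropy/total-SD certainty summaries
   and leave-one-out validation (`guild_phylo_model`).
5. **Predict pairwise interactions** (species × prey group) with a
   stacked ensemble — XGBoost + LightGBM + random forest under a
   logistic super-learner on out-of-fold predictions — using
   phylogenetic eigenvector maps and size as features, scored by AUC
   and TSS with leave-one-region-out transfer checks
   (`interaction_predictor`).
6. **Simulate** the whole study design (Yule tree, Mk guild evolution,
   Brownian sizes, hierarchical Dirichlet diets, multi-region sampling,
   noisy experts) for testing and calibration (`synthetic_data`).

See `docs/methods.md` for model details, priors, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from trophoguild import (synthetic_data as sd, core_data, guild_network,
                         phylo_signal, guild_phylo_model as gpm)

cfg = sd.SimulationConfig(n_species=60, n_guilds=3, n_regions=2,
                          guts_min=10, guts_max=15, seed=7)
ds = sd.simulate_dataset(cfg)

records = core_data.filter_min_guts(ds.records, min_guts=10)
diet = core_data.build_diet_matrix(records)
net = guild_network.BipartiteNetwork.from_diet(diet)
runs = guild_network.modularity_ensemble(net, n_runs=500, base_seed=1)
medoid = guild_network.select_medoid(runs)
print("modules:", len(set(medoid.consumers.values())), "Q = %.3f" % medoid.Q)

guilds = phylo_signal.DiscreteTrait(
    {sp: m + 1 for sp, m in medoid.consumers.items()})
sig = phylo_signal.delta_null_test(ds.tree, guilds, n_shuffles=100, seed=2)
print("delta = %.2f, null median = %.3f, p = %.3f"
      % (sig.delta_obs, sig.null_median, sig.p_value))

model = gpm.fit(guilds, ds.attrs, ds.tree, chains=2, iterations=1000,
                warmup=400, seed=3)
fitted = gpm.fitted_probabilities(model)
print("fitted accuracy: %.2f"
      % (fitted["guild"].to_numpy() == model.guilds).mean())
```

Output:

```
modules: 4 Q = 0.232
delta = 3.92, null median = 0.096, p = 0.030
fitted accuracy: 0.85
```

The network analysis resolves four modules (the three simulated guilds,
one of them split — module count is an output, not a parameter); δ sits
forty-fold above its shuffle-null median (p = 0.03), so the discovered
guilds are phylogenetically conserved; and phylogeny plus body size
recover 85% of the training assignments at this small problem size.

A command-line interface mirrors the stages:

```bash
trophoguild simulate --n-species 60 --seed 7 --out sim/
trophoguild standardize --records sim/records.csv --min-guts 10 --out diet.csv
trophoguild modules --diet diet.csv --runs 500 --seed 1 --out partition.csv
trophoguild signal --tree sim/tree.nwk --trait sim/guilds.csv --seed 2
trophoguild guildmodel fit --tree sim/tree.nwk --trait sim/guilds.csv \
    --attrs sim/attrs.csv --out fitted.csv
trophoguild interactions evaluate --diet diet.csv --tree sim/tree.nwk \
    --attrs sim/attrs.csv --out eval.json
```

All stages are deterministic given their seeds; rerunning a stage with
the same inputs reproduces its output byte for byte.

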