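# bloomnet

Plot-level analysis of plant–flower-visitor networks under experimental
treatment, for community ecologists who manipulate bipartite mutualistic
networks in the field and need the full chain from raw visit records to
treatment-level inference in one reproducible pipeline.

The motivating design is a randomized-block field experiment: fixed
communities of 7 flowering plant species in 8 blocks (site-years), one plot
per block for each of four agrochemical treatments — water control (C), low
fertilizer (F), low herbicide (H), and both (HF) — with every flower-visiting
insect collected, identified and counted over a season. The scientific
question is whether such treatments can steer *network connectance*: the
realized fraction of all potential plant–insect interactions.

## What it computes

For each plot's weighted visitation matrix `A` (plants × insects, entries =
visit counts):

- **Experiment-wide connectance** `C = L / (P · I)` with `L` the number of
  realized links, `P` the plant species that bloomed in the plot, and `I` the
  experiment-wide insect species pool.
- **Degrees** — unweighted `L/S` and weighted `N_v/S`, with `S` the species
  present in the network and `N_v` the total visitor abundance.
- **NODF nestedness** (0–100), and the size/fill-corrected
  **NODFc = (NODF / max-NODF) / (fill · ln √(mn))**, where max-NODF is found
  by a greedy nested seed plus hill-climbing search (exhaustive on tiny
  matrices).
- **Barber's weighted bipartite modularity**
  `Q = (1/F) Σᵢⱼ (Aᵢⱼ − kᵢdⱼ/F) δ(gᵢ,gⱼ)`, maximized by seeded label
  propagation with module agglomeration.
- **Fixed-margin null models** (Patefield / `r2dtable` sampling) with
  z-score standardization `z = (obs − μ_null)/σ_null` and the departure rule
  "mean(z) ± sd(z) excludes 0" per treatment.
- **Hill-number diversity** (q = 0, 1, 2), sample coverage from
  singletons/doubletons, and hypergeometric rarefaction of the pooled
  visitors per treatment.
- **Treatment contrasts** from Gaussian linear mixed models (REML): fixed
  effects treatment + log floral display (interaction fitted, pruned when
  non-significant), random intercept per block, Nakagawa marginal and
  conditional R²; plus Kruskal–Wallis/Dunn mean-rank tests of per-species
  foraging breadth with Bonferroni correction, and a Pearson correlation
  matrix across metrics.

A synthetic-experiment generator (`simulate_experiment`) reproduces the
whole design — log-normal floral displays independent of treatment, a
~90-species insect pool with log-normal activity, a fertilizer boost to the
realized fraction of the species pool, a herbicide decrement to visit
intensity — so every stage runs and is testable without field data. The dose
arithmetic for the application schedules (mg/L concentrations → seasonal
g/m², percent of a reference field rate) is included.

## Worked example

```python
import bloomnet as bn

table, metadata, _ = bn.simulate_experiment(bn.SimulationConfig(seed=42))
networks = bn.build_all_networks(table, metadata)
net = networks["block_1_C"]
m = bn.compute_all(net, i_total=len(table.insect_species), seed=0)
print(m.links, round(m.connectance, 3), round(m.nodf, 1), round(m.modularity, 2))
```

prints `45 0.072 31.2 0.46` — plot `block_1_C` realized 45 of the
potential links (connectance 0.072 of the bloomed-plants × insect-pool
possibilities), with moderate nestedness and modularity. Fitting the
mixed models on this season (see `examples/treatment_effects.py`) gives

```
log abundance    C-H: effect -0.320  t -3.37  p 0.002 *
insect_richness  C-F: effect +6.131  t +4.97  p 0.000 *
```

— the herbicide plots received significantly fewer visits (≈ e⁻⁰·³² ≈ 73%
of control) while fertilized plots attracted ≈ 6 additional visitor
species, the two planted treatment signals.

The `examples/` directory has one short script per capability (dose
arithmetic, metrics, null models, diversity, treatment effects, full
pipeline); each prints its numbers with a line on what they mean. A thin
CLI wraps the pipeline: `bloomnet run-all --seed 1 --out results/`.

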