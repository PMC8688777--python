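# carapace

Phylogenetic comparative analysis of body size, lifespan and intrinsic
cancer risk in turtles — with gene-duplication reconstruction, enrichment
analysis, and estimation statistics for kinetic apoptosis assays.

Turtles pose a sharp instance of Peto's paradox: species spanning three
orders of magnitude in body size and lifespans beyond 150 years show
roughly constant — and low (~1.2%) — cancer prevalence.  If the expected
(intrinsic) cancer risk of a species scales as

> **K = size × lifespan⁶**

then lineages that evolved giant bodies and long lives (Galapagos giant
tortoises, sea turtles, softshells) must have evolved compensating
reductions in realized risk.  `carapace` provides the full analysis chain
for quantifying this on a time-calibrated phylogeny:

- **Ancestral reconstruction of continuous traits** — Brownian motion
  (`BrownianMotionASR`) and a heavy-tailed jump model with Student-t
  increments (`JumpDiffusionASR`, MCMC) that lets single branches absorb
  large trait jumps;
- **PGLS** (`PGLS`) of log2 lifespan on log2 size under a Brownian
  covariance matrix, used to infer ancestral lifespans;
- **Intrinsic cancer risk** — per-node log2 K and per-branch relative
  intrinsic cancer risk (RICR) changes, log2(K_child/K_parent), with the
  "X-log2 decreased RICR" reporting convention (`ricr_pipeline`);
- **Gene-duplication histories** — copy numbers encoded as binary
  characters (0 = one copy, 1 = two or more), fitted with a two-state
  reversible Markov model (`TwoStateMarkovModel`, frequencies equal or
  ML-optimised), empirical-Bayes marginal ancestral states with a
  posterior-vs-tip-frequency reliability filter, and per-branch
  duplication/loss counts and rate trees;
- **Over-representation analysis** — hypergeometric and binomial tests
  against a background universe, BH adjustment, cancer/aging category
  proportions and permutation comparisons between lineages;
- **Kinetic assay statistics** — 96-well plate bookkeeping (dilution
  halving, no-cell background), 24-h dose–response slices, and unpaired
  mean differences with 95% BCa bootstrap CIs and two-sided permutation
  p-values (exact enumeration for small groups);
- **Synthetic data** (`carapace.simulate`) — generators with recorded
  ground truth for every input, so the whole pipeline is testable without
  any downloads.

Model classes follow the statsmodels convention: construct from data, call
`.fit()`, get a results object with estimates, uncertainties and
`summary()`.

## Worked example

Simulate a 16-species turtle phylogeny in which one clade's stem branch
carries a planted giant-lineage event (+2 log2 body size, +1 log2
lifespan), then run the full risk pipeline with the jump model:

```python
import carapace as cp
from carapace import simulate as sim

tree, stem, size, life = sim.giant_lineage_scenario(seed=4)
cfg = cp.RunConfig(model="jump", mcmc_iterations=4000,
                   mcmc_burn_in=1500, seed=4)
res = cp.ricr_pipeline(tree, size, life, cfg)
print(res["size_asr"].summary())
print(res["pgls"].summary())
print("planted stem branch:", stem)
print(res["ricr"].nlargest(3, "decreased_ricr_log2")
               [["child_id", "decreased_ricr_log2"]].to_string(index=False))
```

prints

```
Continuous-trait ASR (jump)
  nodes: 31 (16 tips)
  sigma2: 0.000256041 (log2-units^2 per My)
  retained samples: 250 (nu=2.0)
  root estimate: 8.1193
PGLS (Brownian covariance, ML scale)
  n tips: 16
  intercept: 2.07685 (SE 0.357)
  slope:     0.425498 (SE 0.0411)
  sigma2_resid: 0.000116797
planted stem branch: 26
 child_id  decreased_ricr_log2
       26             7.295587
       11             1.002940
        4             0.606565
```

The root body size is reconstructed near its true 2⁸ ≈ 300 mm; the PGLS
slope recovers the simulated allometry; and the planted stem (branch 26)
shows by far the largest decreased-RICR magnitude — ≈ 7.3 log2, close to
the planted 6·(+1) + (+2) = 8 — meaning that lineage must have evolved a
~2⁷-fold reduction in realized cancer risk to keep prevalence constant.

A kinetic-assay comparison at 24 h and 25 μM (the analysis dose after
reagent addition halves a 50 μM nominal dose):

```python
from carapace import assay

plate = assay.build_plate(["C_niger", "G_platynota"], "tunicamycin")
eff = {("C_niger", "tunicamycin"):     dict(emax=400.0, ec50=25.0, hill=1.5),
       ("G_platynota", "tunicamycin"): dict(emax=150.0, ec50=25.0, hill=1.5)}
series, _ = sim.sim_plate(plate, eff, noise_cv=0.05, seed=11)
corr = assay.background_correct(series, plate)
tab = assay.slice_timepoint(corr, 24.0, plate)
at25 = tab[tab["final_uM"] == 25.0]
est = assay.mean_difference(at25[at25.species == "G_platynota"]["value"],
                            at25[at25.species == "C_niger"]["value"], seed=0)
print(est.format(digits=3))
```

```
-128 (95% CI -144, -102), two-sided permutation P = 0.1
```

The weaker responder's luminescence is 128 units below the reference, the
BCa interval excludes zero, and p = 0.1 is the smallest value attainable
by exact enumeration with three wells per group (2/20 partitions).

## Command line

A thin CLI wraps the library: `carapace simulate` writes a complete
synthetic input bundle (Newick tree, trait TSVs, copy-number TSV, plate
CSV + layout, truth JSON); `carapace ricr`, `carapace dup-asr`,
`carapace enrich` and `carapace assay` run the pipeline stages from a YAML
config, each taking `--config`, `--seed`, `--out-dir`, `--verbose`.

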