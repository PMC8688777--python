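# Methods

`carapace` re-implements, as a tested pipeline on synthetic data, a
comparative analysis of body-size/lifespan evolution and intrinsic cancer
risk in turtles: continuous-trait ancestral reconstruction, PGLS inference
of ancestral lifespans, the intrinsic-risk statistic and its per-branch
changes, binary gene-duplication reconstruction, over-representation
analysis, and estimation statistics for kinetic apoptosis assays.  This
note records the models, the defaults and why, the numerical choices, and
what the synthetic data do and do not establish.

## Continuous traits

Traits (carapace length as the body-size proxy, maximum lifespan) enter on
log2 scale; branch lengths are millions of years (My), so the Brownian rate
σ² has units of squared log2-trait per My.

**Brownian ASR.** `BrownianMotionASR.fit()` runs two-pass Gaussian message
passing (tip-to-root precision-weighted combination, then root-to-tip
marginalisation) with a flat prior on the root state.  The point estimates
are the joint maximum-likelihood ancestral states and coincide with the
closed-form GLS reconstruction; the suite checks this against a dense
branch-weighted-Laplacian solver to 1e-8 on random trees.  σ² is estimated
by maximum likelihood (divisor n, not REML; the fit is flagged `ML`).
Polytomies are handled by folding child messages pairwise; the accumulated
contrasts reproduce the GLS quadratic form.

**Jump model.** The study-style alternative to Brownian motion is a
heavy-tailed increment model: per-branch increments are Student-t with ν
degrees of freedom (default ν = 2) and scale c·√t.  Student-t replaces the
alpha-stable family: it preserves the property that matters — a single
branch can absorb a large jump without inflating the global rate — while
having a closed-form density that can be tested (ν → ∞ recovers Brownian
motion; the suite checks agreement with the BM fit at ν = 200 within
Monte-Carlo error of the posterior medians).  Inference is MCMC with flat
priors on node states and a Jeffreys prior on c: random-walk Metropolis on
each internal node, a log-scale walk on c, and a *subtree translation* move
(shift every internal node of a subtree jointly) without which clade-level
shifts mix poorly (split-chain R-hat ≈ 1.2 on planted-jump data).
Proposal scales adapt during burn-in only; thinning is fixed at 10; a
split-chain R-hat above 1.2 on the root state emits a warning, not an
error.  Defaults: 6,000 iterations, 2,000 burn-in.

Identifiability caveats, established empirically with long (40k) chains:
with a flat root prior a jump on a root-child stem is indistinguishable
from an opposite jump on its sibling, and a jump planted on a near-zero-
duration branch is correctly attributed to a longer neighbour (the
increment density at scale c·√t makes the short-branch placement
astronomically expensive).  The planted-jump generator therefore plants on
internal, non-root-adjacent branches of ≥ 20 My where possible, and sizes
the jump as a multiple (default 8) of the root-to-tip SD √(σ²·T) — the
scale on which a jump stands clear of drift accumulated over the whole
tree depth.

**PGLS.** log2 lifespan on log2 size under Brownian covariance
V_ij = shared root-to-MRCA path length, via GLS; residual rate σ²_resid by
ML.  On a star tree this reduces exactly to OLS (tested).  Ancestral
lifespans are the fitted surface evaluated at reconstructed sizes *plus*
the Brownian reconstruction of the tip residuals, so tip lifespans are
reproduced exactly; `lifespan_method="fitted_only"` drops the residual
term.

**Branch statistics.** Δ_b = child − parent estimate (log2); percent
change = 100·(2^Δ − 1); rate multiplier r_b = (Δ²/t_b)/σ̂².  One exact
identity worth knowing: because the joint-ML reconstruction minimises
Σ Δ²/t and the minimum equals n·σ̂², the mean r_b over branches of a
reconstruction is exactly n/(2n−2) ≈ 0.53 for a bifurcating tree — the
familiar calibration E[Δ²/(tσ²)] = 1 holds for *true* increments, not
reconstructed ones.  The suite asserts both statements.

## Intrinsic cancer risk

K = size × lifespan⁶ (lifespan in years; size in whatever proxy is
supplied — carapace length by default; an optional length→mass cube
conversion exists but is off).  All arithmetic is in log space:
log2 K = 6·log2 L + log2 S, so the per-branch change decomposes exactly as
ΔRICR = 6·Δlog2 L + Δlog2 S (tested to 1e-10).  Reporting follows the
field's convention: a positive log2 increase in expected risk is phrased
as an equal-magnitude "decreased RICR" — the evolved reduction in realized
risk needed to keep observed cancer prevalence constant; the raw signed
value is always emitted alongside.  Published per-branch magnitudes for
real turtle lineages are not reproduction targets: they are not derivable
from the stated formula alone and the underlying trait data are not
deposited anywhere this package can reach.

## Gene duplication histories

Copy numbers collapse to binary characters: 1 copy → 0, ≥ 2 copies → 1,
and 0 copies (absence) or unassessed → *missing*.  Absence is deliberately
not state 0 — treating a gene lost from a genome as "single copy" would
manufacture spurious losses; `absence_as_state0` restores the naive
encoding.  The model is the two-state reversible chain (binary GTR for
morphological data) with frequencies equal or ML-optimised ("FO"); the
transition probabilities have closed forms, the likelihood is Felsenstein
pruning vectorised across genes, and model choice is by AIC with ties
broken toward fewer parameters.  Ancestral states are empirical-Bayes
marginal posteriors (inside–outside passing, π as root prior), checked
against exhaustive enumeration over internal state assignments to 1e-10.

A reconstruction is kept only if its posterior probability is at least the
assigned state's observed frequency among that gene's non-missing tips;
tips count as certain, missing tips never anchor events.  A duplication is
a reliable 0→1 parent-to-child argmax transition (losses symmetrically);
requiring *both* endpoints reliable is our resolution of an ambiguity the
source text leaves open.  Duplication rate trees replace branch lengths
with duplications per My.

## Enrichment

Upper-tail hypergeometric (Enrichr-style) and upper-tail binomial
(Panther-style) over-representation per term, against a user-supplied
background universe; both are checked against exact rational combinatorics
for N ≤ 20.  "Enriched" means raw p ≤ 0.05 — the reporting
convention emulated here — with Benjamini–Hochberg values always reported so
users can tighten.  The cancer/aging label on terms is a curated input,
never computed.  Lineage comparisons use the difference of group mean
proportions with a two-sided permutation test.

## Kinetic assays and estimation statistics

The plate model: 96 wells, 5,000 cells/well, three replicates per
(species, dose), one no-cell column carrying drug plus reagent; reagent
addition halves every nominal concentration (so printed 50/1,000/5,000 μM
become the 25/500/2,500 μM analysis doses).  Kinetics are read every
30 min for 48 h; the grid includes t = 0, giving 97 readings — the
protocol text is ambiguous about the initial read and the inclusive grid
is our choice.  Background correction subtracts the per-timepoint no-cell
mean (per drug and channel); negatives are retained.  The necrosis
(fluorescence) channel is carried through but not analysed by default.

Comparisons are estimation statistics: the unpaired mean difference with a
95% BCa bootstrap interval (5,000 stratified resamples; bias z₀ from the
fraction of bootstrap statistics below the observed, acceleration from the
pooled jackknife skewness) and a two-sided permutation p (5,000 reshuffles,
no add-one smoothing so an empty tail prints 0.0; `conservative_p`
switches to (h+1)/(N+1)).  When C(n, n₁) ≤ max(n_perm, 20,000) the
permutation null is enumerated exactly, which makes small-group p-values
integer-exact (3 vs 3 wells: minimum p = 2/20 = 0.1).  Forcing z₀ = 0,
a = 0 collapses BCa to the percentile interval — used as an internal
consistency check, with `scipy.stats.bootstrap(method="BCa")` as an
independent reference in the suite.  A caveat measured during validation:
for n = 10 per group the true coverage of the 95% BCa interval is ≈ 0.905
(ours and scipy's alike) — the well-known small-sample anticonservatism of
BCa.

## Synthetic data

Every input has a generator with recorded ground truth, reproducible
bit-for-bit from (parameters, seed): Yule trees rescaled to a 210-My root
(the approximate crown-turtle depth); Brownian traits with optional
planted jumps; lifespans linear in log2 size with Brownian residuals
(defaults β = 0.5, intercept 4.0 log2 years); duplication histories
simulated with exponential waiting times at s = 0.001/My, π₁ = 0.3 —
rates chosen so a 200-gene set yields tens of duplications spread over the
tree, the regime in which per-branch counts are informative; annotation
universes with planted foreground excess; and plate kinetics
baseline + Emax·Hill(dose)·logistic(t) with multiplicative lognormal noise
(CV 5% — luminescence is positive with roughly constant CV; the protocol
states no noise model) and a no-cell baseline.

What passing recovery tests show — and what they do not: the planted-jump
and giant-lineage scenarios are *designed* so the planted contrast
dominates the background (jumps ~6–8× the root-to-tip SD, stems that
dominate their child branches in duration); they demonstrate that the
machinery attributes changes correctly when a real signal exists, not that
every real jump in noisy data will be found.  The generators also omit
real-data features: measurement error in traits, phylogenetic error,
correlated gene histories, annotation bias, plate edge effects.

## Problem sizes and tolerances

Standard validation sizes (used by the suite and `scripts/acceptance.py`):
oracle equivalences on 20–50 random ≤ 8-tip trees at 1e-8–1e-12; σ²
recovery on 50 × 200-tip trees; two-state recovery at 20 × 500 characters
on 16 tips (root age 10 My so s·T = 1; at the 210-My depth a rate of
0.1/My saturates tips and s is unidentifiable); PGLS slope on 30 × 200
tips; planted-structure scenarios at 20 replicates; ORA null calibration
at 1,000 draws; BCa coverage at 500 × 1,000 resamples.  MCMC defaults
(6,000/2,000) give clean recovery on 16-tip trees; larger trees warrant
proportionally longer chains.

## Known limitations

Student-t is not alpha-stable; rate multipliers are an operationalisation,
not the original software's internal scalars; the empirical-Bayes argmax
event counting ignores within-branch multiple hits (counts are transitions,
not events); BCa is anticonservative at very small n; the CLI assumes the
bundled TSV/CSV layouts.
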