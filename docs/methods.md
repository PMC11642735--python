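# Methods

## The model

Haploid chromosome number is treated as a discrete character evolving on a
rooted time-calibrated phylogeny (branch lengths in millions of years)
under a continuous-time Markov chain. Two event types are allowed: a
fission moves a lineage from count `n` to `n+1` at rate λ_fission, and a
fusion moves it to `n−1` at rate λ_fusion, both constant across lineages
and time within one fit. The generator Q is therefore tridiagonal on a
contiguous count range. No polyploidy, demiploidy or branch-heterogeneous
rates are modelled, and no speciation/extinction rates are estimated: the
tree is conditioned on, not jointly modelled.

The trait-linked variant crosses the count space with a binary trait
(state 0/1 — e.g. small vs large census population, or sedentary vs
migratory). Each trait state carries its own λ_fission/λ_fusion; the trait
flips 0→1 at q01 and 1→0 at q10; a single instantaneous event never
changes count and trait simultaneously. The flattened state index of
`(n, b)` is `b·S + (n − n_min)` with `S` the count-space size; this
convention is fixed because traces and ancestral-state outputs refer to it.

### State space

The count space runs from `max(1, min(observed) − pad)` to
`max(observed) + pad` with `pad = 5` by default. The data never inform
states far outside the observed range, and the regression test that
enlarges the pad from 5 to 10 moves the log-likelihood by `< 1e-4` on
simulated data whose counts sit well inside the bounds; 5 is therefore a
safe, cheap default. Users with rates high enough to push probability
mass to the boundary should raise it.

### Likelihood

Tip data enter as indicator vectors (point mass on the observed state;
for linked models a `(count, trait)` pair where either element may be
`None`, spreading the indicator over all compatible states — this is how
species without a classified trait can be retained). The likelihood is
computed by Felsenstein pruning with per-message renormalisation and
accumulated log scalers, so underflow cannot occur on large trees.

At the root three weightings are available: `"weighted"` (default) weights
each root state by its share of the root conditional likelihood — the
common default of Bayesian discrete-character software; `"flat"` averages
over states; `("fixed", state)` conditions on a known root state. The
root prior the original analyses used is not documented, so this default
is an assumption, flagged here.

Inside the pruning recursion the action of `exp(Qt)` on a
conditional-likelihood vector is computed by **uniformization**: with
μ = max |Q_ii| and A = I + Q/μ (a stochastic matrix),
`exp(Qt) v = Σ_k Pois(k; μt) A^k v`. Every term is non-negative, the
series is evaluated with sparse matrix–vector products in a numba-compiled
kernel, and truncation continues until the cumulative Poisson mass is
within 1e-14 of one *and* the weights have decayed below 1e-18 of their
peak — the second condition keeps full relative accuracy for entries whose
leading contribution is high-order (multi-step transitions on very short
branches). The dense Padé/scaling-and-squaring exponential (scipy) is kept
as the reference implementation behind `transition_probabilities`, and the
test suite checks the pruning path against brute-force enumeration with
scipy matrices to 1e-8, so the fast path and the reference path are
mutually validating.

Marginal ancestral state distributions combine the standard down-pass
conditionals with an up-pass of outside likelihoods; tip distributions are
point masses and each node's distribution sums to one.

## Bayesian fitting

Sampling is univariate slice sampling with stepping-out (initial width
1.0, at most 20 step-outs apportioned randomly), one full parameter sweep
per recorded generation — the default behaviour of the sampling framework
this family of analyses conventionally uses. Chains initialise every
parameter from uniform(0, 1), re-drawing (up to 100 times) if the
posterior is not finite there. Default conventions: 4000 generations with
2000 burn-in for two-parameter fits (including the per-chromosome-class
fits, which use an exponential prior with rate 0.1 to discourage the
occasional excursion to unrealistically high rates); 10000 generations
with 2000 burn-in for six-parameter trait-linked fits. "Uniform priors"
are uniform(0, 100) events/MY by default — effectively flat over plausible
rates but proper, so prior recovery is testable; the bounds are
configurable. Effective sample size and a Geweke z-score are logged per
parameter; there is no automated stopping.

Posterior summaries use central quantile intervals with linear
interpolation between order statistics (the convention is stated because
published analyses rarely state theirs). ΔR is the per-sample difference
of a rate between trait states; its 95% interval lying entirely on one
side of zero is read as evidence for a rate difference, otherwise
"no-evidence". "Mean rate" is the per-sample arithmetic mean of the
fission and fusion rates; summarising per-sample means or averaging the
two posterior means is identical for the mean itself, and the per-sample
series is what the credible interval and the posterior-sample-wise
Spearman correlation (across clades, one rho per posterior sample) are
computed from.

Spearman's rho uses mid-ranks for ties and the two-sided t-approximation
for its p-value at every n (the clade-level analyses have n of 8–12); an
exact permutation p-value is available behind a flag for small n.

## The population-size index

Species are scored on three proxies of effective population size, each
−1/0/+1, positive meaning *smaller* populations:

| trait | ≤ Q1 | middle | > Q3 |
|---|---|---|---|
| range size | +1 | 0 | −1 |
| body mass | −1 | 0 | +1 |

with trophic level scored categorically (carnivore +1, omnivore 0,
herbivore −1). Quartiles are pooled across all species; a clade's score
per trait is the modal per-species score (ties → 0 with a warning); the
three clade scores sum to an index, classed small (1 or 2), medium (0) or
large (−1). Note the mass direction: the published scoring table this
scheme reproduces assigns *large*-bodied clades +1 (small N_e), and the
implementation follows that table. Boundary convention: "lowest quartile"
means ≤ Q1 and "upper quartile" means > Q3; both are documented here
because published prose mixes strict and loose inequalities.

Abundance-based binarization keeps only the outer quartiles (≤ Q1 →
"small", > Q3 → "large") and drops the middle half, mirroring how census
population size is dichotomised before fitting the trait-linked model.

## Tip rates and phylogenetic signal

A tip's rate proxy is |observed count − modal reconstructed count of its
immediate ancestor|, with ancestral-mode ties broken toward the state
nearest the tip's own count (then toward the lower count) so that a tie
never manufactures a spurious outlier. The raw count difference is used
rather than a per-MY rate; any filter of the form "tip rate > 0" is
insensitive to that choice.

Blomberg's K is computed from the Brownian-motion covariance C (shared
root-to-MRCA path lengths): K is the observed ratio of the raw mean
squared deviation (about the phylogenetic mean) to the C-corrected one,
divided by its Brownian expectation `(tr C − n/(1ᵀC⁻¹1))/(n − 1)`. The
permutation test shuffles trait values across tips, one-sided upper tail,
add-one correction, default 1000 permutations. On a star tree both ratios
coincide and K is identically 1.

## Synthetic data

Trees come from a birth–death process conditioned on the number of extant
tips (dendropy's simulator). The process stops exactly at the n-th birth,
which would leave the youngest cherry with zero-length branches; time is
run forward by one exponential waiting time to the next event and stopped
just before it, keeping the process exact and all branch lengths positive.
Counts and linked traits evolve by exact Gillespie simulation of the same
generators the likelihood uses (fusion disabled at count 1 — a reflecting
floor), so simulation and inference share one model by construction and
single-branch tip-state frequencies are tested against `exp(Qt)` rows.
Brownian traits support the signal tests. The score-structured trait-table
generator places per-clade trait values in three well-separated value
bands sized so the pooled quartile thresholds fall in the gaps between
bands, giving each clade a strict plurality in its target band; an
impossible target mix (more outer-quartile demand than a quarter of the
pool) raises an error.

What the simulators do *not* emulate: real karyotype data have multiple
conflicting reports per species (handled in the loaders by modal counts,
ties to the lowest with a warning), phylogenetic uncertainty, non-random
taxon sampling, and correlated micro/macro rearrangement processes (the
two classes are simulated and fitted as independent fission/fusion
processes). Passing tests therefore demonstrate internal statistical
correctness and calibration, not robustness to those features of real
data.

## Problem sizes in the validation suite

The end-to-end suite uses: 200-tip trees, 4000-generation chains (2000
burn-in) and ten replicate datasets for two-parameter recovery; 300-tip
trees and ten seeds for ΔR sign recovery with 600-generation chains (200
burn-in — the six-parameter posterior is strongly concentrated at this
data size, and the recovered intervals sit far below zero); 20000
single-branch replicates for simulator consistency; 100 Brownian
replicates on 50-tip trees plus 200 null datasets for K calibration; and
thinned 10000-generation chains (to 2000 samples) for prior recovery, so
the Kolmogorov–Smirnov comparison measures the sampler's stationary
distribution rather than slice-sampler autocorrelation.

## Known limitations

* Rates are homogeneous across lineages within a fit; clade-specific rates
  require separate per-clade fits.
* The root prior and the original software's state-space padding are
  undocumented upstream; defaults here (likelihood-weighted root, pad 5)
  are reasoned assumptions.
* The linked model estimates six parameters; with few species in one
  trait state its rates are prior-dominated under uniform(0, 100), and ΔR
  intervals widen accordingly.
* The exact-permutation Spearman option enumerates n! permutations and is
  only sensible for n ≤ 8.
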