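# Methods

`glacialsfs` implements an SFS-based population-genomic workflow for
multi-species targeted-sequencing studies: quality and paralog
filtering of genotype calls, folded site-frequency-spectrum
construction with missing data, diversity and differentiation
statistics, composite-likelihood demographic inference, and a
randomization test for synchronous changes in effective population size
across species. This note records the models, conventions, numerical
choices, and the scope of what the synthetic-data tests do and do not
establish.

## Conventions

All effective sizes are diploid: `k` ancestral lineages coalesce at
rate `k(k-1)/(4Ne)` per generation and the population-scaled mutation
rate is `theta = 4*Ne*mu` per site. Times are generations before
present internally; years appear only at the presentation layer
(trajectories), scaled by a per-dataset generation time. Default
scaling constants follow the study system: `mu = 7.77e-9` per site per
generation for angiosperms (generation times 15 or 60 y) and
`mu = 2.7e-8` for conifers (25 y). Spectra are folded throughout
(minor-allele counts); ancestral-allele polarization is out of scope.
VCF positions are 1-based, exclusion regions are written as 0-based
half-open BED; the conversion lives in one place (`glacialsfs.io`).

## Coalescent simulation (`simdata`)

The single-population simulator draws genealogies under
piecewise-constant demography by time-rescaled exponential waiting
times across epochs and drops infinite-sites mutations on branches as a
Poisson process with mean `mu * L_locus * length`. Replicate loci are
independent genealogies; the surveyed length `L` is split evenly across
them. For genotype matrices, haplotypes pair consecutively into
diploids; targeted sequencing of many short fragments is emulated with
`reps` in the hundreds (probe-sized loci of a few hundred bp). Depth is
Poisson (floored at one read), genotype quality is synthesized monotone
in depth as `GQ = min(99, round(10*DP/3))` — an arbitrary but
order-preserving map used only to exercise the filters.

The two-deme isolation-with-migration simulator adds per-lineage
backward migration at rate `Nm/(2*N_deme)` out of each deme, merges
demes `tdiv` generations ago, and optionally switches the ancestral
size at `tsep`. Joint spectra are folded on the total minor count, with
the exact half folded by the deterministic tie rule "keep the
configuration with the smaller count in population 1". A JIT-compiled
kernel (`_twodeme_fast`) implements the identical process for the
model fitter, where the expectation is re-simulated at every objective
evaluation; the pure-Python implementation is the reference and the
data generator, and the two are cross-checked statistically in the
tests. Genealogies that would need more than a set number of events
(extreme-migration parameter corners, which are effectively panmictic)
are rejected by the fitter with a bounded event budget rather than
simulated at arbitrary cost.

The glacial-cycle scenario builder places ten instantaneous events —
an expansion 15 kya, a decline 120 kya, then alternating events every
120 ky to a final decline ~1.08 Mya — with Ne alternating between the
current size and one tenth of it (five cycles). Event times convert to
generations through the generation time, which is the entire point of
the power study: the same calendar history is "long" or "short" in
coalescent units depending on the organism.

Trajectory sets for synchrony calibration are independent Gaussian
random walks in log Ne (step s.d. 0.1, base Ne 1e5) over a shared time
grid; within engineered windows all species are forced monotonically
decreasing toward the present. The calibration grid uses 900 points,
the scale of a joint multi-species grid assembled from several
stairway-style outputs with hundreds of steps each.

## SFS construction and diversity (`sfs`)

Sites with a missing-call fraction above 0.5 are excluded; remaining
sites are projected to the target haploid size (default: half the
sample, rounded down to even) by exact hypergeometric expectation.
Projection of a folded spectrum is well defined because the folded
result of a hypergeometric draw does not depend on which allele is
labelled derived. Mass projected onto count zero joins the monomorphic
cell; `L` counts all surveyed sites of the selected classes, excluded
sites removed. The diversity estimator

    pi = n / (L (n-1)) * sum_sites (1 - p^2 - (1-p)^2),  p = i/n

equals the mean pairwise difference per site and is exactly invariant
under projection (it is the expectation of a two-copy draw); both the
deterministic projection and a stochastic per-site resampling mode
(default 1000 replicates, whose mean estimates the same quantity) are
provided because published workflows have used either. The normalized
transform `phi_i ∝ eta_i * i(n-i) * (1 + [i = n-i]) / n` is flat in
expectation under the standard neutral model, which makes growth
signals (rare-variant excess) visible as a left-end elevation.

## Filters (`qcfilters`)

Caller-annotation thresholds (QD < 0.25, QUAL < 20, SOR > 3.0,
MQ < 30, MQRankSum < -12.5, ReadPosRankSum < -8.0) and genotype
thresholds (DP < 8 or GQ < 20 masked; sites with > 50% missing calls
dropped) use strict inequalities exactly as printed; values at a
threshold pass. Missing annotations pass by default (callers omit
rank-sum statistics where only one genotype class is present); a flag
inverts this.

HDplot computes per site the heterozygote fraction H among non-missing
calls and the pooled read-ratio deviation `D = (A - B) / sqrt(A + B)`,
the z-score of the pooled heterozygote reads against Binomial(N, 1/2).
Sites with H > 0.6 or |D| > 20 are flagged. The windowed region rule
evaluates a symmetric 250-bp window centred on each flagged SNP; when
the window holds at least two SNPs and its paralog fraction exceeds
10%, every SNP inside is excluded. A lone flagged SNP is removed
individually and never expands a region. Region limits extend to the
midpoint between the outermost excluded SNP and the nearest retained
SNP on each side, so the same mask applies to monomorphic positions in
available-genome accounting. Window placement (anchored on flagged
SNPs) is one of several readings of a fraction-per-window rule; it is
the configurable default here.

With 25 diploids per population the false-flag rate of the H threshold
on clean data is below 2%; at very small sample sizes (fewer than ~10
diploids) binomial noise in H alone pushes intermediate-frequency sites
over 0.6, which is a property of the method, not of the implementation.

## Differentiation and isolation by distance (`spatial`)

Pairwise FST is Weir & Cockerham (1984) with variance components summed
over loci (ratio of sums); negative estimates are retained. Isolation
by distance regresses `FST/(1-FST)` on the natural log of the
great-circle distance (haversine, mean Earth radius 6371.0088 km) over
all unordered pairs, the two-dimensional stepping-stone expectation.
Population-specific scaled differentiation defaults to the mean over
partners of `FST/d_km` (the displayed quantity in the source system's
figures); ratio-of-means and log-distance variants are selectable
because the published phrasings disagree, and no report silently
prefers one.

## Demographic inference (`demography`)

The expected folded SFS under piecewise-constant demography is
analytic: expected times `E[T_k]` with `k` ancestral lineages come from
the lineage-count (pure-death) process — Tavare's ancestral-process
coefficients, computed in exact rational arithmetic, integrated epoch
by epoch in closed form — and branch-length shares convert them into
entry expectations. Constant size reproduces Watterson's `theta*L/i`
to machine precision, and the coalescent-scaling identity (scale Ne and
times by c, divide mu by c) holds exactly. Float cancellation in the
alternating coefficient sum limits sample sizes to roughly a hundred
(hard documented limit n = 1000).

Fitting maximises a Poisson composite log-likelihood over folded
entries plus the monomorphic cell (the likelihood the AIC values refer
to). Epoch models (SNM, 2-epoch, 3-epoch) use multistart Nelder-Mead
over log10 parameters with log-uniform starts in the prior box, default
10..1e7 for sizes and times (100 starts by default, fewer in tests);
the 3-epoch second change time is parameterised as a positive increment
over the first, enforcing the ordering. Parametric bootstrap intervals
refit Poisson resamples of the fitted expectation.

Divergence models (strict split, split with migration, each with or
without an ancestral size change, plus the three panmictic references
fitted on the pooled spectrum) use Monte Carlo expectations from the
JIT kernel with common random numbers — the same stream at every
evaluation, making the stochastic objective a deterministic function of
the parameters. Priors: 10..1e9 for sizes and times, 1e-4..1e4 for
effective migrant numbers. The optimiser runs a randomized coarse scan
of the prior box, Nelder-Mead refinements with a wide initial simplex
(±0.7 decade per coordinate, needed to traverse the tdiv-migration
ridge on a rough surface), a short polish at five-fold Monte Carlo
resolution, and reports the likelihood from one ten-fold-resolution
evaluation so AIC differences between models are not dominated by
Monte Carlo noise. `fit_divergence_set` fits the family in order and
warm-starts each richer model from the nested solutions (including
moment anchors: marginal Watterson sizes and a deep split at 100x the
geometric-mean size, the migration-drift-equilibrium regime), and the
reported solution is guaranteed at least as good as every warm start
under the final evaluation. Without this nested seeding the migration
models routinely converge worse than the models they contain.

The stairway-style trajectory bootstraps the spectrum (multinomial
resamples of 67% of the sites), fits free-change-time models with 2 to
5 epochs per replicate (breakpoint counts n/4, n/2, 3n/4, n-2), selects
per replicate by AIC — each richer model warm-started by splitting the
terminal epoch of the previous fit — and reports the per-time median
with 2.5/97.5 percentile bands across 200 replicates by default (tests
and the acceptance script use 20-30). This replaces the per-step theta
estimation of the original stairway approach with AIC-selected epoch
fits; it is validated by recovery properties (flat under constant size
within ±20%, expansion ratios recovered), not by output-identity with
any external tool. The reported span is data-driven: a log grid over
`[0.008, 32] * N_watterson` generations, because outside the
genealogical depth the likelihood is flat and bootstrap medians would
echo the prior. Halving mu doubles sizes and times and leaves the
shape unchanged.

Reversals in a trajectory are counted with a zigzag rule: direction
changes whose amplitude exceeds 10% relative, optionally restricted to
times below a bound. The "last glacial cycle" window is 240 ky — the
expansion-to-expansion period of the most recent cycle — since the
valley bottomed in the 15-120 kya glacial is only certified by the
recovery just beyond it.

## Synchronicity (`synchrony`)

Stairway-style steps become (interval midpoint, Ne) pairs with the most
recent interval dropped; species align on the sorted union of midpoints
by nearest-midpoint lookup, exact ties resolving to the older midpoint.
Kendall's tau-b summarises pairwise rank agreement (NaN for constant
series). Changes `delta Ne(t) = Ne(t) - Ne(t+1)` (t from present to
past, so negative values mean Ne is lower toward the present) are
averaged in 250-point sliding windows; partial edge windows are
dropped. The randomization test permutes each species' delta vector
independently, re-smooths, and records the maximum
simultaneous-decrease count and the longest run of windows in which
every group member decreases; observed values are compared with the
95th percentile of 10,000 permutation nulls (1,000 in scaled runs).
The longest-run statistic carries the primary significance flag: its
null support is wide enough for an approximately calibrated 5% test
(measured type-I error 0.03-0.065 depending on grid resolution),
whereas the species-count statistic is highly discrete (0..k) and its
exceedance test is conservative; both are reported, with add-one
permutation p-values alongside. A direction flag covers the opposite
reading of the time index, since "consecutive positive deltas" is
ambiguous without one. Whether the smoothing window counts joint-grid
points (assumed) or species-native points is a documented choice.

## Problem sizes in tests and the acceptance script

Scaled study conditions used throughout: epoch-model recovery uses 20
datasets of 10,000 probe-sized loci over 3 Mbp at the angiosperm
mutation rate (the targeted-sequencing scale); divergence selection
uses 20 datasets of n=8+8 haploids over 2 Mbp with truth
`tdiv = 1e5 = 5*2Ne` and symmetric `Nm = 2`; the power scenarios use
n=20 haploids over 6 Mbp at the conifer rate with 5 seeds per cell;
synchrony calibration uses 200 null trajectory sets (120 in the
script) at 1,000 permutations. The acceptance script derives all seeds
from `--seed` and recomputes every quantity from scratch.

## What the synthetic tests do and do not show

The generators match the inference model (unlinked loci, free
recombination between and none within loci, no selection, no
sequencing-error model beyond the paralog injector, demography exactly
piecewise-constant). Passing tests therefore certify the estimators,
the optimizer plumbing, and the test calibrations under the stated
models — not robustness to intralocus linkage, background selection,
reference bias, or mis-specified mutation rates in real data. Real
spectra also mix hierarchical population structure into single-
population fits; the pooled-vs-separate robustness check quantifies
that effect on a given dataset but does not remove it.

## Known limitations

- Expected-SFS computation is limited by float cancellation for very
  large n; trajectory resolution is bounded by the 2..5-epoch family.
- Divergence-model expectations are Monte Carlo; AIC differences
  smaller than a few units are below the method's resolution at the
  default budgets.
- The panmictic members of the divergence set are fitted on the pooled
  spectrum, so their AIC values are comparable with each other but only
  heuristically with the two-deme fits (the workflow they mirror shares
  this property).
- `run_pipeline` orchestrates filtering, spectra, diversity and spatial
  statistics; demographic stages run per population only when enabled,
  and synchrony needs externally assembled trajectory sets.
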