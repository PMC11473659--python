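# glacialsfs

SFS-based population-genomic analysis over glacial timescales: build and
summarise folded site frequency spectra from filtered genotype calls,
quantify diversity and isolation by distance, infer piecewise-constant
demographic histories by composite likelihood, and test whether
effective-population-size trajectories of different species decreased in
synchrony.

The package is written for comparative studies of the kind run on
European forest trees — targeted sequencing of a few Mbp in thousands of
individuals across many populations and several species — and every
stage is exercisable end to end on synthetic data generated by its own
coalescent simulators.

## What it computes

**Diversity.** The folded SFS with missing-data handling (sites with
more than 50% missing calls dropped, the rest projected to half the
sample size by exact hypergeometric expectation), and per-site
nucleotide diversity

```
pi = n / (L (n-1)) * sum over segregating sites of (1 - sum_j p_j^2)
```

which equals the mean pairwise difference per site and is invariant
under down-projection. A 1000-replicate stochastic resampling mode and
the normalized spectrum `phi_i ∝ eta_i i(n-i)(1+[i=n-i])/n` (flat under
the standard neutral model) are included.

**Filters.** Caller-annotation thresholds (QD < 0.25, QUAL < 20,
SOR > 3.0, MQ < 30, MQRankSum < −12.5, ReadPosRankSum < −8.0), genotype
masking (DP < 8 or GQ < 20), HDplot paralog detection (heterozygote
excess H > 0.6 or pooled read-ratio deviation |D| > 20 with
D = (A−B)/√(A+B)), and exclusion of regions where paralog-derived SNPs
exceed 10% within 250 bp, with limits at mid-distance to the next
retained SNP.

**Space.** Weir–Cockerham pairwise FST (ratio of sums over loci),
Rousset isolation by distance `FST/(1−FST) = β ln(d_km) + α`, and
population-specific differentiation scaled by distance.

**Demography.** Analytic expected folded SFS under any
piecewise-constant history (exact Watterson limit), Poisson composite
likelihood, multistart fits of constant-size / 2-epoch / 3-epoch models
with AIC comparison and parametric-bootstrap intervals, a seven-model
divergence set (with/without migration and ancestral size change) whose
two-deme expectations come from a JIT-compiled structured coalescent
with common random numbers, a stairway-style model-flexible Ne
trajectory (bootstrap-resampled AIC-selected epoch fits with percentile
bands), the ten-event glacial-cycle power study, and a
pooled-vs-separate population robustness check.

**Synchrony.** Step-midpoint conversion of trajectories, nearest-step
alignment on the joint time grid, Kendall tau-b matrices, 250-point
sliding means of Ne changes, and a 10,000-replicate randomization test
for simultaneous decreases across a species group.

## Worked example

Fitting a ten-fold expansion (ancestral Ne 10,000 → current 100,000 at
5,000 generations ago) from a simulated spectrum of 20 haploid genomes,
10,000 probe-sized loci over 3 Mbp (`examples/04_epoch_inference.py`):

```
S = 5114 segregating sites
    model  k  loglik      aic  delta_aic
0  epoch2  3  -48.71   103.42       0.00
1     SNM  1 -618.77  1239.54    1136.12
two-epoch estimates (truth: NCUR=1e5, NANC=1e4, TBOT=5000):
  NCUR = 99,946
  NANC = 9,745
  TBOT = 5,008
  NCUR: 95% CI [84,201, 151,911]
  NANC: 95% CI [9,344, 10,164]
  TBOT: 95% CI [4,577, 5,499]
```

The expansion is decisive (ΔAIC ≈ 1100 against constant size) and all
three parameters are recovered within a few percent; the wider interval
on the current size reflects the short time the large population has
had to accumulate rare variants.

The other scripts in `examples/` each demonstrate one capability:
simulation and diversity (01), paralog filtering (02), FST and
isolation by distance (03), glacial-cycle trajectories for annual vs
tree life histories (05), the synchronicity test (06), and the
end-to-end VCF pipeline (07).

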