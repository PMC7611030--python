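# Methods

## Partition statistics

A ddPCR reaction is partitioned into ~15 000–20 000 droplets of nominal
volume *v* = 0.85 nL (QX200; configurable — the instrument vendor does not
expose the exact calibrated value, so concentrations are reported in
copies/µL of reaction under this nominal volume). A target at concentration
λ occupies a droplet with probability `p = 1 − exp(−λv)`, so
`λ = −ln(1 − k/n)/v` from `k` positive of `n` accepted droplets. Replicate
wells (up to 16 per assay) are merged by summing counts, which is exact
under independent Poisson seeding.

**Confidence intervals.** The instrument software's 95% "Poisson CI" formula
is proprietary. We use a Wilson 95% binomial interval on `k/n` pushed
through the monotone map `−ln(1−p)/v`; for ratios (fractional abundance,
fetal fraction) the interval is evaluated at paired per-channel extremes,
which is conservative. Differences from instrument-reported intervals are
expected in the third decimal.

**Saturation.** `k = n` makes λ unbounded; it is a hard error, not a clipped
estimate. Saturated input indicates the sample needs dilution, not a wider
prior.

## Fetal fraction

Per genome equivalent, the mother contributes two copies of the
maternal-channel target and none of the paternal-only target; the fetus
contributes one of each (opposite-homozygote SNP, or ZFX/ZFY for a male
fetus). The paternal channel therefore carries share `f/2` of the assay's
total concentration and

    f̂ = 2·λ_pat / (λ_pat + λ_mat)

identically in both modes. ZFX/ZFY mode is refused unless the fetus is
annotated male, since ZFY carries no signal otherwise. QC uses this point
estimate (not the model posterior): samples with `f̂ < 2%` or fewer than 10
positive paternal droplets are excluded before modelling, as is any sample
whose no-template controls show positives (default tolerance 0 droplets,
configurable because single-droplet artifacts occur in practice).

When no paternal sample exists, candidate informative SNVs are selected
from cfDNA sequencing by keeping sites with minor-allele fraction in the
closed interval [1%, 15%] — the window expected for an allele present only
through the fetal compartment; boundary values are kept.

## The joint model

Latent variables per sample: fetal genotype `G ∈ {hom-ref, het}` and fetal
fraction `f`. Observed: four binomial droplet counts. The variant assay's
reference-channel share is

    θ0 = 0.5 + f/2 (G = hom-ref)   or   0.5 (G = het)
    θ  = b·θ0 / (b·θ0 + 1 − θ0)

where `b` is a per-assay reference-detection bias measured on heterozygous
gDNA controls (`b = λ_ref/λ_var` on the control; `b = 1` when unbiased —
occasionally an assay shows a slight reference bias and the odds-scale
correction reproduces the control's apparent fraction exactly). The
deletion (copy-number) mode replaces the allelic pair with a
target/reference-locus pair: the reference-locus concentration is the free
parameter and the target channel sits at ratio `0.5 + f/2` (fetus hom-ref)
vs `0.5` (fetus carries the deletion); this parameterisation avoids
double-counting the total concentration.

**Priors.** Stated only as "vague" in the source analysis, so chosen here
and configurable: `G ~ Bernoulli(0.5)` (Mendelian segregation from a
heterozygous mother), `f ~ Uniform(0, 0.5)` (fetal fractions above 50% do
not occur clinically), and per-assay total concentrations
`C ~ Uniform(0, 5·Ĉ)` where `Ĉ` is the point-estimate concentration from
the merged counts (scale-free enough at these droplet numbers; an empty
channel is floored at ~1 copy over the pooled droplets so the prior never
degenerates). Tests verify that on informative samples the posterior
probability moves < 0.01 under genotype-prior shifts of ±0.2 and a doubled
concentration-prior ceiling. We use the exact binomial partition likelihood
throughout rather than its Poisson approximation.

## Posterior computation

**Quadrature (deterministic oracle).** Given `f` and `G` the two assays
factorise and each concentration integrates out in 1-D; marginal
likelihoods per genotype are then 1-D integrals over `f`. Trapezoid grids
(default 257 points in `f`, 129 per concentration; a floor of 64 is
enforced) with all sums by log-sum-exp, so valid inputs cannot underflow.
Quantiles come from linear interpolation of the gridded CDF. A point prior
`f_low = f_high = 0` reproduces the identifiability limit: the data cannot
distinguish genotypes and the posterior equals the prior.

**MCMC.** Metropolis-within-Gibbs matching the published schedule (4
chains, 1000-iteration adaptation, 10 000 burn-in, 50 000 sampling =
200 000 retained draws): Gaussian random walks on logit-transformed `f` and
concentrations (flat priors contribute only the transform Jacobian), step
sizes adapted toward 44% acceptance during the adaptation phase only
(Robbins–Monro, frozen afterwards so the chain is Markovian), and an exact
Gibbs draw of the binary genotype from its full conditional each sweep.
The sweep is compiled with numba; chains run sequentially inside the
kernel, each on a deterministic stream fanned out from one integer seed.
Split-R̂ and bulk ESS (via ArviZ) are attached to every run; R̂ > 1.05 on
any continuous parameter flags the result (`converged=False`) rather than
rejecting it, and draws are exportable as a flat CSV for trace plots.
Mode-sticking in the discrete genotype is guarded by the quadrature oracle,
which marginalises the genotype exactly; the test suite holds the two
engines to |Δp| ≤ 0.02 over a 20-sample panel spanning f ∈ [0.02, 0.25].

## Calling and workflow

`P(G = hom-ref | data) ≥ 0.95` calls homozygous reference, `≤ 0.05` calls
heterozygous; both comparisons are inclusive (the boundary convention is
ambiguous in the source description, which labels 0.05 and 0.95 both
conclusive and intermediate; endpoints are resolved as conclusive here).
QC failure pre-empts calling at any threshold. Within a pregnancy, samples
are walked in gestational order (unknown ages sort last, with a warning);
the first conclusive call is final, and opposite conclusive calls raise an
error — observed cohorts show complete within-pregnancy concordance, so
discordance means an assay or labelling fault. Cohort **sensitivity** is
correct conclusive calls over all pregnancies (diagnostic yield ×
correctness, the clinical usage) and **specificity** is correct calls over
conclusive calls; the confusion table is returned so other definitions can
be derived.

## Simulator

Samples are generated from exactly the likelihood's data-generating
process: channel concentrations from `(G, f, C_var, C_ff, b)` via the maps
above, then droplet counts `Binomial(n, 1 − exp(−λv))` per well,
independent across wells and channels (distributionally identical to
molecule-level Poisson seeding, and faster; per-droplet copy numbers are
not simulated). Defaults state the emulated world once: 50 copies/µL total
per assay (a typical cfDNA load: a few hundred positives per
15 000-droplet well), 8 replicate wells per assay, cohort fetal fractions
uniform on the observed clinical range [2.5%, 26.1%], genotypes
Bernoulli(0.5). What the simulator does **not** emulate: fluorescence
amplitudes and rain (counts are taken as called), droplet-volume
variability, gestational-age dynamics of `f`, maternal-cell contamination,
and real assay-to-assay chemistry differences beyond a single
multiplicative bias. A green end-to-end test therefore establishes that the
inference is correct for the stated partition model, not that any
particular wet-lab assay meets spec.

## Numerical notes

- All likelihood math is in log space; binomial coefficients via
  log-gamma.
- `λ = 0` with positive counts yields −∞ likelihood (rejection), never an
  exception inside samplers.
- Parameters proposed outside the prior support are rejected by the
  transform construction (sigmoid maps keep values strictly inside).
- Pipeline reports are byte-deterministic given inputs and a seed;
  timestamps appear only in logs.

## Known limitations

- Single-fetus pregnancies only; no aneuploidy, twin, paternal-variant or
  relative-haplotype-dosage modes.
- The concentration prior ceiling (5× the point estimate) is data-dependent;
  with pathological inputs (near-empty assays) the posterior on `f` is
  prior-dominated, which the QC gates are designed to catch first.
- Wilson-based intervals differ slightly from instrument-reported Poisson
  CIs.
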