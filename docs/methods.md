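# Methods

This document specifies the generative model, the inference scheme, the
forward simulator and the statistical procedures implemented in
`clonemapper`, together with the numerical choices and known limitations.

## 1. Data model

The unit of inference is a square tile (default 100 × 100 µm, half-open, so
a point on a shared edge belongs to exactly one tile). For tile
*i* and probe *j* the observation is the integer count
*N<sub>ij</sub>* of decoded, feasible signals, and the exposure is the tile's
nucleus count *n<sub>i</sub>* from segmented cell centroids (optionally
Gaussian-smoothed; smoothing conserves total mass exactly).

A clone phylogeny with clones *k* = 1…K (plus an obligatory `normal`
component) and a probe panel of mutant/wild-type pairs define the genotype
matrix *G<sub>jk</sub>*: the expected number of template copies of probe
*j*'s allele per cell of clone *k*. Defaults assume heterozygous diploid
SNVs (mutant 1, wild-type 1 in carrying clones; 0 and 2 in non-carriers);
a copy-number table can override total and mutant copy numbers per
(locus, clone).

## 2. Generative model

Per-tile clone fractions are a softmax of latent spatial fields:

  w<sub>ik</sub> = softmax<sub>k</sub>( f<sub>k</sub>(x<sub>i</sub>) ),  f<sub>normal</sub> ≡ 0,

with one 2-D Gaussian process per non-reference component (Matérn-3/2
kernel, default lengthscale 300 µm, unit variance). An optional `artefact`
component with a constant genotype row (default 0.1 for every probe) absorbs
spatially structured, genotype-independent signal.

The expected count is

  λ<sub>ij</sub> = n<sub>i</sub> · [ Σ<sub>j′</sub> M<sub>jj′</sub> · c ·
  e<sub>j′</sub> · s<sub>ℓ(j′)</sub> · Σ<sub>k</sub> w<sub>ik</sub> G<sub>j′k</sub>
  + b<sub>j</sub> ],

where *e<sub>j</sub>* is the per-probe detection efficiency (lognormal
prior, sd 0.5, constrained to geometric mean 1 for identifiability),
*s<sub>ℓ</sub>* a per-locus expression scale shared by a mutant/wild-type
pair (lognormal, sd 0.5), *c* a global scale, *b<sub>j</sub>* a per-probe
unspecific rate per cell (lognormal, median 0.002), and *M* an optional
barcode-confusion matrix (per-position misread model over the panel's
barcodes; column mass lost to infeasible codes is dropped). The likelihood
is negative binomial with a global overdispersion φ (lognormal prior,
median 10) or Poisson.

Regional bulk-WGS VAFs augment the likelihood: for bulk sample *s* with
density-weighted mean fractions w̄<sub>s</sub> over its tiles, the model VAF
of a paired locus is the genotype mixture ratio, and observed mutant reads
are binomial at the reported depth; this term enters with weight κ
(default 1).

## 3. Inference

Inference is stochastic variational with a one-sample reparameterized ELBO
estimate per step and **fully analytic gradients** (hand-derived backward
pass through softmax, misdecoding, likelihood and bulk terms; verified
against central finite differences to < 10⁻⁴ relative error in the test
suite, in practice ~10⁻⁶). The GP fields use a whitened inducing-point
parameterization: a regular inducing lattice (spacing 2 tiles) with
f = K<sub>xu</sub> L<sup>−T</sup> z, z ∼ N(0, I) a priori, mean-field
Gaussian posterior on z, and closed-form Gaussian KL terms. Efficiency,
expression, background and overdispersion use mean-field lognormal
posteriors. Optimization is Adam (ascent, lr 0.05, 3000 steps by default),
deterministic given the config seed. The posterior fraction field summary
(mean, 5–95% band) is computed from 64 GP-noise samples at the optimum.

Numerical choices:

- Tiles with zero nucleus count are excluded from the count likelihood;
  under the cell-scaled model their expected signal is zero, and occasional
  background spots on acellular tiles would otherwise contribute unbounded
  per-cell information.
- Bulk mixture VAFs are clipped to [10⁻⁷, 1−10⁻⁷] with zero gradient in the
  clipped region.
- λ is floored at 10⁻¹² inside logarithms.
- All-zero count tensors short-circuit to a normal-dominated map with a
  warning; non-identifiable components (genotype column identical to
  another component's) are warned about before fitting.

## 4. Post-processing

`dominant_clone_map` projects, per tile, the most prevalent tumour clone,
masked where that clone's cancer cell fraction is ≤ 25% or the cell density
is ≤ 300 cells/mm² (both thresholds overridable, including per-component);
exact ties are broken by component order and flagged. Regional composition
matrices are density-weighted means of the fraction field over region tiles.
Replicate concordance reports per-locus and pooled Pearson correlations of
regional VAF matrices with listwise NaN handling and zero-variance flags.

## 5. Forward simulator

`simulate_territories` draws ground-truth clone territories in one of three
modes: `gp_field` (softmaxed independent GP draws, default lengthscale
800 µm, variance 4 — smooth interdigitated territories), `duct_mosaic`
(single-clone discs grouped into lobules over a normal background,
emulating microanatomically confined clonal sweeps; truth fractions are
computed by 4× supersampling of disc membership), and `half_split`
(deterministic two-clone vertical split for boundary benchmarks). Cells are
placed by a Poisson process (default 1000 cells/mm²; discs 2500 over a
background of 500) and assigned clones from the local truth fractions.

`calibrate_signal_scale` solves in closed form for the global scale making
the expected number of detected signals per nucleus hit the target (default
0.82), of which a fixed share (default 5%) is emitted by the uniform
unspecific background process instead of cells. `simulate_experiment` then
draws per-cell, per-probe Poisson counts through true lognormal efficiencies
(sd 0.5) and expression scales (sd 0.3), jitters spot positions (sd 5 µm),
reassigns 2 × 3% of signals to other barcodes — half to infeasible codes
(so the feasible fraction is 97%) and half to a wrong feasible barcode —
and adds the background field. Replicates are fresh serial-section cell
populations from the same truth; bulk samples are exact quadrant
compositions with binomial depth noise (depth 200).

Benchmark geometry: validation regions are 600 µm-radius discs (1.2 mm
diameter, the scale of laser-capture microdissection samples) placed
round-robin across clone territories with 1.5×-radius spacing; 11 fit on
the default 5 × 5 mm tissue. `benchmark_recovery` scores fraction RMSE over
occupied tiles, mean per-locus Pearson r of raw and imputed regional VAFs
against truth, and (for two-clone layouts) boundary displacement in tiles.

## 6. Territory statistics

- **Differential expression**: per-cell counts normalized by the panel
  total (targeted panels lack a global depth), two-sided Mann–Whitney U,
  Benjamini–Hochberg correction; significant iff q < 0.1 and group-mean
  fold change > 1.5 in either direction. Group sizes below 20 cells raise.
  Note that panel normalization is compositional: a strong spike in one
  gene depresses the normalized values of all others.
- **Cell-type enrichment**: Bayesian Poisson GLMM per (cell type, clone) —
  log E[count] = log total + β₀ + β·fraction + u<sub>region</sub>,
  u ∼ N(0, τ²), β ∼ N(0, 5²), τ ∼ half-Normal(1) — sampled with emcee
  (differential-evolution moves, 4000 steps, 1500 burn, fixed seed;
  covariate centred and walkers initialized at the empirical log-rate).
  Convergence is flagged by split-R̂ < 1.05 on β; two-sided posterior tail
  probabilities are BH-corrected across comparisons.
- **Histology association**: Fisher's exact test per feature on the
  clone × category table — exact for 2×2, full fixed-margin enumeration for
  small r×c tables, Monte-Carlo fallback for large ones — with Bonferroni
  correction across tested features; single-category features are skipped
  with a notice.

## 7. Problem sizes and runtime

Single CPU, float64 throughout. The default benchmark (5 × 5 mm → 2500
tiles, 50 probes, 6 components, ~1000 inducing points, 3000 SVI steps) fits
in ~60–90 s. Memory stays well under 1 GiB. The dominant costs are the
(T × M) projector matmul per step and the initial Cholesky of the inducing
kernel.

## 8. Limitations

- The variational posterior is mean-field in the whitened inducing values;
  credible bands on the fraction field ignore posterior correlations
  between components and are typically mildly overconfident.
- Probe efficiencies and the expression scales are global, not spatial;
  spatially varying detection (e.g. section-edge effects) is only absorbed
  by the artefact component.
- The misdecoding matrix models independent per-position misreads; real
  crosstalk between optically similar barcodes is structured.
- The GLMM treats the clone fraction covariate as known, ignoring its
  posterior uncertainty.
- The simulator draws expression per locus, not per cell type, and places
  cells by an inhomogeneous-in-label but spatially Poisson process; it does
  not model cell segmentation errors or optical crowding saturation.
- `duct_mosaic` truth fractions are supersampled approximations near disc
  boundaries (exact to the 25 µm sub-grid).
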