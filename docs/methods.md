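# Methods

## The selection-strength model

A variant's expected share of trait heritability is modelled as

    E[h²_j] = h² · ω_j [2 f_j (1 − f_j)]^(α+1) / Σ_l ω_l [2 f_l (1 − f_l)]^(α+1) ,

so the shares sum to h² exactly. The exponent α couples squared per-allele
effects to heterozygosity: α = 0 means effect size is frequency-independent
(per-SNP heritability grows with heterozygosity), α = −1 means per-SNP
heritability is flat, and α < −1 means rare variants carry more heritability
than common ones. ω_j is a SNP weight, by default the inverse LD score
1/ℓ_j (ℓ_j = Σ_l r²_jl within the variant's LD block); with annotations the
expectation is a sum of per-stratum terms of the same form, one non-negative
h² contribution per stratum.

Marginal association statistics are inflated by LD ("LD dilution"):

    e_j = 1 + n_j · Σ_{l ∈ block(j)} r²_jl · E[h²_l] ≥ 1.

The observed χ² statistic S_j = z_j² is treated as scaled χ²₁, S_j ~ e_j·χ²₁,
giving the weighted quasi-log-likelihood

    ℓ = Σ_j κ_j [ −½log 2π − ½log S_j − ½log e_j − S_j/(2 e_j) ] ,  κ_j = ω_j .

The weights counter LD double-counting; with independent SNPs, unit weights
and Gaussian effects this is the exact marginal likelihood, which is what
makes the recovery tests sharp. Statistics below 1e−8 are floored before
the log term (a measure-zero event in continuous data).

**Profile fit.** For each α on a grid (default 31 points, −1…0.5, step
0.05) the likelihood is maximized over h² ∈ [0, 1] by bounded scalar search
(tolerance 1e−6 on h²; the h² = 0 boundary is checked explicitly). A
quadratic is least-squares fitted to the 7 grid points centred on the
profile maximum and its vertex polished on a fine local grid (quarter steps
within one step of the coarse vertex): the quadratic approximation to a
log-likelihood is a statement about the neighbourhood of its maximum, and
fitting the whole grid lets the far tail of an asymmetric profile drag the
vertex; the two-stage local fit is unbiased in simulation and reduces to the
full-grid fit whenever the profile is exactly quadratic. The MLE is the
vertex −b/(2a), its variance 1/(−2a) (the inverted negative Hessian), and
the two-sided Wald P follows. If the vertex lands within one grid step of a
range boundary the range is extended, once per side, to [−2, 1] (left) or
[−1, 4] (right) and the fit repeated.

**Stability.** A fit is flagged stable iff the quadratic is concave
(a < −1e−6), describes the fitted points well (R² ≥ 0.95 on the fit
window) and the vertex lies strictly inside the final range — an
automatable proxy for visual inspection of profile smoothness; thresholds
are arguments. Unstable fits withhold α̂ and SE.

## Synthetic data: what it emulates

All generators take explicit seeds and are byte-reproducible.

* **Panels.** MAF uniform on [maf_low, maf_high]; contiguous near-equal LD
  blocks with exchangeable correlation (scalar ρ, or a (lo, hi) range drawn
  per block — the range is what gives LD scores spread, which LD-score
  regression needs). ℓ_j and ω_j = 1/ℓ_j follow from the block matrices;
  non-PSD requests are rejected.
* **Effects under the α model.** A causal subset of size
  round(prop_causal·M) (default prop_causal = 1: the fully polygenic case,
  under which the quasi-likelihood is exactly specified) receives
  b_j ~ N(0, c·ω_j[2f_j(1−f_j)]^α) with c solving Σ E[b²]·2f(1−f) = h².
* **Effects under selection-coefficient coupling.** b = δ·S^τ·(1+ε)·sign
  with S ~ Gamma(shape, scale) and ε ~ N(0, noise_sd²); heterozygosity is
  re-drawn as h_j ∝ h_base^(1−γ)·(b_j²)^(−γ) with γ = κ/(1+κ) for coupling
  strength κ. The `strong_selection_limit` preset (γ = 1) makes
  b_j²·2f_j(1−f_j) exactly constant — the architecture the α model
  identifies as α = −1. Only this limit is quantitatively pinned down by
  theory; the rest of the parametrization is a design choice.
* **Summary statistics.** Per LD block, z ~ N(√n·R·b*, R) with b* the
  standardized effects (b* = b·√(2f(1−f))) — the generative twin of the
  expected-χ² model, so generator and estimator are self-consistent.
* **Metabolite sets.** One shared causal set; per causal SNP a k-vector
  u ~ N(0, Σ_g) (Cholesky mixing) scaled by each metabolite's architecture.
  Metabolites with equal α have genetic correlation Σ_g exactly; unequal α
  attenuates it slightly.
* **MR datasets.** True instrument effects g ~ N(0, h²_per_instrument);
  observed exposure effects add noise at SE 1/√n_exp; outcome effects are
  θ·g plus optional pleiotropic noise plus noise at SE 1/√n_out. Defaults
  (30 instruments, h² per instrument 0.01, n = 100,000 both sides) keep
  weak-instrument attenuation around 0.1% — negligible against the
  estimator's SE.
* **Brownian traits.** Tips ~ N(root, rate·C) with C the shared-branch-length
  matrix; random study trees are built by repeatedly joining uniformly
  chosen subtrees with uniform branch lengths on [0.2, 1].

**What the generators do not emulate:** real LD (block-exchangeable only),
allele-frequency spectra (uniform MAF, no demography), confounding or
stratification in the GWAS (the intercept is assumed clean, as the model
assumes), sample overlap between traits, non-Brownian trait evolution, and
measurement platform effects. Passing tests therefore demonstrate internal
consistency of estimators with their generative models at desk scale, not
robustness to the misspecifications real data carry.

## Downstream analyses

**IVW MR.** θ̂ = Σ β_X β_Y/se_Y² / Σ β_X²/se_Y², SE = (Σ β_X²/se_Y²)^(−1/2),
fixed-effect, first-order weights; one instrument reduces exactly to the
Wald ratio. Harmonization joins on variant, sign-flips outcome effects
coded on the swapped allele, accepts strand-complement codings, and drops
palindromic (A/T, C/G) variants — conservative and deterministic.
Estimates with |θ̂| > 0.5 (strict) are flagged as exposure/outcome overlap
artefacts and excluded from the importance score Σ_traits |θ̂|. Instrument
selection (where needed) uses P < 5e−8 and one variant per LD block.

**Conservation.** Concentrations are log-transformed before the Brownian
fit (Brownian motion on a ratio scale is ill-posed; rank aggregation
downstream limits sensitivity; the transform is an argument). The GLS rate
uses the (n−1) REML-style denominator — unbiased under the model. Missing
species are handled by pruning (the covariance of a tip subset is the
corresponding submatrix). Scores are ranked ascending within organs with
average ranks on ties; a metabolite's missing organs are imputed with its
median score over measured organs; the aggregate is the median rank across
organs; metabolites measured in fewer than two organs are excluded.

**Genetic correlations.** E[z1 z2] = √(n1·n2)·ρ_g·ℓ/M + intercept; the
weighted-regression slope times M/√(n1·n2) estimates ρ_g; the free intercept
absorbs the null expectation and sample overlap. SEs by delete-one-block
jackknife over LD blocks. Order of operations, as a fixed pipeline:
estimate → zero entries with P > 0.05 (covariance scale, diagonal
untouched) → precision-weighted bending → normalize. Bending iterates:
eigen-floor the negative eigenvalues, then move each off-diagonal entry a
fraction step·mobility toward the projection with mobility ∝ its estimation
variance (precise entries move least; the diagonal never moves; step 0.5;
at most 1,000 iterations, else an error with diagnostics). PSD inputs pass
through unchanged and the operation is idempotent. Normalization
eigen-floors rounding-level negatives (< 1e−6) so Σ round-trips through
files robustly.

**Correlation-adjusted statistics.** With standardized x and y, the OLS
slope r̂ = (yᵀx)/(xᵀx) is kept as the estimator (unbiased under correlated
errors) and only its variance is adjusted: Var(r̂) = σ̂²·xᵀΣx/(xᵀx)² with
σ̂² = RSS/(n−1) — on the standardized scale diag(Σ) = 1 makes the marginal
residual variance σ². The modified Q uses class means m = Vα̂ with
V rows v(i) (1/n_i on members), Ω = diag(SE)·Σ·diag(SE), W = VΩVᵀ, centers
d = m − ᾱ (ᾱ = unweighted mean of class means; mean over metabolites is an
option) and takes Q = dᵀ·pinv(DWDᵀ)·d, D the centering projector. The
pseudoinverse is deliberate: the plain quadratic form in W cannot be
χ²_{K−1}-distributed, while the inverse-covariance form is exactly so under
the null — confirmed by the 10,000-draw calibration test. Class-versus-rest
uses w = 1/n_i on members, −1/n_(−i) elsewhere, variance wᵀΩw. Per-trait
slope tables carry Benjamini–Hochberg flags at FDR 0.05.

## The end-to-end synthetic study

The pipeline couples one metabolite-level parameter, α_m (evenly spaced
over [−1, 0.4] across 12 metabolites, classes assigned in contiguous
chunks so class means differ), to the two downstream layers: Brownian
rates rate_m ∝ exp(+1.5·α_m) (strong selection ⇒ slow concentration
evolution ⇒ high conservation) and causal-effect scales
∝ exp(−1.2·α_m) (strong selection ⇒ large effects on traits). The study
uses flat SNP weights (ω ≡ 1): under ω = 1/ℓ the generator's per-SNP
heritability is ∝ 1/ℓ and LD-score regression attenuates to zero, so the
flat-weight condition is the one in which the α fit and cross-trait LDSC
are simultaneously well-specified. The expected signatures — negative
Σ-adjusted slope of conservation rank on α̂, negative per-trait and
importance slopes, large heterogeneity Q — all emerge from the fitted
pipeline, not from the generator directly.

Problem sizes (6,000 SNPs in 300 blocks, n = 50,000, h² = 0.4, 12
metabolites, 26 species, 4 organs, 8 traits × 30 instruments) were chosen
so a full run takes about two seconds while every stage still has clear
signal; the recovery and calibration studies in the test suite use 20,000
independent SNPs (α recovery), 500–2,000 replicate datasets (IVW, slope
coverage, Brownian rates) and 10,000 null draws (Q calibration).

## Known limitations

* The quasi-likelihood ignores between-SNP dependence of χ² statistics
  beyond the mean structure; with strong LD its SEs rely on the ω weighting
  rather than a sandwich correction.
* Per-variant sample sizes enter e_j directly; no special treatment of
  heterogeneous-n meta-analysis artefacts.
* Cross-trait LDSC is only exact for flat-weight, α = −1 architectures;
  for other α it is the field-standard approximation.
* Bending holds the diagonal fixed; a matrix whose indefiniteness can only
  be cured by inflating variances would hit the iteration cap and error.
* The α fit's range extension stops at [−2, 1] / [−1, 4]; profiles whose
  maximum lies outside are flagged unstable rather than chased.
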