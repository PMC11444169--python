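# metabsel

Natural-selection inference on metabolite levels from GWAS summary
statistics, with downstream links to disease relevance and cross-species
conservation — exercised end to end on synthetic data with known ground
truth.

## The scientific problem

Stabilizing selection purges alleles with large effects on a trait, so under
selection the squared per-allele effect of a variant falls with its
heterozygosity. The strength of that coupling is summarized by the exponent
α of the MAF/LD-dependent heritability model

    E[b_j² | f_j, ω_j] = (h²/M) · ω_j · [2 f_j (1 − f_j)]^α ,

where `b_j` is the per-allele effect of SNP j, `f_j` its minor allele
frequency, `ω_j` an LD-based SNP weight (default 1/ℓ_j with ℓ_j the LD
score) and h² the trait heritability. α < 0 indicates stabilizing
selection; α > 0 directional or disruptive selection; α = −1 is the
strong-selection limit of selection-coefficient (Eyre–Walker-type) models,
in which every variant contributes equal expected heritability.

`metabsel` implements, for users who work with GWAS summary statistics and
comparative metabolomics:

* **α estimation** — marginal χ² statistics are modelled as scaled χ²₁ with
  LD-diluted expectation `e_j = 1 + n Σ_l r²_jl E[h²_l]`; h² is profiled out
  on a 31-point α grid (−1…0.5, step 0.05, automatic extension to [−2, 1] or
  [−1, 4]); a quadratic fitted around the profile maximum gives the MLE and
  its curvature-based SE.
* **IVW Mendelian randomization** — harmonization, fixed-effect
  inverse-variance weighting, the |θ̂| > 0.5 exposure/outcome-overlap
  filter, and the per-metabolite importance score Σ_traits |θ̂|.
* **Cross-species conservation** — GLS Brownian-motion rate per metabolite
  per organ on a species phylogeny; conservation score = 1/rate; median-rank
  aggregation across organs with median imputation and leave-one-organ-out.
* **Genetic correlations** — cross-trait LD-score regression, zeroing of
  non-significant covariances (P > 0.05), precision-weighted bending to
  positive semidefiniteness, normalization to Σ.
* **Correlation-adjusted inference** — the random-effect slope
  r̂ = (yᵀx)/(xᵀx) with Var(r̂) = σ²·xᵀΣx/(xᵀx)², a modified Cochran's Q for
  heterogeneity of class means of correlated estimates (χ²_{K−1}), and
  class-versus-rest contrasts.
* **Synthetic data** — seeded generators for every input: SNP panels with
  block LD, effects under the α model or the selection-coefficient coupling,
  marginal summary statistics, correlated metabolite sets, MR instrument
  sets, and Brownian traits on trees.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (about 20 s in total):

```bash
python analysis/01_simulate_inputs.py      --seed 1 --out results/study
python analysis/02_fit_selection_strength.py --seed 1 --out results/study
python analysis/03_strong_selection_limit.py --seed 1
python analysis/04_genetic_correlations.py --seed 1 --out results/study
python analysis/05_mendelian_randomization.py --seed 1 --out results/study
python analysis/06_conservation_scores.py  --seed 1 --out results/study
python analysis/07_correlated_inference.py --seed 1 --out results/study
```

Script 03 simulates the strong-selection limit (squared effects ∝ inverse
heterozygosity) and prints

```
"mean_alpha_hat": -1.021244636917353,
"expected": -1.0
```

— the profile fit identifies the frequency-independent architecture as
α ≈ −1, extending its grid to [−2, 1] to do so.

Script 07 joins the fitted α̂ values with conservation ranks and MR
importance under the estimated metabolite correlation matrix Σ and prints
(seed 1):

```
"alpha_vs_conservation_slope": -0.8288970831387477,
"alpha_vs_conservation_p": 1.4872212457694682e-08,
"Q": 87.15938706506134,
"Q_p": 8.924346708328895e-19,
"n_traits_negative_slope": 8
```

The negative conservation slope says metabolites under stronger stabilizing
selection (lower α̂) evolve more slowly across species — the direction the
generative coupling encodes; Q rejects homogeneity of α across the
metabolite classes, which the simulation makes genuinely heterogeneous; and
all 8 per-trait slopes of |causal effect| on α̂ are negative, i.e. strongly
selected metabolites have larger effects on complex traits.

The same stages are available as a CLI (`metabsel simulate|alpha|gencorr|
mr|conserve|stats|run-all|conserve-loo`, with `--config`, `--seed`, `--out`,
`--grid-lo/--grid-hi/--step`, `--organs`) over flat `key = value` config
files.

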