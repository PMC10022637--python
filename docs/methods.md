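# Methods

## Statistical model

All association tests are built on the polygenic linear mixed model

    y = W a + x_j b_j + g + e,   g ~ N(0, s2_g K),   e ~ N(0, s2_e I),

where `y` is the per-variety phenotype, `W` the fixed covariates (always
including an intercept; conditioning markers are appended here), `x_j` the
alt-allele dosage of the tested marker, and `K` the VanRaden realized
relationship matrix `K = W_c W_c' / (2 Σ p_k (1 − p_k))` computed from
column-centered genome-wide dosages. Variance components are estimated by
REML: after one spectral decomposition `K = U Λ U'`, the profile
restricted likelihood is a function of the single ratio
`δ = s2_e / s2_g`, evaluated on a 41-point grid of `log δ ∈ [−10, 10]`
and refined by bounded scalar minimization (`xatol = 1e−8`). This is the
EMMA device; it makes the null fit exact and cheap.

**Quantitative scan.** By default the scan is P3D/EMMAX: `(s2_g, s2_e)`
are fixed at their null estimates and each marker is tested by generalized
least squares under `V = s2_g K + s2_e I`, vectorized across markers via
block elimination of the augmented normal equations. The reported p-value
is a Wald F with a per-marker re-estimated residual scale and `n − c − 1`
denominator degrees of freedom; this reduces *exactly* to the OLS F test
when `s2_g = 0`. Exact per-marker REML refitting (`p3d=False`) exists for
small problems; at genome scale the two differ negligibly because no
single marker dominates K.

**Binary scan.** 0/1 traits are analyzed with the same linear mixed model
(no logistic link, matching common binary GWAS engines for inbred panels).
The statistic is the score `U² / Var(U)` with `U = x' P y` under the null
fit. The p-value uses the exact finite-sample null of the statistic — its
monotone map through the partial correlation to `F(1, n − c − 1)` — rather
than the asymptotic χ²₁: at a few hundred varieties the χ² reference is
measurably deflated (genomic-control λ ≈ 0.97 on null simulations) while
the F reference is centered.

**Degenerate inputs.** If the fixed effects explain the phenotype exactly
(residual variance below `1e−8 × Var(y)`, e.g. conditioning on the causal
marker of a noiseless trait), every remaining marker is reported with
p = 1 — there is nothing left to map. p-values are floored at the smallest
positive double, so `-log10 p` stays finite. Markers monomorphic in the
analysis sample, or with |r| ≥ 1 − 1e−10 to a covariate column, are
excluded with a reason string instead of a p-value.

## Multiple testing and peaks

SimpleM processes each chromosome in consecutive non-overlapping windows
of ≤ 200 markers; each window contributes the smallest number of leading
eigenvalues of its marker Pearson-correlation matrix reaching 99.5% of the
eigenvalue total (the fraction from the original SimpleM recommendation;
both knobs are arguments). `M_eff` is the sum over windows and
chromosomes. Genome-wide cutoffs are `−log10(α / M_eff)` at α = 0.1 and
0.2. Monomorphic markers inside a window carry no correlation information
and are counted as one test each (a deliberately conservative choice; they
cannot occur after QC).

Peak calling is deterministic: markers at or above the cutoff, within
`merge_gap` bp on the same chromosome, form one region, padded by `pad`
bp on both sides (half-open, clipped at zero). Defaults are
`merge_gap = 300 kb`, `pad = 100 kb`; analyses of the simulated panels use
1 Mb / 300 kb so a region spans enough markers for profile correlation —
region scale should track the LD scale of the data at hand.

## The identity test

Method 1 conditions cohort A's scan on cohort B's *genome-wide* top marker
(mapped through the shared-marker table; if the exact marker was not
genotyped in A, the shared marker with max |r| to it within panel B is
used, refusing proxies with |r| < 0.8). Status is judged against the
lenient α = 0.2 cutoff: below it "disappeared"; at or above it but with
the region maximum dropping by ≥ 50% of its unconditional value,
"attenuated"; otherwise "persisted". If conditioning excludes every region
marker (all perfect proxies), the signal is by construction fully absorbed
and the conditional maximum is reported as 0. Method 2 computes R², the
squared Pearson correlation of the two scans' `−log10 p` values over
shared tested markers inside the region (≥ 3 required). The combination
rule is: disappeared ∧ R² ≥ 0.4 ⇒ `identical`; attenuated ∧ R² ≥ 0.4 ⇒
`partially_shared`; persisted ∧ R² < 0.4 ⇒ `distinct`; anything else
`inconclusive`. The 0.4 floor, the 50% attenuation band, and the lenient-
cutoff disappearance rule are explicit parameters — the underlying
judgment is inherently a calibration choice, so the defaults are exposed
and echoed in all reports.

## Phenotype preparation

Multi-environment records are adjusted with `value = μ + variety(fixed) +
u(location×year)(random, iid) + residual`, fit by the same REML machinery
with `K = Z_env Z_env'`; the returned per-variety values are BLUEs
(cell-means coding). Fixed variety effects avoid the shrinkage that would
attenuate downstream GWAS effect sizes; a random-variety BLUP mode exists
as an option. A single observed environment reduces to the raw per-variety
means. Heading dates map to integer days after July 1. Trait-type
designation calls a trait binary when one level holds ≥ 80% of
observations or exactly two levels occur — a numerical stand-in for
"extremely unidirectional by histogram"; the cutoff is an argument.
Ordinal color scores are treated as numeric for quantitative analysis and
binarized by thresholds (score ≤ 1 vs ≥ 2 for any-color; ≤ 4 vs ≥ 5 for
tone). Standardization is plain z-scoring (unit SD); scan p-values are
invariant to it and effects become per-SD units comparable across traits.

## Group comparisons

Haplotypes are assigned by exact match of rounded dosages at defining
polymorphisms; heterozygous calls at defining markers yield "unassigned"
(the panels emulated are inbred). Cross-classified functionality groups
are compared per trait by one-way ANOVA; if significant at α = 0.05,
all-pairs Tukey–Kramer HSD (unequal n) with adjusted p-values from
`scipy.stats.studentized_range`, cross-checked in the test suite against
statsmodels' `pairwise_tukeyhsd` to 1e−6. The compact letter display
assigns one letter per maximal clique of the non-significance graph
(Bron–Kerbosch), so two groups share a letter **iff** their adjusted
p ≥ α; ties at exactly α count as non-significant.

## Synthetic panels

Genotypes follow a founder-mosaic model: per chromosome, `n_founders`
haplotypes are drawn with per-marker alt frequency uniform on
`[maf_floor, 1 − maf_floor]`; each individual's chromosome copies are
founder mosaics with an independent per-interval switch probability
(default 0.02), giving block LD with monotone decay in marker distance.
Defaults: 8 founders, 4 chromosomes × 300 markers over 30 Mb, maf floor
0.1, 2% missing calls injected uniformly (to exercise QC and imputation),
diploid from two independent mosaics. An `inbred` flag doubles a single
haplotype instead — rice varieties are near-homozygous — but both modes
exercise identical downstream math, so the default stays diploid.
Quantitative traits add Gaussian noise scaled so `Var(g)/Var(y)` hits the
requested h² in expectation; binary traits threshold a liability at its
empirical `(1 − prevalence)` quantile so realized prevalence is exact in
every sample; legacy replicates add one shared Gaussian offset per
location-year (sd `env_sd`), per-record residual noise, and random
thinning (default keep 0.8). Two-cohort scenarios draw both panels from
one founder pool with configurable variety overlap (default 0.5 — the real
panels' overlap is unknown, so it is a free parameter) and marker overlap
(default 0.7), always force-retaining causal markers in both marker sets;
causal markers are chosen near the chromosome midpoint subject to
segregating (MAF ≥ 0.15) in every panel.

What the generator does *not* emulate: realistic recombination maps and
demography, selection, multi-allelic sites, genotyping error beyond
missingness, or environment-by-genotype interaction. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every artifact of real regeneration data.

## Validation studies (problem sizes)

The built-in studies in `legacygwas.validation` use: null calibration at
n = 500, m = 2000 over 20 replicates — on *unlinked* markers
(`switch_rate = 1`), because LD only inflates the sampling variance of the
genomic-control median without changing a single-marker test's marginal
calibration; identity-test operating characteristics at n = 300 per
cohort, h²_QTL = 0.3, marker overlap 0.7, 4 × 500 markers (≈ 60 kb
spacing, so a peak region holds a realistic number of shared markers),
50 replicates per scenario; REML heritability recovery at n = 500,
h² = 0.5, 20 replicates; standardized-effect recovery over 20 scenarios
with planned effects 0.05–0.5 SD at n = 500; environment adjustment at 150
varieties × 6 locations × 3 years, env sd 5, residual sd 1, 50% thinning.

## Known limitations

* The binary score test is a linear-model approximation; heavily
  unbalanced case/control splits (< 5 per class) trigger only a warning.
* P3D deflates signals that contribute appreciably to K ("proximal
  contamination"); at the simulated marker counts the effect is
  negligible, but exact REML (`p3d=False`) is the check when in doubt.
* Method 2's R² is unstable below ~10 shared markers; the pipeline
  reports `inconclusive` rather than guessing when fewer than 3 are
  available, but values from small regions deserve skepticism.
* `adjust_env` assumes iid location-year effects; spatial field trends
  and genotype-by-environment interaction are out of scope.
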