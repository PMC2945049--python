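# Methods

## Scientific setting

Systemic lupus erythematosus (SLE) is serologically heterogeneous: patients
differ in which autoantibodies they carry (anti-Ro, -La, -Sm, -RNP,
anti-dsDNA) and in serum interferon-alpha (IFN-α) activity, and both traits
are heritable. `poolgwas` implements an extremes-of-phenotype, case-case
screening design for mapping such subphenotypes with a small cohort:
patients from the top and bottom tertiles of serum IFN-α, co-stratified by
antibody positivity and ancestry, are genotyped as pooled DNA on SNP
arrays; candidate SNPs are selected by a multi-step ranking algorithm and
then tested individually in an independent case cohort against antibody
and IFN-α outcomes, plus a conventional case-control contrast.

The package has five parts: a synthetic-data generator that emulates the
whole study design (no public data exist for it), the pooled-screen
statistics, the candidate-selection algorithm, the validation-stage
statistical battery, and a CLI that chains the stages reproducibly.

## Pooled-screen statistics

For probe *p* of a SNP in pool *j*, the relative allele signal is
RAS = A/(A+B), the A-channel share of hybridization intensity — a proxy
for the pool's A-allele frequency. Per pool we take the mean r_{i,j,k} and
unbiased variance v_{i,j,k} of RAS across the 8 (or 12) probes (i = group,
k = ancestry). Pools with fewer than two surviving probes (a probe is
dropped when A+B = 0) fail QC for that SNP.

Group summaries weight pools by inverse probe-level standard deviation,
normalized to sum to one:

    w_j ∝ 1 / max(sd_j, 1e-6),   r_{i,k} = Σ_j w_j r_{i,j,k},
    v_{i,k} = Σ_j w_j² v_{i,j,k} / n_probes_j

v_{i,k} is the sampling variance of the weighted mean under independent
probe noise. The SD floor (1e-6 on the RAS scale) gives constant-RAS pools
a large but finite weight. A `variant="printed"` switch reproduces an
alternative published form of these sums (r = Σ r/v, v = Σ(v/n)²) for
comparison; it is not a mean and not used by default.

The cross-ancestry statistic Studentizes the high-low difference within
each ancestry and combines the terms Stouffer-style:

    Z = (1/√K) Σ_k (r_{1,k} − r_{0,k}) / √(v_{0,k} + v_{1,k})

Per-ancestry Studentization makes Z robust to allele-frequency
heterogeneity and population stratification (no between-ancestry contrast
is ever formed); the 1/√K factor keeps Z approximately standard normal
under the null for any number of ancestries K — without it the null SD is
√K, which would make the statistic's scale depend on how many ancestries
were retained after QC. The raw sum is available via `normalize_z=False`.

Calibration is defined against the **intensity-noise null**: all pools
share one true dosage fraction and differ only by probe noise. Under that
null (2000 SNPs, default 26-pool design) the empirical SD of Z is ≈ 1.1
and the |Z| > 1.96 rate ≈ 0.077 — slightly heavy-tailed because the group
variances are estimated from only 2–6 pools × 8 probes, making each term
t-like with modest degrees of freedom. Under the *full* generator the null
spread of Z is far larger: pools are random draws of 8–48 chromosomes, so
pool-to-pool binomial composition variance (SD ≈ 0.1–0.16 on the frequency
scale) dwarfs probe noise, and the probe-variance-based weights do not
model it. This is a property of the design being emulated, not an
implementation artifact; it is why the screen is treated as an enrichment
device, never as a calibrated test.

The Silhouette score complements Z: with clusters fixed by phenotype label
and |Δ mean RAS| as the distance, each pool scores s = (b−a)/max(a,b)
(s = 0 for singleton clusters or when max(a,b) = 0), averaged over pools.
It operates on pool-level means; probe-level variants exist but are not
reproduced here.

## Candidate selection

1. Rank by |Z| descending (either allele may be enriched in either group,
   so the sign is not informative); keep the top 200.
2. Remove SNPs whose Silhouette rank (descending) exceeds 200.
3. Re-rank survivors by |Z|; keep the top 50.
4. Keep SNPs within 100 kb of a named gene whose locus carries an
   immune-relevance flag; when two survivors share a gene, keep the
   |Z|-stronger one.

Ties break by Silhouette descending, then SNP id, making the output
deterministic. The immune-relevance flag is an *input*: it stands for an
expert literature/database review that cannot be mechanized faithfully.
The 100 kb "near a gene" window is configurable; validated associations in
this literature sit > 100 kb from gene bodies, so the default is
deliberately generous.

## Validation-stage statistics

- **QC**: call rate must exceed 0.98 and the exact Hardy-Weinberg test
  must give P > 0.01 within every ancestry. The HWE test enumerates all
  heterozygote counts conditional on allele counts and sums probabilities
  ≤ the observed configuration's (monomorphic SNPs: P = 1); the exact test
  is used because per-ancestry genotype-class counts can be small.
- **Serology screening**: per ancestry set and antibody, a logistic model
  with additive 0/1/2 genotype coding, backward elimination of predictors
  with P > 0.1 (Wald), complete cases per model. If ≥ 2 SNPs survive,
  pairwise interaction terms are added and subjected to the same
  elimination. Degenerate or separated fits are flagged and dropped from
  retention rather than raising. Joint ancestry sets pool subjects with a
  forced ancestry-indicator covariate (the alternative — stratified fits —
  is not implemented; the indicator-covariate form keeps one OR per SNP).
- **Combination outcomes**: when one SNP associates with two antibodies,
  derived outcomes (x AND y; x AND NOT y, directions from the coefficient
  signs) are compared against the individual-antibody models by AIC. The
  combination is reported as best fit only when its AIC undercuts the best
  individual model by ≥ 2 — the conventional "positive evidence" edge,
  used because the outcomes differ so likelihood-ratio tests do not apply.
- **Odds ratios**: Wald, exp(β ± 1.96 se) — symmetric on the log scale,
  matching how such intervals are printed.
- **IFN-α comparisons**: two-sided Mann-Whitney U; exact enumeration when
  the combined n ≤ 20 without ties, tie-corrected normal approximation
  (no continuity correction, so identical samples give P = 1) otherwise.
  Genotype grouping is dominant (carriers vs non-carriers) for stratified
  comparisons; homozygote-vs-homozygote is available. The activity score
  is (raw − reference mean)/reference SD against a healthy reference
  population.
- **Case-control**: 2×2 allele-count table (two alleles per subject),
  1-df chi-square without continuity correction, Woolf-interval allelic
  OR; zero cells flag the OR as undefined.
- **Ancestry PCs**: genotype matrix mean-imputed per SNP, columns
  standardized, PC1 from the SVD, sign fixed so the first subject scores
  ≥ 0. Subjects split at the median PC1 ("central value"; midrange
  available) into two bins; each self-reported group's concordance is its
  majority-bin fraction; independence is tested by chi-square. Antibody
  models are refit with PC1 as a quantitative covariate and the
  coefficient changes reported without any automatic significance verdict.
- **Multiplicity**: P-values are reported unadjusted; Bonferroni
  thresholds (α/#SNPs and α/(#SNPs × 5 traits)) accompany the run summary.

## Synthetic-data generator

The generator's defaults are the emulated study's design: a screening
cohort of 104 SLE patients (high-IFN/antibody-positive vs
low-IFN/antibody-negative: Asian 8/8, African 12/8, European 12/24,
Hispanic 12/20), pooled four at a time within (ancestry, group) strata
(26 pools); a validation cohort of 538 cases (African 280, European 173,
Hispanic 85) and 522 controls (African 361, European 161).

Key modeling choices, with defaults:

- **Genotypes**: per-(SNP, ancestry) baseline frequency uniform on
  (0.05, 0.5); HWE draws Binomial(2, p); SNPs independent (no LD).
  Spiked SNPs add a configurable delta to the high group's frequency.
- **Probe intensities**: a fixed total intensity (2000 arbitrary units)
  split between channels by the pool's true dosage fraction, plus
  independent Gaussian noise per channel (SD 50 units, truncated at 0 —
  the simplest model producing the probe-level RAS variance the weighting
  scheme needs; 50/2000 yields probe RAS noise of ~0.02–0.035, typical of
  pooled-array data).
- **Antibodies**: case prevalences Ro 0.30, La 0.12, Sm 0.15, RNP 0.25,
  dsDNA 0.35 (typical SLE cohort values); a shared standard-normal latent
  factor with loadings (Sm 1.0, RNP 1.0, others 0.3) induces the
  clinically observed co-occurrence structure, which the
  combination-outcome machinery needs. Configured effects enter as
  per-allele log-odds; combination effects ("x+y", "x-y") draw the joint
  event from its own logistic model and fill the complement by rejection
  from baseline marginals. Controls carry a flat 2% prevalence.
- **IFN-α**: log-normal raw activity (log-mean 0, log-SD 0.8), location
  shifted by +0.8 on the log scale when the configured scenario's
  indicator fires: `independent` (risk-allele carrier), `antibody_mediated`
  (antibody-positive), or `cooperative` (both together) — the three
  association patterns the validation stage must distinguish. Scores are
  standardized against a reference mean 1.0 and SD 0.5. IFN-α is strongly
  right-skewed in patients, hence log-normal rather than normal.
- **Age**: cases ~N(40, 12), controls ~N(50, 12) years (controls older by
  design); age is deliberately not linked to genotype.

What the generator does **not** emulate: linkage disequilibrium, array
image artifacts, batch effects, differential DNA quality between pools,
antibody assay error, and admixture gradients within self-reported
ancestries (ancestry enters only through allele-frequency differences).
Passing tests therefore demonstrate correctness of the statistics and
procedures under the stated model, not performance on real arrays.

## Problem sizes and numerical conventions

Simulation-based tests use sizes chosen to give stable Monte-Carlo
verdicts at desk scale: 2000 SNPs for null calibration of Z; 500
replicates for odds-ratio recovery (at the design's stratum sizes, n=280
and n=258); 300–500 replicates for stepwise retention and CI coverage;
full enumeration oracles up to n=12 (Mann-Whitney) and all genotype
tables up to n=12 plus random tables to n=50 (HWE). The spike-recovery
regression test plants a 0.30 frequency delta: with 8–48 chromosomes per
pooled group, the analysis above puts a 0.15 delta at ≈ 2.3 null-SD —
around fifty-fifty odds of reaching the top 50 of 2000 — whereas 0.30 is
reliably recoverable; monotonicity of |Z| in the delta is tested
separately, including 0.15.

Determinism: every stochastic routine takes a seed or Generator;
per-stage streams derive from (CRC32 tag, seed) so stages are independent
but byte-reproducible; manifests carry no timestamps, so identical
configurations produce identical output trees.

## Known limitations

- The screen's |Z| ranking is an enrichment heuristic; with 104 subjects
  it has limited power against modest frequency differences (see above),
  which is intrinsic to the emulated design.
- AIC comparison of non-nested outcome models is a pragmatic rule; the
  ΔAIC ≥ 2 edge is conventional, not derived.
- The PC1 median split forces equal-sized bins; with very unbalanced
  ancestry compositions the midrange split can be more faithful and is
  available by option.
- Backward stepwise selection inherits all the usual caveats about
  post-selection inference; reported P-values are conditional on the
  selected model and unadjusted by design.
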