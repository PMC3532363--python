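# Methods

This note documents the statistical model behind `mirherit`, the design
choices that were genuinely open, the synthetic-data generator's assumptions,
and what the test suite does and does not establish about real data.

## The RE-score

For one sample, all genes in the expression matrix are ranked ascending
(1 = lowest expression) with ties sharing the average rank. The RE-score of
a miRNA is the mean rank of the genes *not* in its predicted target set
minus the mean rank of its targets; repressed targets therefore push the
score up. Choices behind this definition:

* **Ranking universe** — all genes in the supplied matrix, not the union of
  target sets. Genes reported as zero (below detection) are retained and
  tie-ranked; rank conservation (the size-weighted mean ranks of any
  partition sum to G(G+1)/2) holds per column regardless of ties.
* **Tie rule** — average ranks, the standard convention; the score of a
  fully tied column is exactly 0.
* **`min_targets`** (default 10) — miRNAs with fewer measured targets are
  dropped and logged. Rank means over a handful of genes are too unstable
  to compare across samples; the floor is configurable and the default is
  deliberately conservative.
* **Scale** — RE is in rank units, bounded by the number of genes ranked.
  Comparisons are only meaningful for the same miRNA across samples, never
  between miRNAs.

The **mean RE-score** is the arithmetic mean over scored miRNAs and is the
global trait. Two derived traits matter downstream:

* the **association trait** is the mean over *conventional* miRNAs only.
  Mirtrons bypass DROSHA and serve as the negative-control class; folding
  them into the trait would dilute exactly the signal the association stage
  is looking for.
* the **subtracted mean RE** for a focal miRNA deletes the focal target
  genes from the matrix, rescales every other miRNA on the reduced
  universe, and averages. This removes the mechanical overlap between a
  miRNA's own score and the global mean when the two are compared as
  predictors.

## Heritability from trios

Under the additive polygenic model, offspring genetic value = mid-parent
genetic value + segregation deviation with variance ½·V_A, so the
regression slope of offspring phenotype on mid-parent phenotype estimates
h² directly (no factor-of-two correction). The fit is
`statsmodels` RLM with Huber ψ (tuning constant 1.345) — resistant to a few
outlying cell lines — with population indicators as covariates; `method="ols"`
is available and coincides with the robust fit when no residual crosses the
Huber threshold. The slope's p-value uses the t distribution with n − k
degrees of freedom on the M-estimator's asymptotic standard error; the
robust-regression literature offers no exact finite-sample test, and the
null calibration test confirms the nominal 5% level within Monte-Carlo
error at 40–200 trios. Both two-sided and one-sided (positive-correlation)
p-values are reported so either convention can be applied downstream.

## Target-set permutation null

The question the null answers: is mean-RE heritability a property of the
*specific* predicted target sets, or would any same-shaped collection of
heritably expressed genes look the same? The permutation draws one random
injective map from the distinct expressed target genes into the expressed
genes and applies it to every set simultaneously. Consequences, all tested
exactly: set sizes are preserved, the per-gene membership-count multiset is
preserved, and a gene shared by several sets maps to one shared image.
Unexpressed targets are dropped before mapping since they cannot affect a
rank computed over expressed genes. Injectivity (sampling without
replacement) is what makes size preservation exact; with-replacement
sampling would shrink sets by collision. The permutation p is the plain
proportion of randomizations whose heritability regression p is at or below
the observed one; `add_one=True` switches to (b+1)/(n+1), which is never
zero and strictly valid, at the cost of a grid offset.

## Genotype QC and association

QC order: sample call rate → SNP call rate (both < 0.95 removed) → minor
allele copies (< 5 removed, exactly 5 retained) → Hardy–Weinberg (Pearson
χ², 1 df, allele frequency estimated from counts, zero-expectation classes
excluded, monomorphic ⇒ p = 1) rejected at Benjamini–Hochberg FDR 0.2 →
pairwise identity-by-state on 2,000 randomly chosen surviving markers
(share per marker ∈ {0, ½, 1}, pairwise-complete), dropping one member of
any pair at IBS ≥ 0.95. The cascade is idempotent.

Association is ordinary least squares of the trait on the additive
minor-allele count, per SNP, over non-missing samples (closed-form,
vectorized across SNPs and permutations; a score-test variant n·r² ~ χ²₁ is
available behind a flag and agrees with the t test at these sample sizes).
Adjustments:

* **Bonferroni**: min(1, m·p) over the m tested SNPs.
* **Storey q-values**: π₀ estimated on the λ grid 0.05…0.95 (step 0.05) by
  a cubic-polynomial smoother evaluated at λ = 0.95, falling back to π₀ = 1
  (plain Benjamini–Hochberg) when the estimate leaves (0, 1] or fewer than
  100 tests are supplied. Note q-values may drop below raw p for the
  largest p-values whenever π₀ < 1; the q ≥ p floor is a π₀ = 1 property.
* **Permutation**: family-wise maxT by default — phenotype labels are
  permuted, the minimum p across the panel is recorded per permutation, and
  each SNP's adjusted p is the share of permutations whose minimum reaches
  its observed p. On an LD-free panel this tracks Bonferroni from below; a
  per-SNP mode exists behind a flag for single-marker calibration checks.

## Fisher's exact test and integrative models

The two-sided Fisher p enumerates all 2×2 tables with the observed margins
in log space (safe to totals ~10⁶) and sums the probabilities of tables
whose point probability is ≤ the observed one within relative tolerance
1e-7 — the tie rule of the standard implementations, cross-checked against
an independent enumeration oracle and against `scipy.stats.fisher_exact`.
The association-strength metric for the mirtron overlap regression is
−log₁₀(raw p) (the natural scale for comparing association strengths;
configurable). "Consistently expressed" miRNAs are those non-missing in
≥ 95% of samples and "most variable" selection is by expression variance,
both thresholds configurable since no canonical values exist.

## The synthetic-data generator

The generator emulates a two-population cohort in which a per-sample latent
variable E (miRNA pathway efficiency, variance 1) represses target genes:

    expression(g, s) = baseline(g) + shift(pop(s))
                       − k · [m_conv(g) · E_full(s) + m_mir(g) · E_base(s)]
                       + N(0, σ²),  clipped at 0

where m_conv/m_mir count the conventional/mirtron sets containing gene g,
E_base is the polygenic + environmental part of E, and E_full additionally
carries the causal-SNP shift β·(c − c̄). Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_genes | 3000 | large enough that the 2.5-overlap target pool (~2,240 genes, 75%) sits strictly inside the universe, so untargeted genes exist and repression is target-specific — the property the permutation null tests |
| n_mirnas / n_mirtrons | 50 / 3 | mirtrons are a small minority class in real prediction databases (~5% of predicted miRNAs); mirtron-set overlap with conventional targets dilutes the trait's causal loading, so over-weighting mirtrons distorts the system |
| mean_targets_per_mirna | 100 | hundreds of targets per miRNA, scaled to the 3,000-gene universe |
| mean_sets_per_gene | 2.5 | many-to-many overlap; the pool size is solved from x/(1−e⁻ˣ) = target so the realized mean memberships per targeted gene is controllable |
| n_trios / n_unrelated | 56 / 60 | cohort sizes typical of two-population reference-panel trio and unrelated collections |
| h2_global | 0.68 | a strong-heritability regime for an expression-derived trait; a convenience default, not a claim about any real variance decomposition |
| target_repression_strength k | 5 | strong repression relative to gene noise: the premise of the design is that the latent pathway trait dominates the phenotype (a slope of ~0.7 could not be observed if measurement noise swamped it) |
| noise_sd | 10 | ~10% of the median baseline (log-normal, median 100): microarray-like per-gene noise |
| population_shift | 10 | uniform across genes, hence deliberately rank-neutral — it emulates technical scale offsets between cohorts, which the rank statistic must ignore |
| effect_beta / causal_maf | 1.0 / 0.40 | one latent SD per minor allele at a common variant; at n = 60 a low-frequency causal allele is undetectable against a 500-SNP panel, mirroring the power asymmetry between study populations |
| maf_range | (0.1, 0.5) | genotyping-panel-like spectrum for the null SNPs |
| missing_rate | 0.005 | HapMap-quality call rates (> 99%); higher values interact with the 0.95 call-rate QC filter |

Transmission: parental genetic values are drawn N(0, h²); the child's
genetic value is the mid-parent value plus a segregation deviation of
variance h²/2, giving a stationary variance and an expected child-on-
mid-parent slope of exactly h². `segregation_sd=0` produces deterministic
transmission for degenerate-case tests. For the unrelated cohort, the
causal SNP is drawn in Hardy–Weinberg proportions and its contribution is
added to the latent value *before* expression is generated; missingness is
applied afterwards, being an assay property rather than a biological one.

miRNA expression is baseline + loading·E + noise with mixed-sign N(0,1)
loadings, so the causal locus behaves as a trans-eQTL cluster with
associations in both directions — the signature expected under relative
(pool-normalized) quantification of a global efficiency shift.

**What the generator does not emulate:** linkage disequilibrium and
haplotype structure, realistic allele-frequency spectra per population,
X-chromosome dosage, polygenic (multi-locus) trait architecture,
distributional quirks of real microarray noise, and any sequence-level
biology of target prediction. Passing tests therefore demonstrate that the
estimators recover the truth *under the stated generative model* — rank
statistics, mid-parent regression, permutation calibration — not that the
biological conclusions of any particular study are correct.

## Numerical and degenerate-case conventions

* RE-score is undefined (raises) when no target or no non-target gene is
  measured; a focal set covering the whole universe makes the subtracted
  mean undefined for everyone.
* Monomorphic SNPs are omitted from association (logged), excluded classes
  from the HWE statistic; a fully monomorphic locus gets p = 1.
* Mid-parent regression raises on a constant mid-parent vector; per-miRNA
  scans log and skip such rows rather than fail.
* Collinear covariates in the individual-vs-mean-RE model (|r| > 0.999) are
  flagged but both p-values are still reported.
* TSV floats are written at full shortest-round-trip precision and read
  back with round-trip parsing, so write → read → write is bit-identical;
  the VCF writer emits GT-only v4.2 records with `./.` for missing.
* The pipeline expands one global seed into per-stage seeds via
  `SeedSequence([seed, stage_index])` (kept below 2³¹), so stages re-run
  independently yet reproducibly; every output header records its seed.

## Package shape

The two genuinely model-like components are exposed statsmodels-style —
`MidparentRegression(child, father, mother, population).fit()` returning a
`HeritabilityResult`, and `TraitAssociation(trait, genotypes).fit()`
returning `AssociationResults` with a `summary()` — while the simulator,
scoring, QC and contrasts are plain functions over typed containers, which
matches how they are used (one fit per question vs many calls per
pipeline).

## Problem sizes in the test suite

Statistical tests run at desk scale, chosen to finish in minutes on one
CPU while keeping Monte-Carlo error well inside the asserted tolerances:
heritability recovery uses 100 replicates × 200 trios per h² level;
family-wise calibration 100 replicate panels × 300 SNPs × 5,000
permutations; causal-SNP recovery 100 replicates × 500 SNPs × 1,000
permutations. Monte-Carlo tests are derandomized with fixed seeds; the
acceptance script re-derives all seeds from its `--seed` argument.
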