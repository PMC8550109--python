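# Methods

## Study design model

The design is a crossed subject × collection-method × timepoint layout. One
gold-standard (GS) aliquot per subject is frozen immediately with no
preservative; every other method contributes a day-0 aliquot (frozen within
minutes) and a day-4 aliquot (96 h at ambient temperature, emulating carrier
transport). With 8 subjects and the six default methods this gives 88 samples,
48 of them at day 0. FOBT cards are metagenomics-only: the dried-spot format
yields too little material for LC-MS.

Three paired comparisons per non-GS method define the estimands:
stability (method D4 vs method D0), concordance (method D0 vs GS) and
reliability (method D4 vs GS). Pair members are ordered evaluated-first,
reference-second; the consistency ICC is symmetric in the pair, but outputs
are labeled. Subjects missing either member are dropped from that comparison
with a warning — no imputation, since a reliability estimand on partially
imputed pairs would be circular.

## Consistency ICC

The core statistic is the two-way mixed-effects, single-measures, consistency
ICC — ICC(C,1)/ICC3: from the two-way ANOVA without interaction (rows =
subjects, columns = the two measurement occasions),

    ICC = (MS_rows − MS_error) / (MS_rows + (k−1)·MS_error)

Consistency means a column-constant shift (a preservative biasing every
subject equally) does not reduce agreement. Significance is the upper-tail
probability of F = MS_rows/MS_error on (n−1, (n−1)(k−1)) df. The F-ratio test
of ICC > 0 is one-sided by construction; we report the conventional
upper-tail p. With n < 3 subjects the estimate is returned with p = NA; if all
values are identical the ICC is undefined (NA with a warning). No
multiple-testing adjustment is applied to per-feature ICC p-values by default
(stars mark raw p < 0.05); a BH option is available via
`fecalmethods.inference.bh_adjust`. Spearman rank correlation (mid-ranks for
ties) is the secondary, distribution-robust analysis for GS-referenced
comparisons. Confidence intervals for the ICC are deliberately out of scope.

Transforms are fixed per data type and recorded in the results: square-root
relative abundances for phyla and top-k features, log10 half-minimum-imputed
intensities for metabolites, no transform for diversity metrics.

## Diversity metrics

Five metrics per profile level, fifteen across the species, gene and pathway
levels:

* observed richness — count of features with nonzero abundance;
* Shannon entropy H = −Σ p ln p (natural log; the base is configurable);
* Simpson index 1 − Σ p²;
* Bray-Curtis PC1 and Jaccard PC1 — the first principal coordinate of
  classical metric scaling of the pairwise distance matrix.

Quantitative Jaccard is derived from Bray-Curtis as 2B/(1+B) (a
presence/absence option exists). PCoA is Torgerson scaling: double-center
−D²/2, eigendecompose, scale the leading eigenvector by √λ₁; the sign is fixed
so the first sample's coordinate is ≥ 0, and negative eigenvalues are reported
rather than corrected. One ordination is computed per comparison sample set
(the 2n samples entering one ICC), never per pair and never globally — PC1 is
only defined relative to one embedding, and the comparison set is the scope on
which the ICC is computed. Alpha diversity is computed on (internally
re-normalized) relative abundances; the square-root transform applies only to
abundance values fed to the ICC.

Features present in fewer than 4 samples are removed before analysis
(operationalizing a <5%-prevalence cut at 88 samples; the threshold is a
parameter). Top-k selection ranks by mean relative abundance with
lexicographic tie-breaks for determinism.

## Metabolomics preprocessing

The fixed chain, idempotent on its own output:

1. **QC RSD** — per feature, sample SD over arithmetic mean across present
   pooled-QC injections; undefined below two present values.
2. **Adduct collapse** — one ion per adduct group, keeping the lowest QC RSD;
   fallback to fewest missing values when no RSD is defined, then
   lexicographic. Counting of "metabolites" everywhere downstream is
   after collapse.
3. **QC missingness filter** — drop features missing in >50% of QC
   injections (strictly greater: exactly half survives).
4. **Detectability** — per feature × method, the fraction of subjects with at
   least one present value among that method's samples (both timepoints
   pooled); a per-timepoint scope is also exposed. Counts at the ≥50/≥80/100%
   levels are monotone non-increasing by construction.
5. **Restriction** — analyses keep features meeting the level (default 80%)
   in every method entering the comparison, i.e. the method-∩-GS feature set
   for GS-referenced modes.
6. **Imputation + log10** — missing values become half the feature's minimum
   present value *within the comparison scope*, then log10. Scoping to the
   comparison set reconciles per-method and per-comparison readings of the
   half-minimum rule; the same feature may impute differently in different
   comparisons, and imputed values always sit strictly below the scope
   minimum. Features entirely missing in scope are excluded (nothing to
   anchor the imputation).

Percent-of-reference overlap is rounded half-up to one decimal to match how
such tables are conventionally printed.

## PERMANOVA

Sequential (Type-I) decomposition of the Gower-centered inner-product matrix
G = −½ C (D∘D) C: terms are projected in the order subject → method → time
(order is user-visible because Type-I SS depends on it), R² = SS_term/SS_total,
and p-values come from unrestricted permutations of sample labels
(p = (count+1)/(n_perm+1), default n_perm = 999, seed mandatory). On Euclidean
distance matrices the single-factor R² equals classical ANOVA SSB/SST, which
the tests exploit as an oracle; no dispersion (betadisper-style) test is
included. A term with a single level is a hard error (zero df).

## Group comparisons

Two-sided Wilcoxon rank-sum (exact null when tie-free and min(n) ≤ 8,
otherwise tie-corrected normal approximation with continuity correction),
Kruskal-Wallis with tie correction, Dunn's pairwise z tests on mean ranks
with the pooled tie-adjusted variance, and Benjamini-Hochberg step-up
adjustment across each family. For two groups, Dunn's z² reproduces the
Kruskal-Wallis H and the tie-corrected rank-sum z — properties the suite
checks numerically.

## Grading rubric

Metagenomics, per method × mode, over exactly the 19 designated metrics
(4 phyla + 15 diversity metrics): `++` when ≥ 10 ICCs are ≥ 0.75, `+` when
6–9 are, `−` below 6. The published band edges overlap ("++ … ≥10" vs
"+ … 6 to 11"); the `++` band is evaluated first, making `+` effectively 6–9.
Metabolomics, from the median per-metabolite ICC: `++` above 0.70, `+` in
[0.45, 0.70], `−` below 0.45; methods without metabolite data grade `NA`.
Every grade is recomputable from the stored per-feature ICC panel alone.

## Synthetic-data generator

Per feature f and sample (subject s, method m, timepoint t), on the natural
log scale:

    y = μ_f + b(s,f) + m(s,m,f) + 1[t=D4]·(δ_m·u(m,f) + σ_t,m·z(s,m,f)) + ε

with b ~ N(0, σ_b²), m(s,m,f) ~ N(0, σ_m²), u(m,f) ~ N(0,1) a fixed
per-feature systematic drift direction scaled by δ_m, and ε ~ N(0, σ_e²). GS
samples carry no method or drift terms. Microbiome tables are exponentiated
and column-normalized (compositional closure); metabolite intensities remain
unclosed, are left-censored at a hard detection limit (explicit missingness,
never zero), and carry pooled-QC injection columns (noisy replicates of the
per-feature pooled geometric mean) plus optional duplicated adduct ions with
doubled QC noise so the collapse step has something real to do. All draws
come from one seeded generator, and draw shapes depend only on the design —
matched seeds stay matched when a variance component is dialed, which is what
makes the drift-monotonicity checks exact rather than stochastic.

Defaults encode the study conditions: 8 subjects, the six methods above,
σ_b = 1.0 dominating σ_m ≈ 0.3 and σ_e ≈ 0.2 (so subjects explain the large
majority of distance-matrix variance, methods a few percent, time ~1%);
elevated drift for 95% ethanol in the microbiome defaults and elevated
OMNIgene censoring-adjacent drift in the metabolome defaults encode the
qualitative finding that ethanol is the least stable preservative for
metagenomics while OMNIgene loses the most metabolites — magnitudes are
user-overridable since no quantitative per-method drift values are published.
The metabolome default is 1,998 features with a detection limit in the lower
intensity tail, sized to a real untargeted fecal profile.

For unclosed, uncensored intensities the generator admits a closed-form ICC
target: ICC = σ_s²/(σ_s² + σ_w²) with σ_w² = σ_e² + extra/2, where extra is
σ_t² (stability), σ_m² (concordance) or σ_m² + σ_t² (reliability), and
σ_s² = σ_b² + σ_m² for stability (both members of a stability pair share the
subject-level preservative effect, so it counts as signal) and σ_b² otherwise.
The systematic drift δ_m·u(m,f) is a column effect, removed exactly by the
consistency definition for unclosed data — it degrades microbiome ICCs only
through compositional closure, which redistributes a feature-specific shift
across every other feature in a subject-dependent way. The parameter-recovery
suite verifies the closed form by simulation (median per-feature ICC over
2,000 features within ±0.05 of the target at 50 subjects, ±0.15 at 8).

What the generator does *not* emulate: taxon-taxon correlation structure,
sequencing-depth/count noise, batch effects beyond QC instrument noise,
probabilistic (intensity-graded) dropout, and real adduct chemistry. Passing
tests therefore demonstrate correctness of the estimators and pipeline under
the assumed variance hierarchy, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* Ties: lexicographic feature-id tie-breaks in top-k and adduct collapse;
  mid-ranks in all rank statistics.
* PC1 sign fixed by the first sample; all-coincident samples embed to zeros.
* Two all-zero samples get distance 0 with a warning; all-zero samples report
  zero diversity with a warning.
* The null ICC estimator has finite-sample bias ≈ −1/(n−1); null-behavior
  checks run at 50 subjects where the bias is negligible.
* Percent rounding is decimal half-up, not banker's rounding.
* Problem sizes in the default test/evaluation runs (60–400 features per
  microbiome level, 150–2,000 metabolites, 199–999 permutations) were chosen
  as the smallest scales at which every statistical property under test is
  stable across seeds.

## Known limitations

Sequential PERMANOVA uses unrestricted permutations (no strata), matching
default Adonis behavior; with subject as the first term this is a descriptive
variance partition, not a test respecting repeated measures. The ICC carries
no confidence interval. The per-feature ICC p-values are reported raw. The
grading rubric inherits the coarse published band edges; grades are
three-valued and saturate quickly at low noise.
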