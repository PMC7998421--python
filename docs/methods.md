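# Methods

This note documents the models and procedures implemented in
`hedoseg`, the assumptions behind them, the defaults of the synthetic
cohort generator, and the numerical choices a maintainer should know
about.

## Segmentation model

The unit of analysis is the within-subject association between hedonic
and sensory responses over a four-level sucrose series in a chocolate
pudding base (38, 83, 119, 223 g/kg; the top concentration is
configurable because printed sources for this design disagree between
223 and 233 g/kg). For each subject we compute four Pearson
correlations across the series — liking against sweetness, bitterness,
astringency, and overall flavour — yielding a 4-vector on the *r*
scale.

*Exclusion rule.* The Pearson denominator vanishes when liking or the
paired attribute is constant across the four samples, so the
correlation is undefined. Such subjects are placed on an exclusion
roster with the offending attribute(s) recorded. Zero-variance liking
excludes a subject under the same rule with a distinct reason code: it
breaks the statistic equally, even though in practice the constant
rater almost always appears in astringency (raters who find a chocolate
pudding simply not astringent and score it at or near zero every time).
Incomplete subjects (missing cells) are *skipped with a log entry*, not
excluded — the two rosters answer different questions.

*Clustering.* K-means with k = 3, Lloyd's algorithm to convergence,
best of 50 seeded random initializations by within-cluster sum of
squares (implemented via scikit-learn's `KMeans`; nearest-centroid ties
break toward the lower cluster index in `predict`). The correlation
vectors enter unstandardized — all four dimensions already live on
[−1, 1] — and distance is Euclidean. k defaults to 3; the CLI exposes k
and reports inertia so a user can examine other values, but no
automatic selection is performed. Fitted clusters are ordered by
decreasing size and labelled by the centroid sign-pattern rule
(`r_sweet > 0 ∧ r_flavour > 0` → HighSweetLiker; `r_sweet > 0 ∧
r_flavour < 0` → ModerateSweetLiker; `r_sweet < 0` → InvertedUShaped;
anything else → Unlabeled with a nearest-reference-centroid
suggestion).

A deliberate modelling point: with only n = 4 observations per
correlation, per-subject *r* is noisy. No significance filtering of
per-subject correlations is applied — the noise is part of the feature,
and the clustering operates on the full roster of defined vectors.

## Statistical battery

*Factorial ANOVA.* The cluster × concentration model is fitted by OLS
with effects (sum-to-zero) coding; Type III sums of squares come from
full-model term deletion (statsmodels `anova_lm(typ=3)`). Ratings of
the four samples by the same subject are treated as independent
observations; no repeated-measures or mixed-effects correction is
applied, mirroring the standard practice in this design. LS means are
averages of cell means over the other factor's levels, with standard
errors from the pooled residual mean square. The compact-letter display
compares cluster levels *within* each concentration, Bonferroni-adjusted
over that displayed family only (3 pairs), which is the family shown in
liking-curve figures. Empty cells raise an error naming the cell (Type
III is inestimable there). p-values use the F distribution throughout;
no Welch correction.

*Chi-square with per-cell flags.* Pearson chi-square on the r × c
table. Each cell additionally gets a Fisher exact test on its 2×2
collapse (cell vs rest-of-row / rest-of-column); a cell is flagged
`>`/`<` only when observed differs from expected *and* the per-cell
test is significant at α. Adjusted standardized residuals are reported
alongside for transparency. The 2×2-collapse choice is a documented
operationalization of footnote-level per-cell testing conventions.

*Rank tests.* Kruskal–Wallis uses mid-ranks and the tie-corrected H
with the chi-square approximation; per-group mean ranks are reported
(the convention for familiarity tables). The
Steel–Dwass–Critchlow–Fligner procedure re-ranks each pair of groups
jointly, standardizes the Wilcoxon statistic with the tie-corrected
variance, and refers √2·|z| to the studentized-range distribution with
k groups and infinite degrees of freedom. The asymptotic reference is
appropriate for the group sizes this package targets (hundreds per
cluster); for small groups an exact option refers each statistic to the
seeded Monte-Carlo permutation distribution of the *maximum* pairwise
statistic under joint relabelling (single-step max-q adjustment) —
full enumeration of all relabellings is combinatorially infeasible
beyond toy sizes, so the oracle tests use 4000 seeded permutations.

*Letter displays.* Letters are the maximal cliques of the
non-significance graph at α, so two groups share a letter exactly when
their (adjusted) pairwise comparison is non-significant. α is 0.05
everywhere and configurable per call.

## Scales and questionnaire scoring

The LAM (hedonic, neutral at 50) and gLMS (intensity, quasi-logarithmic
labels) are both 0–100; gLMS label positions beyond the two PROP
cutoffs are shipped for documentation only. PROP taster status is the
mean of two gLMS bitterness replicates: non-taster ≤ 17 ("moderate"),
super-taster ≥ 53 ("very strong"), medium taster otherwise. The
arithmetic mean is the replicate-combination rule (symmetric, standard
in the PROP literature); a single-replicate classification is computed
but flagged.

Questionnaires are data, not code: each instrument declares its item
count, item scale, reverse-item set, aggregation (sum, mean, or
yes-count) and domain → item mapping with the published score range.
Reverse items map through `low + high − x` (an involution) before
aggregation. The engine validates every shipped spec by checking that
the attainable min/max equal the declared range (TAS-20 DIF 7–35,
DDF 5–25, EOT 8–40; PBC 5–25; FNS 10–70; DS-SF 8–40; SP 0–23; SR 0–18;
DEBQ and HTAS mean-scored on their item scales).

One shipped spec needs a caveat: the TAS-20 is widely administered on
7-point items, but the published subscale ranges above are only
attainable with 5-point items (they sum to 20–100). The shipped spec
uses 5-point items to honour the printed ranges; users administering
7-point items should edit the YAML spec (and expect different ranges).
Reverse-item sets and the DEBQ item→domain mapping follow the
instruments' validation literature and are editable in
`src/hedoseg/data/instruments.yaml`; only the declared-range check is
enforced.

## CATA product mapping

Citation matrices are screened attribute-by-attribute with Cochran's Q
(closed form, chi-square reference with k−1 df); attributes with
p ≥ α are dropped. When every respondent row is constant the Q
denominator vanishes and the statistic is reported as undefined with a
warning. Citation counts are aggregated over respondents before
correspondence analysis — standard CATA practice; respondent-level CA
is out of scope.

Correspondence analysis is the SVD of the standardized residual matrix
D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}; row/column principal coordinates are
singular-vector columns scaled by singular values and masses, axes
ordered by inertia. Total inertia × grand total equals the table's
Pearson chi-square (tested cross-module), and the transition formulas
hold to numerical tolerance. Singular values below 1e−12 of the
leading one are treated as null axes, so an independence table yields
zero axes and zero inertia.

Product grouping is a documented operationalization of reading a CA
map: k-means (k = 3, seeded, 50 restarts) on the first two row
principal coordinates, followed by one-to-one matching
(Hungarian assignment) of cluster centroids to three poles — the mean
coordinate of the bitter/astringent attributes, the sweet attribute
coordinate, and the origin (intermediate). Locating poles from fitted
attribute coordinates makes the labelling invariant under axis sign
flips. The polyphenol correlation is a plain Pearson r between an
attribute's citation proportions and a user-supplied (or synthetic)
product-level phenol table, with a two-sided p from the t transform on
n−2 df; n is always reported because the matched-product count drives
the inference.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, with
ground truth retained for recovery scoring.

*Structure.* Cohort size 1208; phenotype mixture (0.389, 0.405, 0.206);
a 70/1208 ≈ 5.8% subpopulation rates astringency with one constant
value drawn uniformly from [0, 7] ("nil or very low"), which places
them on the exclusion roster. Each rating is phenotype curve + subject
intercept (sd 5) + residual noise (sd 7), truncated to [0, 100].

*Curves* (means per concentration; invented magnitudes constrained by
the phenotype shape definitions, which the config validator enforces):
liking High (40, 55, 65, 75), Moderate (35, 55, 70, 70), Inverted-U
(45, 62, 60, 40); sweetness (16, 26, 36, 48) rising; bitterness
(35, 28, 21, 16) and astringency (24, 20, 17, 13) falling; overall
flavour rising for High (28→43), falling for Moderate (43→28), weakly
peaked for Inverted-U.

*Calibration.* The residual sd of 7 was chosen so that the attenuation
of the within-subject correlation — both series carry per-point noise
variance 49 against curve variances of ≈160–170 — puts the
high-sweet-liker sweetness correlation near 0.77, the scale observed
for this segmentation's centroids; the subject intercept cancels in the
correlation and only inflates between-subject spread. With these
defaults the truncation fraction is ≈0.8% (monitored, logged, and
tested < 1%), exclusions are binomial around 70, and the full pipeline
recovers phenotype membership at ≈90% with centroid sign patterns
correct in every dimension. Truncation rather than censoring is used
for simplicity; liking and intensity noise are independent by default
(a knob a user can change by editing curves per phenotype).

*What the generator does not emulate:* session and presentation-order
effects, within-subject correlation between liking and intensity noise,
item-level questionnaire responses (traits are drawn at the score
level), non-Gaussian rating distributions, and any dependence of CATA
citations within respondent beyond the product-group probabilities.
Passing recovery tests therefore demonstrate that the pipeline's
machinery is correct under its own assumptions, not that real cohorts
meet those assumptions.

*Traits and demographics.* Trait draws are phenotype mean + Gaussian
noise clipped to the instrument range. Default means for the
discriminating traits follow the reported cluster orderings (disgust
sensitivity highest in Moderate; sensitivity to punishment and
difficulty-identifying-feelings lowest in Inverted-U;
difficulty-describing-feelings lowest in High; PROP highest in
Moderate; sugar-in-coffee lowest in Inverted-U; Inverted-U oldest;
women over-represented in Moderate and under-represented in High).
Non-discriminating traits share one mean across phenotypes. CATA
probabilities separate a bitter/astringent pole (e.g. P(bitter) = 0.60)
from a sweet pole (P(bitter) = 0.05) across 17 vegetables in three
ground-truth groups, with 201 respondents.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; identical seed and
config reproduce cohorts and k-means fits bit-identically, and a
pipeline rerun from its archived config is byte-identical. The shipped
tests and the acceptance script run the cohort at its natural size
(1208 subjects; 1138 × 4 observations for the factorial df check;
1000 draws for the correlation-space recovery simulation) — these sizes
are the study conditions, and nothing in the suite requires scaling
beyond them. The permutation oracle for the all-pairs rank procedure
uses 4000 seeded relabellings on a 3 × 5 instance, a size at which the
Monte-Carlo error (≈0.008 at p ≈ 0.05) is well inside the 0.10
comparison band that also absorbs small-n asymptotic slack.

## Known limitations

- The factorial ANOVA ignores the repeated-measures structure by
  design (fidelity to the mirrored analysis), so its p-values are
  anti-conservative for correlated within-subject errors.
- The SDCF asymptotic reference is unreliable below ~8 observations per
  group; use `method="permutation"` there.
- The CA product grouping depends on the first two axes only; tables
  whose structure needs three axes will group imperfectly.
- Instrument reverse-item sets are shipped as editable defaults
  validated only against score ranges; exact item-level agreement with
  any particular translation of an instrument is the user's
  responsibility.
- No multiple-testing correction is applied across the many trait/item
  tests (deliberate mirroring); letter displays correct only within
  their displayed family.
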