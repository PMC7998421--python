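# hedoseg

Sweet-liker phenotyping from sensory–liking correlation patterns, with
full statistical characterization of the phenotypes and
check-all-that-apply (CATA) product mapping.

## The problem

Consumers differ systematically in how much sweetness they want: some
like a product more the sweeter it gets, some reach a plateau, and some
have an optimum beyond which liking falls. These *sweet-liker
phenotypes* matter for the acceptability of phenol-rich foods
(vegetables, unsugared coffee and tea, dark chocolate), whose bitterness
and astringency are often masked by added sugar.

`hedoseg` implements a product-based segmentation of these phenotypes.
Each consumer rates liking (Labelled Affective Magnitude scale, 0–100)
and perceived sweetness, bitterness, astringency, and overall flavour
(general Labelled Magnitude Scale, 0–100) for a series of four chocolate
puddings spiked with sucrose at 38, 83, 119, and 223 g/kg. The
segmentation feature for subject *s* is the vector of within-subject
Pearson correlations across the series,

r⁽ˢ⁾ = ( r(liking, sweet), r(liking, bitter), r(liking, astringent), r(liking, flavour) ),

computed over the four samples. Subjects with zero variance in liking or
in any attribute (the correlation is undefined) are placed on an
exclusion roster. K-means (k = 3, 50 seeded restarts, Euclidean distance
on raw *r*) partitions the remaining vectors, and each cluster is named
by its centroid sign pattern:

| phenotype | r_sweet | r_flavour | liking curve |
|---|---|---|---|
| HighSweetLiker | + | + | monotone increasing |
| ModerateSweetLiker | + | − | increasing, plateau at 119 g/kg |
| InvertedUShaped | − | (any) | peaked at 83–119 g/kg |

Around the segmentation sit the tools used to characterize such
phenotypes: factorial ANOVA with Type III sums of squares, LS means and
Bonferroni compact-letter displays; chi-square association with
per-cell Fisher-exact direction flags; Kruskal–Wallis with
Steel–Dwass–Critchlow–Fligner all-pairs comparisons; a scoring engine
for seven personality/attitude questionnaires (TAS-20, PBC, SPSRQ,
FNS, DS-SF, DEBQ, HTAS) plus PROP taster-status classification; and a
CATA pipeline (Cochran's Q screening → correspondence analysis →
product grouping → polyphenol correlation). A seeded synthetic-cohort
generator with known ground truth makes every stage testable.

## Worked example

```bash
hedoseg simulate --n-subjects 1208 --seed 7 --out demo
hedoseg segment demo/ratings.csv --seed 7 --out demo/seg
```

prints

```
 cluster          phenotype   n       pct   r_sweet  r_bitter  r_astringent  r_flavour
       0     HighSweetLiker 473 41.166232  0.812073 -0.719716     -0.455293   0.672318
       1 ModerateSweetLiker 473 41.166232  0.765362 -0.705469     -0.478671  -0.652787
       2    InvertedUShaped 203 17.667537 -0.288504  0.156639      0.237529   0.315509
      -1           excluded  59  4.884106       NaN       NaN           NaN        NaN
inertia: 525.9895 (k=3, restarts=50, seed=7)
```

Reading this: of 1208 simulated subjects, 59 (4.9%) rated at least one
attribute with zero variance and were excluded; the remaining 1149 fall
into two sweet-liking clusters whose liking rises with sweetness
(positive `r_sweet`, distinguished by the sign of `r_flavour`) and a
smaller inverted-U cluster whose liking is negatively related to
sweetness and positively to bitterness and astringency. The centroid
rows are the per-cluster means of the correlation vectors; `inertia` is
the within-cluster sum of squares of the chosen k-means solution.

The same objects are available as a library:

```python
from hedoseg import CohortConfig, generate_ratings, segment_ratings

ratings, truth = generate_ratings(CohortConfig(seed=7))
model, vectors = segment_ratings(ratings, k=3, seed=7)
print(model.centroids.round(3))
```

and the full pipeline (simulate → segment → characterize → cata) runs
with `hedoseg run --seed 7 --out demo_run`.

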