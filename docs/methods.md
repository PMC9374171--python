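# Methods

This note records the scientific and numerical choices behind the package:
the model and its assumptions, what the synthetic-data generator does and
does not emulate, the defaults that matter, and known limitations.

## The analysis pipeline

The package operationalises *pattern identification* — the grouping of
patients into treatment-relevant subtypes — as unsupervised clustering of
sleep-disturbance survey respondents. One row is one respondent; the six
survey sections are demographics, medical history, military duty, sleep
(PSQI, Berlin questionnaire, sleeping environment), diet/nutrition
(dietary-habit items, Nutrition Quotient) and gastrointestinal status
(GSRS, Bristol stool scale). The stages run strictly in order:

1. **Cleaning** (deduplication → inclusion/completeness → outlier bounds),
   with per-stage removal counts logged and conserved
   (`rows_in = rows_out + Σ removed`). Multi-responders are removed
   entirely — a respondent who answered twice is unreliable, so neither
   copy is kept. There is no imputation anywhere: a respondent missing any
   required item is excluded. The outlier bounds are strict inequalities on
   the open-question fields: height outside (110, 200) cm, weight outside
   (40, 160) kg, smoking amount above 5 packs/day, smoking duration above
   20 years.
2. **Scoring** computes every derived instrument score (details below);
   respondents with PSQI global ≤ 5 are then excluded — the analysis
   population is sleep-disturbed by construction — and the remainder is
   split 80/20 uniformly at random with the training size floored
   (2,579 rows → 2,063/516).
3. **Encoding**: nominal items are one-hot expanded over their declared
   level sets; numeric/ordinal/flag items are single columns. Location and
   scale are fitted on training rows only and applied unchanged to test
   rows. Standardisation (not min–max) is the default because the
   autoencoder input should be centred for a symmetric activation.
4. **Feature extraction**: PCA (baseline) and the symmetric deep
   autoencoder `[d, 8J, J, 8J, d]`. The bottleneck grid `1 ≤ J ≤ 10` is
   evaluated with k-fold cross-validation (10 folds by default), each fold
   training on (k−1)/k of the rows and reporting held-out reconstruction
   RMSE; after selection the final model is refit on the full training
   partition (folds are for selection only).
5. **Clustering**: Lloyd k-means, `max_iter = 300`, best of 10 seeded
   restarts; internal validity via the Calinski–Harabasz index and mean
   silhouette for `k = 2..10`; WCSS additionally at `k = 1` for the elbow
   curve. Empty clusters are repaired by reseeding to far points; ties in
   assignment break to the lowest centroid index. The feature-extraction
   method is selected by averaging min–max-normalised CH and silhouette
   over `k ∈ {2, 3, 4}`; the cluster count by the maximum discrete second
   difference of the WCSS curve (ties to the smallest k; near-linear curves
   are flagged "no elbow").
6. **External validation**: for PSQI, GSRS, NQ global and the four NQ
   factors, one-way ANOVA followed by Tukey–Kramer pairwise comparisons
   (`SE = √(MSW/2 · (1/nᵢ + 1/nⱼ))`, studentized-range CIs and p-values);
   for the binary Berlin risk, an uncorrected Pearson chi-squared omnibus
   test on the k×2 table, Yates continuity-corrected chi-squared for
   pairwise 2×2 tables, and odds ratios with log-normal 95% CIs
   (Haldane–Anscombe +0.5 for zero cells). The correction convention —
   omnibus uncorrected, pairwise corrected — reproduces both the omnibus
   and the pairwise reference statistics from the same counts and is noted
   in the report footer. ANOVA and Tukey–Kramer accept either raw vectors
   or `(n, mean, SD)` summaries; the two modes agree exactly when the
   summaries come from the raw data, so published summary tables can be
   re-analysed directly.

## Instrument scoring

* **PSQI**: seven components, each 0–3. Quality, medication = item rating;
  latency = banded minutes (≤15/16–30/31–60/>60) plus the "couldn't sleep
  within 30 min" frequency, re-banded 0/1–2/3–4/5–6; duration banded at
  >7 / ≥6 / ≥5 hours; efficiency = sleep ÷ bed time, banded at
  ≥85/≥75/≥65%; disturbances = sum of nine items banded 0/1–9/10–18/19–27;
  daytime dysfunction = two-item sum re-banded. Global = component sum
  (0–21); the disturbance flag is global > 5, strictly. The two clock-time
  items are represented by their derived time-in-bed. Banding tables are
  module data, not control flow.
* **Berlin**: categories 1 and 2 positive with ≥2 positive symptom items;
  category 3 positive with a blood-pressure history or BMI > 30 kg/m²;
  high risk with ≥2 positive categories. The drowsy-driving sub-question is
  carried but does not count toward the category-2 threshold.
* **GSRS**: fifteen 7-point discomfort items. The default aggregate is the
  zero-based sum Σ(level−1), range 0–90 — the only convention whose range
  is consistent with the reported cluster means; `sum1` and `mean` are
  config switches.
* **NQ**: the published factor weighting is not reproducible from public
  sources, so the default weight table is a documented stand-in with the
  correct structure: 21 items in four factors (balance 7, diversity 5,
  moderation 5, behavior 4), per-level point lists per item, a 0–100
  global score, and the grade rule global ≥ 58 → "good". The whole table is
  data and can be replaced wholesale.
* **Sample size**: `n₀ = z²p(1−p)/e²` deflated by `1 + n₀/N`, rounded up
  (ceiling is the only rounding reproducing both 1,064 completes and
  35,467 invitations at a 3% response rate); the anticipated proportion
  defaults to the conservative p = 0.5.

## The synthetic population

No respondent-level data are public, so the generator is the package's
stand-in for the study conditions, and its defaults *are* those
conditions: ~4,900 respondents, latent cluster weights 1396/98/569
(normalised), per-cluster score targets equal to the published training
summaries (e.g. GSRS 2.18/17.94/6.39, PSQI 8.33/11.57/9.96, the four NQ
factor means, Berlin high-risk rates 11.9/35.7/31.3%), published
demographic and medical-history rates, and injected artifact rates sized
to the reported flow (≈0.7% duplicates, ≈2.8% incomplete, ≈0.4% outliers).

Generation is *score-first*: each instrument total is drawn from a
truncated normal whose location is calibrated so the truncated mean equals
the target, and item vectors are then allocated so the scoring module
reproduces that total exactly, row by row. PSQI components use
quasi-proportional allocation (parts positively coupled to the global, as
severity spreads in real instruments); a uniform random composition was
rejected because it manufactures an anti-correlated item block with an
artefactual dominant variance direction not seen in real data.

The population is organised along one latent **severity axis**: clusters
sit at ordered positions (mild A = 0.0, intermediate C = 1.8, severe
B = 3.8; within-cluster SD 0.2), instrument totals are drawn with a
modest correlation to the latent (quantile-transformed, so the calibrated
marginals are untouched), lifestyle items load on the axis linearly, and a
*hinge* block (environment complaints, meal irregularity, stool form,
duty stress) responds only above severity 2.3. The hinge bends the data
manifold: a linear projection must take the chord of the curve and
shortens between-cluster gaps, while a nonlinear encoder can follow the
arc — this is precisely the mechanism by which autoencoder features beat
PCA for clustering here, and it mirrors the motivating argument for
nonlinear feature extraction on questionnaire data. A single `separation`
scalar interpolates all profiles toward the grand mean so recovery tests
can sweep difficulty (0 = indistinguishable, 1 = default).

What the generator does **not** emulate: item-level response styles
(acquiescence, straight-lining), missingness other than the injected
trailing-section blanks, longitudinal structure, and any real demographic
joint distribution beyond the published marginals. Passing tests therefore
demonstrate that the pipeline behaves as designed under a faithful but
idealised population — not that the subtype structure of any real cohort
would be recovered.

## Numerical and design choices

* **Autoencoder stack**: scikit-learn's multilayer perceptron, advanced
  one epoch at a time (`partial_fit`) so per-epoch validation curves can
  be recorded; MSE is the monotone training surrogate of the reported
  RMSE. Adam, learning rate 1e-3, batch 64, 100 epochs, seeded
  initialisation and shuffling; deterministic in single-threaded runs.
* **Activation**: tanh hidden layers with a linear output. The activation
  is unreported in the source analysis; a rectifier was tried first and
  rejected because at very narrow bottlenecks (J = 1–2) its one-sided dead
  zone collapses whichever end of the dominant severity axis the random
  initialisation maps onto zero, producing seed-dependent recovery
  failures. The symmetric saturating unit is robust; `relu` remains a
  config option.
* **Final-fit restarts**: the refit after grid selection trains 3 seeded
  initialisations and keeps the lowest training RMSE.
* **Scree elbow (PCA `auto`)**: the component count is the 0-based index
  of the maximum second difference of the eigenvalue sequence — the kink
  at the start of the flat tail; the components before it are kept.
* **WCSS elbow**: `k*` at the maximum second difference over consecutive
  k. A guarantee that the curve is non-increasing comes from warm-starting
  each k with the previous solution's centroids plus a far-point split as
  one extra initialisation.
* **Cluster-count selection under unbalanced subtypes**: with weights
  near 68/5/28%, the curvature rule provably prefers k = 2 unless the
  minority cluster sits roughly twice as far from the others as the two
  majority clusters sit from each other — which a bounded embedding cannot
  deliver. On default synthetic data the pipeline therefore typically
  reports k = 2 (the mild-versus-affected split) even though three latent
  subtypes exist and are recoverable (k-means at k = 3 on the selected
  autoencoder features attains adjusted Rand index ≥ 0.9). The automated
  rule replaces a visual judgment that historically favoured k = 3 when
  both 2 and 3 were candidates; the package emits the full curve so a
  human can make that call. On balanced, well-separated clusters the rule
  returns k = 3 reliably.
* **Degenerate inputs**: W = 0 maps the CH index to a large sentinel
  (1e12); all-singleton clusterings have silhouette 0 by convention;
  identical constant groups give F = 0; constant feature columns pass
  through centred with unit scale; unseen categorical levels in test data
  map to an all-zero one-hot block with a warning.

## Problem sizes

Desk-scale defaults keep every stage tractable on one CPU: the test suite
exercises populations of 250–10,000 respondents, and the acceptance script
runs the full pipeline at 2,600 respondents (≈2,300 after filtering,
d = 125 encoded columns) with a 5-fold CV grid over all ten bottleneck
widths — a few minutes end to end. These sizes are the package's own
defaults for reproducible desk runs; all of them are configurable.

## Known limitations

* The NQ weight table is a structural stand-in; absolute NQ scores are not
  comparable to published NQ norms (the grade rule and factor structure
  are).
* The Tukey–Kramer p-values use the exact studentized-range distribution;
  software that tabulates it (and caps p at 0.9/0.001) will differ in the
  extreme tails.
* The 2×2 continuity-correction convention is inferred from the reference
  statistics it reproduces, not from a stated method.
* Cluster-label letters (A/B/C) are assigned by first appearance, not by
  severity; consumers should order clusters by a score of interest (the
  acceptance script orders by GSRS mean).
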