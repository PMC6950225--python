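# Methods

## Problem setting

Two food-composition databases describe overlapping universes of foods
with a shared panel of 62 nutrients (per 100 g edible portion) but no
shared identifier. The target database additionally reports lactose
(g/100 g). The package links query foods to target records and transfers
lactose from the best matches, or predicts lactose directly from the
shared panel. Roughly a quarter of foods are lactose-free — an exact 0,
not a small value — which shapes both the evaluation (zero-first-match
accuracy) and the model compositions (hurdle structure).

## Matching

### Nutrient similarity

The weighted Pearson correlation across the 62 shared nutrients uses
weighted moments: with weights normalized to sum 1, $m(x) = \sum w_k x_k$,
$\mathrm{cov}(x,y) = \sum w_k (x_k - m(x))(y_k - m(y))$, and
$r = \mathrm{cov}(x,y)/\sqrt{\mathrm{cov}(x,x)\,\mathrm{cov}(y,y)}$. This
is the standard weighted-moments correlation; under uniform weights it
reduces exactly to the ordinary PCC, which is the property that pinned the
choice. Weights are non-negative (typically |coefficients| of a bounded
linear lactose model) and apply only to the nutrient factor, never to
text.

A record with zero weighted variance (a constant nutrient vector) has no
defined correlation. Such entries are carried as NaN and rank below every
defined score, including negative ones: no evidence loses to weak evidence
deterministically. A relative tolerance (1e-13 of the weighted mean
square) absorbs cancellation error when deciding degeneracy.

### Text similarity

Descriptions are comma-structured; the first chunk carries the food
identity. Preprocessing: prepend `chunk_repeats` extra copies of the first
chunk (default 1, so it appears twice); lowercase; strip punctuation at
word boundaries, keeping token-internal characters; split on whitespace;
emit within-word character n-grams (default length 3), with words shorter
than the n-gram length kept whole. N-grams never span whitespace — the
stricter of the two readings consistent with tokenizing "burger" into
exactly four 3-grams — and the rule is configurable.

TF-IDF uses the smoothed variant `idf(t) = ln((1+N)/(1+df(t))) + 1` with
raw term counts and L2-normalized document vectors (the long-standing
library default, stated here so results are reproducible bit-for-bit).
The vectorizer is fit on the query and target descriptions jointly: cosine
similarity is only meaningful over one vocabulary, at the cost that
results depend on the corpus — nutrient-only results are batch-independent,
text-fused results are deterministic only for a fixed corpus. Target
descriptions get the same first-chunk repetition as queries by default
(`symmetric_text=False` switches this off).

### Fusion and ranking

The combined matrix is the element-wise product of nutrient-PCC and
text-cosine. A zero in either factor annihilates the score; negative
products are allowed and rank low; undefined nutrient entries stay
undefined. Per query the k highest defined scores are returned
(default k = 5), ties broken by target-table order (stable sort), with the
target's lactose copied onto each match.

## Prediction

* `standardize`: zero mean/unit variance from training rows only;
  zero-variance columns keep scale 1 with a warning. Test statistics never
  enter the fit.
* `remove_outliers`: isolation-forest anomaly scores; exactly
  `ceil(contamination * n)` rows are removed (default contamination 0.013,
  so 5 of 378), which makes the count reproducible rather than dependent
  on percentile interpolation. Deterministic under the seed. When
  `contamination * n < 1` nothing is removed, with a warning.
* `BoundedRegressor`: clips negative predictions to 0; coefficients pass
  through unchanged from the wrapped linear model.
* `ZeroInflatedRegressor`: classifier on the indicator `y > 0` (exact
  zeros are the zero class), regressor on all rows, final prediction =
  binary class × bounded regression. The decision threshold is 0.5 on the
  predicted probability — the canonical default, configurable.
* Baselines: mean, median, median-of-nonzero (errors on all-zero targets),
  and the perfect-classifier-plus-mean ceiling, which needs the true
  targets at predict time and is flagged as such.
* `grid_search_cv`: seeded k-fold (default 10-fold; repeated CV via
  `repeats`), mean R² per grid point, failed points flagged invalid. Ties
  break toward the smallest parameter value. The default LASSO grid is 50
  points log-spaced on [1e-3, 1].
* Hyperparameters published for the original licensed-data study (LASSO
  α = 0.039/0.020/0.022, Ridge α = 59.64/15.20/27.83, logistic C =
  215443.47, FFNN 2×50 with learning rate ≈ 0.0012 / α = 0.029 /
  185 epochs, GBT 100 trees with depths 9/7 and column fraction 0.9/1.0)
  ship as the `published-final` preset. They are data-dependent optima,
  not defaults: they are only reproducible against the original data, and
  the published grid for C (stated as 1e-4 to 1e-6 yet with optimum
  2.15e5) is internally inconsistent, so grids remain user-configurable.
* `feature_importances`: signed coefficients for linear families, signed
  first-layer weight sums for the network (the summary method is labeled
  in the export, since several conventions exist), split frequencies for
  the gradient-boosted trees (non-negative by construction).

LASSO, Ridge, logistic regression, the MLP and the isolation forest are
scikit-learn; gradient boosting is xgboost. The compositions (bounding,
hurdle product, the removal-count rule, the CV tie protocol) are this
package's code.

## Synthetic data

The generator emulates the structure the methods rely on, not any real
database's numbers.

* **Archetypes.** A fixed catalog of 16 dairy-bearing and 16 lactose-free
  food heads, each with a dairy level $d_0$ and a per-nutrient log-scale
  signature. The catalog (including base nutrient magnitudes: energy
  ~160 kcal, calcium ~90 mg, etc.) is part of the generator's definition
  and does not vary with the seed.
* **Dairy factor and lactose.** Each food draws $d$ near its head's
  $d_0$ (lactose-free heads have $d = 0$ and lactose exactly 0; the
  lactose-free fraction is exactly `round(zero_fraction * n)`, default
  0.23). Lactose is $12\,d^{1.5}$ times log-normal noise — monotone in
  $d$ up to noise. On the log scale, $d$ shifts sugar (+1.2), calcium
  (+1.5), potassium (+0.8), riboflavin (+1.0), phosphorus and cholesterol
  up and fiber (−1.5) and iron (−1.0) down, so lactose is recoverable
  from the shared panel. Per-food log-normal individuality (σ = 0.35)
  makes profiles distinctive.
* **Descriptions.** Head + optional variety chunk + 1–3 detail chunks,
  unique per record (real composition tables do not carry duplicate
  descriptions; near-duplicates differ in a detail).
* **Paired targets.** Each query's true counterpart gets independent
  multiplicative log-normal noise per nutrient (CV = `nutrient_noise_cv`,
  default 0.02) and, with probability `description_perturb_rate`
  (default 0.2), one description perturbation — a dropped detail chunk, a
  synonym swap, or an extra chunk; the identity-bearing first chunk is
  never touched, matching how counterpart descriptions differ across real
  databases.
* **Distractors.** One independent distractor per query by default;
  `drymix_fraction` of them get all per-100 g values scaled ×8 and a
  "dry mix (unprepared)" chunk — the unreconstituted-powder failure mode
  where a transferred per-100 g value wildly overstates what was consumed.
* **Branded near-duplicates.** For `branded_fraction` of queries an extra
  unlinked target copies the query's nutrients at CV
  `max(nutrient_noise_cv, 0.02)` — as nutrient-close as the true
  counterpart — with a brand token prepended to the description. These are
  the records that only text can disambiguate; they are why fused matching
  recovers more links than nutrient-only matching, as on real data.
* **Composites.** `make_multifood_queries` rewrites a fraction of query
  descriptions to "A or B" form, linking both targets: the
  multiple-foods-in-one-description case whose single correct match is
  unknowable, visible as elevated top-5 lactose variation.

What the generator does **not** emulate: real nutrient marginal
distributions or inter-nutrient covariance beyond the dairy factor,
recipe/mixture foods, description vocabulary overlap between unrelated
foods, or database-version drift. Passing tests therefore demonstrate
correctness of the machinery and the expected qualitative orderings, not
performance levels on real databases.

The zero-inflated regression generator (`generate_zero_inflated_regression`)
is the controlled analog for the predictor: standard-normal features over
the 62-name panel, a sparse ±coefficient vector on the dairy-marker
nutrients, structural zeros from a noisy threshold on the same latent
signal (label-noise σ = 0.1 of the signal sd), an offset (0.7 signal sd)
keeping the non-zero class clear of the clip at 0, and noise variance set
from the signal variance and the requested SNR (default 5, i.e. a
best-case R² near 0.83). Default study conditions: n = 400 training rows,
23% zeros, held-out evaluation on freshly generated rows.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] after rounding; degeneracy uses the
  relative-variance tolerance above.
* Top-k ties break by target-table order; an all-undefined row yields an
  empty match list with a logged warning.
* The top-5 lactose coefficient of variation uses the population
  (n-divisor) standard deviation; all-zero top-5 lists have CV 0 by
  convention (lactose ≥ 0 rules out a zero mean with nonzero values).
* Missing optional cells (lactose, year, dairy servings) are empty, never
  0; a written 0 is the lactose-free class.
* Food identifiers are opaque strings; leading zeros survive round trips.
* The confidence rule's per-nutrient cutoffs are required configuration
  with no shipped defaults: they are study-specific judgments.

## Problem sizes

The test suite and the acceptance script run the matching conditions at
200 query foods (420 targets) and the prediction conditions at 400
training / 200 held-out rows — large enough for stable rates, small
enough that the whole suite completes in seconds.

## Known limitations

* All-pairs similarity is O(queries × targets); no blocking or clustering
  shortcut is provided.
* No spelling correction, lemmatization, or brand recovery from response
  files; text matching sees only the description string.
* Model persistence has no cross-version guarantees.
* The perfect-classifier baseline is an oracle and breaks the sklearn
  `predict(X)` signature by design.
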