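# nutrimatch

Cross-database food-record linkage and nutrient transfer for dietary
assessment.

Different 24-hour dietary recall systems sit on different food-composition
databases, and some nutrients (lactose is the motivating case) are reported
by only one of them. When a study's recalls come from the system that lacks
the nutrient, the only traditional remedy is a slow manual lookup of every
food in the other system. `nutrimatch` automates the two computational
routes around that bottleneck:

1. **Database matching** — link each query food to its most similar records
   in the target database and transfer the missing nutrient from the best
   match.
2. **Direct prediction** — learn the missing nutrient from the nutrient
   panel the two databases share, with model compositions built for a
   non-negative, zero-inflated response.

## The methods

**Matching.** Let $x_i$ and $y_j$ be the shared nutrient vectors (62
nutrients, per 100 g) of query food $i$ and target food $j$. The
*nutrient-only* similarity is the (optionally weighted) Pearson correlation
across nutrients,

$$r_{ij} = \frac{\sum_k w_k (x_{ik} - \bar{x}_i)(y_{jk} - \bar{y}_j)}
           {\sqrt{\sum_k w_k (x_{ik}-\bar{x}_i)^2\;\sum_k w_k (y_{jk}-\bar{y}_j)^2}},$$

with $\bar{x}_i = \sum_k w_k x_{ik}$ and weights $w \ge 0$ normalized to
sum 1 (uniform weights give the ordinary PCC; the absolute coefficients of
a fitted bounded-LASSO or bounded-Ridge model are the other standard
choice). The *text* similarity is the cosine between TF-IDF vectors over
character 3-grams of the food descriptions; descriptions are
comma-structured with the food identity in the first chunk, so the first
chunk is repeated before tokenization to raise its weight. The
*nutrient + text* similarity is the element-wise product $r_{ij} \cdot
c_{ij}$. The top-k targets per query (k = 5 by default) are returned with
the target's lactose attached.

**Prediction.** Lactose per 100 g is non-negative with a point mass at
exactly 0 (lactose-free foods), so regressors are composed as

* *bounded*: $\hat y = \max(0, f(x))$ for any regressor $f$ (LASSO, Ridge,
  feed-forward network, gradient-boosted trees), and
* *combined* (hurdle): $\hat y = \mathbb{1}[p(x) \ge 0.5] \cdot \max(0, f(x))$,
  where $p$ is a zero/non-zero classifier — predictions are exactly 0
  wherever the classifier says lactose-free.

Features are standardized with training statistics only, and the
$\lceil 0.013\,n \rceil$ most anomalous training rows (isolation-forest
scores) are removed before fitting. Naive baselines (mean, median,
median-of-nonzero, perfect-classifier-plus-mean) calibrate the gains.

Licensed food-composition databases cannot be redistributed, so the
package ships a synthetic-data generator (`nutrimatch.simulate`) that
reproduces the structure both routes depend on: a shared 62-nutrient
panel, ~23% lactose-free foods, lactose coupled positively to sugar,
calcium, potassium and riboflavin and negatively to fiber and iron,
comma-structured descriptions, branded near-duplicates, and per-100 g
"dry-mix" outliers — with ground-truth links for evaluation.

## Worked example

```sh
nutrimatch simulate --n-foods 200 --seed 1 --out-dir bundle
nutrimatch match --query bundle/query.csv --target bundle/target.csv \
    --mode nutrient-text --out matches.csv
nutrimatch evaluate --matches matches.csv --reference reference.csv \
    --links bundle/links.csv --report report.csv
```

(Here `reference.csv` holds the known lactose per query — in a real study
the manual-lookup values, here the linked target's value.) The run prints:

```
n_queries: 200
median_cv_top5: 0.314283549714904
foodlink_first_hits: 199
foodlink_top5_hits: 200
foodlink_queries: 200
zero_first_match_accuracy: 1.0
first_match_r2: 0.9960651853079535
first_match_pcc: 0.9981285539929442
first_match_mae: 0.015477937792314813
n_compared: 200
```

Reading: 199 of 200 queries had their true counterpart returned as the
first match and all 200 within the top five; every lactose-free query got
a lactose-free first match; the lactose transferred from the first match
tracks the reference almost perfectly (R² = 0.996, MAE = 0.015 g); and the
median coefficient of variation of lactose among each query's top-5
matches is 0.31 (smaller = the top matches agree about the food). The
first rows of `matches.csv`:

```
query_id,rank,target_id,target_description,score,lactose_g
00000000,1,50000,"Mashed potatoes, cheddar, frozen, sweetened",0.9999636670626455,0.5848544782881945
00000000,2,60112,"Mashed potatoes, cheddar, sweetened, lowfat, whole",0.8943975213175338,1.510071190167692
```

The library surface mirrors scikit-learn: `FoodMatcher(mode=...).fit(target_db).match(query_db)`,
`BoundedRegressor(Lasso(...)).fit(X, y)`, `ZeroInflatedRegressor(...)` —
all with `get_params`/`set_params`, so they compose with sklearn model
selection.

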