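# parklens

Urban parks are visited by very different kinds of people — tourists and
locals, wildlife watchers and city-scape photographers — and geotagged
social-media photographs are one of the few city-wide windows onto that
variation. `parklens` is a tested, reusable implementation of a
park-user analysis built on such data: it classifies photographs into
content categories from machine-vision keyword sets, groups users by
residential status and by compositional axes of their photo content,
models park photography behaviour, and maps user-group skew across park
polygons. Because raw platform data of this kind cannot be
redistributed, the package ships a first-class synthetic-data generator
with known ground truth, so every stage can be exercised and validated
end to end.

## What it computes

**Photograph classification.** Each photo carries a set of up to ten
keywords (as returned by a vision API). Photos are encoded as binary
keyword indicators; pairwise dissimilarity is the Jaccard distance
d(i,j) = 1 − |K_i ∩ K_j| / |K_i ∪ K_j|; the distance matrix is
clustered agglomeratively under Ward's criterion (Lance–Williams on the
dissimilarities). The number of categories k is chosen with the
L-method: an evaluation graph eval(k) = mean between-cluster − mean
within-cluster pairwise distance is computed on a random 10% sample
(floor 200 photos), and the knee is the breakpoint minimizing the
size-weighted RMSE of a two-line fit, starting from a 20-point window.
Classification quality against manual labels is summarized by a
confusion matrix, overall accuracy and weighted Cohen's kappa, with
mutually confused category pairs suggested for aggregation.

**User groups.** Residential status is the profile country when listed,
else the modal country of the user's geotagged public photos. Per-user
category profiles are compositional: counts → percentages → +1 to every
component → closure. Profiles are mapped to isometric log-ratio (ilr)
coordinates (pivot basis) and summarized by robust PCA
(minimum-covariance-determinant scatter, support fraction 0.75);
loadings are reported in centred log-ratio (clr) space, where each
component's loadings sum to zero.

**Behaviour models.** Counts of park photos per user follow a
negative-binomial (NB2) regression with log link and the log total
upload count as offset: log μ = log(uploads) + xᵀβ, Var = μ + μ²/θ.
The composition of park photos follows a Dirichlet regression in the
'common' parameterisation, log α_c = xᵀβ_c. Regressors (tourist status
and the four user axes) are standardized; backward stepwise selection
(p-values + AIC) and VIF diagnostics are provided.

**Group comparison and mapping.** Category frequencies are compared
between locals and tourists by sampling one photo per user (mean over
50 repetitions), with pooled two-proportion z tests (z² = χ²) and an
effect size d = 2r/√(1−r²), r = √(χ²/N). Per park polygon, the
tourist−local unique-user difference and, for parks with ≥3 users, mean
user-axis scores are computed.

## Worked example

Run the full pipeline on synthetic data from a YAML config:

```yaml
# example.yaml
workdir: example_run
synth: {n_users: 200, photos_per_user_mean: 14.0,
        favs_per_user_mean: 8.0, seed: 11}
k_max: 25
per_stratum: 20
reps: 50
```

```sh
parklens run-all --config example.yaml
```

prints (abridged):

```
simulate: {'n_photos': 4900, 'n_users': 200, ...}
cluster:  {'channels': {'park': 10, 'public': 9, 'favourited': 9}}
assess:   {'park': {'accuracy': 0.965, 'kappa': 0.936}, ...}
users:    {'n_local': 80, 'n_tourist': 120, 'n_unresolved': 0, ...}
models:   {'nb_n': 181, 'dirichlet_n': 35}
freq:     {'n_categories': 10, 'reps': 50}
spatial:  {'n_parks': 12, 'n_occupied': 12}
```

The cluster stage selected 10 park-photo categories (the generator's
true number); the assessment stage classified a stratified sample
against an aligned observer with 96.5% agreement (weighted κ = 0.94).
The fitted count model in `example_run/nb_fit.json` is

```
beta: {intercept: -1.91, status_tourist: -0.31, pPC1: -0.36,
       pPC2: 0.30, fPC1: -0.22, fPC2: 0.20},  theta: 1.99,  n: 181
```

— tourists take fewer park photos per upload than locals, and the
second public axis (the analogue of a 'Wildlife–City' gradient) has a
positive effect on park photography, matching the generator's
configured coefficients (intercept −1.8, tourist −0.4, axis-2 +0.4,
θ = 2). Signs of the PC coefficients are relative to each component's
own sign convention (largest clr loading positive). `tests.csv` holds
the per-category local-vs-tourist z statistics, e.g. category 1:
z = −2.43, χ² = 5.9, p = 0.015, d = 0.41.

Every stage can also be called as a library function; see
`parklens.cluster`, `parklens.users`, `parklens.models`, etc.

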