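# Methods

`copulaforest` grows multivariate regression-tree ensembles whose node
cost preserves the *dependence structure* of the output responses, for
problems — drug-sensitivity prediction being the motivating one — where
several outputs (e.g. AUC responses of a cell line to related drugs)
are coupled through shared mechanisms, possibly nonlinearly.

## Model

Given training features `X (n x M)` and responses `Y (n x r)`, a forest
of `T` un-pruned regression trees is grown on bootstrap resamples.  At
each node a random subset of `m` features is drawn and every
`(feature, threshold)` partition (`x <= z` left, `x > z` right, one
threshold per observed in-node value) is scored by the reduction in a
node cost `D`:

```
gain(split) = D(parent) - D(left) - D(right)
```

Three costs are implemented behind a single `SplitCriterion` interface:

* **SSE** (`"sse"`) — `sum_i (y_i - mean)^2`, summed over response
  columns; the classical univariate criterion.
* **Mahalanobis / covariance** (`"mahalanobis"`, the VMRF criterion) —
  `sum_i (y_i - mu) Lambda^-1 (y_i - mu)^T`, where `Lambda` is the
  covariance of the full training responses, computed once per forest.
  Whitening by `Lambda` penalises child nodes whose responses deviate
  from the training covariance structure, but only linear structure.
* **Copula** (`"copula"`, the CMRF criterion) —

  ```
  D_C = D1 + alpha * D2,
  D1  = 6 * p * Psi(C_node, C_root),
  D2  = sum_j SSE_j / sigma_j^2
  ```

  where `p` is the node size, `C_node` is the empirical copula of the
  node responses (re-ranked *within* the node, so the comparison is
  marginal-free by Sklar's theorem), `C_root` the empirical copula of
  the full training responses, `Psi` the integral over the unit
  hypercube of `|C_node - C_root|`, and `sigma_j^2` the root-node
  variance of response `j`.  The factor 6 normalises `D1` to the same
  `O(p)` range as `D2`: the integral of `C_U - C_L` (the pointwise
  Fréchet–Hoeffding envelope, which bounds `|C1 - C2|` for *any* two
  copulas) equals exactly 1/6 in two dimensions, so `6 * Psi <= 1` up
  to empirical resolution.

Prediction uses the weight representation: a tree assigns training row
`i` the weight "multiplicity of `i` in the leaf containing the query,
divided by leaf size"; the forest averages weights over trees and
applies them to `Y`.  Predictions are therefore convex combinations of
training responses.  Variable importance is the selection frequency of
each feature across all internal nodes of the forest, normalised to
sum to 1.

## Empirical copulas and Psi

Pseudo-observations are within-column average ranks divided by `p`
(`denominator="n+1"` available), making the estimator invariant under
strictly increasing marginal transforms and exactly 1 at the top rank.
The copula is tabulated on a `K^r` lattice at `u = (k1/K, ..., kr/K)`
by sparse deposit plus running sums (`O(p + r K^r)`), and `Psi` is the
lattice mean of the absolute difference.  `K = 10` by default: the
split search cost is linear in `K^r`, and at node sizes of tens of
samples a finer lattice resolves no additional structure (the empirical
copula itself is a step function with `1/p` jumps).  For `r > 3` the
lattice is replaced by 2048 seeded scrambled-Sobol evaluation points.

The split search evaluates all prefixes of the feature-sorted node in
one vectorised sweep: prefix ranks come from cumulative comparison
counts (`O(p^2 r)` per feature) and all prefix copula lattices from a
single scatter plus running sums.  A slow per-candidate path (used for
response matrices containing NaN, and as the test oracle) computes the
identical quantities directly; an acceptance test holds the two paths
to exact agreement against brute-force enumeration.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `T` | 150 | trees per forest (the drug-panel protocol value) |
| `m` | 10 | features drawn per node, redrawn at every node |
| `n_size` | 5 | a node with fewer rows becomes a leaf |
| `bootstrap_frac` | 1.0 | bootstrap draw size (with replacement); 0.8 in the synthetic benchmark protocol |
| `alpha` | 1.0 | copula-cost weight; 1 puts `D1` and `D2` on the scale the factor 6 was designed for |
| `grid_resolution` (`K`) | 10 | copula lattice per axis |
| `min_child` | 1 | optional minimum child size per split (a stricter minimum-leaf reading of `n_size`) |
| `allow_negative_gain` | True | split to `n_size` even when the best gain is non-positive (see below) |

**Stopping rule.** Trees split until the node-size floor.  A
"stop when the best gain is non-positive" variant is available
(`allow_negative_gain=False`) but is *not* the default: under the
copula cost the children's `D1` systematically exceeds the parent's —
a smaller sample's empirical copula sits farther from the root copula
by pure sampling noise — so the non-positive-gain rule degenerates
every copula tree to a stump.  For SSE and Mahalanobis costs the gain
is non-negative by the variance decomposition and the rule is inert.

**Tie rule.** Candidates are scanned feature-ascending then
threshold-ascending; gains equal up to 1e-9 relative are ties and the
first candidate wins.  This makes trees exactly reproducible, at a
price worth knowing: at small deep nodes several features often induce
bit-identical partitions, and all such splits are credited to the
lowest feature index, which biases selection-frequency importance
toward low-index features when trees are grown deep.

## Choosing alpha

* **Grid method** — candidate alphas (default: 10 log-spaced values on
  [0.1, 10]) are each used to train a forest on a secondary 70/30
  train/test split of the training data; the candidate with the best
  mean per-response Pearson correlation wins.  Under cross-validation,
  alpha is re-selected inside each training fold and then fixed for
  all trees of that fold.
* **Pareto method** — minimising `D1 + alpha * D2` is a scalarised
  two-objective problem, so candidate first splits are examined as
  `(D1, D2)` clouds per child over probe trees.  The non-dominated
  frontier of each cloud is approximated by a two-segment least-squares
  fit (breakpoint chosen to minimise total residual; single line below
  4 points); each negatively sloped segment `rho` yields a candidate
  `alpha = -1/rho`.  Steep segments (|rho| > 1) produce alphas below 1,
  shallow ones above 1; the two pooled means are scored like the grid
  method and the better one returned.  Children smaller than the
  minimum copula node size are excluded from the clouds — under the
  degenerate-node convention below they would contribute an exact
  `(0, 0)` that dominates every frontier.  Numerically flat segments
  (slope above −1e-9) are discarded rather than mapped to absurd alphas.

## Numerical conventions and degenerate inputs

* `Psi := 0` for nodes below 3 complete rows (a 1–2-point empirical
  copula is vacuous) and for `r = 1` (every one-dimensional marginal
  has the same trivial copula) — which makes all criteria grow
  *identical* trees in the univariate case.
* `Lambda` is inverted by pseudo-inverse after a `1e-8 * trace`
  diagonal lift, so collinear response panels do not crash the
  covariance criterion.
* Root variances `sigma_j^2` must be positive; a constant response
  column is rejected at criterion construction.
* Responses may contain NaN inside `cost_copula`: `D2` sums observed
  entries per column and `Psi` uses complete rows; the standard
  pipeline instead filters complete cases up front by sample ID.
* NRMSE is the square root of prediction SSE over the centred sum of
  squares (1.0 exactly for mean prediction); the un-rooted variant is
  available (`sqrt=False`).
* All randomness flows through `numpy` `SeedSequence` substreams keyed
  per tree, so enlarging a forest never reshuffles earlier trees and
  identical seeds give bit-identical serialised models.

## Synthetic data

The flagship generator draws `X (n x M)` iid standard normal and sets

```
Y1 = 2 x1 + 5 x2 - 1.5 x3 + x4,      Y2 = (Y1 - mean(Y1))^2
```

(defaults n = 50, M = 10; the centring uses the realised sample mean,
with an analytic-zero variant by flag; responses are noise-free by
default, additive Gaussian noise optional).  The pair is nearly
uncorrelated yet deterministically dependent — precisely the structure
a covariance criterion cannot see and a copula can — and only four
features matter, with |weights| ordered X2 > X1 > X3 > X4, giving
importance rankings a known right answer.  Further models provide
linearly coupled, Clayton(ξ)-coupled (Kendall's tau ξ/(ξ+2)) and
independent response pairs.  None of these emulate real expression
data: features are independent Gaussians without the correlation
blocks, batch structure or heavy tails of microarray panels, so
passing tests demonstrate correctness of the machinery and behaviour
under controlled dependence, not field performance.

Two bundled study protocols (`copulaforest.experiments`) rerun the
benchmark end-to-end: the importance protocol (100 trees, `m = M`, 80%
bootstrap, `n_size = 5`, alpha = 1, 20 replicate seeds) and the 5-fold
CV contrast between the copula and covariance criteria (20 replicates,
T = 25).  Problem sizes were chosen so each protocol completes in a few
minutes on one core while keeping replicate-mean standard errors near
0.01 on the importance scores.

## Known limitations

* On the quadratic benchmark at n = 50 the copula criterion does *not*
  outperform the covariance criterion in out-of-fold Y2 correlation:
  the two are statistically indistinguishable across fixed alphas, and
  data-driven alpha selection does not change the sign.  The bundled
  contrast experiment reports this honestly; claims that the copula
  cost improves *prediction* should be re-examined on data with
  stronger, structured output dependence (large correlated drug
  panels).
* Selection-frequency importance inherits the tie-rule bias described
  above and, like all frequency measures, conflates "selected" with
  "useful"; permutation or out-of-bag importance is out of scope.
* The exhaustive split search is quadratic in node size per feature;
  the implementation targets panels of hundreds of samples and tens of
  pre-filtered features (upstream feature screening, e.g. RELIEFF-style,
  is assumed to have already happened and is not provided).
* Splits are axis-aligned on numeric features only; no surrogate
  splits, pruning, or categorical handling.
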