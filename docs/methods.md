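# Methods

This note records the mathematical conventions, default parameters and
numerical choices behind `scmf`, including every place where a design
decision was required.

## 1. Model and optimization

The objective over factor matrices `X ∈ R^{n×k}`, `Y ∈ R^{m×k}` is

```
L(X, Y) = ½ Σ_ij (A_ij − x_i·y_j)²
        + μ/2 (Σ_i ‖x_i‖² + Σ_j ‖y_j‖²)
        + λ/2 Σ_{i,j} ‖x_i − x_j‖² W_d,ij
        + λ/2 Σ_{i,j} ‖y_i − y_j‖² W_s,ij
```

with `A` binary, `W_d`, `W_s` symmetric non-negative similarities with unit
diagonal. Optimization sweeps the rows of `X`, then the rows of `Y`
(Gauss–Seidel: updated rows are used immediately within a sweep). The row
subproblem is quadratic; its gradient with respect to `x_i` is

```
∂L/∂x_i = x_i (YᵀY + μI) − A_{i,:} Y + λ Σ_{j≠i} (W_d,ij + W_d,ji)(x_i − x_j)
```

and the exact Newton step solves

```
x_i ← (A_{i,:} Y + λ Σ_{j≠i} (W_d,ij + W_d,ji) x_j)
      (YᵀY + μI + λ Σ_{j≠i} (W_d,ij + W_d,ji) I)⁻¹
```

(symmetrically for `y_j`). Because the subproblem is quadratic and the
system matrix is positive definite (`μ > 0`), each row update is the exact
row minimizer and the objective trace is non-increasing; the test suite
checks this property on random instances.

### Diagonal handling

The `j = i` terms of the graph penalty are identically zero
(`‖x_i − x_i‖² = 0`), so the self-similarity `W_ii` contributes nothing to
the gradient or the true curvature. The published update formula, read
literally, includes the `j = i` term in both sums, which inflates the
system matrix by `2λW_ii` and makes the update a damped (majorize–minimize)
step rather than an exact Newton step; it converges to the same fixed
points. The default excludes the diagonal (exact Newton, self-consistent
with the gradient); `Hyperparameters(verbatim_diagonal=True)` selects the
literal damped variant. A test verifies both share fixed points.

### Defaults and convergence

* `k`: `round(k_fraction · min(n, m))` with half-away-from-zero rounding,
  clipped to `[1, min(n, m) − 1]`; default `k_fraction = 0.45`
  (e.g. 121 for a 269×598 matrix).
* `μ = 1`, `λ = 4`: the values selected by the original grid search over
  `2⁻³ … 2³`.
* Initialization: i.i.d. `Uniform(0, 1)/√k` entries from
  `numpy.random.default_rng(seed)`, so initial predicted scores have mean
  ≈ ¼ regardless of `k`.
* Convergence: relative objective change
  `|L_t − L_{t−1}| / max(1, |L_{t−1}|) < tol` (default `1e-6`) or
  `max_sweeps` (default 200). The trace includes the initial objective at
  index 0.

## 2. Similarities

**Drugs.** Jaccard index of binary descriptor vectors:
`J(p, q) = |p ∧ q| / |p ∨ q|`, defined as 0 when the union is empty (an
all-zero drug therefore has self-similarity 0, reported with a warning).

**Diseases.** Each disease's MeSH tree numbers span a DAG of tree-number
prefixes. The contribution of ancestor `d` to disease `A` is

```
C_A(d) = 1                         if d is one of A's own terms
C_A(d) = max over children d' of Δ · C_A(d')   otherwise,  Δ = 0.5
```

the semantic value is `DV(A) = Σ_d C_A(d)`, and

```
S(A, B) = Σ_{d ∈ nodes(A) ∩ nodes(B)} (C_A(d) + C_B(d)) / (DV(A) + DV(B)).
```

Nodes are identified by their tree-number prefix string; `S(A, A) = 1`
exactly, and diseases with disjoint ancestries score 0. An exhaustive
recursive oracle validates the implementation on all small DAG pairs.

## 3. Evaluation protocol

Five-fold cross-validation partitions the known positives into folds of
near-equal size (shuffled with a seeded generator). For each fold the held
positives are set to 0 in the training matrix, the model is refitted
(per-fold seed = base seed + fold index), and scores are evaluated on every
cell that is 0 in the training matrix: the held positives are labeled 1 and
all never-positive cells 0.

* **AUPR** is the tie-grouped step-wise average precision
  `Σ (R_t − R_{t−1}) · P_t` over distinct score thresholds — the convention
  under which the worst ranking of a single positive among `N` cells scores
  exactly `1/N`. (Trapezoidal PR interpolation is deliberately not used; it
  is known to overstate performance between points.)
* **AUC** is the Mann–Whitney statistic with ties counted ½, computed via
  rank sums.
* **SN/SP/ACC/F** require a binarization rule: the default scans all
  thresholds and keeps the one maximizing F; `("fixed", t)` and
  `("top", n)` rules are available.

`grid_search` evaluates every `(k_fraction, μ, λ)` combination on one shared
fold plan and flags the unique best-AUPR row (ties broken by first
occurrence in grid order).

## 4. Synthetic benchmark

Problem sizes throughout the tests (60×60 and 60×80, rank-4 truth, 10 %
positives) are this package's own desk-scale choices. The generator plants
recoverable structure:

* Latent factors `X ∈ R^{n×k_true}`, `Y ∈ R^{m×k_true}` with i.i.d.
  `Gamma(0.5, 1)` entries — non-negative and right-skewed, so drugs have a
  few dominant latent topics.
* Associations: the top `round(richness · n · m)` cells of `X Yᵀ` become 1
  (exact positive count).
* **Label noise** (`noise = 0.3` default): that fraction of positives is
  relocated to uniformly random zero cells. This models the incompleteness
  and error of curated association databases and is essential to the
  benchmark's validity: with noise-free exactly-thresholded labels, the
  association matrix alone fully identifies the planted structure and any
  `λ > 0` strictly hurts, which would make the benchmark unable to detect
  the benefit the constraint provides on real data.
* Similarities: `α · cosine(rows of the true factors) + (1 − α) ·`
  min–max-rescaled symmetric uniform noise, diagonal set to 1;
  `α = 0.9` default controls informativeness.

### Known limitation: λ saturation under dense similarities

Cosine similarity of non-negative rank-4 factors has a high baseline
(mean ≈ 0.55), so the row-update damping term `λ Σ_j (W_ij + W_ji)` is large
even for unrelated entities. At `λ = 4` on these 60-entity fixtures the
graph term dominates the data term and pushes all factors toward a common
mean (a popularity model). Consequences observed and accepted:

* The benefit of `λ = 4` over `λ = 0` is real and reproducible (10/10
  seeds) but modest, and small grids on these fixtures often prefer gentler
  `λ` (1 or 0.125) — expected, since the original `λ = 4` was selected on
  matrices ~20× larger and much sparser similarity structure.
* Monotonicity of held-out AUPR in the similarity informativeness `α` holds
  at gentle `λ` (the regime where the constraint reads the similarity signal
  rather than flattening everything); the test suite pins it at `λ = 1/16`.

## 5. Numerics and reproducibility

* All linear systems are solved with `numpy.linalg.solve` (no explicit
  inverses); all randomness flows through `numpy.random.default_rng` with
  explicit seeds; repeated runs are bit-identical.
* Similarity matrices read from disk are validated: asymmetry beyond `1e-8`
  is averaged away and negatives are clipped, with warnings. `fit` rejects
  asymmetric similarity inputs outright.
* Sorting for metrics uses stable mergesort; threshold groups are formed
  over distinct score values, so results are invariant under any strictly
  monotone transform of the scores.
* Written floats use `%.6g`; computation always stays in full double
  precision.
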