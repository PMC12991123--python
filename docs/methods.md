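# Methods notes

## Model and assumptions

The analysis treats each subject's functional connectome as a complete
weighted graph on `n` regions, edge weights in Fisher-z units, stored as a
vector in the canonical edge order (unordered pairs `(i, j)`, `i < j`,
lexicographic). Negative weights are admitted throughout: the maximum
spanning tree maximizes weight regardless of sign, and nothing in the cycle
algebra requires positivity.

The simplicial complex never includes 2-simplices, so the boundary map
`B2` is the zero map and the Hodge decomposition of edge space has only two
nontrivial parts: the gradient space `img(B1ᵀ)` (flows induced by node
potentials, dimension `n − 1` for a connected graph) and the harmonic space
`ker(B1)` (circulations, dimension `Q = m − n + 1`). The fundamental-cycle
basis spans the harmonic space but is *not* orthogonal — cycles sharing
tree-path edges correlate — which is why projection uses least squares
rather than inner products, and why coefficient noise is amplified by the
diagonal of `(φφᵀ)⁻¹`.

Orientation is ascending node index (edge `(i, j)` points `i → j`); each
cycle's sign is fixed so its closing-edge coefficient is positive. These two
conventions make every cycle vector reproducible bit-for-bit.

### Equivalence of the two cycle constructions

The spectral route (eigenvector of the one-dimensional `ker L1` of the
subgraph MST + closing edge) and the combinatorial route (signed tree path
plus closing edge, scaled to unit norm) provably produce the same vector:
the subgraph has exactly one independent loop, its circulation is the unique
kernel element, and a circulation on a single loop must have equal-magnitude
entries. Both are implemented; the tree-path route is the default because it
builds the full 50,086-cycle basis of a 318-node connectome in about a
second, while per-edge eigendecomposition is kept as the cross-check
(`method="eig"`, exercised over random graphs up to n = 40 in the tests).

### Birth–death decomposition

Kruskal on descending weight with ties broken by ascending canonical edge
index gives a deterministic maximum spanning tree even on degenerate
(equal-weight) inputs. Non-finite weights mark absent edges, so
disconnected inputs are detected and rejected rather than silently spanned.
The step-wise filtration semantics (a birth edge merges two components, a
death edge closes a loop, at every step of the descending-weight sequence)
is enforced by test. Note that the *ascending*-order statement "the graph
stays connected until every death edge is removed" is not a theorem — by
cut optimality a tree edge can be globally lighter than off-tree edges — so
the tests assert the step-wise membership property instead.

## Statistical procedure

- **Design**: intercept, group (0/1, controls = 0), age, sex (0/1), mean
  framewise displacement, site dummies with the first (sorted) site dropped.
  Site enters as fixed effects in the main analysis; the edge-wise
  sensitivity model uses a site random intercept instead.
- **Freedman–Lane**: the reduced (nuisance-only) model is fit once; its
  residuals are permuted within site strata and added back to the reduced
  fit; the full model is refit per iteration. One shared shuffle across all
  cycles preserves the inter-cycle correlation needed for valid max-T.
  Two-sided tests on |T|; direction is read off the sign of β.
- **P-values**: `(1 + exceedances) / (1 + n_perm)` — valid and never zero;
  the smallest attainable p is the floor `1/(1 + n_perm)`.
- **Global p** is defined as the minimum FWER-corrected p over cycles
  (equivalently the corrected p of the largest observed |T|).
- **Effect sizes**: with 0/1 group coding, Cohen's d = β_group divided by
  the residual SD (covariate-adjusted standardized difference);
  partial R² = t²/(t² + df).
- **Edge-wise LME**: REML-fit random-intercept model per edge; an edge whose
  fit fails or yields a non-finite Wald p is recorded as *untested* and
  excluded from BH-FDR, never imputed. With one site the random intercept is
  unidentifiable and the model falls back to per-edge OLS with a warning.
  The q-threshold is `alpha / n_contrasts` when several contrasts are tested
  simultaneously (the study convention of 9 contrasts gives 0.05/9 =
  0.0055556).
- **MST/extra split**: each subject's edge vector is masked by that
  subject's *own* MST (the template basis `φ` stays fixed), giving
  `α_MST + α_Extra = α` exactly by linearity. Because the ambiguity between
  a within-subject paired contrast and separate group tests on the two parts
  cannot be resolved from the procedure description alone, both are
  computed: group GLMs on `α_MST` and `α_Extra` separately plus the paired t
  on their difference, each family BH-FDR corrected.

## Synthetic cohort generator

The generator emulates a multi-site case-control FC study:

| parameter | default | meaning |
|---|---|---|
| `n_nodes` | 16 | template ROIs (complete graph, Uniform(0.1, 0.9) weights) |
| `n_subjects_per_group` | 40 | per group; sites filled round-robin within group |
| `n_sites` | 4 | additive per-site, per-edge offsets, SD `site_sd` |
| `site_sd` | 0.05 | site offsets are centered across sites (they are deviations from the shared template, which is defined as the population mean) |
| `noise_sd` | 0.1 | subject-level Gaussian edge noise (Fisher-z units) |
| `covariate_slopes` | age 0.01, sex 0.02, fd 0.05 | uniform additive slope per edge |
| `effect_size` | 0 | standardized shift per planted cycle coefficient |

Group effects are planted additively in edge space along unit-norm cycle
vectors of the noise-free template's basis, so the planted group-mean shift
in the coefficient domain is *exactly* `effect_size × noise_sd` at the
planted indices and zero elsewhere — the identity `Δα = (φφᵀ)⁻¹ φ (s Σφ_k)
= s` at planted `k` holds by construction. Covariates are standard normal
(age, fd) and Bernoulli(½) (sex, group-balanced sites), matching the 0/1
dummy coding of the design.

What the generator does **not** emulate: empirical FC covariance structure
(edges are independent given the template), hemodynamics, scanner-specific
artifacts, site-by-group confounding, or heavy-tailed motion distributions.
Calibration and recovery results on these cohorts therefore demonstrate
correctness of the *machinery* under a correctly specified model, not
robustness to real-data violations.

Time-series generation inverts the Fisher-z matrix to correlations and
projects to the nearest positive-definite correlation matrix by eigenvalue
clipping at 1e-6 with diagonal renormalization — a z-domain template need
not be a valid correlation matrix — then samples i.i.d. Gaussian vectors
through the Cholesky factor.

### Basis identity at high planted effect

At large `effect_size` the planted shift itself perturbs the cohort-average
graph enough to change its maximum spanning tree, and with it the identity
of the fundamental cycles; a basis re-derived from the contaminated average
is then no longer index-aligned (or even closing-edge-aligned) with the
truth. Ground truth is defined in the noise-free template's basis, so the
recovery experiments project onto that basis; the pipeline accepts a saved
basis (`basis_dir`) for exactly this kind of designated-template analysis —
and because subgroup contrasts must share the main analysis' basis to be
comparable at all.

## Numerical choices

- Zero-eigenvalue tolerance for Betti numbers: `λ < 1e-8 · max(λ_max, 1)` —
  scale-free, robust to `m ≈ 5·10⁴`.
- Correlations clipped to `|r| ≤ 1 − 1e-7` before `atanh`, so collinear
  inputs give a large finite z.
- High-pass filter: Gaussian-weighted running-mean subtraction with kernel
  SD `width_s / (2·tr_s)` samples, truncated at ±4σ and renormalized at the
  series boundaries. The filter-width convention (width ≈ 2σ, FSL-style) is
  a documented choice; "width" could alternatively denote FWHM or a cutoff
  period, and the class constructor exposes the width directly so either
  reading can be configured.
- Projection: dense rank-revealing least squares (`gelsy`) by default with a
  hard error on rank deficiency; sparse normal equations with an LU factor
  and a condition-number warning (above 1e8) as the large-Q option.
- Cluster ids are relabeled by first appearance, making the assignment
  deterministic and order-stable; the similarity-0.5 threshold is applied as
  a cosine-distance-0.5 cut (similarity = 1 − distance).

## Problem sizes

The default test and calibration cohorts use 10–16 nodes (45–120 edges,
36–105 cycles), 48–100 subjects over 1–4 sites, and 120–1000 permutations;
the family-wise error calibration uses 200 replicate cohorts at 500
permutations. These sizes give exact combinatorial ground truth and tight
Monte-Carlo envelopes while keeping the full suite fast; the basis
construction itself is additionally exercised at full connectome scale
(n = 318, m = 50,403, Q = 50,086).

## Known limitations

- Cycle coefficients are defined relative to a single common basis; no
  subject-specific ("individualized") cycle bases.
- The fundamental-cycle basis depends on the template MST: near-ties in
  average edge weights can flip tree membership between otherwise similar
  templates, changing cycle identities (see above).
- The edge-wise LME loops over edges in Python; at full connectome scale
  (5·10⁴ edges) this is the slowest stage and is best run once, not inside
  permutations (it is not permuted in this design).
- `partial R² = t²/(t²+df)` is the squared partial correlation of the group
  regressor; it is not adjusted for shrinkage.
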