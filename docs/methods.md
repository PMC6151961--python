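# Methods

This note documents the models, numerical conventions and design choices of
the package, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Data model and pre-processing

Compounds × descriptors matrices carry a per-descriptor kind flag
(continuous / integer / binary). Kinds absent from the input are inferred
deterministically: a column whose values all lie in {0, 1} is binary, all
whole numbers integer, else continuous. Missing values are rejected rather
than imputed. When descriptor and property tables are joined, the property
table's row order is canonical, which makes all downstream splits
deterministic functions of the input files.

Pre-selection applies three filters in a fixed order:

1. **RSD filter** (default 5 %): removes descriptors with
   100·sd/|mean| below the threshold, using the sample (n−1) standard
   deviation. All-zero columns are removed; a zero mean with positive sd
   leaves RSD undefined and the descriptor is kept. A flag inverts the rule
   for the (unconventional) high-variance reading.
2. **Correlation filter** (default |r| > 0.8): descriptor pairs are visited
   in descending |Pearson r|; in each offending pair the member whose best
   |r| against the two responses is lower is removed; ties keep the earlier
   column. Zero-variance descriptors count as correlation 0 here — removing
   near-constants is the RSD filter's job.
3. **Zero filter**: a continuous descriptor containing any exact zero is
   removed; binary and integer descriptors are exempt. The exemption is what
   makes this reading of "remove descriptors with zero values" coherent —
   zeros are meaningful on count and indicator scales but typically encode
   "not computable" on continuous ones.

Autoscaling (centring + unit sample variance) is the pretreatment everywhere
— PLS, leverage, distances for Kennard–Stone — because every domain
diagnostic used here (leverage sums, T², DModX) presupposes it. The sample
(n−1) sd is used throughout, not the population sd.

**Kennard–Stone** seeds with the globally most distant pair and then
repeatedly adds the candidate maximising the minimum distance to the
selected set; all ties break on the lowest row index, making the split a
pure function of the matrix. Distances are computed on autoscaled
descriptors (constant columns dropped for the distance only).

**Lipophilicity fit**: ordinary least squares of log k on the
organic-modifier fraction φ; the intercept at φ = 0 is log k_w, the slope S.
Collinear input reproduces the line exactly (zero residual).

## Two-response PLS (NIPALS)

The estimator follows the scikit-learn protocol and autoscales X and Y
internally. Components are extracted NIPALS-style with X-deflation and
per-component Y-residual recomputation. The inner loop of NIPALS is a power
iteration whose fixed point is the dominant eigenvector of the q×q matrix
(YᵀX)(XᵀY); with q = 2 responses this eigenproblem is solved in closed form
instead of iterated, which is exact, deterministic (a sign convention fixes
the weight direction), and immune to the stalling that power iteration
suffers when the two eigenvalues are nearly equal — a situation that occurs
routinely in late components whose Y-residual is essentially noise.
Extraction stops early if the Y residual is numerically exhausted; the
fitted attribute `n_components_` records the number actually extracted.

Stored quantities: weights W, X-loadings P, Y-loadings C, rotations
R\* = W(PᵀW)⁻¹, training scores T and their sample covariance S, the
explained variances R²X/R²Y, and the pooled training residual sd
s₀ = √(ΣΣe²/((n−A−1)(p−A))) used by DModX. Predictions for every truncation
1..A come from one fit (NIPALS components are nested), which is what makes
cross-validation inside the GA fitness affordable.

**Cross-validation** for the latent-variable count uses a seeded shuffle
followed by contiguous blocks (k = 7 by default); the per-A error is the sum
over responses of the root-mean-square CV residual in original units, and
the smallest-error A is chosen. k = n gives leave-one-out.

**Metrics**: RMSEE (training) and RMSEP (test) per response as
√(Σ(pred−obsd)²/n); the mean relative error is reported in percent as the
mean of |pred−obsd|/|obsd|, with zero observations excluded under a warning
since the ratio is undefined there.

## GA descriptor selection

Chromosomes are binary membership vectors over the filtered pool, repaired
by random add/drop into the cardinality window (default 5–20). Fitness of a
subset: fit PLS with A chosen by 7-fold CV, then pool training and external
test errors per response,

    η_j = √(((n_T − n_S − 1)·RMSEE_j² + n_P·RMSEP_j²)/(n_T + n_P − n_S − 1)),
    η   = √(η₁² + η₂²),

so that larger subsets discount the training error's weight; η keeps RMSE
units and reduces to the single-response form when one response has zero
error. The external validation set supplies RMSEP (not a CV estimate), so
the selection criterion rewards genuine out-of-sample behaviour at the
split the user fixed.

Search settings: selection function (tournament of 2 / roulette on inverted
fitness / uniform), crossover function (scattered / single-point /
two-point), crossover fraction, mutation rate — mirroring the options of
common GA toolboxes — with elitism of one, so the best-fitness history is
non-increasing by construction. The mutation rate is interpreted on the
chromosome scale: each gene flips with probability 5·rate/p, so a mutated
chromosome sees about 5·rate flips regardless of the descriptor-pool size p.
A literal per-gene reading of rates like 0.2–0.8 would flip dozens of genes
per child on a realistic pool and reduce the search to noise under a 5–20
cardinality constraint. Evaluated subsets are cached by membership, so
re-visited chromosomes are free. The grid search sweeps the cross product of
the tuning ranges with one derived seed per cell and returns all cells
sorted by η.

## Applicability domain

* **Leverage**: h = 1/n + x_cᵀ(X_cᵀX_c)⁻¹x_c on autoscaled selected
  descriptors; training leverages sum to k+1 under this intercept
  convention, and the warning limit is h\* = 3(k+1)/n.
* **Standardized residuals**: residual divided by the training RMSEE per
  response; the Williams rule declares a compound in-domain when |std
  resid| ≤ 3 and h ≤ h\*.
* **Hotelling T²**: t̂ᵀS⁻¹t̂ with the training score covariance;
  critical value A(n−1)/(n−A)·F₁₋α(A, n−A).
* **DModX**: √(Σe²/((p−A)·g))/s₀ with e the scaled-domain reconstruction
  residual x − t̂Pᵀ and g = n/(n−A−1) the standard new-observation variance
  inflation (a query row carries the estimation error of the centring,
  scaling and loadings on top of its own noise). Without g the limit is
  visibly anti-conservative for prediction rows; with it, simulated
  in-model rows exceed the α = 0.05 limit at close to 5 % (the test suite
  measures this). The critical value is √(F₁₋α(p−A, (n−A−1)(p−A))). If the
  training fit is numerically exact (s₀ ≈ 0) the unnormalized residual
  distance is returned, so exact reconstructions report 0.

The F-based DModX limit is an approximation whose calibration additionally
assumes homogeneous residual variance across (scaled) descriptors; with
strongly heterogeneous per-column signal content its tail is heavier than
F. The Monte-Carlo calibration checks therefore use an equal-row-norm
latent frame (every column carries the same signal variance) at n = 200
training rows — at which size the residual finite-n corrections to both
limits are small — and average over replicate fitted models so that the
conditional wobble of a single training draw does not mask the marginal
coverage. These sizes are the package's calibration-check design, chosen
once.

## Model inversion

The inversion searches raw descriptor space for x\* minimising the squared
deviation of the predicted properties from the reference pair, subject to
(i) the Hotelling ellipsoid t̂ᵀS⁻¹t̂ ≤ c₁ with c₁ the T² critical value,
(ii) the reconstruction-residual bound ‖t̂Pᵀ − x‖² ≤ c₂ in scaled units,
with c₂ = s₀²·(p−A)·g·DModX_crit² (the squared residual of a row sitting
exactly on the DModX limit), (iii) training min/max bounds per descriptor,
and (iv) lattice constraints for binary/integer descriptors. Scores are
computed as t̂ = xᵀR\*, the standard PLS projection; the reconstruction
residual uses the loadings P, consistent with the latent-variable
model-inversion framework this follows. The squared-norm reading of the
residual constraint is the default; a scalar comparison of the unsquared
norm against √c₂ is the same set, so no flag is needed.

Solver: a seeded mixed-variable GA — uniform initialisation within bounds
(lattice genes on their lattices), binary tournament selection under a
feasibility-first key (any feasible individual dominates any infeasible one;
infeasible individuals rank by relative constraint violation), scattered
crossover (fraction 0.8), per-gene mutation at rate 0.2 whose continuous
step size anneals geometrically from 20 % to 1 % of the gene's range over
the generations, and elitism of two. The best individual is then polished:
an SLSQP step over the continuous genes (lattice genes frozen) under the
exact constraints, followed by a second SLSQP stage that, at essentially
unchanged objective, minimises the reconstruction residual. The second
stage resolves the inversion's intrinsic degeneracy — once the predicted
properties match the reference, any point within the c₂-ball around the
model plane is equally optimal — by returning the canonical on-plane
representative. With fewer latent variables than responses the score system
is over-determined and a warning is emitted. If no feasible individual is
ever found, the least-violating solution is returned flagged infeasible
rather than raising, so callers can inspect the slacks.

## Screening and rank fusion

Distances to x\* are Euclidean in raw descriptor units on the selected
descriptors (matching the convention in which solution–reference distances
are tabulated); a flag computes them on autoscaled descriptors instead.
Admissibility is leverage-based (h ≤ h\*). Ranks over admissible ligands
ascend with distance, ties broken lexicographically by ligand id. The
optional docking input is either a composite score column or
GlideScore/Prime-Energy components combined as 1.0·GlideScore + 0.05·Prime
Energy; docking ranks ascend with the score (more negative is better). The
final rank is the arithmetic mean of the two ranks rounded half up — the
unique rounding consistent with all thirteen published fusion rows the test
suite reproduces — and equal fused values intentionally share a rank.

## Synthetic data

The generator plants a low-rank latent structure: scores T ~ N(0, I),
informative descriptors X = T·P_trueᵀ·√(n_inf/L) + noise, uninformative
descriptors pure N(0, 1) noise, properties Y = T·C_trueᵀ + noise, labelled
(logkw, logKi). P_true is an orthonormal frame over the informative block
and C_true has unit-norm columns (orthogonal when the latent dimension fits
inside the two-response space): the planted truth is then well-conditioned
and identifiable, so recovery tests measure the search and inversion
machinery rather than accidental near-collinearity of the truth. The first
`n_binary` informative columns are thresholded at their median into {0, 1}
and flagged binary, so subset selection and mixed-integer inversion can
encounter lattice descriptors the way real descriptor blocks contain them.
Defaults (45 compounds, 300 descriptors, 4 latent dimensions, 3 binary,
noise sd 0.3/0.15) emulate the scale of a small sulphonamide QSPR study
after pre-selection.

What the generator does **not** emulate: real descriptor blocks are heavily
collinear, mixed-scale and non-Gaussian, their informative structure is not
exactly low-rank, and binary descriptors are not median splits of latent
factors. Passing recovery tests therefore demonstrate correctness of the
machinery under the stated model, not performance on real Dragon exports.

Test and calibration problem sizes — 20 seeded GA runs on 45×50 with five
planted descriptors, 10 inversion round-trips on 45×7 rank-2 data, 100
replicate models × 100 fresh rows for each coverage check, 10⁵ ligands for
the screening sort — are the package's chosen study sizes for these
properties.

## Known limitations

* The DModX critical limit remains an F-approximation; its printed
  third-party values (computed by proprietary software with an unpublished
  dof correction) are not numeric targets.
* The GA selection criterion uses the external validation set inside the
  fitness; with small validation sets (n_P ≈ 12) the selected subset can
  absorb validation-set noise. This mirrors the modelled workflow and is
  documented rather than altered.
* The inversion returns a single canonical solution; the full null-space
  family of equivalent solutions is not enumerated.
* Library counts, descriptor semantics and anything requiring external
  chemistry software (descriptor computation, docking, MD) are out of
  scope; docking enters only as a score table.
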