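# Methods

## Molecular graphs and atom typing

All descriptors are computed on hydrogen-suppressed heavy-atom graphs:
hydrogens enter only as per-atom counts. Structures are perceived with RDKit
(ring membership, aromaticity, hybridization, implicit-H counts); SDF V2000
coordinates are honored verbatim, and structures without coordinates are
given a single ETKDG conformer with a fixed seed (default 42) when a 3D
descriptor is requested. Multi-fragment inputs are rejected rather than
silently split. Bond distances are shortest-path edge counts on the heavy-atom
graph (BFS via `scipy.sparse.csgraph`); the test suite pins them to an
independent Floyd–Warshall implementation.

Three pharmacophoric atom classes have no universally fixed definition, so
the package fixes simple, testable conventions and makes the predicate
registry configurable per call:

- **donor** (`don`): N or O bearing at least one hydrogen;
- **acceptor** (`acc`): N or O without positive formal charge, excluding
  pyrrole-type aromatic N–H (its lone pair is part of the aromatic sextet);
- **hydrophobic carbon** (`Chyd`): a carbon whose heavy-atom neighbours are
  all carbon.

Aromatic atoms are treated as sp² for the hybridization classes. The
molecular center of mass is mass-weighted over heavy atoms only, consistent
with the hydrogen-suppressed graph, using IUPAC standard atomic weights.

## Descriptor semantics

Occurrence descriptors count **target atoms**, each at most once, that have
at least one source-class atom within the stated bond distance (or within the
stated radius of the center of mass for `com_*_rA` descriptors). Frequency
descriptors count **ordered (source, target) pairs** at exactly the stated
bond distance. An atom satisfying both classes may serve as source and target
but never pairs with itself. These two conventions mirror the "occurrence of
… within" vs "frequency of occurrence of … exactly at" wording of the model
definitions; since the upstream descriptor tool does not publish its exact
pair-counting convention, the choice is fixed here, documented, and
regression-tested against the verbal definitions of all eleven model
descriptors. Frequency names concatenate class tokens (`fsp2Ssp3C7B`); the
parser splits them greedily on the longest known class token, which resolves
every name in the model set uniquely.

The grammar enumerator produces both modes over the 13-class vocabulary for
bond distances up to a cap (default 9) plus center-of-mass radial descriptors
up to a radius cap (default 8 Å), a pool of 3146 named descriptors —
comfortably above the >1600 pool size the models were selected from.

## Activity data

The packaged activity table carries IC50 (mean ± SD, dose–response r²) for
all 21 compounds against the four enzymes, Ki for the two cholinesterases,
and the galantamine/clorgyline reference rows. Two MAO-B entries (5e, 5k) are
right-censored at 1000 nM: they are stored with a censor flag, excluded from
ranges, rankings and any fitting, and compare as least potent in
more-potent-than-standard counts. The loader validates cell counts (84 IC50
cells, 42 Ki cells over the synthesized series) and value sums against
embedded checksums, so silent fixture corruption fails loudly. Potency
conversion is p = 9 − log₁₀(value in nM); pKi uses the Ki columns (AChE,
BChE) and pIC50 the IC50 columns (MAO-A, MAO-B), matching the response
variables of the four published models. Model 1's response is treated as pKi
despite inconsistent response notation in the source equations, matching its
enzyme and the available Ki data; both transforms are exported should a user
prefer the IC50 reading.

## Published models

The four model equations are shipped as a versioned JSON resource with
coefficients at their printed 3-decimal precision and are never refit.
Predictions are linear in the descriptor values; evaluating a model at an
all-zero descriptor vector returns its intercept exactly (7.897, 6.565,
6.898, 5.414), which the acceptance script recomputes at run time. Predicting
from a structure composes descriptor computation (with seeded 3D embedding
for the two `com_*` descriptors) with the linear form. Per-compound
descriptor values and train/test memberships behind the published fits are
unpublished, so the package deliberately makes no claim of reproducing
per-compound fitted values — the prediction path is validated structurally
(intercept identities, linearity, sign behavior, determinism) instead.

## GA-MLR subset selection

Model building follows standard small-n QSAR practice: a seeded random 80/20
train/prediction split (train size = round(0.8·n); 21 compounds → 17/4),
pre-filtering that drops zero-variance columns and one of each descriptor
pair with |r| > 0.95 (threshold configurable), then a genetic algorithm over
fixed-size descriptor subsets with leave-one-out Q² as fitness. GA defaults:
population 50, 200 generations, tournament size 3, one-point crossover at
rate 0.8 with duplicate-gene repair, per-gene mutation rate 0.1, elitism 2 —
desk-scale settings, all overridable from the CLI. Two implementation details
matter at this scale: the population is kept free of duplicate subsets
(duplicates waste fitness evaluations and collapse diversity at population
50), and a deterministic steepest-ascent single-column refinement runs from
every distinct final individual, so the returned subset is always a local
optimum of the Q² landscape. LOO residuals use the exact hat-matrix identity
e_i/(1−h_ii); fitness evaluation is batched linear algebra over many subsets
at once. Both shortcuts are pinned by tests to explicit n-refit brute force.

## Validation battery

For a fitted model the report computes: training R², adjusted R², the overall
regression F statistic, RSS/MSE/RMSE/MAE, residual standard error s, AIC and
BIC in the Gaussian small-sample form n·ln(RSS/n) + penalty with p + 2
parameters (coefficients, intercept, error variance — this form can be
negative at sub-unit residual scales), Lin's concordance correlation,
LOO Q²/PRESS/RMSE_cv/MAE_cv, and mean y-scrambling R² (default 100
permutations, seeded; under the null its expectation is ≈ p/(n−1)). With a
prediction set it adds Q²F1 (error normalized by deviation from the training
mean), Q²F2 (test mean), Q²F3 (per-observation normalization by training
variance), external CCC/RMSE/MAE/PRESS, the through-origin regression slopes
k (ŷ on y) and k′ (y on ŷ), the squared Pearson correlation, and Roy's
r²m = r²(1 − √(r² − r²₀)) computed in both regression directions with the
average and absolute difference reported; a numerically negative r² − r²₀ is
clamped at zero. Golbraikh–Tropsha "closure" variants whose conventions are
not fixed in the source material are out of scope.

## Synthetic data

The planted-signal generator draws descriptor-like counts X ~ Poisson(λ_j)
with column rates λ_j uniform in [0.5, 3] — non-negative, discrete,
zero-inflated like real fragment counts — and responses
y = intercept + X[:, S]β + ε with Gaussian ε. Defaults plant the printed
model-1 coefficients β = (−0.214, −0.271, 0.249) with intercept 7.897, so
recovery experiments double as sign/magnitude sanity checks. Constant columns
are redrawn deterministically from the same stream. When no noise SD is
given it is calibrated on the realized design so the planted signal explains
a target fraction (default 0.9) of response variance.

The toy-molecule generator emits hand-enumerable chain/branch/ring templates
over {C, N, O, S, Cl} plus seeded random chains, each carrying expected
descriptor values computed at generation time by an independent double-loop
pair enumeration. What the synthetic data deliberately does *not* emulate:
correlated descriptor blocks from shared substructures, integer overdispersion,
activity cliffs, or realistic drug-like chemistry — so green recovery tests
demonstrate algorithmic correctness, not performance on real descriptor
matrices.

## Identifiability at the study scale

A property worth stating plainly: with n = 17 training rows and p = 300
candidate columns at signal strength R² ≈ 0.9, exhaustive enumeration of all
C(300,3) = 4,455,100 subsets shows the planted subset is the global Q²_LOO
optimum in only about 60% of seeded replicates — random count columns
out-cross-validate the truth in the remainder. Subset recovery at this scale
is therefore capped well below certainty for *any* search algorithm, and the
package's GA lands within one replicate of that exhaustive ceiling on the
default experiment (see `analysis/04_ga_recovery.py`). OLS coefficient
estimation on the true subset is much better behaved: each planted
coefficient falls within ±2 standard errors of its estimate in ≥ 95% of
replicates.

## Numerical conventions and edge cases

- Rank-deficient designs and zero-variance columns raise errors naming the
  offending descriptors; they are never silently dropped inside a fit.
- Q² and CCC raise on zero-variance responses rather than returning NaN.
- `R2_ext` is NaN when predictions are constant (correlation undefined).
- Ties in potency rankings break lexicographically by compound id (none occur
  in the packaged table).
- All randomness flows through `numpy.random.default_rng(seed)`; every CLI
  command writes its resolved configuration next to its output.

## Limitations

- Donor/acceptor/hydrophobic definitions are reasonable conventions, not a
  reconstruction of the original descriptor tool's unpublished rules; counts
  for `acc`, `don` and `Chyd` descriptors can differ from the original
  software's values. The registry is injectable for users who need different
  rules.
- Conformer-dependent (`com_*`) descriptors depend on the embedding seed;
  the original study's conformer protocol is unknown.
- No tautomer/protonation enumeration, stereo-dependent descriptors, or
  applicability-domain analysis.
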