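# Methods

## The model

`trustcpm` implements connectome-based predictive modeling (CPM) of a
behavioral score from resting-state functional connectivity (RSFC), with the
one-shot trust game's investment (trust propensity, an integer 0–10) as the
target behavior.

**RSFC construction.** Given per-node BOLD time courses for a parcellation of
`n` nodes, connectivity between two nodes is the Fisher z transform
(`atanh`) of their Pearson correlation; each subject yields one symmetric
`n × n` matrix. Correlations are clipped to ±(1 − 10⁻⁷) before the transform
so perfectly correlated series stay finite. Self-connectivity is excluded:
the diagonal is fixed at 0 and never enters feature selection, so the
feature space is the `n(n−1)/2` unordered node pairs ("edges"). All modules
share one canonical edge order — the row-major upper triangle with `i < j` —
making selected-edge indices portable across folds, permutations and
lesions. The default parcellation has 142 cortical nodes in five
large-scale networks (DMN 34, FPN 21, CON 32, SMN 33, OccN 22; 10,011
edges); users can supply any atlas table with the same five labels.

**The CPM recipe.** Per cross-validation fold:

1. *Normalization.* Behavior and every edge are z-scored with the training
   mean and SD (`ddof = 1`); test data reuse the training normalizers. All
   downstream model units are these training z units.
2. *Edge selection.* Partial Spearman correlation between behavior and each
   edge, controlling age, sex (0/1, entered linearly), education years and
   mean framewise displacement: all variables are rank-transformed (average
   ranks for ties), the ranked behavior and ranked edge are residualized on
   the ranked covariates plus intercept by least squares, and the residuals
   are Pearson-correlated. The p-value uses the t approximation with
   `n − 2 − c` degrees of freedom, two-tailed. Edges with `p < α`
   (default α = .01) form the positive or negative network by the sign of
   the partial correlation; the two sets are disjoint by construction.
   Two-tailed screening with sign splitting is used because the
   positive/negative split presupposes both tails are eligible.
3. *Network strength.* Sum of the selected normalized edges, one strength
   per subject per tail.
4. *Linear model.* Ordinary least squares of normalized behavior on
   strength, fitted separately for the positive and the negative network,
   never combined. A fold whose tail selects no edges (or has constant
   strengths) predicts the training mean (0 in z units) and logs a warning
   rather than aborting, keeping the cross-validation totals intact.

**Cross-validation.** Leave-one-out (LOOCV) is the primary scheme, suited to
samples under ~200 subjects; repeated k-fold (default 10 folds × 100
repeats, seeded partitions with per-repeat randomness drawn from the master
seed) is the overfitting control. With `k = n` a k-fold repeat reduces to
LOOCV bit-exactly because both schemes share the identical per-fold code
path. Performance is the Spearman correlation `r` between predicted and
actual behavior (ranks of the raw behavior; the per-fold affine
normalization cannot change them for predictions, and the raw scale is the
natural reference for the actuals) and the mean squared error in normalized
units (each held-out subject's actual is z-scored with its own fold's
training parameters).

## Inference

**Permutation test.** The null of no brain–behavior mapping is simulated by
shuffling the subject labels of the behavioral rows against the fixed
connectomes and rerunning the *entire* cross-validation, selection
included. Two schemes are provided: the default shuffles the covariates
together with the behavior (preserving the behavior–covariate coupling,
which is part of the mapping being tested); the alternative shuffles the
behavioral score alone. Both target the same null when behavior is
exchangeable against the imaging data. P-values follow the plain ratio
definition — `p(r) = #(null r > observed r)/B`,
`p(MSE) = #(null MSE < observed MSE)/B` — which can return exactly 0; an
add-one rule `(count+1)/(B+1)` is available in the configuration. The
default B is 5000. When the configuration selects the repeated k-fold
scheme, the permuted statistic is the mean r (and mean MSE) across repeats,
matching how that control analysis is scored.

**Computational lesioning.** Each network's contribution is probed by
removing its nodes (and every incident edge) and rerunning the full LOOCV,
re-selection included. The lesioned model's `r` is compared against the
whole-brain `r` with a one-tailed Steiger z test for dependent overlapping
correlations (both share the actual-behavior variable): Fisher-transformed
correlations, the mean-correlation (`rbar`) form of the covariance term,
and the Spearman correlation between the two prediction vectors as the
between-predictions correlation, consistent with the rank-based assessment.
Benjamini–Hochberg FDR is applied across the lesioned networks. The
covariance term is clipped at 1 − 10⁻¹² because near-degenerate triples
(both correlations ≈ 1) can push its estimate past 1; the test is outside
its asymptotic comfort zone there anyway.

**Common-edge profiling.** Edges selected in *every* LOOCV iteration form
the common-edge set (defined for LOOCV only; k-fold folds are not a fixed
iteration set and are refused). Counts and proportions are reported per
network, per unordered network pair (15 labels for five networks — a
partition of the edge set), and per node (degree, ties broken by canonical
node index). A between-network common edge counts toward both endpoint
networks; accordingly the default per-network denominator is every possible
edge *incident* to the network, `C(s,2) + s(n−s)`. The within-network-only
reading (`C(s,2)` and within edges only) is available as `mode="within"` —
the incident reading is the package's default because it is the one
consistent with double-counting between-network edges, but the choice is a
genuine ambiguity and both are exposed.

## The behavioral games

Trust game: both players endowed 10 points (1 point = 3 CNY), transfer X ∈
0..10 tripled, return Y ∈ 0..3X; payoffs are `10 − X + Y` (trustor) and
`10 + 3X − Y` (trustee), so total points are `20 + 2X` for any feasible
play. The programmed trustee draws Y uniformly from the integers between
40% and 60% of the tripled transfer (bounds rounded half-even, since play
proceeds in whole points); enumerating every feasible (X, Y) gives the
trustor payment range 30–54 CNY. Dictator game: allocation X ∈ 0..20,
payoffs `20 − X` and `X`. The statistics layer provides the
subject-weighted meta-analytic mean transfer, a one-sample Wilcoxon
signed-rank test against a benchmark proportion (zero differences dropped,
average-rank ties, tie-corrected normal z without continuity correction;
exact enumeration of sign assignments for n ≤ 20), and a pairwise-complete
Spearman correlation screen with BH-FDR q-values. Trust propensity is
X/10 when compared with meta-analytic transfer proportions.

## Synthetic data

The generator emulates the study conditions end-to-end, because the kind of
subject-level data the pipeline targets is shared only on request and no
public fixture exists.

* **Cohort.** 101 subjects (the emulated study's 120 recruited minus
  13 + 4 + 2 exclusions), age ~ N(64.13, 6.39²) years, education ~
  N(11.17, 3.21²) years, P(female) = 0.69, head motion (mean framewise
  displacement) log-normal with median 0.12 mm — comfortably under the
  0.25 mm exclusion threshold, as an included cohort should be.
* **Behavior.** `X ~ Binomial(10, p)`, `logit(p) = a + b·u`, `u ~ N(0,1)`,
  with (a, b) = (−0.4422, 0.9427) solved by Gauss–Hermite quadrature so the
  population mean and SD are 4.08 and 2.41. The binomial-logit form
  reproduces the discrete, bounded, right-spread, non-normal score that
  motivates the rank-based statistics. A dictator-game score correlated
  ~0.28 with trust (mean 9.26, SD 2.37) accompanies it.
* **Connectomes.** Signal is injected on the Fisher-z edge scale directly
  (fast path): background edges are i.i.d. N(0, 0.3²) — 0.3 being a typical
  Fisher-z RSFC spread — and each of the 30 planted edges (default hosts:
  node pairs within DMN ∪ CON) is `β·z(X) + N(0, 0.3²)` with β set so the
  population edge–behavior correlation is 0.4. Planted edges therefore
  share a common behavior-locked factor, as real predictive-network edges
  do. A slower time-series mode (latent temporal factors plus AR(1) node
  noise) exercises the RSFC construction end-to-end.
* **Confounding (off by default).** Optional covariate coefficients enter
  the behavior logit, and the same covariate composite leaks into every
  edge, creating spurious edge–behavior associations that only the
  covariate-controlled screen removes — the regression test for the partial
  correlation.

What the generator does **not** emulate: spatial covariance structure of
real connectomes, physiological/motion artifacts, distance-dependent edge
correlations, site or session effects. Passing tests therefore demonstrate
the *statistical machinery* — selection, cross-validation hygiene,
calibration, localization — not performance on real fMRI.

## Numerical choices

* Training-subset edge ranks are computed exactly (average ties) by a
  drop-rows update of the full-sample ranks — dropping rows D changes the
  rank of v by `Σ_{d∈D} (1[v > v_d] + ½·1[v = v_d])` — so a LOOCV over
  10,011 edges and 101 subjects runs in well under a second.
* The batched permutation engine (behavior-only scheme) hoists every
  permutation-invariant quantity out of the per-fold loop and evaluates all
  permutations' edge screens as one matrix product, in single precision by
  default; it is tested to agree with a literal per-permutation rerun at
  double precision to 1e−8. Single precision perturbs a partial
  correlation by ~1e−6, which can flip an edge sitting that close to the
  selection threshold — immaterial next to Monte Carlo noise in B
  permutations.
* Zero-variance (constant) edges and vanished residuals are flagged
  non-selectable (`rho = 0, p = 1`) rather than erroring.
* Degenerate inputs: constant training behavior raises; a constant
  prediction vector has undefined rank correlation and is reported as
  `r = 0` with `r_defined=False`.
* Seeds: every stochastic component (generator, k-fold partitions,
  permutations, programmed returns) takes a seed or `numpy` Generator;
  per-repeat randomness is drawn sequentially from the master seed.

## Test-suite problem sizes

The simulation suites run at the emulated study scale — n = 101 subjects,
142 nodes, 10,011 edges. Null calibration uses 200 replicate datasets with
B = 99 behavior-shuffle permutations each (the granularity needed to score
rejection at α = .05); recovery and lesion localization use 50 replicates
of the default planted-signal condition; scheme consistency uses 20
repeats of tenfold CV. These sizes put the permutation-test rejection rate,
the null center of `r`, and the recovery rates within tight Monte Carlo
error of their targets while keeping the suite's total runtime modest.

## Known limitations

* The Steiger z comparison treats the estimated `r_between` as known; at
  |r| near 1 the test is unreliable (the implementation clips rather than
  fails, and flags degenerate |r| = 1 inputs with an error).
* The permutation fast path supports LOOCV only; the joint
  behavior+covariate scheme reruns folds directly and is correspondingly
  slower at production B = 5000.
* MSE is defined in normalized units; comparisons across datasets with very
  different behavior variances should rely on `r`.
* The edge screen is mass-univariate by design; no regularized or
  multivariate edge models, and no nested hyperparameter tuning.
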