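# Methods

This note documents the models `mixkin` implements, the conventions and
numerical choices behind them, and what the synthetic-data generators do and
do not emulate.

## Mixture response surfaces

**Region and coding.** The formulation space is a 3-component bounded
simplex: microgreen juice 5–9.5 %, dahi 60–64.5 %, water 15–19.5 %, with a
fixed combined total of 84.5 % (sugar and stabilizer are held constant
outside the mixture). All models are expressed in **L-pseudo-component
coding**, `a_i = (x_i − L_i)/(total − ΣL)`, which maps the region onto the
unit simplex. This is the only coding under which the packaged published
coefficient table reproduces the published optimum predictions (verified
for colour, flavour, flavonoid, ascorbic acid and phenol responses);
actual-percentage coding does not.

**Model.** Scheffé polynomials are intercept-free by construction (the
proportions sum to one, so a constant column would be collinear). The
special cubic degree — three linear, three two-way and one three-way term —
is the study's model for all 16 responses; linear and quadratic degrees are
available. Coefficients are estimated by ordinary least squares
(`numpy.linalg.lstsq` after an explicit rank check; a rank-deficient design
raises an error naming the collinear terms).

**Fit statistics.** The published table names its diagnostics without
formulas; `mixkin` uses the standard response-surface definitions, which
reproduce the printed magnitudes:

* `root_mse = sqrt(SSE/(n−p))`; the table's "Mean ± SD" column is the grand
  mean ± root MSE (consistent with its CV % column);
* `cv_percent = 100·root_mse/grand_mean` (an exact identity in the code);
* R² uses the **mean-corrected** total sum of squares — with no intercept
  the uncorrected form would be ≈ 1 trivially;
* predicted R² = 1 − PRESS/SStot with PRESS from the leave-one-out
  hat-matrix identity `e_i/(1−h_ii)`;
* adequate precision = (max ŷ − min ŷ over design points)/√(p·MSE/n);
* model F = (SSmodel/(p−1))/MSE on mean-corrected totals;
* replicated runs (the 17-run design has five replicated settings) give a
  pure-error/lack-of-fit F decomposition;
* a constant response reports R² = 0 with a warning rather than failing.

**D-optimal selection** uses a greedy build followed by Fedorov exchange on
det(XᵀX) over the Scheffé term matrix; det is non-decreasing across passes,
ties break toward the first candidate index, and an optional seed shuffles
the initial build. Reproducing any particular commercial software's
candidate set or run numbering is out of scope.

## Desirability optimization

Individual responses are scored with Derringer–Suich ramps (maximize,
minimize, two-sided target, in-range indicator; shape exponent `weight`),
combined as the importance-weighted geometric mean. The optimizer does a
coarse feasible grid sweep (default 0.5 % step in actual units) followed by
shrinking pairwise-exchange refinement inside the polytope — robust to the
flat zero regions the ramps create, where gradient methods stall. The
returned point always respects bounds and total to 1e-9, and its D is
never below any grid point's.

The study's own goal/weight table was never published, so the package ships
a documented default (maximize juice, minimize dahi and water,
responses in-range at their observed spans, importance 3) and treats the
study's printed overall desirability (0.781) as context, not a target.

## Degradation kinetics

Each quality index at each storage temperature is fitted on the
linearizing transform of the three classical rate laws: C vs t (zero
order), ln C vs t (first), 1/C vs t (second), by closed-form simple linear
regression. Conventions:

* Indices that **increase** during storage (acidity, FFA, TBA, microbial
  counts on the log₁₀ cfu scale) have the opposite slope sign; k is stored
  as a magnitude plus a direction flag, matching how rate tables print it.
* R² for orders 1 and 2 is computed on the transformed scale (the linear
  workflow being emulated); order selection takes the highest R², ties
  toward the lower order. On noiseless data the true order wins whenever
  the dynamic range is appreciable (verified down to C_max/C_min ≈ 1.5).
* χ² is the reduced residual form Σ(O−P)²/(n−p) on the concentration
  scale; Pearson's Σ(O−P)²/P is scale-fragile for near-zero TBA values.
* **Half-life** is the time for an index to change by half its day-0
  level: C₀/(2k), ln2/k, 1/(kC₀) by order. C₀ defaults to the *observed*
  day-0 value, not the fitted intercept — this reproduces the published
  half-lives for plate count, FFA and overall acceptability exactly; the
  published acidity/TBA half-lives are ~1–2 % below C₀/(2k) from the
  printed values (evidently computed from unrounded inputs) and are not
  used as checks.

## Temperature models

* **Arrhenius** is fitted in its reference-temperature form (ln k on
  1/T − 1/T_ref, T in kelvin, T_ref defaulting to the arithmetic mean of
  the input temperatures), giving Ea = −slope·R and k_ref = exp(intercept).
* **Eyring**: ln(k/T) on 1/T; k is converted from per-day to per-second
  before the ln(k_B/h) = 23.76 intercept decomposition — ΔH is
  unit-invariant, ΔS is not, and the unit choice is recorded in the
  results object. Over the narrow 5–25 °C window ΔH ≈ Ea − R·T̄ to within
  1 %.
* **Ball**: log₁₀D on (T − T_ref) in °C (the model is defined on
  temperature differences), Z = −1/slope, D_ref = 10^intercept,
  D = ln10/k.

Applied to the packaged published rate constants, the activation energies
span ≈ 11.5–21.0 kJ/mol with overall acceptability the largest — matching
the study's narrated 10.251–20.622 kJ/mol band and ordering (exact printed
values were computed from unrounded rate constants that are unavailable) —
and every Eyring entropy is negative. The study's printed Z values
(0.114–0.230 °C) are inconsistent with the Ball definition applied to its
own rate constants, which imply Z in the tens of degrees (they appear to be
a different quantity, possibly the slope −1/Z); `mixkin` implements the
definition and does not test the printed values.

## Shelf life

Shelf life combines the selected order with the Arrhenius model: k is
extrapolated to the storage temperature and the rate law inverted either to
the half-change time or to a caller limit (the log₁₀ 10⁶ cfu/mL ready-to-eat
microbial guideline is provided as a named constant). The headline
convention is the half-change time of the limiting (shortest-lived) index,
which for this product is the total plate count: 3.07/(2·0.1646) = 9.33
days at 5 °C. Stability reports are deterministic: stable ordering and
fixed rounding (k 4 dp, R² 3 dp, t₁/₂ 2 dp), so regeneration is
byte-identical.

## Synthetic data and what passing tests show

`StorageSimConfig` generates exact rate-law trajectories with
Arrhenius-controlled k across temperatures on the study grid (days 0–15
every 3; 5/15/25 °C; 3 replicates), adding i.i.d. Gaussian noise on the
concentration scale — the real data's per-day SDs are roughly constant
(0.00–0.04), not proportional, which motivates the additive default; a
lognormal option covers multiplicative error. Microbial counts are
simulated directly on the log₁₀ cfu scale, as they are reported and fitted.
Defaults mimic the plate-count index (C₀ = 3.07, k_ref = 0.2011/day at
15 °C, Ea = 16 kJ/mol). `MixtureSimConfig` generates responses from a known
Scheffé polynomial on the packaged 17-run design.

The generators deliberately do **not** emulate: replicate-level variance
structure, correlated noise across indices, mechanistic microbial growth
(lag/stationary phases), or day-to-day batch effects. Passing recovery
tests therefore demonstrate the estimators' correctness and calibration
under the stated error model, not robustness to those real-data features.

Calibration figures (seeded Monte-Carlo, recomputed by the acceptance
script): order selection is ≥ 95 % correct at noise equal to 1 % of the
15-day range (200 simulations); Ea recovery from rates with 5 % lognormal
noise at three temperatures has median relative error below 10 % (500
simulations) when the true Ea is at the upper end of the study's range.
That experiment uses the study's headline activation energy
(20.622 kJ/mol, overall acceptability, its most temperature-sensitive
index) as truth; note that the *absolute* Ea error under fixed rate noise
is independent of Ea (≈ 2.4 kJ/mol SD for this design), so the relative
error necessarily exceeds 10 % for indices at the low end (≈ 10–16 kJ/mol)
of the range — a property of the three-temperature design, not of the
estimator.

## Degenerate inputs and tie-breaks

Bounds violations name the offending component; series shorter than three
points, single-temperature rate sets and rank-deficient designs raise
typed errors; non-positive concentrations make log/reciprocal transforms
inapplicable — such orders are flagged and skipped in selection, not
silently dropped. k = 0 signals an infinite half-life explicitly; a flat
Ball line signals infinite Z. Order-selection ties go to the lower order;
D-optimal exchange ties to the first candidate index.

## Data-entry notes on the packaged fixtures

Two design runs are published rounded to 2 dp in a way that violates the
fixed 84.5 % total by 0.01; the fixtures store the evident unrounded values
(…​.875) so the total invariant holds exactly. The rate table's middle
temperature is encoded as 15 °C per the methods text (the table prints
"10"). One garbled adjusted-R² entry is stored as missing, and the
observed ascorbic-acid value at the optimum is stored as printed despite an
internal inconsistency in the source; all such cases are recorded in the
fixture metadata (`datasets/data/metadata.yaml`) and none is used as a
test surface.
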