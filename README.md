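# mixkin

Constrained mixture-design response surfaces, desirability optimization and
degradation-kinetics shelf-life modelling for food quality data.

`mixkin` re-implements, as a tested reusable library, the two-stage analysis
behind a microgreens-enriched fermented dairy (lassi) beverage study:

1. **Formulation.** A 3-component mixture (microgreen juice, dahi, water)
   with a fixed total of 84.5 % and per-component bounds is mapped onto the
   unit simplex by L-pseudo-component coding, `a_i = (x_i - L_i)/(T - ΣL)`,
   and each of 16 sensory/physicochemical/antioxidant responses is modelled
   with an intercept-free Scheffé **special cubic** polynomial

   `y = β_A a + β_B b + β_C c + β_AB ab + β_AC ac + β_BC bc + β_ABC abc`,

   fitted by least squares with the standard response-surface diagnostics
   (R², adjusted/predicted R² via PRESS, CV %, adequate precision,
   lack-of-fit). D-optimal run selection (Fedorov exchange) and
   Derringer–Suich desirability optimization over the constrained simplex
   complete the formulation stage.

2. **Stability.** Quality indices measured over 15 days at 5/15/25 °C are
   fitted by zero-, first- and second-order rate laws on their linearizing
   transforms; the temperature dependence of the rate constant k is
   modelled with the Arrhenius (`ln k = ln k_ref − (Ea/R)(1/T − 1/T_ref)`),
   Eyring (`ln(k/T) = −ΔH/RT + ln(k_B/h) + ΔS/R`) and Ball
   (`log₁₀(D/D_ref) = −(T − T_ref)/Z`, `D = ln10/k`) models, and shelf life
   is predicted as the half-change time `t₁/₂ = C₀/(2k)` (zero order) or
   the time to reach a limit such as the log₁₀ 10⁶ cfu/mL microbial
   guideline.

The study's own data tables (17-run design, published coefficient table,
storage trajectories, rate constants, optimum formulation) ship as packaged
fixtures under `mixkin.datasets`, and `mixkin.simulate` generates synthetic
studies with known ground truth for parameter-recovery experiments.

## Worked example

```python
import mixkin
from mixkin.datasets import load_fixtures, lassi_spec, optimum_amounts

fx = load_fixtures()
spec = lassi_spec()

# 1. refit the total-flavonoid response surface from the 17-run design
res = mixkin.ScheffeMixture(fx.design, "total_flavonoid").fit()
print(res.summary())

# 2. evaluate the published model at the optimum formulation
pseudo = mixkin.to_pseudo([9.189, 60.0, 15.311], spec)
print(mixkin.predict_response(fx.scheffe_models["total_flavonoid"], pseudo))
# 22.48873...  (published prediction: 22.489 mg QUE/100 g)

# 3. storage kinetics and shelf life
tba_5c = next(s for s in fx.storage
              if s.index_name == "tba" and s.temperature == 5)
fit = mixkin.fit_order(tba_5c, 0)
print(round(fit.k, 4))                      # 0.0016 per day
print(round(mixkin.half_life(3.07, 0.1646, 0), 2))   # 9.33 days
```

The refit summary reports `R2 0.9957`, `grand mean 15.3941`, `root MSE
0.3171` — the published table prints R² 0.9960 and 15.38 ± 0.30 for this
response. The 9.33 days is the headline refrigerated shelf life: the
half-change time of the total plate count (day-0 level 3.07 log cfu/mL,
k = 0.1646 log cfu/mL per day at 5 °C).

A thin CLI wraps the same calls:

```sh
mixkin fit-kinetics --storage storage.csv
mixkin shelf-life --storage storage.csv --criterion half_change --temperature 5
mixkin reproduce-paper    # full fixture pipeline, computed vs printed values
```

## Scope notes

The study's published overall-desirability score (0.781) depends on a goal
table that was never published, and its printed Ball Z-values are
inconsistent with the Ball model's own definition applied to the published
rate constants; `mixkin` implements both APIs faithfully but does not treat
those two printed numbers as reproduction targets. See `docs/methods.md`.
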