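# metaripe

Prediction of postharvest ripening time for mature-green tomatoes from
storage period and storage temperature, using the kinetics of pericarp
colour (CIE a*).

Tomatoes harvested at the mature-green stage ripen *metachronously*: fruits
held under identical conditions start developing red colour at different
times. `metaripe` models the red phase of each fruit's CIE a* trajectory
(negative a* = green, positive = red) with a modified sigmoid of the storage
period *x* (days since harvest),

```
a*(x) = α / (1 + e^(βx)) + γ          α > 0, β < 0, γ < 0, α + γ > 0
```

whose upper asymptote α + γ is the fully-ripe colour plateau (observed near
a\* = 24–26). Because breaker — the first visible colour break — is defined
as a\* = 0, inverting the model gives the **time lag** to the onset of red
colour development in closed form:

```
lag = ln[(α + γ) / (−γ)] / β    (days)
```

The package fits the model per fruit (bounded trust-region nonlinear least
squares on the a\* > 0 part of the trajectory), averages parameters into
*universal* cultivar × temperature curves, relates lag to storage
temperature with a cubic polynomial valid on 12–30 °C, and composes curve +
lag into full-range ripening patterns and storage-period tables for the
USDA visual stages (breaker, turning, pink, light red, red). A seeded
synthetic-cohort generator reproduces the statistical structure of a
storage trial (initial a\* in [−6, −5], temperature-dependent lag,
per-fruit onset jitter, daily sampling, measurement noise) so the whole
pipeline is testable without measured data. Average parameter sets for
three reference cultivars (Miracle, Rei-getsu, Momotaro York) at 12, 15,
20, 25 and 30 °C ship with the package.

Intended users: postharvest physiologists and supply-chain engineers who
need to predict when fruit stored at a known constant temperature reaches a
given ripening stage.

## Worked example

Simulate a five-fruit Miracle cohort stored at 15 °C, fit each fruit,
average into a universal curve, and predict the storage period to breaker:

```python
import metaripe as mr

profiles = mr.default_profiles()
cohort = mr.simulate_cohort(profiles["Miracle"], temperature_C=15, n_fruits=5, seed=1)
result = mr.fit_cohort(cohort)
universal = result.universal_curves[0]
fitted_lag = mr.time_lag(universal.params).lag_days
true_lag = mr.time_lag(profiles["Miracle"].params_by_temp[15.0]).lag_days
print(f"fitted universal lag: {fitted_lag:.2f} d (generating value {true_lag:.2f} d)")
for f in result.fits:
    print(f"  {f.fruit_id}: R2={f.gof.r2:.3f} RMSE={f.gof.rmse:.2f} %RMSE={f.gof.pct_rmse:.2f}")
pattern = mr.build_pattern(universal)
print("whole-day storage to breaker:", mr.days_to_stage(pattern, 0.0))
print("equilibrium a* of the universal curve:", f"{universal.params.equilibrium:.1f}")
```

prints

```
fitted universal lag: 12.23 d (generating value 12.50 d)
  Miracle-15C-00: R2=0.997 RMSE=0.41 %RMSE=0.31
  Miracle-15C-01: R2=0.997 RMSE=0.41 %RMSE=0.32
  Miracle-15C-02: R2=0.997 RMSE=0.42 %RMSE=0.31
  Miracle-15C-03: R2=0.995 RMSE=0.55 %RMSE=0.40
  Miracle-15C-04: R2=0.997 RMSE=0.40 %RMSE=0.31
whole-day storage to breaker: 12
equilibrium a* of the universal curve: 30.3
```

The fitted lag lands within a fraction of a day of the generating value
(individual onsets jitter with sd 1 day, so a five-fruit average moves
around it); per-fruit R² sits near 0.997 at the default measurement noise
of 0.5 a\* units. The curve predicts breaker after 12 whole days at 15 °C
and a fully-ripe plateau of a\* ≈ 30.

The same pipeline is available from a shell:

```sh
metaripe simulate --cultivar Miracle --temp 15 --n 5 --seed 1 --out cohort.csv
metaripe fit --input cohort.csv --out fits.json
metaripe predict --params builtin --stages breaker --out breaker.csv
metaripe predict --cultivar Miracle --temp 17        # cubic-interpolated lag
metaripe report                                      # lags, plateaus, stage table
```

`predict --temp 17` reports `Miracle at 17 degC: lag 9.03 days
(interpolated)` — the cubic lag-temperature model evaluated between the
experimental temperatures.

Stage thresholds beyond breaker are configurable (`--stages
"breaker=0,turning=5,pink=10"`); the shipped defaults for
turning/pink/light-red/red are illustrative a\* cut-offs, since the USDA
defines those stages by percentage of red surface rather than by a
chromaticity value.

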