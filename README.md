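# locoeff

Residual-based neuromuscular-readiness analysis for athlete GPS load
monitoring.

Team-sport staff track external load (distances, speed bands,
acceleration counts, accelerometer PlayerLoad) every session and face a
weekly decision: load or unload? `locoeff` implements a residual-based
readiness marker and the analysis chain around it, for sports
scientists and analysts working with session-level monitoring exports.

## The method

1. **Locomotor Efficiency Index (LEI).** A regression model (default:
   a 200-tree random forest, predictions strictly out-of-fold)
   predicts PlayerLoad from seven locomotor features. The residual
   ΔPL = PL̂ − PL is z-scored within each player over the whole
   window:

       LEI = (ΔPL − μ_player) / σ_player

   Positive LEI → the locomotor output cost less body load than
   expected (efficient, recovered); negative → it cost more
   (fatigued). Double sessions are averaged per day.

2. **Weekly scenario grid.** Weekly readiness = mean daily LEI, binned
   at ±0.5 into bad/normal/good. Week-to-week fluctuation of each
   weekly load sum (total distance, distance > 25.2 km/h, mechanical
   load = acc > 3.5 m/s² + dec < −3.5 m/s²) is the percentage change
   (w+1 vs w), binned at ±10%/±30% into five categories.

3. **Mixed-model contrasts.** Within each readiness subset and load
   metric, the signed week-to-week LEI change is regressed on the
   fluctuation categories (reference: *no variation*) with a
   per-player random intercept (REML, Wald inference, outcome
   z-scored → standardized β).

4. **Squad simulator.** A generator with latent per-player fatigue
   following an impulse-response recurrence
   `F(t) = F(t−1)·exp(−1/τ_f) + k_f·impulse(t)` that inflates
   PlayerLoad multiplicatively — known ground truth for validating
   every stage. See `docs/methods.md`.

## Worked example

```python
import locoeff

cfg = locoeff.SimConfig(n_players=40, n_weeks=30, seed=1)
sessions, truth = locoeff.simulate_squad(cfg)
result = locoeff.run_pipeline(sessions, locoeff.PipelineConfig(seed=1))

c = result.coefficients
print(c[(c.metric == "total_distance") & (c.readiness == "bad")])
```

prints (one season-and-a-bit of a 40-player squad, 7388 sessions →
1200 player-weeks → 1158 transitions):

```
readiness          category   beta  ci_low  ci_high  p_value  n
      bad    large_decrease  0.814   0.421    1.207    0.000 45
      bad moderate_decrease  0.207  -0.250    0.665    0.375 63
      bad      no_variation  0.000     NaN      NaN      NaN 45
      bad moderate_increase -0.291  -0.994    0.412    0.417  9
      bad    large_increase  0.176  -0.657    1.010    0.679  7
```

Reading: for player-weeks in **bad** readiness, cutting next week's
total distance by more than 30% raises the following week's LEI by
0.81 standardized units relative to holding the load constant
(p < 0.001) — an unloading prescription the fatigued simulated squad
genuinely benefits from, since its ground-truth fatigue state decays
when the impulse drops. The same pipeline run shows the mirror effect
in normal readiness: a large load increase depresses next week's LEI.

The same chain is available from the shell:

```bash
locoeff simulate --seed 1 --out-dir out
locoeff run --sessions out/sessions.csv --seed 1 --out-dir out
locoeff recover --n-replicates 5 --seed 1 --out-dir out   # recovery harness
```

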