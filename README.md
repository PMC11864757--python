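# epnpop

Population-coding analysis of basal-ganglia output recordings — the
entopeduncular nucleus (EPN), rodent homolog of the primate GPi — in a
freely moving two-alternative forced-choice (2AFC) task.

Mice shuttle across a triangular arena between a waiting corner and two
reward-port corners.  After a 0.8–1.3 s wait, a 0.5 s frequency-modulated
sweep (delta-frequency ∈ {0, ±0.4, ±0.6, ±0.8} octaves) cues a left or
right choice; the animal performs a 150° turn and walks to a port, where
reward is evaluated while it licks.  The package implements the full
analysis chain for such sessions — and a synthetic-session generator with
known ground-truth tuning, so every stage can be validated by parameter
recovery.

## What it computes

* **Session model** (`session_io`) — pose-tracking table, per-unit spike
  trains, trial/event table, lick events; plain-CSV on-disk format with a
  JSON manifest; full invariant validation.
* **Synthetic sessions** (`synthetic_session`) — behavior (psychometric
  choices, difficulty-dependent response times, false alarms, gait and lick
  rhythms) and inhomogeneous-Poisson spikes with the log-link rate

  `rate(t) = exp(b₀ + Σ β·z(x(t)) + reward kernel + κ·cos(φ(t) − μ))`

  with per-context (Return vs Go) kinematic/spatio-temporal coefficients,
  reward-positive/negative responses, and von-Mises phase coupling.
* **Kinematics & events** (`kinematics_events`) — body/head speed, angular
  velocity from the body axis, distances to the waiting corner and goal;
  detection of return start, wait arrival, turn start/mid/end (0°/75°/150°
  of cumulative turn) and port entry; psychometric fits, response-time
  statistics, P(correct) by response-time bin.
* **PETHs** (`peth`) — Gaussian-kernel rates (σ = 25 ms), piecewise-linear
  time-rescaling of each trial onto the mean segment durations, and the
  pseudo-simultaneous condition tensor N×S×D×C×T (units × side × difficulty
  × outcome × time) with the ≥2-trials-per-condition inclusion rule.
* **Population geometry** (`population_geometry`) — instantaneous marginal
  variance Varₘ(t) = (1/N)·Σᵢ Σₘ (rᵢ(t,m) − r̄ᵢ(t))², cosine self-similarity
  CS(t₁,t₂) = ⟨r_t₁, r_t₂⟩/(‖r_t₁‖‖r_t₂‖), PCA with per-unit time-shuffle
  significance, demixed PCA (marginalize → per-part PCA → project), and
  kinematically matched trajectory selection (r ≥ 0.75).
* **Encoding models** (`encoding_models`) — LASSO regressions in 0.2 s
  windows (every 50 ms) with 10-fold cvR², family comparisons, cross-context
  transfer, partial correlations, ΔR², and reward auROC classification.
* **Rhythmic coupling** (`rhythmic_coupling`) — stride extraction from the
  contralateral hindpaw, Hilbert phase in the gait (3–6 Hz) and lick
  (4–10 Hz) bands, spike-phase resultant vectors with Rayleigh tests,
  lick-rate correlations.
* **Population decoding** (`population_decoding`) — linear SVCs with
  grouped 10-fold CV, label-permutation nulls, 5-state quantile
  discretization of continuous variables, and eigenvector-weighted matrices
  for signals in low-variance modes.

Fit-shaped analyses are scikit-learn-style estimators (`DemixedPCA`,
`ConditionPCA`, `LassoEncoder`, `PopulationDecoder`, `PsychometricModel`)
with `fit`/`transform`/`score`, `get_params`, and trailing-underscore fitted
attributes; module-level functions wrap them.

## Worked example

```python
from epnpop import GeneratorConfig, generate_session, AnalysisConfig
from epnpop.kinematics_events import compute_kinematics, detect_events, fit_psychometric
from epnpop.peth import build_peth_tensor, zscore_tensor
from epnpop.population_geometry import dpca

cfg = GeneratorConfig(n_trials=220, n_units=6, seed=11)
bundle, truth = generate_session(cfg)

kin = compute_kinematics(bundle.tracking, bundle.trials, arena_side=cfg.arena_side)
events, flagged = detect_events(kin, bundle.trials, bundle.licks, AnalysisConfig())
slope, bias, lapse, _ = fit_psychometric(
    [t for t in bundle.trials if t.outcome != "false_alarm"])
print(f"psychometric slope {slope:.2f}  bias {bias:+.3f}  flagged trials {len(flagged)}")

tensor = zscore_tensor(build_peth_tensor([(bundle, events)], AnalysisConfig()))
res = dpca(tensor)
for name, k, etv in res.ranking()[:3]:
    print(f"top demixed component: {name}[{k}]  ETV {100 * etv:.1f}%")
```

prints (seed 11):

```
psychometric slope 2.49  bias +0.137  flagged trials 0
top demixed component: time[0]  ETV 11.2%
top demixed component: outcome[0]  ETV 6.0%
top demixed component: time[1]  ETV 4.6%
```

The recovered psychometric slope matches the configured 2.5 per octave, and
every trial's events were detected.  The leading demixed components are
condition-independent temporal dynamics followed by an outcome (reward)
component — the structure the generator plants (shared movement-driven
modulation, reward responses in 60% of units, no difficulty tuning).

The same chain runs from a shell:

```bash
epnpop simulate --out session0 --seed 7 --trials 220 --units 30
epnpop validate session0
epnpop run session0 --stage all          # writes session0/results/
```

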