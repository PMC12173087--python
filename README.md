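# crowdtrack

Continuous-psychophysics measurement of visual crowding: paradigm
simulation, synthetic tracking observers, and the complete spatiotemporal
analysis chain.

## The problem

Visual crowding is the difficulty of recognizing a peripheral target when
clutter surrounds it; its spatial signature is the *critical spacing* (the
target–flanker distance below which perception degrades, ≈ 0.5 × the
target's eccentricity by Bouma's rule). Classical trial-based paradigms
measure the spatial extent of crowding but are slow and say nothing about
its temporal dynamics. In the continuous-tracking alternative, the observer
continuously matches the orientation of a rotating Landolt-C target
(eccentric, optionally surrounded by a ring-shaped flanker whose distance
sweeps over time) with a reference stimulus, yielding a dense report-error
time series. Sudden "jumps" of the target orientation probe how quickly
tracking recovers from a disruption.

`crowdtrack` is for psychophysicists who want to simulate, analyze, or
power-test this paradigm. It provides:

* **paradigm** — stimulus trajectories for the continuous paradigm
  (144 Hz, 40 s trials, 72 °/s rotation, a 0.13 °/s target–flanker distance
  sweep over [0, 5]°, orientation jumps at preselected distances) and the
  trial-based control (7 distances + isolated, 25 repetitions each);
* **observer** — a generative tracking observer with motor latency,
  pursuit lag, hinged distance-dependent report noise (the hinge is the
  observer's true crowding extent *e_c*), and condition-specific
  exponential post-jump recovery;
* **preprocessing** — wrapped report errors in [−180°, 180°),
  threshold-based artifact cleaning keyed to the isolated condition,
  flip-and-average over distance sweeps, post-jump window extraction;
* **metrics** — the headline estimators (notation below);
* **group_stats** — paired *t*-tests, 2×2 within-subject ANOVA with
  partial η², Pearson correlation;
* a CLI: `crowdtrack simulate | analyze | recover`.

## Estimators

* Tracking performance = cosine similarity
  `Σᵢ[cos θs,i cos θr,i + sin θs,i sin θr,i] / (‖(cos θs, sin θs)‖·‖(cos θr, sin θr)‖)`
  = mean cos(report error); 1 is perfect tracking.
* Continuous crowding extent: intersection of the flanked and isolated
  regression lines of absolute report error on target–flanker distance
  (optionally iterated so the flanked line is refit below the current
  estimate — consistent when the hinge lies inside the tested range).
* Trial-based crowding extent: Von Mises MLE per distance gives the
  perceptual error σ = √(−2 ln R̄); a hinged-line analysis intersects the
  flanked σ(d) regression line with the isolated baseline.
* Recovery: E(t) = a·e^(−bt) + c fit to the mean absolute error in the
  300-sample (~2080 ms) post-jump window, with and without dropping the
  first 40 samples (~280 ms motor latency); *b* is the recovery rate, *c*
  the stable baseline. Recovery *time* is the first post-jump sample whose
  errors are statistically indistinguishable (Welch *t*, α = 0.05) from the
  last-50-sample baseline pool.

## Worked example

```python
import numpy as np
from crowdtrack.paradigm import ParadigmConfig
from crowdtrack.observer import ObserverConfig, generate_dataset
from crowdtrack.pipeline import analyze_participant

config = ParadigmConfig()          # 144 Hz, 40 s trials, 72 deg/s rotation
observer = ObserverConfig(seed=5)  # crowding extent 5 deg, baseline noise 10 deg
dataset = generate_dataset(config, [observer], n_runs=2, seed=11)
results = analyze_participant(dataset.participants[0], config)

print("tracking performance:",
      {c: round(v["mean"], 3) for c, v in results["tracking_performance"].items()})
print("crowding extent (deg):",
      {k: round(v, 2) for k, v in results["crowding_extent"].items()})
for cond in ("isolated", "flanked"):
    fit = results["decay"][cond]["pooled"]["corrected"]
    print(f"{cond} recovery: b = {fit['b_per_s']:.2f}/s, baseline c = {fit['c_deg']:.1f} deg")
print("recovery time (ms):",
      {c: round(v) for c, v in results["recovery_time_ms"].items()})
```

prints

```
tracking performance: {'isolated': 0.983, 'flanked': 0.85}
crowding extent (deg): {'continuous_run1': 5.0, 'continuous_run2': 5.0, 'continuous_mean': 5.0, 'trial_based': 5.0}
isolated recovery: b = 3.30/s, baseline c = 7.5 deg
flanked recovery: b = 2.76/s, baseline c = 29.8 deg
recovery time (ms): {'isolated': 965, 'flanked': 694}
```

Reading the output: flankers lower the tracking performance (0.85 vs 0.98);
both paradigms recover the observer's generative crowding extent of 5°;
post-jump recovery is slower (smaller *b*) and stabilizes at a higher
baseline error (*c*) when the target is flanked — the temporal signature of
crowding. Because the flanked baseline is already high, the error returns
to it sooner (694 ms vs 965 ms) even though the decay itself is slower.

The same pipeline runs from the shell:

```bash
crowdtrack simulate --out data/ --seed 1          # 8 observers x 2 runs + trial-based
crowdtrack analyze  --data data/ --out results/   # per-participant + group JSON
crowdtrack recover  --grid 2,3.5,5 --out rec/     # parameter-recovery table
```

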