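# airbreath

Analysis pipeline for **social air-breathing in bimodally breathing
fish**: bimodal intermittent-flow respirometry, behavioural event-stream
synchrony, and mixed-model repeatability — with a ground-truth simulator
of the whole study design so every stage is testable end to end.

## The problem

Air-breathing fish (e.g. the African sharptooth catfish *Clarias
gariepinus*) supplement gill respiration by gulping air at the surface,
which is risky: a surfacing fish becomes visible to predators. In groups,
fish often surface in temporal clusters ("synchronous air-breathing").
Disentangling what drives group surfacing — individual oxygen demand,
aquatic hypoxia, or social interactions such as aggression — requires
joining three kinds of data for the same individuals:

1. **Bimodal respirometry.** Each fish sits in a sealed chamber with a
   water phase and an air phase. In every 15-min cycle the chamber is
   closed for 10 min and the O₂ decline in both phases is recorded, then
   flushed for 5 min. From each closed phase we compute oxygen uptake
   from air (ṀO₂,air, via the ideal-gas law from the kPa decline in the
   air space) and water (ṀO₂,water, via O₂ solubility from the %-air-
   saturation decline), in mmol O₂ kg⁻¹ hr⁻¹. Their sum per cycle is the
   routine metabolic rate (RMR); the **standard metabolic rate (SMR)**
   is the q-th quantile (q = 0.12) of the RMR series over 68 cycles, and
   **%ṀO₂,air** is the percentage of total uptake taken from air.
2. **Behavioural trials.** Groups of four fish are observed for 15 min
   at each of five aquatic oxygen levels (100 → 20% air saturation) and
   a recovery period, with every breath, attack, push and avoid coded.
   Synchrony is the **coefficient of dispersion (CD)** — the
   variance/mean ratio of event counts in 30-s bins (CD > 1 means
   clumped). Trigger attribution asks what fraction of breaths follow,
   within 5 s, a breath by another fish or an agonistic interaction
   involving the breather.
3. **Mixed models.** Traits measured repeatedly per fish (breaths,
   attacks, activity) are analysed with Gaussian LMEs with fish ID
   nested in group as random intercepts, backward elimination of fixed
   effects (drop smallest |t| unless the LRT objects), Nakagawa–
   Schielzeth marginal/conditional R², and **adjusted repeatability**
   R = σ²_id / (σ²_id + σ²_group + σ²_residual) with parametric-
   bootstrap CIs.

The `simulate` module generates optode logs and event streams with
known truth (true SMR, trigger probabilities, variance components),
replicating the 11-groups × 4-fish design, so recovery of every quantity
is checked quantitatively.

## Worked example

```python
import numpy as np
from airbreath import simulate as sim, respirometry as resp, ethogram as eth

cfg = sim.SimConfig(seed=1)

# forward-simulate one fish's chamber (true SMR 2.5, 35% aerial uptake)
rng = np.random.default_rng(0)
log = sim.simulate_fish_trace(cfg, "f1", smr=2.5, pct_air_true=35.0,
                              mass=0.064, rng=rng)
trace = resp.OptodeTrace("f1", log[["time_s", "phase", "value"]])
prof = resp.analyze_chamber(trace, resp.RespirometerGeometry(fish_mass=0.064))
print(f"SMR {prof.smr:.3f} mmol/kg/hr, %MO2air {prof.pct_air:.1f}, "
      f"RMR {prof.rmr:.3f} over {prof.n_cycles} cycles")

# one group trial with follower-triggered breathing
truth = sim.draw_fish_truth(cfg, np.random.default_rng(2))
trial = sim.simulate_group_trial(cfg, "g01", 20, np.random.default_rng(3), truth)
cd = eth.coefficient_of_dispersion([e.time for e in trial.of("breath")])
frac = eth.proximity_fraction(trial, "any_interaction")
print(f"breath CD {cd.cd:.2f} over {cd.n_bins} bins; "
      f"{100 * frac.fraction:.1f}% of {frac.n_breaths} breaths followed "
      f"an agonistic interaction within 5 s")
```

prints

```
SMR 2.543 mmol/kg/hr, %MO2air 35.0, RMR 3.311 over 68 cycles
breath CD 1.89 over 30 bins; 31.0% of 29 breaths followed an agonistic interaction within 5 s
```

The recovered SMR sits within 2% of the built-in 2.5 despite sensor
noise and the activity surcharge; the CD above 1 and the high
interaction-proximity fraction reflect the aggression-triggered
surfacing built into the generator.

The full replica — simulation, respirometry reduction, behavioural
tables, random-structure comparison, backward elimination, repeatability
— runs from the command line:

```bash
airbreath replicate --seed 1 --outdir out/
```

and writes tidy CSVs (`fish_traits`, `synchrony`, `proximity`,
`coefficients`, `repeatability`, …) plus a manifest with the config
hash and every analysis convention in effect. `airbreath dryad` runs
the same analysis on externally deposited tables through a column-
mapping layer.

## Layout

- `src/airbreath/respirometry.py` — trace segmentation, slope fits,
  ṀO₂ conversions, quantile SMR, %ṀO₂,air, N₂-bolus calibration
- `src/airbreath/ethogram.py` — event streams, tallies, CD, proximity
  attribution, dominance
- `src/airbreath/mixed_stats.py` — LMEs (statsmodels MixedLM), random-
  structure comparison, backward elimination, R², repeatability
- `src/airbreath/simulate.py` — ground-truth study generator
- `src/airbreath/pipeline.py`, `cli.py` — orchestration and the
  `airbreath` command
- `docs/methods.md` — modelling assumptions, parameter defaults and
  numerical conventions
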