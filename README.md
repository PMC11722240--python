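# notchdyn

Analysis pipeline for how gut injury accelerates Notch-driven stem-cell
differentiation in the adult *Drosophila* midgut. Fly gut progenitors decide
between stem and enteroblast fate through Notch–Delta lateral inhibition:
Delta on one cell activates Notch on its neighbor, and activated Notch
represses that cell's own Delta, so small asymmetries resolve into opposing
high-Notch/low-Delta (enteroblast) and low-Notch/high-Delta (stem) states.
This package implements the three computational arms of that analysis:

1. **Circuit model** (`notchdyn.circuit`) — the dimensionless two/three-cell
   lateral-inhibition ODE system

   ```
   dN_i/dt = D̄_i^r / (K_N^r + D̄_i^r) − N_i
   dD_i/dt = v · ( 1 / (1 + (N_i/K_D)^h) − D_i )        (v = 1, r = h = 2)
   ```

   with a downstream reporter `R_i = β ∫ N_i dt`, scalar metrics
   (steady-state Delta of the high-Notch cell at t=10; signaling speed =
   mean reporter accumulation over t=4–10), and (K_N, K_D) phase maps.
   Elevated K_D — weakened Delta repression, the injury state — produces
   high-Notch cells that keep high Delta and signal roughly twice as fast.

2. **Intensity classification** (`notchdyn.intensity`) — two-component
   Gaussian mixtures fitted to log10 single-cell Notch-reporter (NRE-GFP)
   intensities, the equal-posterior decision boundary separating NRE^low
   from NRE^hi cells, posterior classification, marker cross-tabs
   (Delta+, PH3+), log-scale histograms, and two-sample K-S comparison.

3. **Trace kinetics** (`notchdyn.tracks`) — the live dual-fluorophore timer
   (fast dGFP / slow RFP) pipeline: per-movie 0–1 normalization, robust
   5-point local-linear ('rlowess') smoothing, QC exclusions, splitting each
   track at its smoothed maximum, least-squares slopes per segment, phase
   patterns (up_only / down_only / up_down), and per-condition rate
   summaries with a rapid-signaling threshold of 0.025 per frame.

`notchdyn.synth` generates every input with known ground truth: bimodal
marker-correlated intensity populations, and timer traces produced by pushing
a promoter-activity profile through the two-compartment maturation/decay
model (dGFP maturation ~0.1 h, half-life ~2 h; RFP ~1.5 h / ~20 h) sampled
every 7.5 min over 20.5 h. `notchdyn.io` / `notchdyn.cli` provide the CSV
interchange formats and a `notchdyn` command-line tool.

## Worked example

```bash
python analysis/01_simulate_circuit.py
```

prints

```
point1_low_kd:  high-Notch cell N(10)=0.339, D(10)=0.353, steady_state_delta=0.353, signaling_speed=0.336
point2_high_kd: high-Notch cell N(10)=0.660, D(10)=0.697, steady_state_delta=0.697, signaling_speed=0.662
point1 at t=40: N=[0.031 0.795], D=[0.984 0.09] (bistability resolves only well after the t=10 phase-map window)
```

At the healthy-like point (K_N=0.5, K_D=0.25) the eventual outcome is the
classic lateral-inhibition split (one cell at N≈0.80/D≈0.09, its partner at
N≈0.03/D≈0.98), while at the injury-like point (K_D=1) the high-Notch cell
keeps Delta at 0.70 and the reporter accumulates twice as fast (0.66 vs 0.34
per unit time) — the model's account of faster differentiation after injury.
Similarly,

```bash
python analysis/03_classify_intensities.py
python analysis/04_trace_kinetics.py
```

fit the condition-wise mixtures (recovered high-mode weights 0.300 healthy /
0.503 injured; boundaries near 10^1.77), report that Delta+ cells shift from
4% NRE^hi in the healthy-like population to 46% in the injured-like one, and
run the trace pipeline on synthetic movies, recovering 25.0% (healthy) vs
57.0% (injured) of cells completing both up- and downregulation within one
20.5-h movie, with a larger median upregulation rate in the injured
condition. All tables land under `results/`.

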