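# spadflim

A desk-scale simulator of an event-driven SPAD TCSPC image sensor for
fluorescence lifetime imaging (FLIM), with the matching analytic pile-up
model and three lifetime estimators.

## What it is for

Time-correlated single photon counting (TCSPC) FLIM builds, per pixel, a
histogram of photon arrival times after each laser pulse and extracts the
fluorophore's exponential decay constant τ from it. Array SPAD sensors that
read out *every* pixel every cycle drown in data; an event-driven
architecture records only the few pixels that actually fired. The
architecture simulated here is a 16×16 SPAD array tiled into 8×8
sub-arrays, each sharing **four** time-to-digital converters (TDCs) behind
an OR-tree: per excitation period at most 4 of 64 pixels are read out (a
1/16 data-rate reduction). The price is pile-up: the OR-tree's pulse width
t_p acts as a dead time (two photons closer than t_p merge and only the
first survives), and a fifth photon in a cycle finds no free TDC.

This package lets you quantify that price. It simulates photon generation
(Bernoulli detection per pixel per pulse at rate p0, single-exponential
arrival times truncated to the laser period), the full readout chain (dead
time, TDC allocation, 10-bit quantization with the code range limited to
950, position encoding and frame validation), and estimates lifetimes from
the resulting code histograms.

## The model in brief

With μ expected photons per sub-array per pulse, the expected per-pixel
detection density under OR-tree dead time is

    c(t) = (1/(N²τ)) e^(−t/τ) · exp(−μ [F(t) − F(max(t−t_p, 0))])

where F(t) = 1 − e^(−t/τ): the undisturbed decay times the probability
that the preceding dead-time window contained no other arrival. The three
estimators of τ from a histogram N_j (bin width h, M bins) are:

* **MLE** — solves `1 + 1/(e^(h/τ)−1) − M/(e^(Mh/τ)−1) = Σ j N_j / N_c`,
  the exact moment condition of the binned, window-truncated exponential;
* **CMM** — the centre of mass `τ = (mean TDC code + ½)·h`,
  optionally followed by a window-truncation calibration that inverts the
  truncated-exponential mean;
* **LSM** — minimizes Pearson's chi-square `Σ (N_j − e_j)²/e_j` against the
  expected binned-exponential counts e_j(τ).

Map accuracy is summarized by the average offset Δτ, the across-pixel
spread σ_τ, and the imaging figure of merit `FoM = τ/√(σ_τ² + Δτ²)`.

## Worked example

```python
import numpy as np
from spadflim import (SensorConfig, DecayMap, simulate_exposure,
                      readout_exposure, build_lifetime_map, compute_metrics)

cfg = SensorConfig()                      # 16x16, 4 TDC/8x8, t_p=360 ps,
                                          # h=97.6 ps, 10 MHz laser, p0=1%
decay = DecayMap.uniform(cfg, tau=10.5)   # uniform 10.5 ns scene
stream = simulate_exposure(cfg, decay, n_pulses=200_000, seed=1)
result = readout_exposure(stream, cfg)
print(result.losses.to_dict())
lmap = build_lifetime_map(result, cfg, "cmm")
rep = compute_metrics(lmap, decay)
print(f"mean tau = {rep.mean_tau:.3f} ns, avg error = "
      f"{rep.avg_error_percent:.2f}%, spread = {rep.sigma_tau*1e3:.0f} ps")
```

prints

```
{'generated': 510746, 'recorded': 505017, 'dead_time_merged': 5399,
 'tdc_exhausted': 296, 'code_overflow': 34, 'invalid_frame': 0}
mean tau = 10.521 ns, avg error = 0.20%, spread = 255 ps
```

Of 510,746 generated photons, ~1.1% are lost to OR-tree merging, TDC
exhaustion and code overflow — the pile-up that shifts the mean CMM
estimate slightly above 10.5 ns. At 10 ms per map (100,000 cycles, ~1000
photons/pixel) the sensor sustains 100 lifetime maps per second.

The same pipeline is scriptable from the shell:

```bash
spadflim readout --tau 10.5 --pulses 100000 --seed 1 --out run/
spadflim estimate run/histogram.csv --method mle
spadflim experiment table1 --scale 0.1 --seed 1 --out exp/
```

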