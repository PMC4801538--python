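# Methods

## Physical model

The simulator targets a 16×16 SPAD TCSPC imager tiled into four
independent 8×8 sub-arrays, each sharing 4 TDCs behind row/column OR-trees.
Per excitation period (T = 100 ns at a 10 MHz laser) each pixel detects at
most one photon: the quenching circuit holds the SPAD off until the global
reset, so intra-pixel dead time never enters. Detection is a Bernoulli
trial with per-pixel rate p0 (default 1%, the regime in which classical
pile-up is negligible), and the arrival time follows the
single-exponential decay of that pixel's lifetime, truncated and
renormalized to [0, T). Background and dark counts, when enabled, are an
independent Bernoulli per pixel per pulse with uniform arrival time; if a
pixel draws both a signal and a background event in one pulse only the
earlier survives.

The readout chain applies, per sub-array per pulse, in order:

1. **OR-tree dead time** (t_p = 360 ps): an event arriving strictly less
   than t_p after the reference event is merged and lost. The default mode
   is *paralyzable* — the reference is the immediately preceding arrival,
   merged or not, because overlapping pulses extend the OR-tree output.
   This is also the reading consistent with the closed-form expected
   density (see below). A nonparalyzable mode (reference = last accepted
   event) is available for comparison.
2. **TDC allocation**: the first 4 surviving events in arrival order get
   TDCs; the rest are lost. Merged events never reach a TDC.
3. **Quantization**: code = ⌊t/h⌋ with h = 97.6 ps; codes ≥ 950 fall
   outside the converter's emitted range and are *discarded*, not
   saturated (saturation would pile spurious counts into the last bin).
   The hardware's reverse START-STOP conversion is an energy optimization
   whose stored code is an affine function of the arrival time; the
   simulator records forward codes directly, which leaves every histogram
   identical up to index reversal.
4. **Position encoding / frame validity**: a frame is valid when the row,
   column and time lists agree in length and no encoder emitted the
   invalid code. With a positive encoder hold time, two events closer than
   it invalidate the whole sub-array frame. The hold time is unspecified
   for the modelled chip and defaults to 0 (mechanism disabled); a switch
   exists for sensitivity studies.

Every generated photon is accounted exactly once: recorded, or attributed
to one of four loss counters (merged, TDC-exhausted, code overflow,
invalid frame). The test suite enforces this conservation and checks the
vectorized pipeline against a per-event reference loop exactly.

## Analytic pile-up model

For a uniform sub-array (mini-SiPM mode) with μ expected photons per pulse
the per-pixel expected detection density is the undisturbed exponential
times the probability that the blocking window [max(t−t_p, 0), t) holds no
other arrival:

    c(t) = (1/(N²τ)) e^(−t/τ) · exp(−μ [F(t) − F(max(t−t_p,0))]),
    F(t) = 1 − e^(−t/τ).

Two source-formula ambiguities are resolved here: the prefactor is
1/(N²τ) so that the μ→0 limit recovers the normalized per-pixel
exponential, and the miss-probability's early branch uses the window
[0, t) (clipped at the excitation) rather than a constant-width window —
the only choice that is consistent between the MSP-mode and array-mode
formulas and keeps the expression a probability. The decaying-exponential
sign in the late branch is likewise enforced. In array mode each pixel has
its own (τ, p0) and a target pixel's density is its own unmodulated
density times the product of all other pixels' miss probabilities. The
Monte Carlo readout agrees with these densities within multinomial
sampling error (tested at 3σ per coarse bin), including the sign
structure of the counts-error curves: suppression is strongest near the
excitation and a slow corner pixel shifts blocking toward late times.

## Estimators

All estimators consume code histograms over the emitted range only
(M = 950 bins): bins 950–1023 of the 10-bit space never carry data, so
the moment conditions use the configured quantized-bin count.

* **MLE**: the moment condition's left side is the exact mean bin index of
  the discretized truncated exponential; it is strictly increasing in τ
  (asserted numerically on the bracket before solving), so Brent's method
  on [h/100, 100T] at relative tolerance 1e−9 finds the unique root.
  Unattainable moments (e.g. all counts in the first bin) are flagged
  non-converged, never clamped.
* **CMM**: τ̂ = (mean code + ½)h — the histogram centroid, with the +½
  applied to the 0-based TDC code (bin centres). The alternative
  convention that applies +½ to 1-based bin indices (one full bin width
  more) is available via `index_origin=1`; the bin-centre convention is
  the default because it is the one the modelled sensor's published
  accuracy tables are consistent with. The centroid ignores window
  truncation and so under-reads long lifetimes (−4.5% at τ = 20 ns in a
  92.7 ns window); `truncation_correction=True` inverts the
  truncated-exponential mean map μ(τ) = τ − T'e^(−T'/τ)/(1−e^(−T'/τ)),
  which is the standard software calibration that extends CMM's usable
  range toward T/4. It is applied in the 5–20 ns resolvability-range
  experiment and off by default.
* **LSM**: Pearson chi-square against expected binned-exponential counts,
  minimized by a 200-point logarithmic scan refined with bounded scalar
  minimization (tolerance 1e−9). The transcendental identity sometimes
  quoted for least squares (squared-count weights; its interval symbol
  read as the bin width h, the only reading with consistent units) is
  available as `mode="equation"`. Degenerate single-bin histograms are
  flagged non-converged.

**A caveat that matters for interpretation**: Pearson chi-square over ~950
mostly low-occupancy bins is a *biased* estimator at realistic photon
budgets — +0.8% at 200k counts and τ = 10.5 ns, +10% at 10k counts, purely
from sampling statistics, with no pile-up involved. LSM accuracy
statements are therefore meaningful only at a stated per-histogram count,
and the package evaluates them at matched counts by pooling pixel
histograms of a uniform scene (`pooled_lifetime_estimates`): pixels are
iid replicas, so pooling k histograms reproduces a k-fold longer exposure
exactly. MLE and CMM have no comparable count-dependent bias.

## Imaging metrics and experiments

Δτ is the mean signed offset of the map, σ_τ the across-pixel standard
deviation of estimates within one map (the natural choice for a
uniform-intensity scene; a per-pixel across-repeats variant can be built
by mapping repeated exposures), the average error |Δτ|/τ·100, and
FoM = τ/√(σ_τ²+Δτ²) — recomputable from the stored fields to machine
precision. At 10 MHz × 1% a pixel collects ~1000 photons in 10 ms, hence
up to 100 maps/s.

The canned experiments: uniform scenes at 10.5/14 ns (accuracy tables),
the interaction study (one slow corner pixel per sub-array among fast
neighbours, per-pixel estimates averaged over the four equivalent corner
replicas), the 5–20 ns range sweep with calibrated CMM, and the
rectangle-on-background phantoms (14 ns on 4 ns; 10.5 ns on 4 ns). The
phantom geometry of the original test scenes is unpublished; a centred
rectangle covering half the array in each dimension is used.

## Problem sizes and what the desk scale shows

The package's standard exposures are 10^6 laser cycles for uniform and
interaction experiments (≈10^4 photons/pixel) and 10 × 10^5 cycles for the
10 ms spread study; the reference accuracy study behind the default
constants simulated 2×10^7 cycles. Mean-bias quantities (CMM/MLE
estimates, pile-up shifts) are photon-budget-independent and reproduce at
desk scale within Monte Carlo error. Count-dependent quantities do not
scale trivially: the LSM bias is evaluated at matched per-histogram counts
via pooling (above), and the interaction-study LSM deviation is reported
at the 10^6-cycle per-pixel budget, where it is dominated by the
chi-square small-count bias (~12%) rather than pile-up (~2.9%).

Two published figures are *not* reproduced by photon statistics alone, and
the package reports its own computed values rather than matching them: the
10 ms across-pixel CMM spread (photon statistics bound it at
σ_t/√N_c ≈ 330 ps; a sensor with per-pixel timing skew and TDC
nonlinearity — circuit effects outside this package's scope — measures
more), and the claim that MLE stays below 1% in the interaction study
(the analytic modulated-density model itself predicts a 2.85% moment
shift at t_p = 360 ps, matching this simulator; all moment-based
estimators inherit it).

## Numerical and design notes

* One RNG per exposure, seeded explicitly; pulses are generated in fixed
  65536-pulse chunks with per-chunk substreams spawned from the root seed,
  so equal seeds give byte-identical streams and a stream's prefix does
  not depend on the requested exposure length.
* Simultaneous arrivals (probability zero under continuous times, possible
  after float rounding) are ordered by (row, col) for deterministic
  testability.
* Truncation, not wrap-around: a photon whose nominal arrival falls past T
  is regenerated inside the window by renormalization, never wrapped into
  the next period — the analytic densities are defined on a single window.
* Histograms accept float (expected) counts so noise-free model histograms
  can be fed to the estimators directly.
* Root brackets, tolerances and degenerate-input behaviour are stated per
  estimator above; non-convergence is always reported via the `converged`
  flag.

## Known limitations

Single-exponential decays only (no IRF convolution, no multi-exponential
unmixing); no SPAD device physics (afterpulsing, crosstalk, PDE spectra);
token-passing/register timing and PLL/GRO behaviour idealized; the
background model is a uniform floor with a clamped per-bin subtraction,
not a full background-estimation algorithm.
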