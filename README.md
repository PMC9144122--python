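# spadflim

Monte Carlo simulation and analytic design tools for fluorescence-lifetime
(FL) measurement with single-photon avalanche diode (SPAD) array detectors.

## The problem

In time-correlated single-photon counting (TCSPC), a sample is excited by a
short laser pulse and single-photon arrival times are histogrammed over many
excitation cycles ("measurement windows"); the fluorescence lifetime τ is
obtained by fitting the single-exponential decay

    I(t) = I0 · exp(−t / τ)

to the histogram. A single-photon detector can register only **one photon
per pixel per window**: at high count rates only the earliest photon on each
pixel survives, the histogram *piles up* toward early times, and the fitted
lifetime is biased low. This first-photon limit is what makes conventional
one-pixel TCSPC slow. An N-pixel SPAD array relaxes the limit — if one pixel
is dead after a hit, another can still catch the next photon — but how far
the count rate can be pushed, and what that costs in measurement time and
data rate, is a quantitative design question. `spadflim` is for detector and
assay designers who want those numbers, and for anyone who wants a faithful,
seeded photon-statistics simulator of the pile-up mechanism itself.

## What the package computes

**Monte Carlo pipeline** (`emission`, `detector`, `estimation`): per window a
Poisson number of photons is drawn at the configured count rate ⟨Nc⟩w; each
photon's arrival time is the exact sum Uniform(0, FWHM) + Exp(turn-off) +
Exp(τ₀), i.e. the laser plateau convolved with the laser falling edge and the
fluorescence decay (defaults: FWHM = 1.25 ns, turn-off = 0.5 ns, τ₀ = 5 ns,
312.5 ps histogram bins, 30,000 windows). Background events are Poisson per
window and uniform in time. Events are distributed uniformly over the pixels,
each pixel keeps its first event per window (pile-up, switchable), and the
detected times are binned. Lifetimes are fitted by unweighted nonlinear least
squares; precision and accuracy over replicates are summarised as

    cv = σ / ⟨τ_fit⟩        (coefficient of variation)
    δτ = ⟨|τ_fit − τ₀|⟩/τ₀  (mean absolute relative error)

with geometric-mean aggregation across conditions. The exact detected-event
intensity under pile-up, μ·f(t)·exp(−(μ/N)·F(t)) for arrival pdf/cdf f, F,
mean rate μ and N pixels, is available in closed form as an oracle and is
verified against the simulation.

**Design calculators** (`assay_design`): to separate two lifetimes τ₁ > τ₂
with assay quality Z′ = 1 − 3(σ₁+σ₂)/|τ₁−τ₂| under Poisson precision
cv ≈ 1/√Nc, the required photon count is

    Nc = [ 3/(1−Z′) · (1+r)/(1−r) ]²,   r = τ₂/τ₁ ,

a window of Δtw = 7τ captures 1 − e⁻⁷ ≈ 99.9 % of emitted photons, the total
measurement time at the maximum pile-up-free rate of 0.31 photons/window/pixel
is ttot = 7000·τ/(0.31·N_pixel), and the data rate for summed per-window pixel
counts at time resolution t_res = 4τ is d_rate = log₂(N_pixel+1)/(4τ).

**Simulation studies** (`pileup_scan`): δτ versus count rate (U-shaped:
photon statistics improve, then pile-up bias takes over), extraction of the
maximum count rate ⟨Nc⟩w,max meeting a self-calibrated accuracy threshold
(the pile-up-free δτ at 1000 counts), its linear scaling with the pixel
count (≈ 0.3 photons/window/pixel), and accuracy versus histogram bin width
via rebinning (flat until t_res ≈ 2τ).

## Worked example

Closed-form design report for a 30-pixel detector measuring a 10 ns
lifetime, with the photon budget for separating 10 ns from 4.1 ns at Z′=0.5:

```bash
$ spadflim design --tau 10 --n-pixel 30 --tau2 4.1 --z-prime 0.5
{
  "cv_at_n_counts": 0.03162277660168379,
  "drate_bit_s": 123854907.75967187,
  "n_pixel": 30,
  "photon_budget": {
    "n_required": 206,
    "n_required_exact": 205.6064349324906,
    "tau1_ns": 10.0,
    "tau2_ns": 4.1,
    "z_prime": 0.5
  },
  "tau_ns": 10.0,
  "ttot_s": 7.526881720430107e-06,
  "window_capture_fraction": 0.9990881180344455,
  "window_duration_ns": 70.0
}
```

206 photon counts separate the two lifetimes at Z′ = 0.5; a 70 ns window
(7 lifetimes) captures 99.9 % of the emission; collecting 1000 counts at
0.31 photons/window/pixel takes 7.5 µs on 30 pixels, at 124 Mbit/s.

One simulated measurement and lifetime fit from the library:

```python
import numpy as np
from spadflim import SimParams, simulate_measurement, fit_lifetime

params = SimParams()  # tau0 = 5 ns, 1.25 ns plateau, 0.5 ns turn-off
rng = np.random.default_rng(7)
hist, res = simulate_measurement(
    params.pulse, params.fluor, params.noise, rate=1000 / 30_000,
    config=params.detector, rng=rng,
)
fit = fit_lifetime(hist, start_after_max_bins=params.fit_start_offset_bins())
print(f"arrived {res.n_arrived}, detected {res.n_detected}, "
      f"tau_fit = {fit.tau_fit_ns:.2f} ns")
# arrived 1038, detected 1019, tau_fit = 5.11 ns
```

At ~0.03 photons/window almost nothing piles up (1019 of 1038 detected; the
19 missing are out-of-window or same-pixel coincidences) and the fitted
lifetime sits within one standard error of the true 5 ns.

The full simulation experiments (precision law, lifetime-vs-rate with
pile-up on/off, accuracy scans, pixel-slope, rebinning study) run as, e.g.:

```bash
spadflim -v run-experiment pixel-slope --seed 1 --scale 0.3 --out out/slope
spadflim -v scan-resolution --seed 1 --out out/resolution
```

Every output directory contains the exact configuration and seed; re-running
reproduces tables byte-identically.

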