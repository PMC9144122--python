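# Methods

## Physical model

One measurement window is one excitation–detection cycle of duration `tw_ns`.
The excitation pulse is modelled as a rectangular plateau of width `fwhm_ns`
followed by an exponential falling edge with time constant `turnoff_ns`; a
fluorophore excited at laser time *s* emits after an additional
Exponential(`tau0_ns`) delay. A photon's arrival time is therefore the exact
sum of three independent draws,

    t = Uniform(0, fwhm) + Exp(turnoff) + Exp(tau0),

which realises the convolution of the pulse shape with the single-exponential
decay without any grid discretisation. The number of fluorescence photons per
window is Poisson(⟨Nc⟩w), where the *count rate* ⟨Nc⟩w is the mean number of
photons that would be detected per window in the absence of pile-up.
Background events (dark counts, stray light) are Poisson(`noise_per_window`)
per window, uniform in time over the window.

The closed-form arrival-time pdf and cdf (uniform ⊗ two exponentials) are
implemented analytically, including the equal-time-constant and zero-plateau
degenerate branches, and are cross-checked in the tests against a
brute-force numeric grid convolution.

### Interpretation choices

- The pulse "turn-off time" is read as the exponential time constant of the
  falling edge, not a 90–10 fall time — the simplest reading consistent with
  a convolution model.
- The plateau is rectangular rather than Gaussian; at FWHM = 1.25 ns and a
  fit range that starts after the histogram maximum, the plateau shape only
  affects the rising edge, which the estimator never uses.

## Detector model

Events are assigned independently and uniformly to one of `n_pixel` pixels
("evenly distributed" read statistically, not round-robin). With pile-up
enabled, each pixel keeps only its earliest event per window; exact-time ties
keep the first event in generation order. SPADs are assumed to reset between
windows (no cross-window dead time). Detected times are quantized into
half-open bins [k·tres, (k+1)·tres) of width `tres_ns` (default 312.5 ps);
events with t ≥ tw are dropped and tallied separately. An off-by-default
`wrap_slow_photons` flag instead folds them into a later window at t mod tw,
modelling "slow" photons being detected as "fast" ones in the next cycle.

For verification, the expected detected-event intensity under pile-up has a
closed form: a Poisson stream of mean μ per window with arrival pdf f,
thinned uniformly onto N pixels, gives independent per-pixel streams of mean
μ/N, and keeping each pixel's first event yields total intensity

    μ · f(t) · exp(−(μ/N) · F(t)),

whose integral is N·(1 − e^(−μ/N)), the expected detected count per window.
Simulated detected-time distributions are required to match this density to
Kolmogorov–Smirnov distance < 0.02 at 10⁵ windows.

The pile-up reduction uses a dense one-slot-per-(window, pixel) minimum
(`np.minimum.at`) when the slot array is affordable, falling back to a
sort-based group-minimum otherwise; both paths are tested to agree.

## Lifetime estimation

Lifetimes are extracted by **unweighted** nonlinear least squares of
I0·exp(−t/τ) against bin counts at bin centers (Levenberg–Marquardt on the
rate parametrisation I0·e^(−kt)), with the initial guess from a
count-weighted log-linear regression and a first-moment fallback at very low
counts. Zero-count bins inside the range are retained; fits that only reach
a non-decaying or near-flat optimum (τ beyond 20 windows) are reported as
failures, not results.

**Fit range.** The default range runs from the histogram maximum plus the
laser turn-off settling span — ⌈4·turnoff/tres⌉ bins, ≈ 2 ns at the default
parameters — to the end of the window. Starting immediately after the
maximum leaves residual pulse contamination (the −e^(−t/turnoff) component
of the convolved decay) inside the range, which we measured as a +4 % bias
in τ_fit at 1000 counts; after the settling span the bias is below 0.5 %.
`fit_lifetime` itself defaults to argmax+1 for bare histograms; the
simulation pipeline always passes the settling-span offset.

**Precision/accuracy statistics.** Over replicate measurements we report
cv = s/⟨τ_fit⟩ (sample standard deviation, n−1) and δτ = ⟨|τ_fit−τ₀|⟩/τ₀.
Because cv and δτ are approximately log-normal across conditions, pooled
values use geometric means with geometric standard errors. Unweighted LS
with the conservative fit start pays an efficiency factor of ≈ 2.4 over the
Poisson bound 1/√Nc (measured cv ≈ 0.078 at Nc = 1000); the 1/√Nc *scaling*
holds with log–log slope −0.5 ± 0.05 over Nc ∈ [10², 10⁴].

## Background level

The background default is `noise_per_window = 0.001` (≈ 30 events per
30,000-window measurement, uniform over the window). The level is not
derivable from first principles here — it stands in for the laser-off count
rate of a real setup — so it was calibrated once so that the pile-up-free
accuracy at the 1000-count operating point is a few percent (measured
δτ ≈ 0.066), the floor a well-suppressed experimental setup reports.
Because the fit model has no offset term, background tilts τ_fit upward;
at ten times this level the 1000-count fit would be ~30 % biased, which is
not a regime the design calculations describe.

## Scan experiments

**Count-rate scans.** For each rate on a log grid, `n_rep` independent
measurements are simulated and fitted; δτ(rate) is U-shaped (statistics
improve with counts until pile-up bias dominates). The **maximum count
rate** ⟨Nc⟩w,max is where the rising branch crosses an accuracy threshold,
located by log-linear interpolation past the last local minimum of the
triplet-smoothed curve. The threshold is **self-calibrated**: the
pile-up-free δτ at 1000 total counts, measured with extra replicates
(hundreds; these calibration runs are far cheaper than the scans). A fixed
threshold can be supplied instead. Fitting ⟨Nc⟩w,max against the pixel
count through the origin gives the maximum count rate **per pixel**; at the
package defaults this slope comes out at ≈ 0.27–0.31 photons/window/pixel
(seed-dependent at desk scale), consistent with one first-photon detection
per ~3 windows per pixel before accuracy degrades.

Desk-scale defaults used by the acceptance script: pixel counts
{1, 3, 10, 30, 100}, 10 grid points over [0.05·N, 1.5·N] photons/window,
50 replicate fits per point, 400 calibration replicates, nw = 30,000
throughout (≈ 1–2 minutes on one CPU). The library default grid
(16 points/decade over [0.01·N, 10·N], 100 replicates) reproduces the same
slope with tighter interpolation at ~20× the cost.

**Rebinning study.** Replicate histograms simulated at fine resolution are
rebinned by integer factors (trailing partial bins are summed for count
conservation but excluded from refits, since their width and effective
center differ) and refitted. Accuracy is flat within ~1.4× of the
finest-resolution value while tres < 2τ and collapses once most counts fall
into one or two bins (tres ≳ 4–6τ). The study is run with a long window
(28τ, emulating a readout-limited cycle), ≥ 10⁴ counts and enough pixels
that pile-up does not confound the binning effect.

## Design calculators

All closed forms are exact evaluations: Z′ = 1 − 3cv(τ₁+τ₂)/|τ₁−τ₂| (equal
cv for both fluorophores, as a two-cv generalisation exists but is not the
default), its inversion Nc = [3/(1−Z′)·(1+r)/(1−r)]² (reported rounded to
nearest by default, with a "ceil" mode since counts are a budget), window
capture P = 1 − e^(−Δtw/τ), ttot = Nc·Δtw/⟨Nc⟩w with Δtw = 7τ and
⟨Nc⟩w = 0.31·N_pixel by default, and d_rate = log₂(N_pixel+1)/(4τ) for
per-window summed pixel counts. The 0.31 default is the slope re-derivable
from the pile-up scans; 7 and 4 are the window and resolution factors
motivated above. cv_from_counts(1000) = 3.16 % is reported as-is wherever a
precision at the 1000-count operating point is needed.

## What the synthetic data does and does not emulate

The generator reproduces Poisson photon statistics, the pulse-convolved
decay, uniform background, pixel thinning and first-photon pile-up. It does
**not** model afterpulsing, crosstalk, per-pixel dark-count heterogeneity,
TDC nonlinearity, a Gaussian illumination profile across the array (all
pixels see the same rate), multi-exponential decays, or instrument-response
deconvolution. Passing tests therefore validate the counting statistics and
the pile-up mechanism, not detector-specific artefacts; absolute accuracy
floors in real hardware will differ with the real noise level and fit
window.

## Numerical choices and degenerate inputs

- All randomness flows from explicit `numpy.random.Generator` streams; named
  experiments derive per-experiment substreams from one seed
  (`SeedSequence([seed, index])`), so outputs are byte-reproducible and
  adding one experiment does not perturb another.
- Bin boundaries are half-open; t = k·tres lands in bin k; t = 0 in bin 0.
- Fits require ≥ 2 bins with counts in range; scans record and exclude fit
  failures with warning tallies rather than aborting.
- `find_max_count_rate` raises (asking for a wider grid) when the δτ curve
  never crosses the threshold on a rising branch inside the grid.
- Equal laser/fluorophore time constants use the Gamma-limit branch of the
  closed-form pdf/cdf.

## Known limitations

- The maximum-rate slope is defined relative to the self-calibrated
  threshold; a stricter accuracy target lowers it. With ~50 replicates per
  grid point the slope carries a few-percent seed scatter.
- The unweighted-LS estimator is ~2.4× less precise than the Poisson bound;
  a weighted or maximum-likelihood estimator would shift both the threshold
  and the bias curve, and with them the extracted maximum rates.
- At count rates far above the maximum (μ/N ≳ 2) fits can fail outright;
  these points are excluded from δτ with warnings, slightly flattening the
  extreme rising branch.
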