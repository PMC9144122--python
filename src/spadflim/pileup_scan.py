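"""Pile-up scan experiments.

Three simulation studies built on the Monte Carlo pipeline:

* ``scan_count_rate`` — relative lifetime accuracy delta_tau versus count
  rate <Nc>w for a fixed pixel count.  The curve is U-shaped: accuracy
  first improves with photon statistics (~1/sqrt(Nc)), then deteriorates
  once first-photon pile-up biases the fitted lifetime low.
* ``find_max_count_rate`` / ``fit_pixel_slope`` — the largest count rate
  <Nc>w,max still meeting an accuracy threshold, extracted per pixel count
  and summarised by a through-origin line fit of <Nc>w,max against the
  number of pixels (the maximum count rate per pixel).
* ``scan_resolution`` — accuracy versus histogram bin width, obtained by
  rebinning finely resolved histograms and refitting.

The accuracy threshold is self-calibrated by default: it is set to the
pile-up-free delta_tau measured at a total of 1000 photon counts, so the
extracted maximum rate answers "how fast can I go while staying as
accurate as a 1000-count pile-up-free measurement".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .detector import DetectorConfig, Histogram, simulate_measurement
from .emission import FluorophoreModel, LaserPulseModel, NoiseModel
from .estimation import FitError, fit_lifetime, relative_error

__all__ = [
    "SimParams",
    "PileUpScan",
    "SlopeFit",
    "ResolutionScan",
    "default_rate_grid",
    "calibrate_threshold",
    "scan_count_rate",
    "find_max_count_rate",
    "fit_pixel_slope",
    "rebin_histogram",
    "scan_resolution",
]


@dataclass(frozen=True)
class SimParams:
    """Bundle of physical and detector parameters for one simulation setup."""

    pulse: LaserPulseModel = LaserPulseModel()
    fluor: FluorophoreModel = FluorophoreModel()
    noise: NoiseModel = NoiseModel()
    detector: DetectorConfig = DetectorConfig()

    def with_detector(self, **overrides) -> "SimParams":
        cfg = self.detector.__dict__ | overrides
        return SimParams(self.pulse, self.fluor, self.noise, DetectorConfig(**cfg))

    def fit_start_offset_bins(self, tres_ns: float | None = None) -> int:
        """Fit-start offset past the histogram maximum, in bins.

        Covers the laser turn-off settling span (four turn-off time
        constants), after which residual pulse contamination of the
        single-exponential decay is below the percent level.
        """
        tres = self.detector.tres_ns if tres_ns is None else tres_ns
        return max(1, int(np.ceil(4.0 * self.pulse.turnoff_ns / tres)))


@dataclass
class PileUpScan:
    """delta_tau versus count rate for one pixel count."""

    n_pixel: int
    rate_grid: np.ndarray
    delta_tau: np.ndarray
    taus_per_rate: list[np.ndarray]
    n_rep: int
    n_fit_failures: np.ndarray
    threshold: float | None = None
    max_rate: float | None = None

    def __post_init__(self) -> None:
        self.rate_grid = np.asarray(self.rate_grid, dtype=np.float64)
        self.delta_tau = np.asarray(self.delta_tau, dtype=np.float64)
        if np.any(np.diff(self.rate_grid) <= 0):
            raise ValueError("rate_grid must be strictly increasing")
        if np.any(self.delta_tau < 0):
            raise ValueError("delta_tau values must be >= 0")


@dataclass
class SlopeFit:
    """Through-origin fit of <Nc>w,max against pixel count."""

    n_pixels: np.ndarray
    max_rates: np.ndarray
    slope: float
    residuals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.n_pixels = np.asarray(self.n_pixels, dtype=np.float64)
        self.max_rates = np.asarray(self.max_rates, dtype=np.float64)
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        self.residuals = self.max_rates - self.slope * self.n_pixels


@dataclass
class ResolutionScan:
    """delta_tau versus time resolution expressed in multiples of tau."""

    tres_factors: np.ndarray
    delta_tau: np.ndarray
    rebin_factors: np.ndarray
    n_rep: int
    n_fit_failures: np.ndarray

    def __post_init__(self) -> None:
        self.tres_factors = np.asarray(self.tres_factors, dtype=np.float64)
        if np.any(self.tres_factors <= 0) or np.any(np.diff(self.tres_factors) <= 0):
            raise ValueError("tres_factors must be positive and increasing")


def default_rate_grid(
    n_pixel: int,
    lo_per_pixel: float = 0.01,
    hi_per_pixel: float = 10.0,
    points_per_decade: int = 16,
) -> np.ndarray:
    """Log-spaced count-rate grid scaled to the pixel count."""
    lo, hi = lo_per_pixel * n_pixel, hi_per_pixel * n_pixel
    n_points = max(2, int(round(np.log10(hi / lo) * points_per_decade)) + 1)
    return np.geomspace(lo, hi, n_points)


def _replicate_taus(
    params: SimParams,
    rate: float,
    n_rep: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Fit n_rep independent simulated measurements; count fit failures."""
    taus = []
    failures = 0
    offset = params.fit_start_offset_bins()
    for _ in range(n_rep):
        hist, _ = simulate_measurement(
            params.pulse, params.fluor, params.noise, rate, params.detector, rng
        )
        try:
            taus.append(
                fit_lifetime(hist, start_after_max_bins=offset).tau_fit_ns
            )
        except FitError:
            failures += 1
    return np.asarray(taus), failures


def calibrate_threshold(
    params: SimParams,
    n_rep: int,
    rng: np.random.Generator,
    n_counts: int = 1000,
) -> float:
    """Pile-up-free delta_tau at a total of ``n_counts`` photon counts.

    Runs replicate measurements with pile-up disabled at the count rate
    that yields ``n_counts`` photons over the configured nw windows; the
    resulting delta_tau is the statistics-dominated accuracy the pile-up
    scans are held to.
    """
    free = params.with_detector(pileup_enabled=False)
    rate = n_counts / free.detector.nw
    taus, failures = _replicate_taus(free, rate, n_rep, rng)
    if taus.size < max(2, n_rep // 2):
        raise FitError(
            f"threshold calibration failed: {failures}/{n_rep} fits failed"
        )
    return relative_error(taus, params.fluor.tau0_ns)


def scan_count_rate(
    n_pixel: int,
    rate_grid: np.ndarray,
    params: SimParams,
    n_rep: int,
    rng: np.random.Generator,
) -> PileUpScan:
    """delta_tau over a count-rate grid at fixed pixel count.

    For each rate, ``n_rep`` independent measurements are simulated and
    fitted; failed fits are excluded with a warning tally.
    """
    rate_grid = np.asarray(rate_grid, dtype=np.float64)
    if rate_grid.size == 0:
        raise ValueError("rate_grid must be nonempty")
    if n_rep < 3:
        raise ValueError(f"n_rep must be >= 3, got {n_rep}")
    scan_params = params.with_detector(n_pixel=n_pixel)
    tau0 = params.fluor.tau0_ns
    delta_tau = np.empty(rate_grid.size)
    taus_per_rate: list[np.ndarray] = []
    n_failures = np.zeros(rate_grid.size, dtype=np.int64)
    for i, rate in enumerate(rate_grid):
        taus, failures = _replicate_taus(scan_params, float(rate), n_rep, rng)
        n_failures[i] = failures
        if failures:
            warnings.warn(
                f"{failures}/{n_rep} fits failed at rate {rate:g} "
                f"(n_pixel={n_pixel}); excluded from delta_tau",
                stacklevel=2,
            )
        if taus.size == 0:
            raise FitError(f"all fits failed at rate {rate:g} (n_pixel={n_pixel})")
        taus_per_rate.append(taus)
        delta_tau[i] = relative_error(taus, tau0)
    return PileUpScan(
        n_pixel=n_pixel,
        rate_grid=rate_grid,
        delta_tau=delta_tau,
        taus_per_rate=taus_per_rate,
        n_rep=n_rep,
        n_fit_failures=n_failures,
    )


def _smooth_log(values: np.ndarray) -> np.ndarray:
    """Triplet moving geometric mean (edges kept as-is)."""
    logs = np.log(values)
    sm = logs.copy()
    if logs.size >= 3:
        sm[1:-1] = (logs[:-2] + logs[1:-1] + logs[2:]) / 3.0
    return np.exp(sm)


def find_max_count_rate(scan: PileUpScan, threshold: float) -> float:
    """Maximum count rate <Nc>w,max meeting an accuracy threshold.

    Locates the rising (pile-up) branch as everything from the last local
    minimum of the triplet-smoothed delta_tau curve onward, then
    log-linearly interpolates the rate at which delta_tau crosses the
    threshold between the last grid point at or below it and the first
    above it.  The scan's ``threshold`` and ``max_rate`` fields are filled.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    d = scan.delta_tau
    if d.size < 2:
        raise ValueError("scan needs >= 2 grid points")
    sm = _smooth_log(d)
    # Last local minimum of the smoothed curve (global min of the suffix).
    minima = [
        i
        for i in range(sm.size)
        if (i == 0 or sm[i] <= sm[i - 1]) and (i == sm.size - 1 or sm[i] < sm[i + 1])
    ]
    i_min = minima[-1] if minima else int(np.argmin(sm))
    if i_min == sm.size - 1 or d[i_min] > threshold:
        raise ValueError(
            "delta_tau curve does not cross the threshold on a rising branch "
            "inside the rate grid; extend the grid to higher count rates "
            "or raise the threshold"
        )
    above = np.nonzero(d[i_min:] > threshold)[0]
    if above.size == 0:
        raise ValueError(
            "delta_tau stays below the threshold on the rising branch; "
            "extend the rate grid to higher count rates"
        )
    j = i_min + int(above[0])  # first point above threshold
    below = np.nonzero(d[i_min:j] <= threshold)[0]
    k = i_min + int(below[-1])  # last point at/below threshold before j
    log_r = np.interp(
        threshold,
        [d[k], d[j]],
        [np.log(scan.rate_grid[k]), np.log(scan.rate_grid[j])],
    )
    max_rate = float(np.exp(log_r))
    scan.threshold = float(threshold)
    scan.max_rate = max_rate
    return max_rate


def fit_pixel_slope(
    n_pixels: np.ndarray, max_rates: np.ndarray
) -> SlopeFit:
    """Through-origin least squares of <Nc>w,max on pixel count.

    slope = sum(x*y) / sum(x*x); a single point is allowed (exact ratio).
    """
    x = np.asarray(n_pixels, dtype=np.float64)
    y = np.asarray(max_rates, dtype=np.float64)
    if x.size != y.size or x.size < 1:
        raise ValueError("need >= 1 (n_pixel, max_rate) pair of equal length")
    slope = float(np.dot(x, y) / np.dot(x, x))
    return SlopeFit(n_pixels=x, max_rates=y, slope=slope)


def rebin_histogram(hist: Histogram, factor: int) -> Histogram:
    """Sum adjacent groups of ``factor`` bins; new tres = factor * tres.

    A trailing partial group is summed into a final bin so total counts are
    conserved exactly.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return Histogram(
            counts=hist.counts.copy(),
            tres_ns=hist.tres_ns,
            tw_ns=hist.tw_ns,
            n_dropped=hist.n_dropped,
        )
    n = hist.n_bins
    n_full = n // factor
    new_counts = hist.counts[: n_full * factor].reshape(n_full, factor).sum(axis=1)
    if n_full * factor < n:
        new_counts = np.append(new_counts, hist.counts[n_full * factor :].sum())
    return Histogram(
        counts=new_counts,
        tres_ns=hist.tres_ns * factor,
        tw_ns=hist.tw_ns,
        n_dropped=hist.n_dropped,
    )


def scan_resolution(
    params: SimParams,
    tres_factors: np.ndarray,
    n_rep: int,
    rng: np.random.Generator,
    rate: float | None = None,
) -> ResolutionScan:
    """Accuracy versus time resolution by rebinning and refitting.

    ``tres_factors`` are target bin widths in multiples of the lifetime
    tau0; each replicate histogram is simulated once at the configured fine
    resolution, rebinned to every factor and refitted.  ``rate`` defaults
    to 1000 counts over the configured windows.
    """
    tres_factors = np.asarray(tres_factors, dtype=np.float64)
    tau0 = params.fluor.tau0_ns
    base_tres = params.detector.tres_ns
    rebin_factors = np.maximum(
        1, np.round(tres_factors * tau0 / base_tres).astype(int)
    )
    coarsest = rebin_factors.max() * base_tres
    if coarsest > params.detector.tw_ns:
        raise ValueError(
            f"coarsest requested resolution ({coarsest:g} ns) exceeds the "
            f"window duration ({params.detector.tw_ns:g} ns)"
        )
    if rate is None:
        rate = 1000 / params.detector.nw

    taus: list[list[float]] = [[] for _ in tres_factors]
    n_failures = np.zeros(tres_factors.size, dtype=np.int64)
    for _ in range(n_rep):
        hist, _ = simulate_measurement(
            params.pulse, params.fluor, params.noise, rate, params.detector, rng
        )
        for i, f in enumerate(rebin_factors):
            rebinned = rebin_histogram(hist, int(f))
            offset = params.fit_start_offset_bins(rebinned.tres_ns)
            # A trailing partial bin has a different width and a shifted
            # effective center, so it is excluded from the refit.
            end = rebinned.n_bins
            if hist.n_bins % int(f):
                end -= 1
            try:
                taus[i].append(
                    fit_lifetime(
                        rebinned,
                        fit_end_bin=end,
                        start_after_max_bins=offset,
                    ).tau_fit_ns
                )
            except FitError:
                n_failures[i] += 1
    delta_tau = np.empty(tres_factors.size)
    for i, t in enumerate(taus):
        if n_failures[i]:
            warnings.warn(
                f"{n_failures[i]}/{n_rep} refits failed at tres factor "
                f"{tres_factors[i]:g}",
                stacklevel=2,
            )
        if not t:
            raise FitError(f"all refits failed at tres factor {tres_factors[i]:g}")
        delta_tau[i] = relative_error(np.asarray(t), tau0)
    return ResolutionScan(
        tres_factors=tres_factors,
        delta_tau=delta_tau,
        rebin_factors=rebin_factors,
        n_rep=n_rep,
        n_fit_failures=n_failures,
    )
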