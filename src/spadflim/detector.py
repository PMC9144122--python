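"""SPAD array detector model.

Events are distributed uniformly over the pixels of the array; when
pile-up is enabled each pixel registers only its first (earliest) event
per measurement window — the "first photon" mechanism that biases
single-photon counting at high rates.  Detected times are quantized into
histogram bins of width ``tres_ns`` over [0, tw).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emission import (
    EmissionSet,
    FluorophoreModel,
    LaserPulseModel,
    NoiseModel,
    arrival_time_cdf,
    arrival_time_pdf,
    sample_emission,
    sample_noise_times,
)

__all__ = [
    "DetectorConfig",
    "DetectionResult",
    "Histogram",
    "assign_pixels",
    "apply_pileup",
    "quantize_and_histogram",
    "simulate_measurement",
    "detected_density_oracle",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Geometry and timing of the SPAD array measurement.

    Parameters
    ----------
    n_pixel:
        Number of SPAD pixels (>= 1).
    tres_ns:
        Histogram bin width / TDC time resolution in ns (default 0.3125,
        i.e. 312.5 ps).
    tw_ns:
        Duration of one measurement window in ns.
    nw:
        Number of measurement windows per measurement (default 30,000).
    pileup_enabled:
        If True each pixel counts at most one photon per window.
    wrap_slow_photons:
        If True, events arriving after the window end re-enter a later
        window at ``t mod tw`` ("slow" photons detected as "fast" ones);
        by default they are dropped.
    """

    n_pixel: int = 1
    tres_ns: float = 0.3125
    tw_ns: float = 35.0
    nw: int = 30_000
    pileup_enabled: bool = True
    wrap_slow_photons: bool = False

    def __post_init__(self) -> None:
        if self.n_pixel < 1:
            raise ValueError(f"n_pixel must be >= 1, got {self.n_pixel}")
        if self.tres_ns <= 0:
            raise ValueError(f"tres_ns must be > 0, got {self.tres_ns}")
        if self.tw_ns < self.tres_ns:
            raise ValueError(
                f"tw_ns ({self.tw_ns}) must be >= tres_ns ({self.tres_ns})"
            )
        if self.nw < 1:
            raise ValueError(f"nw must be >= 1, got {self.nw}")

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.tw_ns / self.tres_ns))


@dataclass
class DetectionResult:
    """Detected (post pile-up) events of one simulated measurement."""

    window: np.ndarray
    time_ns: np.ndarray
    n_arrived: int

    n_detected: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_detected = int(self.time_ns.size)
        if self.n_detected > self.n_arrived:
            raise ValueError("n_detected cannot exceed n_arrived")


@dataclass
class Histogram:
    """Binned photon arrival times: counts over [k*tres, (k+1)*tres).

    Simulated histograms have integer counts; float counts are accepted so
    idealised (noiseless model) histograms can be represented exactly.
    """

    counts: np.ndarray
    tres_ns: float
    tw_ns: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.floating):
            counts = counts.astype(np.int64)
        self.counts = counts
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.tres_ns

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.tres_ns

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def assign_pixels(
    times_in_window: np.ndarray, n_pixel: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform independent pixel label in {0..n_pixel-1} for each event."""
    if n_pixel < 1:
        raise ValueError(f"n_pixel must be >= 1, got {n_pixel}")
    n = np.asarray(times_in_window).size
    return rng.integers(0, n_pixel, n)


def apply_pileup(
    window: np.ndarray,
    pixel: np.ndarray,
    time_ns: np.ndarray,
    pileup_enabled: bool = True,
    n_pixel: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the earliest event per (window, pixel); pass-through if disabled.

    Returns the detected ``(window, time_ns)`` arrays.  Ties on a pixel are
    broken deterministically in favour of the event generated first.
    """
    if not pileup_enabled or time_ns.size == 0:
        return np.asarray(window, dtype=np.int64), np.asarray(time_ns, float)
    window = np.asarray(window, dtype=np.int64)
    pixel = np.asarray(pixel, dtype=np.int64)
    time_ns = np.asarray(time_ns, dtype=np.float64)
    if n_pixel is None:
        n_pixel = int(pixel.max()) + 1
    key = window * n_pixel + pixel
    n_slots = (int(window.max()) + 1) * n_pixel
    if n_slots <= max(4 * time_ns.size, 50_000_000):
        # Dense reduction: one slot per (window, pixel).
        slots = np.full(n_slots, np.inf)
        np.minimum.at(slots, key, time_ns)
        idx = np.flatnonzero(np.isfinite(slots))
        return idx // n_pixel, slots[idx]
    # Sparse fallback: stable sort by (key, time); the first row of each key
    # block is its earliest event, generation order breaking exact ties.
    order = np.lexsort((np.arange(time_ns.size), time_ns, key))
    key_sorted = key[order]
    first = np.empty(key_sorted.size, dtype=bool)
    first[0] = True
    np.not_equal(key_sorted[1:], key_sorted[:-1], out=first[1:])
    keep = order[first]
    return window[keep], time_ns[keep]


def quantize_and_histogram(
    time_ns: np.ndarray, config: DetectorConfig
) -> Histogram:
    """Bin detected times with bin k = floor(t / tres), dropping t >= tw.

    Dropped (out-of-window) events are counted in ``Histogram.n_dropped``
    so that total counts + dropped = input events.
    """
    time_ns = np.asarray(time_ns, dtype=np.float64)
    n_bins = config.n_bins
    bins = np.floor(time_ns / config.tres_ns).astype(np.int64)
    in_window = time_ns < config.tw_ns
    counts = np.bincount(bins[in_window], minlength=n_bins)
    return Histogram(
        counts=counts[:n_bins],
        tres_ns=config.tres_ns,
        tw_ns=config.tw_ns,
        n_dropped=int((~in_window).sum()),
    )


def _wrap_slow_photons(emission: EmissionSet, config: DetectorConfig) -> None:
    """Fold events with t >= tw into subsequent windows at t mod tw."""
    t = emission.time_ns
    shift = np.floor(t / config.tw_ns).astype(np.int64)
    emission.time_ns = t - shift * config.tw_ns
    emission.window = (emission.window + shift) % config.nw


def simulate_measurement(
    pulse: LaserPulseModel,
    fluor: FluorophoreModel,
    noise: NoiseModel,
    rate: float,
    config: DetectorConfig,
    rng: np.random.Generator,
) -> tuple[Histogram, DetectionResult]:
    """Simulate one full TCSPC measurement of ``config.nw`` windows.

    Pipeline: Poisson window counts -> arrival-time sampling -> merge
    background events -> uniform pixel assignment -> one-photon-per-pixel
    pile-up -> quantized histogram.  Deterministic given ``rng`` state.
    """
    emission = sample_emission(rate, config.nw, pulse, fluor, rng)
    emission = emission.merge(
        sample_noise_times(noise, config.tw_ns, config.nw, rng)
    )
    if config.wrap_slow_photons:
        _wrap_slow_photons(emission, config)
    pixel = assign_pixels(emission.time_ns, config.n_pixel, rng)
    det_window, det_time = apply_pileup(
        emission.window,
        pixel,
        emission.time_ns,
        config.pileup_enabled,
        n_pixel=config.n_pixel,
    )
    hist = quantize_and_histogram(det_time, config)
    result = DetectionResult(
        window=det_window, time_ns=det_time, n_arrived=emission.n_arrived
    )
    return hist, result


def detected_density_oracle(
    t: np.ndarray,
    rate: float,
    n_pixel: int,
    pulse: LaserPulseModel,
    fluor: FluorophoreModel,
) -> np.ndarray:
    """Exact expected detected-event intensity under first-photon pile-up.

    Photons arrive as a Poisson stream of mean ``rate`` per window with
    arrival-time pdf f; uniform thinning onto ``n_pixel`` pixels makes each
    pixel an independent Poisson stream of mean rate/n_pixel, of which only
    the first event is kept.  The total detected intensity is therefore::

        rate * f(t) * exp(-(rate / n_pixel) * F(t))

    whose integral over [0, inf) is n_pixel * (1 - exp(-rate/n_pixel)),
    the expected number of detected events per window.
    """
    if n_pixel < 1:
        raise ValueError(f"n_pixel must be >= 1, got {n_pixel}")
    f = arrival_time_pdf(t, pulse, fluor)
    cdf = arrival_time_cdf(t, pulse, fluor)
    return rate * f * np.exp(-(rate / n_pixel) * cdf)
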