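"""Analytic design calculators for SPAD-array lifetime assays.

Closed-form relations linking assay quality (Z' factor), photon budget,
measurement-window duration, count rate, total measurement time and
detector data rate:

* ``z_prime`` / ``required_counts`` — how many photon counts Nc are needed
  to separate two lifetimes tau1 > tau2 at a given Z', using the Poisson
  precision law cv ~ 1/sqrt(Nc).
* ``window_capture_fraction`` — the fraction 1 - exp(-dtw/tau) of emitted
  photons captured by a window of duration dtw; dtw = 7*tau captures 99.9%.
* ``total_measurement_time`` — ttot = Nc/<Nc>w * dtw with <Nc>w =
  per_pixel_rate * n_pixel and dtw = window_factor * tau; with the defaults
  (Nc = 1000, 0.31 counts/window/pixel, 7 lifetimes per window) this is
  ttot = 7000*tau / (0.31 * n_pixel).
* ``data_rate`` — log2(n_pixel + 1) / tres bits per second for summed
  per-window pixel counts at time resolution tres = tres_factor * tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AssayRequirement",
    "DesignPoint",
    "z_prime",
    "z_prime_two_cv",
    "required_counts",
    "cv_from_counts",
    "window_capture_fraction",
    "count_rate",
    "total_measurement_time",
    "data_rate",
    "design_point",
]


@dataclass(frozen=True)
class AssayRequirement:
    """Photon budget needed to separate two lifetimes at a given Z'."""

    z_prime: float
    tau1_ns: float
    tau2_ns: float
    n_required: int
    n_required_exact: float

    def __post_init__(self) -> None:
        if not self.z_prime < 1:
            raise ValueError("z_prime must be < 1")
        r = self.tau2_ns / self.tau1_ns
        if not 0 < r < 1:
            raise ValueError("require tau1 > tau2 > 0")
        if self.n_required < 1:
            raise ValueError("n_required must be >= 1")


@dataclass(frozen=True)
class DesignPoint:
    """Measurement-time and data-rate figures for one detector design."""

    tau_ns: float
    n_pixel: int
    ttot_s: float
    drate_bit_s: float
    n_counts_target: int = 1000
    per_pixel_rate: float = 0.31
    window_factor: float = 7.0
    tres_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.ttot_s <= 0 or self.drate_bit_s <= 0 or self.window_factor <= 0:
            raise ValueError("ttot_s, drate_bit_s and window_factor must be > 0")


def z_prime(tau1: float, tau2: float, cv: float) -> float:
    """Assay quality Z' = 1 - 3*(sigma1 + sigma2)/|tau1 - tau2|.

    Both populations are assumed to share the same coefficient of
    variation, so sigma_i = cv * tau_i and
    Z' = 1 - (tau1 + tau2) * 3 * cv / |tau1 - tau2|.
    Z' >= 0.5 marks an excellent (well separated) assay.
    """
    if tau1 == tau2:
        raise ValueError("tau1 and tau2 must differ")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    return 1.0 - (tau1 + tau2) * 3.0 * cv / abs(tau1 - tau2)


def z_prime_two_cv(tau1: float, tau2: float, cv1: float, cv2: float) -> float:
    """Z' with distinct coefficients of variation for the two fluorophores."""
    if tau1 == tau2:
        raise ValueError("tau1 and tau2 must differ")
    if cv1 < 0 or cv2 < 0:
        raise ValueError("cv values must be >= 0")
    return 1.0 - 3.0 * (cv1 * tau1 + cv2 * tau2) / abs(tau1 - tau2)


def required_counts(
    z_prime_target: float,
    tau1: float,
    tau2: float,
    rounding: str = "nearest",
) -> AssayRequirement:
    """Photon counts needed to reach a target Z' for two lifetimes.

    Inverting Z' = 1 - 3*cv*(tau1+tau2)/(tau1-tau2) with cv = 1/sqrt(Nc)
    gives, with r = tau2/tau1 < 1::

        Nc = [ 3/(1-Z') * (1+r)/(1-r) ]**2

    ``rounding`` is "nearest" (default) or "ceil" — counts are a budget, so
    rounding up is offered for conservative designs.  The exact value is
    kept alongside the integer.
    """
    if not 0 <= z_prime_target < 1:
        raise ValueError(f"z_prime must be in [0, 1), got {z_prime_target}")
    if not tau1 > tau2 > 0:
        raise ValueError("require tau1 > tau2 > 0")
    r = tau2 / tau1
    exact = (3.0 / (1.0 - z_prime_target) * (1.0 + r) / (1.0 - r)) ** 2
    if rounding == "nearest":
        n = int(round(exact))
    elif rounding == "ceil":
        n = int(math.ceil(exact))
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return AssayRequirement(
        z_prime=z_prime_target,
        tau1_ns=tau1,
        tau2_ns=tau2,
        n_required=max(n, 1),
        n_required_exact=exact,
    )


def cv_from_counts(n_counts: float) -> float:
    """Poisson precision law cv ~ 1/sqrt(Nc)."""
    if n_counts < 1:
        raise ValueError(f"n_counts must be >= 1, got {n_counts}")
    return 1.0 / math.sqrt(n_counts)


def window_capture_fraction(dtw_ns: float, tau_ns: float) -> float:
    """Fraction of emitted photons within a window of duration dtw.

    P = 1 - exp(-dtw/tau); dtw = 7*tau gives 99.9%, the usual criterion
    for choosing the measurement-window duration.
    """
    if tau_ns <= 0:
        raise ValueError(f"tau_ns must be > 0, got {tau_ns}")
    if dtw_ns < 0:
        raise ValueError(f"dtw_ns must be >= 0, got {dtw_ns}")
    return 1.0 - math.exp(-dtw_ns / tau_ns)


def count_rate(n_counts: float, nw: int) -> float:
    """Mean detected photons per measurement window, <Nc>w = Nc / nw."""
    if nw < 1:
        raise ValueError(f"nw must be >= 1, got {nw}")
    if n_counts < 0:
        raise ValueError(f"n_counts must be >= 0, got {n_counts}")
    return n_counts / nw


def total_measurement_time(
    tau_ns: float,
    n_pixel: int,
    n_counts_target: float = 1000,
    per_pixel_rate: float = 0.31,
    window_factor: float = 7.0,
) -> float:
    """Total measurement time in seconds.

    ttot = nw * dtw = (Nc / <Nc>w) * dtw with dtw = window_factor * tau and
    <Nc>w = per_pixel_rate * n_pixel; with the defaults this evaluates to
    7000 * tau / (0.31 * n_pixel).  Linear in tau, inversely proportional
    to the pixel count.
    """
    if tau_ns <= 0 or n_pixel < 1:
        raise ValueError("tau_ns must be > 0 and n_pixel >= 1")
    if n_counts_target <= 0 or per_pixel_rate <= 0 or window_factor <= 0:
        raise ValueError("design parameters must be > 0")
    dtw_ns = window_factor * tau_ns
    nw = n_counts_target / (per_pixel_rate * n_pixel)
    return nw * dtw_ns * 1e-9


def data_rate(n_pixel: int, tau_ns: float, tres_factor: float = 4.0) -> float:
    """Detector data rate in bit/s for summed per-window pixel counts.

    One summed count of log2(n_pixel + 1) bits is produced per time bin of
    width tres = tres_factor * tau, so drate = log2(n_pixel+1)/(tres_factor*tau).
    """
    if n_pixel < 1:
        raise ValueError(f"n_pixel must be >= 1, got {n_pixel}")
    if tau_ns <= 0 or tres_factor <= 0:
        raise ValueError("tau_ns and tres_factor must be > 0")
    return math.log2(n_pixel + 1) / (tres_factor * tau_ns * 1e-9)


def design_point(
    tau_ns: float,
    n_pixel: int,
    n_counts_target: int = 1000,
    per_pixel_rate: float = 0.31,
    window_factor: float = 7.0,
    tres_factor: float = 4.0,
) -> DesignPoint:
    """Evaluate measurement time and data rate for one (tau, n_pixel) design."""
    return DesignPoint(
        tau_ns=tau_ns,
        n_pixel=n_pixel,
        ttot_s=total_measurement_time(
            tau_ns, n_pixel, n_counts_target, per_pixel_rate, window_factor
        ),
        drate_bit_s=data_rate(n_pixel, tau_ns, tres_factor),
        n_counts_target=n_counts_target,
        per_pixel_rate=per_pixel_rate,
        window_factor=window_factor,
        tres_factor=tres_factor,
    )
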