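"""Lifetime estimation from arrival-time histograms.

The lifetime is extracted by unweighted nonlinear least squares of the
single-exponential model

    I(t) = I0 * exp(-t / tau_fit)

against histogram bin counts at bin centers.  The fit range starts one bin
after the histogram maximum, so the laser-pulse rise — which the model does
not describe — is excluded, and runs to the end of the window.  Precision
and accuracy over replicate measurements are summarised by the coefficient
of variation cv = sigma / <tau_fit> and the mean absolute relative error
delta_tau = <|tau_fit - tau0| / tau0>; when several such values (e.g. from
different sample positions) are pooled, geometric means are used because cv
and delta_tau are approximately log-normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .detector import Histogram

__all__ = [
    "FitError",
    "FitResult",
    "ReplicateStatistics",
    "fit_lifetime",
    "coefficient_of_variation",
    "relative_error",
    "aggregate_geometric",
    "replicate_statistics",
]


class FitError(RuntimeError):
    """Raised when a lifetime fit cannot be performed or did not converge."""


@dataclass(frozen=True)
class FitResult:
    """Result of a single-exponential lifetime fit."""

    tau_fit_ns: float
    i0: float
    fit_start_bin: int
    fit_end_bin: int
    residual_norm: float

    def __post_init__(self) -> None:
        if self.tau_fit_ns <= 0:
            raise ValueError(f"tau_fit_ns must be > 0, got {self.tau_fit_ns}")


@dataclass(frozen=True)
class ReplicateStatistics:
    """Precision/accuracy summary over replicate lifetime fits."""

    n_rep: int
    mean_tau: float
    sd_tau: float
    cv: float
    delta_tau: float

    def __post_init__(self) -> None:
        if self.cv < 0 or self.delta_tau < 0:
            raise ValueError("cv and delta_tau must be >= 0")


def _exp_model(t: np.ndarray, i0: float, k: float) -> np.ndarray:
    return i0 * np.exp(-k * t)


def fit_lifetime(
    hist: Histogram,
    fit_start_bin: int | None = None,
    fit_end_bin: int | None = None,
    start_after_max_bins: int = 1,
) -> FitResult:
    """Fit I0*exp(-t/tau) to histogram counts by unweighted least squares.

    Parameters
    ----------
    hist:
        Arrival-time histogram.
    fit_start_bin:
        First bin of the fit range; default is ``start_after_max_bins``
        past the histogram maximum (excludes the laser-pulse rise).
    fit_end_bin:
        One past the last bin of the fit range; default is the end of the
        window.  Zero-count bins inside the range are retained.
    start_after_max_bins:
        Offset of the default fit start past the maximum.  The simulation
        pipeline sets this to the laser turn-off settling span (about four
        turn-off time constants) so residual pulse contamination does not
        bias the fitted lifetime; for a bare histogram the default is 1.

    Raises
    ------
    FitError
        If fewer than two bins with photon counts lie in the fit range —
        a line fit needs at least two populated bins — or if the optimiser
        fails or returns a non-decaying solution.
    """
    counts = hist.counts
    if fit_start_bin is None:
        if start_after_max_bins < 1:
            raise FitError("start_after_max_bins must be >= 1")
        fit_start_bin = min(
            int(np.argmax(counts)) + start_after_max_bins, hist.n_bins - 2
        )
    if fit_end_bin is None:
        fit_end_bin = hist.n_bins
    if not 0 <= fit_start_bin < fit_end_bin <= hist.n_bins:
        raise FitError(
            f"invalid fit range [{fit_start_bin}, {fit_end_bin}) "
            f"for a histogram with {hist.n_bins} bins"
        )

    t = hist.bin_centers[fit_start_bin:fit_end_bin]
    y = counts[fit_start_bin:fit_end_bin].astype(np.float64)
    pos = y > 0
    if pos.sum() < 2:
        raise FitError(
            "at least two bins with photon counts are required in the fit "
            f"range [{fit_start_bin}, {fit_end_bin})"
        )

    # Initial guess: count-weighted log-linear regression on the positive
    # bins; at very low counts that regression can be ill-conditioned, in
    # which case the first-moment estimate (mean arrival time past the fit
    # start equals tau for an exponential) takes over.
    tau_moment = float(np.sum(y * (t - t[0])) / y.sum())
    tau_moment = float(np.clip(tau_moment, hist.tres_ns, 10 * hist.tw_ns))
    with np.errstate(all="ignore"):
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1, w=y[pos])
    k0 = -slope
    i0_guess = float(np.exp(intercept)) if np.isfinite(intercept) else float(y.max())
    if not np.isfinite(k0) or k0 <= 0:
        k0 = 1.0 / tau_moment
        i0_guess = float(max(y.max(), 1.0))

    popt = None
    for p0 in ([i0_guess, k0], [float(max(y.max(), 1.0)), 1.0 / tau_moment]):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                cand, _ = curve_fit(
                    _exp_model, t, y, p0=p0, method="lm", maxfev=10_000
                )
        except (RuntimeError, ValueError):
            continue
        # Reject degenerate near-flat optima (tau far beyond the window).
        if np.isfinite(cand[1]) and cand[1] > 1.0 / (20.0 * hist.tw_ns):
            popt = cand
            break
    if popt is None:
        raise FitError("lifetime fit did not converge to a decaying solution")
    i0_fit, k_fit = popt
    resid = y - _exp_model(t, *popt)
    return FitResult(
        tau_fit_ns=float(1.0 / k_fit),
        i0=float(i0_fit),
        fit_start_bin=int(fit_start_bin),
        fit_end_bin=int(fit_end_bin),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
    )


def coefficient_of_variation(taus: np.ndarray) -> float:
    """cv = sample standard deviation / arithmetic mean (n-1 denominator)."""
    taus = np.asarray(taus, dtype=np.float64)
    if taus.size < 2:
        raise ValueError(f"need >= 2 values for cv, got {taus.size}")
    mean = taus.mean()
    if mean == 0:
        raise ValueError("mean lifetime is zero; cv undefined")
    return float(taus.std(ddof=1) / mean)


def relative_error(taus: np.ndarray, tau0: float) -> float:
    """delta_tau = mean over replicates of |tau_fit - tau0| / tau0."""
    if tau0 <= 0:
        raise ValueError(f"tau0 must be > 0, got {tau0}")
    taus = np.asarray(taus, dtype=np.float64)
    if taus.size < 1:
        raise ValueError("need >= 1 fitted lifetime")
    return float(np.mean(np.abs(taus - tau0) / tau0))


def aggregate_geometric(values: np.ndarray) -> tuple[float, float]:
    """Geometric mean and geometric standard error of positive values.

    Returns (exp(mean(log v)), exp(sd(log v)/sqrt(n))); the geometric SEM
    of a single value is 1 (no spread information).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1:
        raise ValueError("need >= 1 value")
    if np.any(values <= 0):
        raise ValueError("geometric aggregation requires positive values")
    logs = np.log(values)
    gmean = float(np.exp(logs.mean()))
    if values.size == 1:
        return gmean, 1.0
    gsem = float(np.exp(logs.std(ddof=1) / np.sqrt(values.size)))
    return gmean, gsem


def replicate_statistics(taus: np.ndarray, tau0: float) -> ReplicateStatistics:
    """Summarise replicate fits: mean, sd, cv and delta_tau vs tau0."""
    taus = np.asarray(taus, dtype=np.float64)
    return ReplicateStatistics(
        n_rep=int(taus.size),
        mean_tau=float(taus.mean()),
        sd_tau=float(taus.std(ddof=1)) if taus.size > 1 else 0.0,
        cv=coefficient_of_variation(taus) if taus.size > 1 else 0.0,
        delta_tau=relative_error(taus, tau0),
    )
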