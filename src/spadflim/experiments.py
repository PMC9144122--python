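"""Named end-to-end experiments, each runnable at reduced scale.

Every experiment maps a study question onto the simulation pipeline and
writes delimited-text tables plus a JSON summary (with the full
configuration and seed) into its own output directory, so any run can be
reproduced byte-identically.

Available experiments:

* ``precision`` — coefficient of variation of the fitted lifetime versus
  total photon counts, pile-up free (the 1/sqrt(Nc) law).
* ``lifetime-vs-rate`` — mean fitted lifetime versus count rate with
  pile-up on and off; the on-curve bends low, the off-curve stays flat.
* ``rate-scan`` — relative accuracy delta_tau versus count rate for one
  pixel count, with the self-calibrated threshold and maximum count rate.
* ``pixel-slope`` — maximum count rate versus pixel count and the
  through-origin slope (maximum count rate per pixel).
* ``resolution`` — relative accuracy versus histogram bin width from
  rebinned and refitted histograms.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig, save_config
from .estimation import FitError, coefficient_of_variation, relative_error
from .pileup_scan import (
    _replicate_taus as _replicate_taus_counted,
    calibrate_threshold,
    default_rate_grid,
    find_max_count_rate,
    fit_pixel_slope,
    scan_count_rate,
    scan_resolution,
)

__all__ = ["EXPERIMENTS", "run_experiment"]

logger = logging.getLogger("spadflim")


def _scaled(n_rep: int, scale: float) -> int:
    return max(3, int(round(n_rep * scale)))


def _replicate_taus(params, rate, n_rep, rng) -> np.ndarray:
    taus, failures = _replicate_taus_counted(params, rate, n_rep, rng)
    if failures:
        logger.warning("%d fits failed at rate %g; excluded", failures, rate)
    return taus


def _exp_precision(config: RunConfig, scale: float, rng) -> tuple[dict, dict]:
    """cv versus total photon counts without pile-up."""
    n_rep = _scaled(config.n_rep, scale)
    params = config.sim_params().with_detector(pileup_enabled=False)
    counts_grid = [100, 1_000, 10_000]
    rows = []
    cvs = []
    for n_counts in counts_grid:
        rate = n_counts / config.nw
        taus = _replicate_taus(params, rate, n_rep, rng)
        cv = coefficient_of_variation(taus)
        delta = relative_error(taus, config.tau0_ns)
        cvs.append(cv)
        rows.append((n_counts, rate, cv, delta, taus.size))
        logger.info("precision: Nc=%d cv=%.4f delta_tau=%.4f", n_counts, cv, delta)
    slope = float(
        np.polyfit(np.log10(counts_grid), np.log10(cvs), 1)[0]
    )
    tables = {
        "precision": (
            "n_counts,rate,cv,delta_tau,n_rep_effective",
            rows,
        )
    }
    return tables, {"loglog_slope_cv_vs_counts": slope, "n_rep": n_rep}


def _exp_lifetime_vs_rate(config: RunConfig, scale: float, rng) -> tuple[dict, dict]:
    """Mean fitted lifetime versus count rate, pile-up on and off."""
    n_rep = _scaled(config.n_rep, scale)
    grid = default_rate_grid(
        config.n_pixel,
        config.rate_lo_per_pixel,
        config.rate_hi_per_pixel,
        max(2, config.points_per_decade // 2),
    )
    tables = {}
    summary = {"n_rep": n_rep}
    for label, enabled in (("pileup_on", True), ("pileup_off", False)):
        params = config.sim_params().with_detector(pileup_enabled=enabled)
        rows = []
        for rate in grid:
            taus = _replicate_taus(params, float(rate), n_rep, rng)
            rows.append((rate, taus.mean(), taus.std(ddof=1), taus.size))
        tables[f"lifetime_vs_rate_{label}"] = (
            "rate,mean_tau_ns,sd_tau_ns,n_rep_effective",
            rows,
        )
        summary[f"mean_tau_at_max_rate_{label}"] = rows[-1][1]
    return tables, summary


def _exp_rate_scan(config: RunConfig, scale: float, rng) -> tuple[dict, dict]:
    """delta_tau versus count rate for the configured pixel count."""
    n_rep = _scaled(config.n_rep, scale)
    params = config.sim_params()
    threshold = calibrate_threshold(params, max(n_rep, 200), rng)
    grid = default_rate_grid(
        config.n_pixel,
        config.rate_lo_per_pixel,
        config.rate_hi_per_pixel,
        config.points_per_decade,
    )
    scan = scan_count_rate(config.n_pixel, grid, params, n_rep, rng)
    summary = {"threshold": threshold, "n_pixel": config.n_pixel, "n_rep": n_rep}
    try:
        summary["max_rate"] = find_max_count_rate(scan, threshold)
    except ValueError as exc:
        summary["max_rate"] = None
        summary["max_rate_error"] = str(exc)
    rows = list(
        zip(
            scan.rate_grid,
            scan.delta_tau,
            (scan.n_rep - scan.n_fit_failures).tolist(),
        )
    )
    return {"rate_scan": ("rate,delta_tau,n_rep_effective", rows)}, summary


def _exp_pixel_slope(config: RunConfig, scale: float, rng) -> tuple[dict, dict]:
    """Maximum count rate per pixel via scans over the pixel-count grid."""
    n_rep = _scaled(config.n_rep, scale)
    params = config.sim_params()
    # The threshold anchors every scan, so it gets extra replicates — the
    # Nc=1000 calibration measurements are cheap compared with the scans.
    threshold = calibrate_threshold(params, max(n_rep, 200), rng)
    logger.info("pixel-slope: self-calibrated threshold delta_tau*=%.4f", threshold)
    rows = []
    for n_pixel in config.pixel_counts:
        grid = default_rate_grid(
            n_pixel,
            config.rate_lo_per_pixel,
            config.rate_hi_per_pixel,
            config.points_per_decade,
        )
        scan = scan_count_rate(n_pixel, grid, params, n_rep, rng)
        max_rate = find_max_count_rate(scan, threshold)
        logger.info("pixel-slope: n_pixel=%d max_rate=%.3f", n_pixel, max_rate)
        rows.append((n_pixel, max_rate))
    fit = fit_pixel_slope([r[0] for r in rows], [r[1] for r in rows])
    summary = {
        "threshold": threshold,
        "slope": fit.slope,
        "n_rep": n_rep,
        "points": {str(n): r for n, r in rows},
    }
    return {"max_rate_vs_pixels": ("n_pixel,max_rate", rows)}, summary


def _exp_resolution(config: RunConfig, scale: float, rng) -> tuple[dict, dict]:
    """delta_tau versus time resolution (rebinning study)."""
    n_rep = _scaled(config.n_rep, scale)
    params = config.sim_params()
    scan = scan_resolution(
        params, np.asarray(config.tres_factors), n_rep, rng, rate=config.rate
    )
    rows = list(
        zip(
            scan.tres_factors,
            scan.rebin_factors.tolist(),
            scan.delta_tau,
            (scan.n_rep - scan.n_fit_failures).tolist(),
        )
    )
    summary = {
        "n_rep": n_rep,
        "delta_tau_finest": float(scan.delta_tau[0]),
        "delta_tau_coarsest": float(scan.delta_tau[-1]),
    }
    return {
        "resolution_scan": ("tres_factor,rebin_factor,delta_tau,n_rep_effective", rows)
    }, summary


EXPERIMENTS = {
    "precision": _exp_precision,
    "lifetime-vs-rate": _exp_lifetime_vs_rate,
    "rate-scan": _exp_rate_scan,
    "pixel-slope": _exp_pixel_slope,
    "resolution": _exp_resolution,
}


def _write_table(path: Path, header: str, rows) -> None:
    lines = [header]
    for row in rows:
        lines.append(
            ",".join(
                f"{v:.10g}" if isinstance(v, float) else str(v) for v in row
            )
        )
    path.write_text("\n".join(lines) + "\n")


def run_experiment(
    name: str,
    config: RunConfig,
    scale_factor: float = 1.0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run a named experiment and write its tables, summary and config.

    Randomness derives from ``config.seed`` through a per-experiment
    substream, so experiments are independent of one another and each run
    with the same seed reproduces its outputs byte-identically.
    """
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; available: {', '.join(sorted(EXPERIMENTS))}"
        )
    if scale_factor <= 0:
        raise ValueError(f"scale_factor must be > 0, got {scale_factor}")
    index = sorted(EXPERIMENTS).index(name)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
    logger.info("running experiment %s (scale %.3g, seed %d)", name, scale_factor, config.seed)
    tables, summary = EXPERIMENTS[name](config, scale_factor, rng)

    out = Path(out_dir) if out_dir is not None else Path(config.out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.json")
    for table_name, (header, rows) in tables.items():
        _write_table(out / f"{table_name}.csv", header, rows)
    summary_full = {
        "experiment": name,
        "seed": config.seed,
        "scale_factor": scale_factor,
        **summary,
    }
    (out / "summary.json").write_text(
        json.dumps(summary_full, indent=2, sort_keys=True, default=float) + "\n"
    )
    logger.info("experiment %s written to %s", name, out)
    return summary_full
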