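"""Ks peak fitting, lineage rate correction, and event dating.

Event-related Ks values pile up in peaks whose position tracks event age
scaled by the lineage substitution rate. The density of a Ks set is
estimated with a Gaussian kernel, a single Gaussian is least-squares
fitted to the density curve, and the shared-event peak (the eudicot
hexaploidization) is used to align lineage clocks: the slowest genome is
the reference, each lineage gets a factor λ = μ_lineage/μ_reference, and
within-genome Ks divide by λ while cross-genome Ks divide by the mean of
the two lineage factors. Dates follow by proportionality against the
hexaploidization calibration interval (115–130 Mya by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

DEFAULT_CALIBRATION = (115.0, 130.0)  # Mya bounds of the shared hexaploidization


@dataclass(frozen=True)
class GaussianPeak:
    mu: float
    sigma: float
    amplitude: float
    r2: float
    n: int  # values inside the fitted range


@dataclass(frozen=True)
class RateCorrection:
    reference_tag: str
    factors: dict[str, float]  # species -> λ ≥ 1, λ_reference = 1

    def adjust_within(self, tag: str, values):
        return np.asarray(values, dtype=float) / self.factors[tag]

    def adjust_cross(self, tag_a: str, tag_b: str, values):
        lam = 0.5 * (self.factors[tag_a] + self.factors[tag_b])
        return np.asarray(values, dtype=float) / lam

    def adjust_peak(self, tag: str, mu: float) -> float:
        return mu / self.factors[tag]

    def adjust_cross_peak(self, tag_a: str, tag_b: str, mu: float) -> float:
        return mu / (0.5 * (self.factors[tag_a] + self.factors[tag_b]))


@dataclass(frozen=True)
class DateEstimate:
    event: str
    t_low: float  # Mya
    t_high: float
    calibration: tuple[float, float]
    peak_ratio: float


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_peak(
    ks_values,
    ks_range: tuple[float, float],
    bandwidth: float | str | None = None,
    grid_points: int = 512,
) -> GaussianPeak:
    """Gaussian-kernel density of the Ks values over ``ks_range``, then a
    single-Gaussian least-squares fit to the density curve.

    Scott's rule sets the kernel bandwidth unless overridden. At least 30
    values must fall inside the range.
    """
    values = np.asarray(ks_values, dtype=float)
    values = values[np.isfinite(values)]
    values = values[(values >= ks_range[0]) & (values <= ks_range[1])]
    if len(values) < 30:
        raise ValueError(
            f"need >= 30 Ks values in range {ks_range}, got {len(values)}"
        )
    x = np.linspace(ks_range[0], ks_range[1], grid_points)
    if values.std() < 1e-3:  # degenerate: essentially a point mass
        return GaussianPeak(mu=float(values.mean()),
                            sigma=max(float(values.std()), 1e-6),
                            amplitude=np.inf, r2=1.0, n=len(values))
    kde = stats.gaussian_kde(values, bw_method=bandwidth or "scott")
    density = kde(x)
    p0 = (float(density.max()), float(x[int(np.argmax(density))]), float(values.std()))
    try:
        popt, _ = curve_fit(_gauss, x, density, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Gaussian fit failed to converge on {len(values)} values "
            f"in {ks_range}: {err}"
        ) from err
    amplitude, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    resid = density - _gauss(x, *popt)
    ss_tot = float(((density - density.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return GaussianPeak(mu=mu, sigma=sigma, amplitude=amplitude, r2=r2, n=len(values))


def correct_rates(shared_event_peaks: dict[str, GaussianPeak | float]) -> RateCorrection:
    """Per-lineage correction factors from the shared-event peaks.

    The species with the smallest peak is the (slowest) reference;
    λ_s = μ_s / μ_reference. After dividing each genome's Ks by λ (and
    cross-genome Ks by the averaged factors) the shared-event peaks align.
    """
    if len(shared_event_peaks) < 2:
        raise ValueError("need shared-event peaks for at least 2 species")
    mus = {
        tag: (peak.mu if isinstance(peak, GaussianPeak) else float(peak))
        for tag, peak in shared_event_peaks.items()
    }
    for tag, mu in mus.items():
        if mu <= 0:
            raise ValueError(f"non-positive shared-event peak for {tag}: {mu}")
    reference = min(sorted(mus), key=lambda t: mus[t])
    factors = {tag: mu / mus[reference] for tag, mu in mus.items()}
    return RateCorrection(reference_tag=reference, factors=factors)


def rate_excess(mu_fast: float, mu_slow: float) -> float:
    """Percent rate excess of the fast lineage: 100 (μ_fast − μ_slow)/μ_slow."""
    if mu_slow <= 0:
        raise ValueError("mu_slow must be positive")
    return 100.0 * (mu_fast - mu_slow) / mu_slow


def date_event(
    mu_event_adjusted: float,
    mu_calibration_adjusted: float,
    calibration: tuple[float, float] = DEFAULT_CALIBRATION,
    event: str = "event",
) -> DateEstimate:
    """Proportional dating: age bounds = (μ_event/μ_calibration) × calibration.

    Reported to 2 decimals (Mya). A ratio above 1.5 — the event would
    substantially predate the calibration — draws a warning.
    """
    if mu_event_adjusted <= 0 or mu_calibration_adjusted <= 0:
        raise ValueError("peaks must be positive")
    ratio = mu_event_adjusted / mu_calibration_adjusted
    if ratio > 1.5:
        logger.warning(
            "event/calibration peak ratio %.3f > 1.5: the dated event would "
            "substantially predate the calibration", ratio,
        )
    t_low, t_high = (round(ratio * c, 2) for c in calibration)
    return DateEstimate(event=event, t_low=t_low, t_high=t_high,
                        calibration=tuple(calibration), peak_ratio=ratio)


def density_curve(ks_values, ks_range, bandwidth=None, grid_points: int = 512):
    """(x, density) of the Gaussian KDE — plot data for Ks panels."""
    values = np.asarray(ks_values, dtype=float)
    values = values[np.isfinite(values)]
    values = values[(values >= ks_range[0]) & (values <= ks_range[1])]
    x = np.linspace(ks_range[0], ks_range[1], grid_points)
    return x, stats.gaussian_kde(values, bw_method=bandwidth or "scott")(x)
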