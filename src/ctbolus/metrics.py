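"""Contrast arrival time, peak time and peak CT number from time-density curves.

Definitions follow test-bolus practice at CT angiography: the arrival time
(CM-AT) is the instant the aortic enhancement first rises a threshold
(default 30 HU) above the unenhanced baseline, minus a fixed lead (default
2 s); the peak time (PT) is measured from the start of contrast injection
to the maximal CT number; the peak CT number (PCTN) is that maximum.
Curves are treated as piecewise-linear between samples.

For measured (noisy, 1-Hz) monitoring curves, :func:`measured_metrics`
applies Savitzky-Golay smoothing and a parabolic refinement of the peak
before extraction — the raw maximum of a noisy sampled curve is biased
upward by the noise amplitude, which would contaminate any downstream fit
of the HU conversion coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .transport import TimeDensityCurve

__all__ = [
    "EnhancementMetrics",
    "NoArrivalError",
    "arrival_time",
    "peak",
    "extract_metrics",
    "measured_metrics",
    "CardiacIndexWindow",
    "threshold_window",
]

log = logging.getLogger(__name__)


class NoArrivalError(ValueError):
    """The curve never rises ``threshold_delta`` HU above baseline."""


@dataclass(frozen=True)
class EnhancementMetrics:
    """CM-AT, PT and PCTN extracted from one time-density curve."""

    cm_at: float          # s
    pt: float             # s from injection start
    pctn: float           # HU
    threshold_delta: float = 30.0
    lead: float = 2.0

    def __post_init__(self) -> None:
        if self.cm_at > self.pt + 1e-9:
            raise ValueError("arrival time cannot follow the peak")


def arrival_time(curve: TimeDensityCurve, threshold_delta: float = 30.0,
                 lead: float = 2.0) -> float:
    """Contrast arrival time (s): threshold crossing minus the lead.

    The first time the enhancement exceeds ``baseline + threshold_delta``
    is located by linear interpolation between samples; ``lead`` seconds
    (default 2) are subtracted.  A negative result is clamped to zero and
    logged.
    """
    enh = curve.enhancement - curve.baseline_hu
    above = enh >= threshold_delta
    if not np.any(above):
        raise NoArrivalError(
            f"curve {curve.roi!r} never reaches {threshold_delta} HU "
            "above baseline")
    i = int(np.argmax(above))
    if i == 0:
        t_cross = float(curve.time[0])
    else:
        t0, t1 = curve.time[i - 1], curve.time[i]
        y0, y1 = enh[i - 1], enh[i]
        t_cross = float(t0 + (threshold_delta - y0) / (y1 - y0) * (t1 - t0))
    at = t_cross - lead
    if at < 0:
        log.warning("arrival time %.2f s before injection start clamped to 0",
                    -at)
        at = 0.0
    return at


def peak(curve: TimeDensityCurve) -> tuple[float, float]:
    """(peak time s, peak CT number HU); ties broken by earliest time."""
    if len(curve.time) == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(curve.enhancement))
    return float(curve.time[i]), float(curve.enhancement[i])


def extract_metrics(curve: TimeDensityCurve, threshold_delta: float = 30.0,
                    lead: float = 2.0) -> EnhancementMetrics:
    """All three enhancement metrics of one (noise-free) curve."""
    pt, pctn = peak(curve)
    at = arrival_time(curve, threshold_delta, lead)
    return EnhancementMetrics(cm_at=min(at, pt), pt=pt, pctn=pctn,
                              threshold_delta=threshold_delta, lead=lead)


def measured_metrics(curve: TimeDensityCurve, threshold_delta: float = 30.0,
                     lead: float = 2.0, smooth_window: int = 5,
                     smooth_order: int = 2) -> EnhancementMetrics:
    """Metrics of a noisy sampled curve, with smoothing and peak refinement.

    The curve is Savitzky-Golay filtered (``smooth_window`` samples,
    polynomial order ``smooth_order``); the peak is then refined by a
    quadratic fit through the samples around the discrete maximum, whose
    vertex gives PT and PCTN with far less noise-induced upward bias than
    the raw sample maximum.
    """
    n = len(curve.time)
    if n < smooth_window:
        smoothed = curve
    else:
        sm = savgol_filter(curve.enhancement, smooth_window, smooth_order)
        smoothed = TimeDensityCurve(
            roi=curve.roi, time=curve.time,
            iodine_concentration=curve.iodine_concentration,
            enhancement=sm, baseline_hu=curve.baseline_hu)
    at = arrival_time(smoothed, threshold_delta, lead)
    i = int(np.argmax(smoothed.enhancement))
    lo, hi = max(0, i - 2), min(n, i + 3)
    if hi - lo >= 3:
        coeff = np.polyfit(smoothed.time[lo:hi], smoothed.enhancement[lo:hi], 2)
        if coeff[0] < 0:
            tv = -coeff[1] / (2 * coeff[0])
            tv = float(np.clip(tv, smoothed.time[lo], smoothed.time[hi - 1]))
            pt, pctn = tv, float(np.polyval(coeff, tv))
        else:
            pt, pctn = peak(smoothed)
    else:
        pt, pctn = peak(smoothed)
    return EnhancementMetrics(cm_at=min(at, pt), pt=pt, pctn=pctn,
                              threshold_delta=threshold_delta, lead=lead)


# --------------------------------------------------------------------------
# cardiac-index threshold windows
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CardiacIndexWindow:
    """Cardiac-index interval over which PCTN stays above a threshold.

    ``upper_open`` means the PCTN never dropped below the threshold before
    the top of the evaluated grid, reported as e.g. "> 6.00".
    """

    ci_min: float | None
    ci_max: float | None
    upper_open: bool = False

    @property
    def empty(self) -> bool:
        return self.ci_min is None

    @property
    def width(self) -> float:
        """Window width on the grid; open upper ends use the grid maximum."""
        if self.empty:
            return 0.0
        return self.ci_max - self.ci_min

    def format_max(self) -> str:
        if self.empty:
            return "-"
        return f"> {self.ci_max:.2f}" if self.upper_open else f"{self.ci_max:.2f}"

    def format_min(self) -> str:
        return "-" if self.empty else f"{self.ci_min:.2f}"


def threshold_window(pctn_by_ci: dict[float, float] | "np.ndarray",
                     threshold: float,
                     ci_grid: np.ndarray | None = None) -> CardiacIndexWindow:
    """Smallest/largest grid cardiac index with PCTN >= ``threshold``.

    Accepts either a ``{cardiac_index: PCTN}`` mapping or a PCTN array
    with an explicit ``ci_grid``.  An all-below curve yields an empty
    window; a PCTN still above threshold at the top of the grid is
    reported with an open upper end.
    """
    if ci_grid is None:
        items = sorted(pctn_by_ci.items())
        ci = np.array([c for c, _ in items])
        val = np.array([v for _, v in items])
    else:
        ci = np.asarray(ci_grid, dtype=float)
        val = np.asarray(pctn_by_ci, dtype=float)
        order = np.argsort(ci)
        ci, val = ci[order], val[order]
    ok = val >= threshold
    if not np.any(ok):
        return CardiacIndexWindow(None, None)
    idx = np.nonzero(ok)[0]
    upper_open = bool(idx[-1] == len(ci) - 1)
    return CardiacIndexWindow(float(ci[idx[0]]), float(ci[idx[-1]]),
                              upper_open=upper_open)
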