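"""Threshold-cycle (Ct) estimation from raw amplification curves.

The Ct of a well is the fractional cycle at which its baseline-corrected
fluorescence first *sustainably* crosses a threshold.  The steps mirror
common instrument practice:

1. fit a least-squares line to the fluorescence over a baseline window
   (default cycles 3-15; the first two cycles are excluded for settling
   artifacts) and subtract it, absorbing both constant offset and drift;
2. set the threshold to 10x the baseline noise SD (the classic "10 sigma"
   rule), floored at 1e-6 of the plate's maximum corrected fluorescence so
   a noise-free curve still gets a finite threshold;
3. locate the first crossing after which the signal stays at or above the
   threshold for at least two cycles (rejecting single-cycle spikes), and
   interpolate between the last sub-threshold and first supra-threshold
   cycle.  Interpolation is linear in log-fluorescence, which is exact for
   the exponential growth phase in which the threshold sits; it falls back
   to plain linear interpolation when the flanking value is non-positive.

A curve with no qualifying crossing within the run is UNDETERMINED
(``CtResult.ct is None``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AmplificationCurve", "CtResult", "baseline_correct", "compute_ct"]

DEFAULT_BASELINE_WINDOW: tuple[int, int] = (3, 15)
_SUSTAIN_CYCLES = 2
_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class AmplificationCurve:
    """Per-cycle fluorescence of one well/channel.

    Cycles are 1-based, strictly increasing and contiguous (instrument
    convention); fluorescence is in arbitrary units and non-negative for
    raw instrument data (baseline-corrected curves may go negative).
    """

    cycles: np.ndarray
    fluorescence: np.ndarray
    raw: bool = True

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=int)
        fluor = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluor)
        if cycles.ndim != 1 or fluor.ndim != 1 or len(cycles) != len(fluor):
            raise ValueError("cycles and fluorescence must be equal-length 1-D series")
        if len(cycles) < 3:
            raise ValueError("amplification curve needs at least 3 cycles")
        if not np.all(np.diff(cycles) == 1):
            raise ValueError("cycles must be strictly increasing and contiguous")
        if self.raw and np.any(fluor < 0):
            raise ValueError("raw fluorescence must be non-negative")

    @property
    def max_cycle(self) -> int:
        return int(self.cycles[-1])


@dataclass(frozen=True)
class CtResult:
    """A threshold cycle, or UNDETERMINED (``ct is None``), with provenance."""

    ct: float | None
    threshold: float
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0

    @property
    def determined(self) -> bool:
        return self.ct is not None

    def __repr__(self) -> str:  # compact: shows up in reports/logs
        ct = "UNDETERMINED" if self.ct is None else f"{self.ct:.2f}"
        return f"CtResult(ct={ct}, threshold={self.threshold:.4g})"


def _window_slice(curve: AmplificationCurve, window: tuple[int, int]) -> slice:
    lo, hi = window
    if hi - lo + 1 < 3:
        raise ValueError(f"baseline window {window} shorter than 3 cycles")
    first = int(curve.cycles[0])
    if lo < first or hi > curve.max_cycle:
        raise ValueError(f"baseline window {window} outside curve cycles")
    return slice(lo - first, hi - first + 1)


def baseline_correct(
    curve: AmplificationCurve,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> AmplificationCurve:
    """Subtract a least-squares line fitted over ``baseline_window``.

    Constant offsets and linear drift are absorbed exactly; the corrected
    fluorescence may be negative.
    """
    sl = _window_slice(curve, baseline_window)
    x = curve.cycles[sl].astype(float)
    y = curve.fluorescence[sl]
    slope, intercept = np.polyfit(x, y, 1)
    corrected = curve.fluorescence - (slope * curve.cycles + intercept)
    return AmplificationCurve(curve.cycles, corrected, raw=False)


def baseline_stats(
    curve: AmplificationCurve,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> tuple[float, float]:
    """Mean and SD of the baseline-corrected signal over the window.

    The SD has ddof=2 because the baseline fit removed two parameters.
    """
    corrected = baseline_correct(curve, baseline_window) if curve.raw else curve
    sl = _window_slice(corrected, baseline_window)
    resid = corrected.fluorescence[sl]
    sd = float(np.std(resid, ddof=2)) if len(resid) > 2 else 0.0
    return float(np.mean(resid)), sd


def pooled_threshold(
    curves: list[AmplificationCurve],
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> float:
    """One auto threshold for a group of wells measured together.

    Baseline noise is an instrument/channel property, so pooling across
    wells (median of per-well baseline SDs — robust to wells whose
    amplification encroaches on the window) estimates it far more
    precisely than any single 13-cycle window can; the threshold is the
    same 10-sigma rule with the same plate-maximum floor.
    """
    if not curves:
        raise ValueError("no curves to pool")
    corrected = [
        baseline_correct(c, baseline_window) if c.raw else c for c in curves
    ]
    sds = [baseline_stats(c, baseline_window)[1] for c in corrected]
    plate_max = max(float(np.max(c.fluorescence)) for c in corrected)
    return max(10.0 * float(np.median(sds)), _FLOOR_FRACTION * plate_max)


def _interpolate_crossing(
    c0: float, f0: float, c1: float, f1: float, threshold: float
) -> float:
    if f0 > 0.0:
        # log-linear: exact for exponential-phase growth
        return c0 + (math.log(threshold) - math.log(f0)) / (math.log(f1) - math.log(f0))
    return c0 + (threshold - f0) / (f1 - f0)


def compute_ct(
    curve: AmplificationCurve,
    mode: str = "auto",
    fixed_threshold: float | None = None,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    plate_max: float | None = None,
) -> CtResult:
    """Estimate the threshold cycle of one amplification curve.

    Parameters
    ----------
    mode
        ``"auto"`` sets threshold = 10 x baseline SD (floored at 1e-6 of
        ``plate_max``); ``"fixed"`` uses ``fixed_threshold`` as given on the
        baseline-corrected scale.
    plate_max
        Maximum baseline-corrected fluorescence over the plate's amplifying
        wells, used for the auto-threshold floor.  Defaults to this curve's
        own maximum when processing a curve in isolation.
    """
    corrected = baseline_correct(curve, baseline_window) if curve.raw else curve
    baseline_mean, baseline_sd = baseline_stats(corrected, baseline_window)

    if mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed mode requires fixed_threshold")
        threshold = float(fixed_threshold)
    elif mode == "auto":
        if plate_max is None:
            plate_max = float(np.max(corrected.fluorescence))
        threshold = max(10.0 * baseline_sd, _FLOOR_FRACTION * plate_max)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if threshold <= 0.0:
        return CtResult(None, threshold, baseline_mean, baseline_sd)

    f = corrected.fluorescence
    c = corrected.cycles
    n = len(f)
    for i in range(1, n):
        if f[i] >= threshold and f[i - 1] < threshold:
            # sustained-crossing guard: stay above threshold >= 2 cycles
            if i + _SUSTAIN_CYCLES - 1 < n and np.all(f[i : i + _SUSTAIN_CYCLES] >= threshold):
                ct = _interpolate_crossing(
                    float(c[i - 1]), float(f[i - 1]), float(c[i]), float(f[i]), threshold
                )
                return CtResult(float(ct), threshold, baseline_mean, baseline_sd)
    return CtResult(None, threshold, baseline_mean, baseline_sd)
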