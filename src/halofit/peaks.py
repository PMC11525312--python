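"""Peak windows, baselines, integrals, and ring-signal (double peak) geometry.

The quantification unit is a user-chosen peak window on a smoothed
chromatogram. A straight baseline spans the window, raw integrals are
computed with the trapezoidal rule on the sampling grid, and the net
integral is raw minus baseline. Ring-shaped (cytotoxically masked) signals
appear as double peaks; their two maxima delimit the outer legs, the only
part of the signal unaffected by the masking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import DataError, NotADoublePeakError, ParameterError
from .image import Chromatogram

#: Minimum prominence (grey values) for a local maximum to count as a ring
#: shoulder; suppresses residual noise maxima on smoothed profiles.
MIN_PROMINENCE = 2.0


@dataclass(frozen=True)
class PeakWindow:
    """Half-open analysis interval [start, end] in position units."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ParameterError("window start must lie before window end")

    def indices(self, chrom: Chromatogram) -> np.ndarray:
        sel = (chrom.positions >= self.start) & (chrom.positions <= self.end)
        idx = np.flatnonzero(sel)
        if len(idx) < 2:
            raise ParameterError("window covers fewer than two samples")
        if self.start < chrom.positions[0] or self.end > chrom.positions[-1]:
            raise ParameterError("window exceeds the chromatogram's range")
        return idx


@dataclass(frozen=True)
class Baseline:
    """Linear baseline through the window's two boundary intensities."""

    left_anchor: tuple[float, float]
    right_anchor: tuple[float, float]

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        (x0, y0), (x1, y1) = self.left_anchor, self.right_anchor
        return y0 + (np.asarray(x, dtype=float) - x0) * (y1 - y0) / (x1 - x0)


@dataclass
class LegSegment:
    """One outer leg, ordered from the shoulder apex outward to the window edge."""

    positions: np.ndarray
    intensities: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class DoublePeak:
    """Two ring shoulders, the valley between them, and the outer legs."""

    left_max: tuple[float, float]
    right_max: tuple[float, float]
    valley: tuple[float, float]
    left_leg: LegSegment
    right_leg: LegSegment
    detection_mode: str = "automatic"

    def __post_init__(self) -> None:
        if not (self.left_max[0] < self.valley[0] < self.right_max[0]):
            raise ParameterError("valley must lie between the two maxima")
        if len(self.left_leg) == 0 or len(self.right_leg) == 0:
            raise ParameterError("legs must be non-empty")

    def leg_data(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated leg samples in ascending position order."""
        x = np.concatenate([self.left_leg.positions[::-1], self.right_leg.positions])
        y = np.concatenate([self.left_leg.intensities[::-1], self.right_leg.intensities])
        return x, y


@dataclass(frozen=True)
class IntegralResult:
    raw_integral: float
    base_integral: float
    intersection_limited: bool = False
    status: str = "ok"

    @property
    def net_integral(self) -> float:
        return self.raw_integral - self.base_integral


def make_baseline(chrom: Chromatogram, window: PeakWindow) -> Baseline:
    """Straight line through the chromatogram's intensities at the window bounds."""
    idx = window.indices(chrom)
    i0, i1 = idx[0], idx[-1]
    return Baseline(
        left_anchor=(chrom.positions[i0], chrom.intensities[i0]),
        right_anchor=(chrom.positions[i1], chrom.intensities[i1]),
    )


def integrate_peak(
    chrom: Chromatogram, window: PeakWindow, baseline: Baseline | None = None
) -> IntegralResult:
    """Trapezoidal raw and baseline integrals of the data over the window."""
    if baseline is None:
        baseline = make_baseline(chrom, window)
    idx = window.indices(chrom)
    x = chrom.positions[idx]
    raw = float(np.trapezoid(chrom.intensities[idx], x))
    base = float(np.trapezoid(baseline(x), x))
    return IntegralResult(raw_integral=raw, base_integral=base)


def integrate_modelled_peak(
    model_positions: np.ndarray,
    model_curve: np.ndarray,
    baseline: Baseline,
) -> IntegralResult:
    """Net integral of a fitted model with intersection-restricted baseline.

    If the modelled curve crosses the baseline inside the window, the base
    integral is evaluated only between the outermost crossing points
    (located by piecewise-linear interpolation of the two sampled curves),
    which avoids overestimating the background under the model's flanks.
    Without a proper crossing pair the full-window base integral is used. A
    model that lies entirely below the baseline yields a warning status and
    a net integral of zero.
    """
    x = np.asarray(model_positions, dtype=float)
    y = np.asarray(model_curve, dtype=float)
    b = np.asarray(baseline(x), dtype=float)
    diff = y - b
    if np.all(diff < 0):
        base = float(np.trapezoid(b, x))
        return IntegralResult(float(np.trapezoid(y, x)), base, status="below-baseline")

    raw = float(np.trapezoid(y, x))
    crossings = _crossing_positions(x, diff)
    if len(crossings) >= 2 and np.any(diff < 0):
        lo, hi = crossings[0], crossings[-1]
        xs = np.concatenate([[lo], x[(x > lo) & (x < hi)], [hi]])
        base = float(np.trapezoid(baseline(xs), xs))
        return IntegralResult(raw, base, intersection_limited=True)
    base = float(np.trapezoid(b, x))
    return IntegralResult(raw, base)


def _crossing_positions(x: np.ndarray, diff: np.ndarray) -> list[float]:
    """Positions where a sampled curve changes sign (tangency excluded)."""
    out: list[float] = []
    s = np.sign(diff)
    for i in range(len(x) - 1):
        if s[i] == 0:
            continue  # exact touch handled as tangency, not a proper crossing
        if s[i + 1] != 0 and s[i + 1] != s[i]:
            t = diff[i] / (diff[i] - diff[i + 1])
            out.append(float(x[i] + t * (x[i + 1] - x[i])))
        elif s[i + 1] == 0 and i + 2 < len(x) and s[i + 2] == -s[i]:
            out.append(float(x[i + 1]))
    return out


def detect_double_peak(chrom: Chromatogram, window: PeakWindow) -> DoublePeak:
    """Locate the two ring shoulders and the valley of a masked signal.

    Local maxima within the window are found on the (smoothed) profile with
    a minimum prominence of 2 grey values; the two highest are taken as the
    ring shoulders, ties broken toward the widest-separated pair. Fewer than
    two maxima raise :class:`NotADoublePeakError` — define the outer legs
    manually in that case.
    """
    idx = window.indices(chrom)
    x = chrom.positions[idx]
    y = chrom.intensities[idx]
    peaks, _ = find_peaks(y, prominence=MIN_PROMINENCE)
    if len(peaks) < 2:
        raise NotADoublePeakError(
            "fewer than two local maxima in the window; not a double peak - "
            "define the outer legs manually"
        )
    li, ri = _best_pair(peaks, y)
    vi = li + 1 + int(np.argmin(y[li + 1 : ri])) if ri > li + 1 else li + 1
    return DoublePeak(
        left_max=(float(x[li]), float(y[li])),
        right_max=(float(x[ri]), float(y[ri])),
        valley=(float(x[vi]), float(y[vi])),
        left_leg=LegSegment(x[: li + 1][::-1].copy(), y[: li + 1][::-1].copy()),
        right_leg=LegSegment(x[ri:].copy(), y[ri:].copy()),
        detection_mode="automatic",
    )


def _best_pair(peaks: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Pair of maxima with the greatest summed height; ties to widest separation."""
    best = None
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            i, j = peaks[a], peaks[b]
            key = (y[i] + y[j], j - i)
            if best is None or key > best[0]:
                best = (key, (i, j))
    return best[1]


def define_legs_manual(
    chrom: Chromatogram, left_leg_window: PeakWindow, right_leg_window: PeakWindow
) -> DoublePeak:
    """Build a double peak from manually chosen leg windows.

    The shoulder apexes are taken as the inner endpoints of the two leg
    windows; used when automatic detection fails.
    """
    if left_leg_window.end >= right_leg_window.start:
        raise ParameterError("leg windows must be disjoint with the left one first")
    li = left_leg_window.indices(chrom)
    ri = right_leg_window.indices(chrom)
    x, y = chrom.positions, chrom.intensities
    lm, rm = li[-1], ri[0]
    if rm <= lm + 1:
        raise ParameterError("leg windows leave no interior samples for the valley")
    vi = lm + 1 + int(np.argmin(y[lm + 1 : rm]))
    return DoublePeak(
        left_max=(float(x[lm]), float(y[lm])),
        right_max=(float(x[rm]), float(y[rm])),
        valley=(float(x[vi]), float(y[vi])),
        left_leg=LegSegment(x[li][::-1].copy(), y[li][::-1].copy()),
        right_leg=LegSegment(x[ri].copy(), y[ri].copy()),
        detection_mode="manual",
    )


def trim_legs(dp: DoublePeak, coverage: float) -> DoublePeak:
    """Truncate the outer legs to a fraction of their length from the inflection.

    ``coverage`` = 1.0 returns the double peak unchanged (the whole outer
    legs). For smaller coverages each leg is reduced to
    ``ceil(coverage * len(leg))`` samples starting at the leg's inflection
    point — the steepest-slope sample, slope by central differences — and
    extending outward toward the window edge. This removes the flat
    transition next to the shoulder apex, which carries little information
    about the underlying peak's width and steepness.
    """
    if not 0 < coverage <= 1:
        raise ParameterError("coverage must lie in (0, 1]")
    if coverage == 1.0:
        return dp
    return replace(
        dp,
        left_leg=_trim_one(dp.left_leg, coverage),
        right_leg=_trim_one(dp.right_leg, coverage),
    )


def _trim_one(leg: LegSegment, coverage: float) -> LegSegment:
    n = len(leg)
    if n < 5:
        raise DataError("leg too short to locate an inflection point")
    slope = np.gradient(leg.intensities, leg.positions)
    infl = int(np.argmax(np.abs(slope)))
    keep = int(np.ceil(coverage * n))
    seg_end = min(infl + keep, n)
    if seg_end - infl < 2:
        raise DataError("trimmed leg degenerates to fewer than two samples")
    return LegSegment(leg.positions[infl:seg_end].copy(), leg.intensities[infl:seg_end].copy())
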