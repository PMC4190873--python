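"""Chromatographic peak detection, integration and QC for SRM traces.

A trace is the intensity of one transition as a function of retention
time.  Apex finding runs on a lightly smoothed signal (5-point moving
average); integration is trapezoidal on the raw samples with the
baseline portion subtracted.  Because the heavy internal standard is
always present while the endogenous (light) peptide may be absent,
integration boundaries for light peaks are anchored on the co-eluting
heavy peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedScoreError

MIN_TRACE_POINTS = 8


@dataclass
class ChromatogramTrace:
    """Retention-time / intensity series for one transition.

    Times are in minutes and strictly increasing; intensities are
    non-negative and finite.  ``meta`` carries identifying fields
    (sample_id, protein_id, peptide_sequence, is_heavy, fragment_label).
    """

    times: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise InvalidInputError("times and intensities must be equal-length 1-D")
        if len(self.times) < MIN_TRACE_POINTS:
            raise InvalidInputError(
                f"trace needs >= {MIN_TRACE_POINTS} points, got {len(self.times)}"
            )
        if not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("retention times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise InvalidInputError("intensities must be finite and non-negative")


@dataclass(frozen=True)
class PeakResult:
    """Integrated peak: apex, boundaries, background-subtracted area.

    ``area`` and ``background`` are in intensity·min; ``background`` is
    the baseline portion under the peak (baseline level x width).
    """

    apex_rt: float
    left_rt: float
    right_rt: float
    area: float
    background: float
    snr: float

    def __post_init__(self) -> None:
        if not self.left_rt <= self.apex_rt <= self.right_rt:
            raise InvalidInputError("apex must lie within integration bounds")
        if self.area < 0 or self.background < 0:
            raise InvalidInputError("area and background must be non-negative")


def smooth(intensities: np.ndarray, width: int = 5) -> np.ndarray:
    """Centred moving average with edge truncation (window shrinks at ends)."""
    x = np.asarray(intensities, dtype=float)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def noise_sd(intensities: np.ndarray) -> float:
    """Robust noise SD from median absolute successive differences.

    First differences cancel slowly varying structure (peaks, baseline
    drift), so the estimate reflects point-to-point noise only.
    """
    d = np.diff(np.asarray(intensities, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def detect_peak(
    trace: ChromatogramTrace,
    rt_window: tuple[float, float],
    k: float = 3.0,
    smooth_width: int = 5,
) -> float | None:
    """Apex retention time of the smoothed maximum inside the window.

    Returns None when the maximum does not rise more than ``k`` noise
    SDs above the baseline (median intensity of the whole trace) —
    i.e. no credible peak.
    """
    lo, hi = rt_window
    if lo >= hi:
        raise InvalidInputError("rt_window must satisfy lo < hi")
    if lo < trace.times[0] or hi > trace.times[-1]:
        raise InvalidInputError(
            f"rt_window ({lo}, {hi}) outside trace range "
            f"({trace.times[0]}, {trace.times[-1]})"
        )
    sm = smooth(trace.intensities, smooth_width)
    mask = (trace.times >= lo) & (trace.times <= hi)
    if not mask.any():
        raise InvalidInputError("rt_window contains no trace points")
    idx = np.flatnonzero(mask)
    apex_local = idx[np.argmax(sm[idx])]
    baseline = float(np.median(trace.intensities))
    sd = noise_sd(trace.intensities)
    if sm[apex_local] <= baseline + k * sd:
        return None
    return float(trace.times[apex_local])


def estimate_background(
    trace: ChromatogramTrace, exclusion: tuple[float, float]
) -> float:
    """Baseline level: median intensity outside the exclusion window."""
    lo, hi = exclusion
    if lo >= hi:
        raise InvalidInputError("exclusion must satisfy lo < hi")
    outside = (trace.times < lo) | (trace.times > hi)
    if not outside.any():
        raise InvalidInputError("exclusion region covers the whole trace")
    return float(np.median(trace.intensities[outside]))


def integrate_peak(
    trace: ChromatogramTrace,
    left_rt: float,
    right_rt: float,
    baseline: float | None = None,
) -> PeakResult:
    """Trapezoidal peak integration over [left_rt, right_rt].

    area = raw trapezoidal integral − baseline x width, clipped at zero;
    background = baseline x width.  When ``baseline`` is not given it is
    estimated as the median intensity outside the integration bounds.
    """
    if not left_rt < right_rt:
        raise InvalidInputError("integration bounds must satisfy left < right")
    if left_rt < trace.times[0] or right_rt > trace.times[-1]:
        raise InvalidInputError("integration bounds outside trace range")
    if baseline is None:
        baseline = estimate_background(trace, (left_rt, right_rt))
    # sample grid restricted to the bounds, with interpolated endpoints
    inner = (trace.times > left_rt) & (trace.times < right_rt)
    t = np.concatenate(([left_rt], trace.times[inner], [right_rt]))
    y = np.concatenate(
        (
            [np.interp(left_rt, trace.times, trace.intensities)],
            trace.intensities[inner],
            [np.interp(right_rt, trace.times, trace.intensities)],
        )
    )
    raw = float(np.trapezoid(y, t))
    width = right_rt - left_rt
    background = max(float(baseline), 0.0) * width
    area = max(raw - background, 0.0)
    inner_max = float(np.max(y))
    sd = noise_sd(trace.intensities)
    snr = float("inf") if sd == 0 else (inner_max - baseline) / sd
    apex_rt = float(t[np.argmax(y)])
    return PeakResult(
        apex_rt=apex_rt,
        left_rt=left_rt,
        right_rt=right_rt,
        area=area,
        background=background,
        snr=snr,
    )


def peak_bounds(
    trace: ChromatogramTrace,
    apex_rt: float,
    frac: float = 0.05,
    smooth_width: int = 5,
) -> tuple[float, float]:
    """Integration bounds: where the smoothed signal falls below
    ``frac`` of its apex height above baseline, walking out from the apex.

    Used on the heavy-standard trace to anchor boundaries for both
    members of a light/heavy pair.
    """
    if not trace.times[0] <= apex_rt <= trace.times[-1]:
        raise InvalidInputError("apex outside trace range")
    sm = smooth(trace.intensities, smooth_width)
    baseline = float(np.median(trace.intensities))
    apex_idx = int(np.argmin(np.abs(trace.times - apex_rt)))
    threshold = baseline + frac * max(sm[apex_idx] - baseline, 0.0)
    left = apex_idx
    while left > 0 and sm[left - 1] > threshold:
        left -= 1
    right = apex_idx
    n = len(sm)
    while right < n - 1 and sm[right + 1] > threshold:
        right += 1
    return float(trace.times[left]), float(trace.times[right])


def coelution_check(
    light_apexes: Sequence[float],
    heavy_apexes: Sequence[float],
    rt_tol: float = 0.2,
) -> tuple[bool, float]:
    """Light/heavy apex agreement: pass iff every |Δrt| <= rt_tol.

    Returns (passed, maximum deviation in minutes).  Symmetric in its
    two apex lists.
    """
    light = np.asarray(light_apexes, dtype=float)
    heavy = np.asarray(heavy_apexes, dtype=float)
    if light.size == 0 or heavy.size == 0:
        raise InvalidInputError("apex lists must be non-empty")
    if light.shape != heavy.shape:
        raise InvalidInputError("light and heavy apex lists must match in length")
    max_dev = float(np.max(np.abs(light - heavy)))
    return max_dev <= rt_tol, max_dev


def transition_rank_similarity(
    observed_areas: Sequence[float], library_intensities: Sequence[float]
) -> float:
    """Cosine similarity between observed and library intensity patterns.

    1 for proportional vectors, 0 for orthogonal; scale-invariant, so it
    checks relative transition ranking rather than absolute response.
    """
    obs = np.asarray(observed_areas, dtype=float)
    lib = np.asarray(library_intensities, dtype=float)
    if obs.shape != lib.shape or obs.size < 2:
        raise InvalidInputError("vectors must have equal length >= 2")
    n_obs = np.linalg.norm(obs)
    n_lib = np.linalg.norm(lib)
    if n_obs == 0 or n_lib == 0:
        raise UndefinedScoreError("similarity undefined for an all-zero vector")
    return float(np.dot(obs, lib) / (n_obs * n_lib))
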