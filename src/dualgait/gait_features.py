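"""From raw phase streams to the 12-dimensional feature vector.

Gait is summarised per trial by four quantities in each task context:

* mean and standard deviation of the *step interval* — the time between two
  consecutive floor contacts of alternating feet (the stepping-speed proxy;
  kept in interval-seconds, not inverted to a rate);
* mean and standard deviation of the *knee-raise amplitude* — per raise
  cycle, the difference between the extended knee angle observed at floor
  contact and the maximally flexed angle at the top of the raise, pooled
  over both legs.

The knee angle is the interior angle at the knee between the segments
knee->hip-centre and knee->ankle, in radians, so that knee-lift height is
normalised across subjects of different stature.  Two cognitive features
(correct-answer rate, mean response time) complete the six per context;
single-task gait comes from the single physical phase, single-task
calculation from the single cognitive phase and all six dual features from
the dual phase: 6 x 2 = 12 features per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import (DegenerateGeometryError, IncompleteTrialError,
                     MissingFeatureError)
from .types import (PHASE_COGNITIVE, PHASE_DUAL, PHASE_PHYSICAL, CalcResponse,
                    FeatureVector, FrameBlock, KneeAngleSeries, Phase,
                    RaiseCycle, SkeletonFrame, StepEvent, TrialSession)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionParams:
    """Tunables of the peak/valley gait-cycle segmentation.

    ``smooth_window_s``: centred moving-average window applied before
    extremum search (absorbs skeleton jitter); ``min_prominence_rad``:
    minimum prominence of a flexion valley for it to count as a raise;
    ``min_separation_s``: minimum time between consecutive valleys, sized to
    adult stepping cadence.  ``population_sd`` selects the 1/n standard
    deviation convention (the default) over the sample 1/(n-1) one.
    """

    smooth_window_s: float = 0.3
    min_prominence_rad: float = 0.05
    min_separation_s: float = 0.4
    population_sd: bool = True


def _sd(values: np.ndarray, population: bool = True) -> float:
    if values.size == 1:
        return 0.0
    return float(np.std(values, ddof=0 if population else 1))


def knee_angle(hip: Sequence[float], knee: Sequence[float],
               ankle: Sequence[float]) -> float:
    """Interior angle at the knee between knee->hip and knee->ankle (rad).

    Computed via atan2 of the cross/dot products for numerical stability
    near 0 and pi.  Raises :class:`DegenerateGeometryError` when either limb
    segment has zero length.
    """
    hip = np.asarray(hip, dtype=float)
    knee = np.asarray(knee, dtype=float)
    ankle = np.asarray(ankle, dtype=float)
    u = hip - knee
    v = ankle - knee
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length limb segment at the knee")
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(u @ v)
    return float(np.arctan2(cross, dot))


def _angles_block(frames: FrameBlock, side: str) -> np.ndarray:
    hip = frames.hip_center
    knee = getattr(frames, f"{side}_knee")
    ankle = getattr(frames, f"{side}_ankle")
    u = hip - knee
    v = ankle - knee
    cross = np.linalg.norm(np.cross(u, v), axis=1)
    dot = np.einsum("ij,ij->i", u, v)
    return np.arctan2(cross, dot)


def knee_angle_series(frames: FrameBlock | Iterable[SkeletonFrame],
                      side: str) -> KneeAngleSeries:
    """Per-frame knee angle for one leg.

    Frames with degenerate geometry (coincident joints) are dropped with a
    logged count; an all-degenerate or <2-frame input is an error.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if not isinstance(frames, FrameBlock):
        frames = FrameBlock.from_frames(list(frames))
    if len(frames) < 2:
        raise MissingFeatureError(
            f"{side} knee angle series", "fewer than 2 frames")
    hip = frames.hip_center
    knee = getattr(frames, f"{side}_knee")
    ankle = getattr(frames, f"{side}_ankle")
    ok = (np.linalg.norm(hip - knee, axis=1) > 0) \
        & (np.linalg.norm(ankle - knee, axis=1) > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropping %d degenerate frame(s) for %s leg", n_bad, side)
    if ok.sum() < 2:
        raise MissingFeatureError(
            f"{side} knee angle series", "all frames degenerate")
    sub = FrameBlock(frames.t[ok], hip[ok], frames.left_knee[ok],
                     frames.right_knee[ok], frames.left_ankle[ok],
                     frames.right_ankle[ok])
    return KneeAngleSeries(t=sub.t, angle=_angles_block(sub, side), side=side)


def _smooth(t: np.ndarray, x: np.ndarray, window_s: float) -> np.ndarray:
    """Centred moving average over a time window (index-based width from the
    median sampling interval; timestamps need not be perfectly uniform)."""
    if window_s <= 0 or len(x) < 3:
        return x
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        return x
    half = max(int(round(window_s / (2 * dt))), 0)
    if half == 0:
        return x
    kernel = np.ones(2 * half + 1)
    padded = np.pad(x, half, mode="edge")
    return np.convolve(padded, kernel / kernel.size, mode="valid")


def detect_raise_cycles(series: KneeAngleSeries,
                        params: ExtractionParams | None = None
                        ) -> list[RaiseCycle]:
    """Segment a knee-angle trace into raise cycles.

    Flexion valleys are local minima of the smoothed angle with the
    configured prominence and separation; each valley is paired with the
    larger of the raw-angle maxima on its two flanks (the extended,
    near-floor angle).  Peak and valley values are read from the *raw*
    series at the extremum refined within the neighbourhood of the smoothed
    extremum, so smoothing does not bias the amplitude.  A trace with no
    qualifying extrema (e.g. a subject standing still) yields an empty list.
    """
    params = params or ExtractionParams()
    if len(series) == 0:
        raise MissingFeatureError("raise cycles", "empty angle series")
    t = series.t
    x = series.angle
    duration = float(t[-1] - t[0])
    if duration <= params.min_separation_s:
        raise MissingFeatureError(
            "raise cycles",
            f"series duration {duration:.2f} s <= min separation")
    smoothed = _smooth(t, x, params.smooth_window_s)
    dt = float(np.median(np.diff(t)))
    distance = max(int(round(params.min_separation_s / dt)), 1)
    valleys, _ = find_peaks(-smoothed, prominence=params.min_prominence_rad,
                            distance=distance)
    if valleys.size == 0:
        return []

    refine = max(int(round(params.smooth_window_s / (2 * dt))), 1)

    def _refined_min(i: int) -> int:
        lo, hi = max(i - refine, 0), min(i + refine + 1, len(x))
        return lo + int(np.argmin(x[lo:hi]))

    cycles: list[RaiseCycle] = []
    bounds = np.concatenate(([0], valleys, [len(x) - 1]))
    for k, v in enumerate(valleys):
        vi = _refined_min(int(v))
        left_lo, right_hi = int(bounds[k]), int(bounds[k + 2])
        left_seg = x[left_lo:vi + 1]
        right_seg = x[vi:right_hi + 1]
        li = left_lo + int(np.argmax(left_seg))
        ri = vi + int(np.argmax(right_seg))
        pi = li if x[li] >= x[ri] else ri
        cycles.append(RaiseCycle(
            peak_t=float(t[pi]), valley_t=float(t[vi]),
            peak_angle=float(x[pi]), valley_angle=float(x[vi]),
            amplitude=float(x[pi] - x[vi])))
    return cycles


def knee_amplitude_stats(cycles: Sequence[RaiseCycle],
                         population_sd: bool = True) -> tuple[float, float]:
    """Mean and standard deviation of per-cycle raise amplitudes."""
    if len(cycles) == 0:
        raise MissingFeatureError("knee amplitude", "no raise cycles detected")
    amps = np.array([c.amplitude for c in cycles], dtype=float)
    return float(np.mean(amps)), _sd(amps, population_sd)


def step_intervals(events: Sequence[StepEvent]) -> np.ndarray:
    """Successive inter-step times restricted to alternating-foot pairs.

    Consecutive same-foot contacts (a stumble or sensor glitch) contribute
    no interval; each skipped pair is logged.
    """
    out = []
    for a, b in zip(events, events[1:]):
        if a.foot == b.foot:
            log.warning("skipping same-foot step pair at t=%.3f/%.3f", a.t, b.t)
            continue
        out.append(b.t - a.t)
    return np.asarray(out, dtype=float)


def step_interval_stats(events: Sequence[StepEvent],
                        population_sd: bool = True) -> tuple[float, float]:
    """Mean and standard deviation of alternating-foot step intervals."""
    if len(events) < 2:
        raise MissingFeatureError("step interval", "fewer than 2 step events")
    intervals = step_intervals(events)
    if intervals.size == 0:
        raise MissingFeatureError("step interval",
                                  "no alternating-foot step pairs")
    return float(np.mean(intervals)), _sd(intervals, population_sd)


def answer_stats(responses: Sequence[CalcResponse]) -> tuple[float, float]:
    """Correct-answer rate and mean response time over answered questions."""
    if len(responses) == 0:
        raise MissingFeatureError("answer statistics", "no responses")
    rate = sum(r.is_correct for r in responses) / len(responses)
    mean_time = float(np.mean([r.response_time for r in responses]))
    return float(rate), mean_time


def _gait_stats(phase: Phase, params: ExtractionParams
                ) -> tuple[float, float, float, float]:
    step_mean, step_sd = step_interval_stats(phase.steps, params.population_sd)
    cycles: list[RaiseCycle] = []
    for side in ("left", "right"):
        series = knee_angle_series(phase.frames, side)
        cycles.extend(detect_raise_cycles(series, params))
    amp_mean, amp_sd = knee_amplitude_stats(cycles, params.population_sd)
    return step_mean, step_sd, amp_mean, amp_sd


def extract_features(session: TrialSession,
                     params: ExtractionParams | None = None) -> FeatureVector:
    """Assemble the 12 features of one trial from its three phases.

    Any feature that cannot be computed raises
    :class:`IncompleteTrialError` naming the feature; callers doing
    complete-case modelling may drop the trial.
    """
    params = params or ExtractionParams()
    session.validate()
    try:
        cog = session.phases[PHASE_COGNITIVE]
        phys = session.phases[PHASE_PHYSICAL]
        dual = session.phases[PHASE_DUAL]
        s_rate, s_time = answer_stats(cog.responses)
        s_step_mean, s_step_sd, s_amp_mean, s_amp_sd = _gait_stats(phys, params)
        d_step_mean, d_step_sd, d_amp_mean, d_amp_sd = _gait_stats(dual, params)
        d_rate, d_time = answer_stats(dual.responses)
    except MissingFeatureError as exc:
        raise IncompleteTrialError(exc.feature, session.subject_id,
                                   session.trial_index) from exc
    return FeatureVector(
        single_step_interval_mean=s_step_mean,
        single_step_interval_sd=s_step_sd,
        single_knee_amplitude_mean=s_amp_mean,
        single_knee_amplitude_sd=s_amp_sd,
        single_answer_rate=s_rate,
        single_answer_time_mean=s_time,
        dual_step_interval_mean=d_step_mean,
        dual_step_interval_sd=d_step_sd,
        dual_knee_amplitude_mean=d_amp_mean,
        dual_knee_amplitude_sd=d_amp_sd,
        dual_answer_rate=d_rate,
        dual_answer_time_mean=d_time,
    )
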