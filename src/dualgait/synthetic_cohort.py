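"""Synthetic dual-task cohorts with the statistical structure the
analysis assumes.

No public dataset of kiosk dual-task sessions exists, so every downstream
stage is exercised on simulated cohorts.  A subject's Mini-Mental State
Examination score (MMSE, 0-30) is drawn from a rounded, clipped normal
calibrated to the reference cohort (mean 24.6, SD 5.24 over 90 subjects;
32 males averaging 81.5 y, 68 females 82.6 y).  Latent behavioural
parameters are linear in the cognitive deficit ``30 - MMSE`` plus
subject-level noise:

* knee-raise amplitude shrinks with deficit (lower-scoring subjects lift
  their knees less);
* step-interval jitter grows with deficit, and grows *faster* under dual
  tasking (cognitive-motor interference: the dual-task cost of every
  behavioural channel is multiplicative and linear in the deficit, with a
  floor of zero cost at MMSE 30);
* calculation accuracy falls and response time rises with deficit.

Subjects at or above the awareness gate (MMSE >= 24 by default) learn from
the printed result sheet: their knee-raise amplitude gains a fixed increment
per completed trial, plateauing at trial 40.

The simulator synthesises raw 3-D joint positions (fixed hip centre, the
ankle swung about the knee through a parametric leg-lift trajectory) so the
knee-angle formula is exercised on points, not on pre-made angle series; the
true angle traces and scheduled per-cycle amplitudes are exposed in each
phase's ``truth`` payload for oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .calc_task import CalcConfig, generate_question
from .errors import ConfigurationError
from .types import (PHASE_COGNITIVE, PHASE_DUAL, PHASE_PHYSICAL, CalcResponse,
                    FrameBlock, Phase, StepEvent, SubjectProfile, TrialSession)

_EXTENDED_ANGLE = 2.95  # standing knee angle, rad (just short of a straight leg)
_THIGH_M = 0.45
_SHANK_M = 0.45
_MIN_CYCLE_AMPLITUDE = 0.08  # keep every scheduled raise above detector prominence


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, MMSE-linked effect sizes and noise scales.

    Slopes are per MMSE point of deficit (30 - MMSE); dual-task costs are
    multiplicative factors linear in the deficit, zero at MMSE 30.  The
    default cohort (60 subjects x 20 trials) is the desk-scale study
    condition used throughout the tests.
    """

    n_subjects: int = 60
    trials_per_subject: int | tuple[int, int] = 20

    # demographics (reference-cohort calibration)
    mmse_mean: float = 24.6
    mmse_sd: float = 5.24
    male_fraction: float = 32 / 90
    age_mean_male: float = 81.5
    age_mean_female: float = 82.6
    age_sd: float = 6.0

    # protocol timing
    cognitive_s: float = 30.0
    physical_s: float = 20.0
    dual_s: float = 30.0
    frame_rate_hz: float = 30.0

    # healthy (MMSE 30) behavioural baselines
    base_knee_amplitude_rad: float = 0.55
    base_step_interval_s: float = 0.60
    base_step_jitter_s: float = 0.02
    base_accuracy: float = 0.97
    base_answer_time_s: float = 2.0

    # MMSE links (per point of deficit)
    amplitude_slope_rad: float = 0.012
    interval_slope_s: float = 0.004
    jitter_slope: float = 0.03
    accuracy_slope: float = 0.010
    answer_time_slope_s: float = 0.05

    # dual-task cost per point of deficit (multiplicative, zero at MMSE 30)
    dual_cost_jitter: float = 0.10
    dual_cost_interval: float = 0.005
    dual_cost_amplitude: float = 0.006
    dual_cost_accuracy: float = 0.004
    dual_cost_answer_time: float = 0.02

    # knee-raise learning (awareness of the printed score)
    learning_gain_rad: float = 0.004
    learning_plateau_trial: int = 40
    learning_mmse_gate: int = 24

    # subject-level noise scales (SDs)
    subject_amplitude_sd: float = 0.05
    subject_interval_sd: float = 0.04
    subject_jitter_rel_sd: float = 0.15
    subject_accuracy_sd: float = 0.03
    subject_answer_time_sd: float = 0.30

    # trial/cycle-level noise scales
    cycle_amplitude_sd: float = 0.05
    answer_time_trial_sd: float = 0.40
    frame_noise_m: float = 0.002
    inter_question_gap_s: float = 0.5

    store_truth: bool = True
    calc: CalcConfig = field(default_factory=CalcConfig)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        tps = self.trials_per_subject
        if isinstance(tps, int):
            if tps < 1:
                raise ConfigurationError("trials_per_subject must be >= 1")
        else:
            lo, hi = tps
            if not (1 <= lo <= hi):
                raise ConfigurationError("trials_per_subject range invalid")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        if self.mmse_sd < 0:
            raise ConfigurationError("mmse_sd must be >= 0")
        for name in ("cognitive_s", "physical_s", "dual_s", "frame_rate_hz",
                     "base_knee_amplitude_rad", "base_step_interval_s",
                     "base_accuracy", "base_answer_time_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("amplitude_slope_rad", "interval_slope_s", "jitter_slope",
                     "accuracy_slope", "answer_time_slope_s",
                     "dual_cost_jitter", "dual_cost_interval",
                     "dual_cost_amplitude", "dual_cost_accuracy",
                     "dual_cost_answer_time", "learning_gain_rad"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        for name in ("base_step_jitter_s", "subject_amplitude_sd",
                     "subject_interval_sd", "subject_jitter_rel_sd",
                     "subject_accuracy_sd", "subject_answer_time_sd",
                     "cycle_amplitude_sd", "answer_time_trial_sd",
                     "frame_noise_m"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        self.calc.validate()


def sample_subjects(config: CohortConfig,
                    rng: np.random.Generator) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    MMSE is a rounded normal clipped to [0, 30]; latent behavioural
    parameters are the configured linear links in the deficit plus
    subject-level Gaussian noise (all deterministic functions of MMSE when
    every noise scale is zero).
    """
    config.validate()
    subjects = []
    for i in range(config.n_subjects):
        mmse = int(np.clip(round(rng.normal(config.mmse_mean, config.mmse_sd)),
                           0, 30))
        deficit = 30.0 - mmse
        gender = "male" if rng.random() < config.male_fraction else "female"
        age_mean = (config.age_mean_male if gender == "male"
                    else config.age_mean_female)
        age = float(np.clip(rng.normal(age_mean, config.age_sd), 60.0, 100.0))
        amplitude = float(np.clip(
            config.base_knee_amplitude_rad
            - config.amplitude_slope_rad * deficit
            + rng.normal(0.0, config.subject_amplitude_sd),
            0.12, _EXTENDED_ANGLE - 0.3))
        interval = float(np.clip(
            config.base_step_interval_s
            + config.interval_slope_s * deficit
            + rng.normal(0.0, config.subject_interval_sd),
            0.35, 1.2))
        jitter = float(
            config.base_step_jitter_s * (1.0 + config.jitter_slope * deficit)
            * math.exp(rng.normal(0.0, config.subject_jitter_rel_sd)))
        accuracy = float(np.clip(
            config.base_accuracy - config.accuracy_slope * deficit
            + rng.normal(0.0, config.subject_accuracy_sd),
            0.5, 1.0))
        answer_time = float(np.clip(
            config.base_answer_time_s
            + config.answer_time_slope_s * deficit
            + rng.normal(0.0, config.subject_answer_time_sd),
            0.6, 4.0))
        gain = (config.learning_gain_rad
                if mmse >= config.learning_mmse_gate else 0.0)
        subjects.append(SubjectProfile(
            subject_id=f"S{i + 1:03d}", age=age, gender=gender, mmse=mmse,
            knee_amplitude_rad=amplitude, step_interval_s=interval,
            step_jitter_s=jitter, calc_accuracy=accuracy,
            calc_time_s=answer_time, learning_gain_rad=gain))
    return subjects


def _leg_geometry(side: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hip = np.array([0.0, 1.0, 0.0])
    lateral = -0.12 if side == "left" else 0.12
    u = np.array([lateral, -1.0, 0.0])
    u /= np.linalg.norm(u)
    w = np.array([0.0, 0.0, 1.0])  # forward axis, orthogonal to u
    return hip, u, w


def _simulate_stepping(name: str, duration: float, interval_mean: float,
                       interval_sd: float, amplitude_mean: float,
                       config: CohortConfig, rng: np.random.Generator
                       ) -> tuple[FrameBlock, list[StepEvent], dict]:
    """Alternating floor contacts plus skeleton frames of the leg-lift
    trajectory phase-locked to them."""
    # floor contacts, alternating feet, left first
    times = [0.2]
    while True:
        gap = max(interval_mean + rng.normal(0.0, interval_sd), 0.25)
        nxt = times[-1] + gap
        if nxt > duration - 0.05:
            break
        times.append(nxt)
    feet = ["left" if i % 2 == 0 else "right" for i in range(len(times))]
    steps = [StepEvent(t=float(t), foot=f) for t, f in zip(times, feet)]

    n_frames = int(math.floor(duration * config.frame_rate_hz))
    t_frames = np.arange(n_frames) / config.frame_rate_hz

    joints: dict[str, np.ndarray] = {}
    truth: dict = {"step_times": [float(t) for t in times], "feet": feet}
    amp_lo = _MIN_CYCLE_AMPLITUDE
    amp_hi = _EXTENDED_ANGLE - 0.15
    for side in ("left", "right"):
        touches = [t for t, f in zip(times, feet) if f == side]
        angle = np.full(n_frames, _EXTENDED_ANGLE)
        amplitudes = []
        for t0, t1 in zip(touches, touches[1:]):
            amp = float(np.clip(
                amplitude_mean + rng.normal(0.0, config.cycle_amplitude_sd),
                amp_lo, amp_hi))
            mask = (t_frames > t0) & (t_frames < t1)
            angle[mask] -= amp * np.sin(np.pi * (t_frames[mask] - t0) / (t1 - t0))
            amplitudes.append(amp)
        hip, u, w = _leg_geometry(side)
        knee = hip + _THIGH_M * u
        # ankle direction at interior knee angle `angle` from the knee->hip axis
        v = (np.cos(angle)[:, None] * (-u)[None, :]
             + np.sin(angle)[:, None] * w[None, :])
        ankle = knee[None, :] + _SHANK_M * v
        joints[f"{side}_knee"] = np.broadcast_to(knee, (n_frames, 3)).copy()
        joints[f"{side}_ankle"] = ankle
        truth[f"{side}_angle"] = angle.tolist()
        truth[f"{side}_amplitudes"] = amplitudes
        truth[f"raise_count_{side}"] = len(amplitudes)
    hip_center = np.broadcast_to(np.array([0.0, 1.0, 0.0]), (n_frames, 3)).copy()
    frames = FrameBlock(t=t_frames, hip_center=hip_center,
                        left_knee=joints["left_knee"],
                        right_knee=joints["right_knee"],
                        left_ankle=joints["left_ankle"],
                        right_ankle=joints["right_ankle"])
    if config.frame_noise_m > 0:
        for name_ in ("hip_center", "left_knee", "right_knee", "left_ankle",
                      "right_ankle"):
            arr = getattr(frames, name_)
            arr += rng.normal(0.0, config.frame_noise_m, size=arr.shape)
    truth["interval_mean"] = interval_mean
    truth["amplitude_mean"] = amplitude_mean
    return frames, steps, truth


def _simulate_answers(duration: float, accuracy: float, time_mean: float,
                      config: CohortConfig, rng: np.random.Generator
                      ) -> tuple[list[CalcResponse], dict]:
    calc = config.calc
    responses = []
    t = 0.0
    while True:
        display_end = t + calc.display_s
        rt = float(np.clip(rng.normal(time_mean, config.answer_time_trial_sd),
                           0.4, calc.answer_window_s))
        if display_end + rt > duration:
            break
        question = generate_question(rng, calc)
        correct = bool(rng.random() < accuracy)
        other = "right" if question.correct_side == "left" else "left"
        chosen = question.correct_side if correct else other
        responses.append(CalcResponse(question=question, chosen_side=chosen,
                                      response_time=rt, is_correct=correct))
        t = display_end + rt + config.inter_question_gap_s
    truth = {"accuracy": accuracy, "answer_time_mean": time_mean}
    return responses, truth


def simulate_trial(subject: SubjectProfile, trial_index: int,
                   config: CohortConfig, rng: np.random.Generator
                   ) -> TrialSession:
    """Simulate one three-phase session for a subject.

    The dual phase applies the configured multiplicative dual-task costs
    (scaled by the subject's deficit); the learning term
    ``gain * min(trial_index, plateau)`` raises the knee amplitude in both
    gait phases for subjects whose awareness gate is on.
    """
    if trial_index < 1:
        raise ConfigurationError("trial_index must be >= 1")
    config.validate()
    deficit = 30.0 - subject.mmse
    learn = subject.learning_gain_rad * min(trial_index,
                                            config.learning_plateau_trial)

    cog_resp, cog_truth = _simulate_answers(
        config.cognitive_s, subject.calc_accuracy, subject.calc_time_s,
        config, rng)
    cognitive = Phase(name=PHASE_COGNITIVE, duration_s=config.cognitive_s,
                      responses=cog_resp,
                      truth=cog_truth if config.store_truth else None)

    phys_frames, phys_steps, phys_truth = _simulate_stepping(
        PHASE_PHYSICAL, config.physical_s, subject.step_interval_s,
        subject.step_jitter_s, subject.knee_amplitude_rad + learn, config, rng)
    physical = Phase(name=PHASE_PHYSICAL, duration_s=config.physical_s,
                     frames=phys_frames, steps=phys_steps,
                     truth=phys_truth if config.store_truth else None)

    dual_interval = subject.step_interval_s * (
        1.0 + config.dual_cost_interval * deficit)
    dual_jitter = subject.step_jitter_s * (
        1.0 + config.dual_cost_jitter * deficit)
    dual_amp = subject.knee_amplitude_rad * (
        1.0 - config.dual_cost_amplitude * deficit) + learn
    dual_acc = float(np.clip(
        subject.calc_accuracy * (1.0 - config.dual_cost_accuracy * deficit),
        0.0, 1.0))
    dual_time = float(np.clip(
        subject.calc_time_s * (1.0 + config.dual_cost_answer_time * deficit),
        0.4, config.calc.answer_window_s))
    dual_frames, dual_steps, dual_truth = _simulate_stepping(
        PHASE_DUAL, config.dual_s, dual_interval, dual_jitter, dual_amp,
        config, rng)
    dual_resp, dual_ans_truth = _simulate_answers(
        config.dual_s, dual_acc, dual_time, config, rng)
    dual_truth.update(dual_ans_truth)
    dual = Phase(name=PHASE_DUAL, duration_s=config.dual_s, frames=dual_frames,
                 steps=dual_steps, responses=dual_resp,
                 truth=dual_truth if config.store_truth else None)

    return TrialSession(
        subject_id=subject.subject_id, trial_index=trial_index,
        phases={PHASE_COGNITIVE: cognitive, PHASE_PHYSICAL: physical,
                PHASE_DUAL: dual},
        mmse=subject.mmse)


def _trial_count(config: CohortConfig, rng: np.random.Generator) -> int:
    tps = config.trials_per_subject
    if isinstance(tps, int):
        return tps
    lo, hi = tps
    return int(rng.integers(lo, hi + 1))


def iter_subject_sessions(config: CohortConfig, rng: np.random.Generator
                          ) -> Iterator[tuple[SubjectProfile, list[TrialSession]]]:
    """Stream (subject, sessions) pairs without holding the whole cohort."""
    for subject in sample_subjects(config, rng):
        count = _trial_count(config, rng)
        yield subject, [simulate_trial(subject, k, config, rng)
                        for k in range(1, count + 1)]


def simulate_cohort(config: CohortConfig, rng: np.random.Generator
                    ) -> tuple[list[SubjectProfile], list[TrialSession]]:
    """Materialise a full cohort: subject profiles plus all their sessions."""
    subjects, sessions = [], []
    for subject, subject_sessions in iter_subject_sessions(config, rng):
        subjects.append(subject)
        sessions.extend(subject_sessions)
    return subjects, sessions
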