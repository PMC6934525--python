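"""Domain containers for dual-task sessions and extracted features.

A :class:`TrialSession` is one run of the kiosk protocol: a single cognitive
phase (two-alternative mental arithmetic), a single physical phase (stepping
in place) and a dual phase combining both.  Skeleton joints are stored as
dense arrays (one row per depth-camera frame) holding only the five joints
any downstream formula consumes: hip centre, both knees, both ankles.
Timestamps are seconds from the start of the enclosing phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np

from .errors import SchemaVersionError, ValidationError

SCHEMA_VERSION = 1
KNOWN_SCHEMA_VERSIONS = (1,)

#: Canonical phase order: features labelled "single" come from the two single
#: phases, all "dual" features from the dual phase.
PHASE_COGNITIVE = "single_cognitive"
PHASE_PHYSICAL = "single_physical"
PHASE_DUAL = "dual"
PHASE_NAMES = (PHASE_COGNITIVE, PHASE_PHYSICAL, PHASE_DUAL)

JOINT_NAMES = ("hip_center", "left_knee", "right_knee", "left_ankle", "right_ankle")

#: Canonical order of the 12 features (6 per task context).
FEATURE_NAMES = (
    "single_step_interval_mean",
    "single_step_interval_sd",
    "single_knee_amplitude_mean",
    "single_knee_amplitude_sd",
    "single_answer_rate",
    "single_answer_time_mean",
    "dual_step_interval_mean",
    "dual_step_interval_sd",
    "dual_knee_amplitude_mean",
    "dual_knee_amplitude_sd",
    "dual_answer_rate",
    "dual_answer_time_mean",
)

#: The six base feature types; each exists once per task context.
BASE_FEATURE_TYPES = (
    "step_interval_mean",
    "step_interval_sd",
    "knee_amplitude_mean",
    "knee_amplitude_sd",
    "answer_rate",
    "answer_time_mean",
)

#: Named column subsets used by the feature-set comparison.
FEATURE_SETS = {
    "single_physical": FEATURE_NAMES[0:4],
    "single_cognitive": FEATURE_NAMES[4:6],
    "single_all": FEATURE_NAMES[0:6],
    "dual": FEATURE_NAMES[6:12],
    "combined": FEATURE_NAMES,
}

MMSE_THRESHOLD = 24  # scores < 24 flag possible cognitive impairment
CLASS_LOW = "low"
CLASS_HIGH = "high"


# ---------------------------------------------------------------------------
# skeleton / gait primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkeletonFrame:
    """A single skeleton frame (metres, sensor coordinates)."""

    t: float
    hip_center: tuple[float, float, float]
    left_knee: tuple[float, float, float]
    right_knee: tuple[float, float, float]
    left_ankle: tuple[float, float, float]
    right_ankle: tuple[float, float, float]


class FrameBlock:
    """Column-oriented storage of skeleton frames.

    ``t`` has shape ``(n,)``; each joint array has shape ``(n, 3)``.
    """

    __slots__ = ("t", "hip_center", "left_knee", "right_knee", "left_ankle",
                 "right_ankle")

    def __init__(self, t, hip_center, left_knee, right_knee, left_ankle,
                 right_ankle):
        self.t = np.asarray(t, dtype=float)
        self.hip_center = np.asarray(hip_center, dtype=float)
        self.left_knee = np.asarray(left_knee, dtype=float)
        self.right_knee = np.asarray(right_knee, dtype=float)
        self.left_ankle = np.asarray(left_ankle, dtype=float)
        self.right_ankle = np.asarray(right_ankle, dtype=float)

    def __len__(self) -> int:
        return self.t.shape[0]

    def __iter__(self) -> Iterator[SkeletonFrame]:
        for i in range(len(self)):
            yield SkeletonFrame(
                t=float(self.t[i]),
                hip_center=tuple(self.hip_center[i]),
                left_knee=tuple(self.left_knee[i]),
                right_knee=tuple(self.right_knee[i]),
                left_ankle=tuple(self.left_ankle[i]),
                right_ankle=tuple(self.right_ankle[i]),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameBlock):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, name), getattr(other, name))
            for name in self.__slots__
        )

    @classmethod
    def from_frames(cls, frames: Sequence[SkeletonFrame]) -> "FrameBlock":
        return cls(
            t=[f.t for f in frames],
            hip_center=[f.hip_center for f in frames],
            left_knee=[f.left_knee for f in frames],
            right_knee=[f.right_knee for f in frames],
            left_ankle=[f.left_ankle for f in frames],
            right_ankle=[f.right_ankle for f in frames],
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "t": self.t.tolist(),
            **{name: getattr(self, name).tolist() for name in JOINT_NAMES},
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FrameBlock":
        return cls(t=d["t"], **{name: d[name] for name in JOINT_NAMES})

    def validate(self) -> None:
        n = len(self)
        for name in self.__slots__:
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in frames.{name}",
                                      field=f"frames.{name}")
            expected = (n,) if name == "t" else (n, 3)
            if arr.shape != expected:
                raise ValidationError(
                    f"frames.{name} has shape {arr.shape}, expected {expected}",
                    field=f"frames.{name}")
        if n > 1 and np.any(np.diff(self.t) < 0):
            raise ValidationError("frame timestamps must be non-decreasing",
                                  field="frames.t")


@dataclass(frozen=True)
class StepEvent:
    """A floor-contact event from the pressure sensor."""

    t: float
    foot: str  # "left" | "right"

    def to_dict(self) -> dict[str, Any]:
        return {"t": self.t, "foot": self.foot}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StepEvent":
        return cls(t=float(d["t"]), foot=str(d["foot"]))


@dataclass(frozen=True)
class KneeAngleSeries:
    """Per-frame knee angle (radians, interior angle hip–knee–ankle)."""

    t: np.ndarray
    angle: np.ndarray
    side: str

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "angle", np.asarray(self.angle, dtype=float))
        if self.t.shape != self.angle.shape:
            raise ValidationError("t and angle must have equal length",
                                  field="angle")

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass(frozen=True)
class RaiseCycle:
    """One knee-raise: extension peak paired with its flexion valley.

    ``peak_angle`` is the extended (near-floor) angle, ``valley_angle`` the
    maximally flexed angle mid-raise; ``amplitude`` their difference.
    """

    peak_t: float
    valley_t: float
    peak_angle: float
    valley_angle: float
    amplitude: float


# ---------------------------------------------------------------------------
# calculation task
# ---------------------------------------------------------------------------

ADDITION = "addition"
SUBTRACTION = "subtraction"
OPERATORS = (ADDITION, SUBTRACTION)

RULE_CARRY_BORROW = "carry_borrow"
RULE_UNIT_PLACE = "unit_place"
RULE_OPERATOR_SWAP = "operator_swap"
DISTRACTOR_RULES = (RULE_CARRY_BORROW, RULE_UNIT_PLACE, RULE_OPERATOR_SWAP)

SIDES = ("left", "right")


@dataclass(frozen=True)
class CalcQuestion:
    """A two-alternative arithmetic question with an error-model distractor."""

    operand_a: int
    operand_b: int
    operator: str
    correct_answer: int
    distractor: int
    distractor_rule: str
    correct_side: str

    def __post_init__(self):
        expected = (self.operand_a + self.operand_b
                    if self.operator == ADDITION
                    else self.operand_a - self.operand_b)
        if self.operator not in OPERATORS:
            raise ValidationError(f"unknown operator {self.operator!r}",
                                  field="operator")
        if self.correct_answer != expected:
            raise ValidationError("correct_answer does not match operands",
                                  field="correct_answer")
        if self.distractor == self.correct_answer:
            raise ValidationError("distractor equals the correct answer",
                                  field="distractor")
        if self.operator == SUBTRACTION and self.operand_a < self.operand_b:
            raise ValidationError("subtraction requires operand_a >= operand_b",
                                  field="operand_a")
        if self.correct_side not in SIDES:
            raise ValidationError(f"unknown side {self.correct_side!r}",
                                  field="correct_side")
        if self.distractor_rule not in DISTRACTOR_RULES:
            raise ValidationError(
                f"unknown distractor rule {self.distractor_rule!r}",
                field="distractor_rule")

    def to_dict(self) -> dict[str, Any]:
        return {
            "operand_a": self.operand_a,
            "operand_b": self.operand_b,
            "operator": self.operator,
            "correct_answer": self.correct_answer,
            "distractor": self.distractor,
            "distractor_rule": self.distractor_rule,
            "correct_side": self.correct_side,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CalcQuestion":
        return cls(**{k: d[k] for k in (
            "operand_a", "operand_b", "operator", "correct_answer",
            "distractor", "distractor_rule", "correct_side")})


@dataclass(frozen=True)
class CalcResponse:
    """A button press answering one question.

    ``response_time`` runs from the moment the two candidates appear to the
    button press.
    """

    question: CalcQuestion
    chosen_side: str
    response_time: float
    is_correct: bool

    def __post_init__(self):
        if self.response_time <= 0:
            raise ValidationError("response_time must be positive",
                                  field="response_time")
        if self.is_correct != (self.chosen_side == self.question.correct_side):
            raise ValidationError(
                "is_correct inconsistent with chosen/correct side",
                field="is_correct")

    def to_dict(self) -> dict[str, Any]:
        return {
            "question": self.question.to_dict(),
            "chosen_side": self.chosen_side,
            "response_time": self.response_time,
            "is_correct": self.is_correct,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CalcResponse":
        return cls(
            question=CalcQuestion.from_dict(d["question"]),
            chosen_side=str(d["chosen_side"]),
            response_time=float(d["response_time"]),
            is_correct=bool(d["is_correct"]),
        )


# ---------------------------------------------------------------------------
# phases and sessions
# ---------------------------------------------------------------------------

@dataclass
class Phase:
    """One protocol phase with whatever streams it produces.

    ``truth`` optionally carries simulator ground truth (true angle traces,
    scheduled per-cycle amplitudes, configured accuracy) so extraction can be
    validated against the generator.
    """

    name: str
    duration_s: float
    frames: FrameBlock | None = None
    steps: list[StepEvent] = field(default_factory=list)
    responses: list[CalcResponse] = field(default_factory=list)
    truth: dict[str, Any] | None = None

    def validate(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ValidationError(f"unknown phase name {self.name!r}",
                                  field="phase.name")
        if not (self.duration_s > 0 and math.isfinite(self.duration_s)):
            raise ValidationError("phase duration must be positive and finite",
                                  field="phase.duration_s")
        if self.frames is not None:
            self.frames.validate()
        times = [e.t for e in self.steps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("step event times must be strictly increasing",
                                  field="phase.steps")
        for e in self.steps:
            if e.foot not in ("left", "right"):
                raise ValidationError(f"unknown foot {e.foot!r}",
                                      field="phase.steps")

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "duration_s": self.duration_s,
            "frames": self.frames.to_dict() if self.frames is not None else None,
            "steps": [e.to_dict() for e in self.steps],
            "responses": [r.to_dict() for r in self.responses],
            "truth": self.truth,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Phase":
        return cls(
            name=d["name"],
            duration_s=float(d["duration_s"]),
            frames=FrameBlock.from_dict(d["frames"]) if d.get("frames") else None,
            steps=[StepEvent.from_dict(e) for e in d.get("steps", [])],
            responses=[CalcResponse.from_dict(r) for r in d.get("responses", [])],
            truth=d.get("truth"),
        )


@dataclass
class TrialSession:
    """One subject-trial: the three phases plus identifying metadata.

    ``mmse`` is the subject's ground-truth score carried along for evaluation
    of downstream estimators; it is not used by feature extraction.
    """

    subject_id: str
    trial_index: int
    phases: dict[str, Phase]
    mmse: int | None = None
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        if self.schema_version not in KNOWN_SCHEMA_VERSIONS:
            raise SchemaVersionError(
                f"unknown schema version {self.schema_version}",
                field="schema_version")
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty",
                                  field="subject_id")
        if not (isinstance(self.trial_index, int) and self.trial_index >= 1):
            raise ValidationError("trial_index must be an integer >= 1",
                                  field="trial_index")
        if tuple(self.phases.keys()) != PHASE_NAMES:
            missing = [p for p in PHASE_NAMES if p not in self.phases]
            raise ValidationError(
                f"session must contain exactly the phases {PHASE_NAMES}; "
                f"missing {missing}", field="phases")
        for name, phase in self.phases.items():
            if phase.name != name:
                raise ValidationError(
                    f"phase stored under {name!r} is named {phase.name!r}",
                    field="phases")
            phase.validate()
        if self.mmse is not None and not (0 <= int(self.mmse) <= 30):
            raise ValidationError("mmse must lie in [0, 30]", field="mmse")

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "subject_id": self.subject_id,
            "trial_index": self.trial_index,
            "mmse": self.mmse,
            "phases": {name: self.phases[name].to_dict() for name in PHASE_NAMES},
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrialSession":
        phases_d = d.get("phases", {})
        return cls(
            subject_id=str(d.get("subject_id", "")),
            trial_index=d.get("trial_index", 0),
            phases={name: Phase.from_dict(p) for name, p in phases_d.items()},
            mmse=d.get("mmse"),
            schema_version=d.get("schema_version", -1),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialSession):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# features, subjects, estimation results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """The 12 single/dual-task features for one trial.

    Step intervals are in seconds (the inter-step time itself, not a rate),
    knee amplitudes in radians, the answer rate a fraction in [0, 1] and the
    answer time in seconds.  "single" gait fields come from the single
    physical phase, "single" calculation fields from the single cognitive
    phase, and all six "dual" fields from the dual phase.
    """

    single_step_interval_mean: float
    single_step_interval_sd: float
    single_knee_amplitude_mean: float
    single_knee_amplitude_sd: float
    single_answer_rate: float
    single_answer_time_mean: float
    dual_step_interval_mean: float
    dual_step_interval_sd: float
    dual_knee_amplitude_mean: float
    dual_knee_amplitude_sd: float
    dual_answer_rate: float
    dual_answer_time_mean: float

    def __post_init__(self):
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"feature {name} is not finite",
                                      field=name)
        for name in FEATURE_NAMES:
            if name.endswith("_sd") and getattr(self, name) < 0:
                raise ValidationError(f"feature {name} must be >= 0", field=name)
        for name in ("single_answer_rate", "dual_answer_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]", field=name)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in FEATURE_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "FeatureVector":
        return cls(**{n: float(d[n]) for n in FEATURE_NAMES})


@dataclass(frozen=True)
class SubjectProfile:
    """A synthetic subject: demographics, true MMSE and latent parameters.

    The latent parameters drive the session simulator: baseline knee-raise
    amplitude (rad), baseline step interval (s), single-task step-interval
    jitter (s), calculation accuracy (fraction), calculation speed (s) and
    the per-trial knee-raise learning gain (rad/trial, zero when the
    awareness gate is off).
    """

    subject_id: str
    age: float
    gender: str  # "male" | "female"
    mmse: int
    knee_amplitude_rad: float
    step_interval_s: float
    step_jitter_s: float
    calc_accuracy: float
    calc_time_s: float
    learning_gain_rad: float

    def __post_init__(self):
        if not 0 <= self.mmse <= 30:
            raise ValidationError("mmse must lie in [0, 30]", field="mmse")
        if self.gender not in ("male", "female"):
            raise ValidationError(f"unknown gender {self.gender!r}",
                                  field="gender")


@dataclass(frozen=True)
class ClassificationMetrics:
    """Recall (positive = low MMSE), specificity and their sum.

    A metric is NaN when its truth class is absent from the evaluated set.
    """

    recall: float
    specificity: float

    @property
    def sum(self) -> float:
        return self.recall + self.specificity

    def to_dict(self) -> dict[str, float]:
        return {"recall": self.recall, "specificity": self.specificity,
                "sum": self.sum}


def mmse_class(score: float) -> str:
    """Binary screening class: scores below 24 are the positive ('low') class."""
    return CLASS_LOW if score < MMSE_THRESHOLD else CLASS_HIGH
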