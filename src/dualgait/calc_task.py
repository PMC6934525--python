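"""Two-alternative arithmetic questions with error-model distractors.

The cognitive task shows the addition or subtraction of two numbers, then
replaces it with two candidate answers (the question and candidates are never
on screen together, loading short-term memory).  The wrong candidate is built
by simulating a common calculation mistake:

``carry_borrow``
    digit-wise addition/subtraction with the carry (or borrow) into the tens
    place dropped, e.g. 27 + 15 -> 32 instead of 42;
``unit_place``
    the units digit of the correct answer perturbed by +/-1, wrapping within
    0-9, the tens digit untouched;
``operator_swap``
    the result of the opposite operator — a + b for a subtraction question,
    |a - b| for an addition question.

A rule that happens to reproduce the correct answer (e.g. ``carry_borrow``
on a sum without a carry) is *inapplicable* and the generator resamples
uniformly among the remaining rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, RuleInapplicableError
from .types import (ADDITION, DISTRACTOR_RULES, OPERATORS, RULE_CARRY_BORROW,
                    RULE_OPERATOR_SWAP, RULE_UNIT_PLACE, SIDES, CalcQuestion)


@dataclass(frozen=True)
class CalcConfig:
    """Question-generation settings.

    Operands default to 1-49 for addition (sums stay two-digit) and a minuend
    up to 99 for subtraction, so every mistake rule is well defined.  The
    question is displayed for ``display_s`` seconds, then the two candidates
    stay up for at most ``answer_window_s`` seconds.
    """

    operand_min: int = 1
    operand_max: int = 49
    minuend_max: int = 99
    operators: tuple[str, ...] = OPERATORS
    rules: tuple[str, ...] = DISTRACTOR_RULES
    display_s: float = 3.0
    answer_window_s: float = 5.0

    def validate(self) -> None:
        if not 0 <= self.operand_min < self.operand_max <= 99:
            raise ConfigurationError(
                "operand range must satisfy 0 <= min < max <= 99 "
                f"(got [{self.operand_min}, {self.operand_max}])")
        if not self.operand_max <= self.minuend_max <= 99:
            raise ConfigurationError("minuend_max must lie in [operand_max, 99]")
        if not self.operators or any(o not in OPERATORS for o in self.operators):
            raise ConfigurationError(f"operators must be a subset of {OPERATORS}")
        if not self.rules or any(r not in DISTRACTOR_RULES for r in self.rules):
            raise ConfigurationError(f"rules must be a subset of {DISTRACTOR_RULES}")
        if self.display_s <= 0 or self.answer_window_s <= 0:
            raise ConfigurationError("display and answer windows must be positive")


def _drop_carry(a: int, b: int, operator: str) -> int:
    """Digit-wise result with the carry/borrow into the tens place dropped."""
    if operator == ADDITION:
        units = (a % 10 + b % 10) % 10
        tens = (a // 10 + b // 10) % 10
    else:
        units = (a % 10 - b % 10) % 10
        tens = (a // 10 - b // 10) % 10
    return tens * 10 + units


def generate_distractor(operand_a: int, operand_b: int, operator: str,
                        rule: str, rng: np.random.Generator) -> int:
    """Produce the wrong candidate for one question under a mistake rule.

    Raises :class:`RuleInapplicableError` when the rule reproduces the
    correct answer so the caller can resample another rule.
    """
    correct = (operand_a + operand_b if operator == ADDITION
               else operand_a - operand_b)
    if rule == RULE_CARRY_BORROW:
        value = _drop_carry(operand_a, operand_b, operator)
    elif rule == RULE_UNIT_PLACE:
        delta = int(rng.choice([-1, 1]))
        units = (correct % 10 + delta) % 10
        value = (correct // 10) * 10 + units
    elif rule == RULE_OPERATOR_SWAP:
        value = (abs(operand_a - operand_b) if operator == ADDITION
                 else operand_a + operand_b)
    else:
        raise ConfigurationError(f"unknown distractor rule {rule!r}")
    if value == correct:
        raise RuleInapplicableError(
            f"rule {rule} reproduces the correct answer {correct} "
            f"for {operand_a} {operator} {operand_b}")
    return value


def generate_question(rng: np.random.Generator,
                      config: CalcConfig | None = None) -> CalcQuestion:
    """Draw one fully determined two-alternative question.

    The operator is drawn uniformly from the configured set, subtraction
    operands are ordered so the result is non-negative, the distractor rule
    is drawn uniformly among the configured rules (resampling inapplicable
    ones) and the side of the correct candidate is uniform.
    """
    config = config or CalcConfig()
    config.validate()
    operator = str(rng.choice(list(config.operators)))
    if operator == ADDITION:
        a = int(rng.integers(config.operand_min, config.operand_max + 1))
        b = int(rng.integers(config.operand_min, config.operand_max + 1))
    else:
        a = int(rng.integers(config.operand_min, config.minuend_max + 1))
        b = int(rng.integers(config.operand_min, config.operand_max + 1))
        if b > a:
            a, b = b, a
    correct = a + b if operator == ADDITION else a - b

    remaining = list(config.rules)
    distractor = None
    rule_used = None
    while remaining:
        rule = str(rng.choice(remaining))
        try:
            distractor = generate_distractor(a, b, operator, rule, rng)
            rule_used = rule
            break
        except RuleInapplicableError:
            remaining.remove(rule)
    if distractor is None:
        raise ConfigurationError(
            f"no configured rule yields a distractor for {a} {operator} {b}")
    return CalcQuestion(
        operand_a=a, operand_b=b, operator=operator, correct_answer=correct,
        distractor=distractor, distractor_rule=rule_used,
        correct_side=str(rng.choice(list(SIDES))))


@dataclass(frozen=True)
class QuestionWindow:
    """Display interval followed by the answer window for one question."""

    display_start: float
    answer_open: float
    answer_close: float


def question_schedule(phase_duration: float, rng: np.random.Generator,
                      config: CalcConfig | None = None) -> list[QuestionWindow]:
    """Plan non-overlapping display-then-answer windows within a phase.

    Windows are packed back to back at full length, so the number of
    questions is whatever fits the phase; a live session may move on earlier
    when the subject answers before the window closes.
    """
    config = config or CalcConfig()
    config.validate()
    if phase_duration <= 0:
        raise ConfigurationError("phase duration must be positive")
    slot = config.display_s + config.answer_window_s
    if slot > phase_duration:
        raise ConfigurationError(
            f"question window ({slot:.1f} s) exceeds phase duration "
            f"({phase_duration:.1f} s)")
    windows = []
    t = 0.0
    while t + slot <= phase_duration + 1e-9:
        windows.append(QuestionWindow(
            display_start=t,
            answer_open=t + config.display_s,
            answer_close=t + slot))
        t += slot
    return windows
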