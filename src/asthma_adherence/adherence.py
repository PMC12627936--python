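"""Adherence-to-effectiveness mapping and transition-matrix construction.

Treatment effectiveness follows a three-branch piecewise curve: directly
proportional up to 30% adherence, ``1 - exp(-5 * (a - 0.2287))`` between
30% and 100%, and exactly 1 at 100% (the exponential branch approaches
~0.979 as a -> 1, so the last branch is a deliberate jump, implemented as
printed in the source formula).

Weekly transition matrices at an intermediate adherence level are the
per-row convex combination of the full-adherence rows and the
zero-adherence (odds-ratio-adjusted) rows, weighted by effectiveness,
then composed with background mortality (death resolved first, remaining
mass scaled by survival) and, from the exacerbation state, with the
asthma case fatality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    CONTROL_STATES,
    ControlState,
    LifeTable,
    ParameterSet,
    ValidationError,
    weekly_mortality,
)

__all__ = [
    "K_SLOPE",
    "OFFSET",
    "PROPORTIONAL_THRESHOLD",
    "TransitionMatrix",
    "effectiveness",
    "or_adjust",
    "zero_adherence_transitions",
    "build_matrix",
]

#: Exponential-branch slope of the adherence-effectiveness curve.
K_SLOPE = 5.0
#: Exponential-branch offset.
OFFSET = 0.2287
#: Below this adherence, effectiveness equals adherence.
PROPORTIONAL_THRESHOLD = 0.30

_N_STATES = 5
_DEAD = int(ControlState.DEAD)
_EXAC = int(ControlState.EXACERBATION)


def effectiveness(a: float) -> float:
    """Treatment effectiveness in [0, 1] for adherence ``a`` in [0, 1].

    Piecewise: ``a`` itself for a <= 0.30; ``1 - exp(-5 * (a - 0.2287))``
    for 0.30 < a < 1; exactly 1.0 at a = 1.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"adherence must be in [0, 1], got {a}")
    if a <= PROPORTIONAL_THRESHOLD:
        return float(a)
    if a >= 1.0:
        return 1.0
    return float(1.0 - np.exp(-K_SLOPE * (a - OFFSET)))


def or_adjust(p: float, or_value: float) -> float:
    """Apply an odds ratio to a probability on the odds scale.

    Returns ``(or*p/(1-p)) / (1 + or*p/(1-p))``; 0 maps to 0 for any OR.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if or_value <= 0:
        raise ValueError(f"odds ratio must be > 0, got {or_value}")
    if p == 0.0:
        return 0.0
    if p == 1.0:
        raise ValueError("odds undefined at p = 1 for a finite odds ratio")
    odds = or_value * p / (1.0 - p)
    return odds / (1.0 + odds)


def zero_adherence_transitions(p: ParameterSet) -> np.ndarray:
    """Weekly move probabilities (3x4, diagonal zero) under no treatment.

    The per-origin odds ratios are applied to the exacerbation-entry
    probabilities; all other moves carry over unchanged and the residual
    stay probability absorbs the change.
    """
    trans = p.full_adherence_transitions.copy()
    for i, origin in enumerate(CONTROL_STATES):
        trans[i, _EXAC] = or_adjust(
            float(trans[i, _EXAC]), float(p.zero_adherence_odds_ratios[i])
        )
        row_sum = float(trans[i].sum())
        if row_sum > 1.0 + 1e-12:
            raise ValidationError(
                [
                    f"zero-adherence moves from {origin.name} sum to {row_sum} > 1 "
                    "after odds-ratio adjustment"
                ]
            )
    return trans


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 weekly transition probabilities with metadata."""

    probs: np.ndarray
    adherence: float
    age: float

    def __post_init__(self):
        m = self.probs
        if m.shape != (_N_STATES, _N_STATES):
            raise ValidationError([f"transition matrix shape {m.shape} != (5, 5)"])
        if np.any(m < -1e-15) or np.any(m > 1.0 + 1e-12):
            raise ValidationError(["transition matrix entry outside [0, 1]"])
        rs = m.sum(axis=1)
        if np.any(np.abs(rs - 1.0) > 1e-12):
            raise ValidationError([f"transition matrix rows sum to {rs.tolist()}"])
        if abs(m[_DEAD, _DEAD] - 1.0) > 1e-15:
            raise ValidationError(["dead state must be absorbing"])


def _moves_to_rows(moves: np.ndarray) -> np.ndarray:
    """3x4 move probabilities -> 3x5 stochastic rows (stay = residual)."""
    rows = np.zeros((3, _N_STATES))
    rows[:, :4] = moves
    for i in range(3):
        rows[i, i] = 1.0 - float(moves[i].sum())
    return rows


def build_matrix(
    p: ParameterSet, a: float, age: float, lt: LifeTable
) -> TransitionMatrix:
    """Weekly 5x5 transition matrix at adherence ``a`` and cohort ``age``.

    Alive control-state rows are ``E(a) * row_full + (1 - E(a)) * row_zero``
    composed with background mortality; the exacerbation row distributes
    survivors of background mortality and case fatality over the recovery
    vector.  Asthma-specific death is reachable only from the exacerbation
    state.
    """
    e = effectiveness(a)
    rows_full = _moves_to_rows(p.full_adherence_transitions)
    rows_zero = _moves_to_rows(zero_adherence_transitions(p))
    blended = e * rows_full + (1.0 - e) * rows_zero

    qw = weekly_mortality(lt, age, p.cycles_per_year, p.sex_mix_female)

    m = np.zeros((_N_STATES, _N_STATES))
    m[:3, :] = blended * (1.0 - qw)
    m[:3, _DEAD] = qw

    death_from_exac = 1.0 - (1.0 - qw) * (1.0 - p.exacerbation_case_fatality)
    m[_EXAC, :3] = p.exacerbation_recovery * (1.0 - death_from_exac)
    m[_EXAC, _DEAD] = death_from_exac

    m[_DEAD, _DEAD] = 1.0

    if np.any(m < 0.0) or np.any(m > 1.0):
        raise ValidationError(
            ["internal consistency error: entry outside [0, 1] after composition"]
        )
    # kill accumulated rounding so downstream row-sum checks are exact
    rs = m.sum(axis=1)
    if np.any(np.abs(rs - 1.0) > 1e-12):
        raise ValidationError([f"rows sum to {rs.tolist()} after composition"])
    return TransitionMatrix(probs=m, adherence=float(a), age=float(age))
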