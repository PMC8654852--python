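"""Deterministic mean-field dynamics of average reputations (h-scores).

The h-score of an individual is the fraction of the (infinite, well-mixed)
population currently holding opinion 1 of it.  Because donor, recipient
and observer are drawn at random, an observer's opinions of the donor and
of the recipient are independent Bernoulli draws parameterised by the
respective h-scores; this independence is the mean-field closure used
throughout.

Two error channels: an execution error ``mu_e`` flips the realized action,
and an assessment error ``mu_a`` flips the opinion the observer's rule
prescribes.  Both are applied once, after the rule output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .strategies import Strategy

__all__ = [
    "ModelParams",
    "HState",
    "act_prob",
    "assess_prob_good",
    "monomorphic_derivative",
    "dimorphic_derivatives",
    "monomorphic_poly",
]


@dataclass(frozen=True)
class ModelParams:
    """Payoffs, error rates and the shared initial h-score.

    ``b`` and ``c`` are the donation-game benefit and cost (``b > c > 0``);
    ``mu_e`` and ``mu_a`` are the execution and assessment error rates, each
    in ``[0, 0.5)``; ``h0`` is the initial h-score shared by every
    individual, resident or mutant.
    """

    b: float = 3.0
    c: float = 1.0
    mu_e: float = 0.0
    mu_a: float = 0.0
    h0: float = 0.5

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError(f"cost must be positive, got c={self.c}")
        if not (self.b > self.c):
            raise ValueError(
                f"the game is a social dilemma only for b > c; got b={self.b}, c={self.c}"
            )
        for name in ("mu_e", "mu_a"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5), got {v}")
        if not (0.0 <= self.h0 <= 1.0):
            raise ValueError(f"h0 must lie in [0, 1], got {self.h0}")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


class HState(NamedTuple):
    """Mean-field coordinates of a resident + rare-mutant population."""

    h_rr: float  #: residents' average opinion of a resident
    h_mr: float  #: residents' average opinion of the mutant
    h_rm: float  #: mutant's average opinion of residents


def _check_prob(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def act_prob(a1: int, a0: int, h, mu_e: float = 0.0):
    """Probability that a donor with action pair ``(a1, a0)`` cooperates
    with a partner it deems good with probability ``h``.

    The intended action ``h*a1 + (1-h)*a0`` is flipped with probability
    ``mu_e``, so the result lies in ``[mu_e, 1 - mu_e]``.  Accepts scalar
    or ndarray ``h``.
    """
    _check_prob("h", h)
    raw = h * a1 + (1.0 - h) * a0
    return raw * (1.0 - mu_e) + (1.0 - raw) * mu_e


def _q(x, mu_a: float):
    """Rule output ``x`` flipped with probability ``mu_a``."""
    return x * (1.0 - mu_a) + (1.0 - x) * mu_a


def _table_mean(table, h_donor, h_recip, mu_a: float):
    """Expected (error-flipped) rule output under independent Bernoulli
    opinions of donor and recipient; ``table`` is (t11, t10, t01, t00)."""
    t11, t10, t01, t00 = (_q(t, mu_a) for t in table)
    return (
        h_donor * (h_recip * t11 + (1.0 - h_recip) * t10)
        + (1.0 - h_donor) * (h_recip * t01 + (1.0 - h_recip) * t00)
    )


def assess_prob_good(C, D, p_coop, h_donor, h_recip, mu_a: float = 0.0):
    """Probability that an observer ends up with opinion 1 of the donor.

    ``p_coop`` is the donor's realized cooperation probability; ``h_donor``
    and ``h_recip`` parameterise the observer's independent prior opinions
    of donor and recipient; ``C``/``D`` are the observer's assessment
    tables.  The recipient's reputation is never updated.
    """
    for name, v in (("p_coop", p_coop), ("h_donor", h_donor), ("h_recip", h_recip)):
        _check_prob(name, v)
    return p_coop * _table_mean(C, h_donor, h_recip, mu_a) + (
        1.0 - p_coop
    ) * _table_mean(D, h_donor, h_recip, mu_a)


def monomorphic_derivative(strategy: Strategy, h, params: ModelParams):
    """d(h_rr)/dt for a monomorphic population at h-score ``h``.

    Equals the probability that a random observation leaves opinion 1 of
    the donor, minus ``h``; a polynomial in ``h`` of degree at most three.
    """
    p = act_prob(strategy.a1, strategy.a0, h, params.mu_e)
    return assess_prob_good(strategy.C, strategy.D, p, h, h, params.mu_a) - h


def dimorphic_derivatives(
    resident: Strategy, mutant: Strategy, state: HState, params: ModelParams
) -> tuple[float, float, float]:
    """Joint time-derivatives ``(dh_rr, dh_mr, dh_rm)`` of the
    resident + rare-mutant system.

    * ``dh_rr``: monomorphic resident dynamics (the mutant is rare).
    * ``dh_mr``: a resident observes the mutant donating to a resident;
      the mutant acts on its own opinion ``h_rm``, the observer judges
      with opinions ``h_mr`` (donor) and ``h_rr`` (recipient) using the
      resident's tables.
    * ``dh_rm``: the mutant observes a resident-resident interaction; its
      opinions of donor and recipient are both ``h_rm`` and it judges with
      its own tables.
    """
    h_rr, h_mr, h_rm = state
    for name, v in zip(("h_rr", "h_mr", "h_rm"), state):
        _check_prob(name, v)
    dh_rr = monomorphic_derivative(resident, h_rr, params)
    p_m = act_prob(mutant.a1, mutant.a0, h_rm, params.mu_e)
    dh_mr = (
        assess_prob_good(resident.C, resident.D, p_m, h_mr, h_rr, params.mu_a) - h_mr
    )
    p_r = act_prob(resident.a1, resident.a0, h_rr, params.mu_e)
    dh_rm = (
        assess_prob_good(mutant.C, mutant.D, p_r, h_rm, h_rm, params.mu_a) - h_rm
    )
    return (float(dh_rr), float(dh_mr), float(dh_rm))


_NODES = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
_VANDER_INV = np.linalg.inv(np.vander(_NODES, 4, increasing=True))


def monomorphic_poly(strategy: Strategy, params: ModelParams) -> np.ndarray:
    """Coefficients (ascending powers, length 4) of the cubic polynomial
    equal to :func:`monomorphic_derivative` as a function of ``h``."""
    vals = np.array([monomorphic_derivative(strategy, x, params) for x in _NODES])
    coeffs = _VANDER_INV @ vals
    coeffs[np.abs(coeffs) < 1e-14] = 0.0
    return coeffs
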