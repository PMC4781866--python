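"""Forward model and closed-form inverses for covert attention allocation.

The task is a cognitive two-armed bandit: each trial shows two rows of three
digits, exactly one of which sums to a value present on a seven-option probe
screen.  The top row holds the match with a fixed programmed probability
``PT`` (the bottom row with ``PB = 1 - PT``).  A subject with limited
capacity attends one row per trial — the top row with latent probability
``p`` — and, when the attended row turns out not to be the matching one,
guesses among the probe options with correct-guess rate ``g`` (chance value
``1/7``).  Conditioning on which row held the match, the correct-response
rates are linear in ``p`` and ``g``::

    PCT = p + (1 - p) * g        # top row held the match
    PCB = (1 - p) + p * g        # bottom row held the match

Lapses of attention and addition errors are absorbed by multiplying both
equations by an accuracy term ``A`` estimated from cued trials (on which the
subject is told which row matters, so errors cannot reflect misallocation).
The two equations invert in closed form, which turns observed accuracy into
an estimate of a covert quantity — the allocation of attention — on a 0-1
scale.  This module houses the forward model, the inverses, and the validity
classification of their solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ConditionDesign",
    "RatePair",
    "AccuracyProfile",
    "AttentionSolution",
    "VARIANT_LINEAR",
    "VARIANT_PAPER",
    "VARIANT_CONSISTENT",
    "VARIANT_ROW",
    "VALID",
    "SPECIOUS_P",
    "SPECIOUS_G",
    "DEGENERATE",
    "chance_guess_rate",
    "forward_conditional_rates",
    "expected_overall_correct",
    "expected_row_correct_frequency",
    "invert_equal_accuracy",
    "invert_row_accuracy",
    "classify_solution",
]

#: Estimator variants (provenance recorded in every solution).
VARIANT_LINEAR = "linear"
VARIANT_PAPER = "equal_accuracy_paper"
VARIANT_CONSISTENT = "equal_accuracy_consistent"
VARIANT_ROW = "row_accuracy"
_VARIANTS = (VARIANT_LINEAR, VARIANT_PAPER, VARIANT_CONSISTENT, VARIANT_ROW)

#: Validity labels.
VALID = "valid"
SPECIOUS_P = "specious_p"
SPECIOUS_G = "specious_g"
DEGENERATE = "degenerate"

# Boundary tolerance for validity classification: round-off must not flag a
# legal boundary solution (p or g exactly 0 or 1) as specious.
BOUNDARY_TOL = 1e-9

# Denominator threshold below which p is unidentifiable.
_DENOM_TOL = 1e-12


def _check_prob(value: float, name: str, tol: float = 1e-9) -> None:
    if not (-tol <= value <= 1.0 + tol):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ConditionDesign:
    """Programmed match probabilities defining a condition.

    ``p_top_match`` (PT) and ``p_bottom_match`` (PB) are the probabilities
    that the top / bottom row contains the digits whose sum appears on the
    probe screen; they are complementary by design.
    """

    p_top_match: float
    p_bottom_match: float

    def __post_init__(self) -> None:
        _check_prob(self.p_top_match, "p_top_match")
        _check_prob(self.p_bottom_match, "p_bottom_match")
        if abs(self.p_top_match + self.p_bottom_match - 1.0) > 1e-12:
            raise ValueError(
                "p_top_match + p_bottom_match must equal 1, got "
                f"{self.p_top_match} + {self.p_bottom_match}"
            )

    @classmethod
    def from_top(cls, p_top_match: float) -> "ConditionDesign":
        """Build a design from PT alone (PB is its complement)."""
        return cls(p_top_match, 1.0 - p_top_match)


@dataclass(frozen=True)
class RatePair:
    """Conditional correct-response rates on uncued trials.

    ``pct``: rate on trials whose top row held the match (PCT);
    ``pcb``: same for the bottom row (PCB).
    """

    pct: float
    pcb: float

    def __post_init__(self) -> None:
        _check_prob(self.pct, "pct")
        _check_prob(self.pcb, "pcb")


@dataclass(frozen=True)
class AccuracyProfile:
    """Cued-trial accuracy: per-cue-row rates and their pooled combination.

    ``pooled`` is the all-cued-trials correct fraction (the paper-style A);
    ``a_top`` / ``a_bottom`` are the row-specific rates used by the
    row-accuracy inversion.
    """

    a_top: float
    a_bottom: float
    pooled: float

    def __post_init__(self) -> None:
        _check_prob(self.a_top, "a_top")
        _check_prob(self.a_bottom, "a_bottom")
        _check_prob(self.pooled, "pooled")

    @classmethod
    def uniform(cls, a: float) -> "AccuracyProfile":
        """All three components equal (equal-accuracy model)."""
        return cls(a, a, a)


@dataclass(frozen=True)
class AttentionSolution:
    """Inferred (p, g) with estimator-variant and validity provenance.

    ``p`` is ``None`` when the inversion is degenerate (p unidentifiable,
    e.g. both conditional rates equal the accuracy term).
    """

    p: Optional[float]
    g: Optional[float]
    variant: str
    validity: str

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


AccuracyLike = Union[AccuracyProfile, float, None]


def _as_row_accuracies(accuracy: AccuracyLike) -> tuple[float, float]:
    if accuracy is None:
        return 1.0, 1.0
    if isinstance(accuracy, AccuracyProfile):
        return accuracy.a_top, accuracy.a_bottom
    a = float(accuracy)
    _check_prob(a, "accuracy")
    return a, a


def chance_guess_rate(n_options: int) -> float:
    """Correct-guess rate of a uniform guesser over ``n_options`` choices.

    With the seven-option probe screen this is 1/7 (prints as 0.143) — the
    expected guess rate for a subject with no usable knowledge of the
    unattended row.
    """
    if n_options < 1:
        raise ValueError(f"n_options must be >= 1, got {n_options}")
    return 1.0 / n_options


def forward_conditional_rates(
    p: float, g: float, accuracy: AccuracyLike = None
) -> RatePair:
    """Expected conditional correct rates (PCT, PCB) for latent (p, g).

    With accuracy terms ``a_top``, ``a_bottom`` (both 1 in the error-free
    model)::

        PCT = a_top * (p + (1 - p) * g)
        PCB = a_bottom * ((1 - p) + p * g)
    """
    _check_prob(p, "p")
    _check_prob(g, "g")
    a_top, a_bottom = _as_row_accuracies(accuracy)
    pct = a_top * (p + (1.0 - p) * g)
    pcb = a_bottom * ((1.0 - p) + p * g)
    return RatePair(pct, pcb)


def expected_overall_correct(
    design: ConditionDesign, p: float, g: float, accuracy: AccuracyLike = None
) -> float:
    """Expected overall correct-response probability.

    The linear combination ``PT*PCT + PB*PCB``: attention to the matching
    row yields a correct answer directly, attention to the other row yields
    one with guess probability ``g``.  Strictly increasing toward p=1 when
    PT > PB (and toward p=0 when PT < PB) for any g < 1, which is why
    maximizing — not probability matching — is the optimizing policy.
    """
    rates = forward_conditional_rates(p, g, accuracy)
    return design.p_top_match * rates.pct + design.p_bottom_match * rates.pcb


def expected_row_correct_frequency(
    design: ConditionDesign, p: float, g: float
) -> float:
    """Unconditional expected relative frequency of correct top-row responses.

    ``PT*p + PT*(1-p)*g``: the top row holds the match and is either
    attended (correct for sure, absent errors) or unattended and guessed.
    At PT=0.75, p=0.75, g=0.143 this evaluates to 0.589 (3 d.p.) — the
    probability-matching benchmark for that condition.
    """
    _check_prob(p, "p")
    _check_prob(g, "g")
    return design.p_top_match * (p + (1.0 - p) * g)


def classify_solution(sol: AttentionSolution, tol: float = BOUNDARY_TOL) -> AttentionSolution:
    """Attach a validity label; clip boundary round-off into [0, 1].

    Sampling error can push inverted values outside the unit interval
    ("specious" solutions: g < 0, or p < 0 or > 1); these are flagged, never
    silently clipped.  Values within ``tol`` of a boundary are treated as
    the boundary itself.
    """
    if sol.p is None:
        return replace(sol, validity=DEGENERATE)
    p, g = float(sol.p), float(sol.g)
    if p < -tol or p > 1.0 + tol:
        return replace(sol, validity=SPECIOUS_P)
    if g < -tol or g > 1.0 + tol:
        return replace(sol, validity=SPECIOUS_G)
    return replace(
        sol, p=min(max(p, 0.0), 1.0), g=min(max(g, 0.0), 1.0), validity=VALID
    )


def invert_equal_accuracy(
    rates: RatePair, a: float = 1.0, variant: str = VARIANT_PAPER
) -> AttentionSolution:
    """Closed-form (p, g) from conditional rates under equal row accuracy.

    Adding the two conditional-rate equations eliminates ``p`` and solving
    gives ``g``; substituting back gives ``p``::

        p = (PCB - A) / (PCT + PCB - 2A)          (both variants)
        g = (PCT + PCB) - A                       (paper variant)
        g = (PCT + PCB - A) / A                   (consistent variant)

    The "paper" variant applies the printed accuracy substitution (A for 1,
    2A for 2) literally; under the multiplicative error model its ĝ equals
    A·g.  The "consistent" variant divides through by A first, so ĝ
    estimates g itself.  Both collapse to the error-free linear model at
    A = 1, recorded as variant ``linear``.

    A zero denominator (PCT + PCB = 2A) leaves p unidentifiable and yields
    a ``degenerate`` solution with ``p=None``.
    """
    if a <= 0.0:
        raise ValueError(f"accuracy a must be positive, got {a}")
    _check_prob(a, "a")
    if variant not in (VARIANT_PAPER, VARIANT_CONSISTENT):
        raise ValueError(f"variant must be paper or consistent, got {variant!r}")

    s = rates.pct + rates.pcb
    if variant == VARIANT_PAPER:
        g = s - a
    else:
        g = (s - a) / a
    recorded = VARIANT_LINEAR if a == 1.0 else variant

    denom = s - 2.0 * a
    if abs(denom) < _DENOM_TOL:
        return AttentionSolution(None, g, recorded, DEGENERATE)
    p = (rates.pcb - a) / denom
    return classify_solution(AttentionSolution(p, g, recorded, VALID))


def _row_closed_form(rates: RatePair, a_top: float, a_bottom: float) -> tuple[float, float]:
    # Dividing each equation by its accuracy reduces the system to the
    # error-free linear one in (u, v) = (PCT/a_top, PCB/a_bottom).
    u = rates.pct / a_top
    v = rates.pcb / a_bottom
    denom = u + v - 2.0
    if abs(denom) < _DENOM_TOL:
        return math.nan, u + v - 1.0
    return (v - 1.0) / denom, u + v - 1.0


def invert_row_accuracy(
    rates: RatePair, accuracy: AccuracyLike, method: str = "closed_form"
) -> AttentionSolution:
    """Solve PCT = a_top·(p + (1−p)g), PCB = a_bottom·((1−p) + pg) for (p, g).

    Under this multiplicative error model the system is linear after
    normalising each rate by its row accuracy, so a closed form exists:
    ``p = (1 − PCB/a_bottom) / (2 − PCT/a_top − PCB/a_bottom)``.  A bounded
    numerical least-squares path (``method="numeric"``) solves the same
    system constrained to the unit square and is the contract of record;
    it agrees with the closed form to well below 1e-6 whenever the exact
    solution lies in [0, 1]².  With ``a_top == a_bottom`` both reduce to
    the equal-accuracy consistent-variant inversion.

    No exception is raised when the system has no solution in [0, 1]²; the
    returned solution carries a specious/degenerate validity flag.
    """
    a_top, a_bottom = _as_row_accuracies(accuracy)
    if a_top <= 0.0 or a_bottom <= 0.0:
        raise ValueError(
            f"row accuracies must be positive, got a_top={a_top}, a_bottom={a_bottom}"
        )
    if method not in ("closed_form", "numeric"):
        raise ValueError(f"unknown method {method!r}")

    p_cf, g_cf = _row_closed_form(rates, a_top, a_bottom)
    if math.isnan(p_cf):
        return AttentionSolution(None, g_cf, VARIANT_ROW, DEGENERATE)
    closed = classify_solution(AttentionSolution(p_cf, g_cf, VARIANT_ROW, VALID))

    if method == "closed_form":
        return closed

    def residuals(x: np.ndarray) -> np.ndarray:
        p, g = x
        return np.array(
            [
                a_top * (p + (1.0 - p) * g) - rates.pct,
                a_bottom * ((1.0 - p) + p * g) - rates.pcb,
            ]
        )

    x0 = np.clip([p_cf, g_cf], 1e-6, 1.0 - 1e-6)
    fit = least_squares(residuals, x0, bounds=([0.0, 0.0], [1.0, 1.0]), xtol=1e-14)
    if fit.cost < 1e-16:
        return classify_solution(
            AttentionSolution(float(fit.x[0]), float(fit.x[1]), VARIANT_ROW, VALID)
        )
    # No solution inside the unit square: report the exact (specious)
    # algebraic solution with its validity flag rather than a clipped fit.
    return closed
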