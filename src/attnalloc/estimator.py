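"""Turn trial logs into per-block attention estimates.

A "block" is any set of trials analysed together — in practice a
half-session (55 uncued + 11 cued trials), a session, or a pooled pair of
sessions.  The estimator tallies correct responses by trial type and
matching row, estimates accuracy from cued trials, and inverts the forward
model.  When sampling error in the cued-accuracy estimate produces a
specious solution (p outside [0, 1] or g < 0), a fallback ladder retries
with accuracy pooled over a wider sample and finally under the idealised
assumptions A = 1, g = 1/7 — mirroring how small cued samples (22 trials
per session) are handled in practice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    DEGENERATE,
    VALID,
    VARIANT_LINEAR,
    VARIANT_PAPER,
    VARIANT_ROW,
    AccuracyProfile,
    AttentionSolution,
    RatePair,
    chance_guess_rate,
    classify_solution,
    invert_equal_accuracy,
    invert_row_accuracy,
)

__all__ = [
    "TrialRecord",
    "BlockCounts",
    "BlockEstimate",
    "TrialValidationError",
    "EstimationError",
    "ZeroCuedTrialsError",
    "validate_record",
    "tally_block",
    "cued_accuracy",
    "estimate_block",
    "pool_blocks",
    "with_cued_from",
    "ACCURACY_POLICIES",
]

ACCURACY_POLICIES = ("session_accuracy", "pooled_accuracy", "assume_perfect")

_FALLBACK_NAMES = {
    "session_accuracy": "none",
    "pooled_accuracy": "pooled_sessions",
    "assume_perfect": "assumed_perfect",
}


class TrialValidationError(ValueError):
    """A trial record violates the task's structural invariants."""


class EstimationError(RuntimeError):
    """A block cannot yield an attention estimate."""


class ZeroCuedTrialsError(EstimationError):
    """No cued trials in the block: caller must pool or assume A = 1."""


@dataclass(frozen=True)
class TrialRecord:
    """One logged trial of the divided-attention digit task."""

    session: int
    trial: int
    trial_type: str  # "cued" | "uncued"
    cue: str  # "top" | "bottom" | "none"
    top_digits: tuple[int, int, int]
    bottom_digits: tuple[int, int, int]
    match_row: str  # "top" | "bottom"
    probe_options: tuple[int, ...]
    response: int
    correct: bool
    latency_ms: float

    @property
    def top_sum(self) -> int:
        return sum(self.top_digits)

    @property
    def bottom_sum(self) -> int:
        return sum(self.bottom_digits)

    @property
    def match_sum(self) -> int:
        return self.top_sum if self.match_row == "top" else self.bottom_sum


def validate_record(rec: TrialRecord) -> None:
    """Enforce the structural invariants of a single trial record.

    Raises :class:`TrialValidationError` naming the offending trial when the
    cue is inconsistent with the trial type, the probe does not contain the
    matching sum exactly once, or the correctness flag contradicts the
    response.
    """
    where = f"session {rec.session} trial {rec.trial}"
    if rec.trial_type == "cued":
        if rec.cue not in ("top", "bottom"):
            raise TrialValidationError(f"{where}: cued trial with cue {rec.cue!r}")
    elif rec.trial_type == "uncued":
        if rec.cue != "none":
            raise TrialValidationError(f"{where}: uncued trial with cue {rec.cue!r}")
    else:
        raise TrialValidationError(f"{where}: unknown trial_type {rec.trial_type!r}")
    if rec.match_row not in ("top", "bottom"):
        raise TrialValidationError(f"{where}: unknown match_row {rec.match_row!r}")
    for name, digits in (("top", rec.top_digits), ("bottom", rec.bottom_digits)):
        if len(digits) != 3 or any(not 1 <= d <= 7 for d in digits):
            raise TrialValidationError(f"{where}: bad {name} digits {digits!r}")
    if len(rec.probe_options) != 7 or len(set(rec.probe_options)) != 7:
        raise TrialValidationError(
            f"{where}: probe must list 7 distinct options, got {rec.probe_options!r}"
        )
    n_match = sum(1 for opt in rec.probe_options if opt == rec.match_sum)
    if n_match != 1:
        raise TrialValidationError(
            f"{where}: probe contains matching sum {rec.match_sum} {n_match} times"
        )
    if rec.correct != (rec.response == rec.match_sum):
        raise TrialValidationError(
            f"{where}: correct={rec.correct} inconsistent with response "
            f"{rec.response} vs matching sum {rec.match_sum}"
        )
    if rec.latency_ms < 0:
        raise TrialValidationError(f"{where}: negative latency {rec.latency_ms}")


@dataclass(frozen=True)
class BlockCounts:
    """Correct/total tallies partitioned by trial type × matching row."""

    n_uncued_top: int = 0
    n_correct_uncued_top: int = 0
    n_uncued_bottom: int = 0
    n_correct_uncued_bottom: int = 0
    n_cued_top: int = 0
    n_correct_cued_top: int = 0
    n_cued_bottom: int = 0
    n_correct_cued_bottom: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        pairs = (
            ("n_correct_uncued_top", "n_uncued_top"),
            ("n_correct_uncued_bottom", "n_uncued_bottom"),
            ("n_correct_cued_top", "n_cued_top"),
            ("n_correct_cued_bottom", "n_cued_bottom"),
        )
        for correct, total in pairs:
            if getattr(self, correct) > getattr(self, total):
                raise ValueError(f"{correct} exceeds {total}")

    @property
    def n_cued(self) -> int:
        return self.n_cued_top + self.n_cued_bottom

    @property
    def n_uncued(self) -> int:
        return self.n_uncued_top + self.n_uncued_bottom

    @property
    def n_total(self) -> int:
        return self.n_cued + self.n_uncued


@dataclass(frozen=True)
class BlockEstimate:
    """A block's tallies, rates, accuracy and attention solution.

    ``fallback_applied`` records the terminal rung of the accuracy ladder:
    ``none`` (the requested policy sufficed), ``pooled_sessions`` (accuracy
    re-estimated from a wider cued-trial pool) or ``assumed_perfect``
    (A = 1 with g fixed at the chance rate).
    """

    counts: BlockCounts
    rates: Optional[RatePair]
    accuracy: Optional[AccuracyProfile]
    solution: AttentionSolution
    fallback_applied: str = "none"


def tally_block(records: Sequence[TrialRecord]) -> BlockCounts:
    """Tally correct responses by trial type and matching row.

    Records are validated (see :func:`validate_record`) and processed in
    deterministic (session, trial) order.
    """
    if not records:
        raise EstimationError("cannot tally an empty block")
    tal = dict.fromkeys(
        (
            "n_uncued_top",
            "n_correct_uncued_top",
            "n_uncued_bottom",
            "n_correct_uncued_bottom",
            "n_cued_top",
            "n_correct_cued_top",
            "n_cued_bottom",
            "n_correct_cued_bottom",
        ),
        0,
    )
    for rec in sorted(records, key=lambda r: (r.session, r.trial)):
        validate_record(rec)
        kind = "cued" if rec.trial_type == "cued" else "uncued"
        tal[f"n_{kind}_{rec.match_row}"] += 1
        if rec.correct:
            tal[f"n_correct_{kind}_{rec.match_row}"] += 1
    return BlockCounts(**tal)


def cued_accuracy(counts: BlockCounts) -> AccuracyProfile:
    """Accuracy profile (a_top, a_bottom, pooled) from cued-trial tallies.

    Cued trials are the empirical estimate of lapse/arithmetic-error-free
    performance: the subject knows which row matters, so misses cannot
    reflect misallocated attention.  A row with no cued trials inherits the
    pooled rate.
    """
    if counts.n_cued == 0:
        raise ZeroCuedTrialsError(
            "no cued trials in block; pool across sessions or assume A = 1"
        )
    pooled = (counts.n_correct_cued_top + counts.n_correct_cued_bottom) / counts.n_cued
    a_top = (
        counts.n_correct_cued_top / counts.n_cued_top if counts.n_cued_top else pooled
    )
    a_bottom = (
        counts.n_correct_cued_bottom / counts.n_cued_bottom
        if counts.n_cued_bottom
        else pooled
    )
    return AccuracyProfile(a_top, a_bottom, pooled)


def pool_blocks(counts_list: Sequence[BlockCounts]) -> BlockCounts:
    """Elementwise sum of count fields across blocks."""
    if not counts_list:
        raise EstimationError("cannot pool an empty list of blocks")
    fields = [f.name for f in dataclasses.fields(BlockCounts)]
    return BlockCounts(
        **{f: sum(getattr(c, f) for c in counts_list) for f in fields}
    )


def with_cued_from(counts: BlockCounts, accuracy_source: BlockCounts) -> BlockCounts:
    """Keep ``counts``' uncued tallies but take cued tallies from a wider pool.

    Used to estimate a half-session block with session- or pooled-session
    cued accuracy, since cued trials are sparse (11 per half-session).
    """
    return dataclasses.replace(
        counts,
        n_cued_top=accuracy_source.n_cued_top,
        n_correct_cued_top=accuracy_source.n_correct_cued_top,
        n_cued_bottom=accuracy_source.n_cued_bottom,
        n_correct_cued_bottom=accuracy_source.n_correct_cued_bottom,
    )


def _rates_from_counts(counts: BlockCounts) -> RatePair:
    return RatePair(
        counts.n_correct_uncued_top / counts.n_uncued_top,
        counts.n_correct_uncued_bottom / counts.n_uncued_bottom,
    )


def _assume_perfect_solution(rates: RatePair, n_options: int) -> AttentionSolution:
    # A = 1 with g fixed at chance: each conditional-rate equation alone
    # determines p; the two single-equation solutions are averaged.
    g = chance_guess_rate(n_options)
    q = 1.0 - g
    p_top = (rates.pct - g) / q
    p_bottom = (1.0 - rates.pcb) / q
    return classify_solution(
        AttentionSolution((p_top + p_bottom) / 2.0, g, VARIANT_LINEAR, VALID)
    )


def estimate_block(
    counts: BlockCounts,
    policy: str = "session_accuracy",
    *,
    pooled_counts: Optional[BlockCounts] = None,
    variant: str = VARIANT_PAPER,
    n_options: int = 7,
) -> BlockEstimate:
    """Invert a block's tallies into an attention solution, with fallbacks.

    ``policy`` names the starting rung of the accuracy ladder:

    - ``session_accuracy``: accuracy from this block's own cued trials;
    - ``pooled_accuracy``: accuracy from ``pooled_counts`` (e.g. both
      sessions of a subject);
    - ``assume_perfect``: A = 1 and g fixed at ``1/n_options``.

    If the solution at the starting rung is specious, the ladder advances to
    the next rung; every block therefore yields either a valid solution or
    an explicitly flagged one — no silent drops.  ``variant`` selects the
    equal-accuracy inversion printed in the source equations
    (``equal_accuracy_paper``, default), the algebraically consistent form,
    or the row-specific inversion (``row_accuracy``).
    """
    if policy not in ACCURACY_POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    if counts.n_uncued_top == 0 and counts.n_uncued_bottom == 0:
        raise EstimationError("block has no uncued trials for either row")
    if counts.n_uncued_top == 0 or counts.n_uncued_bottom == 0:
        # One conditional rate has a zero denominator: flagged, not imputed.
        return BlockEstimate(
            counts,
            None,
            None,
            AttentionSolution(None, None, VARIANT_LINEAR, DEGENERATE),
            "none",
        )

    rates = _rates_from_counts(counts)
    rungs = ACCURACY_POLICIES[ACCURACY_POLICIES.index(policy) :]

    estimate: Optional[BlockEstimate] = None
    for rung in rungs:
        if rung == "session_accuracy":
            if counts.n_cued == 0:
                continue  # inherit a wider pool's accuracy
            acc = cued_accuracy(counts)
        elif rung == "pooled_accuracy":
            if pooled_counts is None or pooled_counts.n_cued == 0:
                continue
            acc = cued_accuracy(pooled_counts)
        else:
            acc = AccuracyProfile.uniform(1.0)

        if rung == "assume_perfect":
            sol = _assume_perfect_solution(rates, n_options)
        elif variant == VARIANT_ROW:
            sol = invert_row_accuracy(rates, acc)
        else:
            sol = invert_equal_accuracy(rates, acc.pooled, variant)

        fallback = "none" if rung == policy else _FALLBACK_NAMES[rung]
        estimate = BlockEstimate(counts, rates, acc, sol, fallback)
        if sol.validity == VALID:
            return estimate

    assert estimate is not None  # assume_perfect rung always runs
    return estimate
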