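"""Synthetic generator for the divided-attention digit task.

Reproduces the combinatorial and scheduling structure of the behavioral
procedure: 132-trial sessions (22 cued + 110 uncued) split into halves of
66 with a rest after trial 66; two three-digit rows per trial with digits
drawn from 1-7, no all-identical row, row sums on 7-17 with each of the 11
sums appearing equally often across a session; and seven-option probe
screens containing the matching sum exactly once and never the non-matching
row's sum.  Subjects are simulated by configurable policies (fixed
allocation, probability matcher, maximizer, incremental learner) with a
lapse rate and a two-path log-normal latency model: responses mediated by
attention are fast, correct guesses — which require scanning the probe and
failing to find the computed sum — are slow.

All randomness flows from a single root seed through hierarchical
:class:`numpy.random.SeedSequence` streams, so runs are reproducible
byte-for-byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .estimator import TrialRecord
from .model import ConditionDesign

__all__ = [
    "SUM_RANGE",
    "SESSION_TRIALS",
    "SESSION_CUED",
    "SESSION_UNCUED",
    "HALF_TRIALS",
    "RESPONSE_DEADLINE_MS",
    "ScheduleEntry",
    "SessionSchedule",
    "StimulusTrial",
    "SubjectPolicy",
    "BalancedSumAllocator",
    "SchedulingError",
    "generate_row_digits",
    "build_stimulus_trial",
    "build_session_schedule",
    "simulate_subject",
    "subject_rngs",
    "calibrate_exposure",
]

SUM_RANGE = range(7, 18)  # admissible row sums, 11 values
SESSION_TRIALS = 132
SESSION_CUED = 22
SESSION_UNCUED = 110
HALF_TRIALS = 66
HALF_UNCUED = 55
HALF_CUED = 11
RESPONSE_DEADLINE_MS = 20_000.0

# All ordered digit triples from 1-7 with a given sum, excluding triples of
# three identical digits; uniform sampling over these realises the stimulus
# constraints exactly.
_TRIPLES_BY_SUM: dict[int, np.ndarray] = {
    s: np.array(
        [
            t
            for t in itertools.product(range(1, 8), repeat=3)
            if sum(t) == s and len(set(t)) > 1
        ],
        dtype=np.int64,
    )
    for s in SUM_RANGE
}


class SchedulingError(RuntimeError):
    """The balanced-sum allocator or schedule builder cannot proceed."""


@dataclass(frozen=True)
class ScheduleEntry:
    trial_type: str  # "cued" | "uncued"
    cue: str  # "top" | "bottom" | "none"
    match_row: str  # "top" | "bottom"


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered trial plan for one 132-trial session."""

    condition: ConditionDesign
    session_index: int
    trials: tuple[ScheduleEntry, ...]

    def __post_init__(self) -> None:
        if len(self.trials) != SESSION_TRIALS:
            raise ValueError(f"a session has {SESSION_TRIALS} trials")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_cued(self) -> int:
        return sum(1 for t in self.trials if t.trial_type == "cued")

    @property
    def n_uncued(self) -> int:
        return self.n_trials - self.n_cued

    def half(self, which: int) -> tuple[ScheduleEntry, ...]:
        """Trials of half 1 (trials 1-66) or half 2 (trials 67-132)."""
        if which not in (1, 2):
            raise ValueError("half must be 1 or 2")
        lo = (which - 1) * HALF_TRIALS
        return self.trials[lo : lo + HALF_TRIALS]


@dataclass(frozen=True)
class StimulusTrial:
    """One generated stimulus + probe display."""

    top_digits: tuple[int, int, int]
    bottom_digits: tuple[int, int, int]
    match_row: str
    probe_options: tuple[int, ...]

    @property
    def top_sum(self) -> int:
        return sum(self.top_digits)

    @property
    def bottom_sum(self) -> int:
        return sum(self.bottom_digits)

    @property
    def match_sum(self) -> int:
        return self.top_sum if self.match_row == "top" else self.bottom_sum


@dataclass(frozen=True)
class SubjectPolicy:
    """Latent generative parameters of a simulated subject.

    ``kind``:

    - ``fixed``: attend top with constant probability ``p0``;
    - ``matcher``: set p to the running relative frequency of top-row
      matches seen so far (probability matching);
    - ``maximizer``: attend whichever row has the higher running match
      frequency (ties keep the current p);
    - ``learner``: linear-operator update ``p <- (1-lr)p + lr*1{top matched}``
      after each uncued trial, drifting from matching toward the observed
      base rate with time constant ``1/lr`` trials.

    ``lapse_rate`` is 1 − A: the probability that attention or arithmetic
    fails on a trial.  ``error_mode`` resolves a lapse as a wrong answer
    (``wrong_choice``, matching the multiplicative accuracy model) or a
    uniform guess (``random_guess``, an alternative generative hypothesis).
    Latency locations are log-normal medians in ms; the guess path adds
    ~1500 ms over the attend path by default.
    """

    kind: str = "fixed"
    p0: float = 0.5
    learning_rate: float = 0.05
    lapse_rate: float = 0.0
    error_mode: str = "wrong_choice"
    attend_latency_ms: float = 2500.0
    attend_latency_sigma: float = 0.3
    guess_latency_ms: float = 4000.0
    guess_latency_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "matcher", "maximizer", "learner"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.error_mode not in ("wrong_choice", "random_guess"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        for name in ("p0", "learning_rate", "lapse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "attend_latency_ms",
            "attend_latency_sigma",
            "guess_latency_ms",
            "guess_latency_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_row_digits(
    rng: np.random.Generator, target_sum: int
) -> tuple[int, int, int]:
    """Uniform draw of a digit triple (1-7, not all identical) with given sum."""
    if target_sum not in SUM_RANGE:
        raise ValueError(f"target_sum must lie in [7, 17], got {target_sum}")
    table = _TRIPLES_BY_SUM[target_sum]
    return tuple(int(d) for d in table[rng.integers(len(table))])


class BalancedSumAllocator:
    """Allocate row sums for a session so each of the 11 sums appears equally.

    A 132-trial session needs 264 row sums; 264/11 = 24 appearances each.
    Sums are pre-paired into (top, bottom) per trial with the constraint
    that the two rows of a trial never share a sum (otherwise the probe
    could not exclude the non-matching row's sum), repairing collisions by
    swapping across trials.
    """

    def __init__(self, rng: np.random.Generator, n_trials: int = SESSION_TRIALS):
        if n_trials < 1:
            raise SchedulingError("allocator needs at least one trial")
        n_rows = 2 * n_trials
        base, extra = divmod(n_rows, len(SUM_RANGE))
        quota = {s: base for s in SUM_RANGE}
        if extra:
            for s in rng.choice(list(SUM_RANGE), size=extra, replace=False):
                quota[int(s)] += 1
        if max(quota.values()) > n_trials:
            raise SchedulingError("sum quota exceeds one appearance per trial")
        sums = np.repeat(list(quota), list(quota.values()))
        rng.shuffle(sums)
        top, bottom = sums[0::2].copy(), sums[1::2].copy()
        guard = 0
        while True:
            bad = np.flatnonzero(top == bottom)
            if bad.size == 0:
                break
            guard += 1
            if guard > 1000:
                raise SchedulingError("could not pair distinct row sums")
            for i in bad:
                order = rng.permutation(n_trials)
                for j in order:
                    if (
                        j != i
                        and bottom[j] != top[i]
                        and bottom[i] != top[j]
                    ):
                        bottom[i], bottom[j] = bottom[j], bottom[i]
                        break
        self._pairs = list(zip(top.tolist(), bottom.tolist()))
        self._next = 0

    @property
    def remaining(self) -> int:
        return len(self._pairs) - self._next

    def draw(self) -> tuple[int, int]:
        if self._next >= len(self._pairs):
            raise SchedulingError("balanced-sum allocator exhausted")
        pair = self._pairs[self._next]
        self._next += 1
        return pair


def build_stimulus_trial(
    rng: np.random.Generator, match_row: str, sum_allocator: BalancedSumAllocator
) -> StimulusTrial:
    """Generate one stimulus trial from the allocator's next sum pair.

    The probe lists the matching sum plus six distinct distractors drawn
    uniformly without replacement from 7-17 excluding *both* rows' sums, in
    shuffled order.  Excluding the non-matching row's sum is what makes the
    1/7 correct-guess expectation hold for a subject who attended the wrong
    row: their computed sum is never among the options.
    """
    if match_row not in ("top", "bottom"):
        raise ValueError(f"match_row must be 'top' or 'bottom', got {match_row!r}")
    top_sum, bottom_sum = sum_allocator.draw()
    top = generate_row_digits(rng, top_sum)
    bottom = generate_row_digits(rng, bottom_sum)
    match_sum = top_sum if match_row == "top" else bottom_sum
    candidates = [s for s in SUM_RANGE if s != top_sum and s != bottom_sum]
    picked = rng.permutation(len(candidates))[:6]
    options = [candidates[i] for i in picked] + [match_sum]
    order = rng.permutation(7)
    return StimulusTrial(
        top_digits=top,
        bottom_digits=bottom,
        match_row=match_row,
        probe_options=tuple(options[i] for i in order),
    )


def _half_entries(
    rng: np.random.Generator, n_uncued_top: int, n_cued_top: int
) -> list[ScheduleEntry]:
    entries = [
        ScheduleEntry("uncued", "none", "top") for _ in range(n_uncued_top)
    ] + [
        ScheduleEntry("uncued", "none", "bottom")
        for _ in range(HALF_UNCUED - n_uncued_top)
    ]
    entries += [
        ScheduleEntry("cued", "top", "top") for _ in range(n_cued_top)
    ] + [
        ScheduleEntry("cued", "bottom", "bottom")
        for _ in range(HALF_CUED - n_cued_top)
    ]
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


def build_session_schedule(
    rng: np.random.Generator, condition: ConditionDesign, session_index: int = 1
) -> SessionSchedule:
    """Build one session's trial order for a condition.

    Uncued top-match counts realise PT as closely as integers allow: the
    first half gets ``round(PT*55)``, the session total is the nearest
    integer to ``PT*110``, and the second half carries the residual.  Cued
    trials are 11 per half with top-cue probability 0.55 in the first half
    and 0.45 in the second (6/11 then 5/11).  Order within each half is a
    uniform shuffle.
    """
    pt = condition.p_top_match
    total_top = int(round(pt * SESSION_UNCUED))
    first_top = int(round(pt * HALF_UNCUED))
    second_top = total_top - first_top
    if not 0 <= second_top <= HALF_UNCUED:  # pragma: no cover - pt in [0,1]
        raise SchedulingError("inconsistent uncued rounding")
    trials = tuple(
        _half_entries(rng, first_top, 6) + _half_entries(rng, second_top, 5)
    )
    return SessionSchedule(condition, session_index, trials)


def subject_rngs(
    root_seed: int, n_subjects: int
) -> list[np.random.Generator]:
    """Independent per-subject generators spawned from one root seed."""
    return [
        np.random.default_rng(ss)
        for ss in np.random.SeedSequence(root_seed).spawn(n_subjects)
    ]


def _latency(
    rng: np.random.Generator, median_ms: float, sigma: float
) -> float:
    lat = median_ms * float(np.exp(rng.normal(0.0, sigma)))
    return round(min(lat, RESPONSE_DEADLINE_MS), 3)


def simulate_subject(
    schedules: Sequence[SessionSchedule],
    policy: SubjectPolicy,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Simulate one subject over one or more session schedules.

    Uncued trials: the top row is attended with the current allocation p;
    with probability ``lapse_rate`` the trial fails (per ``error_mode``);
    otherwise an attended match is answered correctly via the attend
    latency path, and a missed match triggers a uniform guess over the
    seven probe options via the (slower) guess path.  Cued trials: the cued
    row is attended and answered correctly with probability
    ``1 - lapse_rate``.  Adaptive policies update after every uncued trial
    from the revealed matching row.
    """
    records: list[TrialRecord] = []
    p = policy.p0
    top_matches = 0
    uncued_seen = 0

    for schedule in schedules:
        allocator = BalancedSumAllocator(rng, n_trials=len(schedule.trials))
        for trial_idx, entry in enumerate(schedule.trials, start=1):
            stim = build_stimulus_trial(rng, entry.match_row, allocator)
            match_sum = stim.match_sum

            if entry.trial_type == "cued":
                attended = entry.cue
            elif policy.kind == "maximizer" and uncued_seen > 0 and (
                2 * top_matches != uncued_seen
            ):
                attended = "top" if 2 * top_matches > uncued_seen else "bottom"
            else:
                attended = "top" if rng.random() < p else "bottom"

            lapsed = policy.lapse_rate > 0.0 and rng.random() < policy.lapse_rate
            if lapsed:
                if policy.error_mode == "wrong_choice":
                    wrong = [o for o in stim.probe_options if o != match_sum]
                    response = wrong[rng.integers(len(wrong))]
                else:
                    response = stim.probe_options[rng.integers(7)]
                latency = _latency(
                    rng, policy.guess_latency_ms, policy.guess_latency_sigma
                )
            elif attended == entry.match_row:
                response = match_sum
                latency = _latency(
                    rng, policy.attend_latency_ms, policy.attend_latency_sigma
                )
            else:
                # Computed the wrong row's sum; it is absent from the probe,
                # so the subject scans all options and guesses uniformly.
                response = stim.probe_options[rng.integers(7)]
                latency = _latency(
                    rng, policy.guess_latency_ms, policy.guess_latency_sigma
                )

            records.append(
                TrialRecord(
                    session=schedule.session_index,
                    trial=trial_idx,
                    trial_type=entry.trial_type,
                    cue=entry.cue,
                    top_digits=stim.top_digits,
                    bottom_digits=stim.bottom_digits,
                    match_row=entry.match_row,
                    probe_options=stim.probe_options,
                    response=int(response),
                    correct=bool(response == match_sum),
                    latency_ms=latency,
                )
            )

            if entry.trial_type == "uncued":
                top_matched = entry.match_row == "top"
                top_matches += top_matched
                uncued_seen += 1
                if policy.kind == "matcher":
                    p = top_matches / uncued_seen
                elif policy.kind == "learner":
                    p = (1.0 - policy.learning_rate) * p + (
                        policy.learning_rate * top_matched
                    )
    return records


def calibrate_exposure(
    psychometric_slope: float,
    psychometric_midpoint: float,
    rng: np.random.Generator,
    *,
    floor_ms: float = 10.0,
    max_blocks: int = 200,
) -> float:
    """Staircase search for the shortest exposure sustaining ~90% cued accuracy.

    The simulated subject's cued accuracy follows a logistic psychometric
    function of stimulus duration with the given slope (per ms) and
    midpoint (ms).  The procedure mirrors the calibration phase: a coarse
    descending series (600, 400, 300, 200, 150 ms; 4-trial blocks), then a
    staircase in 16-trial blocks that shortens the exposure while observed
    accuracy stays at or above 90% (a 100% block suggests room to shorten),
    lengthens it when accuracy falls below 90%, and halves the step at each
    reversal down to a ``floor_ms`` step.  Returns the shortest duration
    that met the criterion during refinement.
    """
    if psychometric_slope <= 0:
        raise ValueError("psychometric slope must be positive (monotone accuracy)")

    def acc(duration: float) -> float:
        z = psychometric_slope * (duration - psychometric_midpoint)
        return 1.0 / (1.0 + np.exp(-z))

    def block(duration: float, n: int) -> float:
        return rng.binomial(n, acc(duration)) / n

    coarse = [600.0, 400.0, 300.0, 200.0, 150.0]
    passing = [d for d in coarse if block(d, 4) >= 0.9]
    current = min(passing) if passing else coarse[0]

    step = 50.0
    best: Optional[float] = None
    prev_down: Optional[bool] = None
    for _ in range(max_blocks):
        if step < floor_ms:
            break
        ok = block(current, 16) >= 0.9
        if ok and (best is None or current < best):
            best = current
        if prev_down is not None and prev_down != ok:
            step /= 2.0
        prev_down = ok
        current = max(current - step, floor_ms) if ok else current + step
    return best if best is not None else current
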