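"""Analysis surface: blocking, allocation lines, deviations, latencies, recovery.

The unit of analysis is the half-session block (66 trials: 55 uncued + 11
cued), labelled 1A/1B/2A/2B across two sessions.  Per-condition mean
allocation estimates are regressed on stimulus predictiveness (PT): a slope
of 1 with intercept 0 is perfect probability matching, while maximizing
pushes the fitted slope above 1 (allocations at 0 and 1).  Deviations from
the maximizing solution (0 when PT < 0.5, 1 when PT > 0.5) are square-root
transformed, and latencies of correct responses are summarised by trial
class — correct guesses at the less predictive stimulus are expected to be
slow, attention-mediated responses fast.  ``recovery_experiment`` closes
the loop: simulate cohorts with known latent parameters, estimate them
back, and report bias/RMSE/specious rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimator import (
    BlockEstimate,
    TrialRecord,
    estimate_block,
    pool_blocks,
    tally_block,
    with_cued_from,
)
from .model import VALID, VARIANT_PAPER, ConditionDesign
from .simulator import (
    HALF_TRIALS,
    SubjectPolicy,
    build_session_schedule,
    simulate_subject,
    subject_rngs,
)

__all__ = [
    "Block",
    "AllocationPoint",
    "DeviationRecord",
    "DegenerateFitError",
    "ExcludedConditionError",
    "BLOCK_LABELS",
    "LATENCY_CLASSES",
    "partition_blocks",
    "fit_allocation_line",
    "deviation_from_maximizing",
    "latency_summary",
    "estimate_subject_blocks",
    "RecoveryConfig",
    "RecoveryReport",
    "recovery_experiment",
]

BLOCK_LABELS = ("1A", "1B", "2A", "2B")
LATENCY_CLASSES = ("cued", "uncued_more_predictive", "uncued_less_predictive")


class DegenerateFitError(ValueError):
    """The allocation line cannot be fitted (no spread in predictiveness)."""


class ExcludedConditionError(ValueError):
    """The 1:1 condition has no maximizing solution and is excluded."""


@dataclass(frozen=True)
class Block:
    """One half-session of trials; ``complete`` when all 66 are present."""

    label: str
    records: tuple[TrialRecord, ...]
    complete: bool


@dataclass(frozen=True)
class AllocationPoint:
    """Condition-level mean allocation at a given predictiveness."""

    predictiveness: float
    allocation: float
    block_label: str = ""
    spread: float = float("nan")


@dataclass(frozen=True)
class DeviationRecord:
    """Distance from the maximizing solution and its sqrt transform."""

    deviation: float
    transformed: float


def partition_blocks(records: Sequence[TrialRecord]) -> list[Block]:
    """Split a trial log into half-session blocks (1A, 1B, 2A, ...).

    The boundary is the rest period after trial 66.  Incomplete blocks are
    returned flagged (``complete=False``), never silently truncated.
    """
    ordered = sorted(records, key=lambda r: (r.session, r.trial))
    groups: dict[tuple[int, int], list[TrialRecord]] = {}
    for rec in ordered:
        half = 1 if rec.trial <= HALF_TRIALS else 2
        groups.setdefault((rec.session, half), []).append(rec)
    blocks = []
    for (session, half), recs in sorted(groups.items()):
        label = f"{session}{'A' if half == 1 else 'B'}"
        blocks.append(Block(label, tuple(recs), complete=len(recs) == HALF_TRIALS))
    return blocks


PointLike = Union[AllocationPoint, tuple]


def fit_allocation_line(points: Sequence[PointLike]) -> tuple[float, float]:
    """OLS of allocation on predictiveness over condition means.

    Returns ``(slope, intercept)``.  Slope 1 / intercept 0 is perfect
    probability matching; maximizing inflates the slope above 1.
    """
    xs, ys = [], []
    for pt in points:
        if isinstance(pt, AllocationPoint):
            xs.append(pt.predictiveness)
            ys.append(pt.allocation)
        else:
            xs.append(float(pt[0]))
            ys.append(float(pt[1]))
    if len(xs) < 2:
        raise DegenerateFitError("need at least two points")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("all predictiveness values are equal")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    return float(slope), float(intercept)


def deviation_from_maximizing(
    p_hat: float, condition: ConditionDesign
) -> DeviationRecord:
    """Recode an allocation estimate as distance from the maximizing policy.

    Maximizing predicts p = 0 when PT < 0.5 and p = 1 when PT > 0.5, so the
    deviation is ``p_hat`` or ``1 - p_hat`` respectively.  The square-root
    transform tames the pile-up near zero.  PT = 0.5 has no maximizing
    solution and raises :class:`ExcludedConditionError`.
    """
    pt = condition.p_top_match
    if abs(pt - 0.5) < 1e-12:
        raise ExcludedConditionError("the 1:1 condition is excluded")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must lie in [0, 1], got {p_hat}")
    deviation = p_hat if pt < 0.5 else 1.0 - p_hat
    return DeviationRecord(deviation, math.sqrt(deviation))


def _more_predictive_row(
    records: Sequence[TrialRecord], condition: ConditionDesign
) -> str:
    pt = condition.p_top_match
    if pt > 0.5:
        return "top"
    if pt < 0.5:
        return "bottom"
    # 1:1 condition: split by which row drew more correct uncued responses
    # over the whole run; ties assign the top row.
    top = sum(
        1
        for r in records
        if r.trial_type == "uncued" and r.correct and r.match_row == "top"
    )
    bottom = sum(
        1
        for r in records
        if r.trial_type == "uncued" and r.correct and r.match_row == "bottom"
    )
    return "top" if top >= bottom else "bottom"


def latency_summary(
    records: Sequence[TrialRecord], condition: ConditionDesign
) -> pd.DataFrame:
    """Mean correct-response latency per block and trial class.

    Classes: cued, uncued with the more predictive row correct, uncued with
    the less predictive row correct.  Only correct trials enter the means;
    an empty class appears with ``n = 0`` and NaN statistics rather than
    being dropped.
    """
    more = _more_predictive_row(records, condition)
    rows = []
    for block in partition_blocks(records):
        samples: dict[str, list[float]] = {c: [] for c in LATENCY_CLASSES}
        for rec in block.records:
            if not rec.correct:
                continue
            if rec.trial_type == "cued":
                cls = "cued"
            elif rec.match_row == more:
                cls = "uncued_more_predictive"
            else:
                cls = "uncued_less_predictive"
            samples[cls].append(rec.latency_ms)
        for cls in LATENCY_CLASSES:
            lat = np.asarray(samples[cls], dtype=float)
            n = lat.size
            rows.append(
                {
                    "block": block.label,
                    "trial_class": cls,
                    "n": n,
                    "mean_latency_ms": lat.mean() if n else np.nan,
                    "sem_latency_ms": (
                        lat.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def estimate_subject_blocks(
    records: Sequence[TrialRecord],
    *,
    policy: str = "session_accuracy",
    variant: str = VARIANT_PAPER,
) -> list[tuple[str, BlockEstimate]]:
    """Half-session block estimates for one subject's log.

    Rates come from each block's own uncued trials; the accuracy term comes
    from the enclosing session's cued trials (cued trials are too sparse at
    the half-session level), with the subject's pooled sessions as the
    fallback rung.
    """
    blocks = partition_blocks(records)
    session_counts = {
        s: tally_block([r for r in records if r.session == s])
        for s in sorted({r.session for r in records})
    }
    pooled = pool_blocks(list(session_counts.values()))
    out = []
    for block in blocks:
        session = block.records[0].session
        counts = with_cued_from(tally_block(block.records), session_counts[session])
        est = estimate_block(
            counts, policy, pooled_counts=pooled, variant=variant
        )
        out.append((block.label, est))
    return out


@dataclass(frozen=True)
class RecoveryConfig:
    """Settings for a simulate-then-estimate parameter-recovery study."""

    conditions: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
    n_subjects: int = 20
    n_sessions: int = 2
    policy: SubjectPolicy = field(default_factory=SubjectPolicy)
    estimation_policy: str = "session_accuracy"
    variant: str = VARIANT_PAPER


@dataclass(frozen=True)
class RecoveryReport:
    """Per-block estimates plus cohort-level recovery summaries."""

    config: RecoveryConfig
    estimates: pd.DataFrame
    summary: dict

    def text(self) -> str:
        lines = [
            "parameter recovery report",
            "=========================",
            f"conditions (PT): {', '.join(f'{c:g}' for c in self.config.conditions)}",
            f"subjects/condition: {self.config.n_subjects}; "
            f"sessions: {self.config.n_sessions}",
            f"generator policy: {self.config.policy.kind} "
            f"(p0={self.config.policy.p0:g}, lapse={self.config.policy.lapse_rate:g})",
            f"estimator: {self.config.variant} / {self.config.estimation_policy}",
            "",
        ]
        for key, val in self.summary.items():
            if isinstance(val, dict):
                body = ", ".join(f"{k}: {v:.4f}" for k, v in val.items())
                lines.append(f"{key}: {body}")
            elif isinstance(val, float):
                lines.append(f"{key}: {val:.4f}")
            else:
                lines.append(f"{key}: {val}")
        return "\n".join(lines) + "\n"


def recovery_experiment(
    config: RecoveryConfig, rng_or_seed: Union[int, np.random.Generator]
) -> RecoveryReport:
    """Simulate cohorts, re-estimate attention per block, summarise recovery.

    Reports per-block allocation-line slopes across conditions, the fraction
    of specious solutions and of blocks needing each fallback rung, and —
    for fixed-allocation generators — bias and RMSE of the subject-pooled
    estimates of p and g.  Fully reproducible given a seed.
    """
    if isinstance(rng_or_seed, np.random.Generator):
        root = int(rng_or_seed.integers(2**31))
    else:
        root = int(rng_or_seed)

    rows = []
    rngs = subject_rngs(root, config.n_subjects * len(config.conditions))
    idx = 0
    for pt in config.conditions:
        design = ConditionDesign.from_top(pt)
        for subj in range(config.n_subjects):
            rng = rngs[idx]
            idx += 1
            schedules = [
                build_session_schedule(rng, design, session_index=s + 1)
                for s in range(config.n_sessions)
            ]
            records = simulate_subject(schedules, config.policy, rng)
            for label, est in estimate_subject_blocks(
                records, policy=config.estimation_policy, variant=config.variant
            ):
                rows.append(
                    {
                        "condition_pt": pt,
                        "subject": subj,
                        "block": label,
                        "p_hat": est.solution.p,
                        "g_hat": est.solution.g,
                        "validity": est.solution.validity,
                        "variant": est.solution.variant,
                        "fallback": est.fallback_applied,
                    }
                )
            # Subject-pooled estimate (both sessions) for bias/RMSE.
            pooled = pool_blocks([tally_block(records)])
            est = estimate_block(
                pooled, config.estimation_policy, variant=config.variant
            )
            rows.append(
                {
                    "condition_pt": pt,
                    "subject": subj,
                    "block": "pooled",
                    "p_hat": est.solution.p,
                    "g_hat": est.solution.g,
                    "validity": est.solution.validity,
                    "variant": est.solution.variant,
                    "fallback": est.fallback_applied,
                }
            )
    estimates = pd.DataFrame(rows)

    blocks = estimates[estimates["block"] != "pooled"]
    summary: dict = {
        "specious_fraction": float((blocks["validity"] != VALID).mean()),
        "fallback_fractions": {
            name: float((blocks["fallback"] == name).mean())
            for name in ("none", "pooled_sessions", "assumed_perfect")
        },
    }

    slopes = {}
    for label in sorted(blocks["block"].unique()):
        sub = blocks[(blocks["block"] == label) & blocks["p_hat"].notna()]
        means = sub.groupby("condition_pt")["p_hat"].mean()
        if means.index.nunique() >= 2:
            slope, intercept = fit_allocation_line(list(means.items()))
            slopes[label] = slope
    summary["allocation_slope_by_block"] = slopes

    pooled = estimates[(estimates["block"] == "pooled") & estimates["p_hat"].notna()]
    summary["mean_p_hat_by_condition"] = {
        f"{pt:g}": float(v)
        for pt, v in pooled.groupby("condition_pt")["p_hat"].mean().items()
    }
    if config.policy.kind == "fixed":
        err = pooled["p_hat"] - config.policy.p0
        summary["bias_p"] = float(err.mean())
        summary["rmse_p"] = float(np.sqrt((err**2).mean()))
    g = pooled["g_hat"].dropna()
    if len(g):
        summary["mean_g_hat"] = float(g.mean())
        summary["se_g_hat"] = float(g.std(ddof=1) / np.sqrt(len(g)))
    return RecoveryReport(config, estimates, summary)
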