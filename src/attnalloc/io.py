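"""Trial-log CSV format, run configuration, and artifact metadata.

Trial logs are flat UTF-8 CSV files with one header line and a fixed column
order; digit rows are dash-joined (``"3-5-2"``) and the seven probe options
pipe-joined (``"8|11|14|9|16|7|13"``).  Lines beginning with ``#`` before
the header carry run metadata (seed, config hash) and are ignored by the
parser.  The format round-trips exactly: ``read(write(records)) == records``
field for field.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .estimator import TrialRecord, TrialValidationError, validate_record
from .simulator import SubjectPolicy

__all__ = [
    "COLUMNS",
    "TrialLogError",
    "RunConfig",
    "write_trial_log",
    "read_trial_log",
    "read_log_meta",
    "config_hash",
]

COLUMNS = (
    "session",
    "trial",
    "trial_type",
    "cue",
    "top_digits",
    "bottom_digits",
    "match_row",
    "probe_options",
    "response",
    "correct",
    "latency_ms",
)

PathLike = Union[str, Path]


class TrialLogError(ValueError):
    """A trial-log file is missing, empty, or malformed."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for a simulation/estimation run."""

    condition_p_top: float = 0.75
    n_subjects: int = 8
    n_sessions: int = 2
    policy_kind: str = "fixed"
    p0: float = 0.5
    learning_rate: float = 0.05
    lapse_rate: float = 0.0
    error_mode: str = "wrong_choice"
    estimation_policy: str = "session_accuracy"
    variant: str = "equal_accuracy_paper"
    payment_per_correct: float = 0.10
    feedback_interval: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.condition_p_top <= 1.0:
            raise ValueError("condition_p_top must lie in [0, 1]")
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("subject and session counts must be >= 1")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    def to_policy(self) -> SubjectPolicy:
        return SubjectPolicy(
            kind=self.policy_kind,
            p0=self.p0,
            learning_rate=self.learning_rate,
            lapse_rate=self.lapse_rate,
            error_mode=self.error_mode,
        )

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f: data[f] for f in data if f in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def config_hash(config: Union[RunConfig, dict]) -> str:
    """Short stable hash of a resolved configuration."""
    data = asdict(config) if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _format_record(rec: TrialRecord) -> list[str]:
    return [
        str(rec.session),
        str(rec.trial),
        rec.trial_type,
        rec.cue,
        "-".join(str(d) for d in rec.top_digits),
        "-".join(str(d) for d in rec.bottom_digits),
        rec.match_row,
        "|".join(str(o) for o in rec.probe_options),
        str(rec.response),
        "true" if rec.correct else "false",
        f"{rec.latency_ms:.3f}",
    ]


def write_trial_log(
    records: Sequence[TrialRecord],
    path: PathLike,
    meta: Optional[dict] = None,
) -> None:
    """Write records as CSV; ``meta`` key/values become leading # comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow(_format_record(rec))


def _parse_record(row: dict[str, str], line_no: int) -> TrialRecord:
    def fail(msg: str) -> TrialLogError:
        return TrialLogError(f"line {line_no}: {msg}")

    missing = [c for c in COLUMNS if row.get(c) is None]
    if missing:
        raise fail(f"missing column(s) {missing}")
    try:
        top = tuple(int(d) for d in row["top_digits"].split("-"))
        bottom = tuple(int(d) for d in row["bottom_digits"].split("-"))
    except ValueError as exc:
        raise fail(f"non-digit stimulus token: {exc}") from exc
    try:
        probe = tuple(int(o) for o in row["probe_options"].split("|"))
        rec = TrialRecord(
            session=int(row["session"]),
            trial=int(row["trial"]),
            trial_type=row["trial_type"],
            cue=row["cue"],
            top_digits=top,
            bottom_digits=bottom,
            match_row=row["match_row"],
            probe_options=probe,
            response=int(row["response"]),
            correct=row["correct"].strip().lower() in ("true", "1", "yes"),
            latency_ms=float(row["latency_ms"]),
        )
    except ValueError as exc:
        raise fail(str(exc)) from exc
    try:
        validate_record(rec)
    except TrialValidationError as exc:
        raise fail(str(exc)) from exc
    return rec


def read_trial_log(path: PathLike) -> list[TrialRecord]:
    """Read and validate a trial log; failures name the offending line."""
    path = Path(path)
    if not path.exists():
        raise TrialLogError(f"no such trial log: {path}")
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.readlines()
    body = [(i + 1, ln) for i, ln in enumerate(lines) if not ln.startswith("#")]
    body = [(n, ln) for n, ln in body if ln.strip()]
    if not body:
        raise TrialLogError(f"empty trial log: {path}")
    header_line, *data_lines = body
    header = next(csv.reader([header_line[1]]))
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise TrialLogError(f"{path}: missing column(s) {missing}")
    if not data_lines:
        raise TrialLogError(f"trial log has a header but no records: {path}")
    records = []
    for line_no, line in data_lines:
        values = next(csv.reader([line]))
        row = dict(zip(header, values))
        records.append(_parse_record(row, line_no))
    return records


def read_log_meta(path: PathLike) -> dict[str, str]:
    """Parse the leading ``# key: value`` comment lines of a trial log."""
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if ":" in text:
                key, _, value = text.partition(":")
                meta[key.strip()] = value.strip()
    return meta
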