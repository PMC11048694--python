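"""Key-press scoring for looped four-element motor sequences.

Participants repeatedly execute a fixed four-key sequence ("as if in a
loop") for 20 s per trial, on a MIDI piano or a response pad.  The scorer
walks a pointer through the looped target sequence and classifies every
press as *correct*, *wrong key* (a key that is not part of the sequence)
or *wrong order* (an in-sequence key pressed out of turn).  The number of
correct presses per trial is the dependent performance variable; the
error rate is errors divided by total presses.

After a wrong-order press of sequence element ``j`` the pointer
resynchronises to ``(j + 1) mod 4``: the slip is treated as a skip, so a
single out-of-turn press cannot cascade into a run of spurious errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SequenceSpec",
    "TrialScore",
    "ScoringError",
    "score_trial",
    "score_dataset",
    "read_events",
    "write_trial_scores",
]

EVENT_COLUMNS = ["participant", "task", "trial", "press_index", "key", "time_ms"]
SCORE_COLUMNS = [
    "participant",
    "task",
    "trial",
    "correct",
    "wrong_key",
    "wrong_order",
    "total",
    "error_rate",
]


class ScoringError(ValueError):
    """Raised for malformed key-press input."""


@dataclass(frozen=True)
class SequenceSpec:
    """A looped target sequence of exactly four unique keys.

    Parameters
    ----------
    keys
        Ordered key identifiers (opaque strings; a config-level mapping
        binds MIDI note numbers or pad button ids to them).
    hands
        Optional hand/finger labels parallel to ``keys`` (e.g. the piano
        task's right ring, left middle, right thumb, left thumb).
    """

    keys: tuple[str, ...]
    hands: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        keys = tuple(str(k) for k in self.keys)
        object.__setattr__(self, "keys", keys)
        if len(keys) != 4:
            raise ScoringError(f"sequence must have exactly 4 elements, got {len(keys)}")
        if len(set(keys)) != len(keys):
            raise ScoringError(f"sequence keys must be unique, got {keys}")
        if self.hands is not None and len(self.hands) != len(keys):
            raise ScoringError("hands labels must parallel keys")

    def index(self, key: str) -> int:
        return self.keys.index(key)

    def __contains__(self, key: object) -> bool:
        return key in self.keys


@dataclass(frozen=True)
class TrialScore:
    """Per-trial press counts. ``error_rate`` is None when total == 0."""

    correct: int
    wrong_key: int
    wrong_order: int

    @property
    def total(self) -> int:
        return self.correct + self.wrong_key + self.wrong_order

    @property
    def error_rate(self) -> float | None:
        if self.total == 0:
            return None
        return (self.wrong_key + self.wrong_order) / self.total


def _event_keys(events: Iterable) -> list[str]:
    """Extract the ordered key stream from KeyEvent-like rows or bare keys."""
    keys = []
    for i, ev in enumerate(events):
        if isinstance(ev, str):
            key = ev
        elif hasattr(ev, "key"):
            key = ev.key
        elif isinstance(ev, dict):
            key = ev.get("key")
        else:
            key = ev
        if key is None or (isinstance(key, float) and np.isnan(key)) or str(key) == "":
            raise ScoringError(f"event {i}: key identifier missing or not representable ({ev!r})")
        keys.append(str(key))
    return keys


def score_trial(events: Iterable, seq: SequenceSpec) -> TrialScore:
    """Score one trial's ordered press stream against a looped sequence.

    The pointer starts at position 0.  A press equal to the expected key
    increments ``correct`` and advances the pointer (mod 4); a key absent
    from the sequence increments ``wrong_key`` and leaves the pointer
    unchanged; an in-sequence key pressed out of turn increments
    ``wrong_order`` and resynchronises the pointer to the position after
    the pressed key.

    An empty event stream yields all-zero counts with undefined
    (``None``) error rate.
    """
    keys = _event_keys(events)
    correct = wrong_key = wrong_order = 0
    p = 0
    for key in keys:
        if key == seq.keys[p]:
            correct += 1
            p = (p + 1) % 4
        elif key not in seq:
            wrong_key += 1
        else:
            wrong_order += 1
            p = (seq.index(key) + 1) % 4
    return TrialScore(correct=correct, wrong_key=wrong_key, wrong_order=wrong_order)


def score_dataset(
    events: pd.DataFrame,
    seqs: dict[str, SequenceSpec],
    *,
    expected_trials: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Score every observed participant x task x trial of an event log.

    Parameters
    ----------
    events
        Long table with columns ``participant, task, trial, press_index,
        key, time_ms``.  Presses are ordered by ``press_index`` within a
        trial; ties in ``time_ms`` keep file order (stable sort).
    seqs
        Mapping task name -> :class:`SequenceSpec`.
    expected_trials
        When given (e.g. ``range(1, 21)``), missing trials are reported
        with a warning; they are never fabricated.

    Returns
    -------
    DataFrame with one row per observed participant x task x trial
    (columns :data:`SCORE_COLUMNS`); ``error_rate`` is NaN for empty
    trials.
    """
    missing_cols = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing_cols:
        raise ScoringError(f"event table lacks columns: {missing_cols}")
    dup = events.duplicated(subset=["participant", "task", "trial", "press_index"])
    if dup.any():
        bad = events.loc[dup, ["participant", "task", "trial", "press_index"]].iloc[0]
        raise ScoringError(
            "duplicate press: participant=%s task=%s trial=%s press_index=%s"
            % tuple(bad)
        )
    unknown_tasks = set(events["task"].unique()) - set(seqs)
    if unknown_tasks:
        raise ScoringError(f"no SequenceSpec for task(s): {sorted(unknown_tasks)}")

    rows = []
    ordered = events.sort_values(["participant", "task", "trial", "press_index"], kind="stable")
    for (pid, task, trial), grp in ordered.groupby(["participant", "task", "trial"], sort=True):
        ts = score_trial(grp["key"].tolist(), seqs[task])
        rows.append(
            {
                "participant": pid,
                "task": task,
                "trial": int(trial),
                "correct": ts.correct,
                "wrong_key": ts.wrong_key,
                "wrong_order": ts.wrong_order,
                "total": ts.total,
                "error_rate": np.nan if ts.error_rate is None else ts.error_rate,
            }
        )
    out = pd.DataFrame(rows, columns=SCORE_COLUMNS)

    if expected_trials is not None:
        expected = set(int(t) for t in expected_trials)
        for (pid, task), grp in out.groupby(["participant", "task"]):
            absent = sorted(expected - set(grp["trial"]))
            if absent:
                warnings.warn(
                    f"participant {pid}, task {task}: missing trial(s) {absent}",
                    stacklevel=2,
                )
    return out


def read_events(path) -> pd.DataFrame:
    """Read an ``events.csv`` log (header required, UTF-8)."""
    df = pd.read_csv(path, dtype={"key": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ScoringError(f"{path}: missing columns {missing}")
    return df


def write_trial_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)
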