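"""Scorer unit and property tests, checked against an independent
brute-force pointer simulation."""

import numpy as np
import pandas as pd
import pytest

from skillcurve import synth
from skillcurve.scoring import (
    ScoringError,
    SequenceSpec,
    score_dataset,
    score_trial,
)

SEQ = SequenceSpec(keys=("k1", "k2", "k3", "k4"))


def oracle_score(keys, seq_keys):
    """Independent pointer simulation: returns (correct, wrong_key, wrong_order).

    Re-derived from the scoring rules: expected key advances the
    pointer; an out-of-sequence key is a wrong-key error and leaves the
    pointer alone; an in-sequence unexpected key is a wrong-order error
    and the pointer resumes after the pressed key.
    """
    position = {k: i for i, k in enumerate(seq_keys)}
    counts = {"correct": 0, "wrong_key": 0, "wrong_order": 0}
    expected = 0
    for k in keys:
        if k not in position:
            counts["wrong_key"] += 1
        elif position[k] == expected:
            counts["correct"] += 1
            expected = (expected + 1) % len(seq_keys)
        else:
            counts["wrong_order"] += 1
            expected = (position[k] + 1) % len(seq_keys)
    return counts["correct"], counts["wrong_key"], counts["wrong_order"]


@pytest.mark.parametrize(
    "events, expected",
    [
        (list(SEQ.keys) * 3, (12, 0, 0)),                      # perfect loop
        ([], (0, 0, 0)),                                       # degenerate
        (["k1", "k9", "k2", "k4", "k1"], (3, 1, 1)),           # resync example
        (["k2"], (0, 0, 1)),                                   # lone out-of-turn press
        (["x", "x", "x"], (0, 3, 0)),                          # all off-sequence
    ],
)
def test_score_trial_examples(events, expected):
    ts = score_trial(events, SEQ)
    assert (ts.correct, ts.wrong_key, ts.wrong_order) == expected
    assert ts.total == sum(expected)
    if ts.total == 0:
        assert ts.error_rate is None
    else:
        assert ts.error_rate == (expected[1] + expected[2]) / sum(expected)


def test_scorer_matches_bruteforce_oracle():
    """1000 random logs over an 8-key alphabet agree exactly with the
    independent pointer simulation."""
    rng = np.random.default_rng(42)
    alphabet = [f"k{i}" for i in range(1, 5)] + [f"x{i}" for i in range(1, 5)]
    for _ in range(1000):
        keys = list(rng.choice(alphabet, size=rng.integers(0, 61)))
        ts = score_trial(keys, SEQ)
        assert (ts.correct, ts.wrong_key, ts.wrong_order) == oracle_score(keys, SEQ.keys)
        assert ts.correct + ts.wrong_key + ts.wrong_order == ts.total


def test_appending_correct_press_is_monotone():
    """A correct continuation never decreases `correct` or disturbs the
    error counts already scored."""
    rng = np.random.default_rng(7)
    alphabet = [f"k{i}" for i in range(1, 5)] + ["x1"]
    for _ in range(200):
        keys = list(rng.choice(alphabet, size=rng.integers(0, 30)))
        before = score_trial(keys, SEQ)
        # determine the pointer state by replaying, then append the expected key
        c, wk, wo = oracle_score(keys, SEQ.keys)
        pos = {k: i for i, k in enumerate(SEQ.keys)}
        expected = 0
        for k in keys:
            if k in pos:
                expected = (pos[k] + 1) % 4 if pos[k] != expected else (expected + 1) % 4
        after = score_trial(keys + [SEQ.keys[expected]], SEQ)
        assert after.correct == before.correct + 1
        assert (after.wrong_key, after.wrong_order) == (before.wrong_key, before.wrong_order)


def test_sequence_spec_validation():
    with pytest.raises(ScoringError):
        SequenceSpec(keys=("a", "b", "c"))
    with pytest.raises(ScoringError):
        SequenceSpec(keys=("a", "a", "b", "c"))


def test_unrepresentable_key_rejected():
    with pytest.raises(ScoringError, match="event 1"):
        score_trial(["k1", None, "k2"], SEQ)


def _event_df(rows):
    return pd.DataFrame(rows, columns=["participant", "task", "trial",
                                       "press_index", "key", "time_ms"])


def test_score_dataset_perfect_trials():
    rows = []
    for pid in ("a", "b"):
        for trial in (1, 2):
            for i, k in enumerate(SEQ.keys, start=1):
                rows.append((pid, "piano", trial, i, k, 100.0 * i))
    out = score_dataset(_event_df(rows), {"piano": SEQ})
    assert len(out) == 4
    assert (out["error_rate"] == 0).all()
    assert (out["correct"] == 4).all()


def test_score_dataset_duplicate_press_rejected():
    rows = [("a", "piano", 1, 1, "k1", 0.0), ("a", "piano", 1, 1, "k2", 10.0)]
    with pytest.raises(ScoringError, match="duplicate"):
        score_dataset(_event_df(rows), {"piano": SEQ})


def test_score_dataset_reports_missing_trial():
    rows = [("a", "piano", t, 1, "k1", 0.0) for t in range(1, 21) if t != 7]
    with pytest.warns(UserWarning, match=r"missing trial\(s\) \[7\]"):
        out = score_dataset(_event_df(rows), {"piano": SEQ},
                            expected_trials=range(1, 21))
    assert len(out) == 19


def test_generator_roundtrip_counts():
    """Scoring a generated key log recovers the configured counts."""
    target = pd.DataFrame(
        [{"participant": "p1", "task": "piano", "trial": 1,
          "correct": 30, "wrong_key": 2, "wrong_order": 0}]
    )
    events = synth.gen_keylog(target, seed=1)
    out = score_dataset(events, synth.default_sequences())
    row = out.iloc[0]
    assert (row["correct"], row["wrong_key"], row["wrong_order"]) == (30, 2, 0)
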