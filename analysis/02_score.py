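#!/usr/bin/env python
"""Score the raw key-press logs into per-trial performance and errors.

Reads data/synth/events.csv, classifies every press as correct,
wrong-key or wrong-order against the looped four-element target
sequences, and writes results/trial_scores.csv plus a per-task error
summary (trial-1 vs trial-20 error rates, as in the study's error
analysis).
"""

import argparse
from pathlib import Path

from skillcurve import scoring, synth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--events", type=Path, default=ROOT / "data" / "synth" / "events.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "trial_scores.csv")
    args = ap.parse_args()

    events = scoring.read_events(args.events)
    scores = scoring.score_dataset(events, synth.default_sequences(),
                                   expected_trials=range(1, 21))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    scoring.write_trial_scores(scores, args.out)
    print(f"scored {len(scores)} trials -> {args.out}")
    for task, df in scores.groupby("task"):
        first = df[df["trial"] == 1]["error_rate"].mean() * 100
        last = df[df["trial"] == 20]["error_rate"].mean() * 100
        print(f"  {task}: error rate {first:.1f}% (trial 1) -> {last:.1f}% (trial 20)")


if __name__ == "__main__":
    main()
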