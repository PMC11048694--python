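#!/usr/bin/env python
"""Generate the synthetic study that all downstream analyses consume.

Emulates the study conditions: 86 older adults learning two four-element
motor sequences (piano and response pad), 20 trials of 20 s each, a
15-indicator cognito-motor test battery, per-trial gaze-change counts,
and musicality covariates.  Writes events.csv, trial_scores.csv,
battery.csv, gaze.csv, musicality.csv and truth.json to data/synth/.
"""

import argparse
from pathlib import Path

from skillcurve import synth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=ROOT / "data" / "synth")
    args = ap.parse_args()

    study = synth.simulate_study(seed=args.seed)
    study.write_dir(args.out_dir)
    n_ev = len(study.events)
    print(f"synthetic study written to {args.out_dir}")
    print(f"  participants: {study.config.n_participants}, "
          f"tasks: {study.config.tasks}, trials: {study.config.trials}")
    print(f"  key-press events: {n_ev}, battery: {study.battery.shape}, "
          f"gaze rows: {len(study.gaze)}")


if __name__ == "__main__":
    main()
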