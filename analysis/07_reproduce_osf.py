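#!/usr/bin/env python
"""Re-run the full pipeline on the study's deposited human dataset.

The deposit (https://osf.io/x3zuf/) must be downloaded manually into
data/osf/ together with a column-mapping file data/osf/mapping.yaml
(the deposit's file layout is not documented, so the mapping binds its
column names to the pipeline schemas; see skillcurve.pipeline.ingest_osf).
The pipeline then reproduces the published quantities: CFA fit indices,
population learning rates per task, gaze change points, and the
trial-wise ability associations.
"""

import argparse
import sys
import warnings
from pathlib import Path

import yaml

from skillcurve import curves, pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--deposit", type=Path, default=ROOT / "data" / "osf")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--full", action="store_true",
                    help="study MCMC profile (4 chains x 5000/2000)")
    args = ap.parse_args()

    mapping_file = args.deposit / "mapping.yaml"
    if not mapping_file.exists():
        sys.exit(
            f"deposit not found: place the downloaded files in {args.deposit} "
            f"and describe their columns in {mapping_file}"
        )
    mapping = yaml.safe_load(mapping_file.read_text())
    files = pipeline.ingest_osf(args.deposit, mapping, ROOT / "data" / "osf_ingested")
    mc = (curves.FULL_CONFIG if args.full else curves.REDUCED_CONFIG).with_seed(args.seed)
    cfg = pipeline.RunConfig(out_dir=ROOT / "results" / "osf_run", mcmc=mc,
                             seed=args.seed, **{k: str(v) for k, v in files.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = pipeline.run_pipeline(cfg)
    print(f"report -> {cfg.out_dir} (wall clock {report['wall_clock_s']} s)")


if __name__ == "__main__":
    main()
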