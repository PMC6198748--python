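#!/usr/bin/env python
"""Run the full per-fibril workflow over the simulated cohort.

Reads results/raw/cohort.yaml (written by 01_simulate_cohort.py) and writes
the tensile summary table, the per-fibril stress-strain files, the
post-rupture imaging table and a run log under results/pipeline/.
"""

from pathlib import Path

from fibrilmech import dataset_io

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg_path = RESULTS / "raw" / "cohort.yaml"
    if not cfg_path.exists():
        raise SystemExit("run 01_simulate_cohort.py first "
                         f"({cfg_path} not found)")
    out = dataset_io.run_pipeline(cfg_path, RESULTS / "pipeline")
    for line in out["log"]:
        print(line)
    if out["failures"]:
        raise SystemExit(f"stage failures: {out['failures']}")
    print(f"tables written to {RESULTS / 'pipeline'}")


if __name__ == "__main__":
    main()
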