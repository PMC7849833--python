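#!/usr/bin/env python
"""Calibration and power benchmarks at the full study conditions.

Runs the expression screen on all-null cohorts (2000 genes x 300 samples),
on cohorts with 20 planted effects, on copy-number-confounded cohorts, and
the methylation screen on cohorts with 10 planted probe effects; writes the
measured calibration/recovery quantities to results/benchmarks.json.

By default each benchmark uses 3 seeds to keep the walkthrough quick; pass
--seeds N for the deeper runs used by scripts/acceptance.py (which defaults
to 20/10/10/5).
"""

import argparse
import json
from pathlib import Path

from regsnv import evaluation

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

ap = argparse.ArgumentParser()
ap.add_argument("--seeds", type=int, default=3, help="seeds per benchmark")
ap.add_argument("--base-seed", type=int, default=1000)
args = ap.parse_args()

seeds = list(range(args.base_seed, args.base_seed + args.seeds))

out = {
    "null_calibration": evaluation.null_calibration(seeds),
    "permutation_uniformity": evaluation.permutation_uniformity(args.base_seed),
    "expression_recovery": evaluation.recovery_benchmark(seeds),
    "cna_filter": evaluation.cna_filter_benchmark(seeds),
    "methylation_recovery": evaluation.methylation_recovery_benchmark(seeds),
}
(RESULTS / "benchmarks.json").write_text(json.dumps(out, indent=2) + "\n")
print(json.dumps(out, indent=2))
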