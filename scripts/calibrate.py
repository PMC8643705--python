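#!/usr/bin/env python
"""Reproduce the default calibration by grid search (see adaswitch.calibrate).

Usage:
    python scripts/calibrate.py [--seed N] [--budget coarse|full] [--out PATH]

Writes a calibration YAML compatible with SimParams.from_yaml /
``adaswitch --help`` pipelines.  The shipped default calibration was
generated with this procedure at the 'full' budget.
"""

import argparse

from adaswitch.calibrate import run_calibration


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--budget", choices=["coarse", "full"], default="coarse")
    ap.add_argument("--out", default="calibration.yaml")
    args = ap.parse_args()
    params = run_calibration(seed=args.seed, budget=args.budget)
    params.to_yaml(args.out)
    print(f"calibration written to {args.out}")


if __name__ == "__main__":
    main()
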