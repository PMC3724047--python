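#!/usr/bin/env python
"""(Re)derive the packaged observation-scale calibration table.

Iteratively plants inter-region correlations so that the measured
system-block means — planted-region time courses through the default
preprocessing — equal the packaged scenario's targets, then writes the
calibration JSON the generator loads at run time (keyed by a scenario
fingerprint).  Runs in a few minutes; only needed after changing the
default scenario or the preprocessing defaults.

Usage:  python scripts/calibrate_scenario.py [--runs 48] [--iters 3]
"""

from __future__ import annotations

import argparse

from dmndyn.scenario import default_scenario
from dmndyn.simulate import calibrate_planted_covariance, save_calibration


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--runs", type=int, default=48)
    ap.add_argument("--iters", type=int, default=3)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()
    sc = default_scenario()
    matrices = calibrate_planted_covariance(
        sc, n_runs=args.runs, n_iter=args.iters, verbose=True
    )
    save_calibration(sc, matrices, args.out)
    print("calibration written")


if __name__ == "__main__":
    main()
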