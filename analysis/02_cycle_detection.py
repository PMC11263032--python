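#!/usr/bin/env python
"""Detection power for planted 24-h cycles vs modulation depth and length.

For each (circadian depth, record length) condition, a synthetic cohort is
generated and the fraction of patients with a significant 24-h cycle in
the variance measure (VM) is recorded.  Power should rise with depth and
with record length; depth 0 is a negative control near the nominal 5%.

Scaled down for desk runtime: 20 patients, 2 channels, 2 windows/hour
(duty-cycled); the planted structure is untouched.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ictalcycles.pipeline import patient_cycle, patient_hourly
from ictalcycles.synth import SyntheticConfig, simulate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-patients", type=int, default=20)
    ap.add_argument("--n-sim", type=int, default=2000)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    rows = []
    for depth in (0.0, 0.2, 0.5):
        for n_days in (5, 14):
            cfg = SyntheticConfig(n_patients=args.n_patients, n_channels=2,
                                  n_days=n_days, windows_per_hour=2,
                                  circadian_depth=depth, ied_rate_depth=depth,
                                  coupling_depth=0.0,
                                  seed=args.seed + 1000 * n_days + int(100 * depth))
            cohort = simulate_cohort(cfg, metrics=("VM",))
            rng = np.random.default_rng(args.seed)
            sig = sum(patient_cycle(patient_hourly(pw, "VM"),
                                    n_sim=args.n_sim, rng=rng).significant
                      for pw in cohort)
            rows.append(dict(depth=depth, n_days=n_days,
                             n_patients=args.n_patients, n_significant=sig,
                             fraction=sig / args.n_patients))
            print(f"depth={depth:<4} days={n_days:<3} -> "
                  f"{sig}/{args.n_patients} significant 24-h VM cycles")

    df = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "cycle_power.csv", index=False)
    strong = df[(df.depth == 0.5) & (df.n_days == 14)].fraction.iloc[0]
    null = df[(df.depth == 0.0) & (df.n_days == 14)].fraction.iloc[0]
    print(f"\nAt depth 0.5 / 14 days the VM cycle is found in {strong:.0%} of "
          f"patients; the structureless control sits at {null:.0%}.")
    print(f"Wrote {args.out_dir / 'cycle_power.csv'}")


if __name__ == "__main__":
    main()
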