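#!/usr/bin/env python
"""Seizure phase locking: von Mises recovery and the metric-vs-clock gap.

Part A plants seizures at von Mises-distributed phases of the circadian
driver (kappa in {0.5, 1, 2}) and checks that the pipeline PLV (hourly VM
series -> 2-30 h band phase -> onset-hour phase -> mean resultant) tracks
the population mean resultant I1(k)/I0(k).

Part B runs all five markers plus the cosine daily function (CDF) on one
cohort and reports the group PLV (mean +- SD across patients).  Because
the physiological driver drifts against the wall clock day to day, the
clock-only CDF phase-locks worse than markers that track the driver; the
noisy discharge rate (IEDF) sits between.

Scaled down for desk runtime (8 channels, a few windows/hour).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from ictalcycles.pipeline import patient_hourly, patient_plv, run_cohort
from ictalcycles.summary import summarize_cohort
from ictalcycles.synth import SyntheticConfig, simulate_cohort, simulate_patient_windows

METRICS = ("VM", "TCM", "IEDF", "NS", "SCM")


def recovery(seed: int, out_dir: Path) -> None:
    rows = []
    for kappa in (0.5, 1.0, 2.0):
        plvs = []
        for pid in range(8):
            cfg = SyntheticConfig(n_channels=2, n_days=14, windows_per_hour=4,
                                  circadian_depth=0.5, seizure_phase_kappa=kappa,
                                  n_seizures=30, seed=seed + 50 * int(10 * kappa) + pid)
            pw = simulate_patient_windows(cfg, pid, metrics=("VM",))
            pv, _ = patient_plv(patient_hourly(pw, "VM"), pw.seizure_onsets_s)
            plvs.append(pv)
        expect = i1(kappa) / i0(kappa)
        rows.append(dict(kappa=kappa, expected_plv=expect,
                         pipeline_plv=float(np.mean(plvs)),
                         sd=float(np.std(plvs, ddof=1)), n_patients=len(plvs)))
        print(f"kappa={kappa:<4} I1/I0={expect:.3f}  pipeline PLV="
              f"{np.mean(plvs):.3f} +- {np.std(plvs, ddof=1):.3f}")
    pd.DataFrame(rows).to_csv(out_dir / "plv_recovery.csv", index=False)


def ordering(seed: int, out_dir: Path) -> None:
    cfg = SyntheticConfig(n_patients=12, n_channels=8, n_days=14,
                          windows_per_hour=4, seed=seed + 9000)
    cohort = simulate_cohort(cfg, metrics=METRICS, ns_samples=96)
    results, hourly = run_cohort(cohort, METRICS, n_sim=1000,
                                 rng=np.random.default_rng(seed))
    summ = summarize_cohort(results, hourly)
    summ["plv_summary"].to_csv(out_dir / "plv_ordering.csv")
    print("\nGroup PLV (mean +- SD across patients):")
    for m, row in summ["plv_summary"].iterrows():
        print(f"  {m:<5} {row['mean']:.2f} +- {row['sd']:.2f}")
    crit = summ["plv_summary"].loc[["VM", "TCM", "NS", "SCM"], "mean"].mean()
    print(f"\nCriticality markers average {crit:.2f}; the clock-only CDF "
          f"reaches {summ['plv_summary'].loc['CDF', 'mean']:.2f} (it loses "
          f"only the day-to-day driver drift).")
    print(f"IEDF at {summ['plv_summary'].loc['IEDF', 'mean']:.2f} is "
          f"count-noise limited: at this duty cycle "
          f"({cfg.windows_per_hour} windows/hour) its hourly discharge "
          f"totals are small, so its phase estimate is the noisiest.")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    recovery(args.seed, args.out_dir)
    ordering(args.seed, args.out_dir)
    print(f"\nWrote {args.out_dir / 'plv_recovery.csv'} and "
          f"{args.out_dir / 'plv_ordering.csv'}")


if __name__ == "__main__":
    main()
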