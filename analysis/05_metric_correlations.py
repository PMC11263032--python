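#!/usr/bin/env python
"""Cohort summary: cycle counts, group PLV and inter-metric correlations.

Runs all five markers plus the cosine daily function (CDF) on one
synthetic cohort sharing a single circadian driver, then writes the
cohort table: patients with significant 24-h cycles per marker, group PLV
(mean +- SD), and the patient-averaged Pearson correlation matrix between
hourly marker series (with one-sample t-test stars on Fisher-z values).
With a shared driver every marker should correlate positively with the
CDF and with each other.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from ictalcycles.pipeline import run_cohort
from ictalcycles.summary import summarize_cohort
from ictalcycles.synth import SyntheticConfig, simulate_cohort

METRICS = ("VM", "TCM", "IEDF", "NS", "SCM")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-patients", type=int, default=12)
    ap.add_argument("--n-sim", type=int, default=2000)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = SyntheticConfig(n_patients=args.n_patients, n_channels=8,
                          n_days=14, windows_per_hour=2, seed=args.seed + 77)
    cohort = simulate_cohort(cfg, metrics=METRICS, ns_samples=96)
    results, hourly = run_cohort(cohort, METRICS, n_sim=args.n_sim,
                                 rng=np.random.default_rng(args.seed))
    summ = summarize_cohort(results, hourly)

    summ["cycle_counts"].to_csv(args.out_dir / "cycle_counts.csv")
    summ["plv_summary"].to_csv(args.out_dir / "plv_summary.csv")
    summ["correlations"].round(3).to_csv(args.out_dir / "correlations.csv")
    summ["correlation_stars"].to_csv(args.out_dir / "correlation_stars.csv")
    (args.out_dir / "summary.json").write_text(json.dumps(
        {k: v.to_dict() for k, v in summ.items()}, indent=2, default=str) + "\n")

    print("Patients with significant 24-h cycles:")
    print(summ["cycle_counts"].to_string())
    print("\nGroup PLV:")
    print(summ["plv_summary"].round(3).to_string())
    print("\nMean inter-metric Pearson r (per patient, then averaged):")
    print(summ["correlations"].round(2).to_string())
    cdf_r = summ["correlations"].loc["CDF"].drop("CDF")
    print(f"\nEvery marker correlates with the clock reference "
          f"(CDF r: {cdf_r.min():.2f}..{cdf_r.max():.2f}), as expected when "
          f"one circadian driver gates them all.")
    print(f"Wrote cohort tables to {args.out_dir}/")


if __name__ == "__main__":
    main()
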