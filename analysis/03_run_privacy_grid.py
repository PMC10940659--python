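"""Train the privacy grid: four budgets x three seeds on the desk cohort.

This is the compute step (~10 minutes on one CPU).  Each cell calibrates its
noise multiplier, trains the group-normalized residual CNN with DP-SGD (or
plain training at epsilon = infinity), and persists the per-record prediction
table; the bundle with all metrics lands in results/experiment/bundle.json.
"""

from __future__ import annotations

import logging

from dpfair.pipeline import desk_experiment, run_experiment


def main() -> None:
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(levelname)s %(message)s")
    cfg = desk_experiment(seed=0, output_dir="results/experiment")
    bundle = run_experiment(cfg)
    agg = bundle["aggregate"]["per_epsilon"]
    print("\nmacro AUROC (mean +- sd over seeds):")
    for key in ("0.5", "2", "8", "inf"):
        a = agg[key]
        print(f"  eps={key:>4}: {100 * a['macro_auroc_mean']:.2f} "
              f"+- {100 * a['macro_auroc_std']:.2f} %")
    print("\nparity difference, minority sex subgroup (percent):")
    for key in ("0.5", "2", "8", "inf"):
        a = agg[key]
        print(f"  eps={key:>4}: {100 * a['ptd_sex_mean']:+.2f} "
              f"+- {100 * a['ptd_sex_std']:.2f}")


if __name__ == "__main__":
    main()
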