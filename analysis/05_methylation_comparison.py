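#!/usr/bin/env python
"""Compare the transcriptional gauge with a linear methylation clock.

Simulates a CpG beta matrix whose informative probes track the calibrated
age transform of (age + methylation offset), with the methylation offset
correlated rho=0.7 with the transcriptional offset; applies the generated
clock coefficients; and correlates methylation delta (meth age - chron age)
with the transcriptional delta age per cohort.

Reads scratch/derived/ (run 02 first); writes
results/methylation_comparison.tsv.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from brainclock import io as bio
from brainclock._utils import child_seed
from brainclock.clock import pearson_r
from brainclock.methclock import apply_clock, methylation_delta
from brainclock.synth import generate_methylation

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    core_path = ROOT / "scratch" / "derived" / "core.pkl"
    if not core_path.exists():
        raise SystemExit("run analysis/02_train_clock.py first")
    with open(core_path, "rb") as fh:
        core = pickle.load(fh)

    meth, coef = generate_methylation(
        core.truth, core.samples, noise_sd=0.01, rho=0.7,
        seed=child_seed(seed, "methylation"),
    )
    meth_ages = apply_clock(meth, coef)
    md = methylation_delta(meth_ages, core.samples["age"])

    rows = []
    for name in core.cohort_names:
        idx = core.samples.index[core.samples["cohort"] == name]
        rows.append(
            {
                "cohort": name,
                "meth_vs_chron_r": round(
                    pearson_r(meth_ages.loc[idx], core.samples.loc[idx, "age"]), 4
                ),
                "cross_gauge_delta_r": round(
                    pearson_r(md.loc[idx], core.delta_records.loc[idx, "delta_age"]), 4
                ),
                "meth_delta_vs_true_offset_r": round(
                    pearson_r(md.loc[idx], core.truth.delta.loc[idx]), 4
                ),
                "n": len(idx),
            }
        )
    tab = pd.DataFrame(rows)
    bio.write_results(tab, ROOT / "results" / "methylation_comparison.tsv")
    print(tab.to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
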