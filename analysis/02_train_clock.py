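#!/usr/bin/env python
"""Clean the cohorts, train the transcriptional age clock, compute delta ages.

Each cohort is independently preprocessed (4-SD outlier masking, sample QC,
KNN imputation, standardization, nuisance residualization), the clock is
screened and fitted on the training cohort with (alpha, lambda) tuned
against the validation cohort, and per-cohort recalibration lines turn
molecular ages into delta ages. Ground-truth aging offsets are used only to
report recovery.

Writes the model and small reports to results/, the per-sample delta table
and cleaned state to scratch/derived/ for the downstream scripts.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from brainclock import io as bio
from brainclock import pipeline as pl

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    core = pl.core_run(pl.RunConfig(seed=seed))
    fit = core.fit

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    fit.model.to_json(results / "clock_model.json")
    bio.write_results(core.validation, results / "validation_report.tsv")

    rows = []
    for name in core.cohort_names:
        idx = core.samples.index[core.samples["cohort"] == name]
        sub = core.delta_records.loc[idx]
        rows.append(
            {
                "cohort": name,
                "pearson_r": round(
                    core.validation.set_index("cohort").loc[name, "pearson_r"], 4
                ),
                "delta_sd_years": round(sub["delta_age"].std(ddof=1), 3),
                "delta_recovery_r": round(core.delta_recovery_r(name), 4),
            }
        )
    summary = pd.DataFrame(rows)
    bio.write_results(summary, results / "delta_age_summary.tsv")

    derived = ROOT / "scratch" / "derived"
    derived.mkdir(parents=True, exist_ok=True)
    bio.write_results(core.delta_records.reset_index(), derived / "delta_age.tsv")
    with open(derived / "core.pkl", "wb") as fh:
        pickle.dump(core, fh)

    print(
        f"gene screen: {fit.counts['n_up']} up + {fit.counts['n_down']} down "
        f"at q<0.001 (panel {fit.counts['panel_size']}); "
        f"{fit.counts['n_nonzero']} genes carry nonzero weight "
        f"at alpha={fit.model.alpha}, lambda={fit.model.lam:.1f}"
    )
    print(summary.to_string(index=False))
    print(
        f"\nheld-out cohort: molecular~chronological R={core.held_out_r:.3f}, "
        f"delta-age recovery r={core.delta_recovery_r():.3f}"
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
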