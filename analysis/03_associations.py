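#!/usr/bin/env python
"""Phenotype association panel on the held-out (oldest) cohort.

Runs the covariate-adjusted panel twice — once with delta age as the
exposure (adjusting for e4), once with e4 dose as the exposure (adjusting
for delta age) — over AD diagnosis, cognitive-decline slope and the 38 null
phenotypes, BH-correcting within each exposure family, plus a
control/disease stratified rerun of the cognition association.

Reads scratch/derived/ (run 02 first); writes results/associations.tsv and
results/associations_stratified.tsv.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from brainclock import io as bio
from brainclock.assoc import AssociationSpec, run_panel, stratified_panel

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    core_path = ROOT / "scratch" / "derived" / "core.pkl"
    if not core_path.exists():
        raise SystemExit("run analysis/02_train_clock.py first")
    with open(core_path, "rb") as fh:
        core = pickle.load(fh)

    test = core.samples[core.samples["cohort"] == core.test_cohort]
    null_cols = [c for c in test.columns if c.startswith("null_")]
    outcomes = ["ad_dx", "cognition_slope", *null_cols]
    specs = [
        AssociationSpec(o, exposure="delta_age", covariates=("apoe4", "age", "sex", "rin"))
        for o in outcomes
    ] + [
        AssociationSpec(o, exposure="apoe4", covariates=("delta_age", "age", "sex", "rin"))
        for o in outcomes
    ]
    panel = run_panel(specs, core.delta_records, test)
    bio.write_results(panel, ROOT / "results" / "associations.tsv")

    sig = panel[(panel["q"] < 0.05) & (panel["error"] == "")]
    print(f"{len(sig)}/{len(panel)} associations at q<0.05:")
    print(sig[["outcome", "exposure", "beta", "p", "q", "n"]].to_string(index=False))

    strat = stratified_panel(
        [AssociationSpec("cognition_slope", covariates=("apoe4", "age", "sex"))],
        core.delta_records,
        test.assign(group=test["ad_dx"].map({0: "control", 1: "disease"})),
        "group",
    )
    tab = pd.concat(
        [df.assign(stratum=level) for level, df in strat.items()], ignore_index=True
    )
    bio.write_results(tab, ROOT / "results" / "associations_stratified.tsv")
    print("\ncognition-slope association by diagnosis stratum:")
    print(tab[["stratum", "beta", "p", "n"]].to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
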