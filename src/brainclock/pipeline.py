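"""End-to-end orchestration: simulate -> preprocess -> train -> delta ->
associations / synergy / methylation / markers, with a reproducibility
manifest.

The canonical run trains the clock on the first cohort, tunes it against
the second, and carries out the downstream risk analyses on the third
(oldest) cohort — the design where a clock built on disease-free brains is
applied to a naturalistic aged cohort. All stage outputs are TSV/JSON under
``outdir``; the manifest records config hash, per-stage wall time and
output checksums, so identical config + seed reproduce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as bio
from ._utils import child_seed, sha256_file
from .assoc import AssociationSpec, run_panel
from .clock import ClockHyperparams, pearson_r, predict_molecular_age, recalibrate_delta, train_clock
from .markers import MarkerSet, combine_glial, overlap_test, venn_counts
from .methclock import apply_clock, methylation_delta, write_coefficients
from .preprocess import CovariateSpec, ImputePolicy, OutlierPolicy, preprocess_cohort
from .synergy import BinPolicy, bin_delta, carrier_status, interaction_test, odds_table
from .synth import (
    PhenoConfig,
    SimConfig,
    generate_marker_sets,
    generate_methylation,
    generate_multi_cohort,
    generate_phenotypes,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "CoreResult", "core_run", "run", "load_config"]

DEFAULT_COVARIATES = ("rin", "sex", "pmi", "batch")


@dataclass
class MethParams:
    n_probes: int = 400
    k_informative: int = 50
    noise_sd: float = 0.01
    rho: float = 0.7


@dataclass
class RunConfig:
    """Everything one reproducible demo run needs."""

    seed: int = 0
    outdir: Path = Path("runs/demo")
    sim: SimConfig = field(default_factory=SimConfig)
    pheno: PhenoConfig = field(default_factory=PhenoConfig)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    outlier_policy: OutlierPolicy = field(default_factory=OutlierPolicy)
    impute_policy: ImputePolicy = field(default_factory=ImputePolicy)
    q_threshold: float = 0.001
    hyper: ClockHyperparams = field(default_factory=ClockHyperparams)
    bin_policy: BinPolicy = field(default_factory=BinPolicy)
    case_col: str = "ad_dx"
    meth: MethParams = field(default_factory=MethParams)
    marker_dir: Path | None = None  # optional: read marker lists instead of simulating
    input_files: tuple[str, ...] = ()  # extra files that must exist before running

    def validate(self) -> None:
        missing = [f for f in self.input_files if not Path(f).exists()]
        if self.marker_dir is not None and not Path(self.marker_dir).exists():
            missing.append(str(self.marker_dir))
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if len(self.sim.cohorts) < 3:
            raise ValueError("the demo run needs >= 3 cohorts (train/validate/test)")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def add(self, name: str, started: float, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": name,
                "seconds": round(time.perf_counter() - started, 3),
                "outputs": {str(p): sha256_file(p) for p in outputs},
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "outdir" in raw:
        kwargs["outdir"] = Path(raw["outdir"])
    if "sim" in raw:
        sim = dict(raw["sim"])
        if "cohorts" in sim:
            from .synth import CohortSpec

            sim["cohorts"] = tuple(
                CohortSpec(c["name"], int(c["n_samples"]), tuple(c["age_range"]))
                for c in sim["cohorts"]
            )
        kwargs["sim"] = SimConfig(**sim)
    if "pheno" in raw:
        kwargs["pheno"] = PhenoConfig(**raw["pheno"])
    if "covariates" in raw:
        kwargs["covariates"] = tuple(raw["covariates"])
    if "q_threshold" in raw:
        kwargs["q_threshold"] = float(raw["q_threshold"])
    if "hyper" in raw:
        kwargs["hyper"] = ClockHyperparams(
            alpha_grid=tuple(raw["hyper"].get("alpha_grid", ClockHyperparams().alpha_grid)),
            lambda_grid=tuple(raw["hyper"].get("lambda_grid", ClockHyperparams().lambda_grid)),
        )
    if "bin_policy" in raw:
        kwargs["bin_policy"] = BinPolicy(**raw["bin_policy"])
    if "meth" in raw:
        kwargs["meth"] = MethParams(**raw["meth"])
    for key in ("case_col",):
        if key in raw:
            kwargs[key] = raw[key]
    if "input_files" in raw:
        kwargs["input_files"] = tuple(raw["input_files"])
    if "marker_dir" in raw:
        kwargs["marker_dir"] = Path(raw["marker_dir"])
    return RunConfig(**kwargs)


@dataclass
class CoreResult:
    """In-memory result of the core path (simulate -> clean -> train ->
    predict -> delta), shared by the file-writing pipeline, the analysis
    drivers and the tests."""

    cohort_names: list[str]
    matrices: list[pd.DataFrame]
    samples: pd.DataFrame
    truth: object
    cleaned: dict[str, pd.DataFrame]
    qc: pd.DataFrame
    fit: object
    preds: pd.Series
    delta_records: pd.DataFrame
    lines: dict[str, tuple[float, float]]
    validation: pd.DataFrame

    @property
    def test_cohort(self) -> str:
        return self.cohort_names[2]

    @property
    def held_out_r(self) -> float:
        v = self.validation
        return float(v.loc[v["cohort"] == self.test_cohort, "pearson_r"].iloc[0])

    def delta_recovery_r(self, cohort: str | None = None) -> float:
        idx = self.samples.index[self.samples["cohort"] == (cohort or self.test_cohort)]
        return pearson_r(
            self.delta_records.loc[idx, "delta_age"].to_numpy(),
            self.truth.delta.loc[idx].to_numpy(),
        )


def core_run(config: RunConfig) -> CoreResult:
    """Simulate, clean, train/tune and compute delta ages, all in memory."""
    config.validate()
    sim = dataclasses.replace(config.sim, seed=child_seed(config.seed, "simulate"))
    matrices, samples, truth = generate_multi_cohort(sim)
    samples = generate_phenotypes(
        config.pheno, truth, samples, child_seed(config.seed, "phenotypes")
    )
    cohort_names = [c.name for c in sim.cohorts]

    spec = CovariateSpec(config.covariates)
    cleaned = {}
    qc_rows = []
    for name, mat in zip(cohort_names, matrices):
        cleaned[name], report = preprocess_cohort(
            mat, samples, spec, config.outlier_policy, config.impute_policy
        )
        qc_rows.append(
            {
                "cohort": name,
                "n_flagged_entries": int(report.flags_per_sample.sum()),
                "n_dropped_samples": len(report.dropped_samples),
                "n_dropped_genes": len(report.dropped_genes),
            }
        )

    train_name, valid_name = cohort_names[:2]
    ages = samples["age"]
    fit = train_clock(
        cleaned[train_name],
        ages,
        cleaned[valid_name],
        ages,
        q_threshold=config.q_threshold,
        hyper=config.hyper,
        train_cohort=train_name,
    )
    logger.info("clock: %s, validation R=%.3f", fit.counts, fit.valid_r)

    preds = pd.concat(
        [predict_molecular_age(fit.model, cleaned[n]) for n in cohort_names]
    )
    delta_records, lines = recalibrate_delta(preds, ages, samples["cohort"])
    validation = pd.DataFrame(
        [
            {
                "cohort": n,
                "pearson_r": pearson_r(
                    preds.loc[samples.index[samples["cohort"] == n]].to_numpy(),
                    ages[samples["cohort"] == n].to_numpy(),
                ),
                "n": int((samples["cohort"] == n).sum()),
            }
            for n in cohort_names
        ]
    )
    return CoreResult(
        cohort_names,
        matrices,
        samples,
        truth,
        cleaned,
        pd.DataFrame(qc_rows),
        fit,
        preds,
        delta_records,
        lines,
        validation,
    )


def run(config: RunConfig) -> RunManifest:
    """Execute the full demo pipeline; returns the manifest (also written
    to ``outdir/manifest.json``)."""
    from . import __version__

    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(config), __version__, config.seed)

    # --- core: simulate / preprocess / train / delta ------------------
    t0 = time.perf_counter()
    core = core_run(config)
    cohort_names = core.cohort_names
    samples, truth, fit = core.samples, core.truth, core.fit
    ages = samples["age"]
    test_name = core.test_cohort
    delta_records, preds, validation = core.delta_records, core.preds, core.validation

    outputs = []
    for name, mat in zip(cohort_names, core.matrices):
        p = out / f"expr_{name}.tsv"
        bio.write_matrix(mat, p)
        outputs.append(p)
    sp = out / "samples.tsv"
    bio.write_samples(samples, sp)
    tp = out / "truth_delta.tsv"
    bio.write_samples(truth.delta.to_frame(), tp)
    manifest.add("simulate", t0, outputs + [sp, tp])

    t0 = time.perf_counter()
    qcp = out / "qc_report.tsv"
    bio.write_results(core.qc, qcp)
    manifest.add("preprocess", t0, [qcp])

    t0 = time.perf_counter()
    mp = out / "model.json"
    fit.model.to_json(mp)
    gp = out / "tuning_grid.tsv"
    bio.write_results(fit.grid, gp)
    manifest.add("train", t0, [mp, gp])

    t0 = time.perf_counter()
    dp = out / "delta_age.tsv"
    bio.write_results(delta_records.reset_index(), dp)
    lp = out / "recalibration_lines.tsv"
    bio.write_results(
        pd.DataFrame(
            [{"cohort": c, "slope": s, "intercept": b} for c, (s, b) in core.lines.items()]
        ),
        lp,
    )
    vp = out / "validation_report.tsv"
    bio.write_results(validation, vp)
    manifest.add("delta", t0, [dp, lp, vp])

    # --- associations on the test cohort ------------------------------
    t0 = time.perf_counter()
    test_samples = samples[samples["cohort"] == test_name]
    null_cols = [c for c in samples.columns if c.startswith("null_")]
    outcomes = [config.case_col, "cognition_slope", *null_cols]
    specs = [
        AssociationSpec(o, exposure="delta_age", covariates=("apoe4", "age", "sex", "rin"))
        for o in outcomes
    ] + [
        AssociationSpec(o, exposure="apoe4", covariates=("delta_age", "age", "sex", "rin"))
        for o in outcomes
    ]
    panel = run_panel(specs, delta_records, test_samples)
    ap = out / "associations.tsv"
    bio.write_results(panel, ap)
    manifest.add("associate", t0, [ap])

    # --- synergy -------------------------------------------------------
    t0 = time.perf_counter()
    d = delta_records.loc[test_samples.index, "delta_age"]
    bins = bin_delta(d, config.bin_policy)
    carriers = carrier_status(test_samples["apoe4"])
    table = odds_table(bins, carriers, test_samples[config.case_col])
    inter = interaction_test(d, carriers, test_samples[config.case_col])
    table.attrs["interaction"] = dataclasses.asdict(inter)
    syp = out / "synergy.tsv"
    bio.write_results(table, syp)
    ip = out / "interaction.json"
    with open(ip, "w") as fh:
        json.dump(dataclasses.asdict(inter), fh, indent=1)
    manifest.add("synergy", t0, [syp, ip])

    # --- methylation comparison ---------------------------------------
    t0 = time.perf_counter()
    meth, coef = generate_methylation(
        truth,
        samples,
        n_probes=config.meth.n_probes,
        k_informative=config.meth.k_informative,
        noise_sd=config.meth.noise_sd,
        rho=config.meth.rho,
        seed=child_seed(config.seed, "methylation"),
    )
    meth_ages = apply_clock(meth, coef)
    meth_delta = methylation_delta(meth_ages, ages)
    cross_r = pearson_r(
        meth_delta.reindex(delta_records.index).to_numpy(),
        delta_records["delta_age"].to_numpy(),
    )
    mm = out / "meth_ages.tsv"
    bio.write_results(
        pd.DataFrame(
            {"meth_age": meth_ages, "chron_age": ages, "meth_delta": meth_delta}
        ).reset_index(names="sample_id"),
        mm,
    )
    cp = out / "meth_clock_coefficients.tsv"
    write_coefficients(coef, cp)
    manifest.add("methage", t0, [mm, cp])

    # --- marker overlap ------------------------------------------------
    t0 = time.perf_counter()
    if config.marker_dir is not None:
        from .markers import read_marker_dir

        msets = read_marker_dir(config.marker_dir)
    else:
        msets = {
            k: MarkerSet.from_list(k, v)
            for k, v in generate_marker_sets(
                truth, seed=child_seed(config.seed, "markers")
            ).items()
        }
    glial = combine_glial(msets)
    background = set(fit.stats.index)
    rows = []
    for direction, gene_set in (("down", set(fit.down)), ("up", set(fit.up))):
        for mset in (msets["neuron"], glial):
            only_a, inter_n, only_b = venn_counts(gene_set, mset)
            res = overlap_test(gene_set, mset.genes & background, background)
            rows.append(
                {
                    "age_set": direction,
                    "cell_class": mset.label,
                    "only_age": only_a,
                    "intersection": inter_n,
                    "only_markers": only_b,
                    "background": res.background,
                    "hypergeom_p": res.p,
                }
            )
    mkp = out / "marker_overlap.tsv"
    bio.write_results(pd.DataFrame(rows), mkp)
    manifest.add("markers", t0, [mkp])

    # --- summary -------------------------------------------------------
    truth_delta = truth.delta.reindex(delta_records.index)
    test_idx = test_samples.index
    manifest.summary = {
        "counts": fit.counts,
        "alpha": fit.model.alpha,
        "lambda": fit.model.lam,
        "validation_r": {
            row["cohort"]: row["pearson_r"] for _, row in validation.iterrows()
        },
        "held_out_r": float(
            validation.loc[validation["cohort"] == test_name, "pearson_r"].iloc[0]
        ),
        "delta_recovery_r": pearson_r(
            delta_records.loc[test_idx, "delta_age"].to_numpy(),
            truth_delta.loc[test_idx].to_numpy(),
        ),
        "cross_gauge_delta_r": cross_r,
        "interaction_p": inter.p,
    }
    manifest.write(out / "manifest.json")
    return manifest
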