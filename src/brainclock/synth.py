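"""Synthetic multi-cohort generator with known ground truth.

Emulates the statistical structure the brain-age analysis assumes: a shared
set of monotonically age-regulated transcripts across several postmortem
cohorts, a per-subject aging-rate offset (the quantity the clock's delta age
tries to recover), nuisance structure from RNA quality / sex / postmortem
interval / processing batch, APOE e4 genotypes, and phenotypes generated with
a delta-age x e4 interaction.

The generative model for expression is

    x_gi = mu_g + shift_gc + b_g * (age_i + delta_i) + w_g' z_i + eps_gi

where ``b_g`` is zero for non-age genes, ``delta_i ~ N(0, rate_sd^2)`` is the
subject's aging offset in years, ``z_i`` are standardized nuisance covariates
with gene-specific loadings ``w_g``, and ``eps_gi ~ N(0, noise_sd^2)``.
Expression is on an arbitrary continuous (log-like) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .methclock import MethClockCoefficients, age_transform

__all__ = [
    "CohortSpec",
    "SimConfig",
    "PhenoConfig",
    "TruthRecord",
    "generate_multi_cohort",
    "generate_phenotypes",
    "generate_methylation",
    "inject_outliers",
    "generate_marker_sets",
]


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: name, size and uniform age range (years)."""

    name: str
    n_samples: int
    age_range: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"cohort {self.name}: age_range low must be < high")
        if self.n_samples < 1:
            raise ValueError(f"cohort {self.name}: n_samples must be >= 1")


def _default_cohorts() -> tuple[CohortSpec, ...]:
    # Mimics a broad-age training cohort, a similar validation cohort, and a
    # much older naturalistic cohort (the design under which recalibration
    # lines matter).
    return (
        CohortSpec("cohortA", 250, (25.0, 97.0)),
        CohortSpec("cohortB", 250, (25.0, 90.0)),
        CohortSpec("cohortC", 250, (67.0, 108.0)),
    )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the multi-cohort expression simulation.

    Parameters
    ----------
    cohorts : cohort specs (name, n, age range). All cohorts share gene
        identities and age slopes.
    n_genes, n_up, n_down : total genes and counts with positive / negative
        age slope. Defaults give 500 age genes out of 2,000.
    slope_scale : typical |age slope| in expression units per year. With the
        default noise_sd=1 and a ~70-year age span this puts per-gene R^2 in
        the weak-signal 0.05-0.2 range typical of bulk brain data.
    noise_sd : residual SD in expression units.
    rate_sd : SD (years) of the per-subject aging offset delta_i. Default 5,
        so +/-1 SD corresponds to +/-5 molecular years.
    nuisance_effects : per-covariate loading SDs (expression units) for the
        standardized nuisance design; keys among {"rin","sex","pmi","batch"}.
    cohort_shift_sd : SD of a per-gene, per-cohort mean offset (dataset
        effect removed by per-cohort standardization downstream).
    outlier_rate / outlier_magnitude : optional corruption injected after
        generation (see :func:`inject_outliers`).
    """

    cohorts: tuple[CohortSpec, ...] = field(default_factory=_default_cohorts)
    n_genes: int = 2000
    n_up: int = 250
    n_down: int = 250
    slope_scale: float = 0.02
    noise_sd: float = 1.0
    rate_sd: float = 5.0
    nuisance_effects: dict = field(
        default_factory=lambda: {"rin": 0.3, "sex": 0.2, "pmi": 0.1, "batch": 0.3}
    )
    n_batches: int = 4
    cohort_shift_sd: float = 0.5
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down must not exceed n_genes")
        if self.rate_sd < 0:
            raise ValueError("rate_sd must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        unknown = set(self.nuisance_effects) - {"rin", "sex", "pmi", "batch"}
        if unknown:
            raise ValueError(f"unknown nuisance covariates: {sorted(unknown)}")


@dataclass(frozen=True)
class PhenoConfig:
    """Generative model for genotypes and phenotypes.

    AD status is Bernoulli with
    ``logit p = beta0 + beta_delta*delta + beta_e4*carrier + beta_int*delta*carrier``
    (delta in years, carrier = e4 allele count > 0); cognition slope is
    ``a0 + a_delta*delta + N(0, cog_resid_sd^2)``; ``n_null`` extra phenotypes
    are pure noise, independent of everything (the null panel).
    """

    e4_frequency: float = 0.14
    beta0: float = -1.0
    beta_delta: float = 0.05
    beta_e4: float = 0.8
    beta_int: float = 0.15
    a0: float = 0.0
    a_delta: float = -0.05
    cog_resid_sd: float = 0.25
    n_null: int = 38

    def __post_init__(self):
        if not 0 <= self.e4_frequency <= 1:
            raise ValueError("e4_frequency must be in [0, 1]")
        if self.n_null < 0:
            raise ValueError("n_null must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth for recovery tests.

    delta : per-sample true aging offset (years), mean-zero by construction.
    slopes : per-gene true age slope (expression units / year); 0 off-panel.
    directions : 'up' / 'down' / 'none' per gene.
    rate_sd : the SD delta was drawn with.
    pheno : the PhenoConfig used, once phenotypes have been generated.
    meth_delta : per-sample methylation-gauge offset, once methylation has
        been generated (correlated rho with ``delta``).
    """

    delta: pd.Series
    slopes: pd.Series
    directions: pd.Series
    rate_sd: float
    config: SimConfig
    nuisance_loadings: pd.DataFrame | None = None
    pheno: PhenoConfig | None = None
    meth_delta: pd.Series | None = None


def _nuisance_design(
    samples: pd.DataFrame, effects: dict, n_batches: int
) -> pd.DataFrame:
    """Standardized nuisance columns (one indicator per batch level), only
    for covariates with a configured effect."""
    z = pd.DataFrame(index=samples.index)
    for col in ("rin", "pmi"):
        if col in effects:
            v = samples[col].to_numpy(float)
            sd = v.std(ddof=1)
            z[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    if "sex" in effects:
        z["sex"] = samples["sex"].to_numpy(float) - 0.5
    if "batch" in effects:
        for b in range(n_batches):
            z[f"batch{b}"] = (samples["batch"] == f"b{b}").astype(float)
    return z


def generate_multi_cohort(
    config: SimConfig,
) -> tuple[list[pd.DataFrame], pd.DataFrame, TruthRecord]:
    """Simulate expression for every cohort in ``config``.

    Returns
    -------
    matrices : one genes x samples DataFrame per cohort (shared gene index).
    samples : one table covering all cohorts (index = sample id) with columns
        cohort, age, sex, rin, pmi, batch.
    truth : :class:`TruthRecord` with per-sample offsets and per-gene slopes.

    Two calls with the same config (seed included) are bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene_id")

    mu = rng.normal(6.0, 2.0, config.n_genes)
    slopes = np.zeros(config.n_genes)
    directions = np.array(["none"] * config.n_genes, dtype=object)
    up_idx = np.arange(config.n_up)
    down_idx = np.arange(config.n_up, config.n_up + config.n_down)
    slopes[up_idx] = config.slope_scale * rng.uniform(0.5, 1.5, config.n_up)
    slopes[down_idx] = -config.slope_scale * rng.uniform(0.5, 1.5, config.n_down)
    directions[up_idx] = "up"
    directions[down_idx] = "down"

    covs = list(config.nuisance_effects)
    load_cols, load_scales = [], []
    for c in covs:
        if c == "batch":
            for b in range(config.n_batches):
                load_cols.append(f"batch{b}")
                load_scales.append(config.nuisance_effects[c])
        else:
            load_cols.append(c)
            load_scales.append(config.nuisance_effects[c])
    loadings = rng.normal(0.0, 1.0, (config.n_genes, len(load_cols))) * np.asarray(
        load_scales
    )
    loadings_df = pd.DataFrame(loadings, index=genes, columns=load_cols)

    matrices: list[pd.DataFrame] = []
    sample_frames: list[pd.DataFrame] = []
    deltas: list[pd.Series] = []
    for spec in config.cohorts:
        n = spec.n_samples
        ids = pd.Index([f"{spec.name}_{i:04d}" for i in range(n)], name="sample_id")
        ages = rng.uniform(*spec.age_range, n)
        delta = rng.normal(0.0, config.rate_sd, n) if config.rate_sd > 0 else np.zeros(n)
        tab = pd.DataFrame(
            {
                "cohort": spec.name,
                "age": ages,
                "sex": rng.integers(0, 2, n),
                "rin": rng.normal(7.5, 1.0, n),
                "pmi": rng.normal(15.0, 5.0, n),
                "batch": [f"b{b}" for b in rng.integers(0, config.n_batches, n)],
            },
            index=ids,
        )
        z = _nuisance_design(tab, config.nuisance_effects, config.n_batches)
        shift = (
            rng.normal(0.0, config.cohort_shift_sd, config.n_genes)
            if config.cohort_shift_sd > 0
            else np.zeros(config.n_genes)
        )
        eff_age = ages + delta
        x = (
            mu[:, None]
            + shift[:, None]
            + slopes[:, None] * eff_age[None, :]
            + loadings @ z.to_numpy(float).T
        )
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, x.shape)
        matrices.append(pd.DataFrame(x, index=genes, columns=ids))
        sample_frames.append(tab)
        deltas.append(pd.Series(delta, index=ids))

    samples = pd.concat(sample_frames)
    truth = TruthRecord(
        delta=pd.concat(deltas).rename("delta_true"),
        slopes=pd.Series(slopes, index=genes, name="slope_true"),
        directions=pd.Series(directions, index=genes, name="direction_true"),
        rate_sd=config.rate_sd,
        config=config,
        nuisance_loadings=loadings_df,
    )
    return matrices, samples, truth


def generate_phenotypes(
    pheno: PhenoConfig,
    truth: TruthRecord,
    samples: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Draw e4 genotypes and phenotypes for every sample.

    Adds columns ``apoe4`` (allele count, Binomial(2, freq)), ``ad_dx``
    (0/1 from the logistic interaction model on the *true* offset delta),
    ``cognition_slope``, and ``null_00 .. null_{k-1}`` standard-normal null
    phenotypes. Raises if sample ids do not match the truth record.
    """
    if not samples.index.equals(truth.delta.index):
        missing = samples.index.symmetric_difference(truth.delta.index)
        raise ValueError(
            f"sample ids do not match truth record ({len(missing)} mismatched)"
        )
    rng = np.random.default_rng(seed)
    n = len(samples)
    delta = truth.delta.to_numpy()
    e4 = rng.binomial(2, pheno.e4_frequency, n)
    carrier = (e4 > 0).astype(float)
    logit = (
        pheno.beta0
        + pheno.beta_delta * delta
        + pheno.beta_e4 * carrier
        + pheno.beta_int * delta * carrier
    )
    p_ad = 1.0 / (1.0 + np.exp(-logit))
    out = samples.copy()
    out["apoe4"] = e4
    out["ad_dx"] = rng.binomial(1, p_ad)
    out["cognition_slope"] = (
        pheno.a0 + pheno.a_delta * delta + rng.normal(0.0, pheno.cog_resid_sd, n)
    )
    if pheno.n_null:
        nulls = rng.normal(0.0, 1.0, (n, pheno.n_null))
        null_df = pd.DataFrame(
            nulls,
            index=samples.index,
            columns=[f"null_{j:02d}" for j in range(pheno.n_null)],
        )
        out = pd.concat([out, null_df], axis=1)
    truth.pheno = pheno
    return out


def generate_methylation(
    truth: TruthRecord,
    samples: pd.DataFrame,
    n_probes: int = 400,
    k_informative: int = 50,
    noise_sd: float = 0.01,
    rho: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, MethClockCoefficients]:
    """Simulate a CpG beta matrix plus a linear clock that reads it.

    Informative probes track ``F(age_i + meth_delta_i)`` where ``F`` is the
    piecewise log/linear age-calibration transform and the methylation-gauge
    offset ``meth_delta`` correlates ``rho`` with the transcriptional offset
    ``truth.delta`` (both marginally N(0, rate_sd^2)). Probe slopes are kept
    small enough that betas stay inside [0, 1] without clipping for ages up
    to ~120, so in the noise-free case applying the returned coefficients
    reproduces ``age + meth_delta`` exactly.
    """
    if k_informative > n_probes:
        raise ValueError("k_informative must be <= n_probes")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    ids = samples.index
    ages = samples["age"].to_numpy(float)
    delta = truth.delta.reindex(ids).to_numpy()
    sd = truth.rate_sd
    meth_delta = rho * delta + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, sd, len(ids))
    f = age_transform(ages + meth_delta)

    probes = pd.Index([f"cg{i:06d}" for i in range(n_probes)], name="probe_id")
    # F spans roughly [-3.1, 4.8] for ages 0-120; |slope|<=0.08 around a
    # centered intercept keeps betas in ~[0.18, 0.82].
    f_mid = (age_transform(0.0) + age_transform(120.0)) / 2.0
    slopes = np.zeros(n_probes)
    sign = rng.choice([-1.0, 1.0], k_informative)
    slopes[:k_informative] = sign * rng.uniform(0.04, 0.08, k_informative)
    centers = np.full(n_probes, 0.5) - slopes * f_mid
    centers[k_informative:] = rng.uniform(0.2, 0.8, n_probes - k_informative)

    beta = centers[:, None] + slopes[:, None] * f[None, :]
    if noise_sd > 0:
        beta = beta + rng.normal(0.0, noise_sd, beta.shape)
    beta = np.clip(beta, 0.0, 1.0)
    meth = pd.DataFrame(beta, index=probes, columns=ids)

    w = np.zeros(n_probes)
    w[:k_informative] = 1.0 / (k_informative * slopes[:k_informative])
    intercept = -float(np.dot(w, centers))
    coef = MethClockCoefficients(
        weights=pd.Series(w, index=probes, name="weight"),
        intercept=intercept,
        mean_beta=pd.Series(centers + slopes * f.mean(), index=probes, name="mean_beta"),
    )
    truth.meth_delta = pd.Series(meth_delta, index=ids, name="meth_delta_true")
    return meth, coef


def inject_outliers(
    matrix: pd.DataFrame,
    rate: float,
    magnitude: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a fraction of entries to mean_g +/- magnitude * sd_g.

    Returns the corrupted copy and a boolean truth mask of injected entries;
    entries not selected are bit-identical to the input. ``rate=0`` returns
    an identical copy and an all-False mask.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    mask = rng.random(matrix.shape) < rate
    if mask.any():
        means = matrix.mean(axis=1).to_numpy()
        sds = matrix.std(axis=1, ddof=1).to_numpy()
        signs = rng.choice([-1.0, 1.0], matrix.shape)
        vals = means[:, None] + signs * magnitude * sds[:, None]
        arr = out.to_numpy()
        arr[mask] = vals[mask]
        out = pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)
    return out, pd.DataFrame(mask, index=matrix.index, columns=matrix.columns)


def generate_marker_sets(
    truth: TruthRecord,
    seed: int = 0,
    n_per_type: int = 100,
    overlap_frac: float = 0.15,
) -> dict[str, list[str]]:
    """Build cell-type marker gene lists that partially overlap the age genes.

    Neuronal markers draw ``overlap_frac`` of their genes from the true
    down-regulated set; astrocyte/oligodendrocyte/microglia markers draw from
    the true up-regulated set; the rest are non-age genes. Intended to feed
    the marker-overlap analysis with a known, modest intersection.
    """
    rng = np.random.default_rng(seed)
    down = truth.directions.index[truth.directions == "down"].to_numpy()
    up = truth.directions.index[truth.directions == "up"].to_numpy()
    none = truth.directions.index[truth.directions == "none"].to_numpy()
    n_overlap = int(round(overlap_frac * n_per_type))
    sets: dict[str, list[str]] = {}
    pool_none = rng.permutation(none)
    cursor = 0
    for label, source in [
        ("neuron", down),
        ("astrocyte", up),
        ("oligodendrocyte", up),
        ("microglia", up),
    ]:
        chosen = list(rng.choice(source, size=n_overlap, replace=False))
        filler = list(pool_none[cursor : cursor + n_per_type - n_overlap])
        cursor += n_per_type - n_overlap
        if len(filler) < n_per_type - n_overlap:
            warnings.warn("marker filler pool exhausted; sets smaller than requested")
        sets[label] = chosen + filler
    return sets


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
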