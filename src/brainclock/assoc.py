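"""Covariate-adjusted association of delta age (or e4 dose) with phenotypes.

Each spec fits one multiple-regression model per outcome: linear for
continuous outcomes, logistic for binary ones (family='auto' resolves by
outcome arity), always with the exposure of interest plus the declared
nuisance covariates as regressors. "Subtracting" a covariate means including
it in the model. BH correction is applied across a declared panel, one
family per exposure column, and panels can be rerun within strata
(e.g. control vs disease subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .clock import bh_adjust

__all__ = [
    "AssociationSpec",
    "AssociationResult",
    "AssociationError",
    "fit_association",
    "run_panel",
    "stratified_panel",
]


class AssociationError(ValueError):
    """A spec that cannot be fit at all (constant outcome, bad columns)."""


@dataclass(frozen=True)
class AssociationSpec:
    """outcome: column in the sample table. exposure: 'delta_age' (from the
    delta record table) or a sample-table column such as 'apoe4'.
    family: 'linear' | 'logistic' | 'auto' (binary outcome -> logistic).
    stratum: optional (column, value) filter applied before fitting."""

    outcome: str
    exposure: str = "delta_age"
    covariates: tuple[str, ...] = field(default_factory=tuple)
    family: str = "auto"
    stratum: tuple[str, object] | None = None

    def __post_init__(self):
        if self.exposure in self.covariates:
            raise ValueError("exposure must not appear among the covariates")
        if self.family not in ("linear", "logistic", "auto"):
            raise ValueError("family must be linear, logistic or auto")


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    beta: float
    se: float
    p: float
    n: int
    family: str
    stratum: tuple | None = None
    q: float | None = None
    error: str | None = None

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "exposure": self.exposure,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "q": self.q,
            "n": self.n,
            "family": self.family,
            "stratum": "" if self.stratum is None else f"{self.stratum[0]}={self.stratum[1]}",
            "error": self.error or "",
        }


def _assemble(
    spec: AssociationSpec, delta_records: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    tab = samples.copy()
    if "delta_age" not in tab.columns:
        tab = tab.join(delta_records["delta_age"], how="inner")
    if spec.stratum is not None:
        col, val = spec.stratum
        if col not in tab.columns:
            raise AssociationError(f"stratum column '{col}' not found")
        tab = tab[tab[col] == val]
    needed = [spec.outcome, spec.exposure, *spec.covariates]
    for c in needed:
        if c not in tab.columns:
            raise AssociationError(f"column '{c}' not found")
    return tab[needed].dropna()


def _design(tab: pd.DataFrame, covariates: tuple[str, ...], exposure: str) -> pd.DataFrame:
    cols = [tab[exposure].astype(float)]
    for c in covariates:
        v = tab[c]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.astype(float))
        else:
            cols.extend(
                pd.get_dummies(v, prefix=c, drop_first=True, dtype=float)[d]
                for d in pd.get_dummies(v, prefix=c, drop_first=True).columns
            )
    x = pd.concat(cols, axis=1)
    return sm.add_constant(x, has_constant="add")


def fit_association(
    spec: AssociationSpec, delta_records: pd.DataFrame, samples: pd.DataFrame
) -> AssociationResult:
    """Fit one spec; returns the exposure coefficient, SE and two-sided p.

    Linear models report the slope t-test, logistic the Wald test on the
    log-odds per unit exposure. Rows with any missing value among outcome,
    exposure and covariates are dropped (complete cases); a constant outcome
    raises :class:`AssociationError`; separation / non-convergence in the
    logistic fit is returned as a flagged result, not an exception.
    """
    tab = _assemble(spec, delta_records, samples)
    y = tab[spec.outcome].to_numpy(float)
    n = len(tab)
    if n == 0:
        raise AssociationError(f"no complete cases for outcome '{spec.outcome}'")
    distinct = np.unique(y[~np.isnan(y)])
    if len(distinct) < 2:
        raise AssociationError(f"outcome '{spec.outcome}' is constant")
    family = spec.family
    if family == "auto":
        family = "logistic" if len(distinct) == 2 else "linear"
    x = _design(tab, spec.covariates, spec.exposure)

    if family == "linear":
        fit = sm.OLS(y, x).fit()
        return AssociationResult(
            spec.outcome, spec.exposure, float(fit.params[spec.exposure]),
            float(fit.bse[spec.exposure]), float(fit.pvalues[spec.exposure]),
            n, family, spec.stratum,
        )
    y01 = (y == distinct.max()).astype(float) if set(distinct) != {0.0, 1.0} else y
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y01, x).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise PerfectSeparationError("logistic fit did not converge")
        beta = float(fit.params[spec.exposure])
        se = float(fit.bse[spec.exposure])
        if not (np.isfinite(beta) and np.isfinite(se)) or se > 1e4:
            raise PerfectSeparationError("unstable logistic estimates")
        return AssociationResult(
            spec.outcome, spec.exposure, beta, se,
            float(fit.pvalues[spec.exposure]), n, family, spec.stratum,
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return AssociationResult(
            spec.outcome, spec.exposure, np.nan, np.nan, np.nan, n, family,
            spec.stratum, error=f"separation: {exc}",
        )


def run_panel(
    specs: list[AssociationSpec],
    delta_records: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Fit every spec and BH-correct p-values within each exposure family.

    Rows keep the input order; specs that raise :class:`AssociationError`
    become rows with an error code and no q; flagged (separation) rows keep
    their error code and are excluded from the BH family.
    """
    if not specs:
        raise ValueError("panel needs at least one spec")
    results: list[AssociationResult] = []
    for spec in specs:
        try:
            results.append(fit_association(spec, delta_records, samples))
        except AssociationError as exc:
            results.append(
                AssociationResult(
                    spec.outcome, spec.exposure, np.nan, np.nan, np.nan, 0,
                    spec.family, spec.stratum, error=str(exc),
                )
            )
    for exposure in {r.exposure for r in results}:
        fam = [r for r in results if r.exposure == exposure and r.error is None]
        if fam:
            qs = bh_adjust([r.p for r in fam])
            for r, q in zip(fam, qs):
                r.q = float(q)
    return pd.DataFrame([r.as_row() for r in results])


def stratified_panel(
    specs: list[AssociationSpec],
    delta_records: pd.DataFrame,
    samples: pd.DataFrame,
    stratum_col: str,
    min_n: int = 10,
) -> dict[object, pd.DataFrame]:
    """Run the panel independently within each level of ``stratum_col``.

    Strata with fewer than ``min_n`` samples are skipped with a warning.
    """
    if stratum_col not in samples.columns:
        raise ValueError(f"stratum column '{stratum_col}' not found")
    out: dict[object, pd.DataFrame] = {}
    for level, sub in samples.groupby(stratum_col, sort=True):
        if len(sub) < min_n:
            warnings.warn(f"stratum {stratum_col}={level}: n={len(sub)} < {min_n}, skipped")
            continue
        strat_specs = [replace(s, stratum=None) for s in specs]
        out[level] = run_panel(strat_specs, delta_records, sub)
    return out
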