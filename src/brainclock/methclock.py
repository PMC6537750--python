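"""Linear methylation clock with the piecewise age-calibration transform.

The clock is a user-supplied linear combination of CpG beta values whose
output lives on a transformed age scale: ages below ``adult_age`` are mapped
logarithmically, adult ages linearly,

    F(a) = log(a + 1) - log(adult_age + 1)      if a <= adult_age
         = (a - adult_age) / (adult_age + 1)    otherwise,

and predicted ages are recovered with the inverse map. The methylation delta
age is the plain difference ``methylation age - chronological age`` (not a
regression residual — this deliberately differs from the transcriptional
delta definition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MethClockCoefficients",
    "age_transform",
    "inverse_transform",
    "apply_clock",
    "methylation_delta",
    "read_coefficients",
    "write_coefficients",
]

INTERCEPT_ROW = "(Intercept)"


@dataclass
class MethClockCoefficients:
    """Probe weights + intercept + adult-age constant of a linear clock.

    ``mean_beta`` (optional) supplies per-probe training means used to impute
    probes missing from a target matrix; without it missing probes are filled
    with 0.5.
    """

    weights: pd.Series
    intercept: float
    adult_age: float = 20.0
    mean_beta: pd.Series | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights.to_numpy(float))):
            raise ValueError("clock weights must be finite")
        if not np.isfinite(self.intercept):
            raise ValueError("clock intercept must be finite")
        if self.adult_age <= 0:
            raise ValueError("adult_age must be > 0")
        if self.weights.index.has_duplicates:
            raise ValueError("duplicate probe ids in coefficients")

    @property
    def nonzero(self) -> pd.Index:
        return self.weights.index[self.weights.to_numpy() != 0]


def age_transform(age, adult_age: float = 20.0):
    """Map chronological age (years) to the calibrated clock scale."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    out = np.where(
        a <= adult_age,
        np.log(a + 1.0) - np.log(adult_age + 1.0),
        (a - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def inverse_transform(x, adult_age: float = 20.0):
    """Inverse of :func:`age_transform`: clock scale back to years."""
    v = np.asarray(x, dtype=float)
    out = np.where(
        v <= 0,
        np.exp(v + np.log(adult_age + 1.0)) - 1.0,
        v * (adult_age + 1.0) + adult_age,
    )
    return out if out.ndim else float(out)


def apply_clock(
    matrix: pd.DataFrame,
    coef: MethClockCoefficients,
    min_presence: float = 0.8,
) -> pd.Series:
    """Compute per-sample methylation age (years) from a beta matrix.

    Requires at least ``min_presence`` of the clock's nonzero-weight probes
    to be present in ``matrix``; missing probes are imputed at their training
    mean beta (or 0.5) with a warning.
    """
    vals = matrix.to_numpy(float)
    if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise ValueError("beta values must lie in [0, 1]")
    needed = coef.nonzero
    missing = needed.difference(matrix.index)
    if len(needed) == 0:
        score = np.full(matrix.shape[1], coef.intercept)
        return pd.Series(
            inverse_transform(score, coef.adult_age), index=matrix.columns, name="meth_age"
        )
    presence = 1.0 - len(missing) / len(needed)
    if presence < min_presence:
        raise ValueError(
            f"only {presence:.0%} of clock probes present (need >= {min_presence:.0%}); "
            f"missing: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    sub = matrix.reindex(needed)
    if len(missing):
        if coef.mean_beta is not None:
            fill = coef.mean_beta.reindex(missing).fillna(0.5)
        else:
            fill = pd.Series(0.5, index=missing)
        sub.loc[missing] = np.broadcast_to(
            fill.to_numpy()[:, None], (len(missing), sub.shape[1])
        )
        warnings.warn(
            f"{len(missing)} clock probes missing; imputed at training mean beta"
        )
    w = coef.weights.reindex(needed).to_numpy()
    score = coef.intercept + w @ sub.to_numpy(float)
    return pd.Series(
        inverse_transform(score, coef.adult_age), index=matrix.columns, name="meth_age"
    )


def methylation_delta(meth_ages: pd.Series, chron_ages: pd.Series) -> pd.Series:
    """Elementwise methylation age minus chronological age (years)."""
    if not meth_ages.index.equals(chron_ages.index):
        if set(meth_ages.index) != set(chron_ages.index):
            raise ValueError("sample ids of methylation and chronological ages differ")
        chron_ages = chron_ages.reindex(meth_ages.index)
    return (meth_ages - chron_ages).rename("meth_delta")


def read_coefficients(path) -> MethClockCoefficients:
    """Read a clock coefficient TSV (probe_id, weight[, mean_beta]).

    One reserved row with probe_id ``(Intercept)`` carries the intercept.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in tab.columns or "weight" not in tab.columns:
        raise ValueError("coefficient file needs columns probe_id and weight")
    is_int = tab["probe_id"] == INTERCEPT_ROW
    if is_int.sum() != 1:
        raise ValueError("coefficient file must contain exactly one (Intercept) row")
    intercept = float(tab.loc[is_int, "weight"].iloc[0])
    rest = tab.loc[~is_int]
    weights = pd.Series(
        rest["weight"].to_numpy(float), index=pd.Index(rest["probe_id"], name="probe_id")
    )
    mean_beta = None
    if "mean_beta" in rest.columns and rest["mean_beta"].notna().any():
        mean_beta = pd.Series(
            rest["mean_beta"].to_numpy(float), index=weights.index
        )
    return MethClockCoefficients(weights=weights, intercept=intercept, mean_beta=mean_beta)


def write_coefficients(coef: MethClockCoefficients, path) -> None:
    rows = pd.DataFrame(
        {
            "probe_id": [INTERCEPT_ROW, *coef.weights.index],
            "weight": [coef.intercept, *coef.weights.to_numpy()],
        }
    )
    if coef.mean_beta is not None:
        rows["mean_beta"] = [np.nan, *coef.mean_beta.reindex(coef.weights.index)]
    rows.to_csv(path, sep="\t", index=False, na_rep="NA")
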