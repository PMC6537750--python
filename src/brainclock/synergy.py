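"""Binned delta-age x APOE e4 synergy analysis.

Delta age is binned into younger / neutral / older (fixed +/-5-year
thresholds by default, or +/-1 SD of the cohort's delta distribution), e4
homozygotes and heterozygotes are pooled as carriers, and each (bin x
carrier) cell's odds of being a case are expressed relative to the
whole-cohort odds. A model-based companion tests the continuous
delta x carrier interaction with logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "BinPolicy",
    "InteractionResult",
    "bin_delta",
    "carrier_status",
    "odds_table",
    "interaction_test",
]

BIN_ORDER = ("younger", "neutral", "older")


@dataclass(frozen=True)
class BinPolicy:
    """mode='fixed': thresholds at +/-threshold years. mode='sd': +/-1 SD of
    the supplied deltas. Boundary values (exactly +/-t) are neutral."""

    mode: str = "fixed"
    threshold: float = 5.0

    def __post_init__(self):
        if self.mode not in ("fixed", "sd"):
            raise ValueError("mode must be 'fixed' or 'sd'")
        if self.mode == "fixed" and self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def bin_delta(delta, policy: BinPolicy = BinPolicy()) -> pd.Series:
    """Three-way younger / neutral / older labels for delta values (years)."""
    d = pd.Series(delta, dtype=float) if not isinstance(delta, pd.Series) else delta.astype(float)
    if not np.isfinite(d.to_numpy()).all():
        raise ValueError("delta values must be finite")
    t = policy.threshold if policy.mode == "fixed" else float(d.std(ddof=1))
    if t <= 0:
        raise ValueError("degenerate bin threshold (constant deltas?)")
    labels = np.where(d < -t, "younger", np.where(d > t, "older", "neutral"))
    return pd.Series(
        pd.Categorical(labels, categories=list(BIN_ORDER), ordered=True),
        index=d.index,
        name="delta_bin",
    )


def carrier_status(allele_counts) -> pd.Series:
    """Pool 1 and 2 e4 alleles into 'carrier'; 0 is 'non-carrier'."""
    c = pd.Series(allele_counts) if not isinstance(allele_counts, pd.Series) else allele_counts
    vals = set(pd.unique(c.dropna()))
    if not vals <= {0, 1, 2}:
        raise ValueError(f"allele counts must be in {{0,1,2}}; saw {sorted(vals)}")
    return pd.Series(
        np.where(c > 0, "carrier", "non-carrier"), index=c.index, name="carrier"
    )


def odds_table(
    bins: pd.Series, carriers: pd.Series, cases: pd.Series
) -> pd.DataFrame:
    """Per-cell case odds relative to the whole-cohort odds.

    Rows are the six (delta bin x carrier) cells plus an 'all' reference row
    (relative odds exactly 1). Cells with zero cases or zero controls get
    the Haldane-Anscombe +0.5 continuity correction and a flag; cells with
    n=0 report NaN odds.
    """
    if not (bins.index.equals(carriers.index) and bins.index.equals(cases.index)):
        raise ValueError("bins, carriers and cases must share the same index")
    y = cases.to_numpy(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("case indicator must be 0/1")
    total_cases = int(y.sum())
    total_n = len(y)
    if total_cases == 0 or total_cases == total_n:
        raise ValueError("need at least one case and one control overall")
    cohort_odds = total_cases / (total_n - total_cases)

    rows = []
    for b in BIN_ORDER:
        for cstat in ("non-carrier", "carrier"):
            sel = (bins == b) & (carriers == cstat)
            n = int(sel.sum())
            k = int(y[sel.to_numpy()].sum())
            corrected = False
            if n == 0:
                odds = np.nan
            elif k == 0 or k == n:
                odds = (k + 0.5) / (n - k + 0.5)
                corrected = True
            else:
                odds = k / (n - k)
            rows.append(
                {
                    "delta_bin": b,
                    "carrier": cstat,
                    "n": n,
                    "cases": k,
                    "odds": odds,
                    "relative_odds": odds / cohort_odds if np.isfinite(odds) else np.nan,
                    "corrected": corrected,
                }
            )
    rows.append(
        {
            "delta_bin": "all",
            "carrier": "all",
            "n": total_n,
            "cases": total_cases,
            "odds": cohort_odds,
            "relative_odds": 1.0,
            "corrected": False,
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["cohort_odds"] = cohort_odds
    return out


@dataclass
class InteractionResult:
    """Continuous-model companion to the binned table (a model-based
    addition, not part of the binned analysis itself)."""

    coef: float
    se: float
    p: float
    n: int
    error: str | None = None


def interaction_test(
    delta: pd.Series,
    carrier: pd.Series,
    cases: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> InteractionResult:
    """Wald test of the delta x carrier product term in a logistic model.

    ``carrier`` may be the string labels from :func:`carrier_status` or a
    0/1 indicator. A constant carrier column makes the term inestimable and
    raises; separation is returned as a flagged result.
    """
    if carrier.dtype == object or isinstance(carrier.dtype, pd.CategoricalDtype):
        car = (carrier == "carrier").astype(float)
    else:
        car = carrier.astype(float)
    if car.nunique() < 2:
        raise ValueError("carrier status is constant; interaction inestimable")
    if delta.isna().any() or car.isna().any() or cases.isna().any():
        raise ValueError("missing values in interaction inputs")
    x = pd.DataFrame(
        {"delta_age": delta.astype(float), "carrier": car, "delta_x_carrier": delta * car}
    )
    if covariates is not None:
        x = pd.concat([x, covariates.astype(float)], axis=1)
    x = sm.add_constant(x, has_constant="add")
    y = cases.astype(float)
    n = len(y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise PerfectSeparationError("did not converge")
        coef = float(fit.params["delta_x_carrier"])
        se = float(fit.bse["delta_x_carrier"])
        if not (np.isfinite(coef) and np.isfinite(se)) or se > 1e4:
            raise PerfectSeparationError("unstable estimates")
        return InteractionResult(coef, se, float(fit.pvalues["delta_x_carrier"]), n)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return InteractionResult(np.nan, np.nan, np.nan, n, error=f"separation: {exc}")
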