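"""Glycemic trait handling: subject classification, derived insulin indices,
and the replication-cohort statistics.

The oral glucose tolerance test (OGTT) measures blood glucose at 0, 60 and
120 minutes after a 75 g glucose challenge (Glu0/Glu60/Glu120, mg/dL).
Derived indices:

* HOMA-IR (insulin resistance):  ``Ins0 [uU/mL] * Glu0 [mg/dL] / 405``
* QUICKI  (insulin sensitivity): ``1 / (log10 Ins0 + log10 Glu0)``

Group comparisons use Welch's unequal-variance t-test (raw vectors or
published summary statistics).  Association between methylation at a target
CpG and a trait is estimated by ordinary least squares with age, sex, BMI,
WBC and RBC as covariates: the trait is the response and percent methylation
the predictor, so the reported coefficient is the expected trait change per
methylation percentage point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "homa_ir",
    "quicki",
    "classify_hiGlu60",
    "classify_t2d_replication",
    "welch_t",
    "welch_t_from_summary",
    "trait_regression",
    "add_derived_indices",
    "WelchResult",
    "RegressionResult",
]

DEFAULT_COVARIATES = ("age", "sex", "BMI", "WBC", "RBC")


def homa_ir(Ins0, Glu0):
    """Homeostasis-model insulin resistance index, Ins0 x Glu0 / 405.

    Ins0 in uU/mL, Glu0 in mg/dL (the 405 constant belongs to the mg/dL
    form of the index).  Vectorised over array inputs.
    """
    Ins0 = np.asarray(Ins0, dtype=float)
    Glu0 = np.asarray(Glu0, dtype=float)
    if np.any(Ins0 <= 0) or np.any(Glu0 <= 0):
        raise ValueError("HOMA-IR requires strictly positive Ins0 and Glu0")
    out = Ins0 * Glu0 / 405.0
    return float(out) if out.ndim == 0 else out


def quicki(Ins0, Glu0):
    """Quantitative insulin sensitivity check index, 1/(log10 Ins0 + log10 Glu0)."""
    Ins0 = np.asarray(Ins0, dtype=float)
    Glu0 = np.asarray(Glu0, dtype=float)
    if np.any(Ins0 <= 0) or np.any(Glu0 <= 0):
        raise ValueError("QUICKI requires strictly positive Ins0 and Glu0")
    denom = np.log10(Ins0) + np.log10(Glu0)
    if np.any(denom == 0):
        raise ValueError("QUICKI undefined: log10(Ins0) + log10(Glu0) == 0")
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


def add_derived_indices(traits: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a trait table with HOMA_IR and QUICKI columns added."""
    out = traits.copy()
    out["HOMA_IR"] = homa_ir(out["Ins0"].to_numpy(), out["Glu0"].to_numpy())
    out["QUICKI"] = quicki(out["Ins0"].to_numpy(), out["Glu0"].to_numpy())
    return out


def classify_hiGlu60(Glu0: float, Glu60: float) -> str:
    """Classify a subject by the 60-minute OGTT glucose excursion.

    delta = Glu60 - Glu0: below 20 mg/dL -> ``control`` (flat responder),
    above 100 -> ``case`` (high responder), otherwise ``excluded``.
    """
    delta = Glu60 - Glu0
    if delta < 20:
        return "control"
    if delta > 100:
        return "case"
    return "excluded"


def classify_t2d_replication(Glu0: float, Glu120: float) -> str:
    """Diabetic-case rule for the replication cohort: fasting glucose above
    126 mg/dL *and* 2-hour OGTT glucose above 200 mg/dL (both strict)."""
    return "case" if (Glu0 > 126 and Glu120 > 200) else "non_case"


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t(raw_a, raw_b) -> WelchResult:
    """Welch's two-sample t-test (unequal variances) on raw vectors."""
    a = np.asarray(raw_a, dtype=float)
    b = np.asarray(raw_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's test needs n >= 2 per group")
    return welch_t_from_summary(a.mean(), a.std(ddof=1), a.size,
                                b.mean(), b.std(ddof=1), b.size)


def welch_t_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> WelchResult:
    """Welch's t from published group summaries (mean, SD, n per group).

    Uses the Satterthwaite degrees of freedom; algebraically identical to
    :func:`welch_t` applied to raw data with the same summaries.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("Welch's test needs n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0:
        # no variance in either group: identical means are a degenerate tie
        return WelchResult(t=0.0, df=float(n_a + n_b - 2), p=1.0,
                           degenerate=True)
    t = (mean_a - mean_b) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


@dataclass
class RegressionResult:
    trait: str
    coefficient: float
    p: float
    se: float
    n: int
    covariates: tuple
    model: object = None


def trait_regression(traits: pd.DataFrame, trait_name: str,
                     methylation_col: str = "methylation_target",
                     covariates=DEFAULT_COVARIATES) -> RegressionResult:
    """OLS of a trait on target-CpG methylation with clinical covariates.

    ``sex`` is encoded as an indicator (female = 1, male = 0 reference).
    If the analysed trait is itself in the covariate list it is removed
    (it cannot be both response and covariate).  Complete cases only.
    Raises on a collinear design, naming the offending column.
    """
    covariates = tuple(c for c in covariates if c != trait_name)
    cols = [trait_name, methylation_col, *covariates]
    data = traits[cols].dropna()
    if len(data) < len(covariates) + 3:
        raise ValueError(f"too few complete cases ({len(data)}) for regression")

    X = pd.DataFrame(index=data.index)
    X[methylation_col] = data[methylation_col].astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex_female"] = (data["sex"].astype(str).str.lower()
                               .map({"female": 1.0, "male": 0.0, "f": 1.0, "m": 0.0}))
            if X["sex_female"].isna().any():
                raise ValueError("sex column must contain only male/female labels")
        else:
            X[cov] = data[cov].astype(float)
    X = sm.add_constant(X, prepend=True)

    # collinearity check before fitting so the error names the column
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        for j in range(1, mat.shape[1]):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"collinear design: column {X.columns[j]!r} "
                                 "is linearly dependent on the others")
        raise ValueError("collinear design")

    fit = sm.OLS(data[trait_name].astype(float), X).fit()
    return RegressionResult(
        trait=trait_name,
        coefficient=float(fit.params[methylation_col]),
        p=float(fit.pvalues[methylation_col]),
        se=float(fit.bse[methylation_col]),
        n=int(fit.nobs),
        covariates=covariates,
        model=fit,
    )


def trait_association_table(traits: pd.DataFrame, trait_names,
                            methylation_col: str = "methylation_target",
                            covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Per-trait regression coefficients and p-values for the target CpG."""
    rows = []
    for name in trait_names:
        res = trait_regression(traits, name, methylation_col, covariates)
        rows.append({"trait": name, "r": res.coefficient, "p": res.p,
                     "n": res.n})
    return pd.DataFrame(rows).set_index("trait")
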