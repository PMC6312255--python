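"""Dose/age confounder deconvolution by per-protein backward stepwise OLS.

Dose and age are strongly rank-correlated in the cohort this analysis is
designed for, so naive per-group testing cannot tell a dose effect from an
age effect. Each protein's (Box-Cox transformed) abundance is therefore
modelled on standardized dose, age, their interaction and BMI; terms are
dropped backwards under AIC, and the surviving significant terms determine
a dependency category: dose-only, age-only, dose+age, BMI, or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import AbundanceMatrix, RunConfig, SampleMetadata, ValidationError
from .preprocess import boxcox_mle

__all__ = [
    "FULL_TERMS",
    "FittedModel",
    "build_design",
    "fit_linear_model",
    "backward_stepwise_aic",
    "classify_dependency",
    "deconvolve_matrix",
    "CATEGORIES",
]

FULL_TERMS = ("dose", "age", "dose:age", "bmi")
CATEGORIES = ("dose_only", "age_only", "dose_age", "bmi", "none")


@dataclass
class FittedModel:
    """OLS fit summary used by the stepwise search.

    AIC counts every estimated parameter: the intercept, each retained
    slope, and the residual variance.
    """

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    loglik: float
    aic: float
    n: int


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def build_design(metadata: SampleMetadata, terms: tuple[str, ...]) -> pd.DataFrame:
    """Design matrix on standardized covariates; the interaction column is
    the product of the standardized main effects."""
    dose = _standardize(metadata.dose)
    age = _standardize(metadata.age)
    cols = {"const": np.ones(len(metadata))}
    available = {
        "dose": dose,
        "age": age,
        "dose:age": dose * age,
        "bmi": _standardize(metadata.bmi),
    }
    for t in terms:
        if t not in available:
            raise ValidationError(f"unknown model term {t!r}")
        cols[t] = available[t]
    return pd.DataFrame(cols, index=metadata.sample_ids)


def fit_linear_model(y: np.ndarray, terms: tuple[str, ...], metadata: SampleMetadata) -> FittedModel:
    """OLS of y on the requested standardized terms, with AIC = 2k - 2 llf.

    k counts the intercept, the slopes, and the residual variance. A
    rank-deficient design raises an error naming the collinear columns.
    """
    y = np.asarray(y, float)
    if len(y) != len(metadata):
        raise ValidationError("response length does not match metadata")
    if len(y) <= len(terms) + 2:
        raise ValidationError(f"need n > |terms| + 2, got n={len(y)} terms={terms}")
    X = build_design(metadata, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValidationError(f"rank-deficient design: collinearity among {list(X.columns)}")
    fit = sm.OLS(y, X).fit()
    k = X.shape[1] + 1  # + residual variance
    aic = 2.0 * k - 2.0 * fit.llf
    return FittedModel(
        terms=tuple(terms),
        coefficients={t: float(fit.params[t]) for t in X.columns},
        pvalues={t: float(fit.pvalues[t]) for t in X.columns},
        loglik=float(fit.llf),
        aic=float(aic),
        n=len(y),
    )


def _removable(terms: tuple[str, ...]) -> list[str]:
    """Candidate single-term removals honouring marginality: the dose:age
    interaction must leave the model before either main effect can."""
    if "dose:age" in terms:
        return ["dose:age"] + [t for t in terms if t not in ("dose", "age", "dose:age")]
    return list(terms)


def backward_stepwise_aic(
    y: np.ndarray,
    metadata: SampleMetadata,
    full_terms: tuple[str, ...] = FULL_TERMS,
) -> FittedModel:
    """Backward elimination from the full model under AIC.

    At each step the single removable term whose deletion lowers AIC the
    most is dropped; the search stops when no deletion lowers AIC. Ties are
    broken by removing the term with the larger coefficient p-value in the
    current model, then alphabetically (fully deterministic).
    """
    current = fit_linear_model(y, full_terms, metadata)
    while current.terms:
        candidates = []
        for term in _removable(current.terms):
            reduced_terms = tuple(t for t in current.terms if t != term)
            reduced = fit_linear_model(y, reduced_terms, metadata)
            candidates.append((reduced.aic, term, reduced))
        best_aic = min(c[0] for c in candidates)
        if best_aic >= current.aic - 1e-12:
            break
        tied = [c for c in candidates if c[0] <= best_aic + 1e-9]
        tied.sort(key=lambda c: (-current.pvalues.get(c[1], 0.0), c[1]))
        current = tied[0][2]
    return current


def classify_dependency(model: FittedModel, alpha: float = 0.05) -> str:
    """Map a final stepwise model onto a dependency category.

    dose_only: dose retained and significant, with neither age nor the
    dose:age interaction retained-and-significant; age_only symmetric;
    dose_age: both main effects significant, or the interaction significant;
    bmi: only the BMI term significant; none otherwise.
    """
    sig = {t for t in model.terms if model.pvalues.get(t, 1.0) <= alpha}
    dose_sig = "dose" in sig
    age_sig = "age" in sig
    inter_sig = "dose:age" in sig
    bmi_sig = "bmi" in sig
    if inter_sig or (dose_sig and age_sig):
        return "dose_age"
    if dose_sig:
        return "dose_only"
    if age_sig:
        return "age_only"
    if bmi_sig:
        return "bmi"
    return "none"


def deconvolve_matrix(
    abundance: AbundanceMatrix,
    metadata: SampleMetadata,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every protein's dependency after Box-Cox transformation.

    Returns a per-feature table (category, retained terms, coefficients,
    p-values, Box-Cox lambda, final AIC) and the category counts. Features
    with missing values are fitted on their complete samples, provided
    enough remain.
    """
    config = config or RunConfig()
    abundance.check_samples(metadata)
    meta = metadata.subset(abundance.sample_ids)
    rows = []
    counts = {c: 0 for c in CATEGORIES}
    for fid, series in abundance.values.iterrows():
        vals = series.to_numpy(float)
        mask = np.isfinite(vals)
        sub_meta = meta if mask.all() else meta.subset(list(series.index[mask]))
        y = vals[mask]
        if len(y) <= len(FULL_TERMS) + 2 or np.ptp(y) == 0:
            category, model, lam = "none", None, np.nan
        else:
            tr = boxcox_mle(y)
            lam = tr.lambda_hat
            model = backward_stepwise_aic(tr.transformed_values, sub_meta)
            category = classify_dependency(model, config.posthoc_alpha)
        counts[category] += 1
        row = {
            "feature_id": fid,
            "category": category,
            "retained_terms": ",".join(model.terms) if model else "",
            "boxcox_lambda": lam,
            "final_aic": model.aic if model else np.nan,
            "n_used": int(mask.sum()),
        }
        for t in FULL_TERMS:
            row[f"coef_{t.replace(':', '_x_')}"] = model.coefficients.get(t, np.nan) if model else np.nan
            row[f"p_{t.replace(':', '_x_')}"] = model.pvalues.get(t, np.nan) if model else np.nan
        rows.append(row)
    return pd.DataFrame(rows), counts
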