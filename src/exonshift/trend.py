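"""Covariate-adjusted temporal trends and regional contrasts.

Both analyses are Gaussian linear models fit by ordinary least squares
(continuous response, identity link): the temporal model regresses a
feature's splicing index (or expression) on log10 post-conceptual age plus
whichever of sex / RIN / race the dataset provides; the regional model adds
treatment-coded region contrasts against a user-chosen reference region,
Bonferroni-corrected within feature across regions.

Age enters as log10(post-conceptual days) because the cohorts span four
orders of magnitude (early fetal to late adult); a linear-age mode is
available via ``age_transform="linear"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import (
    FeatureExpression,
    SampleRecord,
    SplicingIndexMatrix,
    sample_frame,
)
from .differential import bonferroni_adjust
from .errors import InsufficientDataError, ValidationError

log = logging.getLogger(__name__)

AGE_TERM = "log10_age"
AgeTransform = Literal["log10", "linear"]

#: Covariates considered, in order, when building a design from metadata.
DEFAULT_COVARIATES = ("sex", "rin", "race")

MIN_SAMPLES_TREND = 8


@dataclass
class LinearFit:
    """OLS fit summary: per-term (estimate, se, t, p) plus fit statistics."""

    coefficients: pd.DataFrame  # index term; columns estimate, se, t, p
    r_squared: float
    df_resid: float
    n: int

    def term(self, name: str) -> pd.Series:
        return self.coefficients.loc[name]


def fit_linear_model(response: Sequence[float], design: pd.DataFrame) -> LinearFit:
    """Least-squares fit of ``response`` on a named-column design matrix.

    The design must include its own intercept column and be full column
    rank; two-sided p-values use the t distribution on the residual df.
    """
    y = np.asarray(response, float)
    X = design.astype(float)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("response and design have different lengths")
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(f"n = {n} observations for {k} terms")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        raise ValidationError(
            f"design is rank deficient (rank {rank} < {k} terms); "
            f"collinear candidates: {_collinear_terms(X)}"
        )
    fit = sm.OLS(y, X).fit()
    coef = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return LinearFit(coef, float(fit.rsquared), float(fit.df_resid), int(n))


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    """Columns whose R-diagonal in a pivoted QR is (near) zero."""
    arr = X.to_numpy(float)
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    return [c for c, d in zip(X.columns, diag) if d < tol]


def build_design(
    meta: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    age_transform: AgeTransform = "log10",
    region_reference: Optional[str] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix from sample metadata; returns (design, covariates_used).

    Covariates that are absent or entirely missing in this dataset are
    dropped (no imputation), mirroring per-dataset covariate availability.
    With ``region_reference`` set, treatment-coded region indicator columns
    ``region_<code>`` are added against that reference.
    """
    cols: dict[str, pd.Series] = {"intercept": pd.Series(1.0, index=meta.index)}
    age = meta["age_pcd"].astype(float)
    cols[AGE_TERM if age_transform == "log10" else "age_pcd"] = (
        np.log10(age) if age_transform == "log10" else age
    )
    used: list[str] = []
    for cov in covariates:
        if cov not in meta.columns or meta[cov].isna().all():
            continue
        if cov == "sex":
            cols["sex_male"] = (
                meta["sex"].astype(str).str.lower().str.startswith("m").astype(float)
            )
            used.append("sex")
        elif cov in ("rin",):
            cols["rin"] = meta["rin"].astype(float)
            used.append("rin")
        else:  # categorical covariate (race, ...)
            dummies = pd.get_dummies(meta[cov].astype(str), prefix=cov, dtype=float)
            for name in dummies.columns[1:]:  # first level is the reference
                cols[name] = dummies[name]
            used.append(cov)
    if region_reference is not None:
        regions = meta["region"].astype(str)
        present = sorted(regions.unique())
        if region_reference not in present:
            raise ValidationError(
                f"reference region {region_reference!r} absent from the data"
            )
        if len(present) < 2:
            raise ValidationError("regional model needs >= 2 regions present")
        for code in present:
            if code == region_reference:
                continue
            cols[f"region_{code}"] = (regions == code).astype(float)
    design = pd.DataFrame(cols)
    return design, used


@dataclass
class TrendResult:
    """Temporal-trend fit for one feature."""

    feature: tuple[str, str]
    response: str
    fit: Optional[LinearFit]
    covariates_used: list[str]
    degenerate: bool = False

    @property
    def age_p(self) -> float:
        if self.degenerate or self.fit is None:
            return 1.0
        return float(self.fit.term(AGE_TERM)["p"])

    @property
    def age_coefficient(self) -> float:
        if self.degenerate or self.fit is None:
            return 0.0
        return float(self.fit.term(AGE_TERM)["estimate"])


def _response_series(
    source: "SplicingIndexMatrix | FeatureExpression | pd.DataFrame",
    feature: tuple[str, str],
) -> pd.Series:
    values = source.values if not isinstance(source, pd.DataFrame) else source
    if feature not in values.index:
        raise ValidationError(f"feature {feature} not found in response table")
    return values.loc[feature]


def age_trend(
    si: "SplicingIndexMatrix | FeatureExpression | pd.DataFrame",
    samples: "Sequence[SampleRecord] | pd.DataFrame",
    feature: tuple[str, str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    age_transform: AgeTransform = "log10",
    response_label: str = "splicing_index",
) -> TrendResult:
    """Fit response ~ f(age) + available covariates for one feature."""
    series = _response_series(si, feature)
    meta = sample_frame(samples)
    shared = series.index.intersection(meta.index)
    series = series.loc[shared].dropna()
    meta = meta.loc[series.index]
    if len(series) < MIN_SAMPLES_TREND:
        raise InsufficientDataError(
            f"{feature}: {len(series)} samples with data (< {MIN_SAMPLES_TREND})"
        )
    if float(series.std(ddof=0)) == 0.0:
        log.warning("%s: constant response; degenerate fit, p = 1", (feature,))
        return TrendResult(feature, response_label, None, [], degenerate=True)
    design, used = build_design(meta, covariates, age_transform)
    fit = fit_linear_model(series.to_numpy(), design)
    return TrendResult(feature, response_label, fit, used)


@dataclass
class RegionalResult:
    """Region contrasts (vs a reference region) for one feature."""

    feature: tuple[str, str]
    reference_region: str
    contrasts: pd.DataFrame  # index region; estimate, p, p_adj, n, low_n
    covariates_used: list[str] = field(default_factory=list)
    fit: Optional[LinearFit] = None

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.contrasts.index[self.contrasts["p_adj"] < alpha])


def regional_model(
    source: "SplicingIndexMatrix | FeatureExpression | pd.DataFrame",
    samples: "Sequence[SampleRecord] | pd.DataFrame",
    feature: tuple[str, str],
    reference_region: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    age_transform: AgeTransform = "log10",
) -> RegionalResult:
    """Fit response ~ region + age + available covariates, contrasts vs reference.

    Per-region contrast p-values are Bonferroni-adjusted over the contrasts
    reported for this feature. Regions with fewer than 3 samples are kept
    but flagged ``low_n``.
    """
    series = _response_series(source, feature)
    meta = sample_frame(samples)
    shared = series.index.intersection(meta.index)
    series = series.loc[shared].dropna()
    meta = meta.loc[series.index]
    if meta["region"].isna().any():
        keep = meta["region"].notna()
        series, meta = series[keep], meta[keep]
    design, used = build_design(
        meta, covariates, age_transform, region_reference=reference_region
    )
    fit = fit_linear_model(series.to_numpy(), design)

    region_terms = [t for t in fit.coefficients.index if t.startswith("region_")]
    codes = [t.removeprefix("region_") for t in region_terms]
    counts = meta["region"].value_counts()
    contrasts = pd.DataFrame(
        {
            "estimate": fit.coefficients.loc[region_terms, "estimate"].to_numpy(),
            "p": fit.coefficients.loc[region_terms, "p"].to_numpy(),
            "n": [int(counts.get(c, 0)) for c in codes],
        },
        index=pd.Index(codes, name="region"),
    )
    contrasts["p_adj"] = bonferroni_adjust(contrasts["p"].to_numpy())
    contrasts["low_n"] = contrasts["n"] < 3
    if contrasts["low_n"].any():
        log.warning("%s: low-n regions %s", feature,
                    list(contrasts.index[contrasts["low_n"]]))
    return RegionalResult(feature, reference_region, contrasts, used, fit)


def region_mean_matrix(
    source: "SplicingIndexMatrix | FeatureExpression | pd.DataFrame",
    samples: "Sequence[SampleRecord] | pd.DataFrame",
) -> pd.DataFrame:
    """Feature x region mean response — heatmap-ready summary."""
    values = source.values if not isinstance(source, pd.DataFrame) else source
    meta = sample_frame(samples)
    shared = values.columns.intersection(meta.index)
    region = meta.loc[shared, "region"]
    return values[shared].T.groupby(region.to_numpy()).mean().T
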