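"""Analysis-ready trait construction: covariate adjustment, rank-based
inverse-normal transformation, and descriptive/correlation reports.

The fixed pipeline order is: exclusions -> derived traits -> residualize on
covariates -> rank inverse-normal transform.  Every trait is adjusted for
sex, age, BMI, height and heart rate, except QTc, which is already
rate-adjusted by Bazett's formula and therefore omits heart rate.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

from .ecg_traits import EcgRecord, TRAITS, apply_exclusions, derived_trait

__all__ = [
    "residualize",
    "rank_inverse_normal",
    "descriptives",
    "correlations",
    "correlation_table",
    "covariates_for_trait",
    "analysis_trait",
    "build_analysis_table",
]

log = logging.getLogger(__name__)

#: covariates used for adjustment; heart rate is dropped for QT (QTc)
BASE_COVARIATES = ("sex", "age", "bmi", "height", "heart_rate")


class CollinearDesignError(ValueError):
    """Design matrix is rank deficient; names the offending column."""


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: pivots beyond the numerical rank are the collinear columns
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise CollinearDesignError(
            f"design is rank deficient; collinear column(s): {', '.join(map(str, bad))}"
        )


def residualize(y: np.ndarray | pd.Series, covariates: pd.DataFrame) -> np.ndarray:
    """Ordinary-least-squares residuals of y on covariates (plus intercept)."""
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(np.asarray(covariates, dtype=float), has_constant="add")
    names = ["intercept", *covariates.columns]
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values among included rows; complete cases only")
    _check_full_rank(X, names)
    return np.asarray(sm.OLS(y, X).fit().resid)


def rank_inverse_normal(x: np.ndarray | pd.Series, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Ties get average ranks; value ``Phi^-1((r - c) / (n + 1 - 2c))`` with the
    default ``c = 3/8`` giving ``(r - 3/8) / (n + 1/4)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to rank transform")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; rank transform undefined")
    r = stats.rankdata(x, method="average")
    p = (r - offset) / (x.size + 1.0 - 2.0 * offset)
    return stats.norm.ppf(p)


def descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/min/max per numeric column (cohort descriptive report)."""
    if len(table) < 3:
        raise ValueError("need at least 3 complete rows for descriptives")
    num = table.select_dtypes(include=[np.number])
    return pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "min": num.min(),
            "max": num.max(),
        }
    )


def correlations(
    traits: pd.DataFrame, covariates: pd.DataFrame | None = None, adjusted: bool = False
) -> pd.DataFrame:
    """Pearson trait-by-trait correlations, optionally after covariate
    adjustment (residualizing every trait on the covariates first)."""
    if len(traits) < 3:
        raise ValueError("need at least 3 complete rows for correlations")
    if adjusted:
        if covariates is None:
            raise ValueError("adjusted correlations require covariates")
        data = traits.apply(lambda col: residualize(col, covariates), axis=0)
    else:
        data = traits
    for col in data.columns:
        if np.ptp(np.asarray(data[col], dtype=float)) == 0:
            raise ValueError(f"constant column {col!r}; correlation undefined")
    return data.corr(method="pearson")


def correlation_table(
    traits: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Combined layout: unadjusted correlations above the diagonal, adjusted
    below, ones on the diagonal."""
    unadj = correlations(traits).to_numpy()
    adj = correlations(traits, covariates, adjusted=True).to_numpy()
    out = np.tril(adj, -1) + np.triu(unadj, 1) + np.eye(len(traits.columns))
    return pd.DataFrame(out, index=traits.columns, columns=traits.columns)


def covariates_for_trait(covariates: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Adjustment design for one trait; QTc omits heart rate."""
    cols = [c for c in BASE_COVARIATES if c in covariates.columns]
    if trait == "QT":
        cols = [c for c in cols if c != "heart_rate"]
    return covariates[cols]


def analysis_trait(
    cohort: Iterable[EcgRecord],
    covariates: pd.DataFrame,
    trait: str,
    mode_12ls: str = "amplitude",
    blom_offset: float = 3.0 / 8.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Run the full per-trait pipeline and return the analysis-ready trait.

    Returns
    -------
    values
        Rank-transformed residuals indexed by individual id (kept rows only).
    report
        Exclusion report with columns id/trait/kept/reason.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    kept, dropped = apply_exclusions(cohort, trait)
    report = pd.DataFrame(
        [(r.id, trait, True, "") for r in kept]
        + [(r.id, trait, False, reason) for r, reason in dropped],
        columns=["id", "trait", "kept", "reason"],
    )
    raw = pd.Series(
        {r.id: derived_trait(r, trait, mode_12ls=mode_12ls) for r in kept},
        name=trait,
        dtype=float,
    )
    cov = covariates_for_trait(covariates, trait).reindex(raw.index)
    complete = ~cov.isna().any(axis=1) & raw.notna()
    if complete.sum() < len(raw):
        log.info("%s: dropping %d incomplete rows", trait, int((~complete).sum()))
    raw, cov = raw[complete], cov[complete]
    resid = residualize(raw, cov)
    values = pd.Series(
        rank_inverse_normal(resid, offset=blom_offset), index=raw.index, name=trait
    )
    log.info(
        "pipeline %s: exclusions -> derived -> residualize -> rank INT (n=%d kept, %d dropped)",
        trait, len(values), len(dropped),
    )
    return values, report


def build_analysis_table(
    cohort: Iterable[EcgRecord],
    covariates: pd.DataFrame,
    traits: Sequence[str] = TRAITS,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analysis-ready values for several traits (NaN where excluded)."""
    cohort = list(cohort)
    cols, reports = {}, []
    for trait in traits:
        vals, rep = analysis_trait(cohort, covariates, trait, **kwargs)
        cols[trait] = vals
        reports.append(rep)
    table = pd.DataFrame(cols).reindex([r.id for r in cohort])
    return table, pd.concat(reports, ignore_index=True)
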