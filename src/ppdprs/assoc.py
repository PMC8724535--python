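"""Association layer: group comparisons and multi-adjusted regression models.

Linear models are ordinary least squares with t-based confidence
intervals; binary outcomes use maximum-likelihood logistic regression
with Wald intervals, the odds ratio reported per unit of the exposure.
Models are complete-case; the default covariates are the two ancestry
components (MDSC1, MDSC2) plus age and sex, except that outcomes already
computed from age and/or sex (the prodromal-PD probability and its
cut-offs, and the total LRs) are adjusted for ancestry only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    outcome: str
    outcome_kind: str  # "binary" | "continuous"
    exposure: str
    covariates: tuple[str, ...] = ("MDSC1", "MDSC2", "age", "sex")
    transform: str = "none"  # "none" | "natural_log", applied to the outcome
    subgroup: str = ""  # free-text description of any row filter already applied

    def __post_init__(self) -> None:
        if self.outcome_kind not in ("binary", "continuous"):
            raise ValueError(f"invalid outcome kind {self.outcome_kind!r}")
        if self.transform not in ("none", "natural_log"):
            raise ValueError(f"invalid transform {self.transform!r}")
        if self.transform == "natural_log" and self.outcome_kind != "continuous":
            raise ValueError("log transform only applies to continuous outcomes")
        if self.outcome in self.covariates:
            raise ValueError("outcome cannot also be a covariate")


@dataclass
class AssociationResult:
    """One fitted model: b (linear) or OR (logistic) with 95% CI and p."""

    estimate: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_used: int
    model: ModelSpec
    converged: bool = True
    scale: str = "beta"  # "beta" | "odds_ratio"

    def as_row(self) -> dict:
        return {
            "outcome": self.model.outcome,
            "exposure": self.model.exposure,
            "covariates": "+".join(self.model.covariates),
            "transform": self.model.transform,
            "subgroup": self.model.subgroup,
            "scale": self.scale,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n": self.n_used,
            "converged": self.converged,
        }


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame, int]:
    cols = [spec.outcome, spec.exposure, *spec.covariates]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise KeyError(f"columns not in data: {missing_cols}")
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    n_before = len(sub)
    sub = sub.dropna()
    y = sub[spec.outcome]
    if spec.transform == "natural_log":
        pos = y > 0
        dropped = int((~pos).sum())
        if dropped:
            logger.info("log transform: dropped %d non-positive outcome rows", dropped)
        sub = sub.loc[pos]
        y = np.log(sub[spec.outcome])
    X = sm.add_constant(sub[[spec.exposure, *spec.covariates]], has_constant="add")
    return y, X, n_before - len(sub)


def fit_linear(data: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """OLS of a continuous outcome on the exposure plus covariates."""
    if spec.outcome_kind != "continuous":
        raise ValueError("fit_linear requires a continuous outcome")
    y, X, _ = _design(data, spec)
    if len(y) <= X.shape[1]:
        raise ValueError("not enough complete-case rows to fit")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return AssociationResult(
        estimate=float(fit.params[spec.exposure]),
        ci_low=float(ci.loc[spec.exposure, 0]),
        ci_high=float(ci.loc[spec.exposure, 1]),
        pvalue=float(fit.pvalues[spec.exposure]),
        n_used=int(fit.nobs),
        model=spec,
        scale="beta",
    )


def fit_logistic(data: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """ML logistic regression; reports OR = exp(beta) with Wald 95% CI.

    Non-convergence (including separation) yields a result with
    ``converged=False`` and NaN estimates rather than a misleading fit.
    """
    if spec.outcome_kind != "binary":
        raise ValueError("fit_logistic requires a binary outcome")
    y, X, _ = _design(data, spec)
    classes = set(y.unique())
    if not classes <= {0, 1} or len(classes) < 2:
        raise ValueError(f"outcome must contain both classes 0/1, got {sorted(classes)}")
    if X[spec.exposure].nunique() < 2:
        raise ValueError("exposure is constant: model not identifiable")
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=False, maxiter=100, tol=1e-8)
        converged = bool(fit.mle_retvals.get("converged", True))
        bse = fit.bse[spec.exposure]
        if not np.isfinite(bse) or bse > 100:
            converged = False  # quasi-separation: SE blown up
    except Exception:  # PerfectSeparationError and friends
        converged = False
        fit = None
    if not converged or fit is None:
        return AssociationResult(
            estimate=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            pvalue=float("nan"),
            n_used=int(len(y)),
            model=spec,
            converged=False,
            scale="odds_ratio",
        )
    b = float(fit.params[spec.exposure])
    se = float(fit.bse[spec.exposure])
    return AssociationResult(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - 1.959963984540054 * se)),
        ci_high=float(np.exp(b + 1.959963984540054 * se)),
        pvalue=float(fit.pvalues[spec.exposure]),
        n_used=int(fit.nobs),
        model=spec,
        scale="odds_ratio",
    )


def quartile_contrast(
    data: pd.DataFrame,
    spec: ModelSpec,
    quartile_col: str,
) -> dict[str, AssociationResult | float]:
    """Quartile-coded exposure contrasts for a binary outcome.

    Fits one model with Q2/Q3/Q4 dummies (Q1 reference, all rows kept) and
    reports each OR vs Q1; a second model codes Q4 vs {Q1,Q2,Q3} as a
    binary exposure; a third treats the quartile as an ordered score 1-4
    and reports the trend p-value.
    """
    if quartile_col not in data.columns:
        raise KeyError(quartile_col)
    counts = data[quartile_col].value_counts()
    out: dict[str, AssociationResult | float] = {}
    if any(counts.get(q, 0) == 0 for q in ("Q1", "Q2", "Q3", "Q4")):
        logger.warning("empty quartile cell: contrast withheld")
        return {"withheld": True}
    work = data.copy()
    for q in ("Q2", "Q3", "Q4"):
        work[f"{quartile_col}_{q}"] = (work[quartile_col] == q).astype(float)
    base_cov = spec.covariates
    for q in ("Q2", "Q3", "Q4"):
        dummy_covs = tuple(f"{quartile_col}_{r}" for r in ("Q2", "Q3", "Q4") if r != q)
        sub = replace(spec, exposure=f"{quartile_col}_{q}", covariates=base_cov + dummy_covs)
        res = fit_logistic(work, sub) if spec.outcome_kind == "binary" else fit_linear(work, sub)
        res.model = replace(res.model, exposure=f"{q}_vs_Q1", covariates=base_cov)
        out[f"{q}_vs_Q1"] = res
    work["q4_vs_rest"] = (work[quartile_col] == "Q4").astype(float)
    sub = replace(spec, exposure="q4_vs_rest")
    out["Q4_vs_others"] = fit_logistic(work, sub) if spec.outcome_kind == "binary" else fit_linear(work, sub)
    work["q_score"] = work[quartile_col].map({"Q1": 1.0, "Q2": 2.0, "Q3": 3.0, "Q4": 4.0})
    sub = replace(spec, exposure="q_score")
    trend = fit_logistic(work, sub) if spec.outcome_kind == "binary" else fit_linear(work, sub)
    out["trend_p"] = trend.pvalue
    return out


def group_compare(values: Sequence[float], group_labels: Sequence, value_kind: str) -> tuple[float, float]:
    """Two-or-more-group comparison dispatched on the declared value kind.

    normal: unpaired t-test (2 groups) or one-way ANOVA (>2);
    non_normal: Mann-Whitney (2) or Kruskal-Wallis (>2);
    categorical: chi-square on the contingency table of values x groups.
    Returns (statistic, two-sided p).
    """
    values = np.asarray(values)
    labels = np.asarray(group_labels)
    if value_kind not in ("normal", "non_normal", "categorical"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if value_kind == "categorical":
        table = pd.crosstab(pd.Series(values), pd.Series(labels)).to_numpy()
        res = stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    samples = [values[labels == g].astype(float) for g in groups]
    if value_kind in ("normal",) and any(len(s) < 2 for s in samples):
        raise ValueError("variance-based tests need >= 2 observations per group")
    if value_kind == "normal":
        if len(groups) == 2:
            res = stats.ttest_ind(samples[0], samples[1])
        else:
            res = stats.f_oneway(*samples)
    else:
        if len(groups) == 2:
            res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        else:
            res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


# covariate rule: outcomes computed from age and/or sex are adjusted for ancestry only
_ANCESTRY_ONLY = ("MDSC1", "MDSC2")
_FULL = ("MDSC1", "MDSC2", "age", "sex")


def battery_outcomes(data: pd.DataFrame) -> list[tuple[str, str, str, tuple[str, ...]]]:
    """(outcome, kind, transform, covariates) rows of the primary model grid."""
    rows: list[tuple[str, str, str, tuple[str, ...]]] = [
        ("ppd_prob", "continuous", "natural_log", _ANCESTRY_ONLY),
        ("ge_30", "binary", "none", _ANCESTRY_ONLY),
        ("ge_50", "binary", "none", _ANCESTRY_ONLY),
        ("risk_lr", "continuous", "natural_log", _ANCESTRY_ONLY),
        ("prodromal_lr", "continuous", "natural_log", _ANCESTRY_ONLY),
    ]
    for col in data.columns:
        if col.startswith("marker_"):
            rows.append((col, "binary", "none", _FULL))
        elif col.startswith("z_"):
            rows.append((col, "continuous", "none", _FULL))
    return rows


def run_model_battery(
    data: pd.DataFrame,
    thresholds: Sequence[float],
    *,
    fully_adjusted_variant: bool = False,
    subgroup: str = "",
) -> pd.DataFrame:
    """The primary model grid: every PRS threshold against every outcome.

    ``data`` is the joined analysis frame (one row per individual) built
    by :func:`ppdprs.pipeline.build_analysis_frame`: ``prs_<t>`` exposure
    columns, pPD probability / cut-offs / total LRs, ``marker_*`` binary
    prodromal markers, ``z_*`` cognitive-domain scores, covariates.
    Returns a tidy frame of nominal (uncorrected) results; a Bonferroni
    column is appended as a labelled convenience only.
    """
    rows = []
    for t in thresholds:
        exposure = f"prs_{t:g}"
        if exposure not in data.columns:
            raise KeyError(f"missing exposure column {exposure}")
        for outcome, kind, transform, covs in battery_outcomes(data):
            cov_sets = [covs]
            if fully_adjusted_variant and covs == _ANCESTRY_ONLY:
                cov_sets.append(_FULL)
            for cov in cov_sets:
                spec = ModelSpec(outcome, kind, exposure, tuple(cov), transform, subgroup)
                try:
                    if kind == "binary":
                        res = fit_logistic(data, spec)
                    else:
                        res = fit_linear(data, spec)
                    row = res.as_row()
                except (ValueError, KeyError):
                    row = {
                        "outcome": outcome,
                        "exposure": exposure,
                        "covariates": "+".join(cov),
                        "transform": transform,
                        "subgroup": subgroup,
                        "scale": "odds_ratio" if kind == "binary" else "beta",
                        "estimate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "pvalue": np.nan,
                        "n": 0,
                        "converged": False,
                    }
                row["threshold"] = t
                rows.append(row)
    table = pd.DataFrame(rows)
    m = table["pvalue"].notna().sum()
    table["bonferroni_p_nonpaper"] = (table["pvalue"] * m).clip(upper=1.0)
    return table


def joint_domain_model(
    data: pd.DataFrame,
    threshold: float,
    kind: str = "continuous",
) -> pd.DataFrame:
    """All five cognitive domains as simultaneous outcomes of one exposure.

    Implemented as one model per domain with the other domains' scores as
    additional covariates, which is the usual way 'including all domains
    in the same model' is operationalized for a single exposure of
    interest.
    """
    exposure = f"prs_{threshold:g}"
    zcols = [c for c in data.columns if c.startswith("z_")]
    rows = []
    for col in zcols:
        others = tuple(c for c in zcols if c != col)
        spec = ModelSpec(col, "continuous", exposure, _FULL + others, "none", "joint-domains")
        res = fit_linear(data, spec)
        row = res.as_row()
        row["threshold"] = threshold
        rows.append(row)
    return pd.DataFrame(rows)
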