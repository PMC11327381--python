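"""Statistical layer: group mixed models, model comparison, cross-sectional
age slopes, and the turns-by-group productivity model.

Hearing group is treatment-coded with CI as the reference level, so the
CA_MATCH / HA_MATCH coefficients read as deviations from the CI group.
Continuous predictors are mean-centered before fitting.  Likelihood-ratio
tests always refit by maximum likelihood (REML log-likelihoods are not
comparable across fixed-effect structures).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .segments_io import AnalysisConfig, HearingGroup

logger = logging.getLogger(__name__)

__all__ = [
    "CoefEstimate",
    "ModelResult",
    "ComparisonResult",
    "SlopeResult",
    "ProductivityResult",
    "DegenerateDesignError",
    "fit_group_model",
    "compare_models",
    "lrt_group_effect",
    "cross_sectional_slopes",
    "voc_duration_slopes",
    "fit_productivity_model",
    "fit_all_models",
    "sensitivity_rerun",
]

GROUP_TERM = "C(hearing_group, Treatment('CI'))"
GROUP_LEVELS = [g.value for g in HearingGroup]


class DegenerateDesignError(ValueError):
    """The requested model cannot be identified on the given data."""


@dataclass(frozen=True, slots=True)
class CoefEstimate:
    estimate: float
    se: float
    t: float
    p: float


@dataclass(slots=True)
class ModelResult:
    """Fitted coefficients plus fit statistics for one model."""

    outcome_name: str
    coefficients: dict[str, CoefEstimate]
    loglik: float
    aic: float
    k_params: int
    n_obs: int
    n_groups: dict[str, int] = field(default_factory=dict)
    method: str = "REML"  # REML | ML | OLS | OLS-fallback
    df_method: str = "normal"

    def coef(self, term: str) -> float:
        return self.coefficients[term].estimate

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "coefficients": {
                k: {"estimate": v.estimate, "se": v.se, "t": v.t, "p": v.p}
                for k, v in self.coefficients.items()
            },
            "loglik": self.loglik,
            "aic": self.aic,
            "k_params": self.k_params,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "method": self.method,
            "df_method": self.df_method,
        }


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    """Likelihood-ratio comparison of two nested ML fits."""

    chi2: float
    df: int
    p: float
    delta_aic: float

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "delta_aic": self.delta_aic,
        }


@dataclass(slots=True)
class SlopeResult:
    """Per-group regression of an environment metric on age (months)."""

    group: str
    age_basis: str  # CHRONO | HEARING
    outcome_name: str
    beta: float
    pearson_r: float
    p: float
    n: int
    available: bool = True

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "age_basis": self.age_basis,
            "outcome_name": self.outcome_name,
            "beta": self.beta,
            "pearson_r": self.pearson_r,
            "p": self.p,
            "n": self.n,
            "available": self.available,
        }


@dataclass(slots=True)
class ProductivityResult:
    """Turns->vocalizations regression with group interaction."""

    model: ModelResult
    group_slopes: dict[str, float]
    interaction_test: ComparisonResult

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "group_slopes": self.group_slopes,
            "interaction_test": self.interaction_test.to_dict(),
        }


def _center(df: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = out[c] - out[c].mean()
    return out


def _check_outcome(df: pd.DataFrame, outcome: str) -> None:
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not present")
    vals = df[outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"outcome {outcome!r} contains non-finite values")


def _check_group_column(df: pd.DataFrame) -> None:
    if "hearing_group" not in df.columns:
        raise KeyError("hearing_group column required")
    if "CI" not in set(df["hearing_group"]):
        raise DegenerateDesignError("CI reference level not represented")


def _mixed_result(
    fit, outcome: str, n_groups: dict[str, int], method: str
) -> ModelResult:
    coefs = {}
    for term in fit.fe_params.index:
        est = float(fit.fe_params[term])
        se = float(fit.bse_fe[term])
        t = est / se if se > 0 else 0.0
        p = 2 * scipy.stats.norm.sf(abs(t)) if se > 0 else 1.0
        coefs[term] = CoefEstimate(est, se, t, p)
    # params holds fixed effects + variance components; residual variance
    # (scale) is profiled out, hence +1
    k = len(fit.params) + 1
    llf = float(fit.llf)
    return ModelResult(
        outcome_name=outcome,
        coefficients=coefs,
        loglik=llf,
        aic=2 * k - 2 * llf,
        k_params=k,
        n_obs=int(fit.nobs),
        n_groups=n_groups,
        method=method,
        df_method="normal",
    )


def _ols_result(fit, outcome: str, method: str = "OLS") -> ModelResult:
    coefs = {}
    for term in fit.params.index:
        est = float(fit.params[term])
        se = float(fit.bse[term])
        t = float(fit.tvalues[term]) if se > 0 else 0.0
        p = float(fit.pvalues[term]) if se > 0 else 1.0
        coefs[term] = CoefEstimate(est, se, t, p)
    k = len(fit.params) + 1  # + residual variance
    llf = float(fit.llf)
    return ModelResult(
        outcome_name=outcome,
        coefficients=coefs,
        loglik=llf,
        aic=2 * k - 2 * llf,
        k_params=k,
        n_obs=int(fit.nobs),
        n_groups={},
        method=method,
        df_method="t",
    )


def fit_group_model(
    long_table: pd.DataFrame,
    outcome: str,
    random_terms: Sequence[str] = ("child",),
    meta: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
    include_group: bool = True,
    reml: bool = True,
) -> ModelResult:
    """Mixed model of ``outcome`` on hearing group with random intercepts.

    ``random_terms`` may be ``("child",)`` (repeated measures such as
    vocalization duration) or ``("child", "hour")`` (hourly outcomes, which
    add crossed hour-of-recording intercepts).  Continuous ``covariates``
    are mean-centered.  Set ``include_group=False`` for the null
    (random-effects-only) model used in likelihood-ratio comparisons.
    """
    df = long_table
    if meta is not None:
        df = df.merge(meta, on="child_id", how="left", validate="many_to_one")
    df = df.copy()
    _check_outcome(df, outcome)
    if include_group:
        _check_group_column(df)
        if df["hearing_group"].nunique() < 2:
            raise DegenerateDesignError("hearing_group has a single level")
    random_terms = tuple(random_terms)
    for term in random_terms:
        col = {"child": "child_id", "hour": "hour_index"}.get(term)
        if col is None:
            raise ValueError(f"unknown random term {term!r}")
        if df[col].nunique() < 2:
            raise DegenerateDesignError(
                f"grouping factor {term!r} has a single level"
            )
    df = _center(df, covariates)

    rhs = ["1"]
    if include_group:
        rhs.append(GROUP_TERM)
    rhs.extend(covariates)
    formula = f"{outcome} ~ {' + '.join(rhs)}"

    n_groups = {"child": int(df["child_id"].nunique())}
    method = "REML" if reml else "ML"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if "hour" in random_terms:
                n_groups["hour"] = int(df["hour_index"].nunique())
                model = sm.MixedLM.from_formula(
                    formula,
                    groups=np.ones(len(df)),
                    vc_formula={
                        "child": "0 + C(child_id)",
                        "hour": "0 + C(hour_index)",
                    },
                    re_formula="0",
                    data=df,
                )
            else:
                model = sm.MixedLM.from_formula(
                    formula, groups=df["child_id"], data=df
                )
            fit = model.fit(reml=reml)
            result = _mixed_result(fit, outcome, n_groups, method)
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError) as exc:
            # zero-variance/degenerate data: fall back to OLS on the same
            # fixed-effect structure so the pipeline keeps moving
            logger.warning(
                "mixed fit for %s degenerate (%s); falling back to OLS",
                outcome, exc,
            )
            fit = smf.ols(formula, data=df).fit()
            result = _ols_result(fit, outcome, method="OLS-fallback")
            result.n_groups = n_groups
    return result


def compare_models(
    null_model: ModelResult, full_model: ModelResult
) -> ComparisonResult:
    """Likelihood-ratio test of nested ML fits (chi-square reference)."""
    for m in (null_model, full_model):
        if m.method == "REML":
            raise ValueError(
                "likelihood-ratio comparison requires maximum-likelihood fits"
            )
    if null_model.n_obs != full_model.n_obs:
        raise ValueError(
            f"models fit on different row counts "
            f"({null_model.n_obs} vs {full_model.n_obs})"
        )
    df = full_model.k_params - null_model.k_params
    if df < 0:
        raise ValueError("full model has fewer parameters than null model")
    chi2 = max(0.0, 2.0 * (full_model.loglik - null_model.loglik))
    p = float(scipy.stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return ComparisonResult(
        chi2=chi2,
        df=df,
        p=p,
        delta_aic=full_model.aic - null_model.aic,
    )


def lrt_group_effect(
    long_table: pd.DataFrame,
    outcome: str,
    random_terms: Sequence[str] = ("child",),
    meta: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
) -> ComparisonResult:
    """LRT for the hearing-group fixed effect (both models refit by ML)."""
    null = fit_group_model(
        long_table, outcome, random_terms, meta, covariates,
        include_group=False, reml=False,
    )
    full = fit_group_model(
        long_table, outcome, random_terms, meta, covariates,
        include_group=True, reml=False,
    )
    return compare_models(null, full)


def _age_column(age_basis: str) -> str:
    basis = age_basis.upper()
    if basis == "CHRONO":
        return "chrono_age_mo"
    if basis == "HEARING":
        return "hearing_age_mo"
    raise ValueError(f"unknown age basis {age_basis!r}")


def _slope_rows(
    per_child_table: pd.DataFrame, age_basis: str, config: AnalysisConfig
) -> list[tuple[str, pd.DataFrame]]:
    """(group, rows) pairs for a cross-sectional analysis.

    Chronological basis: every group on its own chronological ages.
    Hearing basis: CI children only, restricted to those at or above the
    minimum hearing experience.
    """
    basis = age_basis.upper()
    if basis == "CHRONO":
        return [
            (g, per_child_table[per_child_table["hearing_group"] == g])
            for g in GROUP_LEVELS
            if (per_child_table["hearing_group"] == g).any()
        ]
    sub = per_child_table[
        (per_child_table["hearing_group"] == "CI")
        & (per_child_table["hearing_age_mo"] >= config.min_hearing_age_mo)
    ]
    return [("CI", sub)]


def cross_sectional_slopes(
    per_child_table: pd.DataFrame,
    outcome: str,
    age_basis: str = "CHRONO",
    config: AnalysisConfig | None = None,
) -> list[SlopeResult]:
    """Per-group OLS slope of a per-child outcome on age, with Pearson r.

    Groups with fewer than 3 children are flagged unavailable (NaN
    estimates) rather than dropped.
    """
    config = config or AnalysisConfig()
    _check_outcome(per_child_table, outcome)
    age_col = _age_column(age_basis)
    results = []
    for group, rows in _slope_rows(per_child_table, age_basis, config):
        x = rows[age_col].to_numpy(dtype=float)
        y = rows[outcome].to_numpy(dtype=float)
        if len(rows) < 3 or np.ptp(x) == 0:
            results.append(
                SlopeResult(
                    group=group,
                    age_basis=age_basis.upper(),
                    outcome_name=outcome,
                    beta=float("nan"),
                    pearson_r=float("nan"),
                    p=float("nan"),
                    n=len(rows),
                    available=False,
                )
            )
            continue
        fit = scipy.stats.linregress(x, y)
        results.append(
            SlopeResult(
                group=group,
                age_basis=age_basis.upper(),
                outcome_name=outcome,
                beta=float(fit.slope),
                pearson_r=float(fit.rvalue),
                p=float(fit.pvalue),
                n=len(rows),
            )
        )
    return results


def voc_duration_slopes(
    voc_dur_table: pd.DataFrame,
    per_child_table: pd.DataFrame,
    age_basis: str = "CHRONO",
    config: AnalysisConfig | None = None,
) -> list[SlopeResult]:
    """Per-group age slope of segment-level vocalization durations.

    The slope comes from a mixed model on the raw durations with child
    random intercepts (a repeated measure); the Pearson r is computed on
    per-child mean durations, mirroring the per-child summaries used
    elsewhere.
    """
    config = config or AnalysisConfig()
    age_col = _age_column(age_basis)
    meta_cols = ["child_id", "hearing_group", "chrono_age_mo", "hearing_age_mo"]
    merged = voc_dur_table.merge(
        per_child_table[meta_cols].drop_duplicates("child_id"),
        on="child_id",
        how="left",
    )
    results = []
    for group, child_rows in _slope_rows(per_child_table, age_basis, config):
        rows = merged[merged["child_id"].isin(child_rows["child_id"])]
        n_children = rows["child_id"].nunique()
        if n_children < 3 or np.ptp(rows[age_col].to_numpy(dtype=float)) == 0:
            results.append(
                SlopeResult(
                    group=group,
                    age_basis=age_basis.upper(),
                    outcome_name="voc_duration_ms",
                    beta=float("nan"),
                    pearson_r=float("nan"),
                    p=float("nan"),
                    n=n_children,
                    available=False,
                )
            )
            continue
        df = rows.copy()
        df["age_c"] = df[age_col] - df[age_col].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM.from_formula(
                "duration_ms ~ age_c", groups=df["child_id"], data=df
            ).fit(reml=True)
        beta = float(fit.fe_params["age_c"])
        se = float(fit.bse_fe["age_c"])
        p = 2 * scipy.stats.norm.sf(abs(beta / se)) if se > 0 else 1.0
        # r on per-child summaries
        summ = df.groupby("child_id").agg(
            age=(age_col, "first"), mean_dur=("duration_ms", "mean")
        )
        r, _ = scipy.stats.pearsonr(summ["age"], summ["mean_dur"])
        results.append(
            SlopeResult(
                group=group,
                age_basis=age_basis.upper(),
                outcome_name="voc_duration_ms",
                beta=beta,
                pearson_r=float(r),
                p=float(p),
                n=n_children,
            )
        )
    return results


def fit_productivity_model(per_child_table: pd.DataFrame) -> ProductivityResult:
    """Predict hourly child vocalizations from hourly conversational turns.

    Linear regression controlling for chronological age, with a
    turns-by-group interaction (CI reference).  Per-group slopes are the CI
    slope plus the group's interaction deviation.  The interaction is
    tested against the no-interaction model by ML likelihood ratio.
    """
    df = per_child_table.copy()
    for col in ("cvc_per_hr", "ctc_per_hr", "chrono_age_mo"):
        _check_outcome(df, col)
    _check_group_column(df)
    df = _center(df, ["ctc_per_hr", "chrono_age_mo"])

    full_formula = (
        f"cvc_per_hr ~ chrono_age_mo + ctc_per_hr * {GROUP_TERM}"
    )
    null_formula = (
        f"cvc_per_hr ~ chrono_age_mo + ctc_per_hr + {GROUP_TERM}"
    )
    fit_full = smf.ols(full_formula, data=df).fit()
    fit_null = smf.ols(null_formula, data=df).fit()
    model = _ols_result(fit_full, "cvc_per_hr")
    comparison = compare_models(
        _ols_result(fit_null, "cvc_per_hr"), model
    )

    ci_slope = model.coef("ctc_per_hr")
    slopes = {"CI": ci_slope}
    for level in ("CA_MATCH", "HA_MATCH"):
        term = f"ctc_per_hr:{GROUP_TERM}[T.{level}]"
        if term in model.coefficients:
            slopes[level] = ci_slope + model.coef(term)
    return ProductivityResult(
        model=model, group_slopes=slopes, interaction_test=comparison
    )


# ---------------------------------------------------------------------------
# whole-analysis driver + sensitivity rerun

SLOPE_OUTCOMES = ("awc_per_hr", "adult_sec_per_hr", "cvc_per_hr", "ctc_per_hr")


def fit_all_models(
    per_child_table: pd.DataFrame,
    hourly_table: pd.DataFrame | None = None,
    voc_dur_table: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Fit the full statistical layer on one set of analysis tables."""
    config = config or AnalysisConfig()
    meta_cols = ["child_id", "hearing_group", "chrono_age_mo", "hearing_age_mo"]
    meta = per_child_table[meta_cols].drop_duplicates("child_id")

    results: dict = {"group_models": {}, "group_lrt": {}, "slopes": []}
    if hourly_table is not None and len(hourly_table):
        for outcome in ("words", "adult_min", "voc_count"):
            results["group_models"][outcome] = fit_group_model(
                hourly_table, outcome, ("child", "hour"), meta=meta
            )
            results["group_lrt"][outcome] = lrt_group_effect(
                hourly_table, outcome, ("child", "hour"), meta=meta
            )
    if voc_dur_table is not None and len(voc_dur_table):
        results["group_models"]["voc_duration_ms"] = fit_group_model(
            voc_dur_table, "duration_ms", ("child",), meta=meta
        )
        results["group_lrt"]["voc_duration_ms"] = lrt_group_effect(
            voc_dur_table, "duration_ms", ("child",), meta=meta
        )
    for basis in ("CHRONO", "HEARING"):
        for outcome in SLOPE_OUTCOMES:
            results["slopes"].extend(
                cross_sectional_slopes(per_child_table, outcome, basis, config)
            )
        if voc_dur_table is not None and len(voc_dur_table):
            results["slopes"].extend(
                voc_duration_slopes(
                    voc_dur_table, per_child_table, basis, config
                )
            )
    results["productivity"] = fit_productivity_model(per_child_table)
    return results


def _coef_frame(results: dict, label: str) -> pd.DataFrame:
    rows = []
    for outcome, model in results["group_models"].items():
        for term, est in model.coefficients.items():
            rows.append(
                {
                    "run": label,
                    "model": f"group:{outcome}",
                    "term": term,
                    "estimate": est.estimate,
                    "se": est.se,
                }
            )
    for slope in results["slopes"]:
        rows.append(
            {
                "run": label,
                "model": f"slope:{slope.outcome_name}:{slope.age_basis}",
                "term": slope.group,
                "estimate": slope.beta,
                "se": float("nan"),
            }
        )
    prod = results["productivity"]
    for term, est in prod.model.coefficients.items():
        rows.append(
            {
                "run": label,
                "model": "productivity",
                "term": term,
                "estimate": est.estimate,
                "se": est.se,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_rerun(
    per_child_table: pd.DataFrame,
    hourly_table: pd.DataFrame | None = None,
    voc_dur_table: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Refit everything with ``config.exclude_child_ids`` removed.

    Returns the full-cohort results, the reduced-cohort results, and a
    paired table of coefficient shifts.  Excluding an id absent from the
    cohort is a warning-level no-op; emptying a hearing group is an error.
    """
    config = config or AnalysisConfig()
    excluded = set(config.exclude_child_ids)
    present = set(per_child_table["child_id"])
    missing = excluded - present
    if missing:
        logger.warning(
            "sensitivity rerun: excluded id(s) not in cohort: %s",
            sorted(missing),
        )
    keep = ~per_child_table["child_id"].isin(excluded)
    reduced = per_child_table[keep]
    for g in per_child_table["hearing_group"].unique():
        if (reduced["hearing_group"] == g).sum() == 0:
            raise DegenerateDesignError(
                f"exclusion empties hearing group {g}"
            )

    def _subset(tbl):
        if tbl is None:
            return None
        return tbl[~tbl["child_id"].isin(excluded)]

    full = fit_all_models(per_child_table, hourly_table, voc_dur_table, config)
    red = fit_all_models(
        reduced, _subset(hourly_table), _subset(voc_dur_table), config
    )
    shifts = _coef_frame(full, "full").merge(
        _coef_frame(red, "reduced"),
        on=["model", "term"],
        suffixes=("_full", "_reduced"),
    )
    shifts["shift"] = shifts["estimate_reduced"] - shifts["estimate_full"]
    return {"full": full, "reduced": red, "shifts": shifts}


def slopes_to_frame(slopes: Iterable[SlopeResult]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in slopes])
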