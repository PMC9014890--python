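"""Mixed-effects pre/post models, estimated means, percent change, chi-square.

Two model families are fitted per outcome (steps/day and MVPA min/week), both
linear mixed models with a participant-level random intercept, estimated by
restricted maximum likelihood (REML) so weeks missing at random are handled
without imputation:

* the **period model** regresses the weekly outcome on period (pre vs post)
  plus the number of valid weekday and weekend wear days in the week;
* the **weekly model** replaces period with study week as a categorical fixed
  effect (reference = week 1), giving per-week estimated means for
  trajectory plots.

Estimated (marginal) means are computed at the sample means of the wear-day
covariates with model-based standard errors. Wald F statistics use a
containment-style denominator df, ``n_obs - n_groups - k_fixed + 1``
(recorded in ``MixedModelResult.df_method``); with 17 participants no richer
small-sample correction is attempted and reported df are approximate.

Demographic inclusion/exclusion comparisons use the Pearson chi-square test
without continuity correction, dropping categories with zero total count
(the only way the test is defined for tables with structural zeros).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .exceptions import ConvergenceError, InsufficientDataError
from .weekly_aggregation import POST, PRE, StudyDesign

OUTCOMES = ("steps_per_day", "mvpa_min_per_week")

_COVARIATES = ["n_valid_weekdays", "n_valid_weekend_days"]


@dataclass
class MixedModelResult:
    """Fixed effects, F tests and estimated means from one mixed-model fit."""

    outcome: str
    fixed_effects: list  # (term, estimate, se)
    f_tests: list  # (term, F, df_num, df_den, p)
    estimated_means: list  # (level, mean, ci_lo, ci_hi, se)
    fit_method: str
    df_method: str
    n_participants: int
    n_week_observations: int

    def mean_for(self, level) -> float:
        for lev, mean, *_ in self.estimated_means:
            if lev == level:
                return mean
        raise KeyError(level)

    def se_for(self, level) -> float:
        for lev, _, _, _, se in self.estimated_means:
            if lev == level:
                return se
        raise KeyError(level)


@dataclass
class ContingencyResult:
    """Pearson chi-square comparison of two groups over one categorical."""

    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame


def _valid_weeks(weeks: pd.DataFrame, outcome: str) -> pd.DataFrame:
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    data = weeks[weeks["is_valid_week"]].dropna(subset=[outcome]).copy()
    data["participant_id"] = data["participant_id"].astype(str)
    return data


def _active_covariates(data: pd.DataFrame) -> list:
    # constant wear-day covariates are collinear with the intercept; drop them
    return [c for c in _COVARIATES if data[c].nunique() > 1]


def _containment_ddf(n_obs: int, n_groups: int, k_fixed: int) -> float:
    ddf = n_obs - n_groups - k_fixed + 1
    if ddf <= 0:
        raise InsufficientDataError(
            "not enough week observations to estimate denominator df"
        )
    return float(ddf)


def _fit_reml(formula: str, data: pd.DataFrame):
    model = smf.mixedlm(formula, data=data, groups=data["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:  # singular design
            raise ConvergenceError(f"mixed model fit failed: {exc}") from exc
    if np.any(~np.isfinite(res.fe_params)):
        raise ConvergenceError("mixed model fit produced non-finite fixed effects")
    return res


def _fe_cov(res) -> tuple[pd.Series, pd.DataFrame]:
    fe = res.fe_params
    cov = res.cov_params().loc[fe.index, fe.index]
    return fe, cov


def _lincomb(L: np.ndarray, fe: pd.Series, cov: pd.DataFrame):
    est = float(L @ fe.to_numpy())
    se = float(np.sqrt(L @ cov.to_numpy() @ L))
    return est, se


def _design_row(names, cov_means: pd.Series, dummies: dict) -> np.ndarray:
    """Design-matrix row for an estimated mean: intercept 1, covariates at
    their sample means, categorical dummies as given, everything else 0."""
    row = []
    for name in names:
        if name == "Intercept":
            row.append(1.0)
        elif name in cov_means.index:
            row.append(float(cov_means[name]))
        else:
            row.append(float(dummies.get(name, 0.0)))
    return np.array(row)


def _wald_f(L: np.ndarray, fe: pd.Series, cov: pd.DataFrame, ddf: float):
    """Wald F for the q-row contrast matrix L (q x k)."""
    L = np.atleast_2d(L)
    q = L.shape[0]
    diff = L @ fe.to_numpy()
    middle = L @ cov.to_numpy() @ L.T
    stat = float(diff @ np.linalg.solve(middle, diff))
    f = stat / q
    p = float(scipy.stats.f.sf(f, q, ddf))
    return f, q, p


def _degenerate_result(outcome, data, levels, value) -> MixedModelResult:
    # zero-variance outcome: REML is undefined, but the answer is exact
    means = [(lev, float(value), float(value), float(value), 0.0) for lev in levels]
    term = "period" if set(levels) == {PRE, POST} else "study_week"
    return MixedModelResult(
        outcome=outcome,
        fixed_effects=[("Intercept", float(value), 0.0)],
        f_tests=[(term, 0.0, max(len(levels) - 1, 1), float(len(data)), 1.0)],
        estimated_means=means,
        fit_method="REML",
        df_method="degenerate (zero outcome variance)",
        n_participants=data["participant_id"].nunique(),
        n_week_observations=len(data),
    )


def fit_period_model(weeks: pd.DataFrame, outcome: str) -> MixedModelResult:
    """Fit the pre/post mixed model for one outcome on valid weeks.

    Fixed effects: period (reference = pre) plus valid weekday / weekend day
    counts; random intercept per participant; REML. Returns the period F test
    and pre/post estimated means with 95% CIs.
    """
    data = _valid_weeks(weeks, outcome)
    both = data.groupby("participant_id")["period"].nunique()
    if (both == 2).sum() < 2:
        raise InsufficientDataError(
            "period model needs >=2 participants with valid weeks in both periods"
        )
    if np.ptp(data[outcome].to_numpy()) == 0:
        return _degenerate_result(outcome, data, [PRE, POST], data[outcome].iloc[0])

    covariates = _active_covariates(data)
    formula = f"{outcome} ~ C(period, Treatment(reference='{PRE}'))"
    if covariates:
        formula += " + " + " + ".join(covariates)
    res = _fit_reml(formula, data)
    fe, cov = _fe_cov(res)
    n_obs = len(data)
    n_groups = data["participant_id"].nunique()
    ddf = _containment_ddf(n_obs, n_groups, len(fe))

    period_term = [name for name in fe.index if name.startswith("C(period")]
    L_period = np.array([[1.0 if name in period_term else 0.0 for name in fe.index]])
    f, q, p = _wald_f(L_period, fe, cov, ddf)

    cov_means = data[covariates].mean() if covariates else pd.Series(dtype=float)
    tcrit = scipy.stats.t.ppf(0.975, ddf)
    means = []
    for level in (PRE, POST):
        dummies = {t: (1.0 if level == POST else 0.0) for t in period_term}
        L = _design_row(fe.index, cov_means, dummies)
        est, se = _lincomb(L, fe, cov)
        means.append((level, est, float(est - tcrit * se), float(est + tcrit * se), se))

    return MixedModelResult(
        outcome=outcome,
        fixed_effects=[(n, float(fe[n]), float(res.bse_fe[n])) for n in fe.index],
        f_tests=[("period", f, q, ddf, p)],
        estimated_means=means,
        fit_method="REML",
        df_method="containment",
        n_participants=n_groups,
        n_week_observations=n_obs,
    )


def fit_weekly_model(weeks: pd.DataFrame, outcome: str) -> MixedModelResult:
    """Fit the categorical study-week mixed model for one outcome.

    Same structure as :func:`fit_period_model` with period replaced by study
    week (reference = the earliest week present); returns per-week estimated
    means with 95% CIs for trajectory plots.
    """
    data = _valid_weeks(weeks, outcome)
    levels = sorted(data["study_week"].unique())
    if len(levels) < 2:
        raise InsufficientDataError("weekly model needs >=2 study weeks represented")
    if data["participant_id"].nunique() < 2:
        raise InsufficientDataError("weekly model needs >=2 participants")
    if np.ptp(data[outcome].to_numpy()) == 0:
        return _degenerate_result(outcome, data, levels, data[outcome].iloc[0])

    ref = levels[0]
    covariates = _active_covariates(data)
    formula = f"{outcome} ~ C(study_week, Treatment(reference={ref}))"
    if covariates:
        formula += " + " + " + ".join(covariates)
    res = _fit_reml(formula, data)
    fe, cov = _fe_cov(res)
    n_obs = len(data)
    n_groups = data["participant_id"].nunique()
    ddf = _containment_ddf(n_obs, n_groups, len(fe))

    week_terms = {
        w: f"C(study_week, Treatment(reference={ref}))[T.{w}]"
        for w in levels
        if w != ref
    }
    L_week = np.array(
        [
            [1.0 if name == term else 0.0 for name in fe.index]
            for term in week_terms.values()
        ]
    )
    f, q, p = _wald_f(L_week, fe, cov, ddf)

    cov_means = data[covariates].mean() if covariates else pd.Series(dtype=float)
    tcrit = scipy.stats.t.ppf(0.975, ddf)
    means = []
    for w in levels:
        dummies = {term: (1.0 if term == week_terms.get(w) else 0.0)
                   for term in week_terms.values()}
        L = _design_row(fe.index, cov_means, dummies)
        est, se = _lincomb(L, fe, cov)
        means.append((int(w), est, float(est - tcrit * se), float(est + tcrit * se), se))

    return MixedModelResult(
        outcome=outcome,
        fixed_effects=[(n, float(fe[n]), float(res.bse_fe[n])) for n in fe.index],
        f_tests=[("study_week", f, q, ddf, p)],
        estimated_means=means,
        fit_method="REML",
        df_method="containment",
        n_participants=n_groups,
        n_week_observations=n_obs,
    )


def percent_change(pre_mean: float, post_mean: float) -> float:
    """Signed percent change 100 x (post - pre)/pre, one decimal.

    Rounded half away from zero, the display convention of the pre/post
    summary table. ``pre_mean`` must be positive.
    """
    if pre_mean <= 0:
        raise ValueError("pre_mean must be > 0")
    if post_mean < 0:
        raise ValueError("post_mean must be >= 0")
    raw = 100.0 * (float(post_mean) - float(pre_mean)) / float(pre_mean)
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def proportion_percent(k: int, n: int) -> int:
    """Integer percent 100*k/n, rounded half away from zero (report style)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    return int(
        Decimal(repr(100.0 * float(k) / float(n))).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


def compare_demographics(
    included: pd.DataFrame, excluded: pd.DataFrame, variable: str
) -> ContingencyResult:
    """Pearson chi-square of inclusion status x ``variable`` category.

    Categories with zero total count across both groups are dropped before
    the test (df reflects the reduced table). No continuity correction.
    """
    counts_inc = included[variable].value_counts()
    counts_exc = excluded[variable].value_counts()
    categories = sorted(set(counts_inc.index) | set(counts_exc.index))
    table = pd.DataFrame(
        {
            "included": [int(counts_inc.get(c, 0)) for c in categories],
            "excluded": [int(counts_exc.get(c, 0)) for c in categories],
        },
        index=pd.Index(categories, name=variable),
    ).T
    table = table.loc[:, table.sum(axis=0) > 0]
    table = table.loc[table.sum(axis=1) > 0, :]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InsufficientDataError(
            "chi-square needs >=2 non-empty categories in both dimensions"
        )
    stat, p, df, _ = scipy.stats.chi2_contingency(table.to_numpy(), correction=False)
    return ContingencyResult(
        statistic=float(stat), df=int(df), p_value=float(p), table=table
    )


def summarize_results(
    period_models: dict,
    weekly_models: dict,
    design: StudyDesign,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the pre/post results table and per-week estimated-mean series.

    ``period_models`` and ``weekly_models`` map outcome name ->
    :class:`MixedModelResult`. When ``out_dir`` is given, writes
    ``results_table.csv``, ``weekly_means.csv`` and one trajectory figure per
    outcome (``fig_steps.png``, ``fig_mvpa.png``). Reported SEs are
    model-based.
    """
    rows = []
    for outcome, model in period_models.items():
        pre_mean = model.mean_for(PRE)
        post_mean = model.mean_for(POST)
        term, f, q, ddf, p = model.f_tests[0]
        rows.append(
            {
                "outcome": outcome,
                "pre_mean": pre_mean,
                "pre_se": model.se_for(PRE),
                "post_mean": post_mean,
                "post_se": model.se_for(POST),
                "pct_change": percent_change(pre_mean, post_mean),
                "F": f,
                "df_num": q,
                "df_den": ddf,
                "p": p,
            }
        )
    results_table = pd.DataFrame(rows)

    weekly_rows = []
    for outcome, model in weekly_models.items():
        for week, mean, lo, hi, _se in model.estimated_means:
            weekly_rows.append(
                {
                    "outcome": outcome,
                    "study_week": week,
                    "mean": mean,
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
    weekly_means = pd.DataFrame(
        weekly_rows, columns=["outcome", "study_week", "mean", "ci_lo", "ci_hi"]
    )

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        results_table.to_csv(os.path.join(out_dir, "results_table.csv"), index=False)
        weekly_means.to_csv(os.path.join(out_dir, "weekly_means.csv"), index=False)
        _plot_weekly(weekly_means, design, out_dir)
    return results_table, weekly_means


_FIG_NAMES = {"steps_per_day": "fig_steps.png", "mvpa_min_per_week": "fig_mvpa.png"}
_FIG_LABELS = {
    "steps_per_day": "Steps per day",
    "mvpa_min_per_week": "MVPA minutes per week",
}


def _plot_weekly(weekly_means: pd.DataFrame, design: StudyDesign, out_dir) -> None:
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for outcome, g in weekly_means.groupby("outcome"):
        fig, ax = plt.subplots(figsize=(6, 4))
        err = np.vstack([g["mean"] - g["ci_lo"], g["ci_hi"] - g["mean"]])
        ax.errorbar(g["study_week"], g["mean"], yerr=err, fmt="o-", capsize=3)
        ax.axvline(design.closure_week - 0.5, linestyle="--", color="grey")
        ax.set_xlabel("Study week")
        ax.set_ylabel(_FIG_LABELS.get(outcome, outcome))
        ax.set_title(f"Estimated weekly means (95% CI): {_FIG_LABELS.get(outcome, outcome)}")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, _FIG_NAMES.get(outcome, f"fig_{outcome}.png")))
        plt.close(fig)
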