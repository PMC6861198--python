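"""Trial-wise value regressors for the scanner task and group statistics.

For each (non-excluded) participant, every scanner trial is assigned the
subjective value of the wheel they chose — their fitted attitudes plugged
into the expected-utility model — and, as a model-agnostic variant, the
objective expected value (probability x amount, attitudes replaced by
alpha=1, beta=0; the occluded wheel uses the .5 reference probability).
Values are demeaned per participant within condition, since risk and
ambiguity enter the downstream GLM as separate parametric regressors, and
written in a BIDS-events dialect (onset, duration, trial_type,
response_time, modulation).

The group layer reproduces the study's behavioral statistics on any
cohort: gamble proportions per condition, attitude-behaviour (partial)
correlations, polynomial age regressions, reaction-time contrasts and
exit-rating summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

from .estimation import FitResult
from .model import AttitudeParams, recode_ambiguity, subjective_value_of_choice

__all__ = [
    "REGRESSOR_COLUMNS",
    "GroupReport",
    "build_modulators",
    "write_events_tsv",
    "partial_correlation",
    "group_behavior_report",
]

#: Column order of the events table.
REGRESSOR_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "choice",
    "response_time",
    "sv_raw",
    "sv_demeaned",
    "ev_raw",
    "ev_demeaned",
]


def _demean_within(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Subtract the group mean (NaNs ignored and preserved)."""
    out = np.full_like(values, np.nan, dtype=float)
    for g in pd.unique(groups):
        mask = (groups == g) & ~np.isnan(values)
        if mask.any():
            out[mask] = values[mask] - values[mask].mean()
    return out


def build_modulators(fit: FitResult, fmri_trials: pd.DataFrame, fmri_choices: pd.DataFrame) -> pd.DataFrame:
    """Events table with demeaned subjective- and expected-value modulators.

    The decision event lasts 1 s plus the response time; trials without a
    response get trial_type ``"missing"`` and carry no modulator.  Demeaning
    is per condition, so each condition's modulator sums to (numerically)
    zero.  Excluded participants are refused.
    """
    if fit.excluded:
        raise ValueError(f"participant excluded ({fit.exclusion_reason}); no regressors built")
    merged = fmri_trials.merge(fmri_choices, on="trial_id", how="left", validate="1:1")
    choice = merged["choice"].fillna("missing").to_numpy(object)
    rt_s = merged["rt_ms"].to_numpy(float) / 1000.0

    sv = subjective_value_of_choice(merged, choice, fit.params)
    ev = subjective_value_of_choice(merged, choice, AttitudeParams(1.0, 0.0, fit.params.mu))

    condition = np.where(choice == "missing", "missing", merged["condition"].to_numpy(object))
    out = pd.DataFrame(
        {
            "onset": merged["onset_s"].to_numpy(float),
            "duration": 1.0 + rt_s,
            "trial_type": condition,
            "choice": choice,
            "response_time": rt_s,
            "sv_raw": sv,
            "ev_raw": ev,
        }
    )
    mod_groups = out["trial_type"].to_numpy(object)
    out["sv_demeaned"] = _demean_within(np.where(condition == "missing", np.nan, sv), mod_groups)
    out["ev_demeaned"] = _demean_within(np.where(condition == "missing", np.nan, ev), mod_groups)
    return out[REGRESSOR_COLUMNS]


def write_events_tsv(modulators: pd.DataFrame, path, column: str = "sv_demeaned") -> None:
    """Write a BIDS-style events file with one modulation column."""
    events = modulators[["onset", "duration", "trial_type", "response_time", column]].copy()
    events = events.rename(columns={column: "modulation"})
    events["onset"] = events["onset"].round(3)
    events["duration"] = events["duration"].round(3)
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def partial_correlation(x, y, controls):
    """Pearson correlation of ``x`` and ``y`` after removing ``controls``.

    ``controls`` is an (n,) or (n, k) array of covariates regressed out of
    both variables (equivalently: correlation of OLS residuals).  Returns
    ``(r, p)``.  Collinear controls are rejected.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.atleast_2d(np.asarray(controls, float))
    if c.shape[0] != len(x):
        c = c.T
    n, k = c.shape
    if len(x) != len(y) or n != len(x):
        raise ValueError("x, y and controls must have equal length")
    if n <= k + 2:
        raise ValueError("need n > n_controls + 2 observations")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("controls are collinear")
    # a variable fully explained by the controls has a zero-variance
    # residual: its partial correlation with anything is zero
    for v in (x, y):
        resid = v - design @ np.linalg.lstsq(design, v, rcond=None)[0]
        if resid.std() <= 1e-12 * max(v.std(), 1.0):
            return 0.0, 1.0
    df = pd.DataFrame({"x": x, "y": y, **{f"c{i}": c[:, i] for i in range(k)}})
    res = pg.partial_corr(data=df, x="x", y="y", covar=[f"c{i}" for i in range(k)])
    pcol = "p_val" if "p_val" in res.columns else "p-val"
    return float(res["r"].iloc[0]), float(res[pcol].iloc[0])


@dataclass
class GroupReport:
    """Per-participant measures plus the group-level statistics."""

    per_participant: pd.DataFrame
    statistics: dict
    n_included: int
    flags: list


def _gamble_props(trials: pd.DataFrame, choices: pd.DataFrame) -> dict:
    m = trials.merge(choices, on="trial_id", validate="1:1")
    m = m[m["choice"] != "missing"]
    out = {}
    for cond in ("risk", "ambiguity"):
        sub = m[m["condition"] == cond]
        out[f"prop_gamble_{cond}"] = float((sub["choice"] == "gamble").mean()) if len(sub) else np.nan
        out[f"rt_mean_{cond}"] = float(sub["rt_ms"].mean()) if len(sub) else np.nan
    fifty = m[(m["condition"] == "risk") & (m["win_probability"] == 0.5)]
    out["prop_gamble_risk50"] = float((fifty["choice"] == "gamble").mean()) if len(fifty) else np.nan
    return out


def _corr_block(stats_dict, flags, name, attitude, behaviour, age, extra_controls=None):
    # near-machine-precision spread counts as zero variance (identical
    # agents produce bitwise-near-identical fits)
    if np.std(attitude) < 1e-10 or np.std(behaviour) < 1e-10:
        stats_dict[name] = {"r": np.nan, "p": np.nan}
        flags.append(f"{name}: undefined (zero variance)")
        return
    r, p = stats.pearsonr(attitude, behaviour)
    entry = {"r": float(r), "p": float(p)}
    pr, pp = partial_correlation(attitude, behaviour, age)
    entry["partial_r_age"] = pr
    entry["partial_p_age"] = pp
    if extra_controls is not None:
        pr, pp = partial_correlation(attitude, behaviour, extra_controls)
        entry["partial_r_risk50"] = pr
        entry["partial_p_risk50"] = pp
        pr, pp = partial_correlation(attitude, behaviour, np.column_stack([extra_controls, age]))
        entry["partial_r_risk50_age"] = pr
        entry["partial_p_risk50_age"] = pp
    stats_dict[name] = entry


def _age_polynomials(stats_dict, name, attitude, age):
    res = {}
    for degree in (1, 2, 3):
        X = sm.add_constant(np.column_stack([age**d for d in range(1, degree + 1)]))
        fit = sm.OLS(attitude, X).fit()
        res[f"degree{degree}"] = {
            "coefs": [float(c) for c in fit.params],
            "r2": float(fit.rsquared),
            "f_p": float(fit.f_pvalue),
            "top_term_p": float(fit.pvalues[-1]),
        }
    res["linear_slope"] = res["degree1"]["coefs"][1]
    res["linear_slope_se"] = float(
        sm.OLS(attitude, sm.add_constant(age)).fit().bse[1]
    )
    stats_dict[name] = res


def group_behavior_report(cohort, fits, min_included: int = 10) -> GroupReport:
    """Group-level behavioral statistics for a (synthetic) cohort.

    ``fits`` must align with ``cohort.participants``; excluded fits are
    dropped before any statistic.  Computes, per included participant,
    scanner gamble proportions (risk, ambiguity, 50:50-risk subset), mean
    RTs per condition, fitted attitudes (ambiguity recoded so higher =
    more seeking) and exit-rating means; then the group tests: paired
    comparison of z-scored attitudes, polynomial age regressions,
    attitude-behaviour (partial) correlations and the RT contrast.
    """
    if len(fits) != len(cohort.participants):
        raise ValueError("fits must align with cohort.participants")
    rows = []
    for part, fit in zip(cohort.participants, fits):
        if fit.excluded:
            continue
        row = {
            "participant_id": part.participant_id,
            "age_years": part.age_years,
            "alpha": fit.params.alpha,
            "beta_recoded": recode_ambiguity(fit.params.beta),
        }
        row.update(_gamble_props(cohort.fmri_design, part.fmri_choices))
        er = part.exit_ratings
        row["rating_mean_risk"] = float(er.loc[er["condition"] == "risk", "rating"].mean())
        row["rating_mean_ambiguity"] = float(er.loc[er["condition"] == "ambiguity", "rating"].mean())
        rows.append(row)
    per = pd.DataFrame(rows)
    if len(per) < min_included:
        raise ValueError(f"need at least {min_included} included participants, got {len(per)}")

    flags: list = []
    statistics: dict = {}
    age = per["age_years"].to_numpy()
    alpha = per["alpha"].to_numpy()
    beta_rec = per["beta_recoded"].to_numpy()

    statistics["attitude_means"] = {
        "alpha_mean": float(alpha.mean()),
        "alpha_sd": float(alpha.std(ddof=1)),
        "beta_recoded_mean": float(beta_rec.mean()),
        "beta_recoded_sd": float(beta_rec.std(ddof=1)),
    }
    if alpha.std() > 0 and beta_rec.std() > 0:
        t, p = stats.ttest_rel(stats.zscore(alpha), stats.zscore(beta_rec))
        statistics["paired_z_attitudes"] = {"t": float(t), "p": float(p)}
    else:
        statistics["paired_z_attitudes"] = {"t": np.nan, "p": np.nan}
        flags.append("paired_z_attitudes: undefined (zero variance)")

    _age_polynomials(statistics, "age_regression_alpha", alpha, age)
    _age_polynomials(statistics, "age_regression_beta", beta_rec, age)

    risk50 = per["prop_gamble_risk50"].to_numpy()
    _corr_block(statistics, flags, "alpha_vs_gamble_risk", alpha, per["prop_gamble_risk"].to_numpy(), age)
    _corr_block(statistics, flags, "alpha_vs_gamble_ambiguity", alpha, per["prop_gamble_ambiguity"].to_numpy(), age, risk50)
    _corr_block(statistics, flags, "beta_vs_gamble_ambiguity", beta_rec, per["prop_gamble_ambiguity"].to_numpy(), age, risk50)
    _corr_block(statistics, flags, "beta_vs_gamble_risk", beta_rec, per["prop_gamble_risk"].to_numpy(), age)

    t, p = stats.ttest_rel(per["rt_mean_ambiguity"], per["rt_mean_risk"])
    statistics["rt_contrast"] = {
        "rt_mean_risk": float(per["rt_mean_risk"].mean()),
        "rt_mean_ambiguity": float(per["rt_mean_ambiguity"].mean()),
        "t": float(t),
        "p": float(p),
    }
    statistics["gamble_proportions"] = {
        "risk_mean": float(per["prop_gamble_risk"].mean()),
        "ambiguity_mean": float(per["prop_gamble_ambiguity"].mean()),
    }

    statistics["exit_ratings"] = {
        "risk_mean": float(per["rating_mean_risk"].mean()),
        "ambiguity_mean": float(per["rating_mean_ambiguity"].mean()),
    }
    _corr_block(statistics, flags, "alpha_vs_rating_risk", alpha, per["rating_mean_risk"].to_numpy(), age)
    _corr_block(statistics, flags, "alpha_vs_rating_ambiguity", alpha, per["rating_mean_ambiguity"].to_numpy(), age)
    _corr_block(statistics, flags, "beta_vs_rating_ambiguity", beta_rec, per["rating_mean_ambiguity"].to_numpy(), age)
    _corr_block(statistics, flags, "beta_vs_rating_risk", beta_rec, per["rating_mean_risk"].to_numpy(), age)

    return GroupReport(per_participant=per, statistics=statistics, n_included=len(per), flags=flags)
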