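"""Maximum-likelihood estimation of risk and ambiguity attitudes.

Per participant, the three decision parameters (alpha, beta, mu) are fit
by minimising the negative log-likelihood of the observed gamble/safe
choices under the logistic choice rule, using Nelder-Mead simplex searches
restarted from a grid of starting values to escape local minima.  Bound
constraints are enforced by smooth reparameterisations so the simplex runs
unconstrained:

* alpha = 2.5 * expit(t0)       -> (0, 2.5)
* beta  = tanh(t1)              -> (-1, 1)
* mu    = exp(t2), clamped to [1e-4, 10]

The central object is :class:`AttitudeEstimator`, a scikit-learn style
estimator (``fit`` / ``predict_proba`` / ``get_params``); the functional
surface (``negative_log_likelihood``, ``fit_attitudes``,
``detect_dominance_violations``, ``apply_exclusions``) wraps it.

Data-quality rules mirror the study protocol: participants who gamble on
at least half of the stochastic-dominance probe trials (gamble amount ==
safe amount, so the sure wheel dominates) are excluded, as are risk
attitudes more than 3.5 sample SDs above the sample mean, and degenerate
(all-gamble / all-safe) responders.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .model import (
    ALPHA_BOUNDS,
    BETA_BOUNDS,
    MU_BOUNDS,
    AttitudeParams,
    choice_probability,
    expected_utility,
)

__all__ = [
    "AttitudeEstimator",
    "FitResult",
    "DEFAULT_START_GRID",
    "negative_log_likelihood",
    "fit_attitudes",
    "detect_dominance_violations",
    "apply_exclusions",
]

#: Default restart grid: spans the attitude ranges seen in adolescent
#: samples (alpha roughly 0.1-1.5, beta the full [-1, 1]) and three orders
#: of choice noise.
DEFAULT_START_GRID = tuple(
    AttitudeParams(a, b, m)
    for a, b, m in itertools.product((0.2, 0.6, 1.0, 1.4), (-0.6, 0.0, 0.6), (0.05, 0.5, 2.0))
)

_LOG_FLOOR = 1e-12
_NLL_CAP = -math.log(_LOG_FLOOR)  # per-trial cap implied by the log floor


@dataclass
class FitResult:
    """Outcome of one participant's attitude fit.

    ``params`` holds the maximum-likelihood attitudes; ``nll`` the negative
    log-likelihood at the optimum; ``dominance_violation_rate`` the gamble
    rate on dominance-probe trials (NaN if the design has no probes).
    ``excluded``/``exclusion_reason`` implement the data-quality rules
    ("none", "dominance", "outlier" or "degenerate").
    """

    params: AttitudeParams
    nll: float
    converged: bool
    n_trials_used: int
    best_start: AttitudeParams
    dominance_violation_rate: float
    excluded: bool = False
    exclusion_reason: str = "none"


def _to_theta(params: AttitudeParams) -> np.ndarray:
    a = min(max(params.alpha / ALPHA_BOUNDS[1], 1e-9), 1 - 1e-9)
    b = min(max((params.beta + 1.0) / 2.0, 1e-9), 1 - 1e-9)
    return np.array([math.log(a / (1 - a)), math.atanh(2 * b - 1), math.log(params.mu)])


def _from_theta(theta) -> AttitudeParams:
    t0 = min(max(float(theta[0]), -40.0), 40.0)
    t1 = min(max(float(theta[1]), -40.0), 40.0)
    t2 = min(max(float(theta[2]), -40.0), 40.0)
    alpha = ALPHA_BOUNDS[1] / (1.0 + math.exp(-t0))
    beta = math.tanh(t1)
    mu = min(max(math.exp(t2), MU_BOUNDS[0]), MU_BOUNDS[1])
    # keep strictly inside open bounds for AttitudeParams validity
    alpha = min(max(alpha, 1e-12), ALPHA_BOUNDS[1])
    beta = min(max(beta, BETA_BOUNDS[0]), BETA_BOUNDS[1])
    return AttitudeParams(alpha, beta, mu)


def _extract_arrays(trials: pd.DataFrame):
    p = trials["win_probability"].to_numpy(float)
    halfA = 0.5 * trials["ambiguity_level"].to_numpy(float)
    logx = np.log(trials["gamble_amount"].to_numpy(float))
    logsafe = np.log(trials["safe_amount"].to_numpy(float))
    return p, halfA, logx, logsafe


def _choices_to_binary(choices) -> np.ndarray:
    arr = np.asarray(choices)
    if arr.dtype.kind in "ifb":
        return arr.astype(float)
    return (arr.astype(object) == "gamble").astype(float)


def _make_objective(p, halfA, logx, logsafe, y):
    """Closure computing the NLL from the transformed parameter vector.

    Uses log(expit(z)) = -logaddexp(0, -z) for stability; each trial's
    contribution is capped at -log(1e-12), the floor applied to choice
    probabilities so deterministic responders stay finite.
    """
    sign = 2.0 * y - 1.0
    mu_lo, mu_hi = MU_BOUNDS

    def nll_theta(theta):
        # clip the unconstrained coordinates so exp() cannot overflow when
        # the simplex wanders far out; the mapped parameters saturate there
        t0 = min(max(float(theta[0]), -40.0), 40.0)
        t1 = min(max(float(theta[1]), -40.0), 40.0)
        t2 = min(max(float(theta[2]), -40.0), 40.0)
        alpha = ALPHA_BOUNDS[1] / (1.0 + math.exp(-t0))
        beta = math.tanh(t1)
        mu = min(max(math.exp(t2), mu_lo), mu_hi)
        q = np.clip(p - beta * halfA, 0.0, 1.0)
        diff = q * np.exp(alpha * logx) - np.exp(alpha * logsafe)
        z = sign * diff / mu
        return float(np.minimum(np.logaddexp(0.0, -z), _NLL_CAP).sum())

    return nll_theta


def negative_log_likelihood(params: AttitudeParams, trials: pd.DataFrame, choices) -> float:
    """Negative log-likelihood of gamble/safe choices under the model.

    Trials whose choice is ``"missing"`` are dropped; an empty usable set
    is rejected.  Log arguments are floored at 1e-12.
    """
    arr = np.asarray(choices, dtype=object)
    usable = arr != "missing"
    if not usable.any():
        raise ValueError("no usable (non-missing) trials")
    trials = trials.loc[np.asarray(usable)]
    y = _choices_to_binary(arr[usable])
    obj = _make_objective(*_extract_arrays(trials), y)
    return obj(_to_theta(params))


class AttitudeEstimator(BaseEstimator):
    """Scikit-learn style estimator of risk/ambiguity attitudes.

    Parameters
    ----------
    start_grid : sequence of AttitudeParams, optional
        Restart points for the simplex search (default
        :data:`DEFAULT_START_GRID`).
    tol : float
        Convergence tolerance on the negative log-likelihood.
    max_iter : int
        Iteration cap per restart.

    Attributes
    ----------
    alpha_, beta_, mu_ : float
        Maximum-likelihood attitudes.
    params_ : AttitudeParams
    nll_ : float
        Negative log-likelihood at the optimum.
    converged_ : bool
        Whether the winning restart converged.
    n_trials_used_ : int
    best_start_ : AttitudeParams
        Restart whose search produced the optimum.
    start_nlls_ : numpy.ndarray
        Objective evaluated at each grid start (the returned ``nll_`` never
        exceeds any of these).

    Examples
    --------
    >>> est = AttitudeEstimator().fit(trials, choices)   # doctest: +SKIP
    >>> est.alpha_, est.beta_, est.mu_                   # doctest: +SKIP
    """

    def __init__(self, start_grid=None, tol: float = 1e-6, max_iter: int = 2000):
        self.start_grid = start_grid
        self.tol = tol
        self.max_iter = max_iter

    def _validate(self, X: pd.DataFrame, y):
        required = {"win_probability", "ambiguity_level", "gamble_amount", "safe_amount"}
        if not required.issubset(X.columns):
            raise ValueError(f"trial table must contain columns {sorted(required)}")
        y = _choices_to_binary(y)
        if len(y) != len(X):
            raise ValueError("trials and choices must align")
        if len(y) == 0:
            raise ValueError("no usable trials")
        return y

    def fit(self, X: pd.DataFrame, y):
        """Fit attitudes to one participant's choices.

        ``X`` is a trial table (rows aligned with ``y``); ``y`` holds the
        choices as ``"gamble"``/``"safe"`` strings or a 0/1 array.  Missing
        trials must already be dropped.
        """
        y = self._validate(X, y)
        obj = _make_objective(*_extract_arrays(X), y)
        grid = tuple(self.start_grid) if self.start_grid is not None else DEFAULT_START_GRID

        best = None
        start_nlls = np.empty(len(grid))
        for i, start in enumerate(grid):
            theta0 = _to_theta(start)
            start_nlls[i] = obj(theta0)
            res = minimize(
                obj,
                theta0,
                method="Nelder-Mead",
                options={
                    "fatol": self.tol,
                    "xatol": 1e-4,
                    "maxiter": self.max_iter,
                    "maxfev": self.max_iter,
                },
            )
            if best is None or res.fun < best[0].fun:
                best = (res, start)

        res, start = best
        params = _from_theta(res.x)
        self.params_ = params
        self.alpha_, self.beta_, self.mu_ = params.alpha, params.beta, params.mu
        self.nll_ = float(res.fun)
        self.converged_ = bool(res.success)
        self.n_trials_used_ = int(len(y))
        self.best_start_ = start
        self.start_nlls_ = start_nlls
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-trial probability of choosing the gamble, columns [safe, gamble]."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        eu_g = expected_utility(
            X["gamble_amount"].to_numpy(float),
            X["win_probability"].to_numpy(float),
            X["ambiguity_level"].to_numpy(float),
            self.alpha_,
            self.beta_,
        )
        eu_s = X["safe_amount"].to_numpy(float) ** self.alpha_
        pg = choice_probability(eu_g, eu_s, self.mu_)
        return np.column_stack([1.0 - pg, pg])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Most probable choice per trial (``"gamble"`` or ``"safe"``)."""
        pg = self.predict_proba(X)[:, 1]
        return np.where(pg >= 0.5, "gamble", "safe")

    def score(self, X: pd.DataFrame, y) -> float:
        """Mean log-likelihood per trial (higher is better)."""
        y = self._validate(X, y)
        obj = _make_objective(*_extract_arrays(X), y)
        return -obj(_to_theta(self.params_)) / len(y)


def detect_dominance_violations(trials: pd.DataFrame, choices) -> float:
    """Gamble rate on stochastic-dominance probe trials.

    Probes are trials whose gamble amount equals the safe amount: the sure
    wheel pays the gamble's winning amount with certainty, so gambling is a
    dominance violation.  Missing responses are not counted.  Raises if the
    design contains no probes.
    """
    arr = np.asarray(choices, dtype=object)
    probe = (
        trials["gamble_amount"].to_numpy(float) == trials["safe_amount"].to_numpy(float)
    ) & (arr != "missing")
    n_probe = int(probe.sum())
    if n_probe == 0:
        raise ValueError("design contains no dominance-probe trials")
    return float((arr[probe] == "gamble").sum() / n_probe)


def fit_attitudes(
    trials: pd.DataFrame,
    choices,
    start_grid=None,
    min_trials: int = 20,
) -> FitResult:
    """Fit one participant and attach data-quality diagnostics.

    Missing responses are dropped from the likelihood (not imputed).
    All-gamble / all-safe responders are fit but flagged ``degenerate``
    (their likelihood pushes alpha to a bound).  The dominance-violation
    rate is NaN when the design has no probe trials (e.g. the scanner
    task).
    """
    arr = np.asarray(choices, dtype=object)
    usable = arr != "missing"
    if int(usable.sum()) < min_trials:
        raise ValueError(f"need at least {min_trials} usable trials, got {int(usable.sum())}")
    trials_u = trials.loc[np.asarray(usable)]
    y = _choices_to_binary(arr[usable])

    try:
        dom = detect_dominance_violations(trials, choices)
    except ValueError:
        dom = float("nan")

    est = AttitudeEstimator(start_grid=start_grid).fit(trials_u, y)
    result = FitResult(
        params=est.params_,
        nll=est.nll_,
        converged=est.converged_,
        n_trials_used=est.n_trials_used_,
        best_start=est.best_start_,
        dominance_violation_rate=dom,
    )
    degenerate = bool(np.all(y == 1.0) or np.all(y == 0.0)) or not result.converged
    if degenerate:
        result.excluded = True
        result.exclusion_reason = "degenerate"
    return result


def apply_exclusions(
    fits,
    dominance_threshold: float = 0.5,
    outlier_sd: float = 3.5,
):
    """Apply the cohort-level exclusion rules; returns annotated copies.

    A fit is excluded if its dominance-violation rate reaches
    ``dominance_threshold``, or if its alpha lies more than ``outlier_sd``
    sample SDs above the sample mean.  The mean/SD are computed on fits not
    excluded for dominance (degenerate fits are also left out, as their
    alpha sits at a transform bound).  Zero SD excludes nobody.
    """
    fits = [dataclasses.replace(f) for f in fits]
    if len(fits) < 2:
        raise ValueError("need at least two fits")
    for f in fits:
        if not math.isnan(f.dominance_violation_rate) and f.dominance_violation_rate >= dominance_threshold:
            f.excluded = True
            f.exclusion_reason = "dominance"
    clean = [f for f in fits if f.exclusion_reason == "none"]
    alphas = np.array([f.params.alpha for f in clean])
    if len(alphas) >= 2:
        sd = float(alphas.std(ddof=1))
        if sd > 0.0:
            cut = float(alphas.mean()) + outlier_sd * sd
            for f in clean:
                if f.params.alpha > cut:
                    f.excluded = True
                    f.exclusion_reason = "outlier"
    return fits


def fits_to_frame(fits, participant_ids=None) -> pd.DataFrame:
    """Tabulate FitResults (one row per participant) for CSV export."""
    from .model import recode_ambiguity

    rows = []
    for i, f in enumerate(fits):
        pid = participant_ids[i] if participant_ids is not None else i
        rows.append(
            {
                "participant_id": pid,
                "alpha": f.params.alpha,
                "beta_native": f.params.beta,
                "beta_recoded": recode_ambiguity(f.params.beta),
                "mu": f.params.mu,
                "nll": f.nll,
                "converged": f.converged,
                "n_trials_used": f.n_trials_used,
                "dominance_violation_rate": f.dominance_violation_rate,
                "excluded": f.excluded,
                "exclusion_reason": f.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)
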