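"""Expected-utility model of choice under risk and ambiguity.

A gamble pays ``x`` euros with probability ``p`` (and nothing otherwise).
Under ambiguity, a fraction ``A`` of the probability wheel is occluded and
the reference probability under the occluder is .5.  The subjective value
of such a gamble is modelled with a power utility function plus an
ambiguity penalty on the probability weight:

    EU(x, p, A) = (p - beta * A / 2) * x ** alpha

``alpha`` is the risk attitude (1 = risk neutral, < 1 averse, > 1 seeking)
and ``beta`` the ambiguity attitude (0 = neutral, > 0 averse, < 0 seeking:
an averse decider behaves as if the hidden probability were below .5).
Choices between a gamble and a sure amount are stochastic, with a logistic
rule on the expected-utility difference:

    Pr(gamble) = 1 / (1 + exp(-(EU_gamble - EU_safe) / mu))

where ``mu`` is the choice-stochasticity (temperature) parameter: small
``mu`` approaches deterministic EU maximisation, large ``mu`` random choice.

All functions are vectorised over numpy arrays; the safe option is treated
as a degenerate gamble (p = 1, A = 0), so one expression covers both wheels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "AttitudeParams",
    "ALPHA_BOUNDS",
    "BETA_BOUNDS",
    "MU_BOUNDS",
    "perceived_probability",
    "expected_utility",
    "choice_probability",
    "subjective_value_of_choice",
    "recode_ambiguity",
]

#: Parameter bounds enforced throughout the package.  beta in [-1, 1] keeps
#: the perceived probability of a fully ambiguous wheel (p=.5, A=1) inside
#: [0, 1]; alpha and mu bounds bracket the attitudes seen in adolescent
#: samples with generous margin.
ALPHA_BOUNDS = (0.0, 2.5)
BETA_BOUNDS = (-1.0, 1.0)
MU_BOUNDS = (1e-4, 10.0)


@dataclass(frozen=True)
class AttitudeParams:
    """Individual decision parameters.

    Parameters
    ----------
    alpha : float
        Risk attitude (power-utility curvature), in (0, 2.5].
    beta : float
        Ambiguity attitude in [-1, 1]; positive = averse, negative =
        seeking.  This is the model's native sign convention; reports use
        :func:`recode_ambiguity` so that higher = more seeking.
    mu : float
        Choice stochasticity (logistic temperature), in [1e-4, 10].
    """

    alpha: float
    beta: float
    mu: float

    def __post_init__(self) -> None:
        if not ALPHA_BOUNDS[0] < self.alpha <= ALPHA_BOUNDS[1]:
            raise ValueError(f"alpha {self.alpha} outside ({ALPHA_BOUNDS[0]}, {ALPHA_BOUNDS[1]}]")
        if not BETA_BOUNDS[0] <= self.beta <= BETA_BOUNDS[1]:
            raise ValueError(f"beta {self.beta} outside {BETA_BOUNDS}")
        if not MU_BOUNDS[0] <= self.mu <= MU_BOUNDS[1]:
            raise ValueError(f"mu {self.mu} outside {MU_BOUNDS}")


def _check_unit_interval(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def perceived_probability(p, ambiguity, beta):
    """Probability weight (p - beta * A / 2), clamped to [0, 1].

    The raw expression can leave the unit interval at extreme ``beta``;
    values outside [0, 1] are meaningless as probabilities and destabilise
    likelihood fitting, so the weight is clamped.
    """
    p = _check_unit_interval("p", p)
    ambiguity = _check_unit_interval("ambiguity", ambiguity)
    return np.clip(p - beta * ambiguity / 2.0, 0.0, 1.0)


def expected_utility(x, p, ambiguity, alpha, beta):
    """EU(x, p, A) = (p - beta * A / 2) * x ** alpha.

    ``x`` must be strictly positive (the task offers gains only).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("amount x must be positive")
    return perceived_probability(p, ambiguity, beta) * x ** alpha


def choice_probability(eu_gamble, eu_safe, mu):
    """Logistic probability of choosing the gamble over the safe wheel.

    Computed overflow-safely (``scipy.special.expit``), so temperatures
    down to the 1e-4 bound are handled without warnings.
    """
    if not np.all(np.asarray(mu) > 0.0):
        raise ValueError("mu must be positive")
    diff = np.asarray(eu_gamble, dtype=float) - np.asarray(eu_safe, dtype=float)
    return expit(diff / mu)


def subjective_value_of_choice(trials, choices, params: AttitudeParams):
    """Subjective value of the wheel each participant actually chose.

    Parameters
    ----------
    trials : pandas.DataFrame
        Trial table with columns ``win_probability``, ``ambiguity_level``,
        ``gamble_amount``, ``safe_amount`` (one row per trial).
    choices : array-like of str
        Per-trial choice, ``"gamble"``, ``"safe"`` or ``"missing"``.
    params : AttitudeParams
        The participant's fitted attitudes.

    Returns
    -------
    numpy.ndarray
        EU of the chosen wheel per trial; NaN where the choice is missing
        (such trials carry no value and are excluded downstream).
    """
    choices = np.asarray(choices, dtype=object)
    eu_gamble = expected_utility(
        trials["gamble_amount"].to_numpy(float),
        trials["win_probability"].to_numpy(float),
        trials["ambiguity_level"].to_numpy(float),
        params.alpha,
        params.beta,
    )
    # the safe wheel is a degenerate gamble: p = 1, A = 0
    eu_safe = trials["safe_amount"].to_numpy(float) ** params.alpha
    sv = np.where(choices == "gamble", eu_gamble, eu_safe)
    sv = np.where(choices == "missing", np.nan, sv)
    return sv


def recode_ambiguity(beta):
    """Flip the ambiguity-attitude sign so that higher = more seeking.

    The model's native convention has beta > 0 for aversion; behavioral
    reports use the negated value for readability.  Involution:
    ``recode(recode(b)) == b``.
    """
    return -np.asarray(beta, dtype=float) if np.ndim(beta) else -float(beta)
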