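"""Synthetic adolescent cohort generator.

Creates agents whose choice behaviour follows the expected-utility model
with the logistic choice rule, with attitude distributions calibrated to
the published sample statistics of a large adolescent wheel-of-fortune
study (risk attitude mean .60, SD .26; native-convention ambiguity
attitude mean +.25, SD .36; a small positive linear age trend in risk
attitude, b = .015 per year), plus condition-dependent reaction times
(slower under ambiguity) and slider-scale exit ratings of perceived
riskiness (ambiguous wheels rated riskier than risky wheels on average).

Everything is driven by a single integer seed through a
``numpy.random.SeedSequence`` tree, so cohorts are exactly reproducible.
The generator emulates the *statistical structure* the downstream analysis
assumes, not individual real participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .design import build_behavioral_design, build_fmri_design
from .model import ALPHA_BOUNDS, BETA_BOUNDS, AttitudeParams, choice_probability, expected_utility

__all__ = [
    "CohortConfig",
    "ParticipantRecord",
    "Cohort",
    "sample_participants",
    "simulate_choices",
    "simulate_exit_ratings",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generating distributions of the synthetic cohort.

    Attitude means/SDs, reaction-time means (ms) and rating means are the
    published group statistics; mu (choice stochasticity) is log-normal
    with median ``mu_median`` — the published work reports no mu summary,
    and 0.1 yields choice consistency comparable to attentive participants.
    """

    n_participants: int = 188
    age_range: tuple = (12.0, 22.0)
    alpha_mean: float = 0.60
    alpha_sd: float = 0.26
    age_alpha_slope: float = 0.015     # risk attitude per year of age
    beta_mean: float = 0.25            # native convention (recoded report: -.25)
    beta_sd: float = 0.36
    mu_median: float = 0.1
    mu_logsd: float = 0.5
    rt_mean_risk_ms: float = 597.06
    rt_mean_ambiguity_ms: float = 641.59
    rt_logsd: float = 0.3
    rating_mean_risk: float = 52.52
    rating_mean_ambiguity: float = 62.75
    rating_noise_sd: float = 8.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("alpha_sd", "beta_sd", "mu_logsd", "rt_logsd", "rating_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")


@dataclass
class ParticipantRecord:
    """One synthetic participant: generating truth plus simulated data."""

    participant_id: int
    age_years: float
    true_params: AttitudeParams
    behavioral_choices: pd.DataFrame | None = None
    fmri_choices: pd.DataFrame | None = None
    exit_ratings: pd.DataFrame | None = None


@dataclass
class Cohort:
    """A fully simulated cohort sharing one behavioral and one fMRI design."""

    config: CohortConfig
    behavioral_design: pd.DataFrame
    fmri_design: pd.DataFrame
    participants: list = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        from .model import recode_ambiguity

        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "age_years": [p.age_years for p in self.participants],
                "alpha_true": [p.true_params.alpha for p in self.participants],
                "beta_true": [p.true_params.beta for p in self.participants],
                "beta_recoded_true": [recode_ambiguity(p.true_params.beta) for p in self.participants],
                "mu_true": [p.true_params.mu for p in self.participants],
            }
        )


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Truncated-normal draws; degenerate SD collapses to the (clipped) mean."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0.0:
        out = np.clip(mean, lo, hi)
        return np.broadcast_to(out, size if size is not None else mean.shape).copy()
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_participants(config: CohortConfig) -> list:
    """Draw ages and generating parameters for every participant.

    Ages are uniform over ``age_range``; alpha is normal around a mean
    that climbs with age (``age_alpha_slope`` per year around the range
    midpoint), truncated to (0, 2.5]; beta is normal truncated to [-1, 1];
    mu is log-normal.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_participants
    ages = rng.uniform(*config.age_range, size=n)
    mid = 0.5 * (config.age_range[0] + config.age_range[1])
    alpha_means = config.alpha_mean + config.age_alpha_slope * (ages - mid)
    alphas = _truncated_normal(rng, alpha_means, config.alpha_sd, 1e-6, ALPHA_BOUNDS[1], size=n)
    betas = _truncated_normal(
        rng, np.full(n, config.beta_mean), config.beta_sd, BETA_BOUNDS[0], BETA_BOUNDS[1], size=n
    )
    mus = config.mu_median * np.exp(rng.normal(0.0, config.mu_logsd, size=n)) if config.mu_logsd > 0 else np.full(n, config.mu_median)
    return [
        ParticipantRecord(
            participant_id=i + 1,
            age_years=float(ages[i]),
            true_params=AttitudeParams(float(alphas[i]), float(betas[i]), float(mus[i])),
        )
        for i in range(n)
    ]


def simulate_choices(
    participant: ParticipantRecord,
    trials: pd.DataFrame,
    seed,
    rt_mean_risk_ms: float = 597.06,
    rt_mean_ambiguity_ms: float = 641.59,
    rt_logsd: float = 0.3,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate one run: Bernoulli choices from the logistic rule plus RTs.

    RTs are log-normal with condition-specific means (ambiguity slower);
    they are decorative covariates, not a process model of response times.
    """
    rng = np.random.default_rng(seed)
    p = participant.true_params
    eu_g = expected_utility(
        trials["gamble_amount"].to_numpy(float),
        trials["win_probability"].to_numpy(float),
        trials["ambiguity_level"].to_numpy(float),
        p.alpha,
        p.beta,
    )
    eu_s = trials["safe_amount"].to_numpy(float) ** p.alpha
    pr = choice_probability(eu_g, eu_s, p.mu)
    gamble = rng.random(len(trials)) < pr

    means = np.where(
        trials["condition"].to_numpy(object) == "ambiguity", rt_mean_ambiguity_ms, rt_mean_risk_ms
    )
    # log-normal parameterised so the arithmetic mean equals the target
    rts = rng.lognormal(np.log(means) - rt_logsd**2 / 2.0, rt_logsd)

    choice = np.where(gamble, "gamble", "safe").astype(object)
    if missing_rate > 0.0:
        miss = rng.random(len(trials)) < missing_rate
        choice[miss] = "missing"
        rts = np.where(miss, np.nan, rts)
    return pd.DataFrame(
        {"trial_id": trials["trial_id"].to_numpy(), "choice": choice, "rt_ms": rts}
    )


# exit-rating calibration: base + gain * (1 - p) for risky wheels and
# base + gain * A for ambiguous wheels, shifted by how much the agent's
# attitudes deviate from the cohort means.  Bases are set so that with the
# default design levels the cohort means land near the published 52.52
# (risk) and 62.75 (ambiguity).
_RATING_RISK_GAIN = 40.0
_RATING_AMB_GAIN = 30.0
_RATING_ALPHA_WEIGHT = 15.0
_RATING_BETA_WEIGHT = 15.0

_RISK_WHEELS = (0.125, 0.25, 0.375, 0.50, 0.625, 0.75)
_AMB_WHEELS = (0.25, 0.50, 0.75, 1.0)


def simulate_exit_ratings(
    participant: ParticipantRecord,
    seed,
    config: CohortConfig = CohortConfig(),
) -> pd.DataFrame:
    """Slider ratings (0-100) of perceived riskiness per wheel.

    Ratings fall with win probability, rise with ambiguity level, and are
    shifted down for risk-seeking (high-alpha) agents and up for
    ambiguity-averse (high native-beta) agents, plus Gaussian noise,
    clipped to the slider range.
    """
    rng = np.random.default_rng(seed)
    a_dev = participant.true_params.alpha - config.alpha_mean
    b_dev = participant.true_params.beta - config.beta_mean

    base_risk = config.rating_mean_risk - _RATING_RISK_GAIN * float(np.mean([1 - p for p in _RISK_WHEELS]))
    base_amb = config.rating_mean_ambiguity - _RATING_AMB_GAIN * float(np.mean(_AMB_WHEELS))

    rows = []
    for p in _RISK_WHEELS:
        r = base_risk + _RATING_RISK_GAIN * (1.0 - p) - _RATING_ALPHA_WEIGHT * a_dev
        rows.append(("risk", p, r))
    for a in _AMB_WHEELS:
        r = (
            base_amb
            + _RATING_AMB_GAIN * a
            - _RATING_ALPHA_WEIGHT * a_dev
            + _RATING_BETA_WEIGHT * b_dev
        )
        rows.append(("ambiguity", a, r))
    df = pd.DataFrame(rows, columns=["condition", "level", "rating"])
    if config.rating_noise_sd > 0:
        df["rating"] += rng.normal(0.0, config.rating_noise_sd, size=len(df))
    df["rating"] = df["rating"].clip(0.0, 100.0)
    return df


def simulate_cohort(config: CohortConfig = CohortConfig(), include_fmri: bool = True) -> Cohort:
    """Generate a complete cohort: designs, choices and exit ratings.

    All participants share one behavioral and one scanner design (as in a
    fixed experimental protocol); choice and rating noise are independent
    per participant via spawned seed sequences.
    """
    root = np.random.SeedSequence(config.seed)
    behavioral = build_behavioral_design(config.seed)
    fmri = build_fmri_design(config.seed + 1)

    participants = sample_participants(config)
    child_seeds = root.spawn(3 * config.n_participants)
    for i, part in enumerate(participants):
        part.behavioral_choices = simulate_choices(
            part,
            behavioral,
            child_seeds[3 * i],
            config.rt_mean_risk_ms,
            config.rt_mean_ambiguity_ms,
            config.rt_logsd,
            config.missing_rate,
        )
        if include_fmri:
            part.fmri_choices = simulate_choices(
                part,
                fmri,
                child_seeds[3 * i + 1],
                config.rt_mean_risk_ms,
                config.rt_mean_ambiguity_ms,
                config.rt_logsd,
                config.missing_rate,
            )
        part.exit_ratings = simulate_exit_ratings(part, child_seeds[3 * i + 2], config)
    return Cohort(
        config=config,
        behavioral_design=behavioral,
        fmri_design=fmri,
        participants=participants,
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write designs, per-participant choices/ratings and the truth table."""
    from pathlib import Path

    from .design import write_design

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_design(cohort.behavioral_design, outdir / "design_behavioral.tsv")
    write_design(cohort.fmri_design, outdir / "design_fmri.tsv")
    cohort.truth_frame().to_csv(outdir / "truth.csv", index=False)

    beh = []
    fmri = []
    ratings = []
    for p in cohort.participants:
        b = p.behavioral_choices.assign(participant_id=p.participant_id)
        beh.append(b)
        if p.fmri_choices is not None:
            fmri.append(p.fmri_choices.assign(participant_id=p.participant_id))
        ratings.append(p.exit_ratings.assign(participant_id=p.participant_id))
    pd.concat(beh).to_csv(outdir / "choices_behavioral.tsv", sep="\t", index=False)
    if fmri:
        pd.concat(fmri).to_csv(outdir / "choices_fmri.tsv", sep="\t", index=False)
    pd.concat(ratings).to_csv(outdir / "exit_ratings.tsv", sep="\t", index=False)
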