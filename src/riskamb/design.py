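"""Wheel-of-fortune task designs.

Two designs are generated deterministically from an integer seed:

* the 80-trial behavioral task used for attitude estimation — 24 unique
  risk cells (6 probabilities x 4 amounts) and 16 unique ambiguity cells
  (4 ambiguity levels x 4 amounts), each presented twice, self-paced, no
  outcomes shown;
* the 92-trial scanner task — 46 fully ambiguous and 46 risky gambles
  (30 at p=.5, 8 at p=.75, 8 at p=.25) against a sure 3-euro wheel, with
  amounts 31-34 euros drawn in shuffled blocks of four, and an event
  timeline (pre-trial fixation, response window, jittered decision-outcome
  gap, outcome, jittered ITI).

A seed changes presentation order, side/lid assignment pairing and timing
jitter only; the set of gamble cells is fixed by the design.  Trial tables
are pandas DataFrames with one row per trial (columns below) and round-trip
through tab-separated text files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "BEHAVIORAL_PROBABILITIES",
    "BEHAVIORAL_AMOUNTS",
    "BEHAVIORAL_AMBIGUITY_LEVELS",
    "BEHAVIORAL_SAFE_AMOUNT",
    "FMRI_AMOUNTS",
    "FMRI_SAFE_AMOUNT",
    "build_behavioral_design",
    "build_fmri_design",
    "write_design",
    "read_design",
]

#: Column schema of a trial table (one GambleTrial per row).
TRIAL_COLUMNS = [
    "trial_id",
    "condition",        # "risk" | "ambiguity"
    "win_probability",  # p in [0, 1]; .5 reference under the occluder
    "ambiguity_level",  # A in [0, 1]; 0 for risk trials
    "gamble_amount",    # euros
    "safe_amount",      # euros, paid with certainty
    "task",             # "behavioral" | "fmri"
    "side_gamble",      # "left" | "right"
    "lid_position",     # "top" | "bottom" | "none"
    "onset_s",          # decision onset (fMRI; NaN behavioral)
    "iti_s",            # inter-trial interval (fMRI; NaN behavioral)
]

BEHAVIORAL_PROBABILITIES = (0.125, 0.25, 0.375, 0.50, 0.625, 0.75)
BEHAVIORAL_AMOUNTS = (5.0, 8.0, 20.0, 50.0)
BEHAVIORAL_AMBIGUITY_LEVELS = (0.25, 0.50, 0.75, 1.0)
#: Safe wheel of the behavioral task: the lowest gamble amount, so gambles
#: offering that same amount are stochastic-dominance probes.
BEHAVIORAL_SAFE_AMOUNT = 5.0

FMRI_AMOUNTS = (31.0, 32.0, 33.0, 34.0)
FMRI_SAFE_AMOUNT = 3.0

# fMRI event timing (seconds)
_FIXATION_S = 0.5
_RESPONSE_WINDOW_S = 3.0
_GAP_CHOICES_S = (2.0, 2.5, 3.0, 3.5, 4.0)  # decision-outcome jitter, .5 s steps
_OUTCOME_S = 1.25
_ITI_MAX_S = 9.35


def _sides(n: int, rng: np.random.Generator) -> np.ndarray:
    """Counterbalanced left/right assignment (difference at most one)."""
    sides = np.array(["left", "right"])[np.arange(n) % 2]
    return rng.permutation(sides)


def build_behavioral_design(seed: int) -> pd.DataFrame:
    """Build the 80-trial behavioral design, order shuffled by ``seed``."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in BEHAVIORAL_PROBABILITIES:
        for x in BEHAVIORAL_AMOUNTS:
            for copy in range(2):
                rows.append(("risk", p, 0.0, x, "none"))
    for a in BEHAVIORAL_AMBIGUITY_LEVELS:
        for x in BEHAVIORAL_AMOUNTS:
            # the two copies of each ambiguity cell carry the two lid positions
            for lid in ("top", "bottom"):
                rows.append(("ambiguity", 0.5, a, x, lid))
    df = pd.DataFrame(rows, columns=["condition", "win_probability", "ambiguity_level", "gamble_amount", "lid_position"])
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["side_gamble"] = _sides(len(df), rng)
    df["safe_amount"] = BEHAVIORAL_SAFE_AMOUNT
    df["task"] = "behavioral"
    df["onset_s"] = np.nan
    df["iti_s"] = np.nan
    df["trial_id"] = np.arange(1, len(df) + 1)
    return df[TRIAL_COLUMNS]


def build_fmri_design(seed: int) -> pd.DataFrame:
    """Build the 92-trial scanner design with onsets, shuffled by ``seed``."""
    rng = np.random.default_rng(seed)
    cond = ["risk"] * 46 + ["ambiguity"] * 46
    probs = [0.5] * 30 + [0.75] * 8 + [0.25] * 8 + [0.5] * 46
    amb = [0.0] * 46 + [1.0] * 46
    lids = ["none"] * 46 + ["top"] * 23 + ["bottom"] * 23
    df = pd.DataFrame(
        {"condition": cond, "win_probability": probs, "ambiguity_level": amb, "lid_position": lids}
    )
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)

    # amounts drawn without replacement in blocks of four over the
    # presented order: every amount occurs exactly 23 times
    amounts = np.concatenate([rng.permutation(FMRI_AMOUNTS) for _ in range(len(df) // len(FMRI_AMOUNTS))])
    df["gamble_amount"] = amounts
    df["side_gamble"] = _sides(len(df), rng)
    df["safe_amount"] = FMRI_SAFE_AMOUNT
    df["task"] = "fmri"

    gaps = rng.choice(_GAP_CHOICES_S, size=len(df))
    itis = rng.uniform(0.0, _ITI_MAX_S, size=len(df))
    onsets = np.empty(len(df))
    t = 0.0
    for i in range(len(df)):
        t += _FIXATION_S
        onsets[i] = t
        t += _RESPONSE_WINDOW_S + gaps[i] + _OUTCOME_S + itis[i]
    df["onset_s"] = np.round(onsets, 3)
    df["iti_s"] = np.round(itis, 3)
    df["trial_id"] = np.arange(1, len(df) + 1)
    return df[TRIAL_COLUMNS]


def write_design(df: pd.DataFrame, path) -> None:
    """Write a trial table as a tab-separated file with header."""
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design file lacks columns: {missing}")
    return df[TRIAL_COLUMNS]
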