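"""Independent oracles used by the test suite.

These re-derive quantities by brute force or direct per-trial evaluation,
independently of the library code paths they check.
"""

import math

import numpy as np


def likelihood_product_oracle(trials, choices, alpha, beta, mu):
    """NLL via an explicit per-trial probability product, plain Python math."""
    product = 1.0
    for (_, t), c in zip(trials.iterrows(), choices):
        if c == "missing":
            continue
        q = min(max(t["win_probability"] - beta * t["ambiguity_level"] / 2.0, 0.0), 1.0)
        eu_g = q * t["gamble_amount"] ** alpha
        eu_s = t["safe_amount"] ** alpha
        pr = 1.0 / (1.0 + math.exp(-(eu_g - eu_s) / mu))
        pr = min(max(pr, 1e-12), 1.0 - 1e-12)
        product *= pr if c == "gamble" else (1.0 - pr)
    return -math.log(product)


def dense_grid_search(trials, choices, alphas=None, betas=None, mus=None):
    """Brute-force minimum NLL over a dense attitude grid.

    Vectorised over (beta x trial) per alpha; returns (nll_min, argmin
    params) and the set of betas whose profile NLL is near the minimum
    (the likelihood can be flat in beta for near-deterministic choosers).
    """
    if alphas is None:
        alphas = np.arange(0.01, 2.5001, 0.01)
    if betas is None:
        betas = np.arange(-1.0, 1.0001, 0.01)
    if mus is None:
        mus = np.array([1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0, 2.0])
    y = (np.asarray(choices, dtype=object) == "gamble").astype(float)
    sign = 2.0 * y - 1.0
    p = trials["win_probability"].to_numpy(float)
    halfA = 0.5 * trials["ambiguity_level"].to_numpy(float)
    x = trials["gamble_amount"].to_numpy(float)
    safe = trials["safe_amount"].to_numpy(float)

    best = math.inf
    argmin = None
    beta_profile = np.full(len(betas), math.inf)
    for mu in mus:
        for i, a in enumerate(alphas):
            xa = x**a
            sa = safe**a
            q = np.clip(p[None, :] - betas[:, None] * halfA[None, :], 0.0, 1.0)
            z = sign[None, :] * (q * xa[None, :] - sa[None, :]) / mu
            nll = np.minimum(np.logaddexp(0.0, -z), -math.log(1e-12)).sum(axis=1)
            beta_profile = np.minimum(beta_profile, nll)
            j = int(nll.argmin())
            if nll[j] < best:
                best = float(nll[j])
                argmin = (float(a), float(betas[j]), float(mu))
    near = betas[beta_profile <= best + 0.01]
    return best, argmin, near


def residualization_partial_corr(x, y, controls):
    """Partial correlation by explicit two-stage OLS residualization."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.atleast_2d(np.asarray(controls, float))
    if c.shape[0] != len(x):
        c = c.T
    design = np.column_stack([np.ones(len(x)), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])
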