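"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the ANOVA oracle fits
nested least-squares projections on explicit dummy design matrices and
takes sequential (type-I) sums of squares; the fractional-change oracle
Monte-Carlos the generative model directly with vectorized draws.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _dummies(idx: np.ndarray, levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    out = np.zeros((idx.size, levels - 1))
    for lvl in range(1, levels):
        out[idx == lvl, lvl - 1] = 1.0
    return out


def anova_projection_oracle(y: np.ndarray, error_term: str = "residual") -> dict:
    """Sequential least-squares ANOVA of a (t, b, r) array.

    Fits the nested models 1, 1+T, 1+T+B, 1+T+B+T:B by explicit
    projection and differences the residual sums of squares.  For a
    balanced layout these sequential sums of squares coincide with the
    classical closed-form decomposition.
    """
    y = np.asarray(y, dtype=float)
    t, b, r = y.shape
    flat = y.reshape(-1)
    t_idx = np.repeat(np.arange(t), b * r)
    b_idx = np.tile(np.repeat(np.arange(b), r), t)

    ones = np.ones((flat.size, 1))
    Xt = _dummies(t_idx, t)
    Xb = _dummies(b_idx, b)
    Xtb = np.einsum("ij,ik->ijk", Xt, Xb).reshape(flat.size, -1)

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
        return float(((flat - X @ beta) ** 2).sum())

    rss0 = rss(ones)
    rss1 = rss(np.hstack([ones, Xt]))
    rss2 = rss(np.hstack([ones, Xt, Xb]))
    rss3 = rss(np.hstack([ones, Xt, Xb, Xtb]))

    ss = {
        "treatment": rss0 - rss1,
        "block": rss1 - rss2,
        "interaction": rss2 - rss3,
        "residual": rss3,
        "total": rss0,
    }
    df = {
        "treatment": t - 1,
        "block": b - 1,
        "interaction": (t - 1) * (b - 1),
        "residual": t * b * (r - 1),
        "total": t * b * r - 1,
    }
    ms = {k: ss[k] / df[k] for k in ("treatment", "block", "interaction", "residual")}
    out = {"ss": ss, "df": df, "F": {}, "p": {}}
    for source in ("treatment", "block", "interaction"):
        if error_term == "interaction" and source == "treatment":
            denom, denom_df = ms["interaction"], df["interaction"]
        else:
            denom, denom_df = ms["residual"], df["residual"]
        f_stat = ms[source] / denom
        out["F"][source] = f_stat
        out["p"][source] = float(stats.f.sf(f_stat, df[source], denom_df))
    return out


def mc_fractional_change_oracle(
    multiplier: float,
    well_noise_cv: float,
    replicates: int,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo expectation of the per-plate fractional change.

    Draws ``n_mc`` independent plates of the generative model (plate
    effects cancel within a plate and are omitted), computes
    mean(treatment wells) / mean(control wells) - 1 per plate, and returns
    the Monte-Carlo mean and its standard error.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(well_noise_cv**2))
    mu = -0.5 * sigma**2
    treat = multiplier * rng.lognormal(mu, sigma, (n_mc, replicates)).mean(axis=1)
    ctrl = rng.lognormal(mu, sigma, (n_mc, replicates)).mean(axis=1)
    fc = treat / ctrl - 1.0
    return float(fc.mean()), float(fc.std(ddof=1) / np.sqrt(n_mc))


def random_balanced_layout(rng: np.random.Generator) -> np.ndarray:
    """Random (t, b, r) data with treatment, block and interaction effects."""
    t = int(rng.choice([2, 3, 12]))
    b = int(rng.integers(2, 9))
    r = int(rng.choice([2, 4]))
    y = (
        rng.normal(10, 3, (t, 1, 1))
        + rng.normal(0, 2, (1, b, 1))
        + rng.normal(0, 1, (t, b, 1))
        + rng.normal(0, 1.5, (t, b, r))
    )
    return y
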