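"""Replicated randomized complete block ANOVA.

Plates are blocks and transfected constructs are treatments.  With
replicate wells inside each (treatment, block) cell the design supports the
full two-way decomposition: treatment, block, treatment-by-block
interaction, and a pure-error residual.  For a balanced layout with ``t``
treatments, ``b`` blocks and ``r`` replicates per cell the classical sums
of squares are

    SS_treatment   = r b sum_t (ybar_t.  - ybar)^2
    SS_block       = r t sum_b (ybar_.b  - ybar)^2
    SS_interaction = r   sum_tb (ybar_tb - ybar_t. - ybar_.b + ybar)^2
    SS_residual    = SS_total - (the three above),  SS_total = sum (y - ybar)^2

Each effect is tested against the pooled within-cell residual mean square
(fixed-effects convention); ``error_term="interaction"`` instead tests the
treatment against the interaction mean square, the random-blocks
alternative.  p-values come from the upper tail of the F distribution.

The per-receptor significance used by the hit classifier is the treatment
p-value of a two-level comparison — receptor vs empty-vector control —
run separately per condition on the plate-normalized per-well response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import normalize_wells
from .plate_model import ScreenDesign, as_frame

SOURCES = ("treatment", "block", "interaction", "residual", "total")

# Relative floor below which a sum of squares is considered exactly zero.
# Guards the noise-free limit, where SS that are algebraically zero come
# out as accumulated rounding of order eps^2 * scale.
_DEGENERATE_REL = 1e-12


@dataclass
class AnovaResult:
    """Decomposition table of one balanced two-way ANOVA.

    ``table`` is a frame indexed by source (treatment, block, interaction,
    residual, total) with columns sum_sq, df, mean_sq, F, p.  ``degenerate``
    is set when the residual mean square vanishes; in that limit p is
    reported as 0 for any source with positive SS and 1 otherwise.
    """

    table: pd.DataFrame
    degenerate: bool = False
    response_description: str = ""

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]

    @property
    def treatment_p(self) -> float:
        return float(self.table.loc["treatment", "p"])


def rcbd_anova(
    values: np.ndarray,
    error_term: str = "residual",
    response_description: str = "",
) -> AnovaResult:
    """Balanced two-way ANOVA on a (treatments, blocks, replicates) array.

    Parameters
    ----------
    values
        Array of shape ``(t, b, r)`` with ``t >= 2`` treatment levels,
        ``b >= 2`` blocks and ``r >= 2`` replicates per cell.  Balance is
        required; ragged data should be rejected by the design validator
        before reaching this function.
    error_term
        ``"residual"`` (default) tests every effect against the pooled
        within-cell mean square; ``"interaction"`` tests the treatment
        against the interaction mean square instead.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError(
            "expected a (treatments, blocks, replicates) array; "
            "unbalanced layouts must be resolved by the dataset validator first"
        )
    t, b, r = y.shape
    if t < 2 or b < 2 or r < 2:
        raise ValueError(f"need >= 2 levels in every dimension, got shape {(t, b, r)}")
    if error_term not in ("residual", "interaction"):
        raise ValueError("error_term must be 'residual' or 'interaction'")

    grand = y.mean()
    t_means = y.mean(axis=(1, 2))
    b_means = y.mean(axis=(0, 2))
    cell_means = y.mean(axis=2)

    ss_total = float(((y - grand) ** 2).sum())
    ss_treat = float(r * b * ((t_means - grand) ** 2).sum())
    ss_block = float(r * t * ((b_means - grand) ** 2).sum())
    ss_inter = float(
        r * ((cell_means - t_means[:, None] - b_means[None, :] + grand) ** 2).sum()
    )
    ss_resid = max(ss_total - ss_treat - ss_block - ss_inter, 0.0)

    df = {
        "treatment": t - 1,
        "block": b - 1,
        "interaction": (t - 1) * (b - 1),
        "residual": t * b * (r - 1),
        "total": t * b * r - 1,
    }
    ss = {
        "treatment": ss_treat,
        "block": ss_block,
        "interaction": ss_inter,
        "residual": ss_resid,
        "total": ss_total,
    }

    scale = max(ss_total, y.size * grand**2, 1.0)
    degenerate = ss_resid <= _DEGENERATE_REL * scale
    ms = {s: ss[s] / df[s] for s in ("treatment", "block", "interaction", "residual")}

    rows = {}
    for source in SOURCES:
        if source == "total":
            rows[source] = (ss[source], df[source], np.nan, np.nan, np.nan)
            continue
        if source == "residual":
            rows[source] = (ss[source], df[source], ms[source], np.nan, np.nan)
            continue
        denom = (
            ms["interaction"]
            if (error_term == "interaction" and source == "treatment")
            else ms["residual"]
        )
        denom_df = (
            df["interaction"]
            if (error_term == "interaction" and source == "treatment")
            else df["residual"]
        )
        if denom <= _DEGENERATE_REL * scale:
            # Degenerate error term: any real effect is infinitely
            # significant, no effect at all gives p = 1.
            effect_zero = ss[source] <= _DEGENERATE_REL * scale
            rows[source] = (
                ss[source],
                df[source],
                ms[source],
                np.inf if not effect_zero else 0.0,
                1.0 if effect_zero else 0.0,
            )
            continue
        f_stat = ms[source] / denom
        p = float(stats.f.sf(f_stat, df[source], denom_df))
        rows[source] = (ss[source], df[source], ms[source], f_stat, p)

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["sum_sq", "df", "mean_sq", "F", "p"]
    ).loc[list(SOURCES)]
    table["df"] = table["df"].astype(int)
    return AnovaResult(
        table=table,
        degenerate=degenerate,
        response_description=response_description,
    )


def _cell_array(
    frame: pd.DataFrame, treatments: list[str], r: int
) -> tuple[np.ndarray, list[str]]:
    """Stack per-well values into a (t, b, r) array over the shared plates.

    Only plates where every treatment has exactly ``r`` wells contribute;
    the usable plate ids are returned alongside the array.
    """
    counts = frame.groupby(["plate_id", "construct"], sort=True).size().unstack(
        fill_value=0
    )
    for treatment in treatments:
        if treatment not in counts.columns:
            counts[treatment] = 0
    usable = [
        p for p in counts.index if all(counts.loc[p, tr] == r for tr in treatments)
    ]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 complete plates for treatments {treatments}, "
            f"found {len(usable)}"
        )
    y = np.empty((len(treatments), len(usable), r))
    grouped = frame.groupby(["construct", "plate_id"], sort=False)["norm_rlu"]
    for i, treatment in enumerate(treatments):
        for j, plate in enumerate(usable):
            y[i, j, :] = grouped.get_group((treatment, plate)).to_numpy()
    return y, usable


def treatment_p_for_receptor(
    wells,
    receptor: str,
    condition: str,
    design: ScreenDesign | None = None,
    error_term: str = "residual",
) -> tuple[float, AnovaResult]:
    """Treatment p-value for one receptor in one condition.

    Runs the replicated block ANOVA with treatment factor
    {receptor, empty vector}, block factor plate, and response the
    plate-normalized per-well signal of the requested condition.
    """
    design = design or ScreenDesign()
    frame = as_frame(wells)
    if "norm_rlu" not in frame.columns:
        frame = normalize_wells(frame, design)
    sub = frame[
        (frame["condition"] == condition)
        & (frame["construct"].isin([receptor, design.control_construct]))
    ]
    y, plates = _cell_array(
        sub, [receptor, design.control_construct], design.replicates_per_group
    )
    result = rcbd_anova(
        y,
        error_term=error_term,
        response_description=(
            f"plate-normalized per-well RLU, {condition}, "
            f"{receptor} vs {design.control_construct}, plates {plates}"
        ),
    )
    return result.treatment_p, result


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (step-up, monotone).

    Provided as an option for screens where family-wise control across
    receptors is wanted; the default analysis applies no multiplicity
    correction, and comparisons against the published screen must keep it
    off.
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def anova_frame(results: dict[tuple[str, str], AnovaResult]) -> pd.DataFrame:
    """Long-format table of ANOVA results keyed by (receptor, condition)."""
    parts = []
    for (receptor, condition), res in results.items():
        tab = res.table.reset_index(names="source")
        tab.insert(0, "condition", condition)
        tab.insert(0, "receptor", receptor)
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)
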