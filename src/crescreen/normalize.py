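"""Two-stage normalization of plate luminescence data.

Stage 1 removes the plate (block) scale: every group mean on a plate is
divided by that plate's positive-control mean (forskolin-stimulated
empty-vector wells), so results are comparable between plates.

Stage 2 expresses each treatment relative to its matched control: the
receptor group in a condition is divided by the empty-vector group in the
same condition on the same plate, minus one, giving the fractional
stimulation or inhibition.  Per-plate fractional changes are then averaged
across plates; x100 they are the "percent change over control" axis used
for reporting.

Because the matched control shares the plate's positive-control divisor,
that divisor cancels algebraically in the fractional change.  The
implementation exploits the identity and computes per-plate fractional
changes directly from the group means, so stage 1 affects reported
normalized values (and the ANOVA response) but, by construction, cannot
perturb fractional changes even at the level of floating-point rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .plate_model import (
    BASELINE,
    CONDITIONS,
    FORSKOLIN,
    ScreenDesign,
    as_frame,
)

logger = logging.getLogger(__name__)

#: Columns of the normalized-group frame produced by :func:`normalize_plate`.
NORMALIZED_COLUMNS = (
    "plate_id",
    "construct",
    "condition",
    "group_mean_rlu",
    "normalized_value",
)


class PlateControlError(ValueError):
    """A plate lacks a usable positive-control group."""


@dataclass
class ReceptorSummary:
    """Pooled fractional change of one receptor in one condition.

    ``mean_fractional_change`` is the arithmetic mean of the per-plate
    values; multiplied by 100 it is the percent change over control.
    A summary is usable when at least two plates contributed both the
    receptor group and its matched control.
    """

    receptor: str
    condition: str
    per_plate_fractional_change: list[float] = field(default_factory=list)
    mean_fractional_change: float = float("nan")
    n_plates_used: int = 0
    n_plates_skipped: int = 0
    skip_reasons: list[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return self.n_plates_used >= 2


def normalize_plate(plate_wells, design: ScreenDesign | None = None) -> pd.DataFrame:
    """Normalize one plate's wells by its positive-control mean.

    Returns one row per (construct, condition) group with the group's raw
    mean and its normalized value (group mean / positive-control mean).
    The positive-control group itself normalizes to exactly 1.

    Raises
    ------
    PlateControlError
        If the positive-control group is missing, incomplete, or has a
        non-positive mean.  Screen-level callers catch this and exclude the
        plate with a logged reason.
    """
    design = design or ScreenDesign()
    frame = as_frame(plate_wells)
    plates = frame["plate_id"].unique()
    if len(plates) != 1:
        raise ValueError(f"normalize_plate expects a single plate, got {list(plates)}")
    plate_id = plates[0]

    ctrl, cond = design.positive_control
    pc = frame[(frame["construct"] == ctrl) & (frame["condition"] == cond)]
    if len(pc) != design.replicates_per_group:
        raise PlateControlError(
            f"plate {plate_id}: positive control has {len(pc)} wells, "
            f"expected {design.replicates_per_group}"
        )
    pc_mean = float(pc["rlu"].mean())
    if pc_mean <= 0:
        raise PlateControlError(
            f"plate {plate_id}: positive-control mean {pc_mean} is not positive"
        )

    groups = (
        frame.groupby(["construct", "condition"], sort=True)["rlu"]
        .mean()
        .rename("group_mean_rlu")
        .reset_index()
    )
    groups.insert(0, "plate_id", plate_id)
    groups["normalized_value"] = groups["group_mean_rlu"] / pc_mean
    # The positive control's own entry is 1 by definition; pin it so the
    # invariant holds bit-exactly rather than to within one rounding.
    is_pc = (groups["construct"] == ctrl) & (groups["condition"] == cond)
    groups.loc[is_pc, "normalized_value"] = 1.0
    return groups[list(NORMALIZED_COLUMNS)]


def normalize_screen(
    wells, design: ScreenDesign | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Normalize every plate of a screen; exclude plates with failed controls.

    Returns the concatenated normalized-group frame and the list of
    exclusion reasons (empty when all plates normalized).
    """
    design = design or ScreenDesign()
    frame = as_frame(wells)
    parts: list[pd.DataFrame] = []
    excluded: list[str] = []
    for plate_id, plate in frame.groupby("plate_id", sort=True):
        try:
            parts.append(normalize_plate(plate, design))
        except PlateControlError as err:
            logger.warning("excluding plate %s: %s", plate_id, err)
            excluded.append(str(err))
    if not parts:
        return pd.DataFrame(columns=list(NORMALIZED_COLUMNS)), excluded
    return pd.concat(parts, ignore_index=True), excluded


def normalize_wells(wells, design: ScreenDesign | None = None) -> pd.DataFrame:
    """Per-well stage-1 normalization (well rlu / plate positive-control mean).

    Adds a ``norm_rlu`` column; wells on plates with failed controls are
    dropped.  This per-well normalized response preserves within-group
    replication and is what the block ANOVA analyzes.
    """
    design = design or ScreenDesign()
    frame = as_frame(wells)
    ctrl, cond = design.positive_control
    pc = frame[(frame["construct"] == ctrl) & (frame["condition"] == cond)]
    pc_means = pc.groupby("plate_id")["rlu"].agg(["mean", "size"])
    ok = pc_means[
        (pc_means["size"] == design.replicates_per_group) & (pc_means["mean"] > 0)
    ]["mean"]
    out = frame[frame["plate_id"].isin(ok.index)].copy()
    out["norm_rlu"] = out["rlu"] / out["plate_id"].map(ok)
    return out


def fractional_changes(
    normalized: pd.DataFrame,
    receptor: str,
    design: ScreenDesign | None = None,
) -> dict[str, ReceptorSummary]:
    """Pooled fractional change of ``receptor`` vs its matched control.

    For each condition, the per-plate fractional change is
    (receptor group mean / same-plate empty-vector group mean) - 1,
    averaged over the plates where both groups are present.  Plates lacking
    either group, or with a non-positive control mean, are skipped and
    counted.  Returns one :class:`ReceptorSummary` per condition.
    """
    design = design or ScreenDesign()
    ctrl = design.control_construct
    out: dict[str, ReceptorSummary] = {}
    for condition in CONDITIONS:
        summary = ReceptorSummary(receptor=receptor, condition=condition)
        cond_rows = normalized[normalized["condition"] == condition]
        treat = cond_rows[cond_rows["construct"] == receptor].set_index("plate_id")
        control = cond_rows[cond_rows["construct"] == ctrl].set_index("plate_id")
        for plate_id in normalized["plate_id"].unique():
            if plate_id not in treat.index or plate_id not in control.index:
                summary.n_plates_skipped += 1
                summary.skip_reasons.append(
                    f"plate {plate_id}: missing {receptor} or {ctrl} group "
                    f"in {condition}"
                )
                continue
            c_mean = float(control.loc[plate_id, "group_mean_rlu"])
            if c_mean <= 0:
                summary.n_plates_skipped += 1
                summary.skip_reasons.append(
                    f"plate {plate_id}: non-positive {condition} control mean {c_mean}"
                )
                continue
            t_mean = float(treat.loc[plate_id, "group_mean_rlu"])
            # Stage-1 divisor cancels: (t/pc)/(c/pc) - 1 == t/c - 1.
            summary.per_plate_fractional_change.append(t_mean / c_mean - 1.0)
        summary.n_plates_used = len(summary.per_plate_fractional_change)
        if summary.n_plates_used:
            summary.mean_fractional_change = float(
                sum(summary.per_plate_fractional_change) / summary.n_plates_used
            )
        if not summary.usable:
            logger.warning(
                "receptor %s, condition %s: only %d usable plate(s); summary unusable",
                receptor,
                condition,
                summary.n_plates_used,
            )
        out[condition] = summary
    return out


def summaries_frame(summaries: list[ReceptorSummary]) -> pd.DataFrame:
    """Tabular view of receptor summaries (one row per receptor x condition)."""
    import json

    return pd.DataFrame(
        {
            "receptor": [s.receptor for s in summaries],
            "condition": [s.condition for s in summaries],
            "mean_fractional_change": [s.mean_fractional_change for s in summaries],
            "n_plates_used": [s.n_plates_used for s in summaries],
            "per_plate_values": [
                json.dumps(s.per_plate_fractional_change) for s in summaries
            ],
        }
    )
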