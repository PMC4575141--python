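"""Core data model for plate-based reporter-assay screens.

A screen is a collection of well measurements from one or more 96-well
plates.  Every plate carries two control groups transfected with the empty
expression vector: a sham-dosed baseline group and a forskolin-stimulated
positive-control group.  Plates act as blocks in the downstream analysis;
transfected constructs act as treatments.

The canonical in-memory container for a dataset is a tidy
:class:`pandas.DataFrame` with columns ``plate_id, well, construct,
condition, rlu`` (one row per well).  :class:`WellMeasurement` is the
corresponding record type for callers that prefer typed objects;
:func:`wells_to_frame` / :func:`frame_to_wells` convert between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

#: Condition label for sham-dosed (media only) wells.
BASELINE = "BASELINE"
#: Condition label for wells stimulated with 3 uM forskolin.
FORSKOLIN = "FORSKOLIN"
#: Reserved construct label for the empty expression vector.
EMPTY = "EMPTY"

CONDITIONS = (BASELINE, FORSKOLIN)

#: Column order of the tidy dataset frame.
DATASET_COLUMNS = ("plate_id", "well", "construct", "condition", "rlu")


@dataclass(frozen=True)
class WellMeasurement:
    """One well's raw luminescence reading and its design labels.

    Parameters
    ----------
    plate_id
        Block identifier; all wells sharing a ``plate_id`` were read in the
        same instrument run and share a common plate effect.
    well
        Physical position label (row letter + column number, e.g. ``"B03"``).
        Carried for provenance only; never used in computation.
    construct
        Transfected construct: a receptor name, or :data:`EMPTY` for the
        empty-vector control.
    condition
        :data:`BASELINE` or :data:`FORSKOLIN`.
    rlu
        Raw relative light units (non-negative).
    """

    plate_id: str
    well: str
    construct: str
    condition: str
    rlu: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.rlu < 0:
            raise ValueError(f"rlu must be non-negative, got {self.rlu}")


@dataclass(frozen=True)
class ScreenDesign:
    """Layout constants of the screen.

    Defaults mirror the assay design the package targets: 96-well plates
    holding 12 treatment groups of 4 replicate wells each, with the
    empty-vector baseline group and the forskolin-stimulated empty-vector
    group (the positive control) present on every plate.
    """

    treatments_per_plate: int = 12
    replicates_per_group: int = 4
    n_plates: int = 4
    control_construct: str = EMPTY

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ValueError(
                "replicates_per_group must be >= 2 "
                "(the treatment-by-block interaction requires within-cell replication)"
            )
        if self.treatments_per_plate < 2:
            raise ValueError("treatments_per_plate must be >= 2 (controls alone fill two)")
        if self.n_plates < 2:
            raise ValueError("n_plates must be >= 2 (blocking requires >= 2 blocks)")

    @property
    def positive_control(self) -> tuple[str, str]:
        """(construct, condition) of the per-plate positive control."""
        return (self.control_construct, FORSKOLIN)

    @property
    def receptors_per_plate(self) -> int:
        """Receptors fitting on one plate; each occupies two groups (one per
        condition) and two groups are reserved for the controls."""
        return (self.treatments_per_plate - 2) // 2


def wells_to_frame(wells: Iterable[WellMeasurement]) -> pd.DataFrame:
    """Convert well records to the tidy dataset frame."""
    rows = [(w.plate_id, w.well, w.construct, w.condition, w.rlu) for w in wells]
    return pd.DataFrame(rows, columns=list(DATASET_COLUMNS))


def frame_to_wells(frame: pd.DataFrame) -> list[WellMeasurement]:
    """Convert a tidy dataset frame to well records (validating each row)."""
    return [
        WellMeasurement(
            plate_id=str(r.plate_id),
            well=str(r.well),
            construct=str(r.construct),
            condition=str(r.condition),
            rlu=float(r.rlu),
        )
        for r in frame.itertuples(index=False)
    ]


def as_frame(wells) -> pd.DataFrame:
    """Accept either a tidy frame or an iterable of records; return a frame."""
    if isinstance(wells, pd.DataFrame):
        missing = [c for c in DATASET_COLUMNS if c not in wells.columns]
        if missing:
            raise ValueError(f"dataset frame is missing columns: {missing}")
        return wells
    return wells_to_frame(wells)


def validate_dataset(wells, design: ScreenDesign | None = None) -> list[str]:
    """Check a dataset against the screen design; return a list of violations.

    An empty list means every plate carries complete baseline and
    positive-control groups and every (plate, construct, condition) cell
    holds exactly ``design.replicates_per_group`` wells.  Violations are
    reported as human-readable strings, never raised.
    """
    design = design or ScreenDesign()
    frame = as_frame(wells)
    violations: list[str] = []

    if frame.empty:
        return ["dataset is empty"]

    bad_cond = frame.loc[~frame["condition"].isin(CONDITIONS), "condition"].unique()
    for c in bad_cond:
        violations.append(f"unknown condition label {c!r}")

    neg = frame[frame["rlu"] < 0]
    for r in neg.itertuples(index=False):
        violations.append(
            f"plate {r.plate_id} well {r.well}: negative rlu {r.rlu}"
        )

    dup = frame.duplicated(subset=["plate_id", "well"], keep=False)
    if dup.any():
        for (plate, well), _ in frame[dup].groupby(["plate_id", "well"], sort=True):
            violations.append(f"plate {plate}: duplicate well label {well!r}")

    counts = frame.groupby(
        ["plate_id", "construct", "condition"], sort=True
    ).size()
    expected = design.replicates_per_group
    for (plate, construct, condition), n in counts.items():
        if n != expected:
            violations.append(
                f"plate {plate}: group ({construct}, {condition}) has "
                f"{n} wells, expected {expected}"
            )

    ctrl = design.control_construct
    for plate in sorted(frame["plate_id"].unique()):
        for condition in CONDITIONS:
            if (plate, ctrl, condition) not in counts.index:
                kind = (
                    "positive-control" if condition == FORSKOLIN else "baseline control"
                )
                violations.append(
                    f"plate {plate}: missing {kind} group ({ctrl}, {condition})"
                )

    return violations


def receptors_in(wells) -> list[str]:
    """Sorted receptor labels present in a dataset (control excluded)."""
    frame = as_frame(wells)
    return sorted(c for c in frame["construct"].unique() if c != EMPTY)
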