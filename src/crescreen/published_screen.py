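"""The published 40-receptor orphan-GPCR screen and its summary statistics.

This module ships the reported group assignment of each of the 40 class-A
orphan receptors screened for constitutive cAMP-pathway activity, and
recomputes the screen-level tallies from those assignments: how many
receptors showed constitutive activity at all (groups A-D), and how many
acted in an inhibitory (groups A, B, C) versus stimulatory (groups B, D)
direction on CRE-mediated expression.

Raw per-well luminescence for the screen was never deposited, so the
fixture carries group membership only; per-receptor magnitudes exist only
as figure bars and are deliberately not encoded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .classify import Classification, GROUPS

#: Criteria implied by membership in each response group, used to derive
#: the inhibitory / stimulatory direction tallies.
GROUP_CRITERIA: dict[str, frozenset[int]] = {
    "A": frozenset({2, 3}),
    "B": frozenset({1, 3}),
    "C": frozenset({3}),
    "D": frozenset({1}),
    "E": frozenset(),
    "OTHER": frozenset({2}),
}

#: Criteria that correspond to inhibition (2, 3) vs stimulation (1) of
#: CRE-mediated expression.
_INHIBITORY_CRITERIA = {2, 3}
_STIMULATORY_CRITERIA = {1}


@dataclass(frozen=True)
class PublishedRecord:
    """One receptor's reported outcome in the published screen."""

    receptor: str
    reported_group: str
    notes: str = ""


@dataclass(frozen=True)
class ScreenSummary:
    """Screen-level tallies derived from per-receptor group assignments."""

    group_counts: dict[str, int]
    n_total: int
    n_constitutive: int
    pct_constitutive: float
    n_inhibitory: int
    n_stimulatory: int
    pct_inhibitory: float
    pct_stimulatory: float


def published_fixture() -> list[PublishedRecord]:
    """The 40 receptors with their reported groups, as a record list."""
    with resources.files("crescreen.data").joinpath("published_screen.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        frame = pd.read_csv(fh, keep_default_na=False)
    records = [
        PublishedRecord(r.receptor, r.group, r.notes)
        for r in frame.itertuples(index=False)
    ]
    names = [r.receptor for r in records]
    assert len(records) == 40 and len(set(names)) == 40
    assert all(r.reported_group in GROUPS for r in records)
    return records


def _group_of(item) -> tuple[str, str]:
    """(receptor, group) from a PublishedRecord or a Classification."""
    if isinstance(item, PublishedRecord):
        return item.receptor, item.reported_group
    if isinstance(item, Classification):
        return item.receptor, item.group
    receptor, group = item  # plain (receptor, group) pair
    return receptor, group


def summarize(items) -> ScreenSummary:
    """Tally group counts and direction statistics over a screen's outcomes.

    Accepts published records, pipeline classifications, or plain
    (receptor, group) pairs.  Receptors labelled UNEVALUABLE are excluded
    from all tallies.  Inhibitory and stimulatory counts are derived from
    group membership via the criteria each group implies — a receptor in
    group B counts in both directions.
    """
    pairs = [_group_of(x) for x in items]
    for receptor, group in pairs:
        if not group:
            raise ValueError(f"receptor {receptor!r} has no group assigned")
    pairs = [(r, g) for r, g in pairs if g != "UNEVALUABLE"]
    if not pairs:
        raise ValueError("no evaluable receptors to summarize")

    counts: dict[str, int] = {g: 0 for g in (*GROUPS, "OTHER")}
    for _, group in pairs:
        if group not in counts:
            raise ValueError(f"unknown group label {group!r}")
        counts[group] += 1
    if counts["OTHER"] == 0:
        del counts["OTHER"]

    n_total = len(pairs)
    n_constitutive = n_total - counts.get("E", 0)
    n_inhibitory = sum(
        c for g, c in counts.items() if GROUP_CRITERIA[g] & _INHIBITORY_CRITERIA
    )
    n_stimulatory = sum(
        c for g, c in counts.items() if GROUP_CRITERIA[g] & _STIMULATORY_CRITERIA
    )
    return ScreenSummary(
        group_counts=counts,
        n_total=n_total,
        n_constitutive=n_constitutive,
        pct_constitutive=100.0 * n_constitutive / n_total,
        n_inhibitory=n_inhibitory,
        n_stimulatory=n_stimulatory,
        pct_inhibitory=100.0 * n_inhibitory / n_total,
        pct_stimulatory=100.0 * n_stimulatory / n_total,
    )


def star_annotation(p: float) -> str:
    """Figure-style significance mark: ``**`` below 0.01, ``*`` below 0.05,
    otherwise the literal p-value (the convention for flagging
    non-significant comparisons explicitly)."""
    if math.isnan(p):
        return "n/a"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return format(p, ".3g")


def render_report(
    summary: ScreenSummary, classifications: list[Classification] | None = None
) -> str:
    """Deterministic plain-text report of a screen's outcome.

    Includes the group tallies and, when classifications are given, a
    bar-chart-style table of percent change per receptor and condition
    with the star annotation for each comparison.
    """
    lines = ["Constitutive-activity screen summary", "=" * 37]
    for group in sorted(summary.group_counts):
        lines.append(f"  group {group}: {summary.group_counts[group]} receptor(s)")
    lines.append(
        f"  constitutively active: {summary.n_constitutive} of {summary.n_total}"
        f" ({summary.pct_constitutive:.0f}%)"
    )
    lines.append(
        f"  inhibitory: {summary.n_inhibitory} ({summary.pct_inhibitory:.0f}%)"
        f"  stimulatory: {summary.n_stimulatory} ({summary.pct_stimulatory:.0f}%)"
    )
    if classifications:
        lines.append("")
        lines.append(f"{'receptor':<20}{'condition':<12}{'% change':>10}  significance")
        for c in sorted(classifications, key=lambda c: c.receptor):
            if c.group == "UNEVALUABLE":
                lines.append(f"{c.receptor:<20}{'-':<12}{'-':>10}  unevaluable: {c.reason}")
                continue
            for condition, change, p in (
                ("baseline", c.baseline_change, c.baseline_p),
                ("forskolin", c.forskolin_change, c.forskolin_p),
            ):
                lines.append(
                    f"{c.receptor:<20}{condition:<12}{100 * change:>9.1f}%"
                    f"  {star_annotation(p)}"
                )
    return "\n".join(lines) + "\n"
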