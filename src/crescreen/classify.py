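"""Constitutive-activity calling and five-group classification.

A receptor is called constitutively active when its effect is both large
and statistically supported: the magnitude must meet one of three
thresholds and the block-ANOVA treatment p-value for the *same condition*
must fall below alpha.

    criterion 1: baseline fractional change >= +2.00 (>= 200% elevation)
    criterion 2: baseline fractional change <= -0.40 (>= 40% inhibition)
    criterion 3: forskolin-condition fractional change <= -0.40

Significance is evaluated per condition per criterion: a large inhibition
of the forskolin response whose own p-value misses alpha does not satisfy
criterion 3, however extreme the magnitude.

The criteria patterns map onto five response groups:

    A: inhibition of both baseline and forskolin-stimulated expression
       (criteria 2 and 3)
    B: baseline stimulation with forskolin-response inhibition
       (criteria 1 and 3)
    C: forskolin-response inhibition only (criterion 3 alone)
    D: baseline stimulation without forskolin-response inhibition
       (criterion 1, not 3)
    E: no criterion met — no constitutive activity
    OTHER: baseline inhibition without forskolin-response inhibition
       (criterion 2, not 3) — a pattern no screened receptor has shown;
       kept explicit rather than coerced into A so that evaluation
       metrics stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass

from .plate_model import BASELINE, FORSKOLIN, ScreenDesign, as_frame
from .normalize import ReceptorSummary

GROUPS = ("A", "B", "C", "D", "E")
UNEVALUABLE = "UNEVALUABLE"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and significance level for constitutive-activity calling.

    ``stimulation_threshold`` is on the fractional-change scale: the default
    +2.0 means the treated group must reach at least three times its control
    (a 200% elevation).  Reading "200%" as two-fold instead is a matter of
    setting the threshold to 1.0.  Inhibition thresholds are negative
    fractional changes; -0.40 is a 40% knockdown.
    """

    stimulation_threshold: float = 2.0
    baseline_inhibition_threshold: float = -0.40
    forskolin_inhibition_threshold: float = -0.40
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.stimulation_threshold <= 0:
            raise ValueError("stimulation_threshold must be positive")
        for name in ("baseline_inhibition_threshold", "forskolin_inhibition_threshold"):
            v = getattr(self, name)
            if not -1.0 < v < 0.0:
                raise ValueError(f"{name} must lie in (-1, 0), got {v}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass
class Classification:
    """Criteria flags, per-condition statistics and assigned group."""

    receptor: str
    baseline_change: float = float("nan")
    forskolin_change: float = float("nan")
    baseline_p: float = float("nan")
    forskolin_p: float = float("nan")
    crit1: bool = False
    crit2: bool = False
    crit3: bool = False
    group: str = ""
    reason: str = ""

    @property
    def constitutive(self) -> bool:
        return self.crit1 or self.crit2 or self.crit3


def evaluate_criteria(
    baseline: ReceptorSummary,
    forskolin: ReceptorSummary,
    baseline_p: float,
    forskolin_p: float,
    config: ClassifierConfig | None = None,
) -> Classification:
    """Evaluate the three constitutive-activity criteria for one receptor.

    Threshold comparisons are inclusive ("meets"): a fractional change
    exactly at a threshold satisfies the magnitude requirement.  Each
    criterion additionally requires its own condition's treatment p-value
    to be below alpha.
    """
    config = config or ClassifierConfig()
    if baseline.receptor != forskolin.receptor:
        raise ValueError("summaries belong to different receptors")
    cls = Classification(receptor=baseline.receptor)
    if not (baseline.usable and forskolin.usable):
        cls.group = UNEVALUABLE
        cls.reason = "; ".join(baseline.skip_reasons + forskolin.skip_reasons) or (
            "fewer than 2 usable plates in at least one condition"
        )
        return cls

    cls.baseline_change = baseline.mean_fractional_change
    cls.forskolin_change = forskolin.mean_fractional_change
    cls.baseline_p = float(baseline_p)
    cls.forskolin_p = float(forskolin_p)

    base_sig = cls.baseline_p < config.alpha
    fors_sig = cls.forskolin_p < config.alpha
    cls.crit1 = cls.baseline_change >= config.stimulation_threshold and base_sig
    cls.crit2 = cls.baseline_change <= config.baseline_inhibition_threshold and base_sig
    cls.crit3 = cls.forskolin_change <= config.forskolin_inhibition_threshold and fors_sig
    return cls


def assign_group(classification: Classification) -> str:
    """Map criteria flags to the response group (decision table is total)."""
    c1, c2, c3 = classification.crit1, classification.crit2, classification.crit3
    if c2 and c3:
        return "A"
    if c1 and c3:
        return "B"
    if c3:
        return "C"
    if c1:
        return "D"
    if c2:
        return "OTHER"
    return "E"


def classify_screen(
    wells,
    design: ScreenDesign | None = None,
    config: ClassifierConfig | None = None,
    error_term: str = "residual",
    fdr_adjust: bool = False,
) -> list[Classification]:
    """Run the full calling pipeline on a screen dataset.

    Normalizes, pools fractional changes, computes per-condition treatment
    p-values, evaluates the criteria and assigns groups.  Deterministic
    given the dataset; receptors whose summaries are unusable come back
    labelled UNEVALUABLE with a reason, for exclusion from tallies.

    ``fdr_adjust`` applies a Benjamini-Hochberg correction across the
    screen's receptors within each condition before the criteria are
    evaluated.  It defaults off: the screen protocol this package
    reproduces applies no multiplicity correction, and comparisons against
    the published tallies must keep it off.
    """
    from .normalize import fractional_changes, normalize_screen, normalize_wells
    from .plate_model import receptors_in
    from .rcbd_anova import treatment_p_for_receptor

    design = design or ScreenDesign()
    config = config or ClassifierConfig()
    frame = as_frame(wells)

    normalized, _excluded = normalize_screen(frame, design)
    per_well = normalize_wells(frame, design)

    prelim: list[tuple] = []
    for receptor in receptors_in(frame):
        summaries = fractional_changes(normalized, receptor, design)
        base, fors = summaries[BASELINE], summaries[FORSKOLIN]
        if base.usable and fors.usable:
            try:
                base_p, _ = treatment_p_for_receptor(
                    per_well, receptor, BASELINE, design, error_term
                )
                fors_p, _ = treatment_p_for_receptor(
                    per_well, receptor, FORSKOLIN, design, error_term
                )
            except ValueError as err:
                prelim.append((receptor, None, None, None, None, str(err)))
                continue
        else:
            base_p = fors_p = float("nan")
        prelim.append((receptor, base, fors, base_p, fors_p, None))

    if fdr_adjust:
        import numpy as np

        from .rcbd_anova import benjamini_hochberg

        ok = [
            i
            for i, row in enumerate(prelim)
            if row[5] is None and row[1].usable and row[2].usable
        ]
        if ok:
            base_adj = benjamini_hochberg(np.array([prelim[i][3] for i in ok]))
            fors_adj = benjamini_hochberg(np.array([prelim[i][4] for i in ok]))
            for k, i in enumerate(ok):
                r = prelim[i]
                prelim[i] = (r[0], r[1], r[2], float(base_adj[k]), float(fors_adj[k]), None)

    out: list[Classification] = []
    for receptor, base, fors, base_p, fors_p, error in prelim:
        if error is not None:
            cls = Classification(receptor=receptor, group=UNEVALUABLE)
            cls.reason = error
            out.append(cls)
            continue
        cls = evaluate_criteria(base, fors, base_p, fors_p, config)
        if cls.group != UNEVALUABLE:
            cls.group = assign_group(cls)
        out.append(cls)
    return out


def classifications_frame(classifications: list[Classification]):
    """Tabular view of classifications, one row per receptor."""
    import pandas as pd

    return pd.DataFrame(
        {
            "receptor": [c.receptor for c in classifications],
            "baseline_change": [c.baseline_change for c in classifications],
            "forskolin_change": [c.forskolin_change for c in classifications],
            "baseline_p": [c.baseline_p for c in classifications],
            "forskolin_p": [c.forskolin_p for c in classifications],
            "crit1": [c.crit1 for c in classifications],
            "crit2": [c.crit2 for c in classifications],
            "crit3": [c.crit3 for c in classifications],
            "constitutive": [c.constitutive for c in classifications],
            "group": [c.group for c in classifications],
        }
    )
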