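"""Synthetic plate-screen generator with known ground truth.

The generative model is multiplicative throughout, reflecting how
luminescence readouts behave: signals are positive and their dispersion
scales with their mean.  The expected RLU of a well is

    baseline_mean_rlu
      x forskolin_ratio          (forskolin-condition wells only)
      x effect multiplier        (condition-matched, per construct)
      x plate effect             (log-normal, one draw per plate)
      x well noise               (log-normal, one draw per well)

Both random factors are log-normal with log-mean chosen as -sigma^2/2 so
each has expectation exactly 1; group means are therefore unbiased for the
product of the design constants and the construct's effect multiplier.
A shared multiplicative plate effect is precisely the structure that both
the positive-control normalization and the block factor of the downstream
ANOVA are designed to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_model import (
    BASELINE,
    DATASET_COLUMNS,
    EMPTY,
    FORSKOLIN,
    ScreenDesign,
)


@dataclass(frozen=True)
class EffectProfile:
    """Ground-truth multiplicative effect of a construct.

    ``baseline_multiplier`` scales the expected baseline RLU relative to the
    empty-vector baseline control; ``forskolin_multiplier`` scales the
    expected forskolin-stimulated RLU relative to the stimulated control.
    A multiplier ``m`` corresponds to a true fractional change of ``m - 1``
    (so ``m = 0.4`` is 60% inhibition, ``m = 4.0`` is +300% stimulation).
    The empty vector is the identity profile (1.0, 1.0).
    """

    receptor: str
    baseline_multiplier: float
    forskolin_multiplier: float

    def __post_init__(self) -> None:
        if self.baseline_multiplier <= 0 or self.forskolin_multiplier <= 0:
            raise ValueError("effect multipliers must be positive")

    def multiplier(self, condition: str) -> float:
        return (
            self.baseline_multiplier if condition == BASELINE else self.forskolin_multiplier
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Dispersion and scale parameters of the generative model.

    Parameters
    ----------
    baseline_mean_rlu
        Expected empty-vector baseline signal, in RLU.
    forskolin_ratio
        Expected positive-control / baseline-control signal ratio; the
        assay design this package emulates maintains roughly 5:1.
    plate_effect_sd
        Standard deviation, on the natural-log scale, of the per-plate
        multiplicative block effect.
    well_noise_cv
        Coefficient of variation of the per-well multiplicative noise.
    n_plates
        Replicate plates (blocks) per batch.
    seed
        Random seed; must be supplied before simulating (reproducibility
        is mandatory, so there is no implicit entropy source).
    effect_jitter_sd
        Optional log-scale SD of a per-plate jitter applied to each
        receptor's effect multipliers, mimicking the unexplained
        plate-to-plate variability some receptors show (treatment-by-block
        interaction).  Off by default.
    """

    baseline_mean_rlu: float = 20000.0
    forskolin_ratio: float = 5.0
    plate_effect_sd: float = 0.3
    well_noise_cv: float = 0.15
    n_plates: int = 4
    seed: int | None = None
    effect_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_mean_rlu <= 0:
            raise ValueError("baseline_mean_rlu must be positive")
        if self.forskolin_ratio <= 1:
            raise ValueError("forskolin_ratio must exceed 1")
        if min(self.plate_effect_sd, self.well_noise_cv, self.effect_jitter_sd) < 0:
            raise ValueError("dispersion parameters must be >= 0")


#: Archetype effect profiles, one per response pattern the classifier
#: recognises.  Chosen to sit well past the calling thresholds:
#:   A inhibits both conditions, B stimulates baseline and inhibits
#:   forskolin response, C inhibits only the forskolin response,
#:   D stimulates only baseline, E is the null.
ARCHETYPE_EFFECTS: Mapping[str, tuple[float, float]] = {
    "A": (0.4, 0.4),
    "B": (4.0, 0.5),
    "C": (1.0, 0.5),
    "D": (4.0, 1.0),
    "E": (1.0, 1.0),
}


def archetype_profiles() -> dict[str, EffectProfile]:
    """One representative :class:`EffectProfile` per group archetype A-E."""
    return {
        label: EffectProfile(f"R_{label}", b, f)
        for label, (b, f) in ARCHETYPE_EFFECTS.items()
    }


def _lognormal_factors(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Log-normal multiplicative factors with expectation exactly 1."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _well_labels(group_index: int, n_reps: int) -> list[str]:
    """Deterministic physical positions for one treatment group.

    Groups are laid out four wells to a row segment (rows A-H, columns
    1-12); the labels are provenance only and never enter computation.
    """
    row = chr(ord("A") + group_index // 3)
    col0 = (group_index % 3) * 4 + 1
    return [f"{row}{col0 + k:02d}" for k in range(n_reps)]


def simulate_screen(
    profiles: Sequence[EffectProfile],
    design: ScreenDesign | None = None,
    sim: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Simulate a complete screen and return the tidy dataset frame.

    Every plate carries the empty-vector baseline group and the
    forskolin-stimulated positive control.  If more receptors are supplied
    than fit on one plate alongside the controls, they are split into
    batches, each batch simulated on its own set of ``sim.n_plates`` plates
    (plate ids ``B<batch>_P<plate>``).

    Raises
    ------
    ValueError
        If ``sim.seed`` is not set; reproducibility is mandatory.
    """
    design = design or ScreenDesign()
    sim = sim or SimulationConfig()
    if sim.seed is None:
        raise ValueError("SimulationConfig.seed must be set (reproducibility is mandatory)")
    noise_sigma = math.sqrt(math.log1p(sim.well_noise_cv**2))

    per_batch = design.receptors_per_plate
    if per_batch < 1:
        raise ValueError("design leaves no room for receptors beside the controls")
    batches = [
        list(profiles[i : i + per_batch]) for i in range(0, max(len(profiles), 1), per_batch)
    ] or [[]]

    rng = np.random.default_rng(sim.seed)
    r = design.replicates_per_group
    control = EffectProfile(design.control_construct, 1.0, 1.0)

    records: list[tuple] = []
    for b_idx, batch in enumerate(batches, start=1):
        groups = [
            (p, cond) for p in [control, *batch] for cond in (BASELINE, FORSKOLIN)
        ]
        for p_idx in range(1, sim.n_plates + 1):
            plate_id = f"B{b_idx}_P{p_idx}"
            plate_factor = float(_lognormal_factors(rng, sim.plate_effect_sd, ()))
            for g_idx, (profile, cond) in enumerate(groups):
                mult = profile.multiplier(cond)
                if sim.effect_jitter_sd > 0 and profile.receptor != design.control_construct:
                    mult *= float(_lognormal_factors(rng, sim.effect_jitter_sd, ()))
                expected = (
                    sim.baseline_mean_rlu
                    * (sim.forskolin_ratio if cond == FORSKOLIN else 1.0)
                    * mult
                    * plate_factor
                )
                noise = _lognormal_factors(rng, noise_sigma, r)
                for well, eta in zip(_well_labels(g_idx, r), noise):
                    records.append(
                        (plate_id, well, profile.receptor, cond, expected * float(eta))
                    )

    return pd.DataFrame(records, columns=list(DATASET_COLUMNS))


def truth_table(profiles: Sequence[EffectProfile]) -> pd.DataFrame:
    """Ground-truth frame (receptor, multipliers, true fractional changes)."""
    return pd.DataFrame(
        {
            "receptor": [p.receptor for p in profiles],
            "baseline_multiplier": [p.baseline_multiplier for p in profiles],
            "forskolin_multiplier": [p.forskolin_multiplier for p in profiles],
            "true_baseline_change": [p.baseline_multiplier - 1 for p in profiles],
            "true_forskolin_change": [p.forskolin_multiplier - 1 for p in profiles],
        }
    )


def replicated_archetype_profiles(copies: int = 1) -> tuple[list[EffectProfile], dict[str, str]]:
    """``copies`` receptors per archetype, plus a receptor -> archetype map."""
    profiles: list[EffectProfile] = []
    truth: dict[str, str] = {}
    for label, (b, f) in ARCHETYPE_EFFECTS.items():
        for k in range(1, copies + 1):
            name = f"R_{label}{k}" if copies > 1 else f"R_{label}"
            profiles.append(EffectProfile(name, b, f))
            truth[name] = label
    return profiles, truth


def with_seed(sim: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``sim`` with the seed replaced."""
    return replace(sim, seed=int(seed))
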