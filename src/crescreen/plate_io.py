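"""Reading and writing plate datasets and analysis configurations.

Datasets are long-format ("tidy") CSV files with the exact header
``plate_id,well,construct,condition,rlu`` — one row per well, UTF-8,
comma-delimited, ``.`` decimal separator.  Configurations are flat YAML or
JSON mappings; any key not set falls back to its documented default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .classify import ClassifierConfig
from .plate_model import CONDITIONS, DATASET_COLUMNS, as_frame
from .simulate import SimulationConfig

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = list(DATASET_COLUMNS)


class DatasetFormatError(ValueError):
    """The file does not conform to the documented dataset dialect."""


class ConfigError(ValueError):
    """The configuration mapping contains an unknown or invalid key."""


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format dataset CSV into the tidy dataset frame.

    Raises
    ------
    DatasetFormatError
        If a required column is missing or misnamed (the error names the
        missing column), or if any row has a non-numeric or negative ``rlu``
        (the error carries the 1-based data line number).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {','.join(REQUIRED_COLUMNS)}"
        )
    extra = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        frame = frame[REQUIRED_COLUMNS]

    rlu = pd.to_numeric(frame["rlu"], errors="coerce")
    bad = rlu.isna() | (rlu < 0)
    if bad.any():
        i = int(bad.idxmax())
        raise DatasetFormatError(
            f"{path}: line {i + 2}: rlu value {frame['rlu'].iloc[i]!r} "
            "is not a non-negative number"
        )
    out = frame.copy()
    out["rlu"] = rlu.astype(float)

    bad_cond = ~out["condition"].isin(CONDITIONS)
    if bad_cond.any():
        i = int(bad_cond.idxmax())
        raise DatasetFormatError(
            f"{path}: line {i + 2}: condition {out['condition'].iloc[i]!r} "
            f"must be one of {list(CONDITIONS)}"
        )
    return out[REQUIRED_COLUMNS]


def write_dataset(wells, path) -> None:
    """Write a dataset to CSV in a deterministic row order.

    Rows are sorted by (plate_id, construct, condition, well) so that any
    permutation of the same measurements produces a byte-identical file.
    """
    frame = as_frame(wells)
    if frame.empty:
        raise ValueError("refusing to write an empty dataset")
    ordered = frame.sort_values(
        ["plate_id", "construct", "condition", "well"], kind="mergesort"
    )
    ordered.to_csv(path, index=False, columns=REQUIRED_COLUMNS)


# Keys accepted in a configuration mapping, split by the object they feed.
_CLASSIFIER_KEYS = tuple(f.name for f in dataclasses.fields(ClassifierConfig))
_SIMULATION_KEYS = tuple(f.name for f in dataclasses.fields(SimulationConfig))


def read_config(path) -> tuple[ClassifierConfig, SimulationConfig]:
    """Read a flat YAML/JSON mapping into classifier + simulation configs.

    Missing keys take the documented defaults (thresholds +2.00 / -0.40 /
    -0.40, alpha 0.05, forskolin:baseline control ratio 5.0).  An unknown
    key raises :class:`ConfigError` listing the valid keys.
    """
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        mapping = {}
    elif str(path).endswith(".json"):
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text) or {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: configuration must be a flat mapping")

    valid = set(_CLASSIFIER_KEYS) | set(_SIMULATION_KEYS)
    unknown = sorted(set(mapping) - valid)
    if unknown:
        raise ConfigError(
            f"{path}: unknown key(s) {unknown}; valid keys are {sorted(valid)}"
        )

    cls_kwargs = {k: mapping[k] for k in _CLASSIFIER_KEYS if k in mapping}
    sim_kwargs = {k: mapping[k] for k in _SIMULATION_KEYS if k in mapping}
    return ClassifierConfig(**cls_kwargs), SimulationConfig(**sim_kwargs)
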