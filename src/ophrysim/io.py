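"""Typed CSV readers/writers, JSON model (de)serialization, config
parsing and seed management.

CSV dialect: comma-separated, UTF-8, mandatory header row, '.' decimal.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alkenes import AlkeneModel
from .attraction import AttractionModel
from .popsim import SimulationConfig
from .synthetic import CHOICE_COLUMNS, CHOICE_GROUPS, EXPRESSION_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_expression_scent",
    "read_choice_trials",
    "write_expression_scent",
    "write_choice_trials",
    "save_model",
    "load_alkene_model",
    "load_attraction_model",
    "load_sim_config",
    "spawn_seeds",
]


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


def _read_csv(path, required: tuple[str, ...], numeric: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df.empty:
        logger.warning("%s: empty data section", path)
        return df[list(required)]
    bad_rows = []
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0)
        bad_rows.extend((int(i) + 2, col) for i in df.index[bad])  # +2: header + 1-based
        df[col] = values
    if bad_rows:
        detail = "; ".join(f"row {r} ({c})" for r, c in bad_rows[:10])
        raise SchemaError(f"{path}: negative or non-numeric values: {detail}")
    return df[list(required)]


def read_expression_scent(path) -> pd.DataFrame:
    """Read per-individual expression/scent records with validation."""
    return _read_csv(
        path,
        required=EXPRESSION_COLUMNS,
        numeric=("sad2a_expr", "sad5a_expr", "alkene_7", "alkene_9", "alkene_12"),
    )


def read_choice_trials(path) -> pd.DataFrame:
    """Read pollinator-choice trials with validation."""
    df = _read_csv(
        path,
        required=CHOICE_COLUMNS,
        numeric=("alkene_7", "alkene_9", "alkene_12", "visits_cc", "visits_an"),
    )
    if not df.empty:
        unknown = set(df["group"]) - set(CHOICE_GROUPS)
        if unknown:
            raise SchemaError(f"{path}: unknown treatment group(s): {sorted(unknown)}")
        for col in ("visits_cc", "visits_an"):
            if not np.allclose(df[col], np.round(df[col])):
                raise SchemaError(f"{path}: {col} must contain integer counts")
            df[col] = df[col].astype(int)
    return df


def write_expression_scent(df: pd.DataFrame, path) -> None:
    df[list(EXPRESSION_COLUMNS)].to_csv(path, index=False)


def write_choice_trials(df: pd.DataFrame, path) -> None:
    df[list(CHOICE_COLUMNS)].to_csv(path, index=False)


def save_model(model, path) -> None:
    """Serialize an AlkeneModel or AttractionModel to JSON."""
    payload = model.to_dict()
    kind = "alkene" if isinstance(model, AlkeneModel) else "attraction"
    Path(path).write_text(json.dumps({"kind": kind, "model": payload}, indent=2))


def _load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def load_alkene_model(path) -> AlkeneModel:
    d = _load_json(path)
    if d.get("kind") != "alkene":
        raise SchemaError(f"{path}: not an alkene model file")
    return AlkeneModel.from_dict(d["model"])


def load_attraction_model(path) -> AttractionModel:
    d = _load_json(path)
    if d.get("kind") != "attraction":
        raise SchemaError(f"{path}: not an attraction model file")
    return AttractionModel.from_dict(d["model"])


def load_sim_config(path, **overrides) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping (keys = field names)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping of config fields")
    raw.update(overrides)
    if "pollinator_ratio" in raw:
        raw["pollinator_ratio"] = tuple(raw["pollinator_ratio"])
    try:
        cfg = SimulationConfig(**raw)
    except TypeError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    cfg.validate()
    return cfg


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n per-stage seeds (< 2**31) from one master seed."""
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in np.random.SeedSequence(master_seed).spawn(n)]
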