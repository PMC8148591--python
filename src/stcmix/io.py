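"""Reading and writing the package's on-disk formats.

All tables are delimited text (CSV with header); concentration columns carry
the ``_um`` suffix (umol/L) so unit mismatches cannot pass silently.  Design
and scenario files are YAML key-value documents.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .dose_response import Direction, LogisticCRC
from .exceptions import DesignError, IngestionError
from .mixtures import MixtureComponent, MixtureDesign, equitoxic_fractions
from .normalization import RECORD_COLUMNS
from .simulate import Treatment, TrueScenario

__all__ = [
    "read_records",
    "read_table",
    "write_table",
    "load_yaml",
    "design_from_dict",
    "load_design",
    "scenario_from_dict",
    "load_scenario",
]


def read_records(path) -> pd.DataFrame:
    """Read an embryo-level record table, validating the schema."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise IngestionError(f"{path} is empty") from err
    if df.empty:
        raise IngestionError(f"{path} contains no rows")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise IngestionError(f"{path} lacks required columns: {missing}")
    return df


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise IngestionError(f"{path} does not contain a mapping")
    return doc


def _component_crc(entry: dict) -> LogisticCRC:
    try:
        return LogisticCRC(
            slope_b=float(entry["slope"]),
            inflection_e=float(entry["ec50_um"]),
            floor_c=float(entry.get("floor", 0.0)),
            ceiling_d=float(entry.get("ceiling", 100.0)),
            direction=Direction(entry.get("direction", "hyperactivity")),
        )
    except KeyError as err:
        raise DesignError(f"component entry {entry!r} lacks key {err}") from err


def design_from_dict(doc: dict) -> MixtureDesign:
    """Build a MixtureDesign from its YAML form.

    Each component lists ``name, ec50_um, slope, direction`` and either a
    numeric ``fraction`` or the string ``equitoxic``; mixing the two styles
    in one design is rejected.
    """
    entries = doc.get("components") or []
    if len(entries) < 1:
        raise DesignError("design lists no components")
    fracs = [e.get("fraction", "equitoxic") for e in entries]
    equitoxic = [f == "equitoxic" for f in fracs]
    if all(equitoxic):
        ec50s = [float(e["ec50_um"]) for e in entries]
        values = equitoxic_fractions(ec50s)
    elif not any(equitoxic):
        values = [float(f) for f in fracs]
    else:
        raise DesignError("mix of numeric and 'equitoxic' fractions in one design")
    comps = tuple(
        MixtureComponent(name=str(e["name"]), fraction=float(p), crc=_component_crc(e))
        for e, p in zip(entries, values)
    )
    return MixtureDesign(components=comps, label=str(doc.get("label", "")))


def load_design(path) -> MixtureDesign:
    return design_from_dict(load_yaml(path))


def scenario_from_dict(doc: dict) -> TrueScenario:
    """Build a TrueScenario from its YAML form.

    Treatments list a label, a concentration series (must include 0) and
    components with ``fraction, ec50_um, slope, direction`` and an optional
    raw ``ceiling``.
    """
    treatments = []
    for t in doc.get("treatments") or []:
        comps = tuple(
            (float(e.get("fraction", 1.0)), _component_crc(e)) for e in t["components"]
        )
        treatments.append(
            Treatment(
                label=str(t["label"]),
                components=comps,
                concentrations=tuple(float(c) for c in t["concentrations"]),
            )
        )
    if not treatments:
        raise IngestionError("scenario lists no treatments")
    return TrueScenario(treatments=tuple(treatments))


def load_scenario(path) -> TrueScenario:
    return scenario_from_dict(load_yaml(path))
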