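"""From embryo-level coiling counts to fit-ready percent effects.

The assay records spontaneous tail coilings per minute for each embryo.
Absolute coiling frequency varies between independent experiments, so
responses are expressed as the mean percent change versus the unexposed
(concentration 0) embryos *of the same experiment*, and the per-experiment
series are then pooled for curve fitting.

Hyperactivity curves plateau at substance-specific maxima.  To put all
hyperactive substances on a common scale, percent changes are standardized
by each substance's maximal percent effect (the fitted ceiling of its raw
curve), so every standardized curve runs 0-100 and the standardized EC50 is
the raw EC at half the substance's own maximum.  Hypoactivity is expressed
as percent decrease (also 0-100 increasing); an embryo cannot coil less
than never, so decreases are capped at 100%.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dose_response import CrcDataset, Direction, LogisticCRC
from .exceptions import (
    DegenerateControlError,
    IngestionError,
    NormalizationError,
    ParameterError,
)

__all__ = [
    "RECORD_COLUMNS",
    "percent_change",
    "standardize_hyperactivity",
    "max_effect_from_fit",
    "hypoactivity_effect",
    "truncate_at_peak",
    "to_crc_dataset",
]

#: Required columns of an embryo-level record table.
RECORD_COLUMNS = (
    "substance",
    "concentration_um",
    "embryo_id",
    "stc_per_min",
    "replicate",
    "experiment",
)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if records is None or len(records) == 0:
        raise IngestionError("record table is empty")
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise IngestionError(f"record table lacks required columns: {missing}")
    if (records["stc_per_min"] < 0).any():
        raise IngestionError("stc_per_min must be non-negative")
    return records


def percent_change(records: pd.DataFrame) -> pd.DataFrame:
    """Mean percent change in coiling frequency versus control, per
    (experiment, concentration).

    ``records`` holds embryo-level rows for one substance or mixture,
    including its concentration-0 controls.  For each experiment the control
    mean is computed from its own zero-concentration rows; treated groups
    are then expressed as ``100 * (mean_treated - mean_control) /
    mean_control``.  Results from independent experiments are kept as
    separate rows (they are pooled later by fitting all points jointly).

    Returns a tidy frame with columns ``experiment, concentration_um,
    percent_change, se_percent, n_embryos``.  ``se_percent`` is the standard
    error of the treated mean on the percent-change scale (control mean
    treated as the reference constant), used by the antagonism rule.
    """
    records = _check_records(records)
    out = []
    for exp, grp in records.groupby("experiment", sort=True):
        controls = grp[grp["concentration_um"] == 0.0]["stc_per_min"]
        if controls.empty:
            raise NormalizationError(f"experiment {exp!r} has no concentration-0 controls")
        control_mean = float(controls.mean())
        if control_mean == 0.0:
            raise DegenerateControlError(
                f"experiment {exp!r} has zero mean control coiling frequency"
            )
        treated = grp[grp["concentration_um"] > 0.0]
        for conc, sub in treated.groupby("concentration_um", sort=True):
            vals = sub["stc_per_min"].to_numpy(dtype=float)
            mean_pc = 100.0 * (vals.mean() - control_mean) / control_mean
            se = (
                100.0 * vals.std(ddof=1) / np.sqrt(vals.size) / control_mean
                if vals.size > 1
                else np.nan
            )
            out.append(
                {
                    "experiment": exp,
                    "concentration_um": float(conc),
                    "percent_change": mean_pc,
                    "se_percent": se,
                    "n_embryos": int(vals.size),
                }
            )
    return pd.DataFrame(out)


def standardize_hyperactivity(percent_changes, max_effect_m: float):
    """Rescale hyperactivity percent changes so the substance maximum is 100.

    Divides each value by ``max_effect_m`` (the substance's maximal percent
    effect) and multiplies by 100.  Linear and order-preserving, so ranks of
    concentrations by effect are unchanged and the standardized EC50 is the
    raw EC at ``max_effect_m / 2``.
    """
    if not np.isfinite(max_effect_m) or max_effect_m <= 0:
        raise ParameterError(f"max_effect_m must be positive, got {max_effect_m!r}")
    vals = np.asarray(percent_changes, dtype=float)
    out = 100.0 * vals / max_effect_m
    return float(out) if out.ndim == 0 else out


def max_effect_from_fit(raw_crc: LogisticCRC) -> float:
    """Standardization divisor: the fitted ceiling of a raw hyperactivity curve.

    The fitted ceiling is preferred over the largest observed mean because
    observed maxima are single noisy points while the ceiling summarizes the
    whole curve.
    """
    if raw_crc.direction is not Direction.HYPERACTIVITY:
        raise ParameterError("standardization applies to hyperactivity curves only")
    return float(raw_crc.ceiling_d)


def hypoactivity_effect(percent_changes):
    """Map signed percent change to the hypoactivity effect scale.

    A 40% decrease (percent change -40) maps to effect 40.  Decreases beyond
    100% are impossible for a count endpoint; such values are clamped to 100
    with a warning.
    """
    vals = -np.asarray(percent_changes, dtype=float)
    if np.any(vals > 100.0):
        warnings.warn(
            "hypoactivity beyond 100% decrease clamped at 100", RuntimeWarning, stacklevel=2
        )
        vals = np.minimum(vals, 100.0)
    return float(vals) if vals.ndim == 0 else vals


def truncate_at_peak(normalized: pd.DataFrame) -> pd.DataFrame:
    """Drop concentrations above the maximal mean response.

    Biphasic single-substance data (hyperactivity followed by a decline,
    plausibly paralysis) are truncated at the concentration of maximal mean
    percent change before the monotone hyperactivity curve is fitted; the
    declining limb is the business of the antagonism module.
    """
    means = (
        normalized.groupby("concentration_um", sort=True)["percent_change"].mean()
    )
    peak_conc = float(means.idxmax())
    return normalized[normalized["concentration_um"] <= peak_conc].copy()


def to_crc_dataset(
    normalized: pd.DataFrame,
    direction: Direction,
    max_effect_m: float | None = None,
    label: str = "",
) -> CrcDataset:
    """Assemble the fit-ready dataset from a normalized table.

    Hyperactivity values are standardized by ``max_effect_m`` when given
    (otherwise left raw, for the free-ceiling fit that determines the
    divisor); hypoactivity values are sign-flipped to percent decrease.
    Points from all experiments are pooled.
    """
    direction = Direction(direction)
    conc = normalized["concentration_um"].to_numpy(dtype=float)
    pc = normalized["percent_change"].to_numpy(dtype=float)
    if direction is Direction.HYPOACTIVITY:
        eff = hypoactivity_effect(pc)
    elif max_effect_m is not None:
        eff = standardize_hyperactivity(pc, max_effect_m)
    else:
        eff = pc
    return CrcDataset(concentrations=conc, effects=eff, label=label)
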