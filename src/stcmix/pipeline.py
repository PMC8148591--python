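"""End-to-end orchestration: ingest/simulate -> normalize -> fit -> predict -> compare.

The pipeline is deterministic under a fixed seed, and every stage's output
table is a valid input for the next stage.  Per design it produces the CA
and IA prediction curves and EC50s; where observed records exist for a
design label it also fits the observed curve and reports the
predicted/observed EC50 ratio (the informal field benchmark being that
predictions within a factor of 2 count as predictive - printed as context,
not enforced).  Mixed-direction designs are routed to the antagonism
module, with the additive reference built from the same-direction subset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .antagonism import assess_antagonism
from .dose_response import Direction, estimate_ec, fit_ll4
from .exceptions import StcmixError
from .io import design_from_dict, load_yaml, read_records, write_table
from .mixtures import (
    DEFAULT_EFFECT_GRID,
    MixtureComponent,
    MixtureDesign,
    ca_curve,
    ia_curve,
)
from .normalization import (
    max_effect_from_fit,
    percent_change,
    to_crc_dataset,
    truncate_at_peak,
)

__all__ = ["RunConfig", "run_pipeline", "fit_observed"]

log = logging.getLogger("stcmix")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run (round-trips through YAML)."""

    outdir: str
    designs: tuple[dict, ...]
    records: str | None = None
    effect_grid: tuple[float, ...] = tuple(DEFAULT_EFFECT_GRID)
    ci_multiplier: float = 2.0
    antagonism_n_consecutive: int = 2
    antagonism_se_multiplier: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = load_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        doc = {k: v for k, v in doc.items() if k in known}
        if "designs" in doc:
            doc["designs"] = tuple(doc["designs"])
        if "effect_grid" in doc:
            doc["effect_grid"] = tuple(float(x) for x in doc["effect_grid"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["designs"] = list(d["designs"])
        d["effect_grid"] = [float(x) for x in d["effect_grid"]]
        return d


def fit_observed(records: pd.DataFrame, direction: Direction, label: str = ""):
    """Normalize and fit observed records for one substance or mixture.

    Hyperactivity data are truncated at the peak mean response, fitted with
    a free ceiling to obtain the standardization divisor, standardized, and
    refitted on the fixed 0-100 scale.  Hypoactivity data are sign-flipped
    to percent decrease and fitted on the fixed scale directly.

    Returns ``(standardized_crc, normalized_table, max_effect_m)``.
    """
    norm = percent_change(records)
    direction = Direction(direction)
    if direction is Direction.HYPERACTIVITY:
        trunc = truncate_at_peak(norm)
        raw = fit_ll4(
            to_crc_dataset(trunc, direction, label=label),
            fix_ceiling=False,
            direction=direction,
        )
        m = max_effect_from_fit(raw)
        crc = fit_ll4(
            to_crc_dataset(trunc, direction, max_effect_m=m, label=label),
            direction=direction,
        )
        return crc, norm, m
    crc = fit_ll4(to_crc_dataset(norm, direction, label=label), direction=direction)
    return crc, norm, 100.0


def _same_direction_subset(design: MixtureDesign) -> tuple[MixtureDesign, Direction]:
    """Majority-direction subset of a mixed design, fractions renormalized."""
    counts = {d: 0.0 for d in design.directions}
    for c in design.components:
        counts[c.direction] += c.fraction
    keep = max(counts, key=counts.get)
    comps = [c for c in design.components if c.direction is keep]
    total = sum(c.fraction for c in comps)
    comps = tuple(
        MixtureComponent(c.name, c.fraction / total, c.crc) for c in comps
    )
    return MixtureDesign(comps, label=f"{design.label}|{keep.value}-subset"), keep


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact tables under ``config.outdir``.

    Returns a dict of output paths keyed by artifact name.  Any stage error
    is re-raised as a ``StcmixError`` with a stage-labeled message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logfile = outdir / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    log.info("stcmix %s | config sha256:%s | seed %d", __version__, cfg_hash, config.seed)

    artifacts: dict[str, Path] = {"log": logfile}
    grid = np.asarray(config.effect_grid, dtype=float)

    records = None
    if config.records is not None:
        try:
            records = read_records(config.records)
        except StcmixError as err:
            log.error("ingest: %s", err)
            raise
        log.info("ingest: %d embryo records from %s", len(records), config.records)

    comparison_rows = []
    for doc in config.designs:
        try:
            design = design_from_dict(doc)
        except StcmixError as err:
            raise type(err)(f"design stage ({doc.get('label')!r}): {err}") from err
        label = design.label or "design"
        mixed = len(design.directions) > 1

        obs = None
        if records is not None:
            sub = records[records["substance"] == label]
            if not sub.empty:
                obs = sub

        if mixed:
            ref_design, ref_dir = _same_direction_subset(design)
            reference = ca_curve(ref_design, grid)
            write_table(
                pd.DataFrame(
                    {
                        "model": "CA",
                        "concentration_um": reference.concentrations,
                        "effect_percent": reference.effects,
                    }
                ),
                outdir / f"reference_{label}.csv",
            )
            artifacts[f"reference_{label}"] = outdir / f"reference_{label}.csv"
            if obs is not None:
                norm = percent_change(obs)
                report = assess_antagonism(
                    norm,
                    reference,
                    n_consecutive=config.antagonism_n_consecutive,
                    se_multiplier=config.antagonism_se_multiplier,
                )
                path = write_table(
                    pd.DataFrame([dataclasses.asdict(report)]),
                    outdir / f"antagonism_{label}.csv",
                )
                artifacts[f"antagonism_{label}"] = path
                log.info("antagonism %s: verdict=%s", label, report.verdict)
            continue

        ca = ca_curve(design, grid)
        ia = ia_curve(design, grid)
        pred = pd.concat(
            [
                pd.DataFrame(
                    {
                        "model": m.model,
                        "concentration_um": m.concentrations,
                        "effect_percent": m.effects,
                    }
                )
                for m in (ca, ia)
            ]
        )
        path = write_table(pred, outdir / f"predictions_{label}.csv")
        artifacts[f"predictions_{label}"] = path
        row = {
            "design": label,
            "direction": next(iter(design.directions)).value,
            "ca_ec50_um": ca.predicted_ec50,
            "ia_ec50_um": ia.predicted_ec50,
            "observed_ec50_um": np.nan,
            "ca_ratio": np.nan,
            "ia_ratio": np.nan,
        }
        if obs is not None:
            direction = next(iter(design.directions))
            crc, norm, m = fit_observed(obs, direction, label=label)
            write_table(norm, outdir / f"normalized_{label}.csv")
            artifacts[f"normalized_{label}"] = outdir / f"normalized_{label}.csv"
            ec = estimate_ec(50.0, crc, ci_multiplier=config.ci_multiplier)
            row["observed_ec50_um"] = ec.concentration
            row["ca_ratio"] = ca.predicted_ec50 / ec.concentration
            row["ia_ratio"] = ia.predicted_ec50 / ec.concentration
        comparison_rows.append(row)
        log.info(
            "predict %s: CA EC50=%.4g IA EC50=%.4g", label, ca.predicted_ec50, ia.predicted_ec50
        )

    if comparison_rows:
        comp = pd.DataFrame(comparison_rows)
        path = write_table(comp, outdir / "comparison.csv")
        artifacts["comparison"] = path
        log.info(
            "comparison written; predictive benchmark context: ratios within a "
            "factor of 2 are conventionally called predictive"
        )

    log.removeHandler(handler)
    handler.close()
    return {k: str(v) for k, v in artifacts.items()}
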