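"""Seeded generator of synthetic embryo-level coiling datasets.

Emulates the experimental structure of the assay: 20 embryos per dish, 2
replicate dishes per concentration, at least 2 independent experiments, and
control dishes at concentration 0.  Per-embryo coilings-per-minute counts
are drawn from a negative binomial (Poisson when the dispersion is 0) whose
mean follows the scenario's true concentration-response:

    mean = baseline * prod_hyper (1 + h_i(p_i c)/100) * prod_hypo (1 - k_i(p_i c)/100)

so hyperactive components raise and hypoactive components depress the
control rate, combined multiplicatively for opposing-direction mixtures.
Experiment-to-experiment baseline variation is lognormal.  Small-integer
counts with across-embryo overdispersion and a control rate of about 6
coils per minute are the declared noise model; the assay literature does
not pin these down, so the defaults are configuration, not measurement.

Identical seed and configuration give a byte-for-byte identical dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import Direction, LogisticCRC, ll4_effect
from .exceptions import ParameterError

__all__ = [
    "GeneratorConfig",
    "Treatment",
    "TrueScenario",
    "mean_multiplier",
    "simulate_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic assay.

    ``baseline_stc`` is the control coiling rate (coils/min), ``dispersion``
    the negative-binomial overdispersion a in var = mu + a*mu^2 (0 gives
    Poisson), ``experiment_effect_sd`` the lognormal sigma of the
    between-experiment baseline multiplier.  ``seed`` is mandatory.
    """

    seed: int
    baseline_stc: float = 6.0
    dispersion: float = 0.05
    n_embryos_per_dish: int = 20
    n_replicates: int = 2
    n_experiments: int = 2
    experiment_effect_sd: float = 0.15

    def __post_init__(self):
        if self.baseline_stc <= 0:
            raise ParameterError("baseline_stc must be positive")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        for name in ("n_embryos_per_dish", "n_replicates", "n_experiments"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        if self.experiment_effect_sd < 0:
            raise ParameterError("experiment_effect_sd must be >= 0")
        if self.seed is None:
            raise ParameterError("seed is mandatory for reproducibility")


@dataclass(frozen=True)
class Treatment:
    """One exposure series: a substance or mixture with its true curves.

    ``components`` are ``(molar_fraction, LogisticCRC)`` pairs on the raw
    percent-change scale (hyperactivity ceilings may sit below 100); a
    single substance is one component with fraction 1.  ``concentrations``
    are total concentrations in umol/L and must include 0 (controls).
    """

    label: str
    components: tuple[tuple[float, LogisticCRC], ...]
    concentrations: tuple[float, ...]

    def __post_init__(self):
        if 0.0 not in self.concentrations:
            raise ParameterError(
                f"treatment {self.label!r} must include concentration 0 (controls)"
            )
        total = sum(f for f, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"component fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class TrueScenario:
    """The ground truth a synthetic study is generated from."""

    treatments: tuple[Treatment, ...]


def mean_multiplier(treatment: Treatment, conc: float) -> float:
    """True multiplier on the baseline rate at total concentration ``conc``.

    Hyper- and hypoactive components act multiplicatively on the mean;
    the result is clamped at 0 (a count rate cannot be negative).
    """
    m = 1.0
    for fraction, crc in treatment.components:
        eff = float(ll4_effect(fraction * conc, crc))
        if crc.direction is Direction.HYPERACTIVITY:
            m *= 1.0 + eff / 100.0
        else:
            m *= 1.0 - eff / 100.0
    if m < 0.0:
        warnings.warn(
            f"true mean below zero at {conc} umol/L; clamped to 0", RuntimeWarning, stacklevel=2
        )
        m = 0.0
    return m


def _draw_counts(rng: np.random.Generator, mu: float, dispersion: float, size: int) -> np.ndarray:
    if mu <= 0:
        return np.zeros(size, dtype=int)
    if dispersion == 0:
        return rng.poisson(mu, size=size)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def simulate_dataset(scenario: TrueScenario, config: GeneratorConfig) -> pd.DataFrame:
    """Generate the embryo-level record table for a scenario.

    Returns a frame with the columns the normalization stage expects:
    substance, concentration_um, embryo_id, stc_per_min, replicate,
    experiment.  Deterministic for a given (scenario, config).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for treatment in scenario.treatments:
        for exp_idx in range(1, config.n_experiments + 1):
            exp_baseline = config.baseline_stc * float(
                rng.lognormal(mean=0.0, sigma=config.experiment_effect_sd)
            )
            for conc in treatment.concentrations:
                mu = exp_baseline * mean_multiplier(treatment, float(conc))
                for rep_idx in range(1, config.n_replicates + 1):
                    counts = _draw_counts(
                        rng, mu, config.dispersion, config.n_embryos_per_dish
                    )
                    for k, count in enumerate(counts, start=1):
                        rows.append(
                            (
                                treatment.label,
                                float(conc),
                                f"{treatment.label}|E{exp_idx}|c{conc:g}|r{rep_idx}|{k:02d}",
                                float(count),
                                f"r{rep_idx}",
                                f"E{exp_idx}",
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "substance",
            "concentration_um",
            "embryo_id",
            "stc_per_min",
            "replicate",
            "experiment",
        ],
    )
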