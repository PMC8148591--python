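"""Concentration-addition and independent-action mixture prediction.

Concentration addition (Loewe additivity) treats mixture components as
dilutions of one another and predicts the total concentration provoking x%
effect from the components' single-substance ECx values:

    ECx_mix = ( sum_i  p_i / ECx_i )**-1

with p_i the molar fraction of component i.  Independent action (Bliss
independence) combines fractional effects instead:

    E_mix(C) = 1 - prod_i (1 - E_i(p_i * C))

Both operate on standardized curves (floor 0, ceiling 100) so that every
component can reach every effect level; predicting on raw unequal-maximum
curves would leave effects above the weakest component's ceiling undefined.

An *equitoxic* design mixes components in proportion to their EC50s, so each
contributes equal toxic units (concentration / EC50) at any total
concentration.  For such designs CA has the closed form
EC50_mix = (sum_i EC50_i) / n, used here as an independent oracle in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dose_response import Direction, LogisticCRC, ll4_effect, ll4_inverse
from .exceptions import DesignError, DomainError, MixedDirectionError, ParameterError

__all__ = [
    "MixtureComponent",
    "MixtureDesign",
    "PredictionCurve",
    "equitoxic_fractions",
    "equitoxic_design",
    "ca_ecx",
    "ca_curve",
    "ia_effect",
    "ia_ecx",
    "ia_curve",
    "substitution_design",
    "DEFAULT_EFFECT_GRID",
]

#: Default effect grid for prediction curves: 1..99% in 1% steps.
DEFAULT_EFFECT_GRID = np.arange(1.0, 100.0)

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class MixtureComponent:
    """One substance in a mixture: name, molar fraction and its curve."""

    name: str
    fraction: float
    crc: LogisticCRC

    def __post_init__(self):
        if not (np.isfinite(self.fraction) and 0.0 < self.fraction <= 1.0):
            raise DesignError(f"fraction of {self.name!r} must lie in (0, 1], got {self.fraction}")

    @property
    def direction(self) -> Direction:
        return self.crc.direction

    @property
    def ec50(self) -> float:
        return ll4_inverse((self.crc.floor_c + self.crc.ceiling_d) / 2.0, self.crc)


@dataclass(frozen=True)
class MixtureDesign:
    """A named mixture: components with molar fractions summing to 1.

    ``parent_scale`` records, for designs derived by toxic-unit-conserving
    substitution, how many moles of the derived mixture correspond to one
    mole of the parent mixture (1.0 for designs built directly).
    """

    components: tuple[MixtureComponent, ...]
    label: str = ""
    parent_scale: float = 1.0

    def __post_init__(self):
        comps = tuple(self.components)
        if len(comps) < 1:
            raise DesignError("a mixture design needs at least one component")
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise DesignError(f"component names must be unique, got {names}")
        total = sum(c.fraction for c in comps)
        if abs(total - 1.0) > _FRACTION_TOL:
            raise DesignError(f"molar fractions must sum to 1, got {total!r}")
        object.__setattr__(self, "components", comps)

    @property
    def directions(self) -> set[Direction]:
        return {c.direction for c in self.components}

    def fractions_by_name(self) -> dict[str, float]:
        return {c.name: c.fraction for c in self.components}

    def component(self, name: str) -> MixtureComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise DesignError(f"no component named {name!r} in design {self.label!r}")


@dataclass(frozen=True)
class PredictionCurve:
    """CA or IA prediction over a concentration grid, plus the EC50."""

    model: str  # "CA" or "IA"
    concentrations: np.ndarray
    effects: np.ndarray
    predicted_ec50: float

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        eff = np.asarray(self.effects, dtype=float)
        if np.any(np.diff(conc) <= 0):
            raise ParameterError("grid concentrations must be strictly increasing")
        if np.any(np.diff(eff) < 0):
            raise ParameterError("predicted effects must be non-decreasing along the grid")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "effects", eff)

    def effect_at(self, x):
        """Predicted effect at concentration ``x`` by log-linear interpolation."""
        return np.interp(
            np.log10(np.asarray(x, dtype=float)),
            np.log10(self.concentrations),
            self.effects,
        )


def _require_same_direction(design: MixtureDesign, model: str) -> None:
    if len(design.directions) > 1:
        raise MixedDirectionError(
            f"{model} prediction requires components with a common effect direction; "
            f"design {design.label!r} mixes hyper- and hypoactivity - evaluate it with "
            "the antagonism module instead"
        )


def _warn_if_unstandardized(design: MixtureDesign) -> None:
    for c in design.components:
        if not (abs(c.crc.floor_c) < 1e-12 and abs(c.crc.ceiling_d - 100.0) < 1e-9):
            warnings.warn(
                f"component {c.name!r} has a raw curve (floor {c.crc.floor_c}, ceiling "
                f"{c.crc.ceiling_d}); mixture prediction on unequal maxima is unreliable - "
                "standardize curves to a 0-100 scale first (standardize_hyperactivity)",
                RuntimeWarning,
                stacklevel=3,
            )


def equitoxic_fractions(ec50s) -> np.ndarray:
    """Molar fractions proportional to the components' EC50s.

    p_i = EC50_i / sum_j EC50_j, so each component contributes equal toxic
    units at any total concentration.
    """
    ec50s = np.asarray(ec50s, dtype=float)
    if np.any(~np.isfinite(ec50s)) or np.any(ec50s <= 0):
        raise ParameterError(f"EC50s must be positive, got {ec50s}")
    return ec50s / ec50s.sum()


def equitoxic_design(named_crcs, label: str = "") -> MixtureDesign:
    """Build the equitoxic design from ``(name, LogisticCRC)`` pairs."""
    named_crcs = list(named_crcs)
    ec50s = [
        ll4_inverse((crc.floor_c + crc.ceiling_d) / 2.0, crc) for _, crc in named_crcs
    ]
    fracs = equitoxic_fractions(ec50s)
    comps = tuple(
        MixtureComponent(name=name, fraction=float(p), crc=crc)
        for (name, crc), p in zip(named_crcs, fracs)
    )
    return MixtureDesign(components=comps, label=label)


def ca_ecx(level_x: float, design: MixtureDesign) -> float:
    """Concentration-addition ECx: harmonic combination of component ECx values."""
    if not 0.0 < level_x < 100.0:
        raise ParameterError(f"effect level must lie in (0, 100), got {level_x}")
    _require_same_direction(design, "CA")
    _warn_if_unstandardized(design)
    total = 0.0
    for c in design.components:
        target = c.crc.floor_c + (c.crc.ceiling_d - c.crc.floor_c) * level_x / 100.0
        try:
            ecx = ll4_inverse(target, c.crc)
        except DomainError as err:
            raise DomainError(
                f"effect level {level_x}% is unreachable for component {c.name!r}"
            ) from err
        total += c.fraction / ecx
    return 1.0 / total


def ca_curve(design: MixtureDesign, effect_grid=None) -> PredictionCurve:
    """CA prediction curve over an effect grid (default 1..99%)."""
    grid = DEFAULT_EFFECT_GRID if effect_grid is None else np.asarray(effect_grid, dtype=float)
    conc = np.array([ca_ecx(x, design) for x in grid])
    return PredictionCurve("CA", conc, grid, predicted_ec50=ca_ecx(50.0, design))


def ia_effect(total_c, design: MixtureDesign):
    """Independent-action effect (percent) at total concentration ``total_c``.

    Each component sees its partial concentration p_i * C; fractional effects
    E_i in [0, 1) combine as 1 - prod(1 - E_i).
    """
    _require_same_direction(design, "IA")
    _warn_if_unstandardized(design)
    total_c = np.asarray(total_c, dtype=float)
    surv = np.ones_like(total_c, dtype=float)
    for c in design.components:
        frac_effect = (
            np.asarray(ll4_effect(c.fraction * total_c, c.crc), dtype=float) - c.crc.floor_c
        ) / (c.crc.ceiling_d - c.crc.floor_c)
        surv = surv * (1.0 - frac_effect)
    out = 100.0 * (1.0 - surv)
    return float(out) if out.ndim == 0 else out


def ia_ecx(level_x: float, design: MixtureDesign, rtol: float = 1e-8) -> float:
    """Total concentration at which the IA effect equals ``level_x`` percent.

    ``ia_effect`` is monotone in concentration, so the root is found by
    bracketing and Brent's method.  The initial bracket spans three decades
    below the smallest partial EC50 to three decades above the largest
    fraction-scaled EC50, expanded geometrically if necessary.
    """
    if not 0.0 < level_x < 100.0:
        raise ParameterError(f"effect level must lie in (0, 100), got {level_x}")
    _require_same_direction(design, "IA")
    ec50s = np.array([c.ec50 for c in design.components])
    fracs = np.array([c.fraction for c in design.components])
    lo = float(np.min(ec50s * fracs)) / 1e3
    hi = float(np.max(ec50s / fracs)) * 1e3

    f = lambda c: ia_effect(c, design) - level_x
    for _ in range(200):
        if f(lo) < 0:
            break
        lo /= 10.0
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 10.0
    else:
        raise DomainError(
            f"IA effect never reaches {level_x}% (asymptotic maximum too low)"
        )
    if f(hi) <= 0:
        raise DomainError(f"IA effect never reaches {level_x}%")
    return float(brentq(f, lo, hi, rtol=rtol))


def ia_curve(design: MixtureDesign, effect_grid=None) -> PredictionCurve:
    """IA prediction curve over an effect grid (default 1..99%)."""
    grid = DEFAULT_EFFECT_GRID if effect_grid is None else np.asarray(effect_grid, dtype=float)
    conc = np.array([ia_ecx(x, design) for x in grid])
    return PredictionCurve("IA", conc, grid, predicted_ec50=ia_ecx(50.0, design))


def substitution_design(
    design: MixtureDesign,
    replace: str,
    substitute: MixtureComponent | tuple[str, LogisticCRC],
    portion: float = 0.5,
    conserve: str = "share",
) -> MixtureDesign:
    """Replace part of one component with an EC50-equitoxic amount of another.

    Two conserving conventions are offered:

    ``conserve="share"`` (default)
        The replaced component's molar share stays fixed and is split between
        the old and the new substance with toxic-unit weights ``(1 - portion,
        portion)``, i.e. moles proportional to ``((1 - portion) * EC50_old,
        portion * EC50_new)``.  With ``portion = 0.5`` the pair inside the
        share is exactly equitoxic.  Fractions still sum to 1 with no
        renormalization; the molar CA EC50 of the design changes because the
        newcomer carries different potency per mole.

    ``conserve="toxic_units"``
        The toxic units removed from the old component (``portion`` of its
        ``p / EC50``) are added back as the new substance (moles = removed
        toxic units x EC50_new); fractions are renormalized to sum 1 and the
        molar inflation factor is recorded in ``parent_scale``.  Total toxic
        units per parent-equivalent mole are conserved, so the CA-predicted
        EC50 expressed in parent units - ``ca_ecx(50, new) / parent_scale`` -
        is exactly that of the parent design (the dilution-of-each-other
        identity of concentration addition).
    """
    if not 0.0 < portion <= 1.0:
        raise ParameterError(f"portion must lie in (0, 1], got {portion}")
    old = design.component(replace)  # raises DesignError if absent
    if isinstance(substitute, tuple):
        new_name, new_crc = substitute
    else:
        new_name, new_crc = substitute.name, substitute.crc
    if new_name != replace and new_name in design.fractions_by_name():
        raise DesignError(f"substitute {new_name!r} already present in design")
    ec50_old, ec50_new = old.ec50, ll4_inverse(
        (new_crc.floor_c + new_crc.ceiling_d) / 2.0, new_crc
    )

    others = [c for c in design.components if c.name != replace]
    if conserve == "share":
        w_old = (1.0 - portion) * ec50_old
        w_new = portion * ec50_new
        share = old.fraction
        p_old = share * w_old / (w_old + w_new)
        p_new = share * w_new / (w_old + w_new)
        scale = design.parent_scale
    elif conserve == "toxic_units":
        removed_tu = portion * old.fraction / ec50_old
        p_old = old.fraction * (1.0 - portion)
        p_new = removed_tu * ec50_new
        total = sum(c.fraction for c in others) + p_old + p_new
        p_old /= total
        p_new /= total
        others = [MixtureComponent(c.name, c.fraction / total, c.crc) for c in others]
        scale = design.parent_scale * total
    else:
        raise ParameterError(f"unknown conserve mode {conserve!r}")

    comps = list(others)
    if p_old > 0:
        comps.append(MixtureComponent(replace, p_old, old.crc))
    comps.append(MixtureComponent(new_name, p_new, new_crc))
    # keep original ordering where possible: replaced slot keeps its place
    ordered = []
    for c in design.components:
        if c.name == replace:
            if p_old > 0:
                ordered.append(MixtureComponent(replace, p_old, old.crc))
            ordered.append(MixtureComponent(new_name, p_new, new_crc))
        else:
            match = next(x for x in comps if x.name == c.name)
            ordered.append(match)
    label = f"{design.label}|{replace}->{new_name}({portion:g},{conserve})"
    return MixtureDesign(components=tuple(ordered), label=label, parent_scale=scale)
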