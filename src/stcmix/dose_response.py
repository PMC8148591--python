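"""Four-parameter log-logistic concentration-response modelling.

The concentration-response model used throughout the package is the LL.4
curve

    y(x) = c + (d - c) / (1 + (e / x)**b)

with slope ``b > 0``, floor ``c``, ceiling ``d`` and inflection ``e`` (the
EC50 whenever ``c = 0`` and ``d = 100``).  With the ``(e/x)**b``
parameterization the curve is strictly increasing in concentration for any
``b > 0``; hypoactivity responses are therefore modelled as percent
*decrease* from control (also running 0 -> 100), with the effect direction
kept as a reporting flag.

Confidence intervals follow the convention used for the underlying assay:
CI = estimate +/- 2 * SE, with the standard error propagated from the local
curvature of the least-squares objective.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateDataError, DomainError, FitError, ParameterError

__all__ = [
    "Direction",
    "LogisticCRC",
    "CrcDataset",
    "EcEstimate",
    "ll4_effect",
    "ll4_inverse",
    "fit_ll4",
    "estimate_ec",
]

#: CI half-width is this many standard errors.
CI_SE_MULTIPLIER = 2.0


class Direction(str, enum.Enum):
    """Effect direction of a substance in the tail-coiling assay."""

    HYPERACTIVITY = "hyperactivity"
    HYPOACTIVITY = "hypoactivity"


@dataclass(frozen=True)
class LogisticCRC:
    """A fitted (or specified) 4-parameter log-logistic curve.

    Parameters
    ----------
    slope_b
        Hill-type slope, dimensionless, > 0.
    inflection_e
        Inflection concentration in umol/L (> 0); equals the EC50 when the
        floor is 0 and the ceiling 100.
    floor_c, ceiling_d
        Minimum and maximum percent effect. On the standardized scale these
        are fixed at 0 and 100; raw hyperactivity curves may have a ceiling
        below 100.
    se_inflection
        Standard error of ``inflection_e`` in umol/L, if known.
    direction
        Whether the curve describes a coiling-frequency increase or decrease.
    """

    slope_b: float
    inflection_e: float
    floor_c: float = 0.0
    ceiling_d: float = 100.0
    se_inflection: float | None = None
    se_slope: float | None = None
    se_ceiling: float | None = None
    direction: Direction = Direction.HYPERACTIVITY

    def __post_init__(self):
        if not (np.isfinite(self.slope_b) and self.slope_b > 0):
            raise ParameterError(f"slope_b must be positive, got {self.slope_b!r}")
        if not (np.isfinite(self.inflection_e) and self.inflection_e > 0):
            raise ParameterError(
                f"inflection_e must be a positive concentration, got {self.inflection_e!r}"
            )
        if not self.floor_c < self.ceiling_d:
            raise ParameterError(
                f"floor_c ({self.floor_c}) must lie below ceiling_d ({self.ceiling_d})"
            )
        object.__setattr__(self, "direction", Direction(self.direction))

    @property
    def ec50(self) -> float:
        """Concentration at half-maximal effect, (c + d)/2 on the percent scale."""
        return self.inflection_e


@dataclass(frozen=True)
class CrcDataset:
    """Per-concentration responses ready for curve fitting.

    ``concentrations`` are in umol/L; ``effects`` are percent effect on the
    direction-specific scale (hyperactivity percent change or hypoactivity
    percent decrease).  Control (zero-concentration) observations are
    consumed upstream by normalization and must not appear here.
    """

    concentrations: np.ndarray
    effects: np.ndarray
    label: str = ""

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        eff = np.asarray(self.effects, dtype=float)
        if conc.shape != eff.shape or conc.ndim != 1:
            raise ParameterError("concentrations and effects must be equal-length 1-D arrays")
        if not np.all(np.isfinite(conc)) or np.any(conc < 0):
            raise ParameterError("concentrations must be finite and non-negative")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "effects", eff)

    @property
    def n_distinct_nonzero(self) -> int:
        return int(np.unique(self.concentrations[self.concentrations > 0]).size)


@dataclass(frozen=True)
class EcEstimate:
    """An ECx estimate with its +/- 2 SE confidence interval (umol/L)."""

    level_x: float
    concentration: float
    ci_low: float
    ci_high: float
    se: float | None = None


def ll4_effect(x, crc: LogisticCRC):
    """Evaluate the LL.4 curve at concentration ``x`` (umol/L).

    Returns the floor at ``x = 0``; strictly increasing for ``x > 0``.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("concentration must be non-negative")
    out = np.full(x.shape, crc.floor_c, dtype=float)
    pos = x > 0
    out[pos] = crc.floor_c + (crc.ceiling_d - crc.floor_c) / (
        1.0 + (crc.inflection_e / x[pos]) ** crc.slope_b
    )
    return float(out) if out.ndim == 0 else out


def ll4_inverse(y, crc: LogisticCRC):
    """Concentration at which the curve reaches percent effect ``y``.

    Closed form: ``x = e * ((y - c)/(d - y))**(1/b)``.  Defined only strictly
    between the floor and the ceiling; outside that open interval the curve
    never attains ``y`` (concentration-addition predictions are undefined
    there as well).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= crc.floor_c) or np.any(y >= crc.ceiling_d):
        raise DomainError(
            f"effect level {y} outside the open response range "
            f"({crc.floor_c}, {crc.ceiling_d}) of the curve"
        )
    x = crc.inflection_e * ((y - crc.floor_c) / (crc.ceiling_d - y)) ** (1.0 / crc.slope_b)
    return float(x) if x.ndim == 0 else x


def _residual_factory(conc, eff, fix_floor, fix_ceiling, c0, d0):
    logx = np.log10(conc)

    def unpack(theta):
        b = theta[0]
        log_e = theta[1]
        i = 2
        c = c0
        d = d0
        if not fix_floor:
            c = theta[i]
            i += 1
        if not fix_ceiling:
            d = theta[i]
        return b, log_e, c, d

    def resid(theta):
        b, log_e, c, d = unpack(theta)
        # (e/x)^b on log10 scale for conditioning
        pred = c + (d - c) / (1.0 + 10.0 ** (b * (log_e - logx)))
        return pred - eff

    return resid, unpack


def fit_ll4(
    data: CrcDataset,
    fix_floor: bool = True,
    fix_ceiling: bool = True,
    floor: float = 0.0,
    ceiling: float = 100.0,
    direction: Direction = Direction.HYPERACTIVITY,
) -> LogisticCRC:
    """Least-squares fit of the LL.4 model.

    By default the floor and ceiling are fixed at 0 and 100 (the standardized
    scale) and only the slope and inflection are free.  Raw hyperactivity
    curves are fitted with ``fix_ceiling=False`` so the fitted maximum can be
    used as the standardization divisor.

    The fit runs on log10 concentration internally and uses three starts for
    the inflection (geometric mean of the tested concentrations, x0.1, x10)
    to avoid local minima.  Standard errors come from the Gauss-Newton
    approximation of the Hessian at the optimum.
    """
    conc = data.concentrations
    eff = data.effects
    if np.any(conc <= 0):
        raise ParameterError(
            "fit_ll4 expects strictly positive concentrations; "
            "control observations are consumed by normalization"
        )
    if data.n_distinct_nonzero < 4:
        raise DegenerateDataError(
            f"need at least 4 distinct nonzero concentrations, got {data.n_distinct_nonzero}"
        )
    if np.allclose(eff, 0.0):
        raise DegenerateDataError("all responses are zero; no curve to fit")

    resid, unpack = _residual_factory(conc, eff, fix_floor, fix_ceiling, floor, ceiling)

    geo = float(np.exp(np.mean(np.log(conc))))
    starts = []
    d_start = ceiling if fix_ceiling else max(float(np.max(eff)), 1.0)
    for e0 in (geo, geo * 0.1, geo * 10.0):
        theta0 = [1.0, math.log10(e0)]
        if not fix_floor:
            theta0.append(min(float(np.min(eff)), 0.0))
        if not fix_ceiling:
            theta0.append(d_start)
        starts.append(np.asarray(theta0))

    # box constraints keep the search away from degenerate curves: slope in
    # [0.05, 50], inflection within 3 decades of the tested range, ceiling
    # (when free) below 10x the largest observed response
    logx_lo = math.log10(conc.min()) - 3.0
    logx_hi = math.log10(conc.max()) + 3.0
    lo = [0.05, logx_lo]
    hi = [50.0, logx_hi]
    if not fix_floor:
        lo.append(-1000.0)
        hi.append(float(np.max(eff)))
    if not fix_ceiling:
        lo.append(float(np.min(eff)))
        hi.append(max(10.0 * float(np.max(np.abs(eff))), 100.0))
    best = last = None
    for theta0 in starts:
        theta0 = np.clip(theta0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
        sol = least_squares(
            resid, theta0, bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        last = sol
        if sol.success and (best is None or sol.cost < best.cost - 1e-12):
            best = sol
    if best is None:
        raise FitError(
            "LL.4 fit did not converge",
            diagnostics={
                "last_iterate": None if last is None else last.x.tolist(),
                "status": None if last is None else last.status,
            },
        )

    b, log_e, c, d = unpack(best.x)
    if b <= 0 or not np.isfinite(log_e):
        raise FitError("LL.4 fit converged to an invalid parameter set",
                       diagnostics={"theta": best.x.tolist()})
    e = 10.0 ** log_e

    # Gauss-Newton covariance: sigma^2 (J'J)^-1 with sigma^2 = RSS / (n - p)
    n, p = conc.size, best.x.size
    se = np.full(p, np.nan)
    if n > p:
        rss = 2.0 * best.cost
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (n - p)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            pass
    se_b = float(se[0]) if np.isfinite(se[0]) else None
    # delta method: theta is log10(e), so SE(e) = e * ln(10) * SE(log10 e)
    se_e = float(e * math.log(10.0) * se[1]) if np.isfinite(se[1]) else None
    se_d = None
    if not fix_ceiling:
        idx = 2 if fix_floor else 3
        se_d = float(se[idx]) if np.isfinite(se[idx]) else None

    return LogisticCRC(
        slope_b=float(b),
        inflection_e=float(e),
        floor_c=float(c),
        ceiling_d=float(d),
        se_inflection=se_e,
        se_slope=se_b,
        se_ceiling=se_d,
        direction=direction,
    )


def estimate_ec(level_x: float, crc: LogisticCRC, ci_multiplier: float = CI_SE_MULTIPLIER) -> EcEstimate:
    """ECx with a +/- ``ci_multiplier`` * SE confidence interval.

    ``level_x`` is a percent of the curve's own span: the target response is
    ``c + (d - c) * x / 100``, so EC50 equals the inflection whatever the
    ceiling.  Because ECx is proportional to the inflection for fixed slope,
    the delta method gives SE(ECx) = ECx / e * SE(e).
    """
    if not 0.0 < level_x < 100.0:
        raise ParameterError(f"effect level must lie in (0, 100), got {level_x}")
    target = crc.floor_c + (crc.ceiling_d - crc.floor_c) * level_x / 100.0
    conc = ll4_inverse(target, crc)
    if crc.se_inflection is None:
        return EcEstimate(level_x, conc, conc, conc, se=None)
    se = conc / crc.inflection_e * crc.se_inflection
    half = ci_multiplier * se
    return EcEstimate(level_x, conc, conc - half, conc + half, se=se)
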