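"""Opposing-direction mixtures: biphasic fits and antagonism calls.

CA and IA cannot describe a mixture whose components push coiling frequency
in opposite directions.  Antagonism is therefore defined here as a
*counteracting* effect: the observed response of the full mixture falls
below the additive expectation built from its same-direction subset, and may
even flip sign (hyperactivity giving way to net hypoactivity at high
concentration, where a low-EC50 suppressing component dominates).

The rise-then-fall response is summarized by a Gaussian on log10
concentration,

    response(c) = baseline + amplitude * exp(-(log10 c - center)**2 / (2 * width**2)),

with a free baseline so the high-concentration undershoot below control is
representable.  The Gaussian is only preferred when it actually beats the
best monotone LL.4 fit on the same points.

No quantitative antagonism criterion exists in the literature for this
assay; the rule used here - observed mean below the reference prediction by
more than ``se_multiplier`` standard errors at ``n_consecutive`` or more
consecutive tested concentrations - is this package's operationalization,
with both knobs exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dose_response import CrcDataset, Direction, fit_ll4, ll4_effect
from .exceptions import ComparabilityError, DegenerateDataError, ParameterError
from .mixtures import PredictionCurve

__all__ = ["BiphasicFit", "AntagonismReport", "fit_biphasic", "assess_antagonism"]


@dataclass(frozen=True)
class BiphasicFit:
    """Gaussian-on-log-concentration description of a rise-then-fall response."""

    amplitude: float
    center_log10c: float
    width_log10c: float
    baseline: float
    rss: float
    monotone_rss: float
    preferred: str  # "biphasic" or "monotone"

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        z = (np.log10(conc) - self.center_log10c) / self.width_log10c
        out = self.baseline + self.amplitude * np.exp(-0.5 * z * z)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AntagonismReport:
    """Observed-versus-additive comparison for an opposing-direction mixture."""

    reference_model: str
    max_observed_effect: float
    max_predicted_effect: float
    suppression: float
    direction_reversal_concentration: float | None
    verdict: str  # "antagonistic" or "not_antagonistic"
    n_flagged: int = 0


def _gaussian_resid(theta, logc, resp):
    amp, center, logwidth, base = theta
    width = np.exp(logwidth)
    return base + amp * np.exp(-0.5 * ((logc - center) / width) ** 2) - resp


def fit_biphasic(concentrations, responses) -> BiphasicFit:
    """Fit the log-concentration Gaussian and compare it with a monotone fit.

    Requires at least 5 positive concentrations.  If the best monotone LL.4
    curve explains the points at least as well (by residual sum of squares),
    the result is flagged ``preferred="monotone"`` - the data carry no
    biphasic signal.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ParameterError("concentrations and responses must be equal-length 1-D arrays")
    mask = conc > 0
    conc, resp = conc[mask], resp[mask]
    if np.unique(conc).size < 5:
        raise DegenerateDataError("biphasic fit needs at least 5 distinct positive concentrations")

    logc = np.log10(conc)
    means = pd.Series(resp).groupby(pd.Series(conc)).mean()
    center0 = float(np.log10(means.idxmax()))
    amp0 = float(means.max() - min(means.min(), 0.0))
    span = float(logc.max() - logc.min())
    theta0 = np.array([max(amp0, 1.0), center0, np.log(max(span / 4.0, 0.05)), 0.0])
    sol = least_squares(_gaussian_resid, theta0, args=(logc, resp), xtol=1e-10, ftol=1e-10)
    amp, center, logwidth, base = sol.x
    rss = float(2.0 * sol.cost)

    monotone_rss = np.inf
    try:
        crc = fit_ll4(
            CrcDataset(conc, resp),
            fix_floor=False,
            fix_ceiling=False,
        )
        monotone_rss = float(np.sum((ll4_effect(conc, crc) - resp) ** 2))
    except Exception:
        pass

    preferred = "biphasic" if rss < monotone_rss else "monotone"
    return BiphasicFit(
        amplitude=float(amp),
        center_log10c=float(center),
        width_log10c=float(np.exp(logwidth)),
        baseline=float(base),
        rss=rss,
        monotone_rss=monotone_rss,
        preferred=preferred,
    )


def assess_antagonism(
    observed: pd.DataFrame,
    reference: PredictionCurve,
    n_consecutive: int = 2,
    se_multiplier: float = 2.0,
) -> AntagonismReport:
    """Compare an observed opposing-direction mixture with its additive reference.

    ``observed`` is a normalized table (columns ``concentration_um``,
    ``percent_change``, optionally ``se_percent``); rows are averaged over
    experiments per concentration.  ``reference`` is the CA or IA curve of
    the same-direction subset of the mixture, on the signed percent-change
    scale of that subset (hyperactivity positive).

    Verdict is ``antagonistic`` when the observed mean lies below the
    reference prediction by more than ``se_multiplier`` times the observed
    standard error at ``n_consecutive`` or more consecutive tested
    concentrations.  The lowest concentration at which the observed mean
    flips sign relative to control is also reported, if any.
    """
    if n_consecutive < 1:
        raise ParameterError("n_consecutive must be >= 1")
    grouped = observed.groupby("concentration_um", sort=True)
    obs = grouped["percent_change"].mean().to_frame("percent_change")
    if "se_percent" in observed.columns:
        # pooled SE of the across-experiment mean at each concentration
        obs["se_percent"] = grouped["se_percent"].apply(
            lambda s: float(np.sqrt(np.nansum(np.square(s))) / max(s.count(), 1))
        )
    else:
        obs["se_percent"] = grouped["percent_change"].sem()
    obs = obs.reset_index()
    obs = obs[obs["concentration_um"] > 0]
    lo, hi = reference.concentrations.min(), reference.concentrations.max()
    in_range = obs[(obs["concentration_um"] >= lo) & (obs["concentration_um"] <= hi)]
    if in_range.empty:
        raise ComparabilityError(
            "observed concentrations do not overlap the reference prediction range "
            f"[{lo:g}, {hi:g}] umol/L"
        )

    conc = in_range["concentration_um"].to_numpy()
    mean = in_range["percent_change"].to_numpy()
    se = in_range["se_percent"].to_numpy(dtype=float)
    se = np.where(np.isfinite(se), se, 0.0)
    pred = np.asarray(reference.effect_at(conc), dtype=float)

    below = mean < pred - se_multiplier * se
    # longest run of consecutive flagged concentrations
    run = best_run = 0
    for flag in below:
        run = run + 1 if flag else 0
        best_run = max(best_run, run)
    verdict = "antagonistic" if best_run >= n_consecutive else "not_antagonistic"

    # a reversal must clear the same SE criterion, so noise wiggles around
    # zero at sub-effective concentrations do not count as sign flips
    sign_flips = conc[mean < -se_multiplier * se]
    reversal = float(sign_flips.min()) if sign_flips.size else None

    return AntagonismReport(
        reference_model=reference.model,
        max_observed_effect=float(mean.max()),
        max_predicted_effect=float(pred.max()),
        suppression=float(pred.max() - mean.max()),
        direction_reversal_concentration=reversal,
        verdict=verdict,
        n_flagged=int(below.sum()),
    )
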