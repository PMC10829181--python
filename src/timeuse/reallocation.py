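"""Model-based time-reallocation response curves.

Starting from a reference composition (typically the sample's
compositional mean), minutes are reallocated towards or away from one
behaviour -- either pro-rata from all remaining behaviours
(one-for-remaining) or directly from a named donor (one-for-one) -- in
15-minute increments.  The fitted moderation model then predicts the
difference in cognitive z-score between the displaced and the reference
composition, with a delta-method confidence interval from the
coefficient covariance.  Curves are produced per behaviour, swap mode
and brain-volume stratum (above/below the sample-mean adjusted ROI
volume); covariate contributions cancel in the difference, so curves
depend only on the ilr and interaction coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import coda
from .coda import DEFAULT_KAPPA, PART_NAMES
from .models import ILR_COLS, LinearFit

__all__ = [
    "ReallocationSpec",
    "CurvePoint",
    "InfeasibleReallocationError",
    "reallocate",
    "predict_difference",
    "response_curves",
    "mean_split_strata",
]

logger = logging.getLogger(__name__)

DEFAULT_DELTAS = tuple(range(-60, 61, 15))


class InfeasibleReallocationError(ValueError):
    """A reallocation would drive some behaviour to zero or below."""


@dataclass(frozen=True)
class ReallocationSpec:
    """One family of swaps: target behaviour, mode, optional donor, delta grid."""

    target: str
    mode: str = "one_for_remaining"      # or "one_for_one"
    donor: str = None
    deltas: tuple = DEFAULT_DELTAS

    def __post_init__(self):
        if self.target not in PART_NAMES:
            raise ValueError(f"unknown behaviour {self.target!r}")
        if self.mode not in ("one_for_remaining", "one_for_one"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "one_for_one":
            if self.donor is None or self.donor not in PART_NAMES:
                raise ValueError("one_for_one swaps need a donor behaviour")
            if self.donor == self.target:
                raise ValueError("donor must differ from target")
        if 0 not in self.deltas:
            raise ValueError("delta grid must include 0")


@dataclass(frozen=True)
class CurvePoint:
    behaviour: str
    mode: str
    donor: str
    stratum: str
    delta: float
    estimate: float
    ci_low: float
    ci_high: float


def reallocate(ref, target: str, delta: float, mode: str = "one_for_remaining",
               donor: str = None, kappa: float = DEFAULT_KAPPA,
               part_names=PART_NAMES) -> np.ndarray:
    """Displace ``delta`` minutes towards ``target`` from the reference.

    one_for_remaining scales every remaining part by
    ``(kappa - target_new) / (kappa - target_old)`` (pro-rata);
    one_for_one moves the minutes directly from ``donor``.  The output
    sums to ``kappa``; any non-positive resulting part raises, naming it.
    """
    ref = np.asarray(ref, dtype=float)
    if abs(ref.sum() - kappa) > 1e-6 * kappa:
        ref = coda.closure(ref, kappa)
    ti = part_names.index(target)
    new = ref.copy()
    new[ti] = ref[ti] + delta
    if mode == "one_for_remaining":
        scale = (kappa - new[ti]) / (kappa - ref[ti])
        for k in range(len(new)):
            if k != ti:
                new[k] = ref[k] * scale
    elif mode == "one_for_one":
        di = part_names.index(donor)
        new[di] = ref[di] - delta
    else:
        raise ValueError(f"unknown mode {mode!r}")
    bad = [part_names[k] for k in range(len(new)) if new[k] <= 0]
    if bad:
        raise InfeasibleReallocationError(
            f"reallocating {delta:+g} min to {target} leaves non-positive parts: {bad}"
        )
    return new


def _difference_vector(fit: LinearFit, ref, new, roi_value: float):
    """Design-column difference between the displaced and reference rows."""
    order = fit.meta.get("order")
    kappa = fit.meta.get("kappa", DEFAULT_KAPPA)
    z_ref = coda.ilr_pivot(coda.closure(ref, kappa), order=order)
    z_new = coda.ilr_pivot(coda.closure(new, kappa), order=order)
    dz = z_new - z_ref
    d = pd.Series(0.0, index=fit.params.index)
    for k, col in enumerate(ILR_COLS):
        d[col] = dz[k]
    roi_cols = fit.meta.get("roi_cols", ())
    for rc in roi_cols:
        for k, zc in enumerate(ILR_COLS):
            col = f"{zc}:{rc}"
            if col in d.index:
                d[col] = dz[k] * roi_value
    return d


def predict_difference(fit: LinearFit, ref, new, profile: dict,
                       roi_value: float, level: float = 0.95):
    """Predicted cognitive-z difference new vs ref, with a delta-method CI.

    ``profile`` supplies the covariate values of the prediction profile;
    covariates cancel in the difference but the profile must be complete
    (missing covariates raise), keeping the caller honest about what the
    prediction conditions on.  ``roi_value`` is the moderator value
    (design scale: the adjusted volume for a continuous fit, the
    indicator for a categorical fit).
    """
    for cov in fit.meta.get("covariates", ()):
        if cov not in profile:
            raise KeyError(f"prediction profile missing covariate {cov!r}")
    d = _difference_vector(fit, ref, new, roi_value)
    est = float(d @ fit.params)
    var = float(d @ fit.cov_params @ d)
    half = stats.t.ppf(0.5 + level / 2, fit.df_resid) * np.sqrt(max(var, 0.0))
    return est, est - half, est + half


def mean_split_strata(adjusted_roi: pd.Series) -> dict:
    """Stratum labels -> mean adjusted ROI volume above/below the sample mean."""
    thresh = adjusted_roi.mean()
    upper = adjusted_roi[adjusted_roi > thresh]
    lower = adjusted_roi[adjusted_roi <= thresh]
    if upper.empty or lower.empty:
        raise ValueError("mean split produced an empty stratum")
    return {"upper": float(upper.mean()), "lower": float(lower.mean())}


def response_curves(fit: LinearFit, ref, specs, strata: dict,
                    profile: dict = None, level: float = 0.95) -> list:
    """Reallocation response curves per spec x stratum over the delta grid.

    ``strata`` maps stratum label -> moderator ROI value at which to
    predict (e.g. from :func:`mean_split_strata`); infeasible deltas are
    dropped with a logged note.  Returns a flat list of
    :class:`CurvePoint`.
    """
    if profile is None:
        profile = {c: 0.0 for c in fit.meta.get("covariates", ())}
    points = []
    for spec in specs:
        for stratum, roi_value in strata.items():
            for delta in spec.deltas:
                try:
                    new = reallocate(ref, spec.target, delta, spec.mode, spec.donor)
                except InfeasibleReallocationError as err:
                    logger.info("dropping delta %+g for %s (%s): %s",
                                delta, spec.target, stratum, err)
                    continue
                est, lo, hi = predict_difference(fit, ref, new, profile,
                                                 roi_value, level)
                points.append(CurvePoint(spec.target, spec.mode,
                                         spec.donor or "", stratum,
                                         float(delta), est, lo, hi))
    return points


def curves_to_frame(points) -> pd.DataFrame:
    """Flatten curve points to the output CSV schema."""
    return pd.DataFrame([{
        "behaviour": p.behaviour, "mode": p.mode, "donor": p.donor,
        "stratum": p.stratum, "delta_min": p.delta, "estimate": p.estimate,
        "ci_low": p.ci_low, "ci_high": p.ci_high,
    } for p in points])
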