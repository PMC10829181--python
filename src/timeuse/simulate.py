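"""Synthetic cohort generator with plantable effects.

Emulates the statistical structure of a two-site observational cohort of
healthy older adults (n = 378 by default): 4-part daily time-use
compositions drawn logistic-normally (multivariate normal in ilr space),
regional brain volumes with realistic means, spreads and age/sex
loadings, and cognitive composite z-scores generated from an explicit
linear model with composition, ROI-volume and composition-by-volume
interaction effects.  Because the generating coefficients are known,
downstream model fits can be checked for parameter recovery, type-I
error calibration and CI coverage.

Default marginals (compositional means 90.7 / 178.8 / 668.2 / 502.2
min/day for MVPA / LPA / SB / sleep; volume means such as total grey
matter 596 +/- 51 ml; age 65.6 +/- 3.0 years truncated to 60-71.2;
67% female) reproduce the descriptives of the cohort the package is
modelled on.  Log-scale part spreads are set by the delta method from
the printed per-part SDs.  The generator also builds epoch-level ENMO
traces with known ground-truth behaviour labels for exercising the
accelerometry stage.

Each generated table carries ``truth_*`` columns: the standardized
moderator actually used in the cognition model, so recovery tests can
fit against the exact generating design.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .accelerometry import EpochSeries, SleepLog, SleepLogDay
from .coda import DEFAULT_KAPPA, PART_NAMES, closure, ilr_inverse, ilr_pivot, pivot_basis

__all__ = [
    "RoiSpec",
    "CognitionSpec",
    "EffectConfig",
    "default_config",
    "zero_interaction_config",
    "generate_cohort",
    "generate_trace",
]

#: compositional means (min/day) and per-part SDs used for the default
#: time-use distribution, order (mvpa, lpa, sb, sleep)
DEFAULT_COMP_MEAN = np.array([90.7, 178.8, 668.2, 502.2])
DEFAULT_COMP_SD = np.array([47.1, 50.7, 92.2, 57.5])

ROI_ORDER = ("tiv", "total_gm", "frontal", "temporal", "hippocampus", "lateral_ventricle")


@dataclass(frozen=True)
class RoiSpec:
    """Marginal moments and covariate loadings for one volume (ml).

    ``r_age``/``r_sex`` are target marginal correlations with age and
    female sex.  ``log_scale`` draws the volume log-normally (used for
    the skewed lateral ventricles).
    """

    mean: float
    sd: float
    r_age: float = 0.0
    r_sex: float = 0.0
    log_scale: bool = False


def _default_rois():
    return {
        "tiv": RoiSpec(1551.0, 141.2, r_sex=-0.35),
        "total_gm": RoiSpec(596.0, 50.8, r_age=-0.28, r_sex=0.02),
        "frontal": RoiSpec(168.0, 16.9, r_age=-0.10, r_sex=0.12),
        "temporal": RoiSpec(95.3, 9.2, r_age=-0.20, r_sex=-0.01),
        "hippocampus": RoiSpec(6.2, 0.6, r_age=-0.16, r_sex=-0.08),
        "lateral_ventricle": RoiSpec(25.0, 12.5, r_age=0.21, r_sex=-0.01, log_scale=True),
    }


def _default_roi_corr():
    """Residual correlations among ROI latents (ventricles on log scale).

    Printed between-ROI correlations where available; modest assumed
    values for TIV.  Order follows ``ROI_ORDER``.
    """
    R = np.eye(6)

    def st(i, j, v):
        R[i, j] = R[j, i] = v

    st(0, 1, 0.60), st(0, 2, 0.55), st(0, 3, 0.50), st(0, 4, 0.30), st(0, 5, 0.20)
    st(1, 2, 0.67), st(1, 3, 0.70), st(1, 4, 0.19), st(1, 5, -0.24)
    st(2, 3, 0.46), st(2, 4, 0.05), st(2, 5, -0.06)
    st(3, 4, 0.18), st(3, 5, -0.32)
    st(4, 5, -0.21)
    return R


@dataclass(frozen=True)
class CognitionSpec:
    """Linear generating model for one cognitive composite z-score.

    ``y = intercept + beta_age (age - 65.6) + beta_sex female
    + beta_edu (edu - 16.6) + z . beta_ilr + beta_roi r + (z . beta_int) r
    + Normal(0, resid_sd)`` where ``z`` are pivot ilr coordinates of the
    composition (order mvpa, lpa, sb, sleep) and ``r`` is the
    standardized moderator ROI latent.
    """

    name: str
    roi: str
    intercept: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_edu: float = 0.0
    beta_ilr: tuple = (0.0, 0.0, 0.0)
    beta_roi: float = 0.0
    beta_int: tuple = (0.0, 0.0, 0.0)
    resid_sd: float = 0.9
    missing_rate: float = 0.0


def _default_cognition():
    # Signs and rough magnitudes mirror the reported structure: an
    # MVPA-by-frontal-volume interaction for long-term memory (~ +0.25 SD
    # per +30 min MVPA in the lower-volume stratum, ~ -0.05 in the upper),
    # a sleep/SB-by-grey-matter interaction for executive function
    # (~ +/-0.03 SD per 30-min sleep<->SB swap), and a main MVPA effect
    # with no interaction for processing speed.
    return (
        CognitionSpec(
            "long_term_memory_z", roi="frontal",
            beta_age=-0.02, beta_sex=0.10, beta_edu=0.03,
            beta_ilr=(0.35, 0.0, 0.0), beta_roi=0.05,
            beta_int=(-0.65, 0.0, 0.0), resid_sd=0.9, missing_rate=18 / 378,
        ),
        CognitionSpec(
            "executive_function_z", roi="total_gm",
            beta_age=-0.085, beta_sex=-0.35, beta_edu=0.035,
            beta_ilr=(0.0, 0.0, 0.0), beta_roi=0.15,
            beta_int=(0.0, 0.0, 0.50), resid_sd=0.9, missing_rate=15 / 378,
        ),
        CognitionSpec(
            "processing_speed_z", roi="hippocampus",
            beta_age=-0.045, beta_sex=0.0, beta_edu=0.0,
            beta_ilr=(0.30, 0.0, 0.0), beta_roi=0.03,
            beta_int=(0.0, 0.0, 0.0), resid_sd=0.95, missing_rate=10 / 378,
        ),
    )


def _ilr_moments(comp_mean, comp_sd):
    """ilr-space mean/covariance implied by per-part log-normal marginals.

    Log-part SDs come from the delta method (sd/mean); logs are treated
    as independent, and the closure-invariant ilr image is exact:
    ``z = V' log x`` has mean ``V' log m`` and covariance
    ``V' diag(sigma^2) V``.
    """
    m = np.asarray(comp_mean, float)
    sigma = np.asarray(comp_sd, float) / m
    V = pivot_basis(len(m))
    return np.log(m) @ V, V.T @ np.diag(sigma**2) @ V


@dataclass(frozen=True)
class EffectConfig:
    """Full simulation control: sample size, distributions, planted effects."""

    seed: int = 0
    n: int = 378
    kappa: float = DEFAULT_KAPPA
    ilr_mean: np.ndarray = None
    ilr_cov: np.ndarray = None
    age_mean: float = 65.6
    age_sd: float = 3.0
    age_range: tuple = (60.0, 71.2)
    female_prevalence: float = 0.67
    edu_mean: float = 16.6
    edu_sd: float = 3.2
    edu_range: tuple = (7.0, 30.0)
    rois: dict = field(default_factory=_default_rois)
    roi_corr: np.ndarray = field(default_factory=_default_roi_corr)
    site_effect_sd: float = 0.2        # site B offset, in ROI SD units
    distortion_effect_sd: float = -0.1  # distortion-on offset, in ROI SD units
    wmh_mean: float = 1.9
    wmh_sd: float = 3.4
    cognition: tuple = field(default_factory=_default_cognition)

    def __post_init__(self):
        mean, cov = _ilr_moments(DEFAULT_COMP_MEAN, DEFAULT_COMP_SD)
        if self.ilr_mean is None:
            object.__setattr__(self, "ilr_mean", mean)
        else:
            object.__setattr__(self, "ilr_mean", np.asarray(self.ilr_mean, float))
        if self.ilr_cov is None:
            object.__setattr__(self, "ilr_cov", cov)
        else:
            object.__setattr__(self, "ilr_cov", np.asarray(self.ilr_cov, float))
        c = self.ilr_cov
        if not np.allclose(c, c.T):
            raise ValueError("ilr covariance must be symmetric")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("ilr covariance must be positive definite")
        if np.linalg.eigvalsh(self.roi_corr).min() <= 0:
            raise ValueError("ROI correlation matrix must be positive definite")

    def with_(self, **kw) -> "EffectConfig":
        return replace(self, **kw)


def default_config(seed: int = 0, n: int = 378) -> EffectConfig:
    return EffectConfig(seed=seed, n=n)


def zero_interaction_config(seed: int = 0, n: int = 378) -> EffectConfig:
    """Default config with every composition-by-volume interaction zeroed.

    Under this null the interaction Type II F-test p-values are uniform,
    so its rejection rate at alpha calibrates the test's type-I error.
    """
    cfg = EffectConfig(seed=seed, n=n)
    cog = tuple(replace(c, beta_int=(0.0, 0.0, 0.0), missing_rate=0.0)
                for c in cfg.cognition)
    return cfg.with_(cognition=cog)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(cfg: EffectConfig) -> pd.DataFrame:
    """Generate a participant table; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    age = _truncnorm(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)
    female = (rng.random(n) < cfg.female_prevalence).astype(int)
    education = _truncnorm(rng, cfg.edu_mean, cfg.edu_sd, *cfg.edu_range, size=n)
    site = np.where(rng.random(n) < 0.5, "A", "B")
    distortion = (rng.random(n) < 0.5).astype(int)

    # compositions: multivariate normal in ilr space, mapped back
    z = rng.multivariate_normal(cfg.ilr_mean, cfg.ilr_cov, size=n)
    comp = ilr_inverse(z, kappa=cfg.kappa)

    # ROI latents: unit-variance, correlated, with age/sex loadings;
    # age standardized by the truncated-normal moments so the loadings
    # translate into the target marginal correlations
    a, b = [(x - cfg.age_mean) / cfg.age_sd for x in cfg.age_range]
    age_mu = stats.truncnorm.mean(a, b, loc=cfg.age_mean, scale=cfg.age_sd)
    age_sigma = stats.truncnorm.std(a, b, loc=cfg.age_mean, scale=cfg.age_sd)
    age_std = (age - age_mu) / age_sigma
    p = cfg.female_prevalence
    sex_std = (female - p) / np.sqrt(p * (1 - p))
    L = np.linalg.cholesky(cfg.roi_corr)
    u = rng.standard_normal((n, len(ROI_ORDER))) @ L.T
    latent = {}
    for k, name in enumerate(ROI_ORDER):
        spec = cfg.rois[name]
        resid_scale = np.sqrt(max(1.0 - spec.r_age**2 - spec.r_sex**2, 1e-6))
        latent[name] = spec.r_age * age_std + spec.r_sex * sex_std + resid_scale * u[:, k]

    site_off = (site == "B").astype(float) * cfg.site_effect_sd
    dist_off = distortion * cfg.distortion_effect_sd
    rois = {}
    for name in ROI_ORDER:
        spec = cfg.rois[name]
        lat = latent[name] + (0.0 if name == "tiv" else site_off + dist_off)
        if spec.log_scale:
            cv = spec.sd / spec.mean
            s = np.sqrt(np.log1p(cv**2))
            mu = np.log(spec.mean) - s**2 / 2
            rois[name] = np.exp(mu + s * lat)
        else:
            rois[name] = spec.mean + spec.sd * lat

    wmh_s = np.sqrt(np.log1p((cfg.wmh_sd / cfg.wmh_mean) ** 2))
    wmh = np.exp(np.log(cfg.wmh_mean) - wmh_s**2 / 2 + wmh_s * rng.standard_normal(n))

    out = pd.DataFrame({
        "id": [f"P{i:04d}" for i in range(n)],
        "age": age,
        "sex": female,            # female = 1, male = 0
        "education": education,
        "site": site,
        "distortion_correction": distortion,
        "wmh": wmh,
    })
    for name in ROI_ORDER:
        out[name] = rois[name]
    for part, col in zip(PART_NAMES, ["mvpa_min", "lpa_min", "sb_min", "sleep_min"]):
        out[col] = comp[:, PART_NAMES.index(part)]

    # cognition from the explicit linear model; truth moderator kept
    for spec in cfg.cognition:
        r = latent[spec.roi]  # standardized moderator, free of scanner offsets
        y = (spec.intercept
             + spec.beta_age * (age - cfg.age_mean)
             + spec.beta_sex * female
             + spec.beta_edu * (education - cfg.edu_mean)
             + z @ np.asarray(spec.beta_ilr)
             + spec.beta_roi * r
             + (z @ np.asarray(spec.beta_int)) * r
             + spec.resid_sd * rng.standard_normal(n))
        if spec.missing_rate > 0:
            y = np.where(rng.random(n) < spec.missing_rate, np.nan, y)
        out[spec.name] = y
        out[f"truth_roi_std_{spec.roi}"] = r

    return out


#: half-open ENMO bands (mg) the trace generator draws from, chosen
#: strictly inside each behaviour's classification band
_TRACE_BANDS = {
    "sleep": (0.0, 30.0),
    "sb": (1.0, 47.5),
    "lpa": (48.5, 92.5),
    "mvpa": (93.5, 250.0),
}


def generate_trace(day_profile: dict, epoch_seconds: int = 60, seed: int = 0,
                   n_days: int = 7, start_date: dt.date = dt.date(2021, 3, 1),
                   participant_id: str = "SIM"):
    """Build an epoch ENMO trace + sleep log realising ``day_profile``.

    ``day_profile`` maps behaviours (mvpa, lpa, sb, sleep) to minutes
    per day; any shortfall from 1440 becomes logged non-wear during the
    waking day.  Each day places half the sleep before the logged wake
    time and half after bed time, then runs SB, LPA, MVPA and non-wear
    blocks.  Returns ``(EpochSeries, SleepLog, truth_labels)`` with one
    ground-truth label per epoch; ENMO values are drawn strictly inside
    each behaviour's band so reclassification is unambiguous.
    """
    rng = np.random.default_rng(seed)
    epoch_min = epoch_seconds / 60.0
    per_day = 86400 // epoch_seconds
    need = {b: float(day_profile.get(b, 0.0)) for b in ("mvpa", "lpa", "sb", "sleep")}
    total = sum(need.values())
    if total > 1440.0 + 1e-9:
        raise ValueError(f"day profile sums to {total} min > 1440")
    counts = {b: int(round(need[b] / epoch_min)) for b in need}
    if any(abs(counts[b] * epoch_min - need[b]) > 1e-9 for b in need):
        raise ValueError("profile minutes must be whole epochs at this epoch length")
    nonwear_epochs = per_day - sum(counts.values())

    sleep_am = counts["sleep"] // 2
    sleep_pm = counts["sleep"] - sleep_am
    day_labels = (["sleep"] * sleep_am + ["sb"] * counts["sb"]
                  + ["lpa"] * counts["lpa"] + ["mvpa"] * counts["mvpa"]
                  + ["nonwear"] * nonwear_epochs + ["sleep"] * sleep_pm)
    assert len(day_labels) == per_day

    labels, enmo, wear, log_days = [], [], [], {}
    for d in range(n_days):
        date = start_date + dt.timedelta(days=d)
        midnight = pd.Timestamp(date)
        wake = midnight + pd.Timedelta(seconds=sleep_am * epoch_seconds)
        bed = midnight + pd.Timedelta(seconds=(per_day - sleep_pm) * epoch_seconds)
        nw_start = sleep_am + counts["sb"] + counts["lpa"] + counts["mvpa"]
        removals = []
        if nonwear_epochs:
            removals.append((midnight + pd.Timedelta(seconds=nw_start * epoch_seconds),
                             midnight + pd.Timedelta(seconds=(nw_start + nonwear_epochs) * epoch_seconds)))
        log_days[date] = SleepLogDay(date, wake_time=wake, bed_time=bed,
                                     removals=removals)
        labels.extend(day_labels)
        for lab in day_labels:
            lo, hi = _TRACE_BANDS.get(lab, (0.0, 5.0))
            enmo.append(rng.uniform(lo, hi))
            wear.append(lab != "nonwear")

    ts = pd.date_range(pd.Timestamp(start_date), periods=per_day * n_days,
                       freq=pd.Timedelta(seconds=epoch_seconds))
    series = EpochSeries(participant_id, ts, np.array(enmo), np.array(wear),
                         epoch_seconds)
    return series, SleepLog(log_days), np.array(labels, dtype=object)
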