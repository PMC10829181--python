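"""End-to-end orchestration: cohort -> descriptives -> correlations ->
compositional regressions -> moderation models -> reallocation curves.

A run takes a :class:`RunConfig` (built in code or loaded from YAML),
obtains a cohort either by simulation or from a participant CSV,
pre-adjusts ROI volumes, and writes the full set of tabular outputs plus
a manifest recording seeds, row counts at every exclusion step and the
files produced.  All randomness flows from one master seed through
named substreams, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coda, models, reallocation, simulate
from .coda import DEFAULT_KAPPA, PART_NAMES

__all__ = ["RunConfig", "ExclusionLedger", "describe", "run"]

logger = logging.getLogger(__name__)

COMPOSITION_COLS = models.COMPOSITION_COLS
DEFAULT_OUTCOMES = ("long_term_memory_z", "executive_function_z", "processing_speed_z")
DEFAULT_ROIS = ("total_gm", "frontal", "temporal", "hippocampus")
VOLUME_OUTCOMES = ("total_gm", "frontal", "temporal", "hippocampus", "lateral_ventricle")


@dataclass
class RunConfig:
    """Configuration for one analysis run (exactly one input source)."""

    outdir: str = "timeuse_run"
    seed: int = 0
    simulate_n: int = None            # simulate when set ...
    cohort_csv: str = None            # ... or read a participant CSV
    kappa: float = DEFAULT_KAPPA
    covariates: tuple = ("age", "sex", "education")
    outcomes: tuple = DEFAULT_OUTCOMES
    rois: tuple = DEFAULT_ROIS
    roi_form: str = "continuous"
    deltas: tuple = reallocation.DEFAULT_DELTAS
    n_boot: int = 1000
    alpha: float = 0.05
    make_figures: bool = False

    def __post_init__(self):
        if (self.simulate_n is None) == (self.cohort_csv is None):
            raise ValueError("config must set exactly one of simulate_n or cohort_csv")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "outcomes", "rois", "deltas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ExclusionLedger:
    """Row-count audit: input n minus exclusions must equal analysed n."""

    stages: list = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_excluded: int, reason: str = ""):
        n_out = n_in - n_excluded
        if n_excluded < 0 or n_out < 0:
            raise ValueError(f"stage {stage!r}: impossible counts")
        if self.stages and self.stages[-1]["n_out"] != n_in:
            raise ValueError(
                f"stage {stage!r}: n_in={n_in} does not match previous n_out="
                f"{self.stages[-1]['n_out']}"
            )
        self.stages.append({"stage": stage, "n_in": n_in,
                            "n_excluded": n_excluded, "n_out": n_out,
                            "reason": reason})
        return n_out

    @property
    def final_n(self) -> int:
        return self.stages[-1]["n_out"] if self.stages else 0

    @property
    def total_excluded(self) -> int:
        return sum(s["n_excluded"] for s in self.stages)

    def to_records(self):
        return list(self.stages)


def describe(cohort: pd.DataFrame, kappa: float = DEFAULT_KAPPA) -> pd.DataFrame:
    """Descriptives table: mean/SD/min/max per numeric variable, counts for
    categoricals, and both arithmetic and compositional time-use means."""
    rows = []
    for col in cohort.columns:
        if col.startswith("truth_") or col == "id":
            continue
        s = cohort[col]
        if pd.api.types.is_numeric_dtype(s):
            rows.append({"variable": col, "kind": "numeric",
                         "mean": s.mean(), "sd": s.std(ddof=1),
                         "min": s.min(), "max": s.max()})
        else:
            for level, count in s.value_counts().items():
                rows.append({"variable": f"{col}={level}", "kind": "categorical",
                             "count": int(count),
                             "pct": 100.0 * count / s.notna().sum()})
    comp = cohort[list(COMPOSITION_COLS)].dropna().to_numpy(float)
    cmean = coda.compositional_mean(coda.closure(comp, kappa), kappa)
    for name, col, value in zip(PART_NAMES, COMPOSITION_COLS, cmean):
        rows.append({"variable": f"compositional_mean_{name}", "kind": "compositional",
                     "mean": float(value), "pct": float(value / kappa * 100.0)})
    return pd.DataFrame(rows)


def _volume_models(cohort, cfg):
    """Covariate-only and composition models per volumetric outcome,
    with Type II tables, FDR within model, and the quadratic comparison."""
    data = models.add_ilr_columns(cohort, kappa=cfg.kappa)
    cov_terms = tuple(models.Term(c, (c,)) for c in cfg.covariates)
    comp_term = models.Term("composition", models.ILR_COLS)
    rows, quad_rows = [], []
    for roi in VOLUME_OUTCOMES:
        outcome = f"{roi}_adj"
        if roi == "lateral_ventricle":
            data[outcome] = np.log(data[outcome])  # improves model fit for the skewed ventricles
        fit1 = models.fit_model(outcome, cov_terms, data)
        fit2 = models.fit_model(outcome, cov_terms + (comp_term,), data)
        for label, fit in (("1", fit1), ("2", fit2)):
            for t in models.attach_fdr(models.type2_tests(fit)):
                rows.append({"roi": roi, "model": label, "term": t.term,
                             "F": t.F, "df1": t.df1, "df2": t.df2,
                             "p": t.p, "p_adj": t.p_adjusted})
        F, p, _ = models.compare_quadratic(fit2)
        quad_rows.append({"roi": roi, "F": F, "p": p})
    return pd.DataFrame(rows), pd.DataFrame(quad_rows)


def _interaction_models(cohort, cfg):
    data = models.add_ilr_columns(cohort, kappa=cfg.kappa)
    rows, fits = [], {}
    for outcome in cfg.outcomes:
        for roi in cfg.rois:
            fit, tests = models.fit_interaction_model(
                outcome, f"{roi}_adj", data, covariates=cfg.covariates,
                roi_form=cfg.roi_form, kappa=cfg.kappa)
            fits[(outcome, roi)] = fit
            for t in tests:
                rows.append({"outcome": outcome, "roi": roi, "term": t.term,
                             "F": t.F, "df1": t.df1, "df2": t.df2,
                             "p": t.p, "p_adj": t.p_adjusted})
    return pd.DataFrame(rows), fits


def _reallocation_stage(cohort, cfg, interactions, fits, outdir):
    """Response curves for every significant composition x ROI interaction."""
    data = models.add_ilr_columns(cohort, kappa=cfg.kappa)
    comp = coda.closure(cohort[list(COMPOSITION_COLS)].to_numpy(float), cfg.kappa)
    ref = coda.compositional_mean(comp, cfg.kappa)
    specs = [reallocation.ReallocationSpec(b, "one_for_remaining", deltas=cfg.deltas)
             for b in PART_NAMES]
    specs += [reallocation.ReallocationSpec(t, "one_for_one", donor=d, deltas=cfg.deltas)
              for t in PART_NAMES for d in PART_NAMES if d != t]
    frames = []
    sig = interactions[(interactions["term"].str.startswith("composition:"))
                       & (interactions["p_adj"] < cfg.alpha)]
    for _, row in sig.iterrows():
        outcome, roi = row["outcome"], row["roi"]
        fit = fits[(outcome, roi)]
        strata = reallocation.mean_split_strata(data[f"{roi}_adj"])
        profile = {c: float(data[c].mean()) for c in cfg.covariates}
        points = reallocation.response_curves(fit, ref, specs, strata, profile)
        frame = reallocation.curves_to_frame(points)
        frame.insert(0, "outcome", outcome)
        frame.insert(1, "roi", roi)
        frames.append(frame)
        if cfg.make_figures:
            _plot_curves(frame, outcome, roi,
                         outdir / f"curves_{outcome}_{roi}.png")
    if frames:
        return pd.concat(frames, ignore_index=True)
    return pd.DataFrame(columns=["outcome", "roi", "behaviour", "mode", "donor",
                                 "stratum", "delta_min", "estimate",
                                 "ci_low", "ci_high"])


def _plot_curves(frame, outcome, roi, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = frame[frame["mode"] == "one_for_remaining"]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2), sharey=True)
    colors = {"upper": "purple", "lower": "darkorange"}
    for ax, behaviour in zip(axes, PART_NAMES):
        for stratum, grp in sub[sub["behaviour"] == behaviour].groupby("stratum"):
            grp = grp.sort_values("delta_min")
            ax.plot(grp["delta_min"], grp["estimate"], color=colors.get(stratum),
                    label=stratum)
            ax.fill_between(grp["delta_min"], grp["ci_low"], grp["ci_high"],
                            color=colors.get(stratum), alpha=0.2)
        ax.axhline(0, lw=0.5, color="grey")
        ax.set_title(behaviour.upper())
        ax.set_xlabel("reallocation (min)")
    axes[0].set_ylabel(f"predicted difference in {outcome}")
    axes[0].legend(title=roi)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _load_cohort(cfg, ledger: ExclusionLedger):
    if cfg.simulate_n is not None:
        cohort = simulate.generate_cohort(simulate.default_config(cfg.seed, cfg.simulate_n))
        ledger.record("simulated", len(cohort), 0)
        return cohort
    cohort = pd.read_csv(cfg.cohort_csv)
    n0 = len(cohort)
    if "included" in cohort.columns:
        kept = cohort[cohort["included"].astype(bool)].drop(columns=["included"])
        ledger.record("inclusion_screen", n0, n0 - len(kept), "failed wear criteria")
        cohort = kept.reset_index(drop=True)
    else:
        ledger.record("loaded", n0, 0)
    missing_comp = cohort[list(COMPOSITION_COLS)].isna().any(axis=1)
    if missing_comp.any():
        ledger.record("complete_composition", len(cohort), int(missing_comp.sum()),
                      "missing time-use data")
        cohort = cohort[~missing_comp].reset_index(drop=True)
    return cohort


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger = ExclusionLedger()
    cohort = _load_cohort(config, ledger)

    for roi in VOLUME_OUTCOMES:
        cohort[f"{roi}_adj"] = models.adjust_roi(
            cohort[roi], cohort["tiv"], cohort["site"],
            cohort["distortion_correction"])

    outputs = {}

    desc = describe(cohort, config.kappa)
    outputs["descriptives"] = "descriptives.csv"
    desc.to_csv(outdir / outputs["descriptives"], index=False)

    corr_vars = (list(config.covariates) + list(COMPOSITION_COLS)
                 + [f"{r}_adj" for r in VOLUME_OUTCOMES] + list(config.outcomes))
    entries = models.correlation_table(cohort, corr_vars, n_boot=config.n_boot,
                                       seed=config.seed + 1)
    corr = pd.DataFrame([dataclasses.asdict(e) for e in entries])
    outputs["correlations"] = "correlations.csv"
    corr.to_csv(outdir / outputs["correlations"], index=False)

    volume_tables, quad = _volume_models(cohort, config)
    outputs["volume_models"] = "volume_models.csv"
    volume_tables.to_csv(outdir / outputs["volume_models"], index=False)
    outputs["quadratic_tests"] = "quadratic_tests.csv"
    quad.to_csv(outdir / outputs["quadratic_tests"], index=False)

    interactions, fits = _interaction_models(cohort, config)
    outputs["interaction_models"] = "interaction_models.csv"
    interactions.to_csv(outdir / outputs["interaction_models"], index=False)

    curves = _reallocation_stage(cohort, config, interactions, fits, outdir)
    outputs["reallocation_curves"] = "reallocation_curves.csv"
    curves.to_csv(outdir / outputs["reallocation_curves"], index=False)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "n_analysed": int(len(cohort)),
        "exclusions": ledger.to_records(),
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: n=%d, outputs in %s", len(cohort), outdir)
    return manifest
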