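"""Cohort-level statistical stages.

Cognitive composites (z-score and average), ROI volume pre-adjustment
(residualising on total intracranial volume, scanner site and
distortion-correction use), the pairwise correlation table (Pearson /
point-biserial with Fisher-z CIs; symmetric-balance dominance
correlations with bootstrap CIs inside the composition), ordinary
least-squares models with the time-use composition entering as one
3-column ilr term, Type II F-tests respecting marginality, a nested-F
comparison against a quadratic (squared-ilr) alternative, and
Benjamini-Hochberg FDR adjustment within each model's term family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import coda
from .coda import DEFAULT_KAPPA, PART_NAMES

__all__ = [
    "Term",
    "LinearFit",
    "TermTest",
    "CorrelationEntry",
    "make_composite",
    "adjust_roi",
    "fisher_z_ci",
    "correlation_table",
    "add_ilr_columns",
    "fit_model",
    "type2_tests",
    "compare_quadratic",
    "fit_interaction_model",
    "bh_adjust",
]

COMPOSITION_COLS = ("mvpa_min", "lpa_min", "sb_min", "sleep_min")
ILR_COLS = ("ilr_1", "ilr_2", "ilr_3")


@dataclass(frozen=True)
class Term:
    """A named model term spanning one or more design columns.

    Interaction terms are named ``"a:b"``; a term U is a higher-order
    relative of T when T's name appears among U's colon-separated
    components (used to respect marginality in Type II tests).
    """

    name: str
    columns: tuple

    def contains(self, other: "Term") -> bool:
        return other.name != self.name and other.name in self.name.split(":")


@dataclass
class LinearFit:
    """An OLS fit with its term structure and data retained for re-fits."""

    outcome: str
    terms: tuple            # Term, excluding the intercept
    params: pd.Series
    cov_params: pd.DataFrame
    rss: float
    df_resid: int
    n: int
    X: pd.DataFrame = field(repr=False)
    y: pd.Series = field(repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"model has no term {name!r}")


@dataclass(frozen=True)
class TermTest:
    term: str
    F: float
    df1: int
    df2: int
    p: float
    p_adjusted: float = np.nan


@dataclass(frozen=True)
class CorrelationEntry:
    var1: str
    var2: str
    method: str      # pearson | point_biserial | symmetric_balance
    r: float
    ci_low: float
    ci_high: float
    ci_method: str   # fisher_z | bootstrap
    n: int


# ---------------------------------------------------------------------------
# composites and ROI adjustment

def make_composite(test_scores: pd.DataFrame, grouping: dict) -> pd.DataFrame:
    """Z-score each test over its non-missing values, average within composites.

    ``grouping`` maps composite name -> list of test columns (already
    oriented so higher = better).  A participant's composite is the mean
    of their available test z-scores.
    """
    out = {}
    for composite, tests in grouping.items():
        if not tests:
            raise ValueError(f"composite {composite!r} lists no tests")
        zs = []
        for t in tests:
            col = test_scores[t]
            sd = col.std(ddof=1)
            if not sd > 0:
                raise ValueError(f"test {t!r} has zero standard deviation")
            zs.append((col - col.mean()) / sd)
        out[composite] = pd.concat(zs, axis=1).mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=test_scores.index)


def adjust_roi(volume: pd.Series, tiv: pd.Series, site: pd.Series,
               distortion: pd.Series) -> pd.Series:
    """Residualise a volume on TIV, scanner site and distortion use.

    Returns residuals plus the sample mean, keeping the ml scale
    ("corrected" volumes).  Adjusted values are exactly uncorrelated
    with the adjusters in-sample and preserve the sample mean.
    """
    X = pd.DataFrame({
        "tiv": np.asarray(tiv, float),
        "site": pd.Categorical(site).codes.astype(float),
        "distortion": pd.Categorical(distortion).codes.astype(float),
    }, index=volume.index)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear adjusters: TIV/site/distortion design is rank deficient")
    res = sm.OLS(np.asarray(volume, float), X).fit()
    return pd.Series(res.resid + volume.mean(), index=volume.index,
                     name=f"{volume.name}_adj" if volume.name else "adjusted")


# ---------------------------------------------------------------------------
# correlation table

def fisher_z_ci(r: float, n: int, level: float = 0.95):
    """Fisher z-transform CI for a Pearson correlation."""
    if abs(r) >= 1.0:
        return r, r
    zcrit = stats.norm.ppf(0.5 + level / 2)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlation_table(cohort: pd.DataFrame, variables,
                      composition_cols=COMPOSITION_COLS,
                      binary_vars=("sex",), n_boot: int = 1000,
                      seed: int = 0) -> list:
    """All pairwise correlations among ``variables``.

    Pairs of time-use behaviours (both in ``composition_cols``) use the
    symmetric-balance dominance correlation with a seeded percentile
    bootstrap CI; every other pair uses Pearson (point-biserial when one
    variable is binary) with a Fisher-z CI.  Deletion is pairwise
    complete -- except that compositional pairs require all composition
    columns (the balance involves the remaining parts too).
    """
    rng = np.random.default_rng(seed)
    comp_set = [v for v in variables if v in composition_cols]
    entries = []
    for v1, v2 in itertools.combinations(variables, 2):
        if v1 in comp_set and v2 in comp_set:
            sub = cohort[list(composition_cols)].dropna()
            n = len(sub)
            if n < 4:
                raise ValueError(f"too few complete rows for pair ({v1}, {v2})")
            X = sub.to_numpy()
            i, j = composition_cols.index(v1), composition_cols.index(v2)
            r = coda.cor_coda(X, i, j)
            boots = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                boots[b] = coda.cor_coda(X[idx], i, j)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            entries.append(CorrelationEntry(v1, v2, "symmetric_balance",
                                            r, float(lo), float(hi), "bootstrap", n))
        else:
            sub = cohort[[v1, v2]].dropna()
            n = len(sub)
            if n < 4:
                raise ValueError(f"too few complete rows for pair ({v1}, {v2})")
            a, b_ = sub[v1].to_numpy(float), sub[v2].to_numpy(float)
            if a.std() == 0 or b_.std() == 0:
                raise ValueError(f"correlation undefined: constant variable in ({v1}, {v2})")
            r = float(np.corrcoef(a, b_)[0, 1])
            lo, hi = fisher_z_ci(r, n)
            method = "point_biserial" if (v1 in binary_vars or v2 in binary_vars) else "pearson"
            entries.append(CorrelationEntry(v1, v2, method, r, lo, hi, "fisher_z", n))
    return entries


# ---------------------------------------------------------------------------
# linear models with termwise structure

def add_ilr_columns(data: pd.DataFrame, order=None,
                    composition_cols=COMPOSITION_COLS,
                    kappa: float = DEFAULT_KAPPA) -> pd.DataFrame:
    """Append pivot ilr coordinate columns (ilr_1..ilr_3) to a cohort table."""
    comp = coda.closure(data[list(composition_cols)].to_numpy(float), kappa)
    z = coda.ilr_pivot(comp, order=order)
    out = data.copy()
    for k, col in enumerate(ILR_COLS[:z.shape[1]]):
        out[col] = z[:, k]
    return out


def _rss(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def fit_model(outcome: str, terms, data: pd.DataFrame) -> LinearFit:
    """OLS fit of ``outcome`` on the given terms (plus an intercept).

    Listwise deletion over all needed columns.  Multi-column terms (the
    composition's three ilr coordinates, interaction blocks) are kept as
    single named terms so they can be tested jointly.  Rank deficiency
    raises, naming the aliased columns.
    """
    terms = tuple(terms)
    cols = [c for t in terms for c in t.columns]
    sub = data[cols + [outcome]].dropna()
    if len(sub) < len(cols) + 2:
        raise ValueError(f"too few complete rows ({len(sub)}) for {len(cols)} parameters")
    X = sm.add_constant(sub[cols].astype(float), has_constant="add")
    y = sub[outcome].astype(float)

    mat = X.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        aliased = []
        keep = [0]
        for k in range(1, mat.shape[1]):
            if np.linalg.matrix_rank(mat[:, keep + [k]]) == len(keep) + 1:
                keep.append(k)
            else:
                aliased.append(X.columns[k])
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")

    res = sm.OLS(y, X).fit()
    return LinearFit(
        outcome=outcome,
        terms=terms,
        params=res.params,
        cov_params=res.cov_params(),
        rss=float(res.ssr),
        df_resid=int(res.df_resid),
        n=len(sub),
        X=X,
        y=y,
    )


def type2_tests(fit: LinearFit) -> list:
    """Type II F-test for every term, respecting marginality.

    For term T, the comparison model excludes any higher-order relative
    of T (a term whose name contains T as a component); the reduced
    model additionally drops T.  F = ((RSS_reduced - RSS_comparison)/df1)
    / (RSS_comparison/df2), df2 = n - rank(comparison design).
    Multi-column terms are tested jointly.
    """
    y = fit.y.to_numpy()
    tests = []
    for t in fit.terms:
        comparison = [u for u in fit.terms if u is t or not u.contains(t)]
        reduced = [u for u in comparison if u is not t]

        def design(term_list):
            cols = [c for u in term_list for c in u.columns]
            return fit.X[["const"] + cols].to_numpy()

        rss_cmp, rank_cmp = _rss(design(comparison), y)
        rss_red, rank_red = _rss(design(reduced), y)
        df1 = rank_cmp - rank_red
        df2 = fit.n - rank_cmp
        F = max(((rss_red - rss_cmp) / df1) / (rss_cmp / df2), 0.0)
        p = float(stats.f.sf(F, df1, df2))
        tests.append(TermTest(t.name, float(F), df1, df2, p))
    return tests


def attach_fdr(tests) -> list:
    """Return tests with BH-adjusted p-values (one model = one family)."""
    adj = bh_adjust(np.array([t.p for t in tests]))
    return [replace(t, p_adjusted=float(a)) for t, a in zip(tests, adj)]


def compare_quadratic(model2: LinearFit, ilr_term: str = "composition"):
    """Nested F-test of a squared-ilr alternative against the linear model.

    The quadratic model adds the squares of the composition's ilr
    columns (no cross-products) to the existing design.  Returns
    ``(F, p, fit3)``.
    """
    term = model2.term(ilr_term)
    data = model2.X.copy()
    data[model2.outcome] = model2.y
    sq_cols = []
    for c in term.columns:
        sq = f"{c}_sq"
        data[sq] = data[c] ** 2
        sq_cols.append(sq)
    terms3 = model2.terms + (Term(f"{ilr_term}_sq", tuple(sq_cols)),)
    fit3 = fit_model(model2.outcome, terms3, data.drop(columns=["const"]))
    df1 = len(sq_cols)
    df2 = fit3.df_resid
    F = max(((model2.rss - fit3.rss) / df1) / (fit3.rss / df2), 0.0)
    return float(F), float(stats.f.sf(F, df1, df2)), fit3


def _roi_columns(data: pd.DataFrame, roi: str, roi_form: str):
    """Encode the moderator ROI as design columns; returns (data, cols)."""
    data = data.copy()
    if roi_form == "continuous":
        return data, [roi]
    if roi_form == "mean_split":
        col = f"{roi}_upper"
        thresh = data[roi].mean()
        data[col] = (data[roi] > thresh).astype(float)
        if data[col].nunique() < 2:
            raise ValueError(f"empty stratum when mean-splitting {roi}")
        return data, [col]
    if roi_form == "quartiles":
        q = pd.qcut(data[roi], 4, labels=False)
        cols = []
        for lev in (1, 2, 3):
            col = f"{roi}_q{lev + 1}"
            data[col] = (q == lev).astype(float)
            cols.append(col)
        if any(data[c].sum() == 0 for c in cols):
            raise ValueError(f"empty stratum when quartile-splitting {roi}")
        return data, cols
    raise ValueError(f"unknown roi_form {roi_form!r}")


def fit_interaction_model(outcome: str, roi: str, data: pd.DataFrame,
                          covariates=("age", "sex", "education"),
                          roi_form: str = "continuous",
                          order=None, kappa: float = DEFAULT_KAPPA):
    """Moderation model: covariates + composition + ROI + composition x ROI.

    The composition enters as its three pivot ilr coordinates (one joint
    term); the interaction spans ilr x ROI-column products (3 columns
    continuous / mean-split, 9 for quartiles).  Returns ``(LinearFit,
    [TermTest])`` with Type II F-tests and BH-adjusted p-values within
    the model.
    """
    if not all(c in data.columns for c in ILR_COLS):
        data = add_ilr_columns(data, order=order, kappa=kappa)
    data, roi_cols = _roi_columns(data, roi, roi_form)
    int_cols = []
    for rc in roi_cols:
        for zc in ILR_COLS:
            col = f"{zc}:{rc}"
            data[col] = data[zc] * data[rc]
            int_cols.append(col)
    terms = tuple(Term(c, (c,)) for c in covariates) + (
        Term("composition", ILR_COLS),
        Term(roi, tuple(roi_cols)),
        Term(f"composition:{roi}", tuple(int_cols)),
    )
    fit = fit_model(outcome, terms, data)
    fit.meta.update({
        "ilr_term": "composition",
        "roi_term": roi,
        "interaction_term": f"composition:{roi}",
        "roi_form": roi_form,
        "roi_cols": tuple(roi_cols),
        "covariates": tuple(covariates),
        "order": order,
        "kappa": kappa,
    })
    return fit, attach_fdr(type2_tests(fit))


# ---------------------------------------------------------------------------
# multiple testing

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
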