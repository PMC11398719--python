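"""Lifespan statistics: rolling correlations, BCa bootstrap, t-tests,
and the whole-brain local-efficiency regression models.

The rolling correlation slides 10-year age windows in 1-year steps
across the cohort and reports the Pearson correlation between a mean
graph measure and fluid intelligence inside each window, with 95%
bias-corrected and accelerated (BCa) bootstrap intervals.  The
regression models relate mean local efficiency (over a configured
region set) to age, sex, small-worldness, SC total and/or mean SC
distance via ordinary least squares, reported with t-based 95% CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import Cohort


# ---------------------------------------------------------------------------
# BCa bootstrap


def bca_interval(data, statistic, n_boot: int = 1000, alpha: float = 0.05,
                 seed=None) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for ``statistic(data)``.

    ``data`` is an array whose first axis indexes observations (rows are
    resampled jointly, so paired statistics like a correlation work).
    The bias correction z0 comes from the fraction of bootstrap
    replicates below the point estimate; the acceleration ``a`` from the
    jackknife skewness.  A degenerate bootstrap distribution collapses
    the interval to the point estimate.
    """
    data = np.asarray(data, float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    theta = float(statistic(data))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = statistic(data[rng.integers(0, n, n)])
    if np.ptp(boots) == 0:
        return theta, theta
    prop = np.mean(boots < theta) + 0.5 * np.mean(boots == theta)
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = sps.norm.ppf(prop)
    jack = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        jack[i] = statistic(data[idx != i])
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = (d**3).sum() / (6.0 * denom) if denom > 0 else 0.0
    out = []
    for z in (sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z) / (1 - a * (z0 + z))
        out.append(float(np.percentile(boots, 100 * sps.norm.cdf(adj))))
    lo, hi = min(out), max(out)
    return lo, hi


def _pearson(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


# ---------------------------------------------------------------------------
# Rolling correlation


def rolling_correlation(ages, metric, fi, width: float = 10, step: int = 1,
                        n_boot: int = 1000, seed=None) -> pd.DataFrame:
    """Pearson r between a graph measure and fluid intelligence within
    sliding age windows.

    Windows start at integer years from floor(min age) to
    floor(max age) - width + 1 inclusive; membership is half-open
    [start, start + width).  Windows with fewer than 3 subjects report a
    null correlation.  CIs are 95% BCa bootstrap intervals.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    ages = np.asarray(ages, float)
    metric = np.asarray(metric, float)
    fi = np.asarray(fi, float)
    if not len(ages) == len(metric) == len(fi):
        raise ValueError("ages, metric, fi must have equal length")
    first = math.floor(ages.min())
    last = math.floor(ages.max()) - int(width) + 1
    ss = np.random.SeedSequence(seed)
    rows = []
    starts = list(range(first, last + 1, step))
    child = ss.generate_state(max(len(starts), 1))
    for k, start in enumerate(starts):
        inside = (ages >= start) & (ages < start + width)
        n = int(inside.sum())
        row = {"age_start": float(start), "age_end": float(start + width),
               "n": n, "r": np.nan, "ci_low": np.nan, "ci_high": np.nan}
        if n >= 3:
            xy = np.column_stack([metric[inside], fi[inside]])
            r = _pearson(xy)
            lo, hi = bca_interval(xy, _pearson, n_boot=n_boot,
                                  seed=int(child[k]))
            row.update(r=r, ci_low=min(lo, r), ci_high=max(hi, r))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t tests


def t_tests(a, b, paired: bool = False, pooled: bool = False):
    """Two-sided t test: paired (df = n-1) or independent.

    Independent tests use the Welch correction by default; ``pooled``
    switches to the classical equal-variance test (df = n1 + n2 - 2).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        if len(a) < 2:
            raise ValueError("need at least 2 observations")
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0:
            return (0.0, n - 1, 1.0) if d.mean() == 0 else (
                math.copysign(math.inf, d.mean()), n - 1, 0.0)
        t = d.mean() / (sd / math.sqrt(n))
        df = n - 1
        p = 2 * sps.t.sf(abs(t), df)
        return float(t), int(df), float(p)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    df = res.df
    return float(res.statistic), float(df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Regression models


MODEL_TERMS = {
    1: ["age", "sex_male", "small_worldness", "sc_total"],
    2: ["age", "sex_male", "small_worldness", "mean_sc_distance"],
    3: ["age", "sex_male", "small_worldness", "sc_total", "mean_sc_distance"],
}

TERM_NAMES = {
    "const": "Intercept",
    "age": "Age",
    "sex_male": "Sex (male)",
    "small_worldness": "Small-worldness",
    "sc_total": "SC total",
    "mean_sc_distance": "SC distance",
}


@dataclass
class RegressionFit:
    """OLS coefficient table with t-based 95% CIs."""

    table: pd.DataFrame  # term, estimate, ci_low, ci_high, se, t, p
    r_squared: float
    n: int
    dependent: str

    def term(self, name: str) -> pd.Series:
        hit = self.table[self.table["term"] == name]
        if hit.empty:
            raise KeyError(f"term {name!r} not in fit "
                           f"(have {self.table['term'].tolist()})")
        return hit.iloc[0]


def fit_ols(df: pd.DataFrame, dependent: str, terms: list[str],
            cond_threshold: float = 1e10) -> RegressionFit:
    """OLS with intercept; errors on a collinear design naming the terms."""
    X = df[terms].to_numpy(float)
    y = df[dependent].to_numpy(float)
    Xc = sm.add_constant(X, has_constant="add")
    scale = np.abs(Xc).max(axis=0)
    scale[scale == 0] = 1.0
    if np.linalg.cond(Xc / scale) > cond_threshold:
        cm = np.corrcoef(X, rowvar=False)
        bad = [
            f"{terms[i]}~{terms[j]}"
            for i in range(len(terms))
            for j in range(i + 1, len(terms))
            if abs(cm[i, j]) > 0.999
        ]
        raise ValueError(f"collinear design; offending terms: {bad or terms}")
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=0.05)
    names = ["const"] + terms
    table = pd.DataFrame(
        {
            "term": [TERM_NAMES.get(t, t) for t in names],
            "estimate": res.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return RegressionFit(table=table.reset_index(drop=True),
                         r_squared=float(res.rsquared), n=int(res.nobs),
                         dependent=dependent)


def local_efficiency_design(metrics_df: pd.DataFrame, cohort: Cohort,
                            region_labels=None) -> pd.DataFrame:
    """Join per-subject metrics with behavior into a regression frame.

    The dependent variable ``le_mean`` is the mean local efficiency over
    ``region_labels`` (default: all regions).
    """
    le_cols = [c for c in metrics_df.columns if c.startswith("le_")]
    if region_labels is not None:
        wanted = [f"le_{r}" for r in region_labels]
        missing = sorted(set(wanted) - set(le_cols))
        if missing:
            raise KeyError(f"region columns not in metrics table: {missing}")
        le_cols = wanted
        if not le_cols:
            raise ValueError("empty region set")
    m = metrics_df.set_index("id")
    t = cohort.table.set_index("id").loc[m.index.intersection(cohort.ids)]
    m = m.loc[t.index]
    out = pd.DataFrame(
        {
            "id": t.index,
            "le_mean": m[le_cols].mean(axis=1).to_numpy(),
            "age": t["age"].to_numpy(),
            "sex_male": (t["sex"] == "M").astype(float).to_numpy(),
            "small_worldness": m["small_worldness"].to_numpy(),
            "sc_total": m["sc_total"].to_numpy(),
            "mean_sc_distance": m["mean_sc_distance"].to_numpy(),
            "group": t["group"].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def fit_local_efficiency_models(metrics_df: pd.DataFrame, cohort: Cohort,
                                model_id: int, group: str,
                                region_labels=None) -> RegressionFit:
    """Models 1-3: mean local efficiency ~ age + sex (+ whole-brain terms).

    Model 1 uses SC total, Model 2 mean SC distance, Model 3 both; all
    include age, sex (reference female) and small-worldness.  ``group``
    selects YA (< 50 years), OA, or 'all'.
    """
    if model_id not in MODEL_TERMS:
        raise ValueError("model_id must be 1, 2, or 3")
    design = local_efficiency_design(metrics_df, cohort, region_labels)
    if group != "all":
        design = design[design["group"] == group]
    if design.empty:
        raise ValueError(f"no subjects in group {group!r}")
    fit = fit_ols(design, "le_mean", MODEL_TERMS[model_id])
    fit.dependent = f"mean local efficiency ({group}, model {model_id})"
    return fit


def compare_group_estimates(fit_a: RegressionFit, fit_b: RegressionFit,
                            term: str) -> dict:
    """Group difference verdict by the CI-overlap rule.

    'different' iff the two 95% CIs are disjoint.  Conservative relative
    to a formal interaction test, but matches the reporting convention.
    """
    ra, rb = fit_a.term(term), fit_b.term(term)
    disjoint = ra["ci_high"] < rb["ci_low"] or rb["ci_high"] < ra["ci_low"]
    return {
        "term": term,
        "verdict": "different" if disjoint else "not different",
        "ci_a": [float(ra["ci_low"]), float(ra["ci_high"])],
        "ci_b": [float(rb["ci_low"]), float(rb["ci_high"])],
    }
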