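"""Statistical battery: paired Wilcoxon tests, mixed-effects price-change
models, chi-square association, Benjamini-Hochberg adjustment and
descriptive price summaries.

Model structure for both exposure analyses: outcome is the per-100 price
delta; fixed effects are the exposure (five-level reformulation group
with little_change as reference, or the continuous nutrition-score
change) plus container size (standardized) and brand type (multinational
reference); retailer enters as a random intercept.  When the random
effect is degenerate (single retailer or zero variance) the model falls
back to ordinary least squares with a logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .classifier import ReformulationGroup

log = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    n_used: int
    degenerate: bool = False


def wilcoxon_paired(values_y1, values_y2) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on year-2 minus year-1 differences.

    Pairs with a missing value are dropped; zero differences are dropped
    per the standard convention.  Exact null distribution for n <= 25
    non-zero differences, normal approximation with continuity
    correction otherwise.  All-zero differences yield a degenerate
    result with p = 1.
    """
    a = np.asarray(values_y1, dtype=float)
    b = np.asarray(values_y2, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise StatsError("no complete pairs")
    diff = b - a
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0, degenerate=True)
    method = "exact" if nonzero.size <= 25 else "approx"
    res = sps.wilcoxon(
        nonzero,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return WilcoxonResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), n_used=int(nonzero.size)
    )


# ---------------------------------------------------------------------------
# Chi-square and Benjamini-Hochberg


def chi_square(table):
    """Pearson chi-square on an r x c count table (no continuity correction).

    Returns (statistic, df, p).  A zero row/column margin is a hard
    error; expected counts below 5 log a caution.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise StatsError("contingency table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise StatsError("contingency table has a zero margin")
    expected = np.outer(row, col) / obs.sum()
    if (expected < 5).any():
        log.warning("chi-square: %d expected cell(s) below 5", int((expected < 5).sum()))
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(sps.chi2.sf(stat, df))


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Mixed-effects exposure models


@dataclass
class EffectEstimate:
    outcome: str
    term: str
    n: int
    beta: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adj: Optional[float] = None
    grouping: str = "overall"
    fallback_ols: bool = False


@dataclass
class ModelFitInfo:
    n: int = 0
    dropped_groups: list = field(default_factory=list)
    skipped: bool = False
    reason: str = ""
    fallback_ols: bool = False


_GROUP_ORDER = [g.name for g in ReformulationGroup]
_REFERENCE_GROUP = ReformulationGroup.little_change.name
_EXPOSURE_PREFIX = "exposure"


def _pairs_frame(pairs, nutrient=None, use_score_change=False) -> pd.DataFrame:
    rows = []
    for pair in pairs:
        row = {
            "delta_price": pair.delta_price,
            "retailer": pair.record_y1.retailer_id,
            "brand_type": pair.record_y1.brand_type,
            "container_size": pair.record_y1.container_size,
            "tra_category": pair.record_y1.tra_category,
        }
        if nutrient is not None:
            group = pair.groups.get(nutrient)
            row["group"] = group.name if group is not None else None
        if use_score_change:
            row["score_change"] = pair.fsanz_score_change
        rows.append(row)
    frame = pd.DataFrame(rows)
    predictors = ["delta_price", "brand_type", "container_size"]
    predictors += ["group"] if nutrient is not None else []
    predictors += ["score_change"] if use_score_change else []
    frame = frame.dropna(subset=[c for c in predictors if c in frame.columns])
    return frame.reset_index(drop=True)


def _finite_or(value, default):
    value = float(value)
    return value if np.isfinite(value) else default


def _standardize(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def _fit_lmm(frame: pd.DataFrame, fixed_formula: str):
    """Fit a retailer random-intercept model; fall back to OLS when the
    random effect is degenerate.  Returns (params, conf_int frame,
    pvalues, fallback flag).

    The outcome is centred before fitting: a constant added to every
    observation (uniform inflation, say) then cancels in the data the
    optimiser sees, so every non-intercept estimate is invariant to such
    shifts up to float rounding.  Intercepts are never reported.
    """
    outcome = fixed_formula.split("~")[0].strip()
    frame = frame.copy()
    frame[outcome] = frame[outcome] - frame[outcome].mean()
    fallback = False
    result = None
    if frame["retailer"].nunique() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                model = smf.mixedlm(fixed_formula, frame, groups=frame["retailer"])
                result = model.fit(reml=True, method="lbfgs")
                var_re = float(result.cov_re.iloc[0, 0])
                if not result.converged or not np.isfinite(var_re):
                    result = None
            except Exception:
                result = None
    if result is None:
        fallback = True
        log.warning("mixed model degenerate or failed to converge; using OLS fallback")
        result = smf.ols(fixed_formula, frame).fit()
        params = result.params
        conf = result.conf_int(alpha=0.05)
        pvals = result.pvalues
    else:
        params = result.fe_params
        conf = result.conf_int(alpha=0.05).loc[params.index]
        pvals = result.pvalues.loc[params.index]
    return params, conf, pvals, fallback


def fit_reformulation_model(pairs, nutrient: str, min_group_n: int = 5):
    """Price-change ~ reformulation group model for one nutrient.

    Non-reference groups with fewer than ``min_group_n`` pairs are
    dropped before fitting and reported in the fit info.  Returns
    (list of EffectEstimate, ModelFitInfo).
    """
    frame = _pairs_frame(pairs, nutrient=nutrient)
    info = ModelFitInfo(n=len(frame))
    if frame.empty:
        info.skipped, info.reason = True, "no usable pairs"
        return [], info
    counts = frame["group"].value_counts()
    info.dropped_groups = sorted(
        g for g in counts.index if g != _REFERENCE_GROUP and counts[g] < min_group_n
    )
    frame = frame[~frame["group"].isin(info.dropped_groups)].reset_index(drop=True)
    if _REFERENCE_GROUP not in counts.index:
        info.skipped, info.reason = True, "reference group absent"
        return [], info
    if frame["group"].nunique() < 2:
        info.skipped, info.reason = True, "no non-reference group with enough pairs"
        return [], info
    info.n = len(frame)
    frame["container_std"] = _standardize(frame["container_size"].astype(float))
    formula = (
        "delta_price ~ C(group, Treatment('little_change'))"
        " + container_std + C(brand_type, Treatment('multinational'))"
    )
    params, conf, pvals, fallback = _fit_lmm(frame, formula)
    info.fallback_ols = fallback

    estimates = []
    kept_counts = frame["group"].value_counts()
    for name in params.index:
        if not name.startswith("C(group"):
            continue
        level = name.split("[T.")[-1].rstrip("]")
        estimates.append(
            EffectEstimate(
                outcome="delta_price",
                term=f"{nutrient}:{level}",
                n=int(kept_counts.get(level, 0)),
                beta=float(params[name]),
                ci_low=_finite_or(conf.loc[name, 0], float(params[name])),
                ci_high=_finite_or(conf.loc[name, 1], float(params[name])),
                p_raw=_finite_or(pvals[name], 1.0),
                fallback_ols=fallback,
            )
        )
    estimates.sort(key=lambda e: _GROUP_ORDER.index(e.term.split(":")[1]))
    return estimates, info


def fit_fsanz_model(pairs, grouping: str = "overall", min_cell_n: int = 10):
    """Price-change ~ nutrition-score-change slope, overall or per TRA category.

    Cells below ``min_cell_n`` pairs, or with a constant predictor, are
    skipped and logged.  Returns (list of EffectEstimate, list of
    skipped-cell dicts).
    """
    frame = _pairs_frame(pairs, use_score_change=True)
    if grouping == "overall":
        cells = [("overall", frame)]
    elif grouping == "tra_category":
        cells = [(c, sub) for c, sub in frame.groupby("tra_category", sort=True)]
    else:
        raise StatsError(f"unknown grouping {grouping!r}")

    estimates, skipped = [], []
    for label, sub in cells:
        if len(sub) < min_cell_n:
            skipped.append({"cell": label, "n": len(sub), "reason": "below minimum n"})
            continue
        if sub["score_change"].nunique() < 2:
            skipped.append({"cell": label, "n": len(sub), "reason": "constant predictor"})
            continue
        sub = sub.reset_index(drop=True).copy()
        sub["container_std"] = _standardize(sub["container_size"].astype(float))
        terms = ["score_change", "container_std"]
        if sub["brand_type"].nunique() >= 2:
            terms.append("C(brand_type, Treatment('multinational'))")
        formula = "delta_price ~ " + " + ".join(terms)
        params, conf, pvals, fallback = _fit_lmm(sub, formula)
        estimates.append(
            EffectEstimate(
                outcome="delta_price",
                term="score_change",
                n=len(sub),
                beta=float(params["score_change"]),
                ci_low=_finite_or(conf.loc["score_change", 0], float(params["score_change"])),
                ci_high=_finite_or(conf.loc["score_change", 1], float(params["score_change"])),
                p_raw=_finite_or(pvals["score_change"], 1.0),
                grouping=str(label),
                fallback_ols=fallback,
            )
        )
    return estimates, skipped


def adjust_estimates(estimates):
    """BH-adjust raw p-values across one analysis family, in place."""
    if not estimates:
        return estimates
    adjusted = bh_adjust([e.p_raw for e in estimates])
    for est, adj in zip(estimates, adjusted):
        est.p_adj = float(adj)
    return estimates


def estimates_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "grouping": e.grouping,
                "term": e.term,
                "n": e.n,
                "beta": e.beta,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_raw": e.p_raw,
                "p_adj": e.p_adj,
                "fallback_ols": e.fallback_ols,
            }
            for e in estimates
        ],
        columns=[
            "grouping",
            "term",
            "n",
            "beta",
            "ci_low",
            "ci_high",
            "p_raw",
            "p_adj",
            "fallback_ols",
        ],
    )


# ---------------------------------------------------------------------------
# Descriptive price summaries


def summarize_prices(pairs, by: str = "overall") -> pd.DataFrame:
    """Per-cell paired price summary with Wilcoxon and BH-adjusted p.

    Cells: overall, TRA category or retailer.  Each row reports n,
    mean/sd/median per year, the paired Wilcoxon p and the BH-adjusted p
    across the cells of this call (one family).
    """
    rows = []
    for pair in pairs:
        if pair.price_per100_y1 is None or pair.price_per100_y2 is None:
            continue
        if by == "overall":
            cell = "overall"
        elif by == "tra_category":
            cell = pair.record_y1.tra_category or "?"
        elif by == "retailer":
            cell = pair.record_y1.retailer_id
        else:
            raise StatsError(f"unknown grouping {by!r}")
        rows.append({"cell": cell, "y1": pair.price_per100_y1, "y2": pair.price_per100_y2})
    frame = pd.DataFrame(rows, columns=["cell", "y1", "y2"])
    out = []
    for cell, sub in frame.groupby("cell", sort=True):
        res = wilcoxon_paired(sub["y1"].to_numpy(), sub["y2"].to_numpy())
        out.append(
            {
                "cell": cell,
                "n": len(sub),
                "mean_y1": sub["y1"].mean(),
                "sd_y1": sub["y1"].std(ddof=1) if len(sub) > 1 else 0.0,
                "median_y1": sub["y1"].median(),
                "mean_y2": sub["y2"].mean(),
                "sd_y2": sub["y2"].std(ddof=1) if len(sub) > 1 else 0.0,
                "median_y2": sub["y2"].median(),
                "statistic": res.statistic,
                "p_raw": res.pvalue,
                "degenerate": res.degenerate,
            }
        )
    table = pd.DataFrame(
        out,
        columns=[
            "cell",
            "n",
            "mean_y1",
            "sd_y1",
            "median_y1",
            "mean_y2",
            "sd_y2",
            "median_y2",
            "statistic",
            "p_raw",
            "degenerate",
        ],
    )
    if not table.empty:
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    else:
        table["p_adj"] = []
    return table
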