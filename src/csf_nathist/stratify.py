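"""Residual-quartile stratification with propensity matching.

To separate the biology of two correlated disability outcomes (e.g. brain
damage vs lesion load), samples are regressed one outcome on the other;
samples whose residual falls inside the interquartile range are removed,
and the extreme tails (Q1 vs Q3 strata) are then matched 1:1 on a single
covariate via a univariate propensity score (logistic model of stratum
membership), greedy nearest-neighbour on the logit without replacement,
caliper 0.2 SD of the logit.  The matched pairs are discordant on the
residualized outcome but balanced on the covariate, and per-analyte
differences are assessed with paired two-sided t-tests under BH-FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._linmod import simple_slope


@dataclass
class ResidualStrata:
    dependent: str
    independent: str
    residuals: pd.Series
    strata: pd.Series             # "Q1" | "Q3" | "dropped"

    def ids(self, stratum: str) -> list[str]:
        return list(self.strata.index[self.strata == stratum])


@dataclass
class MatchedPairs:
    pairs: list[tuple[str, str]]       # (Q1 sample, Q3 sample)
    covariate: str
    covariate_gap: list[float]
    smd_before: float
    smd_after: float
    diagnostic: str = ""


def residual_strata(y: pd.Series, x: pd.Series) -> ResidualStrata:
    """OLS y ~ x; drop residuals inside the IQR, label the tails Q1/Q3."""
    paired = pd.concat([y, x], axis=1).dropna()
    if len(paired) < 8:
        raise ValueError("need >= 8 samples")
    xv = paired.iloc[:, 1].to_numpy(dtype=float)
    yv = paired.iloc[:, 0].to_numpy(dtype=float)
    slope, intercept = simple_slope(xv, yv)
    resid = yv - (intercept + slope * xv)
    if np.allclose(resid, 0.0):
        raise ValueError("degenerate regression: y is exactly linear in x")
    q1, q3 = np.quantile(resid, [0.25, 0.75])
    labels = np.where(resid < q1, "Q1", np.where(resid > q3, "Q3", "dropped"))
    res = pd.Series(resid, index=paired.index, name="residual")
    strat = pd.Series(labels, index=paired.index, name="stratum")
    return ResidualStrata(dependent=str(y.name), independent=str(x.name),
                          residuals=res, strata=strat)


def _propensity_logit(covariate: np.ndarray,
                      stratum_q3: np.ndarray) -> np.ndarray:
    """Logit of the stratum propensity from a univariate logistic model.

    The univariate logit is affine in the covariate, so greedy matching on
    it is invariant to the fitted scale; on perfect separation (or a
    degenerate fit) the z-scored covariate is a monotone-equivalent score.
    """
    import statsmodels.api as sm

    X = sm.add_constant(covariate)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(stratum_q3, X).fit(disp=0, maxiter=100)
        logit = X @ fit.params
        if not np.all(np.isfinite(logit)):
            raise ValueError
        return np.asarray(logit, dtype=float)
    except Exception:
        sd = covariate.std(ddof=1)
        return (covariate - covariate.mean()) / (sd if sd > 0 else 1.0)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with pooled SD."""
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def propensity_match(strata: ResidualStrata, covariate: pd.Series,
                     caliper: float = 0.2) -> MatchedPairs:
    """Greedy 1:1 nearest-neighbour matching on the propensity logit.

    Q3 samples are processed in descending logit order; each is matched to
    the nearest unused Q1 sample within ``caliper`` SDs of the logit.
    """
    q1_ids = [s for s in strata.ids("Q1") if s in covariate.index]
    q3_ids = [s for s in strata.ids("Q3") if s in covariate.index]
    if not q1_ids or not q3_ids:
        raise ValueError("both strata must be non-empty")
    ids = q1_ids + q3_ids
    cov = covariate.loc[ids].to_numpy(dtype=float)
    is_q3 = np.array([s in set(q3_ids) for s in ids])
    logit = _propensity_logit(cov, is_q3.astype(float))
    logit_s = pd.Series(logit, index=ids)
    sd = logit.std(ddof=1)
    max_gap = caliper * (sd if sd > 0 else 1.0)

    order = sorted(q3_ids, key=lambda s: (-logit_s[s], s))
    available = sorted(q1_ids)
    pairs, gaps = [], []
    for t in order:
        if not available:
            break
        dists = [(abs(logit_s[c] - logit_s[t]), c) for c in available]
        dist, best = min(dists)
        if dist <= max_gap:
            pairs.append((best, t))
            gaps.append(float(abs(covariate[best] - covariate[t])))
            available.remove(best)
    before = _smd(covariate.loc[q3_ids].to_numpy(dtype=float),
                  covariate.loc[q1_ids].to_numpy(dtype=float))
    if pairs:
        after = _smd(covariate.loc[[b for _, b in pairs]].to_numpy(float),
                     covariate.loc[[a for a, _ in pairs]].to_numpy(float))
        diag = ""
    else:
        after = np.nan
        diag = ("no Q1/Q3 pair within the caliper: covariate "
                "distributions do not overlap")
    return MatchedPairs(pairs=pairs, covariate=str(covariate.name),
                        covariate_gap=gaps, smd_before=before,
                        smd_after=after, diagnostic=diag)


def paired_compare(values: pd.DataFrame,
                   pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Paired two-sided t-test (Q3 minus Q1) per analyte, BH across analytes."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 matched pairs")
    a_ids = [a for a, _ in pairs]
    b_ids = [b for _, b in pairs]
    diffs = values.loc[b_ids].to_numpy(float) - values.loc[a_ids].to_numpy(float)
    rows = []
    for j, name in enumerate(values.columns):
        d = diffs[:, j]
        if np.allclose(d.std(ddof=1), 0.0):
            rows.append({"analyte": name, "t": np.nan, "p": np.nan,
                         "mean_difference": float(d.mean()), "skipped": True})
            continue
        t, p = stats.ttest_rel(values.loc[b_ids, name],
                               values.loc[a_ids, name])
        rows.append({"analyte": name, "t": float(t), "p": float(p),
                     "mean_difference": float(d.mean()), "skipped": False})
    out = pd.DataFrame(rows).set_index("analyte")
    out["q"] = np.nan
    tested = ~out["skipped"]
    if tested.any():
        _, q, _, _ = multipletests(out.loc[tested, "p"], method="fdr_bh")
        out.loc[tested, "q"] = q
    return out
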