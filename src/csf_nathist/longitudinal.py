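"""Longitudinal natural-history analyses.

Three questions are answered from repeat visits of untreated patients:

1. *Untreated evolution* — among patients with >= 2 untreated lumbar
   punctures separated by >= 1.5 years, does a biomarker's per-patient
   yearly slope (OLS of value vs age) have non-zero median across the
   cohort?  One-sample Wilcoxon signed-rank per biomarker, BH-FDR.
2. *Baseline predictor* — do patients in the fastest vs slowest tertile of
   a disability-outcome slope (computed from all clinic visits after the
   first untreated LP) differ in biomarker levels at that first LP?
3. *Slope reflector* — restricted to visits between the first and last LP,
   do biomarker yearly slopes differ between the outcome-slope tertiles?

Outcome-slope outliers beyond +/- 3*IQR fences are removed before tertile
assignment; tertile contrasts use two-sided Wilcoxon rank-sum tests with
BH-FDR and a congruence flag against the cross-sectional association sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SlopeRecord:
    patient_id: str
    variable: str
    slope: float          # per year
    intercept: float
    n_visits: int
    span_years: float
    window: str           # "all-visits" | "between-LP"


def select_untreated_longitudinal(meta: pd.DataFrame,
                                  min_span: float = 1.5) -> list[str]:
    """Patients with >= 2 untreated LP samples spanning >= ``min_span`` years.

    ``meta`` is the sample table (one row per LP) with columns patient_id,
    age, treated.
    """
    out = []
    for pid, grp in meta.groupby("patient_id"):
        untreated = grp[~grp["treated"].astype(bool)]
        if len(untreated) >= 2 and \
                untreated["age"].max() - untreated["age"].min() >= min_span:
            out.append(pid)
    return sorted(out)


def per_patient_slopes(values: pd.DataFrame, meta: pd.DataFrame,
                       window: str = "all-visits",
                       lp_flag: str | None = None) -> pd.DataFrame:
    """Per-patient OLS slopes of every column of ``values`` against age.

    ``values`` is indexed like ``meta`` (one row per visit or sample) and
    may hold outcomes, somamers or pathway scores.  With
    ``window="between-LP"`` only visits between each patient's first and
    last LP (inclusive) are used; ``lp_flag`` names the boolean column of
    ``meta`` marking LP visits (default: every row is an LP).  Patients
    with fewer than two usable visits are skipped.

    Returns patients x variables slopes; attrs carry per-patient visit
    counts and spans.
    """
    slopes: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    spans: dict[str, float] = {}
    for pid, grp in meta.groupby("patient_id"):
        if window == "between-LP":
            is_lp = grp[lp_flag].astype(bool) if lp_flag else \
                pd.Series(True, index=grp.index)
            if is_lp.sum() < 2:
                continue
            lp_ages = grp.loc[is_lp, "age"]
            lo, hi = lp_ages.min(), lp_ages.max()
            grp = grp[(grp["age"] >= lo) & (grp["age"] <= hi)]
        elif window != "all-visits":
            raise ValueError(f"unknown window {window!r}")
        sub = values.loc[values.index.intersection(grp.index)]
        ages = meta.loc[sub.index, "age"].to_numpy(dtype=float)
        if len(sub) < 2 or np.ptp(ages) == 0:
            continue
        xm = ages - ages.mean()
        sxx = float(np.sum(xm ** 2))
        Y = sub.to_numpy(dtype=float)
        b = (xm @ (Y - Y.mean(axis=0))) / sxx
        slopes[pid] = dict(zip(values.columns, b))
        counts[pid] = len(sub)
        spans[pid] = float(np.ptp(ages))
    out = pd.DataFrame(slopes).T
    out.index.name = "patient_id"
    out.attrs["n_visits"] = counts
    out.attrs["span_years"] = spans
    out.attrs["window"] = window
    return out


def untreated_evolution_test(slopes: pd.DataFrame) -> pd.DataFrame:
    """One-sample Wilcoxon signed-rank test of zero median slope, per column."""
    if len(slopes) < 6:
        raise ValueError("need >= 6 patients with slopes")
    rows = []
    for name in slopes.columns:
        s = slopes[name].dropna().to_numpy(dtype=float)
        if np.allclose(s, 0.0):
            rows.append({"variable": name, "statistic": np.nan, "p": 1.0,
                         "median_slope": 0.0})
            continue
        res = stats.wilcoxon(s, alternative="two-sided")
        rows.append({"variable": name, "statistic": float(res.statistic),
                     "p": float(res.pvalue),
                     "median_slope": float(np.median(s))})
    out = pd.DataFrame(rows).set_index("variable")
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    return out


def _remove_slope_outliers(anchor: pd.Series, k: float = 3.0) -> pd.Series:
    q1, q3 = anchor.quantile([0.25, 0.75])
    iqr = q3 - q1
    return anchor[(anchor >= q1 - k * iqr) & (anchor <= q3 + k * iqr)]


def assign_tertiles(anchor_slopes: pd.Series,
                    outlier_k: float = 3.0) -> pd.Series:
    """Tertile labels T1/T2/T3 after +/- ``outlier_k``*IQR outlier removal.

    Boundaries sit at the empirical 1/3 and 2/3 quantiles; ties are broken
    by patient ID so group sizes are reproducible.
    """
    kept = _remove_slope_outliers(anchor_slopes.dropna(), outlier_k)
    if len(kept) < 9:
        raise ValueError("need >= 9 patients after outlier removal")
    order = kept.reset_index()
    order.columns = ["patient_id", "slope"]
    order = order.sort_values(["slope", "patient_id"],
                              kind="stable").reset_index(drop=True)
    n = len(order)
    # deterministic rank thirds: sizes differ by at most one
    thirds = np.empty(n, dtype=object)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    pos = 0
    for label, size in zip(["T1", "T2", "T3"], sizes):
        thirds[pos:pos + size] = label
        pos += size
    return pd.Series(thirds, index=order["patient_id"],
                     name="tertile").sort_index()


def tertile_compare(anchor_slopes: pd.Series, analyte: pd.DataFrame,
                    mode: str,
                    cross_sectional_sign: pd.Series | None = None,
                    outlier_k: float = 3.0) -> pd.DataFrame:
    """Fast (T3) vs slow (T1) progressor contrast per analyte.

    ``analyte`` is patients x variables: first-LP biomarker values for
    ``mode="baseline-predictor"`` or per-patient biomarker yearly slopes
    for ``mode="slope-reflector"``.  The congruence flag marks variables
    whose T3-T1 direction matches ``cross_sectional_sign``.
    """
    if mode not in ("baseline-predictor", "slope-reflector"):
        raise ValueError(f"unknown mode {mode!r}")
    tert = assign_tertiles(anchor_slopes, outlier_k)
    t1 = [p for p in tert.index[tert == "T1"] if p in analyte.index]
    t3 = [p for p in tert.index[tert == "T3"] if p in analyte.index]
    if not t1 or not t3:
        raise ValueError("empty tertile after matching to analyte table")
    rows = []
    for name in analyte.columns:
        a = analyte.loc[t1, name].dropna().to_numpy(dtype=float)
        b = analyte.loc[t3, name].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        res = stats.mannwhitneyu(b, a, alternative="two-sided")
        direction = int(np.sign(np.median(b) - np.median(a)))
        congruent = None
        if cross_sectional_sign is not None and name in cross_sectional_sign:
            congruent = bool(direction == int(cross_sectional_sign[name]))
        rows.append({"variable": name, "mode": mode, "n_t1": len(a),
                     "n_t3": len(b), "p": float(res.pvalue),
                     "direction": direction, "congruent": congruent})
    out = pd.DataFrame(rows).set_index("variable")
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    return out
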