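"""Cross-sectional association engine.

Per somamer and outcome, an OLS model ``somamer ~ outcome + sex +
outcome:sex`` is fit on adjusted analyte values; a somamer is called
significant when the outcome coefficient has unadjusted p <= 0.05 **and**
the whole-model Benjamini-Hochberg FDR q <= 0.05, and sex-affected when, in
addition, the sex main effect or the interaction reaches unadjusted
p <= 0.05.  Two-group contrasts use the two-sided Wilcoxon rank-sum test
with BH correction.  Cell-of-origin is assigned from an nTPM cell-type
expression table (max > 5 and max/median > 5), and over-representation of a
cell type among direction-split significant sets is tested with one-sided
chi-squared statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._linmod import multi_ols
from .adjust import SEX_CODE


def fit_outcome_model(adjusted: pd.DataFrame, outcome: pd.Series,
                      sex: pd.Series, outcome_name: str | None = None
                      ) -> pd.DataFrame:
    """Per-somamer outcome x sex linear models.

    Returns one row per somamer: coefficients and two-sided p-values for
    intercept, outcome, sex and the outcome:sex interaction, model R²,
    whole-model p and its BH-FDR q.  Rows of ``adjusted`` with a missing
    outcome are dropped.
    """
    outcome_name = outcome_name or (outcome.name or "outcome")
    common = adjusted.index.intersection(outcome.dropna().index)
    if len(common) < 10:
        raise ValueError("need >= 10 samples with outcome values")
    y_out = outcome.loc[common].to_numpy(dtype=float)
    if np.ptp(y_out) == 0:
        raise ValueError(f"outcome {outcome_name!r} is constant")
    sx = sex.loc[common]
    sx = sx.map(SEX_CODE).to_numpy(dtype=float) if sx.dtype == object \
        else sx.to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y_out), y_out, sx, y_out * sx])
    Y = adjusted.loc[common].to_numpy(dtype=float)
    fit = multi_ols(X, Y)
    _, q, _, _ = multipletests(fit.f_p, method="fdr_bh")
    rec = pd.DataFrame({
        "outcome": outcome_name,
        "n": len(common),
        "coef_intercept": fit.coef[0], "p_intercept": fit.p[0],
        "coef_outcome": fit.coef[1], "p_outcome": fit.p[1],
        "coef_sex": fit.coef[2], "p_sex": fit.p[2],
        "coef_interaction": fit.coef[3], "p_interaction": fit.p[3],
        "r2": fit.r2, "model_p": fit.f_p, "model_q": q,
        "direction": np.sign(fit.coef[1]).astype(int),
    }, index=adjusted.columns.rename("somamer_id"))
    return apply_filter_cascade(rec)


def apply_filter_cascade(records: pd.DataFrame,
                         p_cut: float = 0.05,
                         q_cut: float = 0.05) -> pd.DataFrame:
    """Set the significance verdicts; pure function of the record fields.

    ``significant``: outcome coefficient p <= p_cut AND whole-model
    q <= q_cut.  ``sex_affected``: significant AND (sex main-effect
    p <= p_cut OR interaction p <= p_cut); the two sub-flags are kept
    separately so either reading of the sex filter can be recovered.
    """
    rec = records.copy()
    rec["significant"] = ((rec["p_outcome"] <= p_cut)
                          & (rec["model_q"] <= q_cut))
    rec["sex_main_flag"] = rec["significant"] & (rec["p_sex"] <= p_cut)
    rec["interaction_flag"] = (rec["significant"]
                               & (rec["p_interaction"] <= p_cut))
    rec["sex_affected"] = rec["sex_main_flag"] | rec["interaction_flag"]
    return rec


def two_group_test(adjusted: pd.DataFrame, groups: pd.Series
                   ) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per somamer, BH-corrected.

    ``groups`` must take exactly two values; the reported median difference
    is (second level - first level) with levels in sorted order.
    """
    groups = groups.loc[adjusted.index.intersection(groups.dropna().index)]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"expected 2 groups, got {levels}")
    a_ids = groups.index[groups == levels[0]]
    b_ids = groups.index[groups == levels[1]]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("both groups need >= 2 samples")
    a = adjusted.loc[a_ids].to_numpy(dtype=float)
    b = adjusted.loc[b_ids].to_numpy(dtype=float)
    res = stats.mannwhitneyu(b, a, axis=0, alternative="two-sided")
    med_diff = np.median(b, axis=0) - np.median(a, axis=0)
    _, q, _, _ = multipletests(res.pvalue, method="fdr_bh")
    return pd.DataFrame({
        "statistic": res.statistic, "p": res.pvalue, "q": q,
        "median_difference": med_diff,
        "direction": np.sign(med_diff).astype(int),
    }, index=adjusted.columns.rename("somamer_id"))


def assign_cell_specificity(expr: pd.DataFrame,
                            max_cut: float = 5.0,
                            ratio_cut: float = 5.0) -> pd.Series:
    """Cell type of maximal expression iff max nTPM > 5 and max/median > 5.

    ``expr`` is gene/target x cell type; unassignable targets map to "".
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    vals = expr.to_numpy(dtype=float)
    mx = vals.max(axis=1)
    med = np.median(vals, axis=1)
    argmax = expr.columns.to_numpy()[vals.argmax(axis=1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(med > 0, mx / med, np.inf)
    ok = (mx > max_cut) & (ratio > ratio_cut)
    return pd.Series(np.where(ok, argmax, ""), index=expr.index,
                     name="cell_type")


def enrichment_test(assignments: pd.Series,
                    significant_sets: dict[tuple[str, str], set[str]],
                    background: set[str] | None = None) -> pd.DataFrame:
    """One-sided chi-squared enrichment of cell types in significant sets.

    ``significant_sets`` maps (outcome, direction) -> somamer/target IDs of
    that direction-split significant set; ``background`` defaults to every
    ID in ``assignments``.  For each (cell type, outcome, direction) a 2x2
    table of set membership x cell-type specificity is tested one-sided in
    the enrichment direction (no continuity correction); BH across all
    performed tests.
    """
    background = set(background) if background is not None \
        else set(assignments.index)
    assignments = assignments.loc[[i for i in assignments.index
                                   if i in background]]
    cell_types = sorted({c for c in assignments.unique() if c})
    rows = []
    for (outcome, direction), sig in significant_sets.items():
        sig = set(sig) & background
        n_bg = len(background)
        n_sig = len(sig)
        for ct in cell_types:
            specific = set(assignments.index[assignments == ct])
            a = len(sig & specific)                 # in set, specific
            b = n_sig - a                           # in set, other
            c = len(specific) - a                   # out of set, specific
            d = (n_bg - n_sig) - c
            expected_a = n_sig * len(specific) / n_bg if n_bg else 0.0
            if min(n_sig, len(specific)) == 0 or expected_a == 0:
                rows.append({"cell_type": ct, "outcome": outcome,
                             "direction": direction, "in_set_specific": a,
                             "in_set_total": n_sig,
                             "background_specific": len(specific),
                             "background_total": n_bg,
                             "chi2": np.nan, "p": np.nan, "skipped": True})
                continue
            table = np.array([[a, b], [c, d]], dtype=float)
            chi2, p_two, _, _ = stats.chi2_contingency(table,
                                                       correction=False)
            # one-sided: halve in the enrichment direction, fold otherwise
            p = p_two / 2.0 if a > expected_a else 1.0 - p_two / 2.0
            rows.append({"cell_type": ct, "outcome": outcome,
                         "direction": direction, "in_set_specific": a,
                         "in_set_total": n_sig,
                         "background_specific": len(specific),
                         "background_total": n_bg,
                         "chi2": float(chi2), "p": float(p),
                         "skipped": False})
    out = pd.DataFrame(rows)
    if len(out):
        tested = ~out["skipped"]
        out["q"] = np.nan
        if tested.any():
            _, q, _, _ = multipletests(out.loc[tested, "p"], method="fdr_bh")
            out.loc[tested, "q"] = q
    return out


def spearman_screen(adjusted: pd.DataFrame, outcome: pd.Series
                    ) -> pd.DataFrame:
    """Spearman rho and BH-corrected p per somamer against one outcome."""
    common = adjusted.index.intersection(outcome.dropna().index)
    res = stats.spearmanr(adjusted.loc[common].to_numpy(dtype=float),
                          outcome.loc[common].to_numpy(dtype=float))
    rho = np.atleast_2d(res.statistic)[-1, :-1]
    p = np.atleast_2d(res.pvalue)[-1, :-1]
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"rho": rho, "p": p, "q": q},
                        index=adjusted.columns.rename("somamer_id"))
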