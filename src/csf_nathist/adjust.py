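"""Healthy-control-anchored removal of physiological age and sex effects.

Somamer levels drift with normal aging and differ between sexes; disease
effects must be measured against that physiological background.  The
adjustment is fit exclusively on healthy controls (HC) and applied to every
sample, in two steps:

1. *Reference-confirmed*: somamers flagged age- or sex-associated in an
   external reference list keep a covariate term when the HC fit reproduces
   it (unadjusted coefficient p <= 0.05 **and** matching direction).
2. *Internal-FDR*: all remaining somamers are fit ``value ~ age + sex`` on
   HC; models surviving Benjamini-Hochberg FDR < 0.05 on the whole-model
   p-value are used; the rest fall back to subtracting the HC mean.

After subtracting the HC-fitted prediction (or HC mean), every somamer is
scaled so the HC fitting cohort has mean 0 and SD 1; all downstream effect
sizes are therefore in HC-SD units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._linmod import multi_ols
from .preprocess import ProteomicMatrix

SEX_CODE = {"F": 0.0, "M": 1.0}   # female = 0 by convention


@dataclass
class AdjustmentModel:
    somamer_id: str
    mode: str                      # reference-confirmed | internal-FDR | mean-only
    intercept: float = 0.0
    age_coefficient: float = 0.0   # per year
    sex_coefficient: float = 0.0   # male minus female
    hc_mean: float = 0.0           # raw HC mean (mean-only subtraction)
    hc_sd: float = 1.0             # SD of adjusted HC values (scaling)
    covariates: tuple[str, ...] = ()

    def predict(self, age: np.ndarray, sex_male: np.ndarray) -> np.ndarray:
        if self.mode == "mean-only":
            return np.full_like(np.asarray(age, dtype=float), self.hc_mean)
        return (self.intercept + self.age_coefficient * np.asarray(age, float)
                + self.sex_coefficient * np.asarray(sex_male, float))


@dataclass
class AdjustedMatrix:
    values: pd.DataFrame
    models: dict[str, AdjustmentModel] = field(default_factory=dict)

    def model_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"somamer_id": m.somamer_id, "mode": m.mode,
              "intercept": m.intercept,
              "age_coefficient": m.age_coefficient,
              "sex_coefficient": m.sex_coefficient,
              "hc_mean": m.hc_mean, "hc_sd": m.hc_sd}
             for m in self.models.values()]).set_index("somamer_id")


def _hc_design(hc_meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, bool]:
    age = hc_meta["age"].to_numpy(dtype=float)
    sex = hc_meta["sex"].map(SEX_CODE).to_numpy(dtype=float)
    both_sexes = len(np.unique(sex)) > 1
    return age, sex, both_sexes


def fit_reference_confirmed(matrix: ProteomicMatrix, hc_meta: pd.DataFrame,
                            reference: pd.DataFrame, p_cut: float = 0.05
                            ) -> dict[str, AdjustmentModel]:
    """Step 1: confirm externally reported age/sex associations on HC.

    ``reference`` columns: somamer_id, covariate in {age, sex}, direction in
    {+, -}.  A covariate term is kept when its HC coefficient has
    unadjusted p <= ``p_cut`` and the same sign as the reference; confirmed
    covariates are refit alone so adjusted HC values are exact OLS
    residuals of the retained design.
    """
    if reference.duplicated(["somamer_id", "covariate"]).any():
        raise ValueError("duplicate (somamer, covariate) reference entries")
    hc_ids = [s for s in hc_meta.index if s in matrix.sample_ids]
    hc_meta = hc_meta.loc[hc_ids]
    age, sex, both_sexes = _hc_design(hc_meta)
    if len(np.unique(age)) < 2:
        raise ValueError("HC cohort must span at least two ages")
    if not both_sexes:
        warnings.warn("single-sex HC cohort: sex terms skipped")

    referenced = [s for s in reference["somamer_id"].unique()
                  if s in matrix.somamer_ids]
    if not referenced:
        return {}
    Y = matrix.values.loc[hc_ids, referenced].to_numpy()
    cols = [np.ones_like(age), age] + ([sex] if both_sexes else [])
    X = np.column_stack(cols)
    fit = multi_ols(X, Y)
    coef_row = {"age": 1, "sex": 2 if both_sexes else None}

    confirmed: dict[str, list[str]] = {}
    for _, entry in reference.iterrows():
        sid, cov, direction = (entry["somamer_id"], entry["covariate"],
                               entry["direction"])
        if sid not in referenced or coef_row.get(cov) is None:
            continue
        j = referenced.index(sid)
        row = coef_row[cov]
        beta, p = fit.coef[row, j], fit.p[row, j]
        if p <= p_cut and np.sign(beta) == (1.0 if direction == "+" else -1.0):
            confirmed.setdefault(sid, []).append(cov)

    models: dict[str, AdjustmentModel] = {}
    # refit per retained-covariate pattern, vectorized within each pattern
    patterns: dict[tuple[str, ...], list[str]] = {}
    for sid, covs in confirmed.items():
        patterns.setdefault(tuple(sorted(covs)), []).append(sid)
    for covs, sids in patterns.items():
        cols = [np.ones_like(age)]
        if "age" in covs:
            cols.append(age)
        if "sex" in covs:
            cols.append(sex)
        Xs = np.column_stack(cols)
        sub = multi_ols(Xs, matrix.values.loc[hc_ids, sids].to_numpy())
        for k, sid in enumerate(sids):
            m = AdjustmentModel(somamer_id=sid, mode="reference-confirmed",
                                intercept=float(sub.coef[0, k]),
                                covariates=covs)
            row = 1
            if "age" in covs:
                m.age_coefficient = float(sub.coef[row, k])
                row += 1
            if "sex" in covs:
                m.sex_coefficient = float(sub.coef[row, k])
            models[sid] = m
    return models


def fit_internal(matrix: ProteomicMatrix, hc_meta: pd.DataFrame,
                 remaining: list[str], fdr_cut: float = 0.05
                 ) -> dict[str, AdjustmentModel]:
    """Step 2: internal HC screen of the remaining somamers.

    Fits ``value ~ age + sex`` on HC for every remaining somamer and keeps
    the full model where the BH-adjusted whole-model p-value is below
    ``fdr_cut``; all other somamers get a mean-only model.
    """
    hc_ids = [s for s in hc_meta.index if s in matrix.sample_ids]
    hc_meta = hc_meta.loc[hc_ids]
    age, sex, both_sexes = _hc_design(hc_meta)
    models: dict[str, AdjustmentModel] = {}
    if not remaining:
        return models
    Y = matrix.values.loc[hc_ids, remaining].to_numpy()
    hc_means = Y.mean(axis=0)
    cols = [np.ones_like(age), age] + ([sex] if both_sexes else [])
    X = np.column_stack(cols)
    fit = multi_ols(X, Y)
    _, qvals, _, _ = multipletests(fit.f_p, method="fdr_bh")
    for j, sid in enumerate(remaining):
        if qvals[j] < fdr_cut:
            covs = ("age", "sex") if both_sexes else ("age",)
            models[sid] = AdjustmentModel(
                somamer_id=sid, mode="internal-FDR",
                intercept=float(fit.coef[0, j]),
                age_coefficient=float(fit.coef[1, j]),
                sex_coefficient=float(fit.coef[2, j]) if both_sexes else 0.0,
                covariates=covs)
        else:
            models[sid] = AdjustmentModel(somamer_id=sid, mode="mean-only",
                                          hc_mean=float(hc_means[j]))
    return models


def fit_adjustment(matrix: ProteomicMatrix, hc_meta: pd.DataFrame,
                   reference: pd.DataFrame | None = None,
                   p_cut: float = 0.05, fdr_cut: float = 0.05
                   ) -> dict[str, AdjustmentModel]:
    """Both steps: reference-confirmed first, internal FDR on the rest."""
    models: dict[str, AdjustmentModel] = {}
    if reference is not None and len(reference):
        models = fit_reference_confirmed(matrix, hc_meta, reference, p_cut)
    remaining = [s for s in matrix.somamer_ids if s not in models]
    models.update(fit_internal(matrix, hc_meta, remaining, fdr_cut))
    return models


def apply_adjustment(matrix: ProteomicMatrix,
                     models: dict[str, AdjustmentModel],
                     meta: pd.DataFrame, hc_ids: list[str]
                     ) -> AdjustedMatrix:
    """Subtract HC-fitted predictions from all samples and scale to HC z.

    ``meta`` must carry ``age`` and ``sex`` for every sample in the matrix.
    Somamers with zero HC variance after adjustment are dropped with a
    warning.
    """
    missing = [s for s in matrix.somamer_ids if s not in models]
    if missing:
        raise ValueError(f"{len(missing)} somamers lack adjustment models "
                         f"(first: {missing[0]!r})")
    meta = meta.loc[matrix.sample_ids]
    age = meta["age"].to_numpy(dtype=float)
    sex = meta["sex"].map(SEX_CODE).to_numpy(dtype=float)
    hc_ids = [s for s in hc_ids if s in matrix.sample_ids]
    hc_pos = matrix.values.index.get_indexer(hc_ids)

    out = {}
    kept_models = {}
    for sid in matrix.somamer_ids:
        m = models[sid]
        adj = matrix.values[sid].to_numpy(dtype=float) - m.predict(age, sex)
        hc_adj = adj[hc_pos]
        hc_sd = float(hc_adj.std(ddof=1))
        if hc_sd <= 0 or not np.isfinite(hc_sd):
            warnings.warn(f"somamer {sid!r} has zero HC variance; excluded")
            continue
        # recenter on the (numerically ~0) HC mean before scaling so the
        # HC mean-0 / SD-1 contract holds to machine precision
        adj = (adj - hc_adj.mean()) / hc_sd
        m.hc_sd = hc_sd
        kept_models[sid] = m
        out[sid] = adj
    values = pd.DataFrame(out, index=matrix.sample_ids)
    return AdjustedMatrix(values=values, models=kept_models)


def adjust_pipeline(matrix: ProteomicMatrix, meta: pd.DataFrame,
                    reference: pd.DataFrame | None = None,
                    p_cut: float = 0.05, fdr_cut: float = 0.05
                    ) -> AdjustedMatrix:
    """Fit on HC (diagnosis == "HC" in ``meta``) and apply to all samples."""
    hc_ids = [s for s in matrix.sample_ids
              if meta.at[s, "diagnosis"] == "HC"]
    hc_meta = meta.loc[hc_ids]
    models = fit_adjustment(matrix, hc_meta, reference, p_cut, fdr_cut)
    return apply_adjustment(matrix, models, meta, hc_ids)
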