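"""Composite clinical disability outcomes.

Four outcomes summarize per-visit clinical and imaging measures:

* **CombiWISE** — a weighted linear combination of EDSS, SNRS, T25FW and
  non-dominant-hand 9HPT on a nominal 0-100 scale (higher = more physical
  disability).  The published component weights are external to this
  package; they are supplied as configuration, with a documented placeholder
  default that reconstructs the generator's disability scale.
* **Brain damage** — first principal component of standardized BPFr and
  SDMT, sign-oriented so that higher = worse (negative correlation with
  BPFr); a cognitive/atrophy composite.
* **GMSD** — global MS disability: sum of z-scored CombiWISE and Brain
  damage.
* **SC disability** — residual of CombiWISE regressed on Brain damage;
  physical disability in excess of what brain damage predicts, attributed
  to spinal cord injury.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linmod import simple_slope

COMBIWISE_COMPONENTS = ("EDSS", "SNRS", "T25FW", "NHPT")


@dataclass
class CombiWISEWeights:
    """Component weights, orientations (+1 higher=worse, -1 inverted) and
    offset for the CombiWISE linear combination."""

    weights: dict[str, float]
    orientations: dict[str, int] = field(
        default_factory=lambda: {"EDSS": 1, "SNRS": -1, "T25FW": 1,
                                 "NHPT": 1})
    offset: float = 0.0
    source: str = "configuration"

    def validate(self) -> None:
        for comp in COMBIWISE_COMPONENTS:
            if comp not in self.weights:
                raise ValueError(f"missing CombiWISE weight for {comp}")
            if not np.isfinite(self.weights[comp]):
                raise ValueError(f"non-finite weight for {comp}")


def default_combiwise_weights() -> CombiWISEWeights:
    """Placeholder weights on the documented 0-100 scale.

    Chosen so the combination inverts the synthetic generator's component
    model (EDSS ~ d/15, SNRS ~ 100 - 0.8 d, T25FW ~ 4 + 0.2 d,
    9HPT ~ 18 + 0.15 d for latent disability d in 0-100); each component
    contributes the fraction of the total written in its weight.  Replace
    with the published weights when scoring real data.
    """
    w = {"EDSS": 6.0 / 1.4, "SNRS": 0.5 / 1.4, "T25FW": 1.5 / 1.4,
         "NHPT": 2.0 / 1.4}
    # constant terms of the component models, absorbed into the offset
    offset = (0.5 / 1.4) * 100.0 - (1.5 / 1.4) * 4.0 - (2.0 / 1.4) * 18.0
    return CombiWISEWeights(weights=w, offset=offset,
                            source="synthetic-generator placeholder")


def compute_combiwise(clin: pd.DataFrame,
                      weights: CombiWISEWeights) -> pd.Series:
    """Weighted disability combination; rows missing a component are NaN."""
    weights.validate()
    missing = [c for c in COMBIWISE_COMPONENTS if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns {missing}")
    score = pd.Series(weights.offset, index=clin.index, dtype=float)
    for comp in COMBIWISE_COMPONENTS:
        score = score + (weights.weights[comp]
                         * weights.orientations.get(comp, 1)
                         * clin[comp].astype(float))
    n_missing = int(score.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} visits lack CombiWISE components; "
                      "scores set to NaN")
    return score.rename("CombiWISE")


def compute_brain_damage(clin: pd.DataFrame) -> pd.Series:
    """PC1 of standardized BPFr and SDMT, oriented so higher = worse."""
    sub = clin[["BPFr", "SDMT"]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 visits with both BPFr and SDMT")
    z = sub.to_numpy(dtype=float)
    sd = z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance in BPFr or SDMT")
    z = (z - z.mean(axis=0)) / sd
    # PC1 via SVD of the standardized 2-column matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = z @ vt[0]
    r = np.corrcoef(pc1, sub["BPFr"].to_numpy(dtype=float))[0, 1]
    if r > 0:   # invert so increasing score = increasing disability
        pc1 = -pc1
    out = pd.Series(np.nan, index=clin.index, dtype=float,
                    name="BrainDamage")
    out.loc[sub.index] = pc1
    return out


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if not sd > 0:
        raise ValueError(f"zero variance in {s.name}")
    return (s - s.mean()) / sd


def compute_gmsd(combiwise: pd.Series, brain_damage: pd.Series,
                 normalization: str = "zscore") -> pd.Series:
    """Global MS disability: sum of normalized CombiWISE and Brain damage."""
    if normalization == "zscore":
        a, b = _zscore(combiwise), _zscore(brain_damage)
    elif normalization == "minmax":
        a = (combiwise - combiwise.min()) / (combiwise.max() - combiwise.min())
        b = (brain_damage - brain_damage.min()) / \
            (brain_damage.max() - brain_damage.min())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return (a + b).rename("GMSD")


def compute_sc_disability(combiwise: pd.Series,
                          brain_damage: pd.Series) -> pd.Series:
    """Residual of CombiWISE (y) on Brain damage (x); mean 0 by construction."""
    paired = pd.concat([combiwise, brain_damage], axis=1).dropna()
    if len(paired) < 3:
        raise ValueError("need >= 3 paired CombiWISE / Brain damage scores")
    x = paired.iloc[:, 1].to_numpy(dtype=float)
    y = paired.iloc[:, 0].to_numpy(dtype=float)
    slope, intercept = simple_slope(x, y)
    resid = y - (intercept + slope * x)
    out = pd.Series(np.nan, index=combiwise.index, dtype=float,
                    name="SCDisability")
    out.loc[paired.index] = resid
    return out


def build_outcome_table(clin: pd.DataFrame,
                        weights: CombiWISEWeights | None = None
                        ) -> pd.DataFrame:
    """All four composite outcomes for a clinical table (one row per visit)."""
    weights = weights or default_combiwise_weights()
    cw = compute_combiwise(clin, weights)
    bd = compute_brain_damage(clin)
    gmsd = compute_gmsd(cw, bd)
    scd = compute_sc_disability(cw, bd)
    return pd.DataFrame({"CombiWISE": cw, "BrainDamage": bd,
                         "GMSD": gmsd, "SCDisability": scd})
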