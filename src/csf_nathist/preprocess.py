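"""QC and signal-to-noise filtering of the log-RFU matrix.

Stages, in pipeline order: natural-log transform of raw RFUs; Tukey-fence
outlier flagging in healthy controls with whole-sample dropping; per-somamer
signal-to-noise ratio (SNR) from a variance decomposition that contrasts
between-patient biological spread in MS with within-patient technical spread
in longitudinal healthy-control repeats; SNR filtering; and flooring of
extreme MS values to +/- 3*IQR fences so downstream linear models see
approximately Gaussian inputs.

SNR = sigma_clin^2 / (sigma_clin^2 + sigma_tech^2), where sigma_clin is the
residual SD of the intercept-only model over MS samples and sigma_tech the
residual (within-patient) SD of a random-intercept model over longitudinal
healthy-control samples.  An SNR near 1 means the assay's technical noise is
small relative to true biological variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


@dataclass
class ProteomicMatrix:
    """Samples x somamers matrix with per-sample plate labels."""

    values: pd.DataFrame          # index = sample_id, columns = somamer_id
    plate: pd.Series | None = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicated sample IDs")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated somamer IDs")
        if self.plate is not None:
            self.plate = self.plate.reindex(self.values.index)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def somamer_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, samples: Sequence[str] | None = None,
               somamers: Sequence[str] | None = None) -> "ProteomicMatrix":
        v = self.values
        if samples is not None:
            v = v.loc[list(samples)]
        if somamers is not None:
            v = v[list(somamers)]
        plate = self.plate.loc[v.index] if self.plate is not None else None
        return ProteomicMatrix(values=v, plate=plate)

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        if self.plate is not None:
            df.insert(0, "plate", self.plate)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProteomicMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        plate = None
        if "plate" in df.columns:
            plate = df.pop("plate")
        return cls(values=df.astype(float), plate=plate)


@dataclass
class OutlierFences:
    q1: float
    q3: float
    k: float
    center: str = "quartile"   # "quartile" (Tukey) or "median"
    median: float = 0.0

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lo(self) -> float:
        base = self.q1 if self.center == "quartile" else self.median
        return base - self.k * self.iqr

    @property
    def hi(self) -> float:
        base = self.q3 if self.center == "quartile" else self.median
        return base + self.k * self.iqr


@dataclass
class QCReport:
    flagged_fraction: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    dropped_samples: list[str] = field(default_factory=list)
    floored_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def to_json_dict(self) -> dict:
        return {"flagged_fraction": self.flagged_fraction.to_dict(),
                "dropped_samples": list(self.dropped_samples),
                "floored_counts": {k: int(v) for k, v
                                   in self.floored_counts.items()}}


@dataclass
class SNRRecord:
    somamer_id: str
    sigma_clin: float
    sigma_tech: float
    snr: float
    passed: bool
    degenerate: bool = False


def log_transform(raw: ProteomicMatrix) -> ProteomicMatrix:
    """Elementwise natural log of raw RFUs."""
    vals = raw.values
    bad = vals <= 0
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive RFU at sample {vals.index[i]!r}, "
            f"somamer {vals.columns[j]!r}")
    return ProteomicMatrix(values=np.log(vals), plate=raw.plate)


def _fences_frame(df: pd.DataFrame, k: float,
                  center: str = "quartile") -> tuple[pd.Series, pd.Series]:
    """Per-column (lo, hi) fences; linear-interpolation quantiles."""
    q1 = df.quantile(0.25)
    q3 = df.quantile(0.75)
    iqr = q3 - q1
    if center == "quartile":
        return q1 - k * iqr, q3 + k * iqr
    if center == "median":
        med = df.median()
        return med - k * iqr, med + k * iqr
    raise ValueError(f"unknown fence center {center!r}")


def qc_hc_samples(matrix: ProteomicMatrix, hc_ids: Sequence[str],
                  flag_k: float = 1.5, drop_frac: float = 0.15,
                  center: str = "quartile"
                  ) -> tuple[ProteomicMatrix, QCReport]:
    """Flag HC outlier values per somamer and drop contaminated HC samples.

    Fences are computed over the HC cohort only; an HC sample whose flagged
    fraction exceeds ``drop_frac`` is removed from the whole matrix.  MS
    samples are never dropped.
    """
    hc_ids = [s for s in hc_ids if s in matrix.sample_ids]
    if len(hc_ids) < 4:
        raise ValueError("need at least 4 HC samples for quartile fences")
    hc = matrix.values.loc[hc_ids]
    lo, hi = _fences_frame(hc, flag_k, center)
    flagged = (hc.lt(lo, axis=1) | hc.gt(hi, axis=1))
    frac = flagged.mean(axis=1)
    dropped = list(frac.index[frac > drop_frac])
    if len(dropped) == len(hc_ids):
        raise ValueError("all HC samples exceeded the outlier drop threshold")
    keep = [s for s in matrix.sample_ids if s not in set(dropped)]
    report = QCReport(flagged_fraction=frac, dropped_samples=dropped)
    return matrix.subset(samples=keep), report


def _reml_sigma_tech(y: np.ndarray, groups: np.ndarray) -> float:
    """Residual SD of the one-way random-intercept model, by profile REML.

    The restricted likelihood is profiled down to the variance ratio
    lambda = sigma_b^2 / sigma_e^2 and optimized on a log grid; the
    method-of-moments (two-level ANOVA) estimator is the fallback when the
    optimizer fails.  On balanced designs the two coincide.
    """
    uniq, inv = np.unique(groups, return_inverse=True)
    m = len(uniq)
    n = len(y)
    counts = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=y)
    means = sums / counts
    ss_within = float(np.sum((y - means[inv]) ** 2))

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = counts / (1.0 + lam * counts)
        mu = float(np.sum(w * means) / np.sum(w))
        q = ss_within + float(np.sum(counts * (means - mu) ** 2
                                     / (1.0 + lam * counts)))
        sigma_e2 = q / (n - 1)
        return ((n - 1) * np.log(sigma_e2)
                + float(np.sum(np.log1p(lam * counts)))
                + np.log(float(np.sum(w))))

    mom = _anova_sigma_tech(y, groups)
    if ss_within <= 0:
        return 0.0
    try:
        res = minimize_scalar(neg2_reml, bounds=(-12.0, 12.0),
                              method="bounded",
                              options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        # boundary: random-effect variance collapses to ~0
        if res.x <= -11.9:
            lam = 0.0
        w = counts / (1.0 + lam * counts)
        mu = float(np.sum(w * means) / np.sum(w))
        q = ss_within + float(np.sum(counts * (means - mu) ** 2
                                     / (1.0 + lam * counts)))
        sigma_e2 = q / (n - 1)
        return float(np.sqrt(max(sigma_e2, 0.0)))
    except Exception:
        return mom


def _anova_sigma_tech(y: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments within-group SD (two-level ANOVA), floored at 0."""
    uniq, inv = np.unique(groups, return_inverse=True)
    m = len(uniq)
    n = len(y)
    if n <= m:
        return 0.0
    counts = np.bincount(inv).astype(float)
    means = np.bincount(inv, weights=y) / counts
    ss_within = float(np.sum((y - means[inv]) ** 2))
    return float(np.sqrt(max(ss_within / (n - m), 0.0)))


def compute_snr(matrix: ProteomicMatrix, ms_ids: Sequence[str],
                hc_longitudinal: Mapping[str, Sequence[str]],
                threshold: float = 0.8,
                estimator: str = "reml") -> list[SNRRecord]:
    """Per-somamer SNR from MS cross-sectional and HC longitudinal samples.

    ``hc_longitudinal`` maps patient -> that patient's repeat sample IDs;
    only patients with >= 2 samples contribute to sigma_tech.
    """
    long_pairs = [(pid, sid) for pid, sids in hc_longitudinal.items()
                  for sid in sids if sid in matrix.sample_ids]
    groups = np.array([p for p, _ in long_pairs])
    long_samples = [s for _, s in long_pairs]
    n_multi = sum(1 for pid in set(groups)
                  if np.sum(groups == pid) >= 2)
    if n_multi < 2:
        raise ValueError("need >= 2 HC patients with >= 2 samples each")
    ms_ids = [s for s in ms_ids if s in matrix.sample_ids]
    if len(ms_ids) < 2:
        raise ValueError("need >= 2 MS samples")

    ms_vals = matrix.values.loc[ms_ids].to_numpy()
    sigma_clin = ms_vals.std(axis=0, ddof=1)
    hc_vals = matrix.values.loc[long_samples].to_numpy()

    records = []
    est = _reml_sigma_tech if estimator == "reml" else _anova_sigma_tech
    for j, somamer in enumerate(matrix.somamer_ids):
        sc = float(sigma_clin[j])
        st = float(est(hc_vals[:, j], groups))
        denom = sc * sc + st * st
        if denom <= 0:
            records.append(SNRRecord(somamer, sc, st, np.nan, False,
                                     degenerate=True))
            continue
        snr = sc * sc / denom
        records.append(SNRRecord(somamer, sc, st, snr, snr >= threshold))
    return records


def filter_by_snr(records: Iterable[SNRRecord],
                  threshold: float = 0.8) -> list[str]:
    """Somamer IDs with SNR >= threshold (inclusive), input order kept."""
    return [r.somamer_id for r in records
            if not r.degenerate and r.snr >= threshold]


def snr_table(records: Iterable[SNRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"somamer_id": r.somamer_id, "sigma_clin": r.sigma_clin,
          "sigma_tech": r.sigma_tech, "snr": r.snr, "passed": r.passed}
         for r in records]).set_index("somamer_id")


def floor_ms_outliers(matrix: ProteomicMatrix, ms_ids: Sequence[str],
                      k: float = 3.0, center: str = "quartile"
                      ) -> tuple[ProteomicMatrix, QCReport]:
    """Clamp extreme MS values to per-somamer +/- ``k``*IQR fences.

    Values are floored rather than removed: MS heterogeneity can produce
    biologically real extremes, but unbounded outliers would dominate the
    downstream linear models.  Only MS rows are modified.
    """
    ms_ids = [s for s in ms_ids if s in matrix.sample_ids]
    if len(ms_ids) < 4:
        raise ValueError("need at least 4 MS samples for quartile fences")
    vals = matrix.values.copy()
    ms = vals.loc[ms_ids]
    lo, hi = _fences_frame(ms, k, center)
    floored = ms.clip(lower=lo, upper=hi, axis=1)
    counts = (floored != ms).sum(axis=0)
    vals.loc[ms_ids] = floored
    report = QCReport(floored_counts=counts)
    return ProteomicMatrix(values=vals, plate=matrix.plate), report


def plate_normalize(matrix: ProteomicMatrix,
                    control_ids: Sequence[str]) -> ProteomicMatrix:
    """Optional additive plate correction (disabled by default upstream).

    Subtracts, per somamer, each plate's median offset estimated on the
    given control/HC samples.  A minimal stand-in for vendor plate
    calibration; plates without control samples are left unshifted.
    """
    if matrix.plate is None:
        raise ValueError("matrix has no plate labels")
    vals = matrix.values.copy()
    controls = set(control_ids) & set(matrix.sample_ids)
    if not controls:
        warnings.warn("no control samples found; plate normalization skipped")
        return matrix
    ctrl_vals = matrix.values.loc[sorted(controls)]
    grand = ctrl_vals.median()
    for plate, plate_samples in matrix.plate.groupby(matrix.plate).groups.items():
        plate_ctrl = [s for s in plate_samples if s in controls]
        if not plate_ctrl:
            continue
        offset = matrix.values.loc[plate_ctrl].median() - grand
        vals.loc[list(plate_samples)] = vals.loc[list(plate_samples)] - offset
    return ProteomicMatrix(values=vals, plate=matrix.plate)
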