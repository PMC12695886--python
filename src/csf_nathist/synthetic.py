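"""Synthetic natural-history cohort generator with planted ground truth.

Emulates the data layout of an untreated-MS CSF aptamer-proteomics study:
a sample x somamer relative-fluorescence matrix with plate labels,
per-sample demographics and treatment state, per-visit clinical/imaging
outcomes, a gene x cell-type nTPM table, a GMT pathway file and an external
age/sex reference list.  Every planted effect (age slope, sex offset,
outcome loading, cluster co-regulation, cell-type label, per-patient
progression slope) is recorded in a :class:`GroundTruth` object so each
downstream stage can be tested against known truth.

The generative model is multiplicative on the raw scale: log-RFU values are
Gaussian, ``value = mu + age/sex effects + outcome-latent loadings +
patient random effect (SD ``clin_sd``) + visit noise (SD ``tech_sd``)``,
and the written matrix is ``exp`` of that.  Disease-linked somamer signal
rides on three per-visit latent variables — physical disability (the
CombiWISE generator), brain damage (atrophy/cognition) and lesion activity
(CEL/NEFL) — which also generate the clinical table, so cross-sectional
associations and composite outcomes are internally consistent.  Healthy
controls sit at latent 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Cell types matched between the proteome and single-cell expression data.
CELL_TYPES = (
    "Astrocytes", "B cells", "Dendritic cells", "Endothelial cells",
    "Excitatory neurons", "Fibroblasts", "Granulocytes",
    "Inhibitory neurons", "Lymphatic endothelial cells", "Macrophages",
    "Microglial cells", "Monocytes", "NK cells", "OPC", "Oligodendrocytes",
    "Plasma cells", "Schwann cells", "T cells",
)

#: Latent variables a somamer may load on, and the clinical anchor of each.
OUTCOME_LATENTS = ("combiwise", "brain_damage", "lesion")

MS_SUBTYPES = ("RRMS", "SPMS", "PPMS")


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Counts and noise levels default to a desk-scale rendition of the real
    cohort: healthy controls with a longitudinal subset providing repeat
    lumbar punctures, three MS subtypes with RRMS youngest, within-patient
    technical SD 0.5 and between-patient biological SD 1.5 on the log scale
    (signal-to-noise ratio ~0.9), and a mean disability progression of
    1.45 CombiWISE units per year.
    """

    n_hc_patients: int = 40
    n_hc_longitudinal: int = 12
    n_ms_patients: dict[str, int] = field(
        default_factory=lambda: {"RRMS": 100, "SPMS": 100, "PPMS": 100})
    n_somamer: int = 500
    frac_age_assoc: float = 0.10
    frac_sex_assoc: float = 0.06
    frac_outcome_assoc: dict[str, float] = field(
        default_factory=lambda: {"combiwise": 0.10, "brain_damage": 0.04,
                                 "lesion": 0.06})
    effect_scale: float = 1.0          # effect sizes in units of clin_sd
    tech_sd: float = 0.5               # within-patient log-RFU SD
    clin_sd: float = 1.5               # between-patient biological log-RFU SD
    visit_interval_years: tuple[float, float] = (1.5, 3.0)
    plate_size: int = 96
    plate_effect_sd: float = 0.0       # optional additive per-plate shift
    outlier_rate: float = 0.001
    frac_ms_longitudinal: float = 0.5
    ms_visits: tuple[int, int] = (2, 5)     # LP count range for longitudinal MS
    frac_first_lp_untreated: float = 0.9
    prob_start_treatment: float = 0.4
    prog_slope_mean: float = 1.45      # CombiWISE units / year
    prog_slope_sd: float = 1.2
    frac_destructive: float = 0.2      # patients with extra NEFL per lesion
    destructive_delta: float = 0.5     # log-NEFL offset of that subgroup
    n_pathways: int = 8
    pathway_size: tuple[int, int] = (6, 12)
    n_cluster_groups: int = 4
    cluster_size: tuple[int, int] = (3, 6)
    frac_celltype_labeled: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_hc_patients", "n_somamer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.n_ms_patients.values()):
            raise ValueError("n_ms_patients counts must be positive")
        fracs = {"frac_age_assoc": self.frac_age_assoc,
                 "frac_sex_assoc": self.frac_sex_assoc,
                 "outlier_rate": self.outlier_rate,
                 "frac_ms_longitudinal": self.frac_ms_longitudinal,
                 **{f"frac_outcome_assoc[{k}]": v
                    for k, v in self.frac_outcome_assoc.items()}}
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tech_sd <= 0 or self.clin_sd <= 0:
            raise ValueError("tech_sd and clin_sd must be > 0")
        if self.n_hc_longitudinal > self.n_hc_patients:
            raise ValueError("n_hc_longitudinal exceeds n_hc_patients")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("visit_interval_years", "ms_visits", "pathway_size",
                    "cluster_size"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted parameters of a generated cohort, queryable by somamer ID."""

    somamers: pd.DataFrame      # indexed by somamer_id
    patients: pd.DataFrame      # indexed by patient_id
    latents: pd.DataFrame       # indexed by sample_id: the three latents
    pathways: dict[str, list[str]]
    cluster_groups: dict[str, list[str]]
    outliers: list[tuple[str, str]]
    config: CohortConfig

    def planted(self, kind: str) -> pd.Index:
        """Somamer IDs carrying a planted effect of ``kind``.

        ``kind`` is ``"age"``, ``"sex"`` or one of the outcome-latent names.
        """
        if kind == "age":
            return self.somamers.index[self.somamers["age_slope"] != 0]
        if kind == "sex":
            return self.somamers.index[self.somamers["sex_offset"] != 0]
        col = f"beta_{kind}"
        if col not in self.somamers:
            raise KeyError(f"unknown effect kind {kind!r}")
        return self.somamers.index[self.somamers[col] != 0]

    def null_somamers(self) -> pd.Index:
        """Somamers with no planted effect of any class."""
        s = self.somamers
        effect_cols = ["age_slope", "sex_offset"] + \
            [f"beta_{k}" for k in OUTCOME_LATENTS]
        mask = (s[effect_cols] == 0).all(axis=1) & (s["cluster_group"] == "")
        return s.index[mask]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "somamers": self.somamers.reset_index().to_dict(orient="list"),
            "patients": self.patients.reset_index().to_dict(orient="list"),
            "latents": self.latents.reset_index().to_dict(orient="list"),
            "pathways": self.pathways,
            "cluster_groups": self.cluster_groups,
            "outliers": [list(t) for t in self.outliers],
            "config": _config_to_dict(self.config),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cfg_raw = payload["config"]
        for key in ("visit_interval_years", "ms_visits", "pathway_size",
                    "cluster_size"):
            cfg_raw[key] = tuple(cfg_raw[key])
        return cls(
            somamers=pd.DataFrame(payload["somamers"]).set_index("somamer_id"),
            patients=pd.DataFrame(payload["patients"]).set_index("patient_id"),
            latents=pd.DataFrame(payload["latents"]).set_index("sample_id"),
            pathways=payload["pathways"],
            cluster_groups=payload["cluster_groups"],
            outliers=[tuple(t) for t in payload["outliers"]],
            config=CohortConfig(**cfg_raw),
        )


def _config_to_dict(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("visit_interval_years", "ms_visits", "pathway_size",
                "cluster_size"):
        d[key] = list(d[key])
    return d


# ---------------------------------------------------------------------------
# patient / visit scaffolding
# ---------------------------------------------------------------------------

_AGE_DIST = {  # (mean, sd); RRMS youngest, progressive subtypes older
    "RRMS": (35.0, 8.0),
    "SPMS": (50.0, 9.0),
    "PPMS": (52.0, 9.0),
}

_CW_BASELINE = {  # CombiWISE-scale baseline disability by subtype
    "RRMS": (20.0, 10.0),
    "SPMS": (55.0, 12.0),
    "PPMS": (50.0, 12.0),
}

_LESION_OFFSET = {"RRMS": 1.0, "SPMS": 0.0, "PPMS": -0.2}


def _make_patients(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_hc_patients):
        rows.append({
            "patient_id": f"HC{i + 1:03d}", "diagnosis": "HC",
            "sex": "M" if rng.random() < 0.5 else "F",
            "age_first": rng.uniform(18.0, 75.0),
            "longitudinal": i < cfg.n_hc_longitudinal,
            "prog_slope": 0.0, "cw0": float(np.abs(rng.normal(1.0, 1.0))),
            "destructive": False,
        })
    for subtype in MS_SUBTYPES:
        mu, sd = _AGE_DIST[subtype]
        c0, c0sd = _CW_BASELINE[subtype]
        for i in range(cfg.n_ms_patients.get(subtype, 0)):
            rows.append({
                "patient_id": f"{subtype}{i + 1:03d}", "diagnosis": subtype,
                "sex": "M" if rng.random() < 0.4 else "F",
                "age_first": float(np.clip(rng.normal(mu, sd), 18.0, 80.0)),
                "longitudinal": rng.random() < cfg.frac_ms_longitudinal,
                "prog_slope": float(rng.normal(cfg.prog_slope_mean,
                                               cfg.prog_slope_sd)),
                "cw0": float(np.clip(rng.normal(c0, c0sd), 0.0, 90.0)),
                "destructive": rng.random() < cfg.frac_destructive,
            })
    df = pd.DataFrame(rows).set_index("patient_id")
    df["bmi"] = np.clip(rng.normal(27.0, 5.0, len(df)), 17.0, 45.0)
    df["smoker"] = rng.random(len(df)) < 0.25
    df["race"] = rng.choice(["White", "African American", "Other"],
                            size=len(df), p=[0.65, 0.25, 0.10])
    df["hla_drb1_copies"] = rng.binomial(2, 0.3, len(df))
    return df


def _make_visits(cfg: CohortConfig, patients: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """One row per visit; ``has_lp`` marks visits with a CSF sample."""
    lo, hi = cfg.visit_interval_years
    rows = []
    for pid, p in patients.iterrows():
        if p["diagnosis"] == "HC":
            n_lp = 2 if p["longitudinal"] else 1
            ages = [p["age_first"]]
            for _ in range(n_lp - 1):
                ages.append(ages[-1] + rng.uniform(lo, hi))
            for v, age in enumerate(ages):
                rows.append({"patient_id": pid, "visit": v, "age": age,
                             "has_lp": True, "treated": False,
                             "treatment": ""})
            continue
        n_lp = int(rng.integers(cfg.ms_visits[0], cfg.ms_visits[1] + 1)) \
            if p["longitudinal"] else 1
        lp_ages = [p["age_first"]]
        for _ in range(n_lp - 1):
            lp_ages.append(lp_ages[-1] + rng.uniform(lo, hi))
        # clinic-only follow-up visits interleaved after the first LP
        n_clinic = int(rng.poisson(3)) if p["longitudinal"] else 0
        span = lp_ages[-1] - lp_ages[0] + rng.uniform(0.5, 2.0)
        clinic_ages = sorted(p["age_first"] + rng.uniform(0.2, max(span, 0.4),
                                                          n_clinic))
        visits = sorted([(a, True) for a in lp_ages] +
                        [(a, False) for a in clinic_ages])
        first_untreated = rng.random() < cfg.frac_first_lp_untreated
        if rng.random() < cfg.prob_start_treatment and len(visits) > 1:
            start_idx = int(rng.integers(1, len(visits)))
        else:
            start_idx = len(visits)
        drug = rng.choice(["interferon-beta", "glatiramer", "ocrelizumab",
                           "natalizumab"])
        for v, (age, has_lp) in enumerate(visits):
            treated = v >= start_idx or (v == 0 and not first_untreated)
            rows.append({"patient_id": pid, "visit": v, "age": age,
                         "has_lp": has_lp, "treated": treated,
                         "treatment": drug if treated else ""})
    return pd.DataFrame(rows)


def _clinical_and_latents(cfg: CohortConfig, patients: pd.DataFrame,
                          visits: pd.DataFrame,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Per-visit clinical measures plus the three generating latents."""
    p = patients.loc[visits["patient_id"]].reset_index()
    is_hc = (p["diagnosis"] == "HC").to_numpy()
    age = visits["age"].to_numpy()
    dt = age - p["age_first"].to_numpy()
    n = len(visits)

    cw = p["cw0"].to_numpy() + p["prog_slope"].to_numpy() * dt \
        + rng.normal(0.0, 1.0, n)
    cw = np.where(is_hc, p["cw0"].to_numpy(), np.clip(cw, 0.0, 100.0))
    dz = np.where(is_hc, 0.0, (cw - 40.0) / 20.0)

    a_pat = pd.Series(rng.normal(0.0, 0.8, len(patients)),
                      index=patients.index)
    bd = np.where(is_hc, 0.0,
                  0.6 * dz + a_pat.loc[p["patient_id"]].to_numpy())

    l_pat = pd.Series(rng.normal(0.0, 1.0, len(patients)),
                      index=patients.index)
    lesion = (p["diagnosis"].map(_LESION_OFFSET).fillna(0.0).to_numpy()
              - 0.04 * (age - 40.0)
              + l_pat.loc[p["patient_id"]].to_numpy()
              + rng.normal(0.0, 0.5, n))
    lesion = np.where(is_hc, 0.0, lesion)

    clin = pd.DataFrame({
        "patient_id": visits["patient_id"].to_numpy(),
        "visit": visits["visit"].to_numpy(),
        "age": age,
        "has_lp": visits["has_lp"].to_numpy(),
        "treated": visits["treated"].to_numpy(),
        "treatment": visits["treatment"].to_numpy(),
        "sex": p["sex"].to_numpy(),
        "diagnosis": p["diagnosis"].to_numpy(),
    })
    clin["EDSS"] = np.clip(cw / 15.0 + rng.normal(0, 0.3, n), 0.0, 10.0)
    clin["SNRS"] = np.clip(100.0 - 0.8 * cw + rng.normal(0, 2.0, n),
                           0.0, 100.0)
    clin["T25FW"] = np.maximum(4.0 + 0.20 * cw + rng.normal(0, 0.8, n), 2.0)
    clin["NHPT"] = np.maximum(18.0 + 0.15 * cw + rng.normal(0, 0.8, n), 12.0)
    clin["SDMT"] = np.clip(55.0 - 8.0 * bd - 0.15 * (age - 20.0)
                           + rng.normal(0, 3.0, n), 0.0, 110.0)
    clin["BPFr"] = np.clip(0.87 - 0.0015 * (age - 20.0) - 0.03 * bd
                           + rng.normal(0, 0.008, n), 0.60, 0.95)
    clin["CEL"] = np.where(is_hc, 0,
                           rng.poisson(np.exp(np.clip(0.7 * lesion, -6, 2.5))))
    clin["T2LL"] = np.where(
        is_hc, np.exp(0.2 + rng.normal(0, 0.3, n)),
        np.exp(1.5 + 0.35 * dz + 0.30 * lesion + rng.normal(0, 0.4, n)))
    destr = p["destructive"].to_numpy() & ~is_hc
    clin["NEFL"] = np.exp(6.0 + 0.02 * (age - 40.0)
                          + np.where(is_hc, 0.0, 0.3 + 0.45 * lesion
                                     + 0.30 * dz)
                          + destr * cfg.destructive_delta
                          + rng.normal(0, 0.35, n))
    clin["BMI"] = p["bmi"].to_numpy()
    clin["smoker"] = p["smoker"].to_numpy()
    clin["race"] = p["race"].to_numpy()
    clin["hla_drb1_copies"] = p["hla_drb1_copies"].to_numpy()
    clin["latent_combiwise"] = dz
    clin["latent_brain_damage"] = bd
    clin["latent_lesion"] = lesion
    return clin


# ---------------------------------------------------------------------------
# somamer truth and value generation
# ---------------------------------------------------------------------------

def _make_somamer_truth(cfg: CohortConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    m = cfg.n_somamer
    ids = [f"SL{j + 1:05d}" for j in range(m)]
    truth = pd.DataFrame(index=pd.Index(ids, name="somamer_id"))
    truth["gene"] = [f"GENE{j + 1:04d}" for j in range(m)]
    truth["mu"] = rng.normal(8.0, 0.8, m)
    truth["tech_sd"] = cfg.tech_sd
    truth["clin_sd"] = cfg.clin_sd

    signs = lambda k: rng.choice([-1.0, 1.0], k)  # noqa: E731
    age_mask = rng.random(m) < cfg.frac_age_assoc
    truth["age_slope"] = 0.0
    truth.loc[age_mask, "age_slope"] = (
        signs(age_mask.sum()) * cfg.effect_scale * cfg.clin_sd / 30.0)
    sex_mask = rng.random(m) < cfg.frac_sex_assoc
    truth["sex_offset"] = 0.0
    truth.loc[sex_mask, "sex_offset"] = (
        signs(sex_mask.sum()) * cfg.effect_scale * cfg.clin_sd)
    for latent in OUTCOME_LATENTS:
        frac = cfg.frac_outcome_assoc.get(latent, 0.0)
        mask = rng.random(m) < frac
        col = f"beta_{latent}"
        truth[col] = 0.0
        truth.loc[mask, col] = (signs(mask.sum())
                                * cfg.effect_scale * cfg.clin_sd)

    labeled = rng.random(m) < cfg.frac_celltype_labeled
    types = rng.choice(CELL_TYPES, m)
    truth["cell_type"] = np.where(labeled, types, "")

    # designate neurofilament aptamers (lesion-linked axonal-injury markers;
    # downstream lesion modeling must exclude them by gene name)
    lesion_assoc = list(truth.index[truth["beta_lesion"] > 0])
    nef_ids = list(dict.fromkeys(lesion_assoc + list(truth.index)))[:2]
    for sid, gene in zip(nef_ids, ("NEFL", "NEFH")):
        truth.at[sid, "gene"] = gene
        if truth.at[sid, "beta_lesion"] <= 0:
            truth.at[sid, "beta_lesion"] = cfg.effect_scale * cfg.clin_sd
    return truth


def _assign_groups(cfg: CohortConfig, truth: pd.DataFrame,
                   rng: np.random.Generator
                   ) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Split disability-associated somamers into cluster groups and pathways."""
    disab = list(truth.index[truth["beta_combiwise"] != 0])
    rng.shuffle(disab)
    clusters: dict[str, list[str]] = {}
    pos = 0
    budget = len(disab) // 2    # reserve at least half the pool for pathways
    for g in range(cfg.n_cluster_groups):
        size = int(rng.integers(cfg.cluster_size[0], cfg.cluster_size[1] + 1))
        if pos + size > budget:
            break
        members = disab[pos:pos + size]
        if len(members) >= 2:
            clusters[f"CLUSTERGRP{g + 1}"] = sorted(members)
        pos += size
    remaining = disab[pos:]
    truth["cluster_group"] = ""
    for name, members in clusters.items():
        truth.loc[members, "cluster_group"] = name

    pathways: dict[str, list[str]] = {}
    if remaining:
        for k in range(cfg.n_pathways):
            size = int(rng.integers(cfg.pathway_size[0],
                                    cfg.pathway_size[1] + 1))
            size = min(size, len(remaining))
            members = sorted(rng.choice(remaining, size, replace=False))
            pathways[f"PATHWAY_{k + 1:02d}"] = list(members)
    in_pw = sorted({s for mem in pathways.values() for s in mem})
    truth["in_pathway"] = truth.index.isin(in_pw)
    return pathways, clusters


def _generate_values(cfg: CohortConfig, truth: pd.DataFrame,
                     samples: pd.DataFrame, clin_lp: pd.DataFrame,
                     clusters: dict[str, list[str]],
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, list[tuple[str, str]]]:
    n, m = len(samples), len(truth)
    age = samples["age"].to_numpy()
    male = (samples["sex"] == "M").to_numpy().astype(float)
    log_vals = (truth["mu"].to_numpy()[None, :]
                + np.outer(age, truth["age_slope"].to_numpy())
                + np.outer(male, truth["sex_offset"].to_numpy()))
    for latent in OUTCOME_LATENTS:
        lat = clin_lp[f"latent_{latent}"].to_numpy()
        log_vals += np.outer(lat, truth[f"beta_{latent}"].to_numpy())
    patient_ids = samples["patient_id"].to_numpy()
    uniq, inv = np.unique(patient_ids, return_inverse=True)
    # shared co-regulation factor per cluster group: biological, so drawn
    # per patient (constant across a patient's visits)
    col_index = pd.Index(truth.index)
    for members in clusters.values():
        factor = rng.normal(0.0, 1.0, len(uniq))[inv]
        cols = col_index.get_indexer(members)
        log_vals[:, cols] += np.outer(factor, np.full(len(cols),
                                                      2.0 * cfg.clin_sd))
    # patient random effect (biological) + visit noise (technical)
    b = rng.normal(0.0, cfg.clin_sd, (len(uniq), m))
    log_vals += b[inv, :]
    log_vals += rng.normal(0.0, cfg.tech_sd, (n, m))

    if cfg.plate_effect_sd > 0:
        plates = samples["plate"].to_numpy()
        puniq, pinv = np.unique(plates, return_inverse=True)
        shift = rng.normal(0.0, cfg.plate_effect_sd, len(puniq))
        log_vals += shift[pinv][:, None]

    outliers: list[tuple[str, str]] = []
    if cfg.outlier_rate > 0:
        total_sd = float(np.hypot(cfg.clin_sd, cfg.tech_sd))
        mask = rng.random((n, m)) < cfg.outlier_rate
        ii, jj = np.nonzero(mask)
        for i, j in zip(ii, jj):
            k = rng.uniform(5.0, 10.0)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            log_vals[i, j] = truth["mu"].iloc[j] + sign * k * total_sd
            outliers.append((samples.index[i], truth.index[j]))
    return log_vals, outliers


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig):
    """Generate (ProteomicMatrix, sample table, clinical table, GroundTruth).

    The proteomic matrix holds raw RFU values (``exp`` of the Gaussian
    log-scale model) so the preprocessing log transform is meaningful.
    """
    from .preprocess import ProteomicMatrix

    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _make_patients(config, rng)
    visits = _make_visits(config, patients, rng)
    clinical = _clinical_and_latents(config, patients, visits, rng)

    lp_mask = clinical["has_lp"].to_numpy()
    clin_lp = clinical[lp_mask].reset_index(drop=True)
    sample_ids = [f"S{i + 1:05d}" for i in range(len(clin_lp))]
    clinical["sample_id"] = ""
    clinical.loc[clinical.index[lp_mask], "sample_id"] = sample_ids

    samples = pd.DataFrame({
        "patient_id": clin_lp["patient_id"].to_numpy(),
        "diagnosis": clin_lp["diagnosis"].to_numpy(),
        "treated": clin_lp["treated"].to_numpy(),
        "treatment": clin_lp["treatment"].to_numpy(),
        "age": clin_lp["age"].to_numpy(),
        "sex": clin_lp["sex"].to_numpy(),
        "visit": clin_lp["visit"].to_numpy(),
    }, index=pd.Index(sample_ids, name="sample_id"))
    # longitudinal samples of one patient stay on one plate: chunk by patient
    order = samples.sort_values(["patient_id", "visit"]).index
    plate_of = {sid: f"P{pos // config.plate_size + 1:02d}"
                for pos, sid in enumerate(order)}
    samples["plate"] = [plate_of[s] for s in samples.index]

    truth_df = _make_somamer_truth(config, rng)
    pathways, clusters = _assign_groups(config, truth_df, rng)
    log_vals, outliers = _generate_values(config, truth_df, samples, clin_lp,
                                          clusters, rng)

    matrix = ProteomicMatrix(
        values=pd.DataFrame(np.exp(log_vals), index=samples.index,
                            columns=truth_df.index),
        plate=samples["plate"].copy(),
    )
    latents = clin_lp[["latent_combiwise", "latent_brain_damage",
                       "latent_lesion"]].copy()
    latents.index = pd.Index(sample_ids, name="sample_id")
    truth = GroundTruth(somamers=truth_df, patients=patients,
                        latents=latents, pathways=pathways,
                        cluster_groups=clusters, outliers=outliers,
                        config=config)
    clinical = clinical.drop(columns=["latent_combiwise",
                                      "latent_brain_damage",
                                      "latent_lesion"])
    return matrix, samples, clinical, truth


def generate_reference_list(truth: GroundTruth, noise: float = 0.0,
                            seed: int | None = None) -> pd.DataFrame:
    """External age/sex association list: planted entries plus a ``noise``
    fraction of spurious (somamer, covariate, direction) rows."""
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None
                                else seed)
    rows = []
    s = truth.somamers
    for sid in truth.planted("age"):
        rows.append({"somamer_id": sid, "covariate": "age",
                     "direction": "+" if s.at[sid, "age_slope"] > 0 else "-"})
    for sid in truth.planted("sex"):
        rows.append({"somamer_id": sid, "covariate": "sex",
                     "direction": "+" if s.at[sid, "sex_offset"] > 0 else "-"})
    n_true = len(rows)
    n_false = int(round(noise / (1.0 - noise) * n_true))
    planted_pairs = {(r["somamer_id"], r["covariate"]) for r in rows}
    candidates = [(sid, cov) for sid in s.index for cov in ("age", "sex")
                  if (sid, cov) not in planted_pairs
                  and s.at[sid, "age_slope" if cov == "age"
                           else "sex_offset"] == 0]
    pick = rng.choice(len(candidates), size=min(n_false, len(candidates)),
                      replace=False)
    for idx in pick:
        sid, cov = candidates[idx]
        rows.append({"somamer_id": sid, "covariate": cov,
                     "direction": rng.choice(["+", "-"])})
    return pd.DataFrame(rows, columns=["somamer_id", "covariate", "direction"])


def generate_celltype_table(truth: GroundTruth,
                            seed: int | None = None) -> pd.DataFrame:
    """Gene x cell-type nTPM table consistent with the planted labels.

    Labeled genes satisfy the specificity rule (max nTPM > 5 and
    max/median > 5) for their labeled type; unlabeled genes fail it either
    by a flat profile (ratio ~1) or a low-expression profile (max < 5).
    """
    rng = np.random.default_rng(truth.config.seed + 2 if seed is None
                                else seed)
    genes = truth.somamers["gene"]
    ntpm = pd.DataFrame(index=pd.Index(genes.values, name="gene"),
                        columns=list(CELL_TYPES), dtype=float)
    for sid, gene in genes.items():
        label = truth.somamers.at[sid, "cell_type"]
        if label:
            row = rng.uniform(0.0, 2.0, len(CELL_TYPES))
            row[CELL_TYPES.index(label)] = rng.uniform(30.0, 120.0)
        elif rng.random() < 0.5:
            row = rng.uniform(6.0, 10.0, len(CELL_TYPES))   # flat profile
        else:
            row = rng.uniform(0.0, 3.0, len(CELL_TYPES))    # low everywhere
        ntpm.loc[gene] = row
    return ntpm


def write_cohort(out_dir: str | Path, matrix, samples: pd.DataFrame,
                 clinical: pd.DataFrame, truth: GroundTruth,
                 reference_noise: float = 0.2) -> dict[str, Path]:
    """Write all study inputs as plain-text files; returns the file map."""
    from .pathways import write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    mat_df = matrix.values.copy()
    mat_df.insert(0, "plate", matrix.plate)
    files["matrix"] = out / "matrix.tsv"
    mat_df.to_csv(files["matrix"], sep="\t")
    files["samples"] = out / "samples.tsv"
    samples.to_csv(files["samples"], sep="\t")
    files["clinical"] = out / "clinical.tsv"
    clinical.to_csv(files["clinical"], sep="\t", index=False)
    files["ntpm"] = out / "ntpm.tsv"
    generate_celltype_table(truth).to_csv(files["ntpm"], sep="\t")
    files["reference"] = out / "reference_age_sex.tsv"
    generate_reference_list(truth, noise=reference_noise).to_csv(
        files["reference"], sep="\t", index=False)
    files["pathways"] = out / "pathways.gmt"
    write_gmt(files["pathways"], truth.pathways)
    files["truth"] = out / "ground_truth.json"
    truth.to_json(files["truth"])
    return files
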