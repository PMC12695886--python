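"""End-to-end orchestration of the natural-history pipeline.

``run_all`` executes simulate -> preprocess -> adjust -> outcomes ->
associate -> cel_model -> pathways -> stratify -> longitudinal in
dependency order, writes every tabular product as TSV/JSON under the output
directory, and returns a :class:`RunReport` with per-stage tallies and a
SHA-256 manifest of every written file.  A single global seed fans out to
per-stage seeds (stage name hashed) so stages stay independently
reproducible.  Stages can be skipped; their dependents are disabled with an
explicit diagnostic rather than silently run on missing inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjust as adjust_mod
from . import associate as assoc_mod
from . import cel_model as cel_mod
from . import longitudinal as long_mod
from . import pathways as pw_mod
from . import preprocess as prep_mod
from . import stratify as strat_mod
from .outcomes import build_outcome_table, default_combiwise_weights
from .synthetic import CohortConfig, generate_cohort, write_cohort

STAGES = ("simulate", "preprocess", "adjust", "outcomes", "associate",
          "cel_model", "pathways", "stratify", "longitudinal")

_DEPS = {
    "preprocess": ("simulate",),
    "adjust": ("preprocess",),
    "outcomes": ("simulate",),
    "associate": ("adjust", "outcomes"),
    "cel_model": ("adjust", "outcomes"),
    "pathways": ("associate",),
    "stratify": ("adjust", "outcomes"),
    "longitudinal": ("adjust", "outcomes"),
}


@dataclass
class RunConfig:
    out_dir: str = "run_output"
    seed: int = 0
    cohort: CohortConfig | None = None      # synthetic study conditions
    skip: list[str] = field(default_factory=list)
    snr_threshold: float = 0.8
    flag_k: float = 1.5
    drop_frac: float = 0.15
    floor_k: float = 3.0
    fence_center: str = "quartile"
    plate_normalization: bool = False
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    cel_holdout_frac: float = 0.25
    cel_folds: int = 10
    cel_n_mixing: int = 20
    cluster_seed_thresh: float = 0.7
    cluster_member_thresh: float = 0.5
    caliper: float = 0.2
    min_span_years: float = 1.5
    reference_noise: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort is not None:
            for key in ("visit_interval_years", "ms_visits", "pathway_size",
                        "cluster_size"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            cfg.cohort = CohortConfig(**cohort)
        return cfg


@dataclass
class RunReport:
    stages: dict[str, dict] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"stages": self.stages, "manifest": self.manifest}, indent=1,
            default=str))


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage derived seed; stable across runs and stage reordering."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest[path.name] = _sha256(path)


def run_all(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    manifest = report.manifest

    enabled: dict[str, bool] = {}
    for stage in STAGES:
        deps_ok = all(enabled.get(d, False) for d in _DEPS.get(stage, ()))
        enabled[stage] = stage not in config.skip and deps_ok
        if not enabled[stage]:
            why = ("skipped by request" if stage in config.skip
                   else "disabled: dependency "
                   + ",".join(d for d in _DEPS.get(stage, ())
                              if not enabled.get(d, False)) + " unavailable")
            report.stages[stage] = {"enabled": False, "note": why}

    # ----- simulate -------------------------------------------------------
    if not enabled["simulate"]:
        return report
    cohort_cfg = config.cohort or CohortConfig()
    cohort_cfg = dataclasses.replace(
        cohort_cfg, seed=stage_seed(config.seed, "simulate"))
    matrix_raw, samples, clinical, truth = generate_cohort(cohort_cfg)
    files = write_cohort(out / "inputs", matrix_raw, samples, clinical,
                         truth, reference_noise=config.reference_noise)
    for p in files.values():
        manifest[f"inputs/{p.name}"] = _sha256(p)
    reference = pd.read_csv(files["reference"], sep="\t")
    ntpm = pd.read_csv(files["ntpm"], sep="\t", index_col=0)
    gmt = pw_mod.read_gmt(files["pathways"])
    gene_of = truth.somamers["gene"]
    report.stages["simulate"] = {
        "enabled": True, "n_samples": len(samples),
        "n_somamers": matrix_raw.values.shape[1],
        "n_visits": len(clinical),
    }

    hc_ids = list(samples.index[samples["diagnosis"] == "HC"])
    ms_ids = list(samples.index[samples["diagnosis"] != "HC"])
    untreated_ms = list(samples.index[(samples["diagnosis"] != "HC")
                                      & (~samples["treated"])])

    # ----- preprocess -----------------------------------------------------
    if not enabled["preprocess"]:
        return report
    logged = prep_mod.log_transform(matrix_raw)
    if config.plate_normalization:
        logged = prep_mod.plate_normalize(logged, hc_ids)
    qc_matrix, qc_report = prep_mod.qc_hc_samples(
        logged, hc_ids, flag_k=config.flag_k, drop_frac=config.drop_frac,
        center=config.fence_center)
    hc_ids = [s for s in hc_ids if s in qc_matrix.sample_ids]
    hc_long = {pid: list(grp.index) for pid, grp in
               samples.loc[hc_ids].groupby("patient_id") if len(grp) >= 2}
    snr_records = prep_mod.compute_snr(
        qc_matrix, [s for s in untreated_ms if s in qc_matrix.sample_ids],
        hc_long, threshold=config.snr_threshold)
    high_snr = prep_mod.filter_by_snr(snr_records, config.snr_threshold)
    floored, floor_report = prep_mod.floor_ms_outliers(
        qc_matrix.subset(somamers=high_snr),
        [s for s in ms_ids if s in qc_matrix.sample_ids],
        k=config.floor_k, center=config.fence_center)
    _write(prep_mod.snr_table(snr_records), out / "snr.tsv", manifest)
    (out / "qc_report.json").write_text(json.dumps({
        "hc_qc": qc_report.to_json_dict(),
        "floored": floor_report.to_json_dict()}))
    manifest["qc_report.json"] = _sha256(out / "qc_report.json")
    report.stages["preprocess"] = {
        "enabled": True, "dropped_hc": qc_report.dropped_samples,
        "n_high_snr": len(high_snr),
        "n_floored_cells": int(floor_report.floored_counts.sum()),
    }

    # ----- adjust ---------------------------------------------------------
    if not enabled["adjust"]:
        return report
    meta = samples.loc[list(floored.sample_ids)]
    adjusted = adjust_mod.adjust_pipeline(
        floored, meta, reference, p_cut=config.p_cut,
        fdr_cut=config.fdr_cut)
    _write(adjusted.model_table(), out / "adjustment_models.tsv", manifest)
    _write(adjusted.values, out / "adjusted.tsv", manifest)
    modes = adjusted.model_table()["mode"].value_counts().to_dict()
    report.stages["adjust"] = {"enabled": True, "model_modes": modes}

    # ----- outcomes -------------------------------------------------------
    if not enabled["outcomes"]:
        return report
    weights = default_combiwise_weights()
    outcome_visits = build_outcome_table(clinical, weights)
    outcome_visits["patient_id"] = clinical["patient_id"]
    outcome_visits["sample_id"] = clinical["sample_id"]
    by_sample = outcome_visits[outcome_visits["sample_id"] != ""] \
        .set_index("sample_id")
    sample_outcomes = by_sample[["CombiWISE", "BrainDamage", "GMSD",
                                 "SCDisability"]].copy()
    clin_by_sample = clinical[clinical["sample_id"] != ""] \
        .set_index("sample_id")
    sample_outcomes["CEL"] = clin_by_sample["CEL"].astype(float)
    sample_outcomes["logT2LL"] = np.log(clin_by_sample["T2LL"].astype(float))
    sample_outcomes["logNEFL"] = np.log(clin_by_sample["NEFL"].astype(float))
    sample_outcomes["BMI"] = clin_by_sample["BMI"].astype(float)
    sample_outcomes["HLA_DRB1_copies"] = \
        clin_by_sample["hla_drb1_copies"].astype(float)
    _write(sample_outcomes, out / "outcomes.tsv", manifest)
    report.stages["outcomes"] = {"enabled": True,
                                 "n_scored_samples": len(sample_outcomes)}

    # ----- associate ------------------------------------------------------
    analysis_ids = [s for s in untreated_ms if s in adjusted.values.index] \
        if enabled["adjust"] else []
    if not enabled["associate"]:
        return report
    adj_ms = adjusted.values.loc[analysis_ids]
    sex_ms = samples.loc[analysis_ids, "sex"]
    assoc_frames = []
    for name in sample_outcomes.columns:
        vals = sample_outcomes.loc[analysis_ids, name]
        rec = assoc_mod.fit_outcome_model(adj_ms, vals, sex_ms,
                                          outcome_name=name)
        assoc_frames.append(rec.reset_index())
    associations = pd.concat(assoc_frames, ignore_index=True)
    _write(associations, out / "associations.tsv", manifest, index=False)

    # MS vs HC two-group contrast on all untreated MS + HC
    mshc_ids = analysis_ids + [s for s in hc_ids
                               if s in adjusted.values.index]
    groups = samples.loc[mshc_ids, "diagnosis"].map(
        lambda d: "HC" if d == "HC" else "MS")
    mshc = assoc_mod.two_group_test(adjusted.values.loc[mshc_ids], groups)
    _write(mshc, out / "ms_vs_hc.tsv", manifest)

    cells = assoc_mod.assign_cell_specificity(ntpm)
    cells_somamer = pd.Series(cells.loc[gene_of.loc[adjusted.values.columns]]
                              .to_numpy(), index=adjusted.values.columns,
                              name="cell_type")
    _write(cells_somamer.to_frame(), out / "cell_specificity.tsv", manifest)
    sig_sets = {}
    for name, grp in associations.groupby("outcome"):
        sig = grp[grp["significant"]]
        for direction, sub in sig.groupby("direction"):
            label = "positive" if direction > 0 else "negative"
            sig_sets[(name, label)] = set(sub["somamer_id"])
    sig_sets[("MSvsHC", "positive")] = set(
        mshc.index[(mshc["q"] <= 0.05) & (mshc["direction"] > 0)])
    sig_sets[("MSvsHC", "negative")] = set(
        mshc.index[(mshc["q"] <= 0.05) & (mshc["direction"] < 0)])
    enrich = assoc_mod.enrichment_test(cells_somamer, sig_sets)
    _write(enrich, out / "enrichment.tsv", manifest, index=False)
    report.stages["associate"] = {
        "enabled": True,
        "significant_per_outcome": associations.groupby("outcome")
        ["significant"].sum().astype(int).to_dict(),
        "ms_vs_hc_q05": int((mshc["q"] <= 0.05).sum()),
    }

    # ----- cel_model ------------------------------------------------------
    if enabled["cel_model"]:
        rng = np.random.default_rng(stage_seed(config.seed, "cel_model"))
        cel = sample_outcomes.loc[analysis_ids, "CEL"]
        subtype = samples.loc[analysis_ids, "diagnosis"]
        idx = np.array(analysis_ids)
        holdout_mask = np.zeros(len(idx), dtype=bool)
        for st in subtype.unique():
            pos = np.flatnonzero((subtype == st).to_numpy())
            rng.shuffle(pos)
            holdout_mask[pos[:int(round(config.cel_holdout_frac
                                        * len(pos)))]] = True
        train_ids = list(idx[~holdout_mask])
        test_ids = list(idx[holdout_mask])
        exclude = tuple(adjusted.values.columns[
            gene_of.loc[adjusted.values.columns].isin(["NEFL", "NEFH"])])
        model = cel_mod.train_cel_model(
            adjusted.values.loc[train_ids], cel.loc[train_ids],
            exclude=exclude, n_mixing=config.cel_n_mixing,
            folds=config.cel_folds,
            seed=stage_seed(config.seed, "cel_folds"),
            subtype=subtype.loc[train_ids])
        model.to_json(out / "cel_model.json")
        manifest["cel_model.json"] = _sha256(out / "cel_model.json")
        evaluation = cel_mod.evaluate_model(
            model, adjusted.values.loc[test_ids], cel.loc[test_ids],
            training_ids=set(train_ids))
        pred_ids = analysis_ids + [s for s in hc_ids
                                   if s in adjusted.values.index]
        predicted = model.predict(adjusted.values.loc[pred_ids])
        gate = cel_mod.hc_prediction_gate(
            predicted, samples.loc[pred_ids, "age"],
            [s for s in hc_ids if s in adjusted.values.index])
        lognefl = np.log(clin_by_sample.loc[pred_ids, "NEFL"].astype(float))
        destr = cel_mod.nefl_cel_residuals(lognefl, predicted, gate)
        _write(destr, out / "destructiveness.tsv", manifest)
        report.stages["cel_model"] = {
            "enabled": True, "mixing": model.mixing,
            "penalty": model.penalty,
            "n_nonzero": len(model.coefficients),
            "holdout": {"n": evaluation.n,
                        "spearman_rho": evaluation.spearman_rho,
                        "r_squared": evaluation.r_squared,
                        "ccc": evaluation.ccc},
            "n_above_pi": int(gate.loc[analysis_ids].sum()),
        }

    # ----- pathways -------------------------------------------------------
    pathway_scores = None
    if enabled["pathways"]:
        gmsd = sample_outcomes.loc[analysis_ids, "GMSD"]
        defs = []
        for name, members in gmt.items():
            present = [m for m in members if m in adjusted.values.columns]
            if not present:
                continue
            dirs = pw_mod.infer_directionality(adj_ms, present, gmsd)
            defs.append(pw_mod.PathwayDefinition(
                name=name, members=present, directionality=dirs,
                anchor="GMSD"))
        gmsd_sig = set(
            associations.loc[(associations["outcome"] == "GMSD")
                             & associations["significant"], "somamer_id"])
        in_pathway = {m for d in defs for m in d.members}
        candidates = sorted(gmsd_sig - in_pathway)
        clusters = pw_mod.greedy_cluster(
            adj_ms, candidates, seed_thresh=config.cluster_seed_thresh,
            member_thresh=config.cluster_member_thresh)
        defs += pw_mod.clusters_to_definitions(clusters, adj_ms, gmsd)
        pathway_scores = pw_mod.score_pathways(adjusted.values, defs)
        _write(pathway_scores, out / "pathway_scores.tsv", manifest)
        pw_mod.write_gmt(out / "clusters.gmt",
                         {c.cluster_id: c.members for c in clusters})
        manifest["clusters.gmt"] = _sha256(out / "clusters.gmt")
        dir_rows = [{"pathway": d.name, "somamer_id": m, "direction": v}
                    for d in defs for m, v in d.directionality.items()]
        _write(pd.DataFrame(dir_rows), out / "directionality.tsv", manifest,
               index=False)
        report.stages["pathways"] = {
            "enabled": True, "n_pathways": len(gmt),
            "n_clusters": len(clusters),
            "n_scores": 0 if pathway_scores is None
            else pathway_scores.shape[1]}

    # ----- stratify -------------------------------------------------------
    if enabled["stratify"]:
        first_untreated = (samples.loc[analysis_ids]
                           .reset_index()
                           .sort_values(["patient_id", "age"])
                           .groupby("patient_id").first()["sample_id"])
        base_ids = [s for s in first_untreated if s in sample_outcomes.index]
        strat_results = {}
        for yname, xname in (("BrainDamage", "logT2LL"),
                             ("BrainDamage", "CombiWISE")):
            try:
                strata = strat_mod.residual_strata(
                    sample_outcomes.loc[base_ids, yname],
                    sample_outcomes.loc[base_ids, xname])
                matched = strat_mod.propensity_match(
                    strata, sample_outcomes.loc[base_ids, xname],
                    caliper=config.caliper)
                if len(matched.pairs) >= 3:
                    contrast = strat_mod.paired_compare(
                        adjusted.values, matched.pairs)
                    _write(contrast,
                           out / f"stratify_{yname}_vs_{xname}.tsv",
                           manifest)
                strat_results[f"{yname}~{xname}"] = {
                    "n_pairs": len(matched.pairs),
                    "smd_before": matched.smd_before,
                    "smd_after": matched.smd_after,
                    "note": matched.diagnostic}
            except ValueError as err:
                strat_results[f"{yname}~{xname}"] = {"error": str(err)}
        report.stages["stratify"] = {"enabled": True, **strat_results}

    # ----- longitudinal ---------------------------------------------------
    if enabled["longitudinal"]:
        ms_samples = samples.loc[[s for s in samples.index
                                  if s in adjusted.values.index
                                  and samples.at[s, "diagnosis"] != "HC"]]
        long_patients = long_mod.select_untreated_longitudinal(
            ms_samples.assign(patient_id=ms_samples["patient_id"]),
            min_span=config.min_span_years)
        biomarkers = adjusted.values
        if pathway_scores is not None:
            biomarkers = pd.concat([biomarkers, pathway_scores], axis=1)
        long_rows = ms_samples[(ms_samples["patient_id"].isin(long_patients))
                               & (~ms_samples["treated"])]
        bio_slopes = long_mod.per_patient_slopes(
            biomarkers.loc[long_rows.index], long_rows)
        evolution = long_mod.untreated_evolution_test(bio_slopes)
        _write(evolution, out / "untreated_evolution.tsv", manifest)

        # anchor outcome slopes from all clinic visits after 1st untreated LP
        clin_idx = clinical.reset_index(drop=True)
        ovis = outcome_visits.reset_index(drop=True)
        anchor_rows = []
        for pid, grp in clin_idx.groupby("patient_id"):
            lp = grp[(grp["sample_id"] != "") & (~grp["treated"])]
            if not len(lp):
                continue
            first_age = lp["age"].min()
            follow = grp[grp["age"] >= first_age]
            if len(follow) >= 2 and \
                    follow["age"].max() - first_age >= config.min_span_years:
                anchor_rows.extend(follow.index)
        anchor_meta = clin_idx.loc[anchor_rows]
        anchor_slopes = long_mod.per_patient_slopes(
            ovis.loc[anchor_rows, ["CombiWISE"]], anchor_meta)["CombiWISE"]

        first_lp = (ms_samples[~ms_samples["treated"]]
                    .reset_index().sort_values(["patient_id", "age"])
                    .groupby("patient_id").first()["sample_id"])
        baseline = biomarkers.loc[[s for s in first_lp
                                   if s in biomarkers.index]]
        baseline.index = first_lp.index[[s in biomarkers.index
                                         for s in first_lp]]
        cs_sign = associations[(associations["outcome"] == "CombiWISE")
                               & associations["significant"]] \
            .set_index("somamer_id")["direction"]
        predictor = long_mod.tertile_compare(
            anchor_slopes, baseline, mode="baseline-predictor",
            cross_sectional_sign=cs_sign)
        _write(predictor, out / "tertile_predictor.tsv", manifest)

        # reflector: outcome slopes between first and last LP; biomarker
        # slopes across each patient's LPs
        lp_meta = clin_idx[clin_idx["patient_id"].isin(long_patients)]
        reflect_slopes = long_mod.per_patient_slopes(
            ovis.loc[lp_meta.index, ["CombiWISE"]], lp_meta,
            window="between-LP", lp_flag="has_lp")["CombiWISE"]
        reflector = long_mod.tertile_compare(
            reflect_slopes, bio_slopes, mode="slope-reflector",
            cross_sectional_sign=cs_sign)
        _write(reflector, out / "tertile_reflector.tsv", manifest)
        report.stages["longitudinal"] = {
            "enabled": True, "n_untreated_longitudinal": len(long_patients),
            "n_predictor_patients": int(anchor_slopes.notna().sum()),
            "n_evolving_q05": int((evolution["q"] <= 0.05).sum()),
            "mean_combiwise_slope": float(np.nanmean(anchor_slopes)),
        }

    report.to_json(out / "run_report.json")
    return report
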