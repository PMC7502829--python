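"""End-to-end pipeline: simulate/ingest -> normative EZ -> clusters ->
features -> prognostic models -> internal and external validation.

One global seed fans out to per-stage seeds by fixed offsets, so any
stage can be reproduced in isolation and a rerun with the same
configuration reproduces every number exactly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import normative as nz
from . import prognosis as pg
from .simulate import (
    CohortBundle,
    SimulationConfig,
    generate_cohort,
    label_recovery,
    load_norms_table,
)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (reproducibility without seed collisions)
_OFFSETS = {
    "simulate": 0,
    "replicate": 101,
    "split": 211,
    "bootstrap": 307,
    "mc_null": 401,
    "rfe": 503,
    "permutation": 601,
    "subsampling": 701,
    "svr": 809,
}


def stage_seed(seed: int, stage: str) -> int:
    return (seed + _OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything one full run needs; see docs/methods.md for defaults."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    u: float = 1.96  # EZ voxel threshold when optimization is skipped
    cluster_alpha: float = 0.05
    null_mode: str = "grf"  # 'grf' | 'mc'
    mc_sims: int = 2000
    frequency_fraction: float = 0.25
    connectivity: int = 26
    bootstrap_B: int = 200
    optimize: bool = False  # ROC sweep of (u, alpha) instead of the defaults
    u_grid: tuple = (1.64, 1.96, 2.33, 2.58)
    alpha_grid: tuple = (0.01, 0.05)
    C: float = 1.0
    inner_cv: int | str = 5
    svr_epsilon: float = 0.1
    n_perm: int = 500
    perm_mode: str = "fast"
    subsampling_reps: int = 200
    nested_loocv: bool = True  # refit RFE inside every LOOCV fold
    external: bool = True  # also generate and score a replicate cohort
    seed: int = 0

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["simulation"] = self.simulation.to_dict()
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class CohortAnalysis:
    """Per-cohort intermediate products reused across stages."""

    bundle: CohortBundle
    labels: pd.Series  # patients only, +1 / -1
    adjusted_patients: np.ndarray
    adjusted_controls: np.ndarray
    patient_features: pd.DataFrame
    all_features: pd.DataFrame
    cytokine_patients: pd.DataFrame


def _patient_labels(bundle: CohortBundle) -> pd.Series:
    norms = bundle.config.norms_table
    if norms is None:
        norms = load_norms_table()
    outcomes = bundle.outcomes[bundle.outcomes["group"] == "patient"]
    return label_recovery(outcomes, norms)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis on a synthetic cohort pair.

    Returns a nested result dict (also JSON-serializable through
    ``lesionload.io.save_json``) whose sections mirror the stages:
    normative, clusters, features, classification, regression, domains,
    external, provenance.
    """
    import copy

    seed = config.seed
    config_hash = config.config_hash()
    logger.info("pipeline start (seed=%d, hash=%s)", seed, config_hash)

    sim = copy.copy(config.simulation)
    sim.lesion_specs = list(config.simulation.lesion_specs)
    sim.seed = stage_seed(seed, "simulate")
    bundle = generate_cohort(sim)
    logger.info(
        "simulated cohort: %d controls, %d patients, %d skeleton voxels",
        sim.n_controls, sim.n_patients, bundle.geometry.n_voxels,
    )

    result: dict = {
        "provenance": {
            "config_hash": config_hash,
            "seed": seed,
            "stage_seeds": {k: stage_seed(seed, k) for k in _OFFSETS},
        }
    }

    # --- normative model on the reference half of the controls -----------
    controls = bundle.covariates[bundle.covariates["group"] == "control"]
    ref_cov, normal_cov = nz.split_controls(controls, seed=stage_seed(seed, "split"))
    ref_fa = bundle.image_matrix(list(ref_cov["subject_id"]))
    model = nz.build_normative_model(
        ref_fa, ref_cov, B=config.bootstrap_B, seed=stage_seed(seed, "bootstrap")
    )
    analysis = _analyse_cohort(bundle, model, config, normal_cov)
    normal_ez = nz.compute_ez(analysis.adjusted_controls, model)
    patient_ez = nz.compute_ez(analysis.adjusted_patients, model)
    result["normative"] = {
        "n_reference": model.n_reference,
        "n_normal_controls": len(normal_cov),
        "B": model.B,
        "significant_voxel_fraction": float(model.covariate_model.sig_mask.mean()),
    }

    # --- clusters and features -------------------------------------------
    fwhm = cl.estimate_smoothness(normal_ez, bundle.geometry)
    if config.optimize:
        u, k, auc, sweep = cl.optimize_thresholds(
            patient_ez, normal_ez, bundle.geometry, bundle.atlas, fwhm,
            u_grid=config.u_grid, alpha_grid=config.alpha_grid,
            connectivity=config.connectivity,
        )
        result["threshold_optimization"] = {
            "u": u, "k": k, "auc": auc, "sweep": sweep.to_dict("records")
        }
        extractor = cl.LesionFeatureExtractor(
            bundle.geometry, bundle.atlas, u=u, alpha=config.cluster_alpha,
            frequency_fraction=config.frequency_fraction,
            connectivity=config.connectivity, null_mode=config.null_mode,
            mc_sims=config.mc_sims, fwhm=fwhm, seed=stage_seed(seed, "mc_null"),
        )
        extractor.fit(patient_ez)
        extractor.k_ = k
        extractor.catalogue_ = cl.build_cluster_catalogue(
            patient_ez, u, k, bundle.geometry, bundle.atlas,
            frequency_fraction=config.frequency_fraction,
            connectivity=config.connectivity,
        )
    else:
        extractor = cl.LesionFeatureExtractor(
            bundle.geometry, bundle.atlas, u=config.u, alpha=config.cluster_alpha,
            frequency_fraction=config.frequency_fraction,
            connectivity=config.connectivity, null_mode=config.null_mode,
            mc_sims=config.mc_sims, fwhm=fwhm, seed=stage_seed(seed, "mc_null"),
        )
        extractor.fit(patient_ez)
    catalogue = extractor.catalogue_
    result["clusters"] = {
        "smoothness_fwhm_mm": [float(f) for f in fwhm],
        "extent_threshold": int(extractor.k_),
        "n_clusters": len(catalogue),
        "by_direction": {
            d: sum(1 for c in catalogue.clusters if c.direction == d)
            for d in ("high", "low")
        },
        "provenance": catalogue.provenance,
    }
    logger.info("catalogue: %d clusters (k=%d)", len(catalogue), extractor.k_)

    fa_feat = extractor.transform(
        analysis.adjusted_patients, subject_ids=bundle.patient_ids
    ) if len(catalogue) else pd.DataFrame(index=bundle.patient_ids)
    labels = analysis.labels.loc[fa_feat.index]
    result["labels"] = {
        "n_patients": int(labels.size),
        "n_not_recovered": int((labels == -1).sum()),
    }

    cyt = analysis.cytokine_patients
    combined = pg.combine_domains(fa_feat, cyt) if fa_feat.shape[1] else cyt.copy()

    # --- prognostic models ------------------------------------------------
    domains: dict[str, pd.DataFrame] = {"cytokine": cyt, "combined": combined}
    if fa_feat.shape[1]:
        domains["fa"] = fa_feat
    else:
        logger.warning("no imaging features: continuing with cytokine domain only")
    result["classification"] = {}
    rfe_by_domain: dict[str, pg.RFEResult] = {}
    for name, feats in domains.items():
        if feats.shape[1] < 2:
            continue
        rfe = pg.rfe_select(
            feats, labels, C=config.C, inner_cv=config.inner_cv,
            seed=stage_seed(seed, "rfe"),
        )
        rfe_by_domain[name] = rfe
        report = pg.loocv_classify(feats, labels, subset=rfe.subset, C=config.C)
        report.subsampling = pg.subsampling_report(
            feats, labels, rfe.subset, reps=config.subsampling_reps,
            seed=stage_seed(seed, "subsampling"), C=config.C,
        )
        acc = report.subsampling  # pooled subsampling distribution CI
        report.ci = {"accuracy": (float(acc["ci_lo"].min()), float(acc["ci_hi"].max()))}
        result["classification"][name] = {
            "n_features": feats.shape[1],
            "subset": rfe.subset,
            "weights": {k: float(v) for k, v in rfe.weights.items()},
            "report": report.to_dict(),
        }

    primary = "fa" if "fa" in rfe_by_domain else "combined"
    rfe = rfe_by_domain[primary]
    primary_feats = domains[primary]
    if config.nested_loocv:
        nested = pg.loocv_classify(
            primary_feats, labels, refit_rfe=True, C=config.C,
            inner_cv=config.inner_cv, seed=stage_seed(seed, "rfe"),
        )
        result["classification"][primary]["nested_loocv"] = nested.to_dict()
    p, observed, _ = pg.permutation_test(
        primary_feats, labels, subset=rfe.subset, n_perm=config.n_perm,
        seed=stage_seed(seed, "permutation"), mode=config.perm_mode, C=config.C,
        inner_cv=config.inner_cv,
    )
    result["classification"][primary]["permutation"] = {
        "p": p, "observed_accuracy": observed,
        "n_perm": config.n_perm, "mode": config.perm_mode,
    }

    # --- score regression (subset reused, no re-selection) ----------------
    outcomes = bundle.outcomes.set_index("subject_id").loc[fa_feat.index]
    result["regression"] = {}
    for score, col in (("ips_tmt_a", "tmt_a_followup"), ("wm_bds", "bds_followup")):
        reg = pg.svr_predict(
            primary_feats, outcomes[col], rfe.subset, C=config.C,
            epsilon=config.svr_epsilon, seed=stage_seed(seed, "svr"),
        )
        result["regression"][score] = reg.to_dict()

    # --- importance filtering against all three groups --------------------
    if primary == "fa" and fa_feat.shape[1]:
        all_feat = extractor.transform(
            np.vstack([analysis.adjusted_patients, analysis.adjusted_controls]),
            subject_ids=bundle.patient_ids + list(normal_cov["subject_id"]),
        )
        groups = pd.Series("control", index=all_feat.index)
        groups.loc[labels.index[labels == -1]] = "nonrecovered"
        groups.loc[labels.index[labels == +1]] = "recovered"
        imp = pg.importance_filter(rfe, all_feat, groups)
        result["importance_filter"] = {
            "selected": imp.selected,
            "n_fibers": imp.n_fibers,
            "n_top": imp.n_top,
            "p_threshold": imp.p_threshold,
            "table": imp.table.to_dict("records"),
        }

    # --- external validation on a replicate cohort ------------------------
    if config.external:
        rep_sim = sim.replicate(stage_seed(seed, "replicate"))
        rep_bundle = generate_cohort(rep_sim)
        rep = _analyse_cohort(rep_bundle, model, config, None, extractor=extractor)
        rep_feats = rep.patient_features
        if primary == "combined":
            rep_feats = pg.combine_domains(rep_feats, rep.cytokine_patients)
        ext = pg.external_validate(rfe.estimator, rep_feats, rep.labels)
        result["external"] = {
            "n_patients": int(rep.labels.size),
            "report": ext.to_dict(),
        }
        if "combined" in rfe_by_domain and primary == "fa":
            rep_comb = pg.combine_domains(rep.patient_features, rep.cytokine_patients)
            ext_comb = pg.external_validate(
                rfe_by_domain["combined"].estimator, rep_comb, rep.labels
            )
            result["external"]["combined_report"] = ext_comb.to_dict()

    logger.info("pipeline done")
    return result


def _analyse_cohort(
    bundle: CohortBundle,
    model: nz.NormativeModel,
    config: PipelineConfig,
    normal_cov: pd.DataFrame | None,
    extractor: cl.LesionFeatureExtractor | None = None,
) -> CohortAnalysis:
    """Covariate-adjust a cohort against a (possibly foreign) normative
    model and, when a fitted extractor is given, cut its features."""
    cov = bundle.covariates
    patients = cov[cov["group"] == "patient"]
    ctrl = normal_cov if normal_cov is not None else cov[cov["group"] == "control"]
    pat_fa = bundle.image_matrix(list(patients["subject_id"]))
    ctl_fa = bundle.image_matrix(list(ctrl["subject_id"]))
    adj_pat = nz.adjust_fa(pat_fa, model.covariate_model, patients)
    adj_ctl = nz.adjust_fa(ctl_fa, model.covariate_model, ctrl)
    labels = _patient_labels(bundle)
    cyt = bundle.cytokines.set_index("subject_id").loc[list(patients["subject_id"])]
    pat_feat = pd.DataFrame(index=list(patients["subject_id"]))
    all_feat = pd.DataFrame(index=list(patients["subject_id"]) + list(ctrl["subject_id"]))
    if extractor is not None and len(extractor.catalogue_):
        pat_feat = extractor.transform(adj_pat, subject_ids=list(patients["subject_id"]))
        all_feat = extractor.transform(
            np.vstack([adj_pat, adj_ctl]),
            subject_ids=list(patients["subject_id"]) + list(ctrl["subject_id"]),
        )
    return CohortAnalysis(
        bundle=bundle,
        labels=labels,
        adjusted_patients=adj_pat,
        adjusted_controls=adj_ctl,
        patient_features=pat_feat,
        all_features=all_feat,
        cytokine_patients=cyt,
    )
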