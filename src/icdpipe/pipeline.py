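"""End-to-end orchestration: simulate -> preprocess -> QC -> ICD ->
voxel GLM -> seed networks -> parcellation overlap.

Motion summaries come out of preprocessing, so preprocessing runs on
every simulated subject and QC consumes its summaries; only included
subjects proceed to ICD and the group stages.  Each stage writes its
tables/maps plus a manifest (config hash, seed, package version) under
the run directory; the expensive ICD stage can be resumed from its
cached stack when the manifest matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .glm import Cluster, build_design, cluster_correct, cluster_table, fit_voxelwise
from .icd import icd_subject, smooth_parameter_map
from .images import save_nifti
from .network import (
    NetworkMap,
    OverlapProfile,
    group_network,
    overlap_with_reference,
    pairwise_overlap,
    seed_connectivity,
)
from .preprocess import MotionTrace, PreprocessError, PreprocessSummary, preprocess_subject
from .qc import (
    SubjectRecord,
    apply_qc,
    demographics_table,
    subjects_to_frame,
    write_covariates,
)
from .simulate import SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.resolved(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(stage_dir: Path, stage: str, cfg_hash: str, seed: int,
                    extra: Optional[dict] = None) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": cfg_hash,
        "seed": seed,
        "icdpipe_version": __version__,
    }
    if extra:
        manifest.update(extra)
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _manifest_matches(stage_dir: Path, cfg_hash: str) -> bool:
    path = stage_dir / "manifest.json"
    if not path.exists():
        return False
    try:
        return json.loads(path.read_text()).get("config_hash") == cfg_hash
    except (json.JSONDecodeError, OSError):
        return False


@dataclass
class PipelineResult:
    config: PipelineConfig
    out_dir: Path
    cohort: SyntheticCohort
    included: list[SubjectRecord]
    excluded: list[SubjectRecord]
    alpha_stack: np.ndarray  # (n_included, V_gm)
    beta_stack: np.ndarray
    clusters: dict[str, list[Cluster]] = field(default_factory=dict)
    glm_info: dict[str, dict] = field(default_factory=dict)
    networks: dict[str, NetworkMap] = field(default_factory=dict)
    overlaps: dict[str, OverlapProfile] = field(default_factory=dict)
    pairwise: dict[str, float] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, out_dir, write_volumes: bool = False,
                 resume: bool = False) -> PipelineResult:
    """Run the full analysis on a simulated cohort; returns in-memory
    products and writes tables/maps under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    design = replace(config.sim, seed=config.seed)
    config.to_yaml(out / "resolved_config.yaml")

    # ------------------------------------------------------------------ simulate
    logger.info("stage simulate: n=%d grid=%s", design.n_subjects, design.grid_shape)
    cohort = simulate_cohort(design)
    sim_dir = out / "simulate"
    sim_dir.mkdir(parents=True, exist_ok=True)
    geo = cohort.geometry
    save_nifti(geo.gm.data.astype(np.uint8), design.affine, sim_dir / "mask_gm.nii.gz")
    save_nifti(geo.wm.data.astype(np.uint8), design.affine, sim_dir / "mask_wm.nii.gz")
    save_nifti(geo.ventricles.data.astype(np.uint8), design.affine, sim_dir / "mask_ventricles.nii.gz")
    save_nifti(geo.parcellation.data, design.affine, sim_dir / "parcellation7.nii.gz")
    save_nifti(cohort.truth.slope_main, design.affine, sim_dir / "truth_slope_main.nii.gz")
    save_nifti(cohort.truth.slope_male, design.affine, sim_dir / "truth_slope_male.nii.gz")
    save_nifti(cohort.truth.slope_female, design.affine, sim_dir / "truth_slope_female.nii.gz")
    write_covariates(cohort.subjects, sim_dir / "covariates.tsv")
    if write_volumes:
        for subj, vol, mot in zip(cohort.subjects, cohort.images, cohort.motion):
            save_nifti(vol.data.astype(np.float32), design.affine,
                       sim_dir / f"{subj.subject_id}_bold.nii.gz")
            np.savetxt(sim_dir / f"{subj.subject_id}_motion.txt", mot, fmt="%.6f")
    _write_manifest(sim_dir, "simulate", cfg_hash, config.seed)

    # ---------------------------------------------------------------- preprocess
    pp = config.preprocess
    pre_dir = out / "preprocess"
    pre_dir.mkdir(parents=True, exist_ok=True)
    preprocessed = {}
    summaries: dict[str, PreprocessSummary] = {}
    subjects_with_motion: list[SubjectRecord] = []
    for subj, vol, mot in zip(cohort.subjects, cohort.images, cohort.motion):
        trace = MotionTrace(mot)
        try:
            clean, summary = preprocess_subject(
                vol, trace, geo.gm, geo.wm, geo.ventricles,
                n_discard=pp.n_discard, movement_mm=pp.movement_mm,
                outlier_frac=pp.outlier_frac, fwhm_mm=pp.fwhm_mm, band_hz=pp.band_hz,
            )
            preprocessed[subj.subject_id] = clean
        except PreprocessError as err:
            logger.warning("preprocess flagged %s: %s", subj.subject_id, err)
            summary = PreprocessSummary(
                mean_motion_per_tr=MotionTrace(mot).mean_fd(),
                censor_fraction=1.0, n_censored=-1, n_frames=-1,
            )
        summaries[subj.subject_id] = summary
        subjects_with_motion.append(
            replace(subj, mean_motion_per_tr=summary.mean_motion_per_tr,
                    censor_fraction=summary.censor_fraction)
        )
    pd.DataFrame(
        [
            {"subject_id": sid, "mean_motion_per_tr": s.mean_motion_per_tr,
             "censor_fraction": s.censor_fraction, "n_censored": s.n_censored}
            for sid, s in summaries.items()
        ]
    ).to_csv(pre_dir / "motion_summary.tsv", sep="\t", index=False)
    _write_manifest(pre_dir, "preprocess", cfg_hash, config.seed)

    # ------------------------------------------------------------------------ qc
    qc_dir = out / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    included, excluded = apply_qc(subjects_with_motion, config.qc.motion_mm, config.qc.censor_frac)
    all_records = included + excluded
    subjects_to_frame(all_records)[["subject_id", "qc_pass", "exclusion_reason"]].to_csv(
        qc_dir / "qc_report.tsv", sep="\t", index=False
    )
    if included:
        demographics_table(included).to_csv(qc_dir / "demographics.tsv", sep="\t")
    _write_manifest(qc_dir, "qc", cfg_hash, config.seed,
                    {"n_included": len(included), "n_excluded": len(excluded)})

    # ----------------------------------------------------------------------- icd
    icd_dir = out / "icd"
    stack_path = icd_dir / "stacks.npz"
    included_ids = [s.subject_id for s in included]
    if resume and _manifest_matches(icd_dir, cfg_hash) and stack_path.exists():
        logger.info("stage icd: resuming from cached stacks")
        cached = np.load(stack_path, allow_pickle=False)
        alpha_stack, beta_stack = cached["alpha"], cached["beta"]
    else:
        icd_dir.mkdir(parents=True, exist_ok=True)
        alphas, betas = [], []
        for sid in included_ids:
            maps = icd_subject(preprocessed[sid], geo.gm,
                               chunk_size=config.icd.chunk_size,
                               max_fail_frac=config.icd.max_fail_frac)
            maps = smooth_parameter_map(maps, config.icd.param_fwhm_mm, geo.gm)
            alphas.append(maps.alpha[geo.gm.data])
            betas.append(maps.beta[geo.gm.data])
        alpha_stack = np.stack(alphas) if alphas else np.empty((0, geo.gm.n_voxels))
        beta_stack = np.stack(betas) if betas else np.empty((0, geo.gm.n_voxels))
        np.savez_compressed(stack_path, alpha=alpha_stack, beta=beta_stack)
        _write_manifest(icd_dir, "icd", cfg_hash, config.seed,
                        {"n_subjects": len(included_ids)})

    result = PipelineResult(
        config=config, out_dir=out, cohort=cohort, included=included,
        excluded=excluded, alpha_stack=alpha_stack, beta_stack=beta_stack,
    )

    # ----------------------------------------------------------------------- glm
    glm_dir = out / "glm"
    glm_dir.mkdir(parents=True, exist_ok=True)
    X, terms = build_design(included)
    Y = alpha_stack if config.glm.parameter == "alpha" else beta_stack
    col_ok = np.isfinite(Y).all(axis=0)
    Y_fit = np.where(col_ok, Y, 0.0)  # failed voxels carry no signal; never significant
    fit = fit_voxelwise(Y_fit, X, terms)
    for name in terms:
        coef_map = np.full(design.grid_shape, np.nan)
        coef_map[geo.gm.data] = fit.coef[fit.term_index(name)]
        save_nifti(coef_map, design.affine, glm_dir / f"coef_{name}.nii.gz")
    for term in config.glm.terms:
        clusters, info = cluster_correct(
            Y_fit, X, term, geo.gm, voxel_p=config.glm.voxel_p,
            cluster_alpha=config.glm.cluster_alpha, n_perm=config.glm.n_perm,
            seed=config.seed + 1000, connectivity=config.glm.connectivity, terms=terms,
        )
        result.clusters[term] = clusters
        result.glm_info[term] = info
        cluster_table(clusters).to_csv(glm_dir / f"clusters_{term}.tsv", sep="\t",
                                       index=False, float_format="%.6g")
        mask = np.zeros(design.grid_shape, dtype=np.uint8)
        for c in clusters:
            mask[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = c.cluster_id
        save_nifti(mask, design.affine, glm_dir / f"cluster_mask_{term}.nii.gz")
    _write_manifest(glm_dir, "glm", cfg_hash, config.seed,
                    {t: len(cs) for t, cs in result.clusters.items()})

    # ------------------------------------------------------------------- network
    net_dir = out / "network"
    net_dir.mkdir(parents=True, exist_ok=True)
    for term, clusters in result.clusters.items():
        if not clusters:
            continue
        seed_cluster = clusters[0]  # largest cluster as seed
        z_maps = [
            seed_connectivity(preprocessed[sid], seed_cluster.voxels, geo.gm)
            for sid in included_ids
        ]
        net = group_network(
            z_maps, geo.gm, p_thresh=config.network.p_thresh,
            fdr_thresh=config.network.fdr_thresh,
            positive_only=config.network.positive_only,
        )
        result.networks[term] = net
        save_nifti(net.network_mask.astype(np.uint8), design.affine,
                   net_dir / f"network_{term}.nii.gz")
        save_nifti(np.nan_to_num(net.mean_z), design.affine, net_dir / f"mean_z_{term}.nii.gz")
        profile = overlap_with_reference(net, geo.parcellation)
        result.overlaps[term] = profile
        profile.to_frame().to_csv(net_dir / f"overlap_{term}.tsv", sep="\t",
                                  index=False, float_format="%.4f")
    if len(result.networks) == 2:
        (a_term, a_net), (b_term, b_net) = result.networks.items()
        result.pairwise[f"{b_term}_in_{a_term}"] = pairwise_overlap(
            a_net.network_mask, b_net.network_mask
        )
        result.pairwise[f"{a_term}_in_{b_term}"] = pairwise_overlap(
            b_net.network_mask, a_net.network_mask
        )
        pd.DataFrame(
            [{"pair": k, "pct_overlap": v} for k, v in result.pairwise.items()]
        ).to_csv(net_dir / "pairwise_overlap.tsv", sep="\t", index=False,
                 float_format="%.4f")
    _write_manifest(net_dir, "network", cfg_hash, config.seed)
    logger.info("pipeline complete: %s", out)
    return result
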