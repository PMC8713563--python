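"""Validation experiments for the pipeline.

Each function runs one self-contained experiment — parameter-recovery
checks, calibration simulations, planted-truth end-to-end runs — and
returns plain numbers.  They are driven by the acceptance test suite
and by ``scripts/acceptance.py``; problem sizes default to the study
conditions the experiments are specified at.
"""

from __future__ import annotations

import filecmp
from dataclasses import replace
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .config import demo_config
from .glm import build_design, cluster_correct, fit_voxelwise
from .icd import TAU_GRID, SurvivalCurve, fit_icd, grid_search_icd, icd_model, icd_subject
from .images import Mask3D
from .network import dice, group_network, overlap_with_reference, pairwise_overlap, seed_connectivity
from .pipeline import run_pipeline
from .preprocess import MotionTrace, PreprocessError, preprocess_subject
from .simulate import (
    BACKGROUND_GM,
    SOMATOMOTOR,
    SimDesign,
    default_geometry,
    simulate_covariates,
    simulate_subject_image,
)


# ---------------------------------------------------------------------------
# ICD model recovery and monotonicity


def icd_recovery(n_curves: int = 100, seed: int = 0) -> dict:
    """Fit exact in-family survival curves; report the worst relative
    parameter error and whether a lattice search ever beats the fit."""
    rng = np.random.default_rng(seed)
    max_rel_err = 0.0
    oracle_confirmed = 0
    alphas = np.linspace(0.2, 6.0, 80)
    betas = np.linspace(0.2, 4.0, 60)
    for _ in range(n_curves):
        a, b = rng.uniform(0.5, 4.0), rng.uniform(0.5, 3.0)
        curve = SurvivalCurve(TAU_GRID, icd_model(TAU_GRID, a, b), 1000)
        fit = fit_icd(curve)
        max_rel_err = max(
            max_rel_err, abs(fit.alpha - a) / a, abs(fit.beta - b) / b
        )
        _, _, grss = grid_search_icd(curve, alphas, betas)
        oracle_confirmed += fit.rss <= grss + 1e-12
    return {
        "n": n_curves,
        "max_rel_err": float(max_rel_err),
        "oracle_confirmed_frac": oracle_confirmed / n_curves,
    }


def _sample_empirical_curve(rng, alpha: float, beta: float, n_samples: int) -> SurvivalCurve:
    """Empirical survival of ``n_samples`` draws from the model's implied
    positive-correlation distribution (inverse-CDF sampling)."""
    u = rng.random(n_samples)
    r = np.clip((-np.log(u)) ** (1.0 / beta) / alpha, 0.0, 0.999)
    pos = np.sort(r[r > 0])
    n_le = np.searchsorted(pos, TAU_GRID, side="right")
    return SurvivalCurve(TAU_GRID, 1.0 - n_le / pos.size, int(pos.size))


def icd_dominance(n_pairs: int = 100, seed: int = 0, n_samples: int = 500) -> dict:
    """Stochastic-dominance monotonicity: among empirical curve pairs where
    one curve dominates (uniformly higher survival), the dominated curve
    must never receive the smaller alpha."""
    rng = np.random.default_rng(seed)
    violations = 0
    kept = 0
    while kept < n_pairs:
        a = rng.uniform(0.5, 2.5)
        b = rng.uniform(0.8, 2.5)
        dominating = _sample_empirical_curve(rng, a, b, n_samples)
        dominated = _sample_empirical_curve(rng, a * rng.uniform(1.3, 2.5), b, n_samples)
        if not np.all(dominating.survival >= dominated.survival):
            continue  # sampling noise broke strict dominance; draw again
        kept += 1
        f_dom, f_sub = fit_icd(dominating), fit_icd(dominated)
        if not (f_dom.success and f_sub.success) or f_sub.alpha < f_dom.alpha:
            violations += 1
    return {"n": n_pairs, "violations": violations}


# ---------------------------------------------------------------------------
# connectivity ordering on simulated subjects


def community_alpha_ordering(n_seeds: int = 100, seed: int = 0) -> dict:
    """Simulated block-covariance subjects: mean alpha in the
    high-coupling community must fall below background gray matter."""
    wins = 0
    for k in range(n_seeds):
        design = SimDesign(
            n_subjects=4, seed=seed + k, item_rates=(0.0,) * 9,
            high_motion_frac=0.0,
        )
        geo = default_geometry(design)
        subjects = simulate_covariates(design)
        clean = None
        for i, subj in enumerate(subjects):  # first subject whose censoring leaves a usable fit
            vol, mot, _ = simulate_subject_image(design, geo, subj, i)
            try:
                clean, _ = preprocess_subject(
                    vol, MotionTrace(mot), geo.gm, geo.wm, geo.ventricles
                )
                break
            except PreprocessError:
                continue
        if clean is None:
            continue
        maps = icd_subject(clean, geo.gm)
        a_comm = np.nanmean(maps.alpha[geo.community_map == SOMATOMOTOR])
        a_bg = np.nanmean(maps.alpha[geo.community_map == BACKGROUND_GM])
        wins += a_comm < a_bg
    return {"n": n_seeds, "wins": wins}


# ---------------------------------------------------------------------------
# GLM checks


def ols_oracle(n_instances: int = 1000, seed: int = 0) -> dict:
    """Voxel-wise OLS vs the closed-form normal equations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(15, 60))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 5))])
        Y = rng.standard_normal((n, 3))
        res = fit_voxelwise(Y, X)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        worst = max(worst, float(np.abs(res.coef - oracle).max()))
    return {"n": n_instances, "max_abs_diff": worst}


def interaction_coverage(n_reps: int = 100, n_subjects: int = 300, seed: int = 0,
                         male_slope: float = -0.04, female_slope: float = 0.06,
                         noise_sd: float = 0.4) -> dict:
    """Planted sex-specific TE slopes on alpha: 95% CI coverage of the
    recovered male and female slopes."""
    cover_m = cover_f = 0
    b_te = female_slope
    b_int = male_slope - female_slope
    for rep in range(n_reps):
        design = SimDesign(n_subjects=n_subjects + 60, seed=seed + rep,
                           missing_items_rate=0.0, missing_medu_rate=0.0)
        subs = simulate_covariates(design)[:n_subjects]
        X, names = build_design(subs)
        rng = np.random.default_rng(seed + 10_000 + rep)
        y = b_te * X[:, 1] + b_int * X[:, 3] + rng.normal(0, noise_sd, n_subjects)
        res = fit_voxelwise(y[:, None], X, names)
        tcrit = stats.t.ppf(0.975, res.df)
        XtX_inv = np.linalg.inv(X.T @ X)
        sigma2 = (res.se[1, 0] ** 2) / XtX_inv[1, 1]
        # female slope = te coefficient
        cover_f += abs(res.coef[1, 0] - female_slope) <= tcrit * res.se[1, 0]
        # male slope = te + interaction
        c = np.zeros(X.shape[1])
        c[1] = c[3] = 1.0
        se_m = np.sqrt(c @ XtX_inv @ c * sigma2)
        est_m = res.coef[1, 0] + res.coef[3, 0]
        cover_m += abs(est_m - male_slope) <= tcrit * se_m
    return {
        "n": n_reps,
        "coverage_male_pct": 100.0 * cover_m / n_reps,
        "coverage_female_pct": 100.0 * cover_f / n_reps,
    }


def cluster_fpr(n_datasets: int = 200, n_subjects: int = 100, n_perm: int = 500,
                seed: int = 0, cluster_alpha: float = 0.05,
                grid_shape: tuple[int, int, int] = (20, 20, 12),
                fwhm_mm: float = 4.0) -> dict:
    """Family-wise false-positive rate of the permutation cluster
    correction under the global null.

    Null subject maps are white noise smoothed with the same 4 mm kernel
    the pipeline applies to ICD parameter maps, analyzed over the whole
    grid: the smoothness makes the max-cluster-size statistic close to
    continuous, which is the regime cluster-extent correction is built
    for (with only a handful of isolated suprathreshold voxels the test
    is conservative by construction).
    """
    design = SimDesign(n_subjects=n_subjects + 40, seed=seed,
                       missing_items_rate=0.0, missing_medu_rate=0.0,
                       grid_shape=grid_shape)
    subs = simulate_covariates(design)[:n_subjects]
    X, names = build_design(subs)
    mask = Mask3D(np.ones(grid_shape, bool), design.affine)
    sigma = fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / design.voxel_size_mm
    rng = np.random.default_rng(seed + 1)
    false_positives = 0
    for k in range(n_datasets):
        noise = rng.standard_normal((n_subjects,) + grid_shape)
        smoothed = ndimage.gaussian_filter(noise, sigma=(0, sigma, sigma, sigma))
        Y = smoothed.reshape(n_subjects, -1)
        clusters, _ = cluster_correct(
            Y, X, "te", mask, n_perm=n_perm, seed=seed + 2 + k,
            cluster_alpha=cluster_alpha, terms=names,
        )
        false_positives += bool(clusters)
    return {"n": n_datasets, "fpr": false_positives / n_datasets}


def planted_cluster_detection(n_seeds: int = 10, n_subjects: int = 300,
                              n_perm: int = 500, seed: int = 0,
                              effect_multiple: float = 3.0) -> dict:
    """A 30-voxel contiguous TE effect at ``effect_multiple`` times the
    noise SD: detection rate, Dice against the planted region, and the
    sign of the recovered coefficient."""
    base = SimDesign(n_subjects=n_subjects + 60, seed=seed,
                     missing_items_rate=0.0, missing_medu_rate=0.0)
    geo = default_geometry(base)
    planted = np.zeros(geo.gm.data.shape, bool)
    sm_vox = np.argwhere(geo.community_map == SOMATOMOTOR)[:30]
    planted[sm_vox[:, 0], sm_vox[:, 1], sm_vox[:, 2]] = True
    flat = planted[geo.gm.data]
    detected = 0
    dices = []
    positive_coef = 0
    for k in range(n_seeds):
        subs = simulate_covariates(replace(base, seed=seed + k))[:n_subjects]
        X, names = build_design(subs)
        rng = np.random.default_rng(seed + 500 + k)
        Y = rng.standard_normal((n_subjects, geo.gm.n_voxels))
        Y[:, flat] += effect_multiple * X[:, 1][:, None]
        clusters, _ = cluster_correct(Y, X, "te", geo.gm, n_perm=n_perm,
                                      seed=seed + 900 + k, terms=names)
        if not clusters:
            dices.append(0.0)
            continue
        top = clusters[0]
        got = np.zeros(geo.gm.data.shape, bool)
        got[top.voxels[:, 0], top.voxels[:, 1], top.voxels[:, 2]] = True
        d = dice(got, planted)
        dices.append(d)
        detected += d >= 0.7
        positive_coef += top.average_effect_size > 0
    return {
        "n": n_seeds,
        "detected": detected,
        "min_dice": float(min(dices)),
        "mean_dice": float(np.mean(dices)),
        "positive_coef": positive_coef,
    }


# ---------------------------------------------------------------------------
# seed-network recovery


def seed_network_recovery(n_subjects: int = 50, seed: int = 0,
                          coupling: float = 0.5,
                          p_thresh: float = 1e-6, fdr_thresh: float = 1e-4) -> dict:
    """Seed inside the planted community: the recovered network must match
    the community, its overlap profile must conserve mass, and a subset
    network must show 100% directional overlap."""
    design = SimDesign(
        n_subjects=n_subjects, seed=seed, coupling_somatomotor=coupling,
        te_slope_main=0.0, te_slope_male=0.0, te_slope_female=0.0,
        high_motion_frac=0.0,
    )
    geo = default_geometry(design)
    subs = simulate_covariates(design)
    community = geo.community_map == SOMATOMOTOR
    seed_vox = np.argwhere(community)[:10]
    z_maps = []
    for i, subj in enumerate(subs):
        vol, mot, _ = simulate_subject_image(design, geo, subj, i)
        try:
            clean, _ = preprocess_subject(vol, MotionTrace(mot), geo.gm, geo.wm, geo.ventricles)
        except PreprocessError:
            continue  # flagged subject, as in the pipeline
        z_maps.append(seed_connectivity(clean, seed_vox, geo.gm))
    net = group_network(z_maps, geo.gm, p_thresh, fdr_thresh)
    profile = overlap_with_reference(net, geo.parcellation)
    overlap_sum = sum(profile.percentages.values()) + profile.unlabeled_pct
    sub_mask = net.network_mask.copy()
    sub_idx = np.argwhere(sub_mask)
    if len(sub_idx) > 1:  # carve out a strict subset network
        half = sub_idx[: len(sub_idx) // 2]
        sub_mask = np.zeros_like(sub_mask)
        sub_mask[half[:, 0], half[:, 1], half[:, 2]] = True
    contained = pairwise_overlap(net.network_mask, sub_mask)
    return {
        "n": n_subjects,
        "dice_vs_community": dice(net.network_mask, community),
        "network_voxels": net.n_voxels,
        "overlap_sum": float(overlap_sum),
        "somatomotor_label_pct": profile.percentages[2],
        "subset_pairwise_overlap": contained,
    }


# ---------------------------------------------------------------------------
# end-to-end demo and determinism


_COMPARE_FILES = (
    "glm/clusters_te.tsv",
    "glm/clusters_sex_x_te.tsv",
    "network/overlap_te.tsv",
    "qc/qc_report.tsv",
    "qc/demographics.tsv",
)


def demo_summary(result) -> dict:
    te_clusters = result.clusters.get("te", [])
    out = {
        "n_included": len(result.included),
        "n_excluded": len(result.excluded),
        "te_cluster_count": len(te_clusters),
        "interaction_cluster_count": len(result.clusters.get("sex_x_te", [])),
    }
    if te_clusters:
        out["te_cluster_size"] = te_clusters[0].size
        out["te_effect_size"] = te_clusters[0].average_effect_size
    if "te" in result.overlaps:
        prof = result.overlaps["te"]
        out["te_network_voxels"] = prof.n_voxels
        out["te_network_somatomotor_pct"] = prof.percentages[2]
    return out


def run_demo(seed: int, out_dir, n_subjects: int = 60, n_perm: int = 500):
    cfg = demo_config(seed=seed, n_subjects=n_subjects, n_perm=n_perm)
    return run_pipeline(cfg, out_dir)


def demo_determinism(seed: int, work_dir) -> dict:
    """Two identically seeded demo runs must write byte-identical
    statistical tables."""
    work = Path(work_dir)
    res_a = run_demo(seed, work / "run_a")
    res_b = run_demo(seed, work / "run_b")
    identical = True
    compared = 0
    for rel in _COMPARE_FILES:
        fa, fb = work / "run_a" / rel, work / "run_b" / rel
        if fa.exists() != fb.exists():
            identical = False
            continue
        if fa.exists():
            compared += 1
            identical &= filecmp.cmp(fa, fb, shallow=False)
    return {
        "identical": identical,
        "files_compared": compared,
        "summary": demo_summary(res_a),
    }
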