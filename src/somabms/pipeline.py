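"""End-to-end recovery experiment: simulate -> GLM -> BMS -> ROI statistics.

This orchestrates the full analysis exactly as it would run on acquired
data, but on a synthetic cohort whose ground truth is known: each embedded
lattice region is generated by one candidate model, so the pipeline's own
output can be scored for model recovery, family anti-dilution, and
stimulus-response-profile shape discrimination.

Stages per subject: refit the psychometric observer from the simulated
behaviour (per run, then averaged), rebuild the five modulators from the
refitted observer, estimate per-voxel AR(1) coefficients from a
model-independent design, fit the five candidate GLMs (plus the ten-level
GLM for SRPs), and smooth the resulting log-evidence and level-beta maps.
Group stage: voxel-wise random-effects BMS at the model and family level,
EP/cluster thresholding, subject-peak beta extraction with JZS tests, and
SRP extraction with shape classification.
"""

from __future__ import annotations

import numpy as np

from . import bms as bz
from .bms import FamilyPartition, run_bms_maps, threshold_ep_map
from .design import build_regressors
from .glm import (EvidenceMaps, GLMPrior, build_design_matrix, compute_nuisance_pcs,
                  estimate_ar1, fit_bayesian_glm, smooth_evidence_maps)
from .io import PipelineConfig
from .psychometric import average_fits, fit_logistic
from .roi import (classify_srp_shape, extract_srp, find_subject_peak,
                  fit_ten_level_glm, jzs_onesample_bf, bayes_association_bf)
from .synth import MODELS, SimulationConfig, simulate_subject

__all__ = [
    "default_partition",
    "analyze_subject",
    "run_recovery_experiment",
    "bootstrap_srp_classification",
    "EXPECTED_SHAPES",
]

#: The model family whose members correlate positively with stimulus
#: intensity, versus the two singleton families.
PLUS_FAMILY = ("intensity", "detection", "p_detect")

#: Ground-truth SRP shape per generating model.
EXPECTED_SHAPES = {"intensity": "linear", "detection": "sigmoid",
                   "p_detect": "sigmoid", "uncertainty": "inverse_u",
                   "report": "flat"}


def default_partition() -> FamilyPartition:
    idx = {m: i for i, m in enumerate(MODELS)}
    return FamilyPartition(families={
        "+family": tuple(idx[m] for m in PLUS_FAMILY),
        "uncertainty": (idx["uncertainty"],),
        "report": (idx["report"],),
    }, n_models=len(MODELS))


def analyze_subject(subj, pcfg: PipelineConfig, labels: np.ndarray) -> dict:
    """First-level analysis of one (synthetic or loaded) subject.

    Returns smoothed per-model log-evidence maps summed over runs, per-model
    modulator beta maps (run-averaged, unsmoothed — betas are read out at
    subject peaks), smoothed ten-level beta maps, and behavioural summaries.
    """
    cfg: SimulationConfig = pcfg.simulation
    shape = cfg.shape
    n_vox = int(np.prod(shape))
    prior = GLMPrior(g=pcfg.glm_prior_g, a0=pcfg.glm_prior_a0, b0=pcfg.glm_prior_b0)

    run_fits = [fit_logistic(t.loc[t["trial_type"] == "stim", "intensity_mA"],
                             t.loc[t["trial_type"] == "stim", "detected"])
                for t in subj.trials]
    fit_hat = average_fits(run_fits)

    lnE = np.zeros((len(MODELS), n_vox))
    betas = np.zeros((len(MODELS), n_vox))
    ten = np.zeros((10, n_vox))
    background = labels == 0   # nuisance-tissue compartment for the PCs
    for r, (tab, bold, motion) in enumerate(zip(subj.trials, subj.bold, subj.motion)):
        reg = build_regressors(tab, fit_hat)
        Y = bold.T.astype(np.float64)
        pcs = compute_nuisance_pcs(bold, background)
        drift = np.stack([np.cos(np.pi * (k + 1) * np.arange(cfg.n_volumes) / cfg.n_volumes)
                          for k in range(2)], axis=1)
        nuisance = {"motion": motion, "acomp": pcs, "drift": drift}
        X_base = build_design_matrix(tab, None, reg, cfg.n_volumes, cfg.tr, nuisance)
        rho = estimate_ar1(Y, X_base.to_numpy()) if pcfg.prewhiten else None
        for k, model in enumerate(MODELS):
            X = build_design_matrix(tab, model, reg, cfg.n_volumes, cfg.tr, nuisance)
            res = fit_bayesian_glm(Y, X, prior=prior, rho=rho)
            lnE[k] += res.log_evidence
            betas[k] += res.beta(model) / len(subj.trials)
        ten_r, _ = fit_ten_level_glm(tab, reg, bold, cfg.n_volumes, cfg.tr,
                                     nuisance=nuisance, prior=prior, rho=rho)
        ten += ten_r / len(subj.trials)

    maps = EvidenceMaps(models=list(MODELS), log_evidence=lnE.reshape((-1,) + shape),
                        voxel_size=cfg.voxel_size)
    sm = smooth_evidence_maps(maps, pcfg.evidence_fwhm_mm, pcfg.resample_mm)
    ten_maps = EvidenceMaps(models=[f"level_{i}" for i in range(1, 11)],
                            log_evidence=ten.reshape((-1,) + shape),
                            voxel_size=cfg.voxel_size)
    ten_sm = smooth_evidence_maps(ten_maps, pcfg.evidence_fwhm_mm, pcfg.resample_mm)

    all_t = [t[t["trial_type"] == "stim"] for t in subj.trials]
    detected = np.concatenate([t["detected"].to_numpy(float) for t in all_t])
    match = np.concatenate([(t["report"].to_numpy() == "match").astype(int) for t in all_t])
    rt = np.concatenate([t["response_time"].to_numpy(float) for t in all_t])
    table = np.array([[np.sum((detected == 1) & (match == 1)),
                       np.sum((detected == 1) & (match == 0))],
                      [np.sum((detected == 0) & (match == 1)),
                       np.sum((detected == 0) & (match == 0))]])
    bf10_assoc, bf01_assoc = bayes_association_bf(table)
    behaviour = {
        "detection_rate": float(detected.mean()),
        "rt_detected": float(rt[detected == 1].mean()),
        "rt_undetected": float(rt[detected == 0].mean()),
        "rt_diff": float(rt[detected == 1].mean() - rt[detected == 0].mean()),
        "association_bf10": bf10_assoc,
        "association_bf01": bf01_assoc,
        "t50_hat": fit_hat.t50,
        "t50_true": subj.fit_true.t50,
    }
    return {"log_evidence": sm.log_evidence, "betas": betas.reshape((-1,) + shape),
            "ten_betas": ten_sm.log_evidence, "behaviour": behaviour}


def run_recovery_experiment(pcfg: PipelineConfig | None = None, seed: int = 0,
                            progress: bool = False) -> dict:
    """Full simulate -> analyse -> group-BMS -> ROI experiment; returns all results."""
    pcfg = pcfg or PipelineConfig()
    cfg = pcfg.simulation.model_copy(update={"seed": seed})
    rng = np.random.default_rng(seed)
    from .synth import region_labels
    labels_flat, region_models = region_labels(cfg.shape)
    labels_vol = labels_flat.reshape(cfg.shape)

    per_subject = []
    for s in range(cfg.n_subjects):
        subj = simulate_subject(cfg, rng)
        per_subject.append(analyze_subject(subj, pcfg, labels_flat))
        if progress:
            print(f"subject {s + 1}/{cfg.n_subjects} analysed")
        del subj

    lnE = np.stack([r["log_evidence"] for r in per_subject])     # (S, K, *shape)
    partition = default_partition()
    model_level = run_bms_maps(lnE, partition=None, alpha0=pcfg.alpha0,
                               n_samples=pcfg.ep_samples_map, seed=rng)
    family_level = run_bms_maps(lnE, partition=partition,
                                n_samples=pcfg.ep_samples_map, seed=rng)
    fam_names = family_level["family_names"]
    fam_ep = family_level["family_ep"]                           # (3, *shape)
    model_ep = model_level["ep"]                                 # (5, *shape)

    # family-defined ROIs, then within-family model comparison inside them
    plus_idx = fam_names.index("+family")
    plus_labelled, plus_clusters = threshold_ep_map(fam_ep[plus_idx], pcfg.ep_min,
                                                    pcfg.k_min, pcfg.connectivity)
    plus_mask = plus_labelled > 0
    member_idx = list(partition.families["+family"])
    within_ep = np.zeros((len(member_idx),) + cfg.shape)
    if plus_mask.any():
        sub_lnE = lnE[:, member_idx][:, :, plus_mask]            # (S, 3, Vmask)
        within = run_bms_maps(sub_lnE, partition=None, alpha0=pcfg.alpha0,
                              n_samples=pcfg.ep_samples_map, seed=rng)
        within_ep[:, plus_mask] = within["ep"]

    # ROI masks per model: +family members take the within-family argmax
    # inside family clusters; uncertainty/report threshold their own EP map.
    roi_masks: dict[str, np.ndarray] = {}
    cluster_info: dict[str, list] = {"+family": plus_clusters}
    winner_in_mask = np.argmax(within_ep, axis=0)
    for j, m in enumerate(PLUS_FAMILY):
        roi_masks[m] = plus_mask & (winner_in_mask == j)
    for m in ("uncertainty", "report"):
        k = list(MODELS).index(m)
        labelled, clusters = threshold_ep_map(model_ep[k], pcfg.ep_min,
                                              pcfg.k_min, pcfg.connectivity)
        roi_masks[m] = labelled > 0
        cluster_info[m] = clusters

    # ground-truth recovery metrics
    fam_argmax = np.argmax(fam_ep, axis=0)
    model_argmax = np.argmax(model_ep, axis=0)
    recovery = {}
    for m in MODELS:
        region = labels_vol == region_models[m]
        k = list(MODELS).index(m)
        if m in PLUS_FAMILY:
            frac = float(np.mean(fam_argmax[region] == plus_idx))
        else:
            frac = float(np.mean(model_argmax[region] == k))
        others = [j for j in range(len(MODELS)) if j != k]
        foreign = model_ep[others][:, region]
        recovery[m] = {
            "winner_fraction": frac,
            "model_winner_fraction": float(np.mean(model_argmax[region] == k)),
            "max_foreign_ep": float(foreign.max()),
            "foreign_ep99_voxels": int(np.sum(foreign.max(axis=0) >= pcfg.ep_min)),
        }

    # anti-dilution: family EP vs member EPs inside +family-generated regions
    anti_dilution = {}
    for m in PLUS_FAMILY:
        region = labels_vol == region_models[m]
        fam_mean = float(fam_ep[plus_idx][region].mean())
        member_means = {mm: float(model_ep[list(MODELS).index(mm)][region].mean())
                        for mm in PLUS_FAMILY}
        anti_dilution[m] = {"family_ep": fam_mean, "member_eps": member_means,
                            "margin": fam_mean - max(member_means.values())}

    # subject peaks, betas, JZS tests, and SRPs per data-defined ROI
    roi_stats = {}
    srp_per_subject = {}
    for m in MODELS:
        mask = roi_masks[m]
        if not mask.any():
            roi_stats[m] = None
            continue
        k = list(MODELS).index(m)
        peaks, peak_betas = [], []
        for r in per_subject:
            pk = find_subject_peak(r["log_evidence"], mask, k, cfg.voxel_size)
            peaks.append(pk)
            peak_betas.append(float(r["betas"][k][pk.index]))
        bf10 = jzs_onesample_bf(np.asarray(peak_betas), r=pcfg.jzs_scale)
        srp = extract_srp([r["ten_betas"] for r in per_subject],
                          [p.index for p in peaks],
                          radius_mm=pcfg.srp_radius_mm, voxel_size=cfg.voxel_size)
        srp_per_subject[m] = srp["per_subject"]
        roi_stats[m] = {"mask_size": int(mask.sum()), "peaks": peaks,
                        "peak_betas": peak_betas, "beta_mean": float(np.mean(peak_betas)),
                        "jzs_bf10": bf10, "srp_mean": srp["mean"], "srp_sem": srp["sem"],
                        "srp_shape": classify_srp_shape(srp["mean"], srp["sem"])}

    behaviour = [r["behaviour"] for r in per_subject]
    return {
        "config": pcfg, "seed": seed, "models": list(MODELS),
        "region_models": region_models, "labels": labels_vol,
        "log_evidence": lnE, "model_ep": model_ep, "family_ep": fam_ep,
        "family_names": fam_names, "within_family_ep": within_ep,
        "roi_masks": roi_masks, "clusters": cluster_info,
        "recovery": recovery, "anti_dilution": anti_dilution,
        "roi_stats": roi_stats, "srp_per_subject": srp_per_subject,
        "behaviour": behaviour,
    }


def bootstrap_srp_classification(srp_per_subject: dict[str, np.ndarray],
                                 n_boot: int = 100,
                                 seed: int | np.random.Generator = 0) -> dict:
    """Shape-classification accuracy of group SRPs over bootstrap cohorts.

    For each replicate, subjects are resampled with replacement, the group
    SRP recomputed per region, and its classified shape compared with the
    generating model's expected shape.  Classification uses the full
    cohort's standard error scaled by sqrt(2): a replicate mean carries the
    cohort mean's sampling error *and* the resampling error, each of
    variance ~SEM^2, and the full-cohort SEM is used rather than the
    replicate's own (an n-of-12 resample-with-replacement SEM estimate is
    too noisy to standardise against).  Returns the per-region accuracy and
    the overall fraction of replicate-regions classified correctly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    correct = {m: 0 for m in srp_per_subject}
    sems = {m: np.sqrt(2.0) * arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
            for m, arr in srp_per_subject.items()}
    all_correct = 0
    for _ in range(n_boot):
        rep_ok = True
        for m, arr in srp_per_subject.items():
            idx = rng.integers(0, arr.shape[0], size=arr.shape[0])
            boot = arr[idx]
            shape = classify_srp_shape(boot.mean(axis=0), sems[m])
            if shape == EXPECTED_SHAPES[m]:
                correct[m] += 1
            else:
                rep_ok = False
        all_correct += rep_ok
    acc = {m: c / n_boot for m, c in correct.items()}
    overall = float(np.mean(list(acc.values())))
    return {"per_region": acc, "overall": overall,
            "all_correct_fraction": all_correct / n_boot, "n_boot": n_boot}
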