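"""Synthetic behaviour and BOLD generator.

Raw data from the somatosensory detection study cannot be shared, so every
downstream stage is exercised on simulated cohorts with the statistical
structure the analysis assumes:

* per-participant logistic observers drawn from a population anchored at the
  group calibration values (T50 = 2.40 mA with its between-subject spread,
  and a slope consistent with the printed T01/T99 anchors);
* the 4-run x 100-trial design with normal-weighted intensity allocation,
  counterbalanced matching cues, and null events;
* reaction times drawn from a truncated Gaussian within the 0.15-0.9 s
  response window, shifted faster on detected trials;
* BOLD series on a desk-scale voxel lattice in which six embedded regions
  are generated by one candidate model each (the five experimental
  covariates plus a pure-noise null region), with canonical-HRF responses,
  low-frequency drift, motion-like nuisance signals, and AR(1) noise.

Ground truth (observer parameters, region labels, generating models) is
stored alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.signal import lfilter
from scipy.stats import truncnorm

from . import design as dz
from .design import RegressorSet, allocate_trials, assign_cues, build_regressors, \
    build_trial_table, derive_report, generate_onsets
from .glm import hrf_regressor
from .psychometric import PsychometricFit, derive_intensity_grid, detection_probability

__all__ = [
    "SimulationConfig",
    "SyntheticSubject",
    "SyntheticDataset",
    "region_labels",
    "simulate_behaviour",
    "simulate_bold",
    "simulate_subject",
    "simulate_cohort",
    "simulate_calibration",
]

#: Generative models in canonical order; "null" voxels receive noise only.
MODELS = ("intensity", "detection", "p_detect", "uncertainty", "report")
REGION_MODELS = MODELS + ("null",)

#: 5x4x3 boxes (60 voxels) embedded in the default 20^3 lattice with >=4-voxel
#: gaps, so 8-mm smoothing of 3-mm voxels cannot mix two signal regions.
_BOX = (5, 4, 3)
_OFFSETS = ((2, 2, 2), (12, 2, 2), (2, 12, 2), (12, 12, 2), (2, 2, 12), (12, 12, 12))


class SimulationConfig(BaseModel):
    """All knobs of the generator; defaults are the study's design conditions."""

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = 12
    seed: int = 0

    # psychometric population (mA); slope mean follows from the printed
    # T01/T99 anchors: logit(.99)/(2 * (t50 - T01)) / 2 = 2.05 /mA
    t50_mean: float = 2.40
    t50_sd: float = 0.69
    slope_mean: float = 2.05
    slope_sd: float = 0.35
    slope_min: float = 0.5

    # design
    n_runs: int = 4
    trials_per_run: int = 100
    nulls_per_run: int = 10
    iti_bounds: tuple[float, float] = dz.ITI_BOUNDS
    tr: float = 2.0
    n_volumes: int = 378

    # reaction-time model (seconds); the detected-trial shift varies across
    # subjects with the dispersion printed for the group RT difference
    rt_mean: float = 0.364
    rt_between_sd: float = 0.053
    rt_within_sd: float = 0.08
    rt_detect_shift: float = -0.01177
    rt_shift_between_sd: float = 0.01484
    rt_window: tuple[float, float] = (0.15, 0.9)

    # BOLD model: amplitudes in % signal change, noise marginal SD in %
    shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 3.0
    amplitude: float = 1.0
    onset_amplitude: float = 0.5
    noise_sd: float = 1.0
    ar_coef: float = 0.2
    baseline: float = 100.0
    drift_sd: float = 0.5
    motion_sd: float = 0.2

    # calibration session (15 levels x 20 repetitions in 0.1-mA steps)
    calib_n_levels: int = 15
    calib_reps: int = 20
    calib_step: float = 0.1

    @model_validator(mode="after")
    def _check(self):
        if not (-1.0 < self.ar_coef < 1.0):
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ValueError("noise SD must be finite and non-negative")
        if not (np.isfinite(self.amplitude) and np.isfinite(self.onset_amplitude)):
            raise ValueError("effect amplitudes must be finite")
        last_onset = self.trials_per_run + self.nulls_per_run
        if self.n_volumes * self.tr < last_onset * (self.iti_bounds[0] + 2.0) + 20.0:
            raise ValueError("volumes x TR cannot cover the last trial onset + 20 s")
        return self


@dataclass
class SyntheticSubject:
    """One simulated participant with ground truth attached."""

    fit_true: PsychometricFit
    grid: object
    trials: list[pd.DataFrame]              # one table per run
    regressors: list[RegressorSet]
    bold: list[np.ndarray]                  # (V, T) float32 per run
    motion: list[np.ndarray]                # (T, 6) per run


@dataclass
class SyntheticDataset:
    """A cohort plus the labels needed to score recovery."""

    config: SimulationConfig
    subjects: list[SyntheticSubject]
    labels: np.ndarray                      # flat (V,) region codes, 0 = background
    region_models: dict[str, int]           # model name -> region code


def region_labels(shape: tuple[int, int, int] = (20, 20, 20)) -> tuple[np.ndarray, dict[str, int]]:
    """Flat region-code array and the model -> code mapping for the lattice."""
    lab = np.zeros(shape, dtype=int)
    mapping = {}
    for i, (name, off) in enumerate(zip(REGION_MODELS, _OFFSETS), start=1):
        sl = tuple(slice(o, o + b) for o, b in zip(off, _BOX))
        if any(o + b > s for o, b, s in zip(off, _BOX, shape)):
            raise ValueError("lattice too small for the embedded regions")
        lab[sl] = i
        mapping[name] = i
    return lab.ravel(), mapping


def simulate_behaviour(fit: PsychometricFit, trials: pd.DataFrame,
                       seed: int | np.random.Generator = 0,
                       config: SimulationConfig | None = None,
                       rt_base_mean: float | None = None,
                       rt_shift: float | None = None) -> pd.DataFrame:
    """Fill detection, report, and reaction-time columns of a trial table.

    Detection is Bernoulli at the observer's detection probability for the
    presented intensity; the report follows the cue/percept truth table; RTs
    are truncated-Gaussian within the response window with detected trials
    shifted faster.
    """
    cfg = config or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = trials.copy()
    stim = t["trial_type"].to_numpy() == "stim"
    x = t.loc[stim, "intensity_mA"].to_numpy(float)
    p = detection_probability(fit, x)
    detected = (rng.random(x.size) < p).astype(int)
    cues = t.loc[stim, "cue"].to_numpy()
    reports = [derive_report(c, d) for c, d in zip(cues, detected)]
    mu0 = cfg.rt_mean if rt_base_mean is None else rt_base_mean
    shift = cfg.rt_detect_shift if rt_shift is None else rt_shift
    mu = mu0 + shift * detected
    lo, hi = cfg.rt_window
    a, b = (lo - mu) / cfg.rt_within_sd, (hi - mu) / cfg.rt_within_sd
    rt = truncnorm.rvs(a, b, loc=mu, scale=cfg.rt_within_sd, random_state=rng)
    t.loc[stim, "detected"] = detected.astype(float)
    t.loc[stim, "report"] = reports
    t.loc[stim, "response_time"] = rt
    return t


def _ar1_noise(rng: np.random.Generator, n_vox: int, n_t: int,
               rho: float, sd: float) -> np.ndarray:
    """AR(1) series with marginal SD ``sd`` (innovation SD sd*sqrt(1-rho^2))."""
    w = rng.standard_normal((n_vox, n_t)) * (sd * np.sqrt(1.0 - rho ** 2))
    w[:, 0] = rng.standard_normal(n_vox) * sd
    return lfilter([1.0], [1.0, -rho], w, axis=1)


def _motion_series(rng: np.random.Generator, n_t: int, n_par: int = 6) -> np.ndarray:
    """Slowly varying motion-like nuisance time courses, unit SD, (T, 6)."""
    steps = rng.standard_normal((n_t, n_par))
    walk = np.cumsum(steps, axis=0)
    kernel = np.hanning(21)
    kernel /= kernel.sum()
    smooth = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 0, walk)
    smooth -= smooth.mean(axis=0)
    sd = smooth.std(axis=0)
    sd[sd == 0] = 1.0
    return smooth / sd


def simulate_bold(trials: pd.DataFrame, regressors: RegressorSet,
                  config: SimulationConfig, seed: int | np.random.Generator = 0,
                  labels: np.ndarray | None = None,
                  region_models: dict[str, int] | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, dict[str, int], np.ndarray]:
    """One run of lattice BOLD data: (voxels x time, labels, mapping, motion).

    Region voxels respond to trial onsets with the canonical HRF scaled by
    their generating modulator (plus a common onset response); all non-null
    voxels carry cosine drift and motion-coupled nuisance signal; every voxel
    gets AR(1) Gaussian noise on top of a constant baseline.
    """
    cfg = config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None or region_models is None:
        labels, region_models = region_labels(cfg.shape)
    n_vox = int(np.prod(cfg.shape))
    if labels.size != n_vox:
        raise ValueError("labels do not match the configured lattice shape")
    T = cfg.n_volumes
    duration = T * cfg.tr
    if regressors.onsets.max() + 20.0 > duration:
        raise ValueError("scan duration too short for the last trial onset + 20 s")
    frame_times = np.arange(T) * cfg.tr

    onset_course = hrf_regressor(regressors.onsets, np.ones_like(regressors.onsets),
                                 frame_times)[:, 0]
    courses = {m: hrf_regressor(regressors.onsets, regressors.modulator(m),
                                frame_times)[:, 0] for m in MODELS}

    data = np.full((n_vox, T), cfg.baseline, dtype=np.float64)
    for name, code in region_models.items():
        vox = labels == code
        if name == "null":
            continue
        data[vox] += cfg.onset_amplitude * onset_course + cfg.amplitude * courses[name]

    # nuisance: cosine drift + motion-coupled signal everywhere except the null region
    motion = _motion_series(rng, T)
    drift_basis = np.stack([np.cos(np.pi * (k + 1) * np.arange(T) / T)
                            for k in range(2)], axis=1)
    nuis_basis = np.concatenate([drift_basis, motion], axis=1)  # (T, 8)
    null_code = region_models.get("null", -1)
    contaminated = labels != null_code
    weights = rng.standard_normal((n_vox, nuis_basis.shape[1]))
    weights[:, :2] *= cfg.drift_sd
    weights[:, 2:] *= cfg.motion_sd
    weights[~contaminated] = 0.0
    data += weights @ nuis_basis.T

    data += _ar1_noise(rng, n_vox, T, cfg.ar_coef, cfg.noise_sd)
    return data.astype(np.float32), labels, region_models, motion


def simulate_subject(config: SimulationConfig, rng: np.random.Generator,
                     with_bold: bool = True) -> SyntheticSubject:
    """One participant: observer, design, behaviour, and (optionally) BOLD."""
    cfg = config
    t50 = float(np.clip(rng.normal(cfg.t50_mean, cfg.t50_sd), 0.5, None))
    slope = float(np.clip(rng.normal(cfg.slope_mean, cfg.slope_sd), cfg.slope_min, None))
    fit = PsychometricFit(t50, slope)
    grid = derive_intensity_grid(fit)
    rt_base = float(rng.normal(cfg.rt_mean, cfg.rt_between_sd))
    rt_shift = float(rng.normal(cfg.rt_detect_shift, cfg.rt_shift_between_sd))

    runs = allocate_trials(cfg.n_runs, cfg.trials_per_run, cfg.nulls_per_run, seed=rng)
    labels, mapping = region_labels(cfg.shape)
    trials, regs, bold, motion = [], [], [], []
    for levels in runs:
        onsets = generate_onsets(levels.size, cfg.n_volumes * cfg.tr,
                                 iti_bounds=cfg.iti_bounds, seed=rng)
        cues = assign_cues(levels, seed=rng)
        tab = build_trial_table(levels, onsets, grid, cues)
        tab = simulate_behaviour(fit, tab, seed=rng, config=cfg,
                                 rt_base_mean=rt_base, rt_shift=rt_shift)
        reg = build_regressors(tab, fit)
        trials.append(tab)
        regs.append(reg)
        if with_bold:
            y, labels, mapping, mot = simulate_bold(tab, reg, cfg, seed=rng,
                                                    labels=labels, region_models=mapping)
            bold.append(y)
            motion.append(mot)
    return SyntheticSubject(fit_true=fit, grid=grid, trials=trials, regressors=regs,
                            bold=bold, motion=motion)


def simulate_cohort(config: SimulationConfig, with_bold: bool = True) -> SyntheticDataset:
    """Independent subjects from the population model, fully reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    labels, mapping = region_labels(config.shape)
    subjects = [simulate_subject(config, rng, with_bold=with_bold)
                for _ in range(config.n_subjects)]
    return SyntheticDataset(config=config, subjects=subjects, labels=labels,
                            region_models=mapping)


def simulate_calibration(fit: PsychometricFit, config: SimulationConfig | None = None,
                         seed: int | np.random.Generator = 0,
                         centre: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """A threshold-calibration session: levels centred on the (initial) threshold.

    Returns (intensities, detected) for ``calib_n_levels`` intensities in
    ``calib_step`` increments, each repeated ``calib_reps`` times in random
    order.
    """
    cfg = config or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = fit.t50 if centre is None else centre
    half = (cfg.calib_n_levels - 1) / 2.0
    levels = c + (np.arange(cfg.calib_n_levels) - half) * cfg.calib_step
    x = np.repeat(levels, cfg.calib_reps)
    rng.shuffle(x)
    detected = (rng.random(x.size) < detection_probability(fit, x)).astype(int)
    return x, detected
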