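"""First-level Bayesian GLM with exact model evidence.

Each candidate model is an event-related GLM with a single onset regressor
(all experimental trials), its parametric modulation by one z-scored
experimental covariate, temporal derivatives of both, a reaction-time
modulator, and nuisance columns (motion, tissue-signal principal components,
low-frequency drift, constant).  The models differ only in the parametric
modulator, so differences in log evidence isolate the covariate that best
explains a voxel's response.

Estimation uses the conjugate normal–inverse-gamma family with a Zellner
g-prior on the weights, which yields the marginal likelihood (model
evidence) in closed form per voxel.  Serial correlation is handled by exact
AR(1) generalised least squares: the whitened cross-products are quadratic
polynomials in the AR coefficient, so per-voxel whitening costs no extra
passes over the data.  Spatial regularisation is realised by Gaussian
smoothing of the per-subject log-evidence maps before group-level model
selection (see ``smooth_evidence_maps``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import compute_regressor
from scipy.ndimage import gaussian_filter, zoom
from scipy.special import gammaln

from .design import RegressorSet

__all__ = [
    "GLMPrior",
    "GLMResult",
    "EvidenceMaps",
    "hrf_regressor",
    "build_design_matrix",
    "compute_nuisance_pcs",
    "estimate_ar1",
    "fit_bayesian_glm",
    "smooth_evidence_maps",
]


class RankDeficientDesignError(ValueError):
    """The design matrix is numerically rank deficient."""


@dataclass(frozen=True)
class GLMPrior:
    """Conjugate prior: beta | s2 ~ N(0, s2 * g * (X'X)^-1), s2 ~ InvGamma(a0, b0).

    ``g`` defaults to the number of scans (unit-information prior); the
    inverse-gamma shape/scale are weakly informative.  ``g = inf`` gives the
    flat-prior limit in which the posterior mean equals GLS/OLS.
    """

    g: float | None = None  # None -> number of scans
    a0: float = 0.1
    b0: float = 0.1


@dataclass
class GLMResult:
    """Posterior summaries and log marginal likelihood per voxel."""

    beta_mean: np.ndarray          # (p, V)
    beta_cov: np.ndarray           # (V, p, p), posterior covariance E[s2|y] * P^-1
    a_n: float
    b_n: np.ndarray                # (V,)
    log_evidence: np.ndarray       # (V,), natural log
    columns: list[str]

    def beta(self, name: str) -> np.ndarray:
        return self.beta_mean[self.columns.index(name)]


@dataclass
class EvidenceMaps:
    """Per-subject voxel-wise log evidence (and modulator betas) per model."""

    models: list[str]
    log_evidence: np.ndarray            # (K, nx, ny, nz)
    betas: np.ndarray | None = None     # (K, nx, ny, nz), modulator beta per model
    voxel_size: float = 3.0             # isotropic, mm
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.diag([self.voxel_size] * 3 + [1.0])
        if self.log_evidence.shape[0] != len(self.models):
            raise ValueError("one evidence volume per model required")


_HRF_PEAK_CACHE: dict[float, float] = {}


def _hrf_peak(tr: float) -> float:
    """Peak of the canonical HRF kernel (used to normalise to unit peak)."""
    if tr not in _HRF_PEAK_CACHE:
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf
        _HRF_PEAK_CACHE[tr] = float(spm_hrf(tr, oversampling=50).max())
    return _HRF_PEAK_CACHE[tr]


def hrf_regressor(onsets: np.ndarray, amplitudes: np.ndarray, frame_times: np.ndarray,
                  derivative: bool = False, duration: float = 0.0) -> np.ndarray:
    """Canonical (SPM double-gamma) HRF-convolved regressor sampled at scan times.

    The kernel is normalised to unit peak, so a unit-amplitude event produces
    a peak response of 1 — amplitudes are then directly interpretable as
    percent signal change at the response peak.  Returns shape (T, 1), or
    (T, 2) when the temporal derivative is requested.
    """
    onsets = np.asarray(onsets, dtype=float)
    cond = np.vstack([onsets, np.full_like(onsets, duration),
                      np.asarray(amplitudes, dtype=float)])
    model = "spm + derivative" if derivative else "spm"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg, _ = compute_regressor(cond, model, frame_times)
    tr = float(frame_times[1] - frame_times[0]) if len(frame_times) > 1 else 1.0
    return reg / _hrf_peak(tr)


def build_design_matrix(trials: pd.DataFrame, modulator: str | None,
                        regressors: RegressorSet, n_volumes: int, tr: float,
                        nuisance: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Design matrix for one run and one candidate model.

    Columns (in order): HRF-convolved onset regressor and its temporal
    derivative, the parametric modulation by ``modulator`` and its
    derivative, the RT modulation, any nuisance blocks (each a (T, k) array
    keyed by name, e.g. motion parameters and tissue PCs), and a constant
    last.  ``modulator=None`` omits the modulation columns (used by the
    ten-level and nuisance-only designs).
    """
    frame_times = np.arange(n_volumes) * tr
    onsets = regressors.onsets
    if onsets.max() >= n_volumes * tr:
        raise ValueError("trial onsets extend beyond the scan duration")
    cols: dict[str, np.ndarray] = {}
    onset_reg = hrf_regressor(onsets, np.ones_like(onsets), frame_times, derivative=True)
    cols["onset"], cols["onset_derivative"] = onset_reg[:, 0], onset_reg[:, 1]
    if modulator is not None:
        mod = regressors.modulator(modulator)
        mod_reg = hrf_regressor(onsets, mod, frame_times, derivative=True)
        cols[modulator], cols[f"{modulator}_derivative"] = mod_reg[:, 0], mod_reg[:, 1]
    cols["rt"] = hrf_regressor(onsets, regressors.rt_z, frame_times)[:, 0]
    for name, block in (nuisance or {}).items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape[0] != n_volumes:
            block = block.T
        if block.shape[0] != n_volumes:
            raise ValueError(f"nuisance block {name!r} does not match {n_volumes} scans")
        for k in range(block.shape[1]):
            cols[f"{name}_{k + 1}"] = block[:, k]
    cols["constant"] = np.ones(n_volumes)
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear columns: those whose removal restores full rank
        arr = X.to_numpy()
        bad = [c for i, c in enumerate(X.columns)
               if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == rank]
        raise RankDeficientDesignError(f"design matrix is rank deficient; "
                                       f"collinear columns: {bad}")
    return X


def compute_nuisance_pcs(timeseries: np.ndarray, mask: np.ndarray,
                         n_components: int = 5) -> np.ndarray:
    """Top principal component time courses of the masked voxels, unit variance.

    ``timeseries`` is voxels x time; ``mask`` a boolean voxel selector (the
    tissue compartment whose shared signal should be regressed out).
    Returns (T, n_components) mutually orthogonal scores scaled to unit SD.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < n_components:
        raise ValueError(f"mask must contain at least {n_components} voxels")
    data = np.asarray(timeseries, dtype=float)[mask].T   # (T, Vmask)
    data = data - data.mean(axis=0)
    u, s, _ = np.linalg.svd(data, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    return scores / sd


def estimate_ar1(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-voxel lag-1 autocorrelation of OLS residuals (clipped to ±0.95).

    ``y`` is (T,) or (T, V).  The estimate from a model-independent design
    (shared columns) is reused across all candidate models at a voxel so that
    evidence differences are not confounded by differing whitening.
    """
    y2 = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (T, V)
    beta, *_ = np.linalg.lstsq(X, y2, rcond=None)
    r = y2 - X @ beta
    num = (r[1:] * r[:-1]).sum(axis=0)
    den = (r * r).sum(axis=0)
    rho = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    rho = np.clip(rho, -0.95, 0.95)
    return rho if np.asarray(y).ndim > 1 else rho[0]


def _whitened_crossprods(X: np.ndarray, Y: np.ndarray, rho: np.ndarray):
    """Exact AR(1) GLS cross-products for every voxel.

    For stationary AR(1) correlation R(rho) with unit marginal variance,
    R^-1 = (S0 + rho^2*S0m - rho*(S1+S1')) / (1-rho^2) expressed through
    lag-0/lag-1 cross-products, so X'R^-1X, X'R^-1y and y'R^-1y for all
    voxels follow from seven fixed matrix products.
    """
    T = X.shape[0]
    S0 = X.T @ X
    S0m = X[1:-1].T @ X[1:-1]
    S1 = X[1:].T @ X[:-1]
    S1s = S1 + S1.T
    a0 = X.T @ Y                      # (p, V)
    a_mid = X[1:-1].T @ Y[1:-1]
    a1 = X[1:].T @ Y[:-1] + X[:-1].T @ Y[1:]
    yy0 = (Y * Y).sum(axis=0)
    yy_mid = (Y[1:-1] * Y[1:-1]).sum(axis=0)
    yy1 = 2.0 * (Y[1:] * Y[:-1]).sum(axis=0)
    r = rho[:, None, None]
    denom = 1.0 - rho ** 2
    XtX = (S0[None] + r ** 2 * S0m[None] - r * S1s[None]) / denom[:, None, None]
    Xty = (a0.T + rho[:, None] ** 2 * a_mid.T - rho[:, None] * a1.T) / denom[:, None]
    yty = (yy0 + rho ** 2 * yy_mid - rho * yy1) / denom
    logdetR = (T - 1) * np.log(denom)
    return XtX, Xty, yty, logdetR


def fit_bayesian_glm(y: np.ndarray, X: pd.DataFrame | np.ndarray,
                     prior: GLMPrior = GLMPrior(),
                     rho: float | np.ndarray | None = None) -> GLMResult:
    """Closed-form conjugate Bayesian GLM fit with exact log model evidence.

    ``y`` may be a single time series (T,) or a voxels-in-columns matrix
    (T, V); all voxels share the design but each gets its own posterior and
    evidence.  ``rho`` is an optional AR(1) coefficient (scalar or per voxel)
    applied as exact GLS whitening; the whitening determinant enters the
    evidence so values remain comparable across models *given the same rho*.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    single = ya.ndim == 1
    Y = ya[:, None] if single else ya
    if not (np.isfinite(Y).all() and np.isfinite(Xa).all()):
        raise ValueError("non-finite values in data or design")
    T, p = Xa.shape
    if Y.shape[0] != T:
        raise ValueError(f"y has {Y.shape[0]} rows but design has {T}")
    V = Y.shape[1]
    rho_v = np.zeros(V) if rho is None else np.broadcast_to(
        np.asarray(rho, dtype=float), (V,)).copy()

    XtX, Xty, yty, logdetR = _whitened_crossprods(Xa, Y, rho_v)
    g = float(prior.g) if prior.g is not None else float(T)
    if np.isinf(g):
        shrink, log_prior_term = 1.0, 0.0
    else:
        # P = (1+1/g) X'R^-1X ; 0.5*(log|V0^-1| - log|P|) = -p/2 * log(1+g)
        shrink = g / (1.0 + g)
        log_prior_term = -0.5 * p * np.log1p(g)

    try:
        chol = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError as e:
        raise RankDeficientDesignError("whitened X'X is not positive definite") from e
    beta_gls = np.linalg.solve(XtX, Xty[..., None])[..., 0]  # (V, p)
    m = shrink * beta_gls
    # m' P m with P = X'R^-1X / shrink
    quad = shrink * np.einsum("vp,vp->v", beta_gls, Xty)
    a_n = prior.a0 + 0.5 * T
    b_n = prior.b0 + 0.5 * (yty - quad)
    b_n = np.maximum(b_n, 1e-300)
    log_evidence = (
        -0.5 * T * np.log(2.0 * np.pi)
        - 0.5 * logdetR
        + log_prior_term
        + prior.a0 * np.log(prior.b0) - a_n * np.log(b_n)
        + gammaln(a_n) - gammaln(prior.a0)
    )
    # posterior covariance: E[s2 | y] * P^-1 = b_n/(a_n-1) * shrink * (X'R^-1X)^-1
    inv = np.linalg.inv(XtX)
    beta_cov = (b_n / (a_n - 1.0) * shrink)[:, None, None] * inv
    del chol
    return GLMResult(beta_mean=m.T if not single else m.T,
                     beta_cov=beta_cov, a_n=float(a_n),
                     b_n=b_n if not single else b_n,
                     log_evidence=log_evidence,
                     columns=columns)


def smooth_evidence_maps(maps: EvidenceMaps, fwhm: float,
                         target_voxel_size: float | None = None) -> EvidenceMaps:
    """Gaussian-smooth (and optionally resample) per-model evidence volumes.

    ``fwhm`` is in mm; smoothing acts as the spatial regulariser of the
    pipeline — neighbouring voxels pool their evidence before group-level
    model selection.  ``fwhm = 0`` is the identity; an ``fwhm`` below the
    voxel size triggers a warning (the kernel is narrower than one voxel).
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if 0 < fwhm < maps.voxel_size:
        warnings.warn(f"fwhm {fwhm} mm is smaller than the voxel size "
                      f"{maps.voxel_size} mm; smoothing has little effect")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / maps.voxel_size
    def _proc(vol: np.ndarray) -> np.ndarray:
        out = gaussian_filter(vol, sigma=sigma, mode="nearest") if fwhm > 0 else vol.copy()
        if target_voxel_size is not None and target_voxel_size != maps.voxel_size:
            out = zoom(out, maps.voxel_size / target_voxel_size, order=1)
        return out
    log_e = np.stack([_proc(v) for v in maps.log_evidence])
    betas = (np.stack([_proc(v) for v in maps.betas])
             if maps.betas is not None else None)
    vs = target_voxel_size if target_voxel_size is not None else maps.voxel_size
    return EvidenceMaps(models=list(maps.models), log_evidence=log_e, betas=betas,
                        voxel_size=vs)
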