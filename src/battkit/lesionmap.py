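"""Brain–behaviour mapping of battery component scores.

Inputs are per-patient continuous abnormality volumes on one shared grid
(values in [0, 1], higher = more abnormal tissue).  Analyses:

* **mask building** — restrict every voxelwise analysis to voxels damaged
  in at least a given fraction of patients (lesion-overlap thresholding);
* **Fisher group comparison** — per voxel, a two-sided Fisher exact test of
  damaged/intact proportions between two patient groups;
* **VBCM** — mass-univariate linear models of abnormality on the component
  scores (entered simultaneously) plus covariates, with cluster-extent
  family-wise-error correction by Freedman–Lane permutation of the
  maximum cluster size;
* **RVR** — multivariate prediction of a component score from the masked
  voxel pattern with relevance vector regression (sparse Bayesian linear
  model over a linear patient kernel), leave-one-out cross-validation and
  permutation inference on the cross-validated correlation.

Voxel flattening order is C order (last axis fastest) throughout; all
permutation engines are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "AbnormalityVolume",
    "AnalysisMask",
    "StatMap",
    "RVRFit",
    "build_mask",
    "fisher_voxel_compare",
    "vbcm",
    "residualize",
    "rvr_fit",
    "rvr_posterior_mean",
    "rvr_predict_loocv",
    "volumes_to_matrix",
    "save_volume",
    "load_volume",
]


@dataclass
class AbnormalityVolume:
    """One patient's continuous abnormality map plus summary lesion volume."""

    data: np.ndarray
    patient_id: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("abnormality volume must be 3-D")
        if np.nanmin(self.data) < 0 or np.nanmax(self.data) > 1:
            raise ValueError("abnormality values must lie in [0, 1]")

    @property
    def lesion_volume(self) -> float:
        return float(self.data.sum())


@dataclass
class AnalysisMask:
    """Boolean analysis mask derived from the lesion overlap map."""

    mask: np.ndarray
    overlap_threshold: float
    binarize_at: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class StatMap:
    """Voxelwise t map (inside the mask) with cluster-level inference."""

    t_map: np.ndarray           # full grid, NaN outside mask
    predictor: str
    voxel_p: float
    cluster_alpha: float
    n_permutations: int
    seed: int
    clusters: list[dict]        # id, size, peak_voxel, peak_t, fwe_p
    label_map: np.ndarray | None = None  # cluster id per voxel, 0 elsewhere


@dataclass
class RVRFit:
    """Relevance vector regression state and LOOCV performance."""

    weights: np.ndarray          # dual weights incl. bias (index 0)
    alpha: np.ndarray            # per-weight precisions
    beta: float                  # noise precision
    relevance: np.ndarray        # boolean, weights surviving pruning
    loocv_predictions: np.ndarray
    cv_r: float
    permutation_p: float | None
    n_iter: int


# ---------------------------------------------------------------------------
# masks and simple voxelwise tests
# ---------------------------------------------------------------------------


def volumes_to_matrix(volumes: list[np.ndarray], mask: np.ndarray) -> np.ndarray:
    """Stack masked voxels into a patients × voxels matrix (C order)."""
    return np.stack([np.asarray(v)[mask] for v in volumes])


def build_mask(volumes: list[np.ndarray], threshold: float = 0.10,
               binarize_at: float = 0.3) -> AnalysisMask:
    """Threshold the lesion overlap map to define the analysis region.

    A voxel enters the mask when the fraction of patients whose abnormality
    there reaches ``binarize_at`` is at least ``threshold`` (boundary
    inclusive).
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes")
    shape = np.asarray(volumes[0]).shape
    if any(np.asarray(v).shape != shape for v in volumes):
        raise ValueError("volumes must share one grid")
    overlap = np.mean([np.asarray(v) >= binarize_at for v in volumes], axis=0)
    mask = overlap >= threshold
    if not mask.any():
        raise ValueError("empty analysis mask")
    return AnalysisMask(mask, threshold, binarize_at)


def fisher_voxel_compare(group_a: list[np.ndarray], group_b: list[np.ndarray],
                         mask: AnalysisMask) -> np.ndarray:
    """Two-sided Fisher exact p per masked voxel (damaged/intact × group).

    Inputs are binary damage volumes.  Returns a full-grid p map, NaN
    outside the mask.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = volumes_to_matrix(group_a, mask.mask).astype(bool)
    b = volumes_to_matrix(group_b, mask.mask).astype(bool)
    na, nb = a.shape[0], b.shape[0]
    da, db = a.sum(axis=0), b.sum(axis=0)
    p = np.ones(da.size)
    cache: dict[tuple[int, int], float] = {}
    for v in range(da.size):
        key = (int(da[v]), int(db[v]))
        if key not in cache:
            table = [[key[0], na - key[0]], [key[1], nb - key[1]]]
            cache[key] = stats.fisher_exact(table, alternative="two-sided")[1]
        p[v] = cache[key]
    out = np.full(mask.mask.shape, np.nan)
    out[mask.mask] = p
    return out


# ---------------------------------------------------------------------------
# VBCM with permutation cluster FWE
# ---------------------------------------------------------------------------

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _glm_t(Y: np.ndarray, X: np.ndarray, col: int) -> np.ndarray:
    """t statistics for one design column across all voxel columns of Y."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = np.sum(resid**2, axis=0) / (n - p)
    xtx_inv_jj = (pinv @ pinv.T)[col, col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[col] / np.sqrt(sigma2 * xtx_inv_jj)
    return np.where(np.isfinite(t), t, 0.0)


def _clusters(stat: np.ndarray, mask: np.ndarray, thresh: float,
              sign: int) -> tuple[np.ndarray, list[dict]]:
    """Label suprathreshold clusters (face connectivity) of a signed t map."""
    grid = np.zeros(mask.shape)
    grid[mask] = stat
    supra = (sign * grid >= thresh) & mask
    labels, n_lab = ndimage.label(supra, structure=_FACE_STRUCT)
    info = []
    for lab in range(1, n_lab + 1):
        vox = labels == lab
        tvals = grid[vox]
        peak_flat = np.flatnonzero(vox.ravel())[np.argmax(sign * tvals)]
        info.append({
            "id": lab,
            "size": int(vox.sum()),
            "peak_voxel": tuple(int(c) for c in np.unravel_index(peak_flat, mask.shape)),
            "peak_t": float(tvals[np.argmax(sign * tvals)]),
        })
    return labels, info


def vbcm(volumes: list[np.ndarray], scores, covariates: np.ndarray | None = None,
         voxel_p: float = 0.001, cluster_alpha: float = 0.05,
         n_perm: int = 1000, seed: int = 0, mask: AnalysisMask | None = None,
         direction: int = -1) -> dict[str, StatMap]:
    """Voxel-based correlational mapping with permutation cluster FWE.

    Fits, at every masked voxel, a linear model of abnormality on all
    component scores entered simultaneously plus optional covariates and an
    intercept.  Per component, clusters are formed where the one-sided t
    statistic (default ``direction=-1``: more abnormality ⇔ lower score)
    exceeds the ``voxel_p`` critical value, and cluster extents are
    compared against a Freedman–Lane permutation null of the maximum
    cluster size (residuals of the reduced model — all other predictors —
    are permuted, ``n_perm`` times).

    ``scores`` is a ComponentScores object or (n × k) array; returns one
    :class:`StatMap` per component.
    """
    vals = getattr(scores, "values", scores)
    names = list(getattr(scores, "component_names",
                         [f"C{i + 1}" for i in range(np.asarray(vals).shape[1])]))
    S = np.asarray(vals, dtype=float)
    n = S.shape[0]
    if len(volumes) != n:
        raise ValueError("number of volumes does not match scores")
    C = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if C.shape[0] != n and C.size:
        C = C.T
    X = np.column_stack([np.ones(n), S, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear predictors)")
    if n <= X.shape[1] + 1:
        raise ValueError("too few patients for the design")

    if mask is None:
        mask = build_mask(volumes)
    Y = volumes_to_matrix(volumes, mask.mask)
    df = n - X.shape[1]
    t_crit = stats.t.isf(voxel_p, df)
    rng = np.random.default_rng(seed)
    out: dict[str, StatMap] = {}

    for ci, comp in enumerate(names):
        col = 1 + ci
        t_obs = _glm_t(Y, X, col)
        labels, clusters = _clusters(t_obs, mask.mask, t_crit, direction)

        # Freedman-Lane: fit reduced model (without this component),
        # permute its residuals, re-add fitted values, retest
        Xr = np.delete(X, col, axis=1)
        pr = np.linalg.pinv(Xr)
        fitted_r = Xr @ (pr @ Y)
        resid_r = Y - fitted_r
        max_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            Yb = fitted_r + resid_r[perm]
            tb = _glm_t(Yb, X, col)
            _, cl = _clusters(tb, mask.mask, t_crit, direction)
            max_null[b] = max((c["size"] for c in cl), default=0)
        for c in clusters:
            c["fwe_p"] = float((1 + np.sum(max_null >= c["size"])) / (1 + n_perm))

        tmap = np.full(mask.mask.shape, np.nan)
        tmap[mask.mask] = t_obs
        out[comp] = StatMap(tmap, comp, voxel_p, cluster_alpha, n_perm, seed,
                            clusters, labels)
    return out


def residualize(target: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of target on covariates plus an intercept."""
    y = np.asarray(target, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != y.size:
        C = C.T
    X = np.column_stack([np.ones(y.size), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# relevance vector regression
# ---------------------------------------------------------------------------


def _rvr_core(Phi: np.ndarray, y: np.ndarray, alpha_ceiling: float = 1e9,
              tol: float = 1e-6, max_iter: int = 2000,
              ) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Type-II maximum-likelihood updates for a sparse Bayesian linear model.

    Iterates the standard evidence-maximisation re-estimates
    ``alpha_i = gamma_i / mu_i²`` and ``beta = (N − Σ gamma) / ||y − Phi mu||²``.
    Convergence is declared when either the largest change in log alpha of
    the surviving weights falls below ``tol`` or the marginal log-likelihood
    stops changing (relative change below 1e-8); the latter guards against
    tiny alpha limit cycles or glacial drifts between near-equivalent
    solutions, where the evidence is flat but individual precisions keep
    moving.
    Weights whose precision exceeds ``alpha_ceiling`` are pruned (set
    exactly to zero).  Exhausting ``max_iter`` raises with diagnostics.
    """
    n, m = Phi.shape
    alpha = np.full(m, 1e-4)
    beta = 1.0 / max(np.var(y) * 0.1, 1e-8)
    active = np.ones(m, dtype=bool)
    L_old = -np.inf
    for it in range(1, max_iter + 1):
        Pa = Phi[:, active]
        H = beta * Pa.T @ Pa + np.diag(alpha[active])
        Sigma = np.linalg.inv(H)
        mu = beta * Sigma @ Pa.T @ y
        gamma = 1.0 - alpha[active] * np.diag(Sigma)
        resid = y - Pa @ mu
        rss = float(resid @ resid)
        _, logdet_h = np.linalg.slogdet(H)
        L = 0.5 * (np.sum(np.log(alpha[active])) + n * np.log(beta) - logdet_h
                   - beta * rss - mu @ (alpha[active] * mu) - n * np.log(2 * np.pi))
        with np.errstate(divide="ignore"):
            alpha_new = gamma / mu**2
        alpha_new = np.where(np.isfinite(alpha_new), alpha_new, alpha_ceiling * 10)
        beta = (n - gamma.sum()) / max(rss, 1e-12)
        old = np.log(np.clip(alpha[active], 1e-300, None))
        new = np.log(np.clip(alpha_new, 1e-300, None))
        alpha[active] = alpha_new
        keep = alpha[active] < alpha_ceiling
        still = np.flatnonzero(active)[~keep]
        active[still] = False
        if not active.any():
            return np.zeros(m), alpha, beta, it
        converged = (np.max(np.abs(new[keep] - old[keep])) < tol
                     or (np.isfinite(L_old) and abs(L - L_old) < 1e-8 * (1 + abs(L))))
        if converged:
            mu_full = np.zeros(m)
            mu_full[active] = mu[keep]
            return mu_full, alpha, beta, it
        L_old = L
    raise RuntimeError(
        f"RVR failed to converge after {max_iter} iterations "
        f"(active weights: {int(active.sum())}, beta: {beta:.3g})")


def rvr_posterior_mean(Phi: np.ndarray, y: np.ndarray, alpha: np.ndarray,
                       beta: float) -> np.ndarray:
    """Posterior mean weights at frozen hyperparameters.

    ``mu = beta (beta PhiᵀPhi + diag(alpha))⁻¹ Phiᵀ y`` — identical to the
    penalised (generalised-ridge) least-squares solution, which serves as a
    closed-form check on the iterative machinery.
    """
    A = np.diag(np.asarray(alpha, dtype=float))
    H = beta * Phi.T @ Phi + A
    return beta * np.linalg.solve(H, Phi.T @ y)


def rvr_fit(features: np.ndarray, target: np.ndarray, **kw) -> RVRFit:
    """Fit RVR on a linear kernel over patients (no cross-validation)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    mu = X.mean(axis=0)
    K = (X - mu) @ (X - mu).T
    scale = np.mean(np.abs(np.diag(K))) or 1.0
    Phi = np.column_stack([np.ones(X.shape[0]), K / scale])
    w, alpha, beta, it = _rvr_core(Phi, y, **kw)
    return RVRFit(w, alpha, beta, alpha < 1e9, np.full_like(y, np.nan),
                  np.nan, None, it)


def _loocv_predictions(X: np.ndarray, y: np.ndarray, **kw) -> np.ndarray:
    """Full-refit LOOCV predictions of an RVR with a linear patient kernel.

    Features are mean-centred using training-fold statistics only; the
    kernel scale is likewise estimated on the training fold.
    """
    n = X.shape[0]
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xt, yt = X[tr], y[tr]
        mu = Xt.mean(axis=0)
        Kt = (Xt - mu) @ (Xt - mu).T
        scale = np.mean(np.abs(np.diag(Kt))) or 1.0
        Phi = np.column_stack([np.ones(n - 1), Kt / scale])
        w, _, _, _ = _rvr_core(Phi, yt, **kw)
        k_test = (X[i] - mu) @ (Xt - mu).T / scale
        preds[i] = w[0] + k_test @ w[1:]
    return preds


def rvr_predict_loocv(features: np.ndarray, target: np.ndarray,
                      n_perm: int = 1000, seed: int = 0, **kw) -> RVRFit:
    """RVR prediction of a behavioural target from masked voxel features.

    LOOCV (full refit per fold) yields out-of-sample predictions;
    ``cv_r`` is the Pearson correlation between observed and predicted.
    Significance comes from permutation testing: the target is shuffled
    ``n_perm`` times, the complete LOOCV is rerun on each shuffle, and
    ``permutation_p = (1 + #{perm cv_r ≥ observed}) / (1 + n_perm)``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 patients")
    if np.std(y) == 0:
        raise ValueError("constant target")
    fit = rvr_fit(X, y, **kw)
    preds = _loocv_predictions(X, y, **kw)
    if np.std(preds) == 0:
        cv_r = 0.0
    else:
        cv_r = float(np.corrcoef(y, preds)[0, 1])

    perm_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(y.size)]
            pp = _loocv_predictions(X, yp, **kw)
            r = 0.0 if np.std(pp) == 0 else np.corrcoef(yp, pp)[0, 1]
            if r >= cv_r:
                count += 1
        perm_p = (1 + count) / (1 + n_perm)

    return RVRFit(fit.weights, fit.alpha, fit.beta, fit.relevance,
                  preds, cv_r, perm_p, fit.n_iter)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def save_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    import nibabel as nib
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    import nibabel as nib
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
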