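"""Latent-dimension analysis of assessment-battery score matrices.

The central object is a patients × tests matrix of percent-correct scores.
Deficits in the population are assumed to vary gradedly along a small number
of orthogonal latent dimensions (e.g. phonology, semantics, executive skill,
speech quanta in post-stroke aphasia), so the analysis pipeline is:

1. scale every test to percent and z-standardise per test;
2. choose the number of principal components by k-fold cross-validated
   reconstruction error (element-wise deletion scheme, see
   :func:`crossval_component_count`);
3. fit a varimax-rotated PCA at the selected dimensionality;
4. obtain per-patient component scores by the regression method;
5. quantify generalisability by leave-one-out reconstruction correlation.

All randomness is routed through explicit integer seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreMatrix",
    "ZMatrix",
    "CVCurve",
    "FactorModel",
    "ComponentScores",
    "standardize",
    "impute_test_means",
    "varimax",
    "fit_rotated_pca",
    "component_scores",
    "crossval_component_count",
    "loo_generalizability",
    "match_components",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ScoreMatrix:
    """Patients × tests percent-correct scores (0–100), NaN = missing."""

    values: np.ndarray
    patient_ids: list[str]
    test_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.test_names = [str(t) for t in self.test_names]
        n, m = self.values.shape
        if n != len(self.patient_ids) or m != len(self.test_names):
            raise ValueError("values shape does not match id/name lengths")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        if len(set(self.test_names)) != m:
            raise ValueError("duplicate test names")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.values < 0) | (self.values > 100))
        if bad:
            raise ValueError(f"{int(bad)} scores outside [0, 100]")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_tests(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.test_names,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))

    def write_csv(self, path) -> None:
        # %.17g round-trips doubles exactly
        self.to_frame().to_csv(path, na_rep="NA", float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "ScoreMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"],
                         float_precision="round_trip")
        return cls.from_frame(df)


@dataclass
class ZMatrix:
    """Per-test z-scores with the reference statistics used to compute them."""

    values: np.ndarray
    patient_ids: list[str]
    test_names: list[str]
    reference_means: np.ndarray
    reference_sds: np.ndarray


@dataclass
class CVCurve:
    """Reconstruction RMSE (z-units) as a function of component count."""

    rmse_by_k: dict[int, float]
    folds: int
    k_selected: int


@dataclass
class FactorModel:
    """Varimax-rotated PCA solution.

    ``loadings`` are test–component correlations (tests × k), ``rotation``
    the orthogonal k × k matrix mapping unrotated to rotated loadings,
    ``variance_explained`` the per-component percent of total test variance
    after rotation, and ``scoring_coefficients`` the regression-method
    weights such that ``scores = Z @ scoring_coefficients``.
    """

    loadings: np.ndarray
    rotation: np.ndarray
    variance_explained: np.ndarray
    scoring_coefficients: np.ndarray
    test_names: list[str]
    component_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.component_names:
            self.component_names = [f"C{i + 1}" for i in range(self.loadings.shape[1])]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings**2, axis=1)

    def loading_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.test_names,
                            columns=self.component_names)


@dataclass
class ComponentScores:
    """Per-patient positions on the latent components (z-like units)."""

    values: np.ndarray
    patient_ids: list[str]
    component_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.component_names,
        )


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------


def standardize(scores: ScoreMatrix, reference: tuple[np.ndarray, np.ndarray] | None = None) -> ZMatrix:
    """z-standardise each test column (sample sd, n−1 denominator).

    ``reference`` supplies (means, sds) from a training sample so held-out
    patients can be placed on the training scale; by default the matrix is
    self-referenced.  A zero-variance test is an error because its z-scores
    are undefined.
    """
    x = scores.values
    if reference is None:
        means = np.nanmean(x, axis=0)
        sds = np.nanstd(x, axis=0, ddof=1)
    else:
        means, sds = (np.asarray(a, dtype=float) for a in reference)
    bad = np.flatnonzero(~(sds > 0))
    if bad.size:
        names = ", ".join(scores.test_names[j] for j in bad)
        raise ValueError(f"zero-variance test(s), cannot standardise: {names}")
    z = (x - means) / sds
    return ZMatrix(z, list(scores.patient_ids), list(scores.test_names), means, sds)


def impute_test_means(z: np.ndarray) -> np.ndarray:
    """Replace missing cells by their column mean (0 for an all-missing column)."""
    out = np.array(z, dtype=float)
    col_means = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    idx = np.where(np.isnan(out))
    out[idx] = col_means[idx[1]]
    return out


# ---------------------------------------------------------------------------
# varimax rotation
# ---------------------------------------------------------------------------


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-8,
            max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation of a loading matrix.

    Maximises the varimax criterion (variance of squared loadings within
    each column) with Kaiser row normalisation: rows are scaled to unit
    communality before rotation and rescaled afterwards, which stops
    high-communality tests from dominating the criterion.  Uses the
    classical pairwise planar-rotation algorithm with the closed-form
    optimal angle per factor pair (quartic trigonometric identity), swept
    until the criterion stops increasing.  Unlike the SVD fixed-point
    iteration, the pairwise sweep cannot stall in period-2 cycles on
    perfectly patterned loadings.

    Returns ``(rotated_loadings, rotation)`` with
    ``rotated = loadings @ rotation`` and ``rotation`` orthogonal.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1)
    if kaiser:
        h = np.sqrt(np.sum(L**2, axis=1))
        h = np.where(h > 0, h, 1.0)
        B = L / h[:, None]
    else:
        B = L.copy()
    R = np.eye(k)

    def crit(M: np.ndarray) -> float:
        sq = M**2
        return float(np.sum(sq**2) - np.sum(np.sum(sq, axis=0) ** 2) / p)

    c_old = crit(B)
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = B[:, i], B[:, j]
                u = x**2 - y**2
                v = 2 * x * y
                su, sv = u.sum(), v.sum()
                num = 2 * (u @ v) - 2 * su * sv / p
                den = (u @ u) - (v @ v) - (su**2 - sv**2) / p
                phi = 0.25 * np.arctan2(num, den)
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                B[:, [i, j]] = B[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        c_new = crit(B)
        if c_new - c_old <= tol * (1 + abs(c_old)):
            break
        c_old = c_new
    return loadings @ R, R


def varimax_criterion(loadings: np.ndarray, kaiser: bool = True) -> float:
    """Value of the (row-normalised) varimax objective for a loading matrix."""
    L = np.asarray(loadings, dtype=float)
    if kaiser:
        h = np.sqrt(np.sum(L**2, axis=1))
        h = np.where(h > 0, h, 1.0)
        L = L / h[:, None]
    p = L.shape[0]
    sq = L**2
    return float(np.sum(sq**2) - np.sum(np.sum(sq, axis=0) ** 2) / p)


# ---------------------------------------------------------------------------
# PCA fitting and scoring
# ---------------------------------------------------------------------------


def _pca_loadings(z: np.ndarray, k: int) -> np.ndarray:
    """Correlation-scaled loadings of the first k principal components."""
    n = z.shape[0]
    zc = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    eig = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    return vt[:k].T * np.sqrt(eig[:k])


def fit_rotated_pca(z: ZMatrix, k: int) -> FactorModel:
    """Varimax-rotated PCA of a complete z-matrix.

    Components are ordered by descending post-rotation variance explained;
    each component's sign is fixed so its largest-magnitude loading is
    positive.  Scoring coefficients use the regression method,
    ``W = R⁻¹ L`` with R the observed correlation matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(z.values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("z-matrix contains missing values; impute first")
    n_tests = x.shape[1]
    L0 = _pca_loadings(x, k)
    L, R = varimax(L0)

    # order by rotated variance explained, dominant loading positive
    var_expl = np.sum(L**2, axis=0) / n_tests * 100.0
    order = np.argsort(-var_expl)
    L, R, var_expl = L[:, order], R[:, order], var_expl[order]
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(k)])
    signs = np.where(signs == 0, 1.0, signs)
    L, R = L * signs, R * signs

    corr = np.corrcoef(x, rowvar=False)
    W = np.linalg.pinv(corr) @ L
    return FactorModel(L, R, var_expl, W, list(z.test_names))


def component_scores(model: FactorModel, z: ZMatrix) -> ComponentScores:
    """Regression-method factor scores, ``Z @ scoring_coefficients``."""
    if list(z.test_names) != list(model.test_names):
        raise ValueError("test names of z-matrix do not match the model")
    vals = np.asarray(z.values, dtype=float) @ model.scoring_coefficients
    return ComponentScores(vals, list(z.patient_ids), list(model.component_names))


# ---------------------------------------------------------------------------
# cross-validation of the component count
# ---------------------------------------------------------------------------


def _reconstruct_elementwise(z_test: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Element-wise reconstruction of held-out rows from a PCA basis.

    For every test j, entry j of each held-out row is predicted by
    least-squares projection of the remaining entries onto the training
    basis with row j deleted.  This avoids the information leak of naive
    row projection (where the entry predicts itself).

    ``basis`` is tests × k with orthonormal-in-test-space columns.
    """
    n, m = z_test.shape
    pred = np.empty_like(z_test)
    for j in range(m):
        keep = np.delete(np.arange(m), j)
        Bj = basis[keep]                     # (m-1) × k
        coef, *_ = np.linalg.lstsq(Bj, z_test[:, keep].T, rcond=None)
        pred[:, j] = basis[j] @ coef
    return pred


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def crossval_component_count(scores: ScoreMatrix, folds: int = 5,
                             k_max: int | None = None, seed: int = 0) -> CVCurve:
    """Select the PCA dimensionality by k-fold cross-validated RMSE.

    Patients are partitioned into ``folds`` folds.  For each candidate k a
    PCA is fit on the training patients (standardised by training means and
    sds); each held-out patient row is reconstructed element-wise and the
    squared errors pooled over folds into one RMSE per k.  The selected k
    minimises RMSE, with ties broken toward the smaller k (parsimony).
    """
    n, m = scores.values.shape
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < folds:
        raise ValueError("more folds than patients")
    if k_max is None:
        k_max = m
    if k_max < 1 or k_max > m:
        raise ValueError("k_max must be in [1, n_tests]")

    rng = np.random.default_rng(seed)
    fold_idx = _fold_indices(n, folds, rng)
    sse = {k: 0.0 for k in range(1, k_max + 1)}
    n_cells = {k: 0 for k in range(1, k_max + 1)}

    for test_rows in fold_idx:
        train_rows = np.setdiff1d(np.arange(n), test_rows)
        train = ScoreMatrix(scores.values[train_rows],
                            [scores.patient_ids[i] for i in train_rows],
                            scores.test_names)
        z_train = standardize(train)
        zt = impute_test_means(z_train.values)
        z_test = (scores.values[test_rows] - z_train.reference_means) / z_train.reference_sds
        z_test = impute_test_means(z_test)

        zc = zt - zt.mean(axis=0)
        _, s, vt = np.linalg.svd(zc, full_matrices=False)
        max_rank = int(np.sum(s > s[0] * 1e-10))
        for k in range(1, k_max + 1):
            basis = vt[: min(k, max_rank)].T
            pred = _reconstruct_elementwise(z_test, basis)
            sse[k] += float(np.sum((z_test - pred) ** 2))
            n_cells[k] += z_test.size

    rmse = {k: np.sqrt(sse[k] / n_cells[k]) for k in sse}
    best = min(rmse, key=lambda k: (rmse[k], k))
    return CVCurve(rmse, folds, best)


def loo_generalizability(scores: ScoreMatrix, k: int) -> float:
    """Leave-one-out generalisability of a k-component solution.

    Each patient in turn is held out; the PCA basis is refit on the rest,
    the held-out row is reconstructed element-wise, and all (observed,
    predicted) z-score cells are pooled into a single Pearson correlation.
    """
    n = scores.n_patients
    if n < 3:
        raise ValueError("need at least 3 patients")
    obs_all, pred_all = [], []
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        train = ScoreMatrix(scores.values[rest],
                            [scores.patient_ids[j] for j in rest],
                            scores.test_names)
        z_train = standardize(train)
        zt = impute_test_means(z_train.values)
        zc = zt - zt.mean(axis=0)
        _, s, vt = np.linalg.svd(zc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10))
        basis = vt[: min(k, rank)].T
        z_row = (scores.values[i] - z_train.reference_means) / z_train.reference_sds
        z_row = impute_test_means(z_row[None, :])
        pred = _reconstruct_elementwise(z_row, basis)
        obs_all.append(z_row.ravel())
        pred_all.append(pred.ravel())
    obs = np.concatenate(obs_all)
    pred = np.concatenate(pred_all)
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("constant pooled vector, correlation undefined")
    return float(np.corrcoef(obs, pred)[0, 1])


# ---------------------------------------------------------------------------
# component matching across batteries
# ---------------------------------------------------------------------------


def match_components(a: ComponentScores, b: ComponentScores
                     ) -> tuple[list[tuple[str, str, float]], pd.DataFrame]:
    """Match components of two solutions on shared patients.

    Computes all pairwise Pearson correlations between the component-score
    columns of ``a`` and ``b`` (restricted to common patients) and pairs
    them greedily by descending |r|, one-to-one.  Returns the matching as
    ``(name_a, name_b, r)`` triples (signed r) plus the full correlation
    matrix (a-components × b-components).
    """
    common = [p for p in a.patient_ids if p in set(b.patient_ids)]
    if not common:
        raise ValueError("no common patients")
    ai = [a.patient_ids.index(p) for p in common]
    bi = [b.patient_ids.index(p) for p in common]
    av, bv = a.values[ai], b.values[bi]
    ka, kb = av.shape[1], bv.shape[1]
    corr = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            corr[i, j] = np.corrcoef(av[:, i], bv[:, j])[0, 1]
    cm = pd.DataFrame(corr, index=a.component_names, columns=b.component_names)

    matching: list[tuple[str, str, float]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    flat = sorted(((abs(corr[i, j]), i, j) for i in range(ka) for j in range(kb)),
                  reverse=True)
    for _, i, j in flat:
        if i in used_a or j in used_b:
            continue
        matching.append((a.component_names[i], b.component_names[j], float(corr[i, j])))
        used_a.add(i)
        used_b.add(j)
        if len(matching) == min(ka, kb):
            break
    return matching, cm
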