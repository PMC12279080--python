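"""Positive-unlabeled classification under covariate shift (PUc).

The learning problem: the observed cell population is a mixture
``p(x) = alpha * p_plus(x) + (1 - alpha) * p_minus(x)`` of healthy (positive)
and senescent (negative) cells. Only positives are labeled (young donors);
the unlabeled training sample comes from middle-aged donors and the unlabeled
test sample from aged donors, whose *healthy* cells are themselves shifted by
aging programs unrelated to senescence — a covariate shift
(``p_train(x) != p_test(x)`` while ``p(y|x)`` is shared).

The classifier minimizes the importance-weighted unbiased PU risk

    R(g) = alpha * E_{x~p+_train}[ l~(g(x)) w(x) ] + E_{x~p_train}[ l(-g(x)) w(x) ]

where ``w(x) = p_test(x) / p_train(x)`` is the density ratio,
``l`` is a margin loss and ``l~(z) := l(z) - l(-z)``. For any loss with
``l(z) - l(-z) = -z`` (squared and double-hinge both qualify) the composite
term is linear, and with the squared loss the minimizer over a
linear-in-parameter Gaussian-kernel model has a closed ridge form.

The density ratio is estimated by unconstrained least-squares importance
fitting (uLSIF): a Gaussian-kernel expansion whose coefficients minimize the
least-squares distance to the true ratio, with closed-form solution and
k-fold cross-validation of the same criterion for bandwidth/ridge selection.

Conventions: the decision is ``sign(g(x))`` with ``+1`` = healthy and ``-1``
= senescent; ties (g == 0) go to the positive class.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "PCAProjection",
    "DensityRatioModel",
    "PUcModel",
    "fit_pca",
    "estimate_density_ratio",
    "fit_puc",
    "classify",
    "puc_risk",
    "median_bandwidth",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Kernel helpers

def _sq_dists(X, C):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    d2 = (X * X).sum(1)[:, None] + (C * C).sum(1)[None, :] - 2.0 * X @ C.T
    return np.maximum(d2, 0.0)


def gaussian_kernel(X, centers, bandwidth: float) -> np.ndarray:
    """Gaussian kernel matrix K[i, l] = exp(-||x_i - c_l||^2 / (2 s^2))."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return np.exp(-_sq_dists(X, centers) / (2.0 * bandwidth**2))


def median_bandwidth(X, max_points: int = 500, rng=None) -> float:
    """Median pairwise Euclidean distance heuristic (subsampled for speed)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] > max_points:
        rng = rng or np.random.default_rng(0)
        X = X[rng.choice(X.shape[0], size=max_points, replace=False)]
    d2 = _sq_dists(X, X)
    iu = np.triu_indices_from(d2, k=1)
    med = float(np.median(np.sqrt(d2[iu])))
    if not np.isfinite(med) or med <= 0:
        raise ValueError("degenerate input: median pairwise distance is zero")
    return med


# ---------------------------------------------------------------------------
# PCA projection

@dataclass
class PCAProjection:
    """Per-cell-type PCA restricted to a gene subset (centered, unscaled)."""

    genes: list[str]
    mean_: np.ndarray
    components_: np.ndarray  # (n_components, n_genes)
    explained_variance_ratio_: np.ndarray
    n_components: int

    def _matrix(self, expr):
        if hasattr(expr, "var_names"):  # AnnData
            X = expr[:, self.genes].X
        else:
            X = expr
        from scipy import sparse
        X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)
        if X.shape[1] != len(self.genes):
            raise ValueError(f"expected {len(self.genes)} genes, got {X.shape[1]} columns")
        return X

    def transform(self, expr) -> np.ndarray:
        X = self._matrix(expr)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores) -> np.ndarray:
        return np.asarray(scores) @ self.components_ + self.mean_


def fit_pca(expr, genes=None, n_components: int = 10) -> PCAProjection:
    """Fit a centered, unscaled PCA on the pooled cells of one cell type.

    ``expr`` is an AnnData (``genes`` selects columns by symbol) or a dense
    matrix. Inputs are assumed log-normalized. Raises if there are fewer
    than ``n_components + 1`` cells.
    """
    if hasattr(expr, "var_names"):
        genes = list(genes) if genes is not None else list(expr.var_names)
        missing = set(genes) - set(expr.var_names)
        if missing:
            raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}...")
        X = expr[:, genes].X
    else:
        X = expr
        genes = list(genes) if genes is not None else [f"g{i}" for i in range(np.shape(X)[1])]
    from scipy import sparse
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} cells, got {X.shape[0]}")
    k = min(n_components, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    return PCAProjection(genes=genes, mean_=pca.mean_, components_=pca.components_,
                         explained_variance_ratio_=pca.explained_variance_ratio_,
                         n_components=k)


# ---------------------------------------------------------------------------
# Density-ratio estimation (uLSIF)

@dataclass
class DensityRatioModel:
    """Gaussian-kernel density-ratio model w(x) ~= p_test(x) / p_train(x).

    Coefficients are clipped at zero, so predicted weights are nonnegative.
    If ``normalization`` is set, predictions are rescaled so the mean weight
    over the training sample is one.
    """

    centers: np.ndarray
    bandwidth: float
    coefficients: np.ndarray
    normalization: float = 1.0
    cv_score: float = float("nan")

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.centers.shape[1]:
            raise ValueError(f"dimension mismatch: model has {self.centers.shape[1]} features, "
                             f"input has {X.shape[1]}")
        w = gaussian_kernel(X, self.centers, self.bandwidth) @ self.coefficients
        return np.maximum(w, 0.0) / self.normalization


def _ulsif_solve(K_tr, k_te_mean, ridge):
    H = K_tr.T @ K_tr / K_tr.shape[0]
    theta = np.linalg.solve(H + ridge * np.eye(H.shape[0]), k_te_mean)
    return np.maximum(theta, 0.0)


def estimate_density_ratio(train_points, test_points, n_centers: int = 100,
                           bandwidth: float | None = None,
                           sigma_scales=(0.5, 1.0, 2.0),
                           ridge_grid=(1e-3, 1e-2, 1e-1),
                           n_folds: int = 5, normalize: bool = True,
                           seed: int = 0) -> DensityRatioModel:
    """Fit a uLSIF density-ratio model w(x) = p_test(x) / p_train(x).

    Kernel centers are sampled from the test sample (at most ``n_centers``).
    Bandwidth and ridge are chosen by k-fold cross-validation of the uLSIF
    squared-error criterion J = 0.5 * E_train[w^2] - E_test[w] (lower is
    better; minimized by the true ratio).
    """
    Xtr = np.atleast_2d(np.asarray(train_points, dtype=float))
    Xte = np.atleast_2d(np.asarray(test_points, dtype=float))
    if Xtr.size == 0 or Xte.size == 0:
        raise ValueError("train and test samples must be nonempty")
    if Xtr.shape[1] != Xte.shape[1]:
        raise ValueError("train and test samples must have the same dimensionality")
    pooled = np.vstack([Xtr, Xte])
    if np.any(pooled.std(axis=0) == 0) and np.all(pooled.std(axis=0) == 0):
        raise ValueError("degenerate input: zero variance in all dimensions")
    rng = np.random.default_rng(seed)
    idx = rng.choice(Xte.shape[0], size=min(n_centers, Xte.shape[0]), replace=False)
    centers = Xte[idx]
    sigma0 = bandwidth if bandwidth is not None else median_bandwidth(pooled, rng=rng)
    sigmas = [sigma0] if bandwidth is not None else [s * sigma0 for s in sigma_scales]

    folds_tr = np.resize(np.arange(n_folds), Xtr.shape[0])
    folds_te = np.resize(np.arange(n_folds), Xte.shape[0])
    rng.shuffle(folds_tr)
    rng.shuffle(folds_te)

    best = (np.inf, sigmas[0], ridge_grid[0])
    for sigma in sigmas:
        K_tr = gaussian_kernel(Xtr, centers, sigma)
        K_te = gaussian_kernel(Xte, centers, sigma)
        for ridge in ridge_grid:
            score = 0.0
            for f in range(n_folds):
                fit_tr, val_tr = folds_tr != f, folds_tr == f
                fit_te, val_te = folds_te != f, folds_te == f
                theta = _ulsif_solve(K_tr[fit_tr], K_te[fit_te].mean(axis=0), ridge)
                w_tr = K_tr[val_tr] @ theta
                w_te = K_te[val_te] @ theta
                score += 0.5 * np.mean(w_tr**2) - np.mean(w_te)
            if score < best[0]:
                best = (score, sigma, ridge)
    _, sigma, ridge = best
    K_tr = gaussian_kernel(Xtr, centers, sigma)
    K_te = gaussian_kernel(Xte, centers, sigma)
    theta = _ulsif_solve(K_tr, K_te.mean(axis=0), ridge)
    model = DensityRatioModel(centers=centers, bandwidth=sigma, coefficients=theta,
                              cv_score=float(best[0]))
    if normalize:
        mean_w = float(np.mean(model.predict(Xtr)))
        if mean_w <= 0:
            raise ValueError("density-ratio fit collapsed to zero weights")
        model.normalization = mean_w
    return model


# ---------------------------------------------------------------------------
# PUc risk and classifier

def _loss(z, loss: str):
    z = np.asarray(z, dtype=float)
    if loss == "squared":
        return (1.0 - z) ** 2 / 4.0
    if loss == "double_hinge":
        return np.maximum(-z, np.maximum(0.0, 0.5 - 0.5 * z))
    raise ValueError(f"unknown loss {loss!r}")


def puc_risk(g_pos, g_unl, w_pos, w_unl, alpha: float, loss: str = "squared") -> float:
    """Empirical importance-weighted unbiased PU risk of a fixed decision function.

    ``g_pos``/``g_unl`` are the decision values at positive and unlabeled
    *training* points, ``w_pos``/``w_unl`` the density-ratio weights there.
    Both supported losses satisfy ``l(z) - l(-z) = -z``, so the composite
    positive-class term is ``-g * w``.
    """
    g_pos = np.asarray(g_pos, dtype=float)
    g_unl = np.asarray(g_unl, dtype=float)
    w_pos = np.broadcast_to(np.asarray(w_pos, dtype=float), g_pos.shape)
    w_unl = np.broadcast_to(np.asarray(w_unl, dtype=float), g_unl.shape)
    term_pos = alpha * float(np.mean(-g_pos * w_pos))
    term_unl = float(np.mean(_loss(-g_unl, loss) * w_unl))
    return term_pos + term_unl


@dataclass
class PUcModel:
    """Linear-in-parameter Gaussian-kernel PU classifier under covariate shift."""

    centers: np.ndarray
    bandwidth: float
    coef: np.ndarray       # kernel coefficients plus trailing intercept
    alpha: float
    loss: str = "squared"
    density_ratio: DensityRatioModel | None = None
    risk_: float = float("nan")
    ridge_: float = float("nan")
    seed: int = 0
    diagnostics: dict = field(default_factory=dict)

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.centers.shape[1]:
            raise ValueError(f"dimension mismatch: model has {self.centers.shape[1]} features, "
                             f"input has {X.shape[1]}")
        K = gaussian_kernel(X, self.centers, self.bandwidth)
        return K @ self.coef[:-1] + self.coef[-1]

    def predict(self, X) -> np.ndarray:
        return classify(self, X)


def _design(X, centers, sigma):
    K = gaussian_kernel(X, centers, sigma)
    return np.hstack([K, np.ones((K.shape[0], 1))])


def _fit_theta(Phi_P, Phi_U, w_P, w_U, alpha, ridge, loss):
    m = Phi_P.shape[1]
    if loss == "squared":
        A = Phi_U.T @ (w_U[:, None] * Phi_U) / (2.0 * Phi_U.shape[0]) + 2.0 * ridge * np.eye(m)
        b = alpha * Phi_P.T @ w_P / Phi_P.shape[0] - Phi_U.T @ w_U / (2.0 * Phi_U.shape[0])
        for bump in range(6):
            try:
                theta = np.linalg.solve(A, b)
                if np.all(np.isfinite(theta)):
                    return theta
            except np.linalg.LinAlgError:
                pass
            warnings.warn("singular PUc system; increasing ridge regularization")
            A += (10.0 ** (bump + 1)) * ridge * np.eye(m)
        raise np.linalg.LinAlgError("PUc ridge system could not be solved")
    # double hinge: convex, solved iteratively
    def objective(theta):
        g_P = Phi_P @ theta
        g_U = Phi_U @ theta
        r = (alpha * np.mean(-g_P * w_P) + np.mean(_loss(-g_U, "double_hinge") * w_U)
             + ridge * theta @ theta)
        return r
    res = optimize.minimize(objective, np.zeros(m), method="L-BFGS-B")
    return res.x


def fit_puc(positives, unlabeled_train, unlabeled_test, alpha: float = 0.9, *,
            n_centers: int = 200, bandwidth: float | None = None,
            ridge_grid=(1e-3,), loss: str = "squared",
            importance: str = "ulsif", center_source: str = "unlabeled_train",
            dr_options: dict | None = None, seed: int = 0) -> PUcModel:
    """Fit the PUc classifier by minimizing the importance-weighted PU risk.

    Parameters
    ----------
    positives, unlabeled_train, unlabeled_test
        Feature matrices (e.g. PCA scores): labeled healthy cells from the
        young group, unlabeled cells from the middle group, unlabeled cells
        from the aged group. The density ratio is estimated between
        ``unlabeled_train`` (numerator: test) and evaluated at both training
        samples.
    alpha
        Mixture proportion: assumed fraction of the unlabeled population
        that is healthy; must lie in (0, 1].
    importance
        ``"ulsif"`` (estimate w by uLSIF) or ``"uniform"`` (force w == 1,
        i.e. plain unweighted PU learning).
    center_source
        Where the classifier's kernel centers are sampled from:
        ``"unlabeled_train"``, ``"unlabeled_test"`` or ``"both"``.

    The ridge penalty defaults to a single fixed value; passing several
    values in ``ridge_grid`` selects one by 2-fold cross-validation of the
    held-out empirical PUc risk.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    X_P = np.atleast_2d(np.asarray(positives, dtype=float))
    X_U = np.atleast_2d(np.asarray(unlabeled_train, dtype=float))
    X_T = np.atleast_2d(np.asarray(unlabeled_test, dtype=float))
    if min(X_P.shape[0], X_U.shape[0], X_T.shape[0]) == 0:
        raise ValueError("all three samples must be nonempty")
    if not (X_P.shape[1] == X_U.shape[1] == X_T.shape[1]):
        raise ValueError("samples must share dimensionality")
    rng = np.random.default_rng(seed)

    dr = None
    if importance == "ulsif":
        dr = estimate_density_ratio(X_U, X_T, seed=int(rng.integers(2**31)),
                                    **(dr_options or {}))
        w_U = dr.predict(X_U)
        w_P = dr.predict(X_P)
    elif importance == "uniform":
        w_U = np.ones(X_U.shape[0])
        w_P = np.ones(X_P.shape[0])
    else:
        raise ValueError(f"unknown importance mode {importance!r}")

    pool = {"unlabeled_train": X_U, "unlabeled_test": X_T,
            "both": np.vstack([X_U, X_T])}.get(center_source)
    if pool is None:
        raise ValueError(f"unknown center_source {center_source!r}")
    idx = rng.choice(pool.shape[0], size=min(n_centers, pool.shape[0]), replace=False)
    centers = pool[idx]
    sigma = bandwidth if bandwidth is not None else median_bandwidth(np.vstack([X_P, X_U]), rng=rng)

    Phi_P = _design(X_P, centers, sigma)
    Phi_U = _design(X_U, centers, sigma)

    ridge_grid = list(ridge_grid)
    best_ridge = ridge_grid[0]
    if len(ridge_grid) > 1:
        half_P = rng.permutation(X_P.shape[0]) % 2 == 0
        half_U = rng.permutation(X_U.shape[0]) % 2 == 0
        best_score = np.inf
        for ridge in ridge_grid:
            score = 0.0
            for fit_P, fit_U in ((half_P, half_U), (~half_P, ~half_U)):
                theta = _fit_theta(Phi_P[fit_P], Phi_U[fit_U], w_P[fit_P], w_U[fit_U],
                                   alpha, ridge, loss)
                score += puc_risk(Phi_P[~fit_P] @ theta, Phi_U[~fit_U] @ theta,
                                  w_P[~fit_P], w_U[~fit_U], alpha, loss)
            if score < best_score:
                best_score, best_ridge = score, ridge

    theta = _fit_theta(Phi_P, Phi_U, w_P, w_U, alpha, best_ridge, loss)
    risk = puc_risk(Phi_P @ theta, Phi_U @ theta, w_P, w_U, alpha, loss)
    return PUcModel(centers=centers, bandwidth=sigma, coef=theta, alpha=alpha,
                    loss=loss, density_ratio=dr, risk_=risk, ridge_=best_ridge,
                    seed=seed,
                    diagnostics={"mean_w_unlabeled": float(np.mean(w_U)),
                                 "mean_w_positive": float(np.mean(w_P))})


def classify(model: PUcModel, points) -> np.ndarray:
    """Label points: -1 (senescent) where g(x) < 0, else +1 (healthy)."""
    g = model.decision_function(points)
    return np.where(g < 0, -1, 1).astype(int)


# ---------------------------------------------------------------------------
# Persistence: JSON metadata + array payload in one .npz file

def save_model(model: PUcModel, path) -> None:
    meta = {"alpha": model.alpha, "loss": model.loss, "bandwidth": model.bandwidth,
            "risk": model.risk_, "ridge": model.ridge_, "seed": model.seed,
            "has_dr": model.density_ratio is not None}
    arrays = {"centers": model.centers, "coef": model.coef,
              "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if model.density_ratio is not None:
        dr = model.density_ratio
        arrays.update(dr_centers=dr.centers, dr_coef=dr.coefficients,
                      dr_params=np.array([dr.bandwidth, dr.normalization]))
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> PUcModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        dr = None
        if meta["has_dr"]:
            dr = DensityRatioModel(centers=z["dr_centers"], bandwidth=float(z["dr_params"][0]),
                                   coefficients=z["dr_coef"],
                                   normalization=float(z["dr_params"][1]))
        return PUcModel(centers=z["centers"], bandwidth=float(meta["bandwidth"]),
                        coef=z["coef"], alpha=float(meta["alpha"]), loss=meta["loss"],
                        density_ratio=dr, risk_=float(meta["risk"]),
                        ridge_=float(meta["ridge"]), seed=int(meta["seed"]))
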