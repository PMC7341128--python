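"""Genomic prediction models: RR-BLUP, GBLUP heritability, PC-only regression.

The core model is random regression BLUP (RR-BLUP),

    y_i = beta_0 + sum_j beta_j x_ij + eps_i,
    beta_j ~ N(0, sigma_beta^2),   eps_i ~ N(0, sigma_E^2),

with markers coded -1/0/1 (homozygote / heterozygote / homozygote).  The
variance components are estimated by REML.  Because the number of markers p
typically exceeds the number of individuals n, the restricted likelihood is
profiled through the n x n kernel K = X X^T: with the intercept projected
out and K's eigenvectors orthogonal to 1 denoted U (eigenvalues theta_i),
the rotated data eta = U^T y are independent with variance
sigma_beta^2 (theta_i + lambda), lambda = sigma_E^2 / sigma_beta^2.  REML
then reduces to a one-dimensional search over log lambda (coarse grid on
[-10, 10] followed by bounded local refinement), and marker BLUPs follow as

    beta_hat = X^T (K + lambda I)^{-1} (y - 1 beta0_hat),

with beta0_hat the GLS intercept at lambda_hat.  The same machinery with K
replaced by a genomic relationship matrix A gives GBLUP and the
narrow-sense heritability estimate sigma_u^2 / (sigma_u^2 + sigma_e^2).

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
compose with sklearn model selection; the module-level functions
(:func:`rrblup_fit`, :func:`pca_fit_predict`, ...) are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .popsim import GenotypeMatrix

__all__ = [
    "RRBLUP",
    "PCRegression",
    "RRBLUPFit",
    "KinshipMatrix",
    "code_markers",
    "rrblup_fit",
    "predict_gebv",
    "sum_gebv",
    "pca_fit_predict",
    "kinship",
    "narrow_h2",
]


def code_markers(genotypes: GenotypeMatrix | np.ndarray, coding: str | None = None) -> np.ndarray:
    """Map dosages onto the [-1, 1] marker code used by RR-BLUP.

    discrete {0,1,2} maps to dosage - 1; posterior-mean dosages in [0,1]
    map to 2*dosage - 1, so the heterozygote (dosage 1, resp. 0.5) codes 0.
    """
    if isinstance(genotypes, GenotypeMatrix):
        values, coding = genotypes.values, genotypes.coding
    else:
        values = np.asarray(genotypes, dtype=float)
        if coding is None:
            raise ValueError("coding must be given for a bare array")
    if coding == "discrete_012":
        return values - 1.0
    if coding == "dosage_01":
        return 2.0 * values - 1.0
    raise ValueError(f"unknown coding {coding!r}")


# ---------------------------------------------------------------------------
# REML core (shared by RR-BLUP and GBLUP heritability)
# ---------------------------------------------------------------------------

def _reml_lambda(y: np.ndarray, K: np.ndarray, log_lambda_bounds=(-10.0, 10.0),
                 n_grid: int = 41, rel_tol: float = 1e-8):
    """Profile REML over lambda for y = 1 mu + u + e, u ~ N(0, sigma^2 K).

    Returns (lambda_hat, sigma_hat^2 [variance of u-scale component],
    restricted log-likelihood at the optimum, eigenvalues theta, eta).
    """
    n = len(y)
    # restrict K to the orthocomplement of the intercept via an explicit
    # Householder basis: with a rank-deficient K the zero eigenspace of the
    # projected kernel is degenerate and eigenvector pruning is not safe
    u = np.ones(n) / np.sqrt(n)
    v = u - np.eye(n)[0]
    H = np.eye(n) - 2.0 * np.outer(v, v) / (v @ v)   # H e1 = u, H symmetric
    Q = H[:, 1:]                                      # orthonormal basis ⊥ 1
    theta, U = eigh(Q.T @ K @ Q)
    theta = np.clip(theta, 0.0, None)
    eta = U.T @ (Q.T @ y)
    m = n - 1

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = theta + lam
        sigma2 = float(np.sum(eta**2 / denom)) / m
        return float(np.sum(np.log(denom)) + m * np.log(max(sigma2, 1e-300)))

    lo, hi = log_lambda_bounds
    grid = np.linspace(lo, hi, n_grid)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(a, b), method="bounded",
        options={"xatol": rel_tol},
    )
    log_lam = float(res.x) if res.fun <= vals[i] else float(grid[i])
    lam = float(np.exp(log_lam))
    denom = theta + lam
    sigma2 = float(np.sum(eta**2 / denom)) / m
    ll = -0.5 * (
        float(np.sum(np.log(denom))) + m * np.log(max(sigma2, 1e-300)) + m * (1.0 + np.log(2.0 * np.pi))
    )
    return lam, sigma2, ll


def _gls_intercept(y: np.ndarray, K: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """GLS intercept at fixed lambda; also returns Vinv @ (y - 1 b0)."""
    n = len(y)
    V = K + lam * np.eye(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    b0 = float(np.ones(n) @ Vinv_y) / float(np.ones(n) @ Vinv_1)
    return b0, Vinv_y - b0 * Vinv_1


class RRBLUP(RegressorMixin, BaseEstimator):
    """Ridge-regression BLUP of marker effects with REML variance components.

    Parameters
    ----------
    lmbda : float, optional
        Fixed ridge ratio sigma_E^2 / sigma_beta^2.  When None (default)
        lambda is estimated by REML.
    log_lambda_bounds : tuple of float
        Search interval for log(lambda) during REML.
    n_grid : int
        Coarse grid size before bounded local refinement.
    rel_tol : float
        Tolerance of the local refinement (on log lambda).

    Attributes
    ----------
    intercept_ : float
        GLS intercept beta_0 at the fitted lambda.
    coef_ : ndarray of shape (p,)
        Marker-effect BLUPs beta_hat.
    lambda_ : float
        Fitted (or fixed) ridge ratio.
    sigma_beta_sq_, sigma_e_sq_ : float
        REML variance components (marker-effect and residual variance).
    log_reml_ : float
        Restricted log-likelihood at the optimum (None for fixed lambda).
    """

    def __init__(self, lmbda: float | None = None,
                 log_lambda_bounds: tuple = (-10.0, 10.0),
                 n_grid: int = 41, rel_tol: float = 1e-8):
        self.lmbda = lmbda
        self.log_lambda_bounds = log_lambda_bounds
        self.n_grid = n_grid
        self.rel_tol = rel_tol

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] < 2:
            raise ValueError("RR-BLUP needs at least 2 individuals")
        if np.allclose(X, X[0]):
            raise ValueError("all marker columns are constant; nothing to fit")
        K = X @ X.T
        # genetic-variance scale of the induced GBLUP: mean diag of the
        # column-centered cross product (centering does not change REML,
        # which only sees K projected off the intercept)
        Xc = X - X.mean(axis=0)
        self._mean_diag_k = float(np.mean(np.sum(Xc**2, axis=1)))
        if self.lmbda is not None:
            if self.lmbda <= 0:
                raise ValueError("fixed lambda must be positive")
            lam = float(self.lmbda)
            self.log_reml_ = None
            # residual-scale components are not identified at fixed lambda
            self.sigma_beta_sq_ = np.nan
            self.sigma_e_sq_ = np.nan
        else:
            lam, sigma_b2, ll = _reml_lambda(
                y, K, self.log_lambda_bounds, self.n_grid, self.rel_tol
            )
            self.log_reml_ = ll
            self.sigma_beta_sq_ = sigma_b2
            self.sigma_e_sq_ = lam * sigma_b2
        b0, w = _gls_intercept(y, K, lam)
        self.lambda_ = lam
        self.intercept_ = b0
        self.coef_ = X.T @ w
        self.n_features_in_ = X.shape[1]
        return self

    def gebv(self, X) -> np.ndarray:
        """Genomic estimated breeding values X @ beta_hat (no intercept).

        The intercept is a location shift and cancels in Pearson-correlation
        accuracy; GEBVs are therefore reported without it.
        """
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} markers, model was fitted with {self.n_features_in_}"
            )
        return X @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Phenotype-scale prediction: intercept + GEBV."""
        return self.intercept_ + self.gebv(X)

    @property
    def h2_(self) -> float:
        """Genomic heritability under the induced GBLUP: 1 / (1 + lambda_K).

        With u = X beta, Var(u) = sigma_beta^2 K.  Scaling K to mean
        diagonal 1 gives sigma_u^2 = sigma_beta^2 * mean(diag K), hence
        h2 = sigma_u^2 / (sigma_u^2 + sigma_E^2).  Requires REML fit.
        """
        check_is_fitted(self, "coef_")
        if self.log_reml_ is None:
            raise ValueError("h2_ requires a REML fit (lmbda=None)")
        return float(self._mean_diag_k / (self._mean_diag_k + self.lambda_))


class PCRegression(RegressorMixin, BaseEstimator):
    """Structure-only prediction: OLS of the trait on top marker PCs.

    Markers are column-centered and the top-q left singular directions
    (principal component loadings) extracted; the trait is regressed on the
    training individuals' scores and predicted from the validation scores.
    By default the PCA basis is computed from the matrix passed to ``fit``;
    pass ``X_reference`` to compute loadings (and centering) from a larger
    genotype-only matrix, e.g. the entire panel including validation
    individuals — phenotypes never enter the PCA.

    Parameters
    ----------
    n_components : int, default 7
        Number of principal components q.
    """

    def __init__(self, n_components: int = 7):
        self.n_components = n_components

    def fit(self, X, y, X_reference=None):
        X, y = check_X_y(X, y, y_numeric=True)
        q = self.n_components
        if q < 1:
            raise ValueError("n_components must be >= 1")
        ref = X if X_reference is None else check_array(X_reference)
        self.center_ = ref.mean(axis=0)
        Xc = ref - self.center_
        # right singular vectors = loadings over markers
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
        if q > rank:
            raise ValueError(f"n_components={q} exceeds marker-matrix rank {rank}")
        self.components_ = vt[:q]
        scores = (X - self.center_) @ self.components_.T
        design = np.column_stack([np.ones(len(y)), scores])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = check_array(X)
        scores = (X - self.center_) @ self.components_.T
        return self.intercept_ + scores @ self.coef_


# ---------------------------------------------------------------------------
# Kinship / GBLUP heritability
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Genomic relationship matrix with individual ids."""

    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self):
        A = np.asarray(self.values, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        if A.shape[0] != len(self.individual_ids):
            raise ValueError("id list does not match matrix dimension")
        self.values = A

    @property
    def n(self) -> int:
        return self.values.shape[0]


def kinship(X_coded: np.ndarray, individual_ids: list[str] | None = None,
            ridge: float = 1e-6) -> KinshipMatrix:
    """Centered cross-product genomic relationship matrix.

    Columns of the coded marker matrix are centered; A = Xc Xc^T / c with c
    the mean diagonal of Xc Xc^T, so diag(A) averages 1.  A small ridge
    (default 1e-6) is added to the diagonal for invertibility; pass
    ``ridge=0`` for the raw normalized matrix.
    """
    X = np.asarray(X_coded, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("kinship needs at least 2 individuals")
    Xc = X - X.mean(axis=0)
    G = Xc @ Xc.T
    c = float(np.mean(np.diag(G)))
    if c <= 0:
        raise ValueError("all markers are monomorphic; kinship undefined")
    A = G / c + ridge * np.eye(X.shape[0])
    ids = individual_ids if individual_ids is not None else [str(i) for i in range(X.shape[0])]
    return KinshipMatrix(values=A, individual_ids=list(ids))


def narrow_h2(y: np.ndarray, A: KinshipMatrix | np.ndarray) -> float:
    """Narrow-sense heritability by REML variance-component ratio.

    Fits y = 1 mu + u + e with u ~ N(0, A sigma_u^2) and returns
    sigma_u^2 / (sigma_u^2 + sigma_e^2).  With diag(A) averaging 1 this is
    the usual genomic heritability.
    """
    K = A.values if isinstance(A, KinshipMatrix) else np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != K.shape[0]:
        raise ValueError("phenotype / kinship dimension mismatch")
    eigvals = np.linalg.eigvalsh(K)
    if eigvals.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semi-definite")
    lam, _, _ = _reml_lambda(y, K)
    # Var(u_i) ~ sigma_u^2 * mean diag(A); lambda = sigma_e^2 / sigma_u^2
    d = float(np.mean(np.diag(K)))
    return float(d / (d + lam))


def lambda_from_phenotypes(y: np.ndarray, A: KinshipMatrix | np.ndarray) -> float:
    """Trait-specific ridge ratio sigma_e^2 / sigma_u^2 from a GBLUP REML fit."""
    K = A.values if isinstance(A, KinshipMatrix) else np.asarray(A, dtype=float)
    lam, _, _ = _reml_lambda(np.asarray(y, dtype=float), K)
    return float(lam)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

@dataclass
class RRBLUPFit:
    """Fitted RR-BLUP summary: intercept, BLUPs, variance components."""

    intercept: float
    effects: np.ndarray
    sigma_beta_sq: float
    sigma_e_sq: float
    lmbda: float
    log_reml: float | None
    coding: str = "coded_pm1"

    @property
    def n_markers(self) -> int:
        return len(self.effects)


def rrblup_fit(y: np.ndarray, X: np.ndarray, lmbda: float | None = None) -> RRBLUPFit:
    """Fit RR-BLUP on a coded marker matrix; see :class:`RRBLUP`."""
    est = RRBLUP(lmbda=lmbda).fit(X, y)
    return RRBLUPFit(
        intercept=est.intercept_,
        effects=est.coef_,
        sigma_beta_sq=est.sigma_beta_sq_,
        sigma_e_sq=est.sigma_e_sq_,
        lmbda=est.lambda_,
        log_reml=est.log_reml_,
    )


def predict_gebv(fit: RRBLUPFit, X_new: np.ndarray) -> np.ndarray:
    """GEBVs X_new @ beta_hat; the intercept is omitted (cancels in Pearson r)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != fit.n_markers:
        raise ValueError(
            f"X_new has {X_new.shape[1]} markers, fit has {fit.n_markers}"
        )
    return X_new @ fit.effects


def sum_gebv(gebv_a: np.ndarray, gebv_b: np.ndarray,
             ids_a: list | None = None, ids_b: list | None = None) -> np.ndarray:
    """Element-wise sum of two GEBV vectors over the same target individuals.

    Used by the two-panel configuration where a model is trained in each
    whole panel and the target's combined GEBV is the sum of both
    predictions.  If id lists are given they must match element-wise.
    """
    a = np.asarray(gebv_a, dtype=float)
    b = np.asarray(gebv_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("GEBV vectors must have equal length")
    if ids_a is not None and ids_b is not None and list(ids_a) != list(ids_b):
        raise ValueError("GEBV vectors are not aligned: individual ids differ")
    return a + b


def pca_fit_predict(
    X_all: np.ndarray,
    y_train: np.ndarray,
    train_idx: np.ndarray,
    valid_idx: np.ndarray,
    q: int = 7,
) -> np.ndarray:
    """PC-only model: regress y_train on top-q PC scores, predict validation.

    The PCA basis is computed once from all individuals' genotypes (no
    phenotypes involved), mirroring a single panel-level scree analysis.
    """
    X_all = np.asarray(X_all, dtype=float)
    est = PCRegression(n_components=q)
    est.fit(X_all[train_idx], np.asarray(y_train, dtype=float), X_reference=X_all)
    return est.predict(X_all[valid_idx])
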