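"""Exploratory factor analysis: principal axis factoring, Kaiser retention,
Promax rotation, and regression/Bartlett factor scores.

Principal axis factoring iterates the eigendecomposition of the correlation
matrix with its diagonal replaced by communality estimates (initialized at
squared multiple correlations) until the communalities stabilize.  The
Kaiser rule retains factors whose eigenvalues of the ORIGINAL (unreduced)
correlation matrix exceed 1 — the SPSS convention.  Promax first finds a
(Kaiser-normalized) varimax solution, powers it up into a simple-structure
target, and fits that target by oblique Procrustes, yielding correlated
factors.  Kappa defaults to 4 (the SPSS default).

Factor scores:

* regression (Thurstone): ``W = R^{-1} S`` with structure ``S = Lambda Phi``,
  scores ``F = Z W``;
* Bartlett: ``W = Psi^{-1} Lambda (Lambda' Psi^{-1} Lambda)^{-1}`` with
  uniquenesses ``Psi``, a weighted least-squares estimate with unit-ish
  variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class FactorError(ValueError):
    pass


@dataclass
class FactorModel:
    loadings: pd.DataFrame            # measure x factor (pattern matrix)
    communalities: pd.Series
    factor_corr: np.ndarray           # factor x factor (identity if unrotated)
    eigenvalues: np.ndarray           # of the original correlation matrix, desc
    variance_explained: np.ndarray    # per factor, fraction of total variance
    n_factors: int
    rotation: str = "none"
    converged: bool = True
    n_iter: int = 0

    @property
    def measures(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def structure(self) -> pd.DataFrame:
        """Structure matrix ``Lambda Phi`` (loading-score correlations)."""
        return pd.DataFrame(self.loadings.to_numpy() @ self.factor_corr,
                            index=self.loadings.index,
                            columns=self.loadings.columns)

    @property
    def uniquenesses(self) -> pd.Series:
        return 1.0 - self.communalities

    def reconstructed(self) -> np.ndarray:
        """Model-implied correlation matrix Lambda Phi Lambda' + diag(psi)."""
        lam = self.loadings.to_numpy()
        return lam @ self.factor_corr @ lam.T + np.diag(self.uniquenesses.to_numpy())

    def eigen_table(self) -> pd.DataFrame:
        """Scree-style table of eigenvalues and cumulative variance."""
        ev = self.eigenvalues
        return pd.DataFrame({
            "eigenvalue": ev,
            "proportion": ev / ev.sum(),
            "cumulative": np.cumsum(ev) / ev.sum(),
        }, index=pd.RangeIndex(1, len(ev) + 1, name="component"))

    def display_loadings(self, cutoff: float = 0.30) -> pd.DataFrame:
        """Display copy with |loading| < cutoff suppressed (blank)."""
        lam = self.loadings.copy()
        return lam.mask(lam.abs() < cutoff).round(3)


def _check_corr(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise FactorError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-8):
        raise FactorError("correlation matrix must be symmetric")
    if np.linalg.eigvalsh(r).min() < -1e-8:
        raise FactorError("correlation matrix must be positive semidefinite")
    return r


def kaiser_n_factors(corr: np.ndarray) -> int:
    """Number of eigenvalues of the unreduced correlation matrix strictly > 1."""
    return int((np.linalg.eigvalsh(_check_corr(corr)) > 1.0).sum())


def smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, the initial communality estimates."""
    inv = np.linalg.pinv(corr)
    return 1.0 - 1.0 / np.diag(inv)


def paf_extract(corr: np.ndarray | pd.DataFrame,
                n_factors: int | None = None,
                tol: float = 1e-4, max_iter: int = 100) -> FactorModel:
    """Principal axis factoring of a correlation matrix.

    ``n_factors=None`` applies the Kaiser rule; a retained count of zero
    returns an empty model (no factor has an eigenvalue above 1).  Heywood
    communalities are clipped to 0.999 with a warning; non-convergence within
    ``max_iter`` warns and returns the last iterate.
    """
    if isinstance(corr, pd.DataFrame):
        names = list(corr.columns)
        r = _check_corr(corr.to_numpy())
    else:
        r = _check_corr(corr)
        names = [f"m{i:02d}" for i in range(r.shape[0])]
    m = r.shape[0]
    eigvals = np.linalg.eigvalsh(r)[::-1]
    k = kaiser_n_factors(r) if n_factors is None else int(n_factors)
    cols = [f"factor{j + 1}" for j in range(k)]
    if k == 0:
        return FactorModel(
            loadings=pd.DataFrame(np.zeros((m, 0)), index=names, columns=cols),
            communalities=pd.Series(np.zeros(m), index=names),
            factor_corr=np.zeros((0, 0)), eigenvalues=eigvals,
            variance_explained=np.zeros(0), n_factors=0)
    if k > m:
        raise FactorError(f"cannot extract {k} factors from {m} measures")

    comm = np.clip(smc(r), 0.0, 0.999)
    converged = False
    lam = np.zeros((m, k))
    it = 0
    for it in range(1, max_iter + 1):
        reduced = r.copy()
        np.fill_diagonal(reduced, comm)
        w, v = np.linalg.eigh(reduced)
        idx = np.argsort(w)[::-1][:k]
        lam = v[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
        new_comm = (lam**2).sum(axis=1)
        if (new_comm >= 1.0).any():
            warnings.warn("Heywood case: communality >= 1 clipped to 0.999")
            new_comm = np.clip(new_comm, 0.0, 0.999)
        delta = np.abs(new_comm - comm).max()
        comm = new_comm
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"PAF did not converge in {max_iter} iterations; "
                      "returning last iterate")
    # deterministic sign: largest-|loading| entry of each factor positive
    for j in range(k):
        pivot = np.argmax(np.abs(lam[:, j]))
        if lam[pivot, j] < 0:
            lam[:, j] = -lam[:, j]
    return FactorModel(
        loadings=pd.DataFrame(lam, index=names, columns=cols),
        communalities=pd.Series(comm, index=names),
        factor_corr=np.eye(k),
        eigenvalues=eigvals,
        variance_explained=(lam**2).sum(axis=0) / m,
        n_factors=k,
        converged=converged,
        n_iter=it,
    )


def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (SVD algorithm, Kaiser row normalization).

    Returns (rotated loadings, rotation matrix).
    """
    lam = np.asarray(loadings, dtype=float).copy()
    m, k = lam.shape
    if k < 2:
        return lam, np.eye(k)
    if normalize:
        norms = np.sqrt((lam**2).sum(axis=1))
        norms[norms == 0] = 1.0
        lam = lam / norms[:, None]
    rot = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        basis = lam @ rot
        u, s, vt = np.linalg.svd(
            lam.T @ (basis**3 - basis @ np.diag((basis**2).sum(axis=0)) / m))
        rot = u @ vt
        d_new = s.sum()
        if d_new < d_old * (1.0 + tol):
            break
        d_old = d_new
    lam = lam @ rot
    if normalize:
        lam = lam * norms[:, None]
    return lam, rot


def promax_rotate(model: FactorModel, kappa: int = 4) -> FactorModel:
    """Oblique Promax rotation of an unrotated factor model.

    Varimax pre-rotation, power-``kappa`` simple-structure target, oblique
    Procrustes fit; the returned model carries the pattern loadings and the
    factor correlation matrix.  A single factor gets the identity rotation.
    """
    if model.rotation != "none":
        raise FactorError("promax_rotate expects an unrotated model")
    k = model.n_factors
    if k < 1:
        raise FactorError("cannot rotate an empty model")
    if k == 1:
        return FactorModel(
            loadings=model.loadings.copy(), communalities=model.communalities.copy(),
            factor_corr=np.eye(1), eigenvalues=model.eigenvalues,
            variance_explained=model.variance_explained.copy(), n_factors=1,
            rotation="promax", converged=model.converged, n_iter=model.n_iter)
    x, _ = varimax(model.loadings.to_numpy())
    target = x * np.abs(x) ** (kappa - 1)
    coef = np.linalg.solve(x.T @ x, x.T @ target)
    # rescale so the implied factor variances are 1
    d = np.sqrt(np.diag(np.linalg.inv(coef.T @ coef)))
    coef = coef * d
    pattern = x @ coef
    phi = np.linalg.inv(coef.T @ coef)
    # sign convention as in extraction
    for j in range(k):
        pivot = np.argmax(np.abs(pattern[:, j]))
        if pattern[pivot, j] < 0:
            pattern[:, j] = -pattern[:, j]
            phi[j, :] = -phi[j, :]
            phi[:, j] = -phi[:, j]
    m = pattern.shape[0]
    ss = np.diag(pattern.T @ pattern)  # SS pattern loadings (reporting only)
    return FactorModel(
        loadings=pd.DataFrame(pattern, index=model.loadings.index,
                              columns=model.loadings.columns),
        communalities=model.communalities.copy(),
        factor_corr=phi,
        eigenvalues=model.eigenvalues,
        variance_explained=ss / m,
        n_factors=k,
        rotation="promax",
        converged=model.converged,
        n_iter=model.n_iter,
    )


def factor_scores(data: pd.DataFrame, model: FactorModel,
                  method: str = "regression",
                  corr: np.ndarray | None = None) -> pd.DataFrame:
    """Subject x factor score estimates from standardized data.

    ``method="regression"`` uses Thurstone weights ``R^{-1} Lambda Phi``;
    ``method="bartlett"`` uses uniqueness-weighted least squares.  A singular
    observed correlation matrix is ridge-stabilized (1e-8) with a warning.
    """
    if list(data.columns) != model.measures:
        raise FactorError("data columns must match the model's measure set")
    z = data.to_numpy(float)
    lam = model.loadings.to_numpy()
    if method == "regression":
        r = np.corrcoef(z.T) if corr is None else np.asarray(corr, dtype=float)
        if np.linalg.cond(r) > 1e12:
            warnings.warn("singular correlation matrix; ridge-stabilizing (1e-8)")
            r = r + 1e-8 * np.eye(r.shape[0])
        weights = np.linalg.solve(r, lam @ model.factor_corr)
    elif method == "bartlett":
        psi_inv = 1.0 / np.clip(model.uniquenesses.to_numpy(), 1e-8, None)
        middle = lam.T * psi_inv @ lam
        weights = (psi_inv[:, None] * lam) @ np.linalg.inv(middle)
    else:
        raise FactorError(f"unknown score method {method!r}")
    scores = z @ weights
    return pd.DataFrame(scores, index=data.index,
                        columns=model.loadings.columns)
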