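"""Principal axes of the ecosystem-function space and their significance.

The sites x EFP matrix is z-transformed (complete-case), decomposed by PCA on
the correlation structure, and two resampling tests qualify the result: an
eigenvalue permutation test for the number of significant components (a
stand-in with the same purpose as dimensionality tests based on comparing
observed eigenvalues to a null), and a bootstrapped-eigenvector test for
loading significance combined with the 1/sqrt(p) magnitude threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles

__all__ = ["AxesResult", "ztransform", "run_pca", "test_dimensionality",
           "bootstrap_loadings", "principal_angles_deg"]


@dataclass
class AxesResult:
    """Eigenstructure of the standardized EFP matrix."""

    eigenvalues: np.ndarray          # variance units, descending
    explained_fraction: np.ndarray   # per component, sums to 1
    loadings: pd.DataFrame           # variables x components, unit-norm columns
    scores: pd.DataFrame             # sites x components
    contributions: pd.DataFrame      # percent, columns sum to 100
    n_significant_components: int | None = None
    significant_loadings: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)


def ztransform(matrix: pd.DataFrame, min_values: int = 3) -> pd.DataFrame:
    """Standardize each EFP column to mean 0, s.d. 1 (complete-case rows).

    Rows with any missing EFP are dropped; the count is recorded in
    ``result.attrs['n_dropped']``. A zero-variance column is an error naming
    the offending EFP.
    """
    full = matrix.dropna()
    n_dropped = len(matrix) - len(full)
    for col in full.columns:
        if full[col].count() < min_values:
            raise ValueError(f"column {col!r} has fewer than {min_values} values")
        sd = full[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance EFP column: {col!r}")
    z = (full - full.mean()) / full.std(ddof=1)
    z.attrs["n_dropped"] = n_dropped
    return z


def _pca_core(z: np.ndarray):
    """SVD-based PCA of an already standardized matrix (ddof=1 eigenvalues)."""
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = s**2 / (n - 1)
    loadings = vt.T                         # unit-norm eigenvectors, columns
    scores = u * s                          # = z @ loadings
    # deterministic sign: largest-|loading| entry per component is positive
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    return eig, loadings, scores


def run_pca(z: pd.DataFrame) -> AxesResult:
    """PCA of the standardized EFP matrix.

    Eigenvalues of the correlation structure in descending order; loadings
    are unit-norm eigenvectors with a deterministic sign convention;
    contributions are 100 x loading^2 (sum to 100 per component).
    """
    if len(z) < 10:
        raise ValueError("PCA requires at least 10 complete-case sites")
    zv = z.to_numpy(dtype=float)
    if not np.all(np.isfinite(zv)):
        raise ValueError("standardized matrix contains non-finite values")
    eig, loadings, scores = _pca_core(zv)
    comps = [f"PC{k + 1}" for k in range(len(eig))]
    return AxesResult(
        eigenvalues=eig,
        explained_fraction=eig / eig.sum(),
        loadings=pd.DataFrame(loadings, index=z.columns, columns=comps),
        scores=pd.DataFrame(scores, index=z.index, columns=comps),
        contributions=pd.DataFrame(100.0 * loadings**2, index=z.columns,
                                   columns=comps),
    )


def test_dimensionality(z: pd.DataFrame, n_boot: int = 499,
                        seed: int = 0) -> int:
    """Number of significant components by an eigenvalue permutation test.

    Each column is permuted independently ``n_boot`` times; component k is
    significant when its observed eigenvalue exceeds the 95th percentile of
    the k-th permuted eigenvalues. The count of the leading run of
    significant components is returned. Deterministic given ``seed``.
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    rng = np.random.default_rng(seed)
    zv = z.to_numpy(dtype=float)
    n, p = zv.shape
    eig_obs, _, _ = _pca_core(zv)
    null = np.empty((n_boot, p))
    perm = zv.copy()
    for b in range(n_boot):
        for j in range(p):
            perm[:, j] = zv[rng.permutation(n), j]
        null[b], _, _ = _pca_core(perm)
    thresh = np.quantile(null, 0.95, axis=0)
    sig = eig_obs > thresh
    k = 0
    while k < p and sig[k]:
        k += 1
    return k


def bootstrap_loadings(z: pd.DataFrame, n_boot: int = 999, seed: int = 0,
                       alpha: float = 0.05,
                       n_components: int | None = None) -> pd.DataFrame:
    """Loading significance by the bootstrapped-eigenvector method.

    Sites are resampled with replacement; each bootstrap PCA's components are
    matched and sign-aligned to the original by maximal absolute correlation
    of the loading vectors. A loading is significant iff its bootstrap
    (1 - alpha) percentile CI excludes 0 and its original magnitude exceeds
    1/sqrt(p). Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    zv = z.to_numpy(dtype=float)
    n, p = zv.shape
    _, load0, _ = _pca_core(zv)
    ncomp = n_components or min(n, p)
    boot = np.empty((n_boot, p, ncomp))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        zb = zv[idx]
        zb = zb - zb.mean(axis=0)
        sd = zb.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        _, lb, _ = _pca_core(zb / sd)
        # match bootstrap components to originals by max |corr|, then align sign
        corr = load0[:, :ncomp].T @ lb
        taken = np.zeros(lb.shape[1], dtype=bool)
        for k in range(ncomp):
            order = np.argsort(-np.abs(corr[k]))
            j = next(j for j in order if not taken[j])
            taken[j] = True
            boot[b, :, k] = lb[:, j] * np.sign(corr[k, j] if corr[k, j] != 0 else 1.0)
    lo = np.quantile(boot, alpha / 2, axis=0)
    hi = np.quantile(boot, 1 - alpha / 2, axis=0)
    ci_excludes_zero = (lo > 0) | (hi < 0)
    magnitude_ok = np.abs(load0[:, :ncomp]) > 1.0 / np.sqrt(p)
    comps = [f"PC{k + 1}" for k in range(ncomp)]
    return pd.DataFrame(ci_excludes_zero & magnitude_ok, index=z.columns,
                        columns=comps)


def principal_angles_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Principal angles (degrees) between the column spans of two matrices."""
    qa, _ = np.linalg.qr(np.asarray(a, dtype=float))
    qb, _ = np.linalg.qr(np.asarray(b, dtype=float))
    return np.rad2deg(subspace_angles(qa, qb))
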