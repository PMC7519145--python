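"""Covariance structures for reaction-norm G×E models.

Three kernels drive the models: the genomic relationship matrix G = XX′/p
from standardized SNP dosages, the environmental relationship Ω = WW′/q from
standardized ECs, and their record-level Hadamard product (Z_g G Z_g′)#Ω for
SNP-by-EC interactions (PSD by the Schur product theorem). Each structure
carries a truncated eigendecomposition K ≈ UΛU′, which is what makes Gaussian
effect sampling and prediction tractable: an effect with covariance Kσ² is
re-parameterized as u = UΛ^{1/2}δ with δ ~ N(0, Iσ²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "CovarianceStructure",
    "genomic_relationship",
    "environmental_relationship",
    "interaction_covariance",
    "eigendecompose_psd",
]

#: relative eigenvalue truncation threshold (λ kept iff λ > tol·λmax)
EIG_TOL = 1e-10


def eigendecompose_psd(K: np.ndarray, tol: float = EIG_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Truncated eigendecomposition of a symmetric PSD matrix.

    Returns (U, Λ) with eigenvalues λ > tol·λmax, descending. Raises if K is
    asymmetric beyond 1e-8 relative.
    """
    K = np.asarray(K, dtype=float)
    scale = max(np.abs(K).max(), 1.0)
    if not np.allclose(K, K.T, atol=1e-8 * scale):
        raise ValueError("kernel matrix is not symmetric")
    lam, U = scipy.linalg.eigh((K + K.T) / 2.0)
    lam = lam[::-1]
    U = U[:, ::-1]
    lmax = max(lam[0], 0.0)
    keep = lam > tol * lmax
    return U[:, keep], lam[keep]


@dataclass
class CovarianceStructure:
    """A kernel over a row index plus its truncated spectral factorization.

    ``row_keys`` names the kernel rows (cultivar ids, record keys, ...).
    ``factor`` = UΛ^{1/2} so that K ≈ factor @ factor.T.
    """

    K: np.ndarray
    row_keys: list
    tag: str = "kernel"
    U: np.ndarray = field(init=False)
    lam: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape[0] != self.K.shape[1] or self.K.shape[0] != len(self.row_keys):
            raise ValueError("kernel shape does not match row keys")
        self.U, self.lam = eigendecompose_psd(self.K)

    @property
    def rank(self) -> int:
        return len(self.lam)

    @property
    def factor(self) -> np.ndarray:
        return self.U * np.sqrt(self.lam)

    def reconstruction_error(self) -> float:
        return float(np.abs(self.factor @ self.factor.T - self.K).max())

    def row_index(self, keys) -> np.ndarray:
        pos = {k: i for i, k in enumerate(self.row_keys)}
        try:
            return np.array([pos[k] for k in keys], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"row key {e} not in kernel index") from None

    def to_csv(self, path) -> None:
        pd.DataFrame(self.K, index=self.row_keys, columns=self.row_keys).to_csv(path)

    def to_hdf5(self, h5group) -> None:
        h5group.create_dataset("K", data=self.K)
        h5group.create_dataset("row_keys", data=np.array([str(k) for k in self.row_keys], dtype="S"))
        h5group.attrs["tag"] = self.tag


def genomic_relationship(X: pd.DataFrame) -> CovarianceStructure:
    """G = XX′/p from a centered/scaled cultivar × SNP matrix."""
    p = X.shape[1]
    if p == 0:
        raise ValueError("no SNPs (p = 0)")
    Xv = X.to_numpy(dtype=float)
    if np.isnan(Xv).any():
        raise ValueError("X contains missing values; impute first")
    G = Xv @ Xv.T / p
    return CovarianceStructure(G, row_keys=list(X.index), tag="G")


def environmental_relationship(W: pd.DataFrame) -> CovarianceStructure:
    """Ω = WW′/q from a centered/scaled environment × EC matrix (rank ≤ q)."""
    q = W.shape[1]
    if q == 0:
        raise ValueError("no environmental covariates (q = 0)")
    Wv = W.to_numpy(dtype=float)
    Om = Wv @ Wv.T / q
    return CovarianceStructure(Om, row_keys=list(W.index), tag="Omega")


def interaction_covariance(
    Zg: np.ndarray, G: CovarianceStructure, Om: CovarianceStructure, row_keys: list | None = None
) -> CovarianceStructure:
    """(Z_g G Z_g′) # Ω — the record-level SNP-by-EC interaction kernel.

    ``Zg`` is the records × cultivars incidence matrix; ``Om`` must be indexed
    by the same records (after expansion to record level).
    """
    Zg = np.asarray(Zg, dtype=float)
    n = Zg.shape[0]
    if Om.K.shape[0] != n:
        raise ValueError(
            f"row mismatch: Zg has {n} records but Omega is {Om.K.shape[0]}×{Om.K.shape[0]}"
        )
    if Zg.shape[1] != G.K.shape[0]:
        raise ValueError("Zg columns do not match the genomic kernel")
    ZGZ = Zg @ G.K @ Zg.T
    K = ZGZ * Om.K
    return CovarianceStructure(K, row_keys=row_keys or Om.row_keys, tag="Hadamard")
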