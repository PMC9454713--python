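"""Genomic relationship matrices and single-step H⁻¹ assembly.

The (weighted) VanRaden genomic relationship matrix is

    G = Z D Z' / q,      q = sum_i 2 p_i (1 - p_i),

where ``Z`` is the allele-frequency-centred dosage matrix, ``D`` a diagonal
matrix of SNP weights (all 1 initially) and ``q`` a normalising factor kept
fixed across weight iterations — the weights themselves are renormalised so
that ``sum_i d_i 2 p_i (1 - p_i)`` is conserved, which keeps the implied
total genetic variance constant.

``G`` from real panels is often singular (clones, many more animals than
informative dimensions), so a blended ``G_b = (1-tau) G + tau A22`` is used
before inversion.  The single-step inverse is then

    H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A22⁻¹]

with the correction confined to the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "SnpWeightState",
    "center_genotypes",
    "vanraden_g",
    "blend_g",
    "h_inverse",
]


@dataclass
class SnpWeightState:
    """Diagonal SNP weights with their allele frequencies and normaliser.

    Invariant: ``sum(d * 2p(1-p)) == q`` after every normalisation; ``q`` is
    fixed at its D = I value.
    """

    d: np.ndarray
    p: np.ndarray
    q: float = None
    iteration: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("SNP weights must be non-negative")
        if self.q is None:
            self.q = float(np.sum(2.0 * self.p * (1.0 - self.p)))
        if self.q <= 0:
            raise ValueError("normalising factor q must be positive")

    @classmethod
    def initial(cls, p: np.ndarray) -> "SnpWeightState":
        p = np.asarray(p, dtype=float)
        return cls(d=np.ones_like(p), p=p)

    def het_sum(self) -> float:
        """Current value of sum(d_i * 2 p_i (1-p_i))."""
        return float(np.sum(self.d * 2.0 * self.p * (1.0 - self.p)))


def center_genotypes(
    dosages: np.ndarray, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Centre dosages as Z = M - 2p; missing entries mean-imputed to Z = 0.

    ``freqs`` defaults to the observed frequency in the genotyped animals.
    Monomorphic columns are rejected (they should have been removed by QC).
    """
    d = np.asarray(dosages, dtype=float)
    miss = d < 0
    if freqs is None:
        with np.errstate(invalid="ignore"):
            freqs = np.where(miss, 0.0, d).sum(axis=0) / (
                2.0 * (~miss).sum(axis=0)
            )
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        bad = np.flatnonzero((freqs <= 0) | (freqs >= 1))
        raise ValueError(
            f"monomorphic columns (p=0 or 1) at indices {bad[:10].tolist()}; run QC first"
        )
    Z = d - 2.0 * freqs
    Z[miss] = 0.0
    return Z, freqs


def vanraden_g(Z: np.ndarray, weights: SnpWeightState) -> np.ndarray:
    """Weighted VanRaden genomic relationship matrix G = Z D Z' / q."""
    if Z.shape[1] != len(weights.d):
        raise ValueError("Z and weight vector are not conformable")
    return (Z * weights.d) @ Z.T / weights.q


def blend_g(G: np.ndarray, A22: np.ndarray, tau: float = 0.05) -> np.ndarray:
    """Blend G with A22 for invertibility: G_b = (1-tau) G + tau A22.

    Raises with a diagnostic if the blend is still not positive definite.
    """
    if G.shape != A22.shape:
        raise ValueError("G and A22 are not conformable")
    Gb = (1.0 - tau) * G + tau * A22
    if tau > 0:
        try:
            np.linalg.cholesky(Gb)
        except np.linalg.LinAlgError as exc:
            wmin = float(np.linalg.eigvalsh(Gb).min())
            raise np.linalg.LinAlgError(
                f"blended G not positive definite (min eigenvalue {wmin:.3e}); "
                f"increase tau (got {tau})"
            ) from exc
    return Gb


def h_inverse(
    a_inv: sparse.spmatrix,
    g_b: np.ndarray,
    a22_mat: np.ndarray,
    genotyped_index: np.ndarray,
) -> sparse.csr_matrix:
    """Single-step H⁻¹ = A⁻¹ plus the genotyped-block correction G_b⁻¹ − A22⁻¹.

    ``genotyped_index`` maps rows of ``g_b``/``a22_mat`` to pedigree positions
    (rows of ``a_inv``), in the same order.
    """
    idx = np.asarray(genotyped_index, dtype=np.int64)
    n = a_inv.shape[0]
    if len(idx) == 0:
        return sparse.csr_matrix(a_inv)
    if g_b.shape != (len(idx), len(idx)) or a22_mat.shape != g_b.shape:
        raise ValueError("genotyped_index does not match G_b / A22 dimensions")
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("genotyped_index out of pedigree range")
    corr = np.linalg.inv(g_b) - np.linalg.inv(a22_mat)
    rows = np.repeat(idx, len(idx))
    cols = np.tile(idx, len(idx))
    block = sparse.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    out = (sparse.csr_matrix(a_inv) + block.tocsr()).tocsr()
    return out
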