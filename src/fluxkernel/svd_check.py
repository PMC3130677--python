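"""Numerical SVD kernel for cross-validating the exact elimination kernel.

The nullspace of N can also be read off a singular value decomposition
N = u @ diag(s) @ v.T: the columns of v belonging to (numerically) zero
singular values span the kernel.  That orthonormal basis V_ker is dense
and its columns mix fluxes across the whole network; to compare it with
the exact kernel R we rebase it on the same independent fluxes:

    R_svd = V_ker @ inv(V_indep),

where V_indep holds the rows of V_ker at the independent flux indices.
The SVD alone gives no reliable way to pick that partition, so it is taken
from the exact elimination.  The condition number of V_indep governs how
many digits the rebasing loses; the maximal relative flux error
``epsilon_svd`` measures the achieved discrepancy against the exact kernel
(the number of inaccurate digits tracks the order of magnitude of the
condition number).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import FluxPartition
from .rational_sparse import RationalSparseMatrix

__all__ = ["SvdKernel", "svd_kernel", "epsilon_svd", "principal_angles",
           "float_sparsity"]


@dataclass(frozen=True)
class SvdKernel:
    """SVD nullspace basis rebased onto the chosen independent fluxes."""

    V_ker: np.ndarray        # n x f, orthonormal columns
    V_indep: np.ndarray      # f x f, rows of V_ker at independent indices
    R_svd: np.ndarray        # n x f, = V_ker @ inv(V_indep)
    condition: float         # extreme singular-value ratio of V_indep


class SvdConsistencyError(RuntimeError):
    """Numerical nullspace dimension disagrees with the exact rank."""


def svd_kernel(N: RationalSparseMatrix, partition: FluxPartition,
               rank_tol: float | None = None) -> SvdKernel:
    """Compute the SVD kernel of N rebased on the given flux partition.

    ``rank_tol`` overrides the singular-value threshold separating the
    kernel from the image; the default is the standard
    ``max(m, n) * eps * sigma_max`` rank tolerance.
    """
    f = partition.f
    if f < 1:
        raise ValueError("the kernel is trivial (f = 0); there is nothing "
                         "to cross-validate")
    if partition.n != N.n_cols:
        raise ValueError(f"partition covers {partition.n} fluxes but the "
                         f"matrix has {N.n_cols} columns")
    A = N.to_float_array()
    _, s, vt = np.linalg.svd(A, full_matrices=True)
    if rank_tol is None:
        smax = s[0] if s.size else 0.0
        rank_tol = max(A.shape) * np.finfo(float).eps * smax
    num_rank = int(np.sum(s > rank_tol))
    if N.n_cols - num_rank != f:
        raise SvdConsistencyError(
            f"numerical nullspace dimension {N.n_cols - num_rank} != exact "
            f"f = {f}; adjust rank_tol (threshold {rank_tol:g})")
    V_ker = vt[num_rank:, :].T                     # n x f, orthonormal
    indep = np.asarray(partition.independent, dtype=int)
    V_indep = V_ker[indep, :]
    sv = np.linalg.svd(V_indep, compute_uv=False)
    if sv[-1] == 0.0:
        raise SvdConsistencyError(
            "V_indep is singular: the chosen independent fluxes do not "
            "parameterize the SVD nullspace")
    condition = float(sv[0] / sv[-1])
    R_svd = V_ker @ np.linalg.inv(V_indep)
    return SvdKernel(V_ker=V_ker, V_indep=V_indep, R_svd=R_svd,
                     condition=condition)


def epsilon_svd(R_gje: RationalSparseMatrix, R_svd: np.ndarray) -> float:
    """Maximal relative flux error of the numerical kernel.

    ``max_ij |R_svd[i,j] - R_gje[i,j]| / max_ij |R_gje[i,j]|`` with the
    exact kernel as reference.  Zero iff the matrices agree entry for
    entry.
    """
    R_svd = np.asarray(R_svd, dtype=float)
    if R_svd.shape != (R_gje.n_rows, R_gje.n_cols):
        raise ValueError(f"shape mismatch: exact kernel "
                         f"{R_gje.n_rows}x{R_gje.n_cols}, numerical kernel "
                         f"{R_svd.shape}")
    ref = R_gje.to_float_array()
    scale = np.max(np.abs(ref)) if ref.size else 0.0
    if scale == 0.0:
        return float(np.max(np.abs(R_svd))) if R_svd.size else 0.0
    return float(np.max(np.abs(R_svd - ref)) / scale)


def principal_angles(A, B) -> np.ndarray:
    """Principal angles (radians) between the column spaces of A and B.

    Small angles are computed from sines (SVD of the projection residual)
    rather than cosines, which lose all precision below ~1e-8.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    cos = np.linalg.svd(qa.T @ qb, compute_uv=False)
    cos = np.clip(cos, -1.0, 1.0)
    sin = np.linalg.svd(qb - qa @ (qa.T @ qb), compute_uv=False)
    sin = np.sort(np.clip(sin, -1.0, 1.0))  # ascending, pairs with cos desc
    theta = np.where(cos ** 2 < 0.5, np.arccos(cos), np.arcsin(sin))
    return theta


def float_sparsity(M: np.ndarray, tol: float = 0.0) -> float:
    """Fraction of entries with magnitude <= tol (exact zeros by default)."""
    M = np.asarray(M)
    if M.size == 0:
        raise ValueError("sparsity undefined for an empty matrix")
    return float(np.mean(np.abs(M) <= tol))


def svd_report(N: RationalSparseMatrix, kernel_result) -> dict:
    """Comparison report between exact and SVD kernels, JSON-friendly."""
    from .rational_sparse import sparsity

    sk = svd_kernel(N, kernel_result.partition)
    return {
        "f": kernel_result.partition.f,
        "condition": sk.condition,
        "epsilon_svd": epsilon_svd(kernel_result.R, sk.R_svd),
        "sparsity_gje": float(sparsity(kernel_result.R)),
        "sparsity_svd": float_sparsity(sk.V_ker),
    }
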