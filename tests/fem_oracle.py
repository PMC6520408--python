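"""Independent brute-force eigen-oracle for free elastic vibration.

A plain trilinear hexahedral finite-element discretisation of a freely
vibrating isotropic block, assembled from first principles (8-node bricks,
2x2x2 Gauss quadrature, consistent mass).  It shares no code with the
Rayleigh-Ritz solver it cross-checks.  FEM eigenvalues converge O(h^2) from
above, so Richardson extrapolation over two uniform meshes sharpens the
reference values.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh


def _hex_element_matrices(E, nu, rho, dx, dy, dz):
    """Stiffness (24x24) and consistent mass for one rectangular brick."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    # node order: (i, j, k) bits of 0..7 -> corner of [0,dx]x[0,dy]x[0,dz]
    corners = np.array([[(n >> 0) & 1, (n >> 1) & 1, (n >> 2) & 1]
                        for n in range(8)], dtype=float)
    g = np.array([-1, 1]) / np.sqrt(3)
    Ke = np.zeros((24, 24))
    Me = np.zeros((24, 24))
    detJ = (dx / 2) * (dy / 2) * (dz / 2)
    for gx in g:
        for gy in g:
            for gz in g:
                xi = np.array([gx, gy, gz])
                # trilinear shape functions and parent-space derivatives
                signs = 2 * corners - 1
                N = np.prod((1 + signs * xi) / 2, axis=1)
                dN = np.zeros((8, 3))
                for a in range(3):
                    terms = (1 + signs * xi) / 2
                    t = terms.copy()
                    t[:, a] = signs[:, a] / 2
                    dN[:, a] = np.prod(t, axis=1)
                dN[:, 0] *= 2 / dx
                dN[:, 1] *= 2 / dy
                dN[:, 2] *= 2 / dz
                B = np.zeros((6, 24))
                for n in range(8):
                    bx, by, bz = dN[n]
                    B[0, 3 * n] = bx
                    B[1, 3 * n + 1] = by
                    B[2, 3 * n + 2] = bz
                    B[3, 3 * n + 1] = bz
                    B[3, 3 * n + 2] = by
                    B[4, 3 * n] = bz
                    B[4, 3 * n + 2] = bx
                    B[5, 3 * n] = by
                    B[5, 3 * n + 1] = bx
                Ke += B.T @ D @ B * detJ
                Nm = np.zeros((3, 24))
                for n in range(8):
                    Nm[:, 3 * n:3 * n + 3] = np.eye(3) * N[n]
                Me += rho * Nm.T @ Nm * detJ
    return Ke, Me


def fem_free_vibration_khz(E_gpa: float, nu: float, rho_mgmm3: float,
                           dims_mm, n_elem: int, n_modes: int = 12) -> np.ndarray:
    """Lowest elastic-mode frequencies (kHz) of a free isotropic block."""
    E = E_gpa * 1e9
    rho = rho_mgmm3 * 1000.0
    L = np.asarray(dims_mm, dtype=float) * 1e-3
    ne = n_elem
    nn = ne + 1
    dx, dy, dz = L / ne
    Ke, Me = _hex_element_matrices(E, nu, rho, dx, dy, dz)

    def nid(i, j, k):
        return (i * nn + j) * nn + k

    rows, cols, kv, mv = [], [], [], []
    for i in range(ne):
        for j in range(ne):
            for k in range(ne):
                nodes = [nid(i + ((n >> 0) & 1), j + ((n >> 1) & 1),
                             k + ((n >> 2) & 1)) for n in range(8)]
                dofs = np.array([3 * n + c for n in nodes for c in range(3)])
                rows.append(np.repeat(dofs, 24))
                cols.append(np.tile(dofs, 24))
                kv.append(Ke.ravel())
                mv.append(Me.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    ndof = 3 * nn ** 3
    K = sp.csr_matrix((np.concatenate(kv), (rows, cols)), shape=(ndof, ndof))
    M = sp.csr_matrix((np.concatenate(mv), (rows, cols)), shape=(ndof, ndof))
    shift = 0.1 * K.diagonal().mean() / M.diagonal().mean()
    # deterministic start vector and a generous Krylov margin: shift-invert
    # Lanczos can otherwise drop a partner inside a degenerate cluster
    vals = eigsh(K, k=n_modes + 14, M=M, sigma=-shift,
                 return_eigenvectors=False, v0=np.ones(ndof))
    vals = np.sort(np.clip(vals, 0, None))[6:6 + n_modes]
    return np.sqrt(vals) / (2 * np.pi) / 1e3


def fem_free_vibration_extrapolated_khz(E_gpa, nu, rho_mgmm3, dims_mm,
                                        n_coarse=8, n_fine=12,
                                        n_modes=12) -> np.ndarray:
    """Richardson-extrapolated frequencies from two uniform meshes.

    FEM squared frequencies err ~ C h^2, so f^2_exact ~ (f_f^2 - r*f_c^2)/(1-r)
    with r = (h_fine/h_coarse)^2.  Per-index pairing is consistent because
    both uniform meshes split symmetry multiplets the same way.
    """
    fc = fem_free_vibration_khz(E_gpa, nu, rho_mgmm3, dims_mm, n_coarse,
                                n_modes)
    ff = fem_free_vibration_khz(E_gpa, nu, rho_mgmm3, dims_mm, n_fine,
                                n_modes)
    r = (n_coarse / n_fine) ** 2
    f2 = (ff ** 2 - r * fc ** 2) / (1 - r)
    return np.sqrt(np.clip(f2, 0, None))
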