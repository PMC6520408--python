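"""Orthotropic elastic constants in Voigt notation.

The specimen frame follows the bone-sample convention: axis 1 is radial,
axis 2 transverse, axis 3 longitudinal (aligned with the osteons).  Nine
independent stiffness entries describe an orthotropic material:
C11, C22, C33, C12, C13, C23, C44, C55, C66 (GPa).  Engineering moduli and
Poisson ratios are obtained from the compliance matrix S = C^-1:
E_k = 1/S_kk and nu_ij = -S_ij * E_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElasticConstants",
    "REFERENCE_CORTICAL",
    "voigt_index",
    "stiffness_tensor",
]

#: Voigt pair -> index map (0-based), standard ordering 11,22,33,23,13,12.
_VOIGT = {(0, 0): 0, (1, 1): 1, (2, 2): 2,
          (1, 2): 3, (2, 1): 3, (0, 2): 4, (2, 0): 4, (0, 1): 5, (1, 0): 5}


def voigt_index(i: int, j: int) -> int:
    """Map a tensor index pair (0-based) to its Voigt index."""
    return _VOIGT[(i, j)]


@dataclass(frozen=True)
class ElasticConstants:
    """Nine orthotropic stiffness constants (GPa, Voigt notation)."""

    c11: float
    c22: float
    c33: float
    c12: float
    c13: float
    c23: float
    c44: float
    c55: float
    c66: float

    def as_array(self) -> np.ndarray:
        """The nine constants in the canonical order (11,22,33,12,13,23,44,55,66)."""
        return np.array([self.c11, self.c22, self.c33, self.c12, self.c13,
                         self.c23, self.c44, self.c55, self.c66], dtype=float)

    @classmethod
    def from_array(cls, c: np.ndarray) -> "ElasticConstants":
        c = np.asarray(c, dtype=float)
        if c.shape != (9,):
            raise ValueError("expected nine stiffness constants")
        return cls(*c)

    @classmethod
    def from_isotropic(cls, E: float, nu: float) -> "ElasticConstants":
        """Build the (degenerate orthotropic) tensor of an isotropic solid."""
        if not (E > 0 and -1 < nu < 0.5):
            raise ValueError("need E > 0 and -1 < nu < 0.5")
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        diag = lam + 2 * mu
        return cls(diag, diag, diag, lam, lam, lam, mu, mu, mu)

    @classmethod
    def from_voigt_matrix(cls, C: np.ndarray) -> "ElasticConstants":
        C = np.asarray(C, dtype=float)
        if C.shape != (6, 6) or not np.allclose(C, C.T):
            raise ValueError("expected a symmetric 6x6 Voigt matrix")
        return cls(C[0, 0], C[1, 1], C[2, 2], C[0, 1], C[0, 2], C[1, 2],
                   C[3, 3], C[4, 4], C[5, 5])

    def voigt_matrix(self) -> np.ndarray:
        """6x6 symmetric stiffness matrix."""
        C = np.zeros((6, 6))
        C[0, 0], C[1, 1], C[2, 2] = self.c11, self.c22, self.c33
        C[0, 1] = C[1, 0] = self.c12
        C[0, 2] = C[2, 0] = self.c13
        C[1, 2] = C[2, 1] = self.c23
        C[3, 3], C[4, 4], C[5, 5] = self.c44, self.c55, self.c66
        return C

    def compliance_matrix(self) -> np.ndarray:
        """6x6 compliance matrix S = C^-1 (1/GPa)."""
        return np.linalg.inv(self.voigt_matrix())

    def is_positive_definite(self) -> bool:
        try:
            np.linalg.cholesky(self.voigt_matrix())
            return True
        except np.linalg.LinAlgError:
            return False

    def engineering_moduli(self) -> dict[str, float]:
        """Engineering moduli E1..E3 (GPa) and Poisson ratios from S = C^-1."""
        S = self.compliance_matrix()
        E1, E2, E3 = 1.0 / S[0, 0], 1.0 / S[1, 1], 1.0 / S[2, 2]
        return {
            "E1": E1, "E2": E2, "E3": E3,
            "nu12": -S[0, 1] * E1,
            "nu13": -S[0, 2] * E1,
            "nu23": -S[1, 2] * E2,
        }

    @property
    def E3(self) -> float:
        """Longitudinal (osteonal-axis) engineering modulus, GPa."""
        return self.engineering_moduli()["E3"]

    def scaled(self, factor: float) -> "ElasticConstants":
        """Uniformly scale every stiffness entry (preserves anisotropy ratios)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ElasticConstants.from_array(self.as_array() * factor)


def stiffness_tensor(constants: ElasticConstants) -> np.ndarray:
    """Full fourth-order stiffness tensor C_ijkl (3,3,3,3) from Voigt entries."""
    Cv = constants.voigt_matrix()
    C4 = np.empty((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    C4[i, j, k, l] = Cv[voigt_index(i, j), voigt_index(k, l)]
    return C4


#: Reference orthotropic tensor for human femoral cortical bone (GPa), used
#: by the synthetic cohort as the anisotropy template that gets scaled to a
#: target longitudinal modulus.  Values are typical mid-shaft means.
REFERENCE_CORTICAL = ElasticConstants(
    c11=19.4, c22=20.2, c33=30.9,
    c12=10.1, c13=10.7, c23=10.4,
    c44=6.23, c55=5.61, c66=4.52,
)
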