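"""The reaction–diffusion model of spreading-depression wave segments.

Activator–inhibitor dynamics with global inhibitory feedback:

    du/dt = u - u^3/3 - v + D * Lap_LB(u)
    dv/dt = eps * (u + beta + k * S),   S = integral of Heaviside(u) dA

The activator ``u`` carries front propagation, the inhibitor ``v`` the
recovery phase and — through the feedback term ``k*S``, proportional to the
excited surface area — the confinement of the wave into a localized segment.
On a curved cortical sheet the Laplacian becomes the Laplace–Beltrami
operator, discretised here as the cotangent finite-element stiffness matrix
with barycentric lumped mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

from .surfaces import SurfaceError, TriSurface

#: Published parameter sets: the bump-scattering study and the patient-V1
#: study (larger threshold and coupling select a smaller segment).
PRESETS = {
    "bump-study": dict(epsilon=0.04, beta=0.9, k=0.003, D=1.0),
    "v1-study": dict(epsilon=0.04, beta=1.2, k=0.0045, D=1.0),
}


@dataclass(frozen=True)
class RDParameters:
    """Model constants.

    epsilon : time-scale separation between activator and inhibitor.
    beta : excitation threshold; the rest state is (u, v) = (-beta, -beta + beta^3/3).
    k : global-feedback coupling (k = 0 disables confinement).
    D : activator diffusion coefficient.
    heaviside_threshold : the u-level above which tissue counts as excited.
    """

    epsilon: float = 0.04
    beta: float = 0.9
    k: float = 0.003
    D: float = 1.0
    heaviside_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.D <= 0 or self.k < 0:
            raise ValueError("require epsilon > 0, D > 0, k >= 0")

    @classmethod
    def preset(cls, name: str) -> "RDParameters":
        return cls(**PRESETS[name])


@dataclass
class RDState:
    """Per-dof activator/inhibitor fields at model time ``t``."""

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have identical shapes")

    def copy(self) -> "RDState":
        return RDState(self.u.copy(), self.v.copy(), self.t)


def reaction_rates(u, v, params: RDParameters, S: float = 0.0):
    """Local reaction terms (du, dv); pure and elementwise.

    du = u - u^3/3 - v;  dv = eps * (u + beta + k*S).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    du = u - u ** 3 / 3.0 - v
    dv = params.epsilon * (u + params.beta + params.k * S)
    return du, dv


def rest_state(params: RDParameters) -> Tuple[float, float]:
    """Fixed point (u*, v*) of the local dynamics with the feedback term 0:
    u* = -beta, v* = u* - u*^3/3."""
    u = -params.beta
    return u, u - u ** 3 / 3.0


def uniform_rest_state(params: RDParameters, n_dofs: int) -> RDState:
    u, v = rest_state(params)
    return RDState(np.full(n_dofs, u), np.full(n_dofs, v))


# ---------------------------------------------------------------------------
# Discrete Laplace–Beltrami operator
# ---------------------------------------------------------------------------

@dataclass
class LBOperator:
    """Cotangent stiffness + barycentric lumped mass on the dof set.

    ``stiffness`` is the symmetric positive-semidefinite cotan matrix S with
    zero row sums; the Laplace–Beltrami operator acts as
    ``Lap(f) = -M^{-1} S f``.  Periodic vertex identifications are folded
    in; no-flux boundaries are natural (no extra rows).
    """

    stiffness: csr_matrix
    lumped_mass: np.ndarray
    boundary: str = "natural"

    @property
    def n_dofs(self) -> int:
        return len(self.lumped_mass)

    def apply(self, f: np.ndarray) -> np.ndarray:
        """Pointwise Laplace–Beltrami of a dof field: -M^{-1} S f."""
        return -(self.stiffness @ f) / self.lumped_mass


def assemble_laplace_beltrami(surface: TriSurface) -> LBOperator:
    """Assemble the cotangent FEM Laplace–Beltrami operator.

    Per triangle with corner angles alpha_i, the edge opposite corner i gets
    weight cot(alpha_i)/2; geometry is taken from the embedded (unfolded)
    vertices, then rows/columns are folded onto dofs, so a periodic seam
    behaves exactly like interior.
    """
    v = surface.vertices
    f = surface.faces
    areas = surface.face_areas
    if (areas <= 1e-14).any():
        raise SurfaceError("degenerate (zero-area) triangles in surface")

    i0, i1, i2 = f[:, 0], f[:, 1], f[:, 2]
    e0 = v[i2] - v[i1]   # edge opposite corner 0
    e1 = v[i0] - v[i2]
    e2 = v[i1] - v[i0]
    # cot(alpha_k) = -e_i . e_j / (2 * area), for {i,j} != k
    cot0 = -np.einsum("ij,ij->i", e1, e2) / (2 * areas)
    cot1 = -np.einsum("ij,ij->i", e2, e0) / (2 * areas)
    cot2 = -np.einsum("ij,ij->i", e0, e1) / (2 * areas)

    ff = surface.folded_faces
    j0, j1, j2 = ff[:, 0], ff[:, 1], ff[:, 2]
    rows, cols, vals = [], [], []
    for (a, b, w) in ((j1, j2, cot0), (j2, j0, cot1), (j0, j1, cot2)):
        half = 0.5 * w
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [-half, -half, half, half]
    n = surface.n_dofs
    S = coo_matrix((np.concatenate(vals),
                    (np.concatenate(rows), np.concatenate(cols))),
                   shape=(n, n)).tocsr()
    S.sum_duplicates()
    # cancel float round-off so constants are annihilated exactly
    from scipy.sparse import diags
    S = (S - diags(np.asarray(S.sum(axis=1)).ravel())).tocsr()
    M = surface.vertex_areas(folded=True)
    if (M <= 0).any():
        raise SurfaceError("dofs with zero lumped mass")
    boundary = "natural" if surface.dof_map is None else "periodic"
    return LBOperator(stiffness=S, lumped_mass=M, boundary=boundary)


def excited_area(state: RDState, op_or_surface, params: Optional[RDParameters] = None
                 ) -> float:
    """Excited surface area S = sum of lumped masses where u > threshold.

    This is the discrete Heaviside integral driving the global feedback;
    accepts either an :class:`LBOperator` or a :class:`TriSurface`.
    """
    if isinstance(op_or_surface, LBOperator):
        mass = op_or_surface.lumped_mass
    else:
        mass = op_or_surface.vertex_areas(folded=True)
    if len(mass) != len(state.u):
        raise ValueError("state is not congruent with the surface")
    thr = params.heaviside_threshold if params is not None else 0.0
    return float(mass[state.u > thr].sum())
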