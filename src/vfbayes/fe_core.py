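"""Constitutive law and global matrix assembly for linear triangles.

The fold is a plane-strain, in-plane isotropic, linear viscoelastic body.
Per layer the elasticity matrix acting on the engineering strain vector
[eps_xx, eps_zz, gamma_xz] is

    C = [[lam + 2 mu, lam,        0 ],
         [lam,        lam + 2 mu, 0 ],
         [0,          0,          mu]]

with Lame parameters mu = E / (2 (1 + nu)), lam = nu E / ((1 + nu)(1 - 2 nu)).
Viscous damping follows the Kelvin-Voigt substitution mu -> mu + eta d/dt
applied where the shear modulus appears in the Lame split
C = lam * J + mu * S, J = [[1,1,0],[1,1,0],[0,0,0]], S = diag(2, 2, 1):
the stress gains the term eta S eps_dot, so the damping integrand is
eta B^T S B.  Substituting into the factored form C / mu instead would
damp dilatation with the quasi-incompressible amplification
(lam + 2 mu)/mu ~ 2000 at nu = 0.4995, which suppresses self-oscillation
at any physical viscosity; the shear-only form is the one that leaves the
fold able to phonate at the viscosities the silicone priors span.

Assembly is the standard constant-strain-triangle construction with the
consistent mass matrix; the degree-of-freedom ordering is
[alpha_1..alpha_N, beta_1..beta_N] (all x displacements, then all z).
Mesh coordinates are millimetres; assembly converts to SI metres, with unit
out-of-plane depth (the anterior-posterior length enters only in observed
quantities).  Viscosity is carried in Poise and converted to Pa s here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MaterialProperties",
    "ConstitutiveMatrices",
    "SystemMatrices",
    "ConstitutiveDomainError",
    "SingularElementError",
    "DegenerateSystemError",
    "lame_parameters",
    "constitutive",
    "element_matrices",
    "assemble",
    "apply_constraints",
    "POISE_TO_PA_S",
]

POISE_TO_PA_S = 0.1
MM = 1e-3  # mesh unit -> metres


class ConstitutiveDomainError(ValueError):
    """(E, nu) outside the positive-definiteness domain E > 0, -1 < nu < 1/2."""


class SingularElementError(ValueError):
    pass


class DegenerateSystemError(ValueError):
    pass


@dataclass(frozen=True)
class MaterialProperties:
    """Parameter vector of the fold model (SI units unless suffixed).

    ``e_bdy``, ``e_cvr``, ``e_lig`` are the layer Young's moduli in Pa;
    ``rho`` kg/m^3; ``eta_poise`` in Poise (1 P = 0.1 Pa s); ``p_sub`` /
    ``p_sup`` in Pa; ``x0_mm`` caps the initial x-coordinate of every node
    (midline value = no medial compression).
    """

    rho: float = 1049.75
    eta_poise: float = 3.0
    e_bdy: float = 11.8e3
    e_cvr: float = 600.0
    e_lig: float = 2.0e3
    nu: float = 0.4995
    p_sub: float = 1000.0
    p_sup: float = 0.0
    x0_mm: float = 8.40

    def __post_init__(self):
        for name in ("e_bdy", "e_cvr", "e_lig"):
            if getattr(self, name) <= 0:
                raise ConstitutiveDomainError(f"{name} must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ConstitutiveDomainError("nu must lie in (-1, 1/2)")
        if self.rho <= 0:
            raise ConstitutiveDomainError("rho must be positive")
        if self.eta_poise < 0:
            raise ConstitutiveDomainError("eta must be non-negative")
        if self.x0_mm < 0:
            raise ConstitutiveDomainError("x0 must be non-negative")

    @property
    def eta(self) -> float:
        """Viscosity in Pa s."""
        return self.eta_poise * POISE_TO_PA_S

    def layer_modulus(self, layer_index: int) -> float:
        return (self.e_bdy, self.e_lig, self.e_cvr)[layer_index]

    def with_(self, **kw) -> "MaterialProperties":
        return replace(self, **kw)


#: dilatational and shear shape matrices of the Lame split C = lam J + mu S
LAME_J = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
SHEAR_S = np.array([[2.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class ConstitutiveMatrices:
    C: np.ndarray  # 3x3 plane-strain elasticity matrix, Pa
    S: np.ndarray  # viscous shape matrix (shear part), C = lam J + mu S
    mu: float
    lam: float


def lame_parameters(E: float, nu: float) -> tuple[float, float]:
    """Lame parameters (mu, lam) from Young's modulus and Poisson ratio."""
    if E <= 0 or not -1.0 < nu < 0.5:
        raise ConstitutiveDomainError(
            f"(E, nu) = ({E}, {nu}) outside the admissible domain"
        )
    mu = E / (2.0 * (1.0 + nu))
    lam = nu * E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu, lam


def constitutive(E: float, nu: float) -> ConstitutiveMatrices:
    mu, lam = lame_parameters(E, nu)
    C = lam * LAME_J + mu * SHEAR_S
    return ConstitutiveMatrices(C=C, S=SHEAR_S.copy(), mu=mu, lam=lam)


# ---------------------------------------------------------------------------
# element level


def _strain_displacement(coords_m: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant B matrix (3 x 6) and area for a linear triangle.

    Local dof order [a1, a2, a3, b1, b2, b3] (x displacements then z).
    """
    x, z = coords_m[:, 0], coords_m[:, 1]
    area = 0.5 * (
        (x[1] - x[0]) * (z[2] - z[0]) - (x[2] - x[0]) * (z[1] - z[0])
    )
    if area <= 0:
        raise SingularElementError(f"non-positive element area {area}")
    b = np.array([z[1] - z[2], z[2] - z[0], z[0] - z[1]]) / (2 * area)
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]]) / (2 * area)
    B = np.zeros((3, 6))
    B[0, :3] = b
    B[1, 3:] = c
    B[2, :3] = c
    B[2, 3:] = b
    return B, area


def element_matrices(
    coords_mm: np.ndarray, props: MaterialProperties, layer_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Consistent (Me, De, Ke) for one triangle, local dofs [a1..3, b1..3].

    Unit out-of-plane depth; exact closed forms (constant-strain element).
    """
    B, area = _strain_displacement(np.asarray(coords_mm, float) * MM)
    cm = constitutive(props.layer_modulus(layer_index), props.nu)
    mass_block = props.rho * area / 12.0 * np.array(
        [[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]
    )
    Me = np.zeros((6, 6))
    Me[:3, :3] = mass_block
    Me[3:, 3:] = mass_block
    Ke = area * B.T @ cm.C @ B
    De = area * B.T @ (props.eta * cm.S) @ B
    return Me, De, Ke


# ---------------------------------------------------------------------------
# global level


@dataclass
class SystemMatrices:
    """Assembled global operators (CSR) with constraint bookkeeping.

    Before :func:`apply_constraints`, ``free_dofs`` covers all 2N dofs.
    After, M/D/K are the reduced operators on the free dofs and
    ``free_dofs`` maps reduced index -> original dof (x dof of node i is
    ``i``, z dof is ``n_nodes + i``).
    """

    M: sp.csr_matrix
    D: sp.csr_matrix
    K: sp.csr_matrix
    n_nodes: int
    free_dofs: np.ndarray
    fixed_dofs: np.ndarray

    def dof_map(self, node: int) -> tuple[int, int]:
        return node, self.n_nodes + node

    @property
    def reduced_index(self) -> np.ndarray:
        """original dof -> reduced index (-1 if fixed)."""
        idx = np.full(2 * self.n_nodes, -1, np.int64)
        idx[self.free_dofs] = np.arange(len(self.free_dofs))
        return idx


def assemble(
    mesh, props: MaterialProperties, volumetric: str = "nodal"
) -> SystemMatrices:
    """Scatter-add element matrices into global sparse M, D, K.

    ``volumetric`` selects how the dilatational (lambda) part of the
    stiffness is integrated:

    * ``"nodal"`` (default): mean-dilatation mixed integration -- the
      volumetric strain is averaged over node-centred patches before being
      penalised.  Constant-strain triangles lock volumetrically at
      nu = 0.4995 (the discrete incompressibility constraints outnumber
      the dofs), which stiffens the fold by roughly an order of magnitude
      and suppresses self-oscillation entirely; nodal averaging restores
      the physical compliance while passing the uniform-strain patch test
      and preserving the rigid-body nullspace.
    * ``"element"``: the textbook displacement form (exact per-element
      integration of the full C), available for comparison studies.

    The shear part and the viscous damping are element-wise in either mode.
    """
    n = mesh.n_nodes
    if mesh.layer_of_element.min() < 0 or mesh.layer_of_element.max() > 2:
        raise ValueError("inconsistent layer label")
    if volumetric not in ("nodal", "element"):
        raise ValueError("volumetric must be 'nodal' or 'element'")
    rows, cols = [], []
    mv, dv, kv = [], [], []
    # nodal mean-dilatation bookkeeping
    g_rows, g_cols, g_vals = [], [], []
    node_vol = np.zeros(n)
    node_lam_vol = np.zeros(n)
    for tri, lay in zip(mesh.triangles, mesh.layer_of_element):
        coords_m = mesh.node_coords[tri] * MM
        B, area = _strain_displacement(coords_m)
        cm = constitutive(props.layer_modulus(int(lay)), props.nu)
        mass_block = props.rho * area / 12.0 * np.array(
            [[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]
        )
        Me = np.zeros((6, 6))
        Me[:3, :3] = mass_block
        Me[3:, 3:] = mass_block
        De = area * B.T @ (props.eta * cm.S) @ B
        if volumetric == "element":
            Ke = area * B.T @ cm.C @ B
        else:
            Ke = area * B.T @ (cm.mu * SHEAR_S) @ B
            div = B[0] + B[1]  # constant dilatation operator of the element
            for a in range(3):
                node = tri[a]
                w = area / 3.0
                node_vol[node] += w
                node_lam_vol[node] += w * cm.lam
                gdof_e = np.concatenate([tri, n + tri])
                g_rows.append(np.full(6, node))
                g_cols.append(gdof_e)
                g_vals.append(w * div)
        gdof = np.concatenate([tri, n + tri])
        rr, cc = np.meshgrid(gdof, gdof, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        mv.append(Me.ravel())
        dv.append(De.ravel())
        kv.append(Ke.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    shape = (2 * n, 2 * n)
    M = sp.coo_matrix((np.concatenate(mv), (rows, cols)), shape=shape).tocsr()
    D = sp.coo_matrix((np.concatenate(dv), (rows, cols)), shape=shape).tocsr()
    K = sp.coo_matrix((np.concatenate(kv), (rows, cols)), shape=shape).tocsr()
    if volumetric == "nodal":
        G = sp.coo_matrix(
            (
                np.concatenate(g_vals),
                (np.concatenate(g_rows), np.concatenate(g_cols)),
            ),
            shape=(n, 2 * n),
        ).tocsr()
        inv_vol = sp.diags(1.0 / node_vol)
        G = inv_vol @ G  # row i = volume-averaged dilatation at node i
        lam_node = node_lam_vol / node_vol  # patch-averaged lambda
        K = K + G.T @ sp.diags(lam_node * node_vol) @ G
        K = K.tocsr()
    return SystemMatrices(
        M=M,
        D=D,
        K=K,
        n_nodes=n,
        free_dofs=np.arange(2 * n, dtype=np.int64),
        fixed_dofs=np.empty(0, np.int64),
    )


def apply_constraints(sys: SystemMatrices, fixed_nodes) -> SystemMatrices:
    """Eliminate both dofs of each fixed node (row/column removal)."""
    fixed_nodes = np.asarray(fixed_nodes, np.int64)
    n = sys.n_nodes
    fixed = np.unique(np.concatenate([fixed_nodes, n + fixed_nodes]))
    mask = np.ones(2 * n, bool)
    mask[fixed] = False
    free = np.nonzero(mask)[0]
    if free.size == 0:
        raise DegenerateSystemError("all nodes fixed")
    return SystemMatrices(
        M=sys.M[np.ix_(free, free)].tocsr(),
        D=sys.D[np.ix_(free, free)].tocsr(),
        K=sys.K[np.ix_(free, free)].tocsr(),
        n_nodes=n,
        free_dofs=free,
        fixed_dofs=fixed,
    )


def export_matrix_market(sys: SystemMatrices, prefix) -> None:
    """Debug export of M, D, K as MatrixMarket files ``<prefix>_{M,D,K}.mtx``."""
    from scipy.io import mmwrite

    for name, mat in (("M", sys.M), ("D", sys.D), ("K", sys.K)):
        mmwrite(f"{prefix}_{name}.mtx", mat)
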