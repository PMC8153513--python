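"""Time integration of M th'' + D th' + K th = F with midline contact.

Scheme
------
The semi-discrete system is advanced with a three-level finite-difference
scheme: central differences for the inertia and damping terms and the
stiffness term averaged over the two outer levels,

    M (th_{n+1} - 2 th_n + th_{n-1}) / h^2
  + D (th_{n+1} - th_{n-1}) / (2 h)
  + K (th_{n+1} + th_{n-1}) / 2  =  F_n .

Averaging K over th_{n+1} and th_{n-1} keeps the scheme second-order and
exactly non-dissipative for eta = 0 while making it unconditionally
stable.  Stability matters here: with nu = 0.4995 the dilatational wave
speed in the stiffest layer is ~60 m/s, so at the default h = 0.05 ms a
fully explicit update would sit far beyond its omega*h < 2 limit on any
mesh of practical density.  The update solves

    (M/h^2 + D/2h + K/2) th_{n+1} = F_n + (2M/h^2) th_n
                                    - (M/h^2 - D/2h + K/2) th_{n-1},

with the left-hand operator factorised once per simulation (a dense
inverse; the constrained systems here have a few hundred dofs).

Contact
-------
Collision with the opposing (mirror-image) fold is a hard midline
constraint: any node whose x-coordinate crosses the midline after a step
is projected back onto it.  The force required to hold it there is read
off as the residual of the discretised momentum balance at the clamped
dof, which is compressive while contact persists; a node is released
simply by the unconstrained update carrying it off the wall.  Holding a
node at the midline across consecutive steps makes its centred velocity
vanish, so no separate velocity reset is applied.

Medial compression
------------------
A pre-phonatory squeeze is imposed through ``x0``: before integration the
static problem K th0 = F_c is solved under the constraint that no node
x-coordinate exceeds ``x0``, by an active-set iteration (clamp every node
proud of x0, relax the rest, clamp new violators, release tensile
reactions).  For this linear material the fixed point is path-independent,
so the iteration reproduces the limit of pushing nodes medially in small
increments with elastic relaxation in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla
from numba import njit

from .aeroforce import (
    A_FLOOR_MM2,
    _area_profile,
    _bernoulli,
    _nodal_forces,
    flow_rate,
)
from .fe_core import MaterialProperties, SystemMatrices, assemble, apply_constraints

__all__ = [
    "SimState",
    "SimulationResult",
    "Integrator",
    "PrestressError",
    "IntegrationBlowupError",
    "prestress_solve",
    "step",
    "enforce_contact",
    "contact_pressure",
    "simulate",
    "DEFAULT_H_MS",
    "DEFAULT_DURATION_MS",
]

DEFAULT_H_MS = 0.05
DEFAULT_DURATION_MS = 550.0
BLOWUP_DISP_M = 0.05  # |displacement| beyond 50 mm is unphysical
MM = 1e-3


class PrestressError(RuntimeError):
    pass


class IntegrationBlowupError(RuntimeError):
    def __init__(self, step_index: int, msg: str = ""):
        self.step_index = step_index
        super().__init__(msg or f"integration blew up at step {step_index}")


# ---------------------------------------------------------------------------
# pre-stress (medial compression)


def prestress_solve(
    sys: SystemMatrices,
    mesh,
    x0_mm: float,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> np.ndarray:
    """Static displacement (metres, reduced dofs) with every node x <= x0.

    Returns zeros when the resting geometry already satisfies the cap.
    Raises :class:`PrestressError` on active-set non-convergence.
    """
    midline = mesh.geometry.midline_x if mesh.geometry is not None else None
    if midline is not None and not 0.0 <= x0_mm <= midline + 1e-12:
        raise PrestressError(f"x0 = {x0_mm} mm outside [0, midline]")
    nf = len(sys.free_dofs)
    # reduced indices that are x dofs, with their rest coordinates (mm)
    is_x = sys.free_dofs < sys.n_nodes
    x_red = np.nonzero(is_x)[0]
    x_rest = mesh.node_coords[sys.free_dofs[x_red], 0]

    theta = np.zeros(nf)
    active = x_red[x_rest > x0_mm + 1e-12]
    if active.size == 0:
        return theta
    K = sys.K.tocsc()
    for _ in range(max_iter):
        target = (x0_mm - x_rest[np.searchsorted(x_red, active)]) * MM
        mask = np.ones(nf, bool)
        mask[active] = False
        ff = np.nonzero(mask)[0]
        rhs = -K[np.ix_(ff, active)] @ target
        theta = np.zeros(nf)
        theta[active] = target
        theta[ff] = spla.spsolve(K[np.ix_(ff, ff)].tocsc(), rhs)
        pos = x_rest + theta[x_red] * 1e3
        violators = x_red[pos > x0_mm + 1e-9]
        reaction = (K @ theta)[active]
        tensile = active[reaction > tol * max(1.0, np.abs(reaction).max())]
        new_active = np.unique(np.concatenate([active, violators]))
        new_active = np.setdiff1d(new_active, tensile)
        if new_active.size == 0:
            raise PrestressError("active set emptied while cap still violated")
        if np.array_equal(new_active, active) and violators.size == 0:
            resid = K @ theta
            resid[active] = 0.0
            scale = max(np.abs(K @ theta).max(), 1e-30)
            if np.abs(resid).max() > 1e-8 * scale:
                raise PrestressError(
                    f"static residual {np.abs(resid).max():.3e} above tolerance"
                )
            return theta
        active = new_active
    raise PrestressError(f"active set did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# integrator operators


@dataclass
class SimState:
    """Integrator state after a step (displacements in metres, reduced dofs)."""

    t: float
    theta: np.ndarray
    theta_prev: np.ndarray
    contact_set: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    contact_force: np.ndarray = field(default_factory=lambda: np.empty(0))
    _unconstrained: np.ndarray | None = None
    _rhs: np.ndarray | None = None

    @property
    def theta_dot(self) -> np.ndarray:
        """Backward-difference velocity diagnostic (m/s); the scheme itself
        is displacement-only."""
        return (self.theta - self.theta_prev) / self._h

    _h: float = 1.0


class Integrator:
    """Dense operators for the three-level scheme on the constrained system."""

    def __init__(self, sys: SystemMatrices, mesh, h_s: float):
        self.sys = sys
        self.mesh = mesh
        self.h = h_s
        M = sys.M.toarray()
        D = sys.D.toarray()
        K = sys.K.toarray()
        self.A = M / h_s**2 + D / (2 * h_s) + K / 2.0
        self.Ainv = np.linalg.inv(self.A)
        self.C1 = 2.0 * M / h_s**2
        self.C2 = -(M / h_s**2 - D / (2 * h_s) + K / 2.0)
        # x-dof bookkeeping for midline contact
        is_x = sys.free_dofs < sys.n_nodes
        self.x_red = np.nonzero(is_x)[0].astype(np.int64)
        self.x_rest_mm = mesh.node_coords[sys.free_dofs[self.x_red], 0].copy()
        self.midline_mm = mesh.geometry.midline_x

    def step(self, state: SimState, F_ext: np.ndarray) -> SimState:
        """One unconstrained update; contact is enforced separately."""
        b = F_ext + self.C1 @ state.theta + self.C2 @ state.theta_prev
        theta_new = self.Ainv @ b
        if not np.all(np.isfinite(theta_new)) or (
            np.abs(theta_new).max() > BLOWUP_DISP_M
        ):
            raise IntegrationBlowupError(int(round(state.t / self.h)) + 1)
        out = SimState(
            t=state.t + self.h,
            theta=theta_new,
            theta_prev=state.theta.copy(),
            _unconstrained=theta_new.copy(),
            _rhs=b,
        )
        out._h = self.h
        return out

    def enforce_contact(self, state: SimState) -> SimState:
        """Project penetrating nodes onto the midline and record the
        compressive holding force (N per unit depth) from the step residual."""
        pos = self.x_rest_mm + state.theta[self.x_red] * 1e3
        pen = pos > self.midline_mm
        if not np.any(pen):
            state.contact_set = np.empty(0, np.int64)
            state.contact_force = np.empty(0)
            return state
        clamped = self.x_red[pen]
        theta_unc = (
            state._unconstrained if state._unconstrained is not None else state.theta
        )
        state.theta = state.theta.copy()
        state.theta[clamped] = (
            self.midline_mm - self.x_rest_mm[pen]
        ) * MM
        delta = state.theta[clamped] - theta_unc[clamped]
        # residual of the discrete momentum balance at the clamped dofs:
        # A th_proj - b = A (th_proj - th_unc), nonzero only through the
        # clamped columns
        f_wall = self.A[np.ix_(clamped, clamped)] @ delta
        state.contact_set = self.sys.free_dofs[clamped]
        state.contact_force = -f_wall  # compressive > 0
        return state


def step(state: SimState, integ: Integrator, F_ext: np.ndarray, h: float) -> SimState:
    if abs(h - integ.h) > 1e-15:
        raise ValueError("step size must match the integrator operators")
    return integ.step(state, F_ext)


def enforce_contact(state: SimState, integ: Integrator) -> SimState:
    return integ.enforce_contact(state)


# ---------------------------------------------------------------------------
# fused simulation kernel


@njit(cache=True)
def _run_kernel(
    Ainv,
    A,
    C1,
    C2,
    theta0,
    n_steps,
    h,
    x_red,
    x_rest_mm,
    chain_ix,
    chain_iz,
    chain_x0,
    chain_z0,
    chain_pos_of_xdof,
    midline_mm,
    l_gl_mm,
    p_sub,
    p_sup,
    a_floor,
    supraglottal_mode,
    record_hist,
    theta_hist,
    F_hist,
    gaw,
    a_min_out,
    contact_out,
    blow_disp,
):
    nf = theta0.shape[0]
    n_chain = chain_ix.shape[0]
    theta_prev = theta0.copy()
    theta_cur = theta0.copy()
    chain = np.empty((n_chain, 2))
    if record_hist:
        theta_hist[0] = theta0
    for n in range(n_steps):
        # deformed surface chain (mm)
        for k in range(n_chain):
            dx = theta_cur[chain_ix[k]] * 1e3 if chain_ix[k] >= 0 else 0.0
            dz = theta_cur[chain_iz[k]] * 1e3 if chain_iz[k] >= 0 else 0.0
            chain[k, 0] = chain_x0[k] + dx
            chain[k, 1] = chain_z0[k] + dz
        A_prof = _area_profile(chain[:, 0], midline_mm, l_gl_mm, a_floor)
        p, a_min = _bernoulli(A_prof, p_sub, p_sup, supraglottal_mode)
        Fsurf = _nodal_forces(p, chain)
        F = np.zeros(nf)
        for k in range(n_chain):
            if chain_ix[k] >= 0:
                F[chain_ix[k]] += Fsurf[k, 0]
            if chain_iz[k] >= 0:
                F[chain_iz[k]] += Fsurf[k, 1]
        b = F + C1 @ theta_cur + C2 @ theta_prev
        theta_new = Ainv @ b
        # midline contact: project and record the holding force
        max_abs = 0.0
        for i in range(nf):
            a = abs(theta_new[i])
            if a > max_abs:
                max_abs = a
        if not np.isfinite(max_abs) or max_abs > blow_disp:
            return n + 1
        n_clamp = 0
        for j in range(x_red.shape[0]):
            i = x_red[j]
            if x_rest_mm[j] + theta_new[i] * 1e3 > midline_mm:
                n_clamp += 1
        if n_clamp > 0:
            cl = np.empty(n_clamp, np.int64)
            cj = np.empty(n_clamp, np.int64)
            m = 0
            for j in range(x_red.shape[0]):
                i = x_red[j]
                if x_rest_mm[j] + theta_new[i] * 1e3 > midline_mm:
                    cl[m] = i
                    cj[m] = j
                    m += 1
            delta = np.empty(n_clamp)
            for m in range(n_clamp):
                old = theta_new[cl[m]]
                theta_new[cl[m]] = (midline_mm - x_rest_mm[cj[m]]) * MM_
                delta[m] = theta_new[cl[m]] - old
            for m in range(n_clamp):
                f = 0.0
                for mm2 in range(n_clamp):
                    f += A[cl[m], cl[mm2]] * delta[mm2]
                pos = chain_pos_of_xdof[cl[m]]
                if pos >= 0:
                    contact_out[n, pos] = -f
        # observables at the new state
        wmax = -1e30
        for k in range(n_chain):
            dx = theta_new[chain_ix[k]] * 1e3 if chain_ix[k] >= 0 else 0.0
            xk = chain_x0[k] + dx
            if xk > wmax:
                wmax = xk
        hw = midline_mm - wmax
        if hw < 0.0:
            hw = 0.0
        gaw[n] = 2.0 * hw * l_gl_mm
        a_min_out[n] = a_min
        if record_hist:
            theta_hist[n + 1] = theta_new
            F_hist[n] = F
        theta_prev = theta_cur
        theta_cur = theta_new
    return 0


MM_ = 1e-3  # module-level constant visible to the jitted kernel


# ---------------------------------------------------------------------------
# results


@dataclass
class SimulationResult:
    """Output of :func:`simulate`, sampled at the solver rate 1/h."""

    times: np.ndarray  # s, sample k is the state after step k+1
    gaw_raw: np.ndarray  # glottal area, mm^2
    a_min_series: np.ndarray  # minimum channel area, mm^2
    q_series: np.ndarray  # Bernoulli flow rate, mL/s
    contact_force_series: np.ndarray  # (n, n_chain) N per unit depth
    h_s: float
    props: MaterialProperties
    mesh: object
    status: str = "ok"
    failed_step: int = -1
    theta_hist: np.ndarray | None = None  # (n+1, nf) incl. initial state
    F_hist: np.ndarray | None = None  # (n, nf) aero load per step
    sys: SystemMatrices | None = None
    theta0: np.ndarray | None = None

    @property
    def fps(self) -> float:
        """Solver output rate in frames/s (h = 0.05 ms -> 20,000 fps)."""
        return 1.0 / self.h_s

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def contact_pressure_series(self) -> np.ndarray:
        """(n, n_chain) contact pressure in Pa (tributary-length convention)."""
        trib = _tributary_lengths_m(self.mesh)
        return self.contact_force_series / trib[None, :]

    def node_trajectories(self) -> np.ndarray:
        if self.theta_hist is None:
            raise ValueError("simulation was run without record_history=True")
        return self.theta_hist


def _surface_chain_nodes(mesh) -> np.ndarray:
    chain = getattr(mesh, "surface_chain", None)
    if chain is not None:
        return chain
    return mesh.free_surface


def _tributary_lengths_m(mesh) -> np.ndarray:
    """Half the sum of adjacent surface-edge lengths per chain node (m)."""
    chain = _surface_chain_nodes(mesh)
    xy = mesh.node_coords[chain] * MM
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    trib = np.zeros(len(chain))
    trib[:-1] += 0.5 * seg
    trib[1:] += 0.5 * seg
    return trib


def contact_pressure(contact_force_per_depth: np.ndarray, mesh) -> np.ndarray:
    """Contact force (N per unit depth) -> pressure (Pa).

    The nodal force in newtons is the per-depth value times the glottal
    length; dividing by tributary length x glottal length cancels the
    length, so pressure = per-depth force / tributary length.
    """
    return np.asarray(contact_force_per_depth) / _tributary_lengths_m(mesh)


# ---------------------------------------------------------------------------
# driver


def simulate(
    props: MaterialProperties,
    mesh,
    duration_ms: float = DEFAULT_DURATION_MS,
    h_ms: float = DEFAULT_H_MS,
    record_history: bool = False,
    supraglottal_mode: bool = True,
    catch_blowup: bool = False,
    engine: str = "numba",
) -> SimulationResult:
    """Self-oscillation run: pre-stress, then the aero/step/contact loop.

    Deterministic for fixed inputs.  Unstable parameter draws raise
    :class:`IntegrationBlowupError` unless ``catch_blowup`` is set, in
    which case a result with ``status='failed'`` is returned (the sampler
    maps it to zero weight).
    """
    geom = mesh.geometry
    if geom is None:
        raise ValueError("mesh must carry its geometry")
    h = h_ms * 1e-3
    n_steps = int(round(duration_ms / h_ms))
    sys0 = assemble(mesh, props)
    sys = apply_constraints(sys0, mesh.fixed_nodes)
    theta0 = prestress_solve(sys, mesh, min(props.x0_mm, geom.midline_x))
    integ = Integrator(sys, mesh, h)

    chain_nodes = _surface_chain_nodes(mesh)
    red = sys.reduced_index
    chain_ix = red[chain_nodes].astype(np.int64)
    chain_iz = red[sys.n_nodes + chain_nodes].astype(np.int64)
    chain_x0 = mesh.node_coords[chain_nodes, 0].copy()
    chain_z0 = mesh.node_coords[chain_nodes, 1].copy()
    chain_pos = np.full(len(sys.free_dofs), -1, np.int64)
    for k, ix in enumerate(chain_ix):
        if ix >= 0:
            chain_pos[ix] = k

    nf = len(sys.free_dofs)
    gaw = np.zeros(n_steps)
    a_min = np.zeros(n_steps)
    contact = np.zeros((n_steps, len(chain_nodes)))
    theta_hist = np.zeros((n_steps + 1, nf) if record_history else (1, 1))
    F_hist = np.zeros((n_steps, nf) if record_history else (1, 1))

    if engine == "numba":
        failed_at = _run_kernel(
            integ.Ainv,
            integ.A,
            integ.C1,
            integ.C2,
            theta0,
            n_steps,
            h,
            integ.x_red,
            integ.x_rest_mm,
            chain_ix,
            chain_iz,
            chain_x0,
            chain_z0,
            chain_pos,
            geom.midline_x,
            geom.length_ap,
            props.p_sub,
            props.p_sup,
            A_FLOOR_MM2,
            supraglottal_mode,
            record_history,
            theta_hist,
            F_hist,
            gaw,
            a_min,
            contact,
            BLOWUP_DISP_M,
        )
    else:
        failed_at = _run_python(
            integ,
            theta0,
            n_steps,
            chain_ix,
            chain_iz,
            chain_x0,
            chain_z0,
            chain_pos,
            geom,
            props,
            supraglottal_mode,
            record_history,
            theta_hist,
            F_hist,
            gaw,
            a_min,
            contact,
        )

    status = "ok" if failed_at == 0 else "failed"
    if status == "failed" and not catch_blowup:
        raise IntegrationBlowupError(
            failed_at,
            f"integration blew up at step {failed_at} "
            f"(p_sub={props.p_sub}, E=({props.e_bdy}, {props.e_cvr}, "
            f"{props.e_lig}), rho={props.rho}, eta={props.eta_poise} P, "
            f"x0={props.x0_mm})",
        )
    times = (np.arange(n_steps) + 1) * h
    return SimulationResult(
        times=times,
        gaw_raw=gaw,
        a_min_series=a_min,
        q_series=flow_rate(a_min, props.p_sub, props.p_sup),
        contact_force_series=contact,
        h_s=h,
        props=props,
        mesh=mesh,
        status=status,
        failed_step=failed_at if failed_at else -1,
        theta_hist=theta_hist if record_history else None,
        F_hist=F_hist if record_history else None,
        sys=sys,
        theta0=theta0,
    )


def _run_python(
    integ,
    theta0,
    n_steps,
    chain_ix,
    chain_iz,
    chain_x0,
    chain_z0,
    chain_pos,
    geom,
    props,
    supraglottal_mode,
    record_hist,
    theta_hist,
    F_hist,
    gaw,
    a_min_out,
    contact_out,
):
    """Reference pure-python loop built from the public step/contact ops;
    must match the fused kernel bit-for-bit on stable runs."""
    from .aeroforce import area_profile, bernoulli_pressure, nodal_forces

    nf = theta0.shape[0]
    state = SimState(t=0.0, theta=theta0.copy(), theta_prev=theta0.copy())
    state._h = integ.h
    if record_hist:
        theta_hist[0] = theta0
    for n in range(n_steps):
        dx = np.where(chain_ix >= 0, state.theta[np.maximum(chain_ix, 0)], 0.0)
        dz = np.where(chain_iz >= 0, state.theta[np.maximum(chain_iz, 0)], 0.0)
        chain = np.stack([chain_x0 + dx * 1e3, chain_z0 + dz * 1e3], axis=1)
        A_prof = area_profile(chain, geom.midline_x, geom.length_ap)
        p = bernoulli_pressure(
            A_prof, props.p_sub, props.p_sup, supraglottal_mode=supraglottal_mode
        )
        Fsurf = nodal_forces(p, chain)
        F = np.zeros(nf)
        np.add.at(F, chain_ix[chain_ix >= 0], Fsurf[chain_ix >= 0, 0])
        np.add.at(F, chain_iz[chain_iz >= 0], Fsurf[chain_iz >= 0, 1])
        try:
            state = integ.step(state, F)
        except IntegrationBlowupError:
            return n + 1
        state = integ.enforce_contact(state)
        for dof, f in zip(state.contact_set, state.contact_force):
            pos = chain_pos[np.nonzero(integ.sys.free_dofs == dof)[0][0]]
            if pos >= 0:
                contact_out[n, pos] = f
        dxn = np.where(chain_ix >= 0, state.theta[np.maximum(chain_ix, 0)], 0.0)
        xk = chain_x0 + dxn * 1e3
        gaw[n] = 2.0 * max(0.0, geom.midline_x - xk.max()) * geom.length_ap
        a_min_out[n] = A_prof.min()
        if record_hist:
            theta_hist[n + 1] = state.theta
            F_hist[n] = F
    return 0
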