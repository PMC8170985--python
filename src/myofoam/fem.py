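"""Minimal explicit-dynamics finite element solver.

Trilinear hex8 elements with full 2x2x2 Gauss quadrature, lumped mass,
internal forces from the hyperelastic foam material, central-difference time
integration under the CFL critical time step (with optional selective mass
scaling to a target step), and rigid-plane penalty contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .material import DeformationState, FoamMaterial, RateDependentFoam
from .metrics import ElementHistory, effective_strain

log = logging.getLogger(__name__)

Material = FoamMaterial | RateDependentFoam


class NegativeVolumeError(RuntimeError):
    """An element Jacobian went non-positive during the run."""

    def __init__(self, element: int):
        super().__init__(f"negative volume error in element {element}")
        self.element = element


class InstabilityError(RuntimeError):
    """Kinetic energy grew beyond the configured ratio."""


# ---------------------------------------------------------------------------
# hex8 shape functions

_XI_NODES = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)

_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = _XI_NODES * _G  # 2x2x2, unit weights

_FACES = np.array(
    [
        [0, 1, 2, 3], [4, 5, 6, 7], [0, 1, 5, 4],
        [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7],
    ]
)


def _shape_gradients() -> np.ndarray:
    """dN_a/dxi at each Gauss point, shape (8 gp, 8 nodes, 3)."""
    out = np.empty((8, 8, 3))
    for g, xi in enumerate(GAUSS_POINTS):
        for a, s in enumerate(_XI_NODES):
            out[g, a, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
            out[g, a, 1] = 0.125 * s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2])
            out[g, a, 2] = 0.125 * s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1])
    return out


_DNDXI = _shape_gradients()


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Mesh:
    """Hex8 mesh with part ids per element."""

    nodes: np.ndarray        # (N, 3)
    elements: np.ndarray     # (E, 8) node indices
    element_part: np.ndarray  # (E,)
    part_labels: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        self.element_part = np.asarray(self.element_part, dtype=int)
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError("elements must be (E, 8)")
        if self.elements.max(initial=-1) >= len(self.nodes):
            raise ValueError("element references a missing node")
        if len(self.element_part) != len(self.elements):
            raise ValueError("element_part length mismatch")
        grads, det = _ref_gradients(self.nodes, self.elements)
        if np.any(det <= 0):
            e = int(np.argwhere(np.any(det <= 0, axis=1))[0, 0])
            raise ValueError(f"non-positive reference Jacobian in element {e}")
        self._dndX0 = grads
        self._gp_vol0 = det  # unit Gauss weights
        self.reference_volumes = det.sum(axis=1)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def characteristic_lengths(self) -> np.ndarray:
        """Per-element length: volume / largest face area."""
        X = self.nodes[self.elements]  # (E, 8, 3)
        areas = np.empty((self.n_elements, 6))
        for f, face in enumerate(_FACES):
            a, b, c, d = (X[:, i] for i in face)
            areas[:, f] = 0.5 * np.linalg.norm(np.cross(c - a, d - b), axis=1)
        return self.reference_volumes / areas.max(axis=1)


def _ref_gradients(nodes: np.ndarray, elements: np.ndarray):
    """Reference shape-function gradients dN/dX and gp volumes.

    Returns (dndX (E, 8gp, 8nodes, 3), detJ (E, 8gp)).
    """
    X = nodes[elements]  # (E, 8, 3)
    jac = np.einsum("eai,gaj->egij", X, _DNDXI)  # jac[i,j] = dX_i/dxi_j
    det = np.linalg.det(jac)
    inv = np.linalg.inv(jac)  # inv[i,j] = dxi_i/dX_j
    # dN_a/dX_j = dN_a/dxi_i * dxi_i/dX_j
    dndX = np.einsum("gai,egij->egaj", _DNDXI, inv)
    return dndX, det


@dataclass
class TimestepInfo:
    """CFL bookkeeping: per-element critical step and mass-scaling report."""

    char_length: np.ndarray
    wave_speed: np.ndarray
    dt_critical: np.ndarray
    dt: float
    safety: float
    added_mass: float = 0.0
    added_mass_pct: float = 0.0


@dataclass
class RigidPlane:
    """Penalty contact against an infinite rigid plane.

    Nodes on the negative side of ``normal`` (measured from ``point``)
    receive a normal force ``penalty * depth`` plus a dashpot term
    (``damping_ratio`` of critical for the node mass) that suppresses
    penalty chatter; the total normal force never pulls (no adhesion).
    """

    point: np.ndarray
    normal: np.ndarray
    penalty: float | None = None
    damping_ratio: float = 1.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(self.normal)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            raise ValueError("plane normal must be unit length")

    def forces(self, x: np.ndarray, v: np.ndarray | None = None,
               masses: np.ndarray | None = None) -> np.ndarray:
        depth = (self.point - x) @ self.normal  # > 0 means penetration
        f = np.zeros_like(x)
        pen = depth > 0
        fn = depth[pen] * self.penalty
        if v is not None and masses is not None and self.damping_ratio > 0:
            c = 2.0 * self.damping_ratio * np.sqrt(self.penalty * masses[pen])
            fn = fn - c * (v[pen] @ self.normal)
        f[pen] = np.outer(np.maximum(fn, 0.0), self.normal)
        return f


@dataclass
class SmoothRamp:
    """Prescribed displacement u(t) = amplitude * s(t / t_end), smoothstep."""

    nodes: np.ndarray
    dof: int
    amplitude: float
    t_end: float

    def __call__(self, t: float) -> float:
        tau = min(max(t / self.t_end, 0.0), 1.0)
        return self.amplitude * tau * tau * (3.0 - 2.0 * tau)


@dataclass
class PrescribedMotion:
    """Fixed-function displacement on a node set along one axis."""

    nodes: np.ndarray
    dof: int
    displacement: Callable[[float], float]


@dataclass
class SimulationConfig:
    termination: float = 0.05
    dt: float | None = None            # fixed step; None -> CFL auto
    dt2ms: float | None = None         # mass-scale to this target step
    safety: float = 0.9
    output_interval: float | None = None
    contacts: list[RigidPlane] = field(default_factory=list)
    gravity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    motions: list[PrescribedMotion | SmoothRamp] = field(default_factory=list)
    initial_velocity: np.ndarray | None = None
    damping_alpha: float = 0.0
    contact_penalty_factor: float = 0.1
    instability_ratio: float = 10.0
    rate_smoothing_tau: float = 1e-4   # EMA time constant for strain rate (s)
    seed: int = 0
    units: str = "si"

    def __post_init__(self) -> None:
        if self.termination <= 0:
            raise ValueError("termination time must be positive")
        if not 0 < self.safety <= 1:
            raise ValueError("safety factor must lie in (0, 1]")
        if self.output_interval is not None and self.output_interval <= 0:
            raise ValueError("output interval must be positive")
        self.gravity = np.asarray(self.gravity, dtype=float)


@dataclass
class RunResult:
    times: np.ndarray
    element_histories: list[ElementHistory]
    node_displacements: np.ndarray       # (T, N, 3)
    contact_force: np.ndarray            # (T, 3) resultant over all planes
    energy: dict[str, np.ndarray]
    manifest: dict
    timestep: TimestepInfo
    # contact resultant at every cycle (not just output frames), so peak
    # extraction does not alias the short first-impact transient
    contact_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    contact_series: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))


# ---------------------------------------------------------------------------
# element operations


def element_deformation(mesh: Mesh, u: np.ndarray, eid: int) -> list[DeformationState]:
    """Deformation state at each Gauss point of one element."""
    if not 0 <= eid < mesh.n_elements:
        raise ValueError(f"element {eid} does not exist")
    ue = u[mesh.elements[eid]]  # (8, 3)
    states = []
    for g in range(8):
        F = np.eye(3) + ue.T @ mesh._dndX0[eid, g]
        if np.linalg.det(F) <= 0:
            raise NegativeVolumeError(eid)
        states.append(DeformationState.from_gradient(F))
    return states


def _deformation_batch(mesh: Mesh, u: np.ndarray):
    """F, J at every Gauss point of every element: (E, 8, 3, 3), (E, 8)."""
    ue = u[mesh.elements]  # (E, 8, 3)
    F = np.eye(3) + np.einsum("eai,egaj->egij", ue, mesh._dndX0)
    J = np.linalg.det(F)
    return F, J


def internal_forces(
    mesh: Mesh,
    u: np.ndarray,
    materials: dict[int, Material],
    rates: np.ndarray | None = None,
    return_fields: bool = False,
):
    """Assembled internal force vector (N, 3) from Gauss quadrature.

    Stress is integrated in the current configuration (spatial gradients and
    current volumes), so an unconstrained body is self-equilibrated.  With
    ``return_fields`` the per-element mean Cauchy stress, mean log strain and
    current volume are also returned.
    """
    F, J = _deformation_batch(mesh, u)
    if np.any(J <= 0):
        bad = np.argwhere(J <= 0)
        raise NegativeVolumeError(int(bad[0, 0]))

    B = F @ np.swapaxes(F, -1, -2)
    w, V = np.linalg.eigh(B)
    lam = np.sqrt(np.maximum(w, 1e-300))  # (E, 8, 3)

    sigma_p = np.empty_like(lam)
    for pid, mat in materials.items():
        sel = mesh.element_part == pid
        if not np.any(sel):
            continue
        r = rates[sel] if rates is not None else None
        sigma_p[sel] = mat.principal_stress(lam[sel], J[sel], rate=r)
    sigma = np.einsum("ega,egia,egja->egij", sigma_p, V, V)

    # spatial gradients in the current configuration
    x = mesh.nodes + u
    dndx, detj = _ref_gradients(x, mesh.elements)
    # f_a,i = sum_g sigma_ij dN_a/dx_j dv_g
    fe = np.einsum("egij,egaj,eg->eai", sigma, dndx, detj)
    f = np.zeros_like(u)
    np.add.at(f, mesh.elements, fe)

    if not return_fields:
        return f
    gp_vol = detj
    tot = gp_vol.sum(axis=1)
    mean_sigma = np.einsum("egij,eg->eij", sigma, gp_vol) / tot[:, None, None]
    logl = np.log(lam)
    eps = np.einsum("ega,egia,egja->egij", logl, V, V)
    mean_eps = np.einsum("egij,eg->eij", eps, gp_vol) / tot[:, None, None]
    return f, {"stress": mean_sigma, "strain": mean_eps, "volume": tot}


def lumped_mass(mesh: Mesh, materials: dict[int, Material]) -> np.ndarray:
    """Row-sum lumped nodal masses: rho_e * V_e / 8 per hex node."""
    rho = _element_density(mesh, materials)
    return _lump(mesh, rho)


def _element_density(mesh: Mesh, materials: dict[int, Material]) -> np.ndarray:
    rho = np.empty(mesh.n_elements)
    for pid, mat in materials.items():
        d = mat.density
        if d <= 0:
            raise ValueError(f"part {pid}: density must be positive")
        rho[mesh.element_part == pid] = d
    return rho


def _lump(mesh: Mesh, rho: np.ndarray) -> np.ndarray:
    m = np.zeros(mesh.n_nodes)
    np.add.at(m, mesh.elements.ravel(),
              np.repeat(rho * mesh.reference_volumes / 8.0, 8))
    return m


def critical_timestep(
    mesh: Mesh,
    materials: dict[int, Material],
    safety: float = 0.9,
    rho: np.ndarray | None = None,
) -> TimestepInfo:
    """CFL step: dt = safety * min_e(L_e / c_e) with c = sqrt((K+4G/3)/rho)."""
    if not 0 < safety <= 1:
        raise ValueError("safety factor must lie in (0, 1]")
    if rho is None:
        rho = _element_density(mesh, materials)
    stiff = np.empty(mesh.n_elements)
    for pid, mat in materials.items():
        sel = mesh.element_part == pid
        stiff[sel] = (mat.constants.bulk_modulus
                      + 4.0 * mat.constants.shear_modulus / 3.0)
    c = np.sqrt(stiff / rho)
    L = mesh.characteristic_lengths()
    dtc = L / c
    return TimestepInfo(char_length=L, wave_speed=c, dt_critical=dtc,
                        dt=float(safety * dtc.min()), safety=safety)


def apply_mass_scaling(
    mesh: Mesh,
    materials: dict[int, Material],
    dt_target: float,
    safety: float = 0.9,
) -> tuple[np.ndarray, TimestepInfo]:
    """Selective mass scaling to reach a target time step.

    Elements with a critical step below the target get their density
    multiplied by (dt_target / dt_crit)^2; all others are untouched.  Returns
    the scaled per-element densities and a report carrying the added mass.
    """
    if dt_target <= 0:
        raise ValueError("target time step must be positive")
    rho = _element_density(mesh, materials)
    info = critical_timestep(mesh, materials, safety, rho=rho)
    factor = np.maximum(dt_target / info.dt_critical, 1.0) ** 2
    rho_scaled = rho * factor
    total = float(np.sum(rho * mesh.reference_volumes))
    added = float(np.sum((rho_scaled - rho) * mesh.reference_volumes))
    info2 = critical_timestep(mesh, materials, safety, rho=rho_scaled)
    info2.added_mass = added
    info2.added_mass_pct = 100.0 * added / total
    info2.dt = dt_target
    return rho_scaled, info2


def central_difference_step(
    u: np.ndarray,
    v_half: np.ndarray,
    masses: np.ndarray,
    f_int: np.ndarray,
    f_ext: np.ndarray,
    dt: float,
    damping_alpha: float = 0.0,
):
    """One central-difference update; returns (u_new, v_half_new, a).

    ``v_half`` is the velocity at t - dt/2.  Non-finite forces abort with a
    diagnostic rather than propagating NaNs.
    """
    if np.any(masses <= 0):
        raise ValueError("nodal masses must be strictly positive")
    net = f_ext - f_int
    if not np.all(np.isfinite(net)):
        raise InstabilityError("non-finite force encountered; step aborted")
    a = net / masses[:, None]
    if damping_alpha:
        a -= damping_alpha * v_half
    v_new = v_half + a * dt
    u_new = u + v_new * dt
    return u_new, v_new, a


# ---------------------------------------------------------------------------
# time loop


def run_simulation(
    mesh: Mesh,
    materials: dict[int, Material],
    config: SimulationConfig,
) -> RunResult:
    """Explicit time loop to the termination time.

    Writes element/node/contact/energy histories at the output interval and
    audits the energy balance (kinetic + internal - external).  Terminates
    early with a named status on negative element volume or energy blow-up.
    """
    parts = set(np.unique(mesh.element_part))
    missing = parts - set(materials)
    if missing:
        raise ValueError(f"no material for parts {sorted(missing)}")

    # time step and optional mass scaling
    if config.dt2ms is not None:
        rho, ts = apply_mass_scaling(mesh, materials, config.dt2ms, config.safety)
        dt = config.dt2ms
    else:
        rho = _element_density(mesh, materials)
        ts = critical_timestep(mesh, materials, config.safety, rho=rho)
        dt = config.dt if config.dt is not None else ts.dt
        ts.dt = dt
    # contact penalty adds stiffness not seen by the material CFL estimate
    masses = _lump(mesh, rho)
    k_contact = 0.0
    for plane in config.contacts:
        if plane.penalty is None:
            pid0 = int(mesh.element_part[0])
            K = materials[pid0].constants.bulk_modulus
            L = float(np.median(mesh.characteristic_lengths()))
            plane.penalty = config.contact_penalty_factor * K * L
        k_contact = max(k_contact, plane.penalty)
    if k_contact > 0 and config.dt is None and config.dt2ms is None:
        # resolve the penalty spring well below its stability bound
        # (omega * dt ~ 0.3) so the contact work integrates cleanly
        dt_contact = config.safety * 0.3 * np.sqrt(masses.min() / k_contact)
        dt = min(dt, float(dt_contact))
        ts.dt = dt

    n_steps = int(np.ceil(config.termination / dt))
    out_every = config.output_interval or max(config.termination / 100.0, dt)
    out_stride = max(1, int(round(out_every / dt)))

    rate_present = any(isinstance(m, RateDependentFoam) for m in materials.values())

    u = np.zeros_like(mesh.nodes)
    v_half = (np.tile(np.asarray(config.initial_velocity, dtype=float), (mesh.n_nodes, 1))
              if config.initial_velocity is not None else np.zeros_like(u))

    rates = np.zeros(mesh.n_elements) if rate_present else None
    eff_prev = np.zeros(mesh.n_elements)

    w_int = 0.0
    w_ext = 0.0
    ke0 = 0.5 * float(np.sum(masses[:, None] * v_half**2))

    times, disp_frames, contact_frames = [], [], []
    contact_times_all, contact_all = [], []
    elem_stress, elem_strain, elem_vol = [], [], []
    e_kin, e_int, e_ext = [], [], []
    status = "normal"
    failed_elem: int | None = None
    cycles = 0
    t = 0.0

    def record(fields, v_centered):
        times.append(t)
        disp_frames.append(u.copy())
        contact_frames.append(fc_total.copy())
        elem_stress.append(fields["stress"])
        elem_strain.append(fields["strain"])
        elem_vol.append(fields["volume"])
        e_kin.append(0.5 * float(np.sum(masses[:, None] * v_centered**2)))
        e_int.append(w_int)
        e_ext.append(w_ext)

    fc_total = np.zeros(3)
    try:
        f_int, fields = internal_forces(mesh, u, materials, rates,
                                        return_fields=True)
        f_ext, fc_total = _external_forces(mesh, u, masses, config, v_half)
        record(fields, v_half)
        # half kick to start the staggered scheme: v at +dt/2
        a0 = (f_ext - f_int) / masses[:, None]
        if config.damping_alpha:
            a0 = a0 - config.damping_alpha * v_half
        v_half = v_half + a0 * (dt / 2.0)
        for _ in range(n_steps):
            # advance displacements with v^{n+1/2}
            u_new = u + v_half * dt
            t_new = t + dt
            for motion in config.motions:
                target = motion.displacement(t_new) if isinstance(
                    motion, PrescribedMotion) else motion(t_new)
                v_half[motion.nodes, motion.dof] = (
                    target - u[motion.nodes, motion.dof]) / dt
                u_new[motion.nodes, motion.dof] = target

            du = u_new - u
            prev_fint, prev_fext = f_int, f_ext
            u, t = u_new, t_new
            cycles += 1

            f_int, fields = internal_forces(mesh, u, materials, rates,
                                            return_fields=True)
            f_ext, fc_total = _external_forces(mesh, u, masses, config,
                                             v_half)
            if config.contacts:
                contact_times_all.append(t)
                contact_all.append(fc_total.copy())
            # trapezoidal work increments over the step
            w_int += 0.5 * float(np.sum((prev_fint + f_int) * du))
            w_ext += 0.5 * float(np.sum((prev_fext + f_ext) * du))

            # velocity update v^{n+3/2} from forces at t^{n+1}
            _, v_new_half, a = central_difference_step(
                u, v_half, masses, f_int, f_ext, dt, config.damping_alpha)
            v_centered = v_half + a * (dt / 2.0)
            for motion in config.motions:
                nd, dof = motion.nodes, motion.dof
                tgt = motion.displacement if isinstance(
                    motion, PrescribedMotion) else motion
                w_cur = v_half[nd, dof]
                w_next = (tgt(t + dt) - tgt(t)) / dt
                # discrete reaction force driving the constrained dofs; its
                # work is external energy supplied through the boundary
                r = (masses[nd] * ((w_next - w_cur) / dt
                                   + config.damping_alpha * w_cur)
                     - (f_ext[nd, dof] - f_int[nd, dof]))
                w_ext += float(np.sum(r * w_cur * dt))
                v_new_half[nd, dof] = w_next
                v_centered[nd, dof] = 0.5 * (w_cur + w_next)
            v_half = v_new_half

            if rate_present:
                eff = effective_strain(fields["strain"])
                raw = np.abs(eff - eff_prev) / dt
                beta = dt / max(config.rate_smoothing_tau, dt)
                rates += beta * (raw - rates)
                eff_prev = eff

            if cycles % out_stride == 0 or cycles == n_steps:
                record(fields, v_centered)
                ke = e_kin[-1]
                # spurious energy: audit residual relative to supplied energy
                resid = abs(ke + w_int - w_ext - ke0)
                ref = max(ke0, abs(w_ext), 1e-12)
                if resid > config.instability_ratio * ref:
                    raise InstabilityError(
                        f"energy-balance residual {resid:g} exceeds "
                        f"{config.instability_ratio}x reference {ref:g}")
    except NegativeVolumeError as err:
        status = "negative_volume"
        failed_elem = err.element
        log.warning("run terminated: %s", err)
    except InstabilityError as err:
        status = "instability"
        log.warning("run terminated: %s", err)

    times_arr = np.array(times)
    histories = _build_histories(mesh, times_arr, elem_stress, elem_strain,
                                 elem_vol)
    energy = {
        "kinetic": np.array(e_kin),
        "internal": np.array(e_int),
        "external": np.array(e_ext),
    }
    manifest = {
        "dt": dt,
        "cycles": cycles,
        "termination_time": config.termination,
        "final_time": t,
        "added_mass": ts.added_mass,
        "added_mass_pct": ts.added_mass_pct,
        "termination_status": status,
        "failed_element": failed_elem,
        "seed": config.seed,
        "units": config.units,
        "n_nodes": mesh.n_nodes,
        "n_elements": mesh.n_elements,
    }
    return RunResult(
        times=times_arr,
        element_histories=histories,
        node_displacements=np.array(disp_frames),
        contact_force=np.array(contact_frames),
        energy=energy,
        manifest=manifest,
        timestep=ts,
        contact_times=np.array(contact_times_all),
        contact_series=(np.array(contact_all) if contact_all
                        else np.zeros((0, 3))),
    )


def _external_forces(mesh, u, masses, config, v=None):
    f = masses[:, None] * config.gravity
    fc_total = np.zeros(3)
    x = mesh.nodes + u
    for plane in config.contacts:
        fc = plane.forces(x, v, masses)
        f = f + fc
        fc_total += fc.sum(axis=0)
    return f, fc_total


def _build_histories(mesh, times, stress, strain, volume) -> list[ElementHistory]:
    if len(times) == 0:
        return []
    stress = np.array(stress)  # (T, E, 3, 3)
    strain = np.array(strain)
    volume = np.array(volume)  # (T, E)
    out = []
    for e in range(mesh.n_elements):
        pid = int(mesh.element_part[e])
        label = mesh.part_labels.get(pid, {})
        out.append(
            ElementHistory(
                eid=e,
                part=pid,
                tissue=label.get("tissue", "other"),
                side=label.get("side", "na"),
                volume=float(mesh.reference_volumes[e]),
                times=times,
                stress=stress[:, e],
                strain=strain[:, e],
                volume_series=volume[:, e],
            )
        )
    return out
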