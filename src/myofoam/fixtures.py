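"""Deterministic generators for test articles.

* an 8-element cuboid (1 mm edges, no loading, 50 ms) for timestep and
  regression checks,
* a single-element uniaxial coupon with unit gauge dimensions,
* a soft block dropped onto a rigid plane (seat-contact surrogate),
* synthetic element histories with closed-form metric/injury outputs.

The shipped soft-tissue curve is a generic convex engineering stress-strain
stand-in; it does not claim to match any licensed tissue dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deckio import CurveCard, DeckSubset, MatCard, PartCard, build_problem
from .fem import (
    Mesh,
    PrescribedMotion,
    RigidPlane,
    RunResult,
    SimulationConfig,
    SmoothRamp,
    run_simulation,
)
from .material import FoamMaterial, LoadCurve, RateTable
from .metrics import ElementHistory


@dataclass
class Fixture:
    """A runnable problem plus the manifest needed to regenerate it."""

    name: str
    mesh: Mesh
    materials: dict
    config: SimulationConfig
    manifest: dict
    deck: DeckSubset | None = None

    def run(self) -> RunResult:
        return run_simulation(self.mesh, self.materials, self.config)


# ---------------------------------------------------------------------------
# materials


def default_soft_tissue_curve(n: int = 25, max_strain: float = 0.6) -> LoadCurve:
    """Generic convex soft-tissue engineering curve (SI units, Pa).

    stress = s0 * (exp(k * strain) - 1) sampled on a uniform strain grid; a
    clearly-labelled stand-in, not a licensed tissue dataset.
    """
    strain = np.linspace(0.0, max_strain, n)
    stress = 2000.0 * (np.expm1(2.5 * strain))
    return LoadCurve(strain=strain, stress=stress, sfo=1.0)


def default_rate_table(scales=(1.0, 1.8, 2.6), rates=(1.0, 10.0, 25.0)) -> RateTable:
    """Rate table built from ordinate-scaled copies of the default curve (SI)."""
    base = default_soft_tissue_curve()
    entries = tuple(
        (r, LoadCurve(base.strain.copy(), base.stress * s, sfo=1.0))
        for r, s in zip(rates, scales)
    )
    return RateTable(entries)


def _grid_mesh(dims, nelems, origin=(0.0, 0.0, 0.0), part: int = 1,
               labels: dict | None = None) -> Mesh:
    nx, ny, nz = nelems
    xs = np.linspace(0, dims[0], nx + 1) + origin[0]
    ys = np.linspace(0, dims[1], ny + 1) + origin[1]
    zs = np.linspace(0, dims[2], nz + 1) + origin[2]
    nodes = np.array([(x, y, z) for z in zs for y in ys for x in xs])

    def nid(i, j, k):
        return k * (ny + 1) * (nx + 1) + j * (nx + 1) + i

    elems = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    elems = np.array(elems)
    return Mesh(nodes=nodes, elements=elems,
                element_part=np.full(len(elems), part),
                part_labels={part: labels or {"tissue": "muscle", "side": "na"}})


def _card_moduli(curve: LoadCurve, sfo_max: float = 10.0) -> tuple[float, float]:
    """Conservative bulk/shear moduli for the CFL estimate from curve slope."""
    tangent = float(np.max(np.diff(curve.scaled_stress) / np.diff(curve.strain)))
    K = max(3.0 * tangent * sfo_max, 1e4)
    return K, K / 5.0


# ---------------------------------------------------------------------------
# cuboid8


def make_cuboid8(
    curve: LoadCurve | None = None,
    sfo: float = 1.0,
    rate_table: RateTable | None = None,
    termination_ms: float = 50.0,
    seed: int = 0,
) -> Fixture:
    """2x2x2 mesh of 1 mm cuboid elements, no loading (deck units mm-ms-kg)."""
    curve = curve or default_soft_tissue_curve()
    deck = DeckSubset()
    nid = 1
    for z in range(3):
        for y in range(3):
            for x in range(3):
                deck.nodes[nid] = (float(x), float(y), float(z))
                nid += 1

    def node_id(i, j, k):
        return k * 9 + j * 3 + i + 1

    eid = 1
    for k in range(2):
        for j in range(2):
            for i in range(2):
                deck.solids[eid] = (1, (
                    node_id(i, j, k), node_id(i + 1, j, k),
                    node_id(i + 1, j + 1, k), node_id(i, j + 1, k),
                    node_id(i, j, k + 1), node_id(i + 1, j, k + 1),
                    node_id(i + 1, j + 1, k + 1), node_id(i, j + 1, k + 1),
                ))
                eid += 1

    K, G = _card_moduli(curve)
    gpa = 1e-9  # Pa -> GPa for the mm-ms-kg deck
    if rate_table is None:
        deck.curves[1] = CurveCard(
            lcid=1, sfa=1.0, sfo=sfo,
            points=np.column_stack([curve.strain, curve.stress * gpa]),
        )
        mat = MatCard(mid=1, rho=1e-6, km=K * gpa, mu=0.05, g=G * gpa,
                      sigf=0.0, lcid=1, pr=0.3)
    else:
        for i, (rate, c) in enumerate(rate_table.entries, start=1):
            deck.curves[i] = CurveCard(
                lcid=i, sfa=1.0, sfo=c.sfo,
                points=np.column_stack([c.strain, c.stress * gpa]),
            )
        deck.tables[1] = [(rate / 1e3, i + 1)  # 1/s -> 1/ms
                          for i, (rate, _) in enumerate(rate_table.entries)]
        mat = MatCard(mid=1, rho=1e-6, km=K * gpa, mu=0.05, g=G * gpa,
                      sigf=0.0, tbid=1, pr=0.3)
    deck.mats[1] = mat
    deck.parts[1] = PartCard(pid=1, title="muscle cuboid", secid=1, mid=1)
    deck.endtim = termination_ms

    mesh, materials, config = build_problem(deck, units="mm_ms_kg")
    config.seed = seed
    config.output_interval = config.termination / 25.0
    manifest = {
        "fixture": "cuboid8", "sfo": sfo, "seed": seed,
        "rate_table": rate_table is not None, "units": "mm_ms_kg",
        "termination_ms": termination_ms,
    }
    return Fixture("cuboid8", mesh, materials, config, manifest, deck=deck)


# ---------------------------------------------------------------------------
# uniaxial coupon


def make_uniaxial_coupon(
    curve: LoadCurve | None = None,
    sfo: float = 1.0,
    nu: float = 0.3,
    max_strain: float = 0.4,
    speed_fraction: float = 0.002,
    seed: int = 0,
) -> Fixture:
    """Single unit-dimension element under a quasi-static axial ramp.

    The axial faces are prescribed (one fixed, one ramped with a smoothstep);
    the lateral faces are free.  The density used for inertia is scaled with
    the ordinate scale so the dynamic trajectory is identical across SFO
    values and the stress response scales exactly; in the quasi-static limit
    inertia is a numerical artifact, so this does not change the answer.
    """
    curve = curve or default_soft_tissue_curve()
    K, G = _card_moduli(curve, sfo_max=1.0)
    rho = 1000.0
    mat = FoamMaterial.from_curve(
        curve, nu, sfo=1.0, density=rho, bulk_modulus=K, shear_modulus=G)
    mat.scale = sfo
    mat.mass_scale = sfo

    mesh = _grid_mesh((1.0, 1.0, 1.0), (1, 1, 1))
    c = np.sqrt((K + 4 * G / 3) / rho)  # base wave speed (unscaled inertia)
    dt = 0.3 * 1.0 / c
    t_end = 1.5 * max_strain / (speed_fraction * c)

    fixed = np.where(mesh.nodes[:, 0] < 1e-12)[0]
    moving = np.where(mesh.nodes[:, 0] > 1.0 - 1e-12)[0]
    config = SimulationConfig(
        termination=t_end,
        dt=dt,
        output_interval=t_end / 200.0,
        motions=[
            PrescribedMotion(nodes=fixed, dof=0, displacement=lambda t: 0.0),
            SmoothRamp(nodes=moving, dof=0, amplitude=max_strain, t_end=t_end),
        ],
        damping_alpha=0.2 * c,
        seed=seed,
    )
    manifest = {
        "fixture": "uniaxial_coupon", "sfo": sfo, "nu": nu,
        "max_strain": max_strain, "dt": dt, "t_end": t_end, "seed": seed,
        "units": "si",
    }
    return Fixture("uniaxial_coupon", mesh, {1: mat}, config, manifest)


def coupon_response(result: RunResult) -> tuple[np.ndarray, np.ndarray]:
    """(engineering strain, nominal stress) series from a coupon run.

    Nominal stress is recovered from the element-mean Cauchy stress via
    sigma_nom = sigma_xx * J / lambda_axial with the Hencky strain history.
    """
    h = result.element_histories[0]
    eps = h.strain
    lam_ax = np.exp(eps[:, 0, 0])
    J = np.exp(np.trace(eps, axis1=1, axis2=2))
    nominal = h.stress[:, 0, 0] * J / lam_ax
    return lam_ax - 1.0, nominal


def coupon_lateral_stretch(result: RunResult) -> np.ndarray:
    """Lateral stretch series exp(eps_yy) from a coupon run."""
    return np.exp(result.element_histories[0].strain[:, 1, 1])


# ---------------------------------------------------------------------------
# drop block


def make_drop_block(
    curve: LoadCurve | None = None,
    sfo: float = 1.0,
    impact_speed: float = 0.5,
    dims: tuple[float, float, float] = (0.1, 0.1, 0.1),
    nelems: tuple[int, int, int] = (2, 2, 4),
    termination: float = 0.15,
    nu: float = 0.3,
    penalty: float = 1e4,
    contact_damping_ratio: float = 0.3,
    seed: int = 0,
) -> Fixture:
    """Soft block with initial downward velocity onto a rigid plane (SI).

    The contact penalty and its dashpot are held fixed across SFO values so
    resultant-force comparisons across stiffness scales are like-for-like.
    The default impact speed keeps the block out of the deep-crush regime
    where convex foam hardening equalises peak forces across stiffness
    scales.
    """
    if impact_speed < 0:
        raise ValueError("impact speed must be non-negative")
    curve = curve or default_soft_tissue_curve()
    K, G = _card_moduli(curve, sfo_max=max(sfo, 10.0))
    rho = 1000.0
    mat = FoamMaterial.from_curve(
        curve, nu, sfo=sfo, density=rho, bulk_modulus=K, shear_modulus=G)

    mesh = _grid_mesh(dims, nelems,
                      labels={"tissue": "soft", "side": "na"})
    config = SimulationConfig(
        termination=termination,
        output_interval=termination / 160.0,
        contacts=[RigidPlane(point=np.zeros(3), normal=np.array([0.0, 0, 1.0]),
                             penalty=penalty,
                             damping_ratio=contact_damping_ratio)],
        initial_velocity=np.array([0.0, 0.0, -impact_speed]),
        seed=seed,
    )
    manifest = {
        "fixture": "drop_block", "sfo": sfo, "impact_speed": impact_speed,
        "dims": list(dims), "nelems": list(nelems), "penalty": penalty,
        "termination": termination, "seed": seed, "units": "si",
    }
    return Fixture("drop_block", mesh, {1: mat}, config, manifest)


# ---------------------------------------------------------------------------
# synthetic histories


def make_synthetic_histories(
    seed: int,
    n_elements: int = 10,
    volume_range: tuple[float, float] = (1e-9, 5e-9),
    peak_strains: np.ndarray | None = None,
    plastic_fraction: float = 0.0,
    plastic_increment: float = 0.002,
    n_steps: int = 20,
    duration: float = 0.05,
    modulus: float = 1e5,
) -> list[ElementHistory]:
    """Seeded element histories with prescribed peak effective strains.

    Strain paths are uniaxial-incompressible ramps diag(e, -e/2, -e/2) with
    e rising linearly to the prescribed peak, so the effective strain equals
    e exactly and every injury-module output is computable in closed form
    from the schedule.
    """
    if n_elements < 1:
        raise ValueError("need at least one element")
    rng = np.random.default_rng(seed)
    if peak_strains is None:
        peak_strains = rng.uniform(0.1, 1.0, n_elements)
    peak_strains = np.asarray(peak_strains, dtype=float)
    if len(peak_strains) != n_elements:
        raise ValueError("peak_strains length mismatch")
    volumes = rng.uniform(*volume_range, n_elements)
    times = np.linspace(0.0, duration, n_steps + 1)
    ramp = times / duration
    n_plastic = int(round(plastic_fraction * n_elements))
    base = np.diag([1.0, -0.5, -0.5])
    out = []
    for i in range(n_elements):
        e = peak_strains[i] * ramp
        strain = e[:, None, None] * base
        stress = modulus * strain
        plastic = None
        if i < n_plastic:
            plastic = np.repeat(plastic_increment * base[None], len(times), axis=0)
            plastic[0] = 0.0  # no increment at the initial sample
        out.append(
            ElementHistory(
                eid=i,
                part=1 + i % 2,
                tissue="muscle" if i % 2 == 0 else "soft",
                side="left" if (i // 2) % 2 == 0 else "right",
                volume=float(volumes[i]),
                times=times,
                stress=stress,
                strain=strain,
                plastic_increments=plastic,
            )
        )
    return out
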