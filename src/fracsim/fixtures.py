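"""Programmatic test inputs: calibration osteotomy, single-element
remodelling rig, 1D consolidation column and a miniature callus model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .driver import SimulationConfig
from .geometry import GeometrySpec, MeshModel, build_fracture_model
from .materials import PoroMaterial
from .poroelastic import solve_daily_loading
from .remodelling import (
    BoneState,
    RemodelParams,
    damage_resorption_rate,
    damage_update,
    density_modulus_law,
    remodel_time_scales,
    sed_remodelling_rate,
)

__all__ = [
    "make_fixture",
    "make_column",
    "SingleElementRig",
    "calibration_ifm",
]

FIXTURE_NAMES = (
    "calibration_osteotomy",
    "single_element",
    "consolidation_column",
    "toy_callus",
)


def make_column(height: float = 10.0, n_elems: int = 40, width: float = 1.0,
                material: PoroMaterial | None = None):
    """Plane-strain 1D consolidation column (drained at the loaded top).

    All nodes are laterally constrained; use with
    ``solve_daily_loading(..., extra_fix_x=range(mesh.n_nodes))``.
    Returns (mesh, materials).
    """
    if material is None:
        # nearly incompressible constituents -> classical Terzaghi response
        material = PoroMaterial(1.0, 0.0, 1e-10, 0.5, 1e9, 1e9)
    zs = np.linspace(0.0, height, n_elems + 1)
    nodes = np.empty((2 * (n_elems + 1), 2))
    nodes[0::2, 0] = 0.0
    nodes[1::2, 0] = width
    nodes[0::2, 1] = zs
    nodes[1::2, 1] = zs
    elements = np.array(
        [[2 * i, 2 * i + 1, 2 * i + 3, 2 * i + 2] for i in range(n_elems)],
        dtype=int,
    )
    region = np.asarray(["callus_focus"] * n_elems, dtype=object)
    mesh = MeshModel(nodes, elements, region, axisymmetric=False)
    top = np.array([2 * n_elems, 2 * n_elems + 1])
    mesh.boundary_nodes["loaded_end"] = top
    mesh.boundary_nodes["fixed_end"] = np.array([0, 1])
    mesh.boundary_nodes["drainage"] = top
    mesh.boundary_faces["loaded_end"] = np.array(
        [[n_elems - 1, 2 * n_elems, 2 * n_elems + 1]]
    )
    return mesh, [material] * n_elems


@dataclass
class SingleElementRig:
    """One bone element under a prescribed daily uniaxial stress.

    Applies the site-specific SED rule (and optionally fatigue damage) with
    the per-month density-change cap; closed-form mechanics, no FE solve.
    """

    rho: float = 1.0
    params: RemodelParams = field(default_factory=RemodelParams)
    damage: bool = False

    def __post_init__(self):
        self.state = BoneState(rho=np.array([float(self.rho)]))

    def psi(self, sigma: float) -> float:
        E = density_modulus_law(self.state.rho[0])
        return sigma ** 2 / (2.0 * E * self.state.rho[0])

    def step(self, sigma: float, dt: float = 1.0) -> float:
        """One daily increment; returns the accepted dt."""
        p = self.params
        psi = self.psi(sigma)
        r_sed = sed_remodelling_rate(psi, self.state.rho, p)
        r_dmg = np.zeros(1)
        if self.damage:
            damage_update(self.state, sigma, self.state.rho,
                          p.cycles_per_day, dt, p)
            r_dmg = damage_resorption_rate(self.state, self.state.rho,
                                           p.cycles_per_day, p)
        f_sed, f_dmg = remodel_time_scales(r_sed, r_dmg, dt, p)
        dt_acc = dt * min(1.0, f_sed, f_dmg)
        self.state.rho = np.clip(
            self.state.rho + (r_sed + r_dmg) * dt_acc, p.rho_min, p.rho_max
        )
        return dt_acc

    def run(self, sigma: float, days: float = 1500.0, dt: float = 1.0):
        """Iterate daily loading; returns (times, densities)."""
        t, ts, rs = 0.0, [0.0], [float(self.state.rho[0])]
        while t < days:
            t += self.step(sigma, dt)
            ts.append(t)
            rs.append(float(self.state.rho[0]))
        return np.asarray(ts), np.asarray(rs)


def calibration_ifm(mesh: MeshModel, load_N: float = 500.0,
                    fixator_stiffness: float = 380.0,
                    materials=None) -> float:
    """Initial inter-fragmentary displacement (mm) of the calibration model.

    The unilateral external fixator is not meshed; it acts as an axial
    spring in parallel with the FE callus stiffness (documented
    reconstruction; set ``fixator_stiffness=0`` for the bare callus).
    """
    from .geometry import assign_region_materials

    if materials is None:
        materials = assign_region_materials(mesh)
    snap = solve_daily_loading(mesh, materials, load_N, load_kind="force")
    spec = mesh.spec
    g2 = spec.fracture_gap / 2.0
    tol = 1e-9
    nodes = mesh.nodes
    top = np.flatnonzero(np.abs(nodes[:, 1] - g2) < tol)
    bot = np.flatnonzero(np.abs(nodes[:, 1] + g2) < tol)
    ifm_fe = abs(snap.displacement[top, 1].mean()
                 - snap.displacement[bot, 1].mean())
    if ifm_fe <= 0:
        return 0.0
    k_callus = load_N / ifm_fe
    return load_N / (k_callus + fixator_stiffness)


def make_fixture(name: str):
    """Build a named programmatic fixture.

    Returns a dict whose keys depend on the fixture: always ``config``
    and/or ``mesh``; the single-element fixture returns a ``rig``; the
    consolidation column returns ``materials``.
    """
    if name == "calibration_osteotomy":
        spec = GeometrySpec.calibration_defaults()
        config = SimulationConfig(
            geometry=spec, condition="LC_A", fixed_load_N=500.0,
        )
        return {"mesh": build_fracture_model(spec), "config": config}
    if name == "single_element":
        return {"rig": SingleElementRig(), "config": SimulationConfig()}
    if name == "consolidation_column":
        mesh, materials = make_column()
        return {"mesh": mesh, "materials": materials}
    if name == "toy_callus":
        spec = GeometrySpec(variant="unplated", fracture_gap=3.0,
                            mesh_target_size=1.2)
        config = SimulationConfig(geometry=spec, condition="LC_A")
        return {"mesh": build_fracture_model(spec), "config": config}
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
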