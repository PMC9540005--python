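"""Linear biphasic (u-p) finite-element solver for one daily loading event.

Bilinear quads with displacement and pore-pressure degrees of freedom at
every node (2D analogue of a trilinear u-p-T brick), backward-Euler
consolidation.  Mechanics runs in mm / N / MPa / seconds; the stimulus
velocity is reported in um/s.

The geometry-dependent element operators are computed once per mesh and
cached, so repeated solves with updated materials (one per simulated day)
only reassemble material-weighted matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MeshModel

__all__ = [
    "FieldSnapshot",
    "solve_daily_loading",
    "deviatoric_strain",
    "fluid_velocity_magnitude",
    "element_strain_energy_density",
    "material_arrays",
]

_GP = np.array(
    [[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float
) / np.sqrt(3.0)


def deviatoric_strain(eps1, eps2, eps3):
    """Octahedral (deviatoric) strain from principal strains.

    (2/3) * sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2); zero for purely
    volumetric states and symmetric under permutation of the inputs.
    """
    e1, e2, e3 = np.asarray(eps1), np.asarray(eps2), np.asarray(eps3)
    return (2.0 / 3.0) * np.sqrt(
        (e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2
    )


def fluid_velocity_magnitude(wf_vector):
    """Euclidean norm of the relative fluid-velocity vector (um/s in, um/s out)."""
    w = np.asarray(wf_vector, dtype=float)
    return float(np.linalg.norm(w)) if w.ndim == 1 else np.linalg.norm(w, axis=-1)


def element_strain_energy_density(stress, strain, rho):
    """SED per unit apparent density: (1/2) sigma:eps / rho (MPa cm^3/g).

    ``stress`` and ``strain`` are full tensors (… x 3 x 3) or matching
    Voigt arrays; ``rho`` must be positive.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    s, e = np.asarray(stress, float), np.asarray(strain, float)
    if s.shape != e.shape:
        raise ValueError("stress and strain shapes differ")
    if s.shape[-2:] == (3, 3):
        u = 0.5 * np.einsum("...ij,...ij->...", s, e)
    else:
        u = 0.5 * np.einsum("...i,...i->...", s, e)
    return u / rho


@dataclass
class FieldSnapshot:
    """Per-element mechanics fields from one daily loading event."""

    eps_dev: np.ndarray        # peak-in-time octahedral strain, -
    wf_mag: np.ndarray         # peak-in-time fluid speed, um/s
    sigma: np.ndarray          # end-of-step von Mises effective stress, MPa
    energy: np.ndarray         # end-of-step strain energy density U, MPa
    psi: np.ndarray            # U / rho, MPa cm^3/g
    displacement: np.ndarray   # (n_nodes, 2) end-of-step, mm
    pressure: np.ndarray       # (n_nodes,) end-of-step pore pressure, MPa
    reaction: float            # total axial reaction at the fixed end, N
    applied: float             # total applied axial force, N

    def stimulus_inputs(self):
        return self.eps_dev, self.wf_mag


class FemWorkspace:
    """Geometry-dependent element operators, cached per mesh."""

    def __init__(self, mesh: MeshModel):
        self.mesh = mesh
        conn = mesh.elements
        coords = mesh.nodes[conn]               # (ne, 4, 2)
        ne = conn.shape[0]
        self.ne = ne
        self.nn = mesh.n_nodes
        self.axi = mesh.axisymmetric
        ns = 4 if self.axi else 3
        self.ns = ns

        ngp = 4
        self.N = np.empty((ngp, 4))
        dNdxi = np.empty((ngp, 4, 2))
        for g, (xi, eta) in enumerate(_GP):
            self.N[g] = 0.25 * np.array(
                [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                 (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
            )
            dNdxi[g] = 0.25 * np.array(
                [[-(1 - eta), -(1 - xi)], [(1 - eta), -(1 + xi)],
                 [(1 + eta), (1 + xi)], [-(1 + eta), (1 - xi)]]
            )

        # jacobians: J[e,g,i,j] = sum_a dN_a/dxi_i * x_a,j
        J = np.einsum("gai,eaj->egij", dNdxi, coords)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        invJ = np.empty_like(J)
        invJ[..., 0, 0] = J[..., 1, 1] / detJ
        invJ[..., 1, 1] = J[..., 0, 0] / detJ
        invJ[..., 0, 1] = -J[..., 0, 1] / detJ
        invJ[..., 1, 0] = -J[..., 1, 0] / detJ
        # dNdx[e,g,a,i]
        dNdx = np.einsum("egij,gaj->egai", invJ, dNdxi)
        self.dNdx = dNdx

        rg = np.einsum("ga,ea->eg", self.N, coords[..., 0])
        self.weight = detJ * (np.abs(rg) if self.axi else 1.0)

        # strain-displacement operator B[e,g,ns,8] (dofs ur0,uz0,ur1,...)
        B = np.zeros((ne, ngp, ns, 8))
        B[..., 0, 0::2] = dNdx[..., 0]
        B[..., 1, 1::2] = dNdx[..., 1]
        if self.axi:
            B[..., 2, 0::2] = self.N[None, :, :] / rg[..., None]
            B[..., 3, 0::2] = dNdx[..., 1]
            B[..., 3, 1::2] = dNdx[..., 0]
        else:
            B[..., 2, 0::2] = dNdx[..., 1]
            B[..., 2, 1::2] = dNdx[..., 0]
        self.B = B
        nvol = 3 if self.axi else 2
        self.bvol = B[..., :nvol, :].sum(axis=2)

        # dof maps
        self.edof = np.empty((ne, 8), dtype=int)
        self.edof[:, 0::2] = 2 * conn
        self.edof[:, 1::2] = 2 * conn + 1
        self.pdof = 2 * self.nn + conn

        def idx(rowdofs, coldofs):
            nr, nc = rowdofs.shape[1], coldofs.shape[1]
            r = np.repeat(rowdofs[:, :, None], nc, axis=2).ravel()
            c = np.repeat(coldofs[:, None, :], nr, axis=1).ravel()
            return r, c

        self.kk_idx = idx(self.edof, self.edof)
        self.cc_idx = idx(self.edof, self.pdof)
        self.pp_idx = idx(self.pdof, self.pdof)
        self.ndof = 3 * self.nn

    def elastic_D(self, E, nu):
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        ns = self.ns
        D = np.zeros((self.ne, ns, ns))
        nvol = ns - 1
        D[:, :nvol, :nvol] = lam[:, None, None]
        for i in range(nvol):
            D[:, i, i] += 2 * mu
        D[:, nvol, nvol] = mu
        return D

    def assemble(self, E, nu, alpha, invQ, k_mm):
        """Material-weighted global blocks K, C, S, H (CSR)."""
        D = self.elastic_D(E, nu)
        w = self.weight
        DB = np.einsum("eij,egjk->egik", D, self.B)
        Ke = np.einsum("eg,egji,egjk->eik", w, self.B, DB)
        Ce = np.einsum("eg,e,egi,ga->eia", w, alpha, self.bvol, self.N)
        Se = np.einsum("eg,e,ga,gb->eab", w, invQ, self.N, self.N)
        He = np.einsum("eg,e,egai,egbi->eab", w, k_mm, self.dNdx, self.dNdx)

        nd = self.ndof
        K = sp.coo_matrix((Ke.ravel(), self.kk_idx), shape=(nd, nd)).tocsr()
        C = sp.coo_matrix((Ce.ravel(), self.cc_idx), shape=(nd, nd)).tocsr()
        S = sp.coo_matrix((Se.ravel(), self.pp_idx), shape=(nd, nd)).tocsr()
        H = sp.coo_matrix((He.ravel(), self.pp_idx), shape=(nd, nd)).tocsr()
        return K, C, S, H


def _workspace(mesh: MeshModel) -> FemWorkspace:
    ws = getattr(mesh, "_fem_workspace", None)
    if ws is None:
        ws = FemWorkspace(mesh)
        mesh._fem_workspace = ws
    return ws


def material_arrays(materials, ne: int) -> dict[str, np.ndarray]:
    """Normalize a material description to per-element parameter arrays.

    Accepts a list of :class:`PoroMaterial` (one per element) or a dict of
    arrays with keys E, nu, k_mm, alpha, invQ, porosity.
    """
    if isinstance(materials, dict):
        out = {key: np.asarray(materials[key], dtype=float)
               for key in ("E", "nu", "k_mm", "alpha", "invQ", "porosity")}
    else:
        if len(materials) != ne:
            raise ValueError("need one material per element")
        out = {
            "E": np.array([m.E for m in materials]),
            "nu": np.array([m.nu for m in materials]),
            "k_mm": np.array([m.k_mm for m in materials]),
            "alpha": np.array([m.biot_alpha for m in materials]),
            "invQ": np.array([m.storage_compressibility for m in materials]),
            "porosity": np.array([m.porosity for m in materials]),
        }
    if np.any(out["E"] <= 0):
        raise ValueError("non-physical material: E <= 0")
    if np.any(out["nu"] >= 0.5):
        raise ValueError("non-physical material: nu >= 0.5")
    return out


def _loaded_end_forces(mesh, ws, traction: float) -> tuple[np.ndarray, float]:
    """Consistent nodal forces for axial traction on the loaded end.

    Returns the force vector (u dofs only) and the total applied axial
    force in N (axisymmetric integrals carry the 2*pi factor in the total
    only; the assembled system is per radian... both are kept per-radian
    internally and scaled once here for reporting).
    """
    f = np.zeros(ws.ndof)
    total = 0.0
    for e, a, b in mesh.boundary_faces["loaded_end"]:
        xa, xb = mesh.nodes[a, 0], mesh.nodes[b, 0]
        length = abs(xb - xa)
        if length == 0:
            continue
        if mesh.axisymmetric:
            ra, rb = abs(xa), abs(xb)
            fa = traction * length * (2 * ra + rb) / 6.0
            fb = traction * length * (ra + 2 * rb) / 6.0
            total += traction * length * (ra + rb) / 2.0 * 2 * np.pi
        else:
            fa = fb = traction * length / 2.0
            total += traction * length
        f[2 * a + 1] -= fa
        f[2 * b + 1] -= fb
    return f, total


def solve_daily_loading(
    mesh: MeshModel,
    materials,
    load: float,
    duration: float = 1.0,
    n_steps: int = 4,
    *,
    load_kind: str = "stress",
    load_shape: str = "ramp",
    ramp_time: float | None = None,
    rho=None,
    times=None,
    fix_nodes=None,
    extra_fix_x=None,
    drain_nodes=None,
) -> FieldSnapshot:
    """One ramp-and-hold consolidation solve of a daily loading event.

    ``load`` is an axial compressive stress in MPa (``load_kind='stress'``)
    or a total axial force in N (``load_kind='force'``) applied on the
    loaded end; the distal end is fully fixed and the callus outer surface
    drains freely.  Returns peak-in-time stimulus fields and end-of-step
    stress/energy per element.
    """
    ws = _workspace(mesh)
    mats = material_arrays(materials, ws.ne)
    ne, nn = ws.ne, ws.nn

    if load_kind == "force":
        # convert to an equivalent uniform traction over the loaded faces
        area = 0.0
        for _, a, b in mesh.boundary_faces["loaded_end"]:
            xa, xb = mesh.nodes[a, 0], mesh.nodes[b, 0]
            if mesh.axisymmetric:
                area += np.pi * abs(xb**2 - xa**2)
            else:
                area += abs(xb - xa)
        traction = load / area if area > 0 else 0.0
    elif load_kind == "stress":
        traction = load
    else:
        raise ValueError(f"unknown load_kind {load_kind!r}")

    K, C, S, H = ws.assemble(
        mats["E"], mats["nu"], mats["alpha"], mats["invQ"], mats["k_mm"]
    )
    f_full, total_force = _loaded_end_forces(mesh, ws, traction)

    # Dirichlet sets
    if fix_nodes is None:
        fix_nodes = mesh.boundary_nodes["fixed_end"]
    if drain_nodes is None:
        drain_nodes = mesh.boundary_nodes.get("drainage", np.empty(0, int))
    fixed = set()
    for n in np.asarray(fix_nodes, dtype=int):
        fixed.add(2 * n)
        fixed.add(2 * n + 1)
    if mesh.axisymmetric:
        axis_nodes = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
        for n in axis_nodes:
            fixed.add(2 * n)
    if extra_fix_x is not None:
        for n in np.asarray(extra_fix_x, dtype=int):
            fixed.add(2 * n)
    for n in np.asarray(drain_nodes, dtype=int):
        fixed.add(2 * nn + n)
    fixed = np.fromiter(sorted(fixed), dtype=int)
    if fixed.size == 0:
        raise ValueError("unconstrained mesh: no Dirichlet conditions")

    free_mask = np.ones(ws.ndof, dtype=bool)
    free_mask[fixed] = False
    proj = sp.diags(free_mask.astype(float))
    pin = sp.diags((~free_mask).astype(float))

    ramp = duration if ramp_time is None else min(ramp_time, duration)
    if times is None:
        if ramp < duration:
            # resolve the ramp, then geometric spacing through the hold
            n_ramp = max(2, n_steps // 2)
            t_ramp = np.linspace(ramp / n_ramp, ramp, n_ramp)
            n_hold = max(1, n_steps - n_ramp)
            t_hold = ramp * (duration / ramp) ** (
                np.arange(1, n_hold + 1) / n_hold
            )
            times = np.concatenate([t_ramp, t_hold])
        else:
            times = np.linspace(duration / n_steps, duration, n_steps)
    times = np.asarray(times, dtype=float)

    u = np.zeros(ws.ndof)  # combined u/p vector
    peak_eps_dev = np.zeros(ne)
    peak_wf = np.zeros(ne)

    Ct = C.T
    lu = None
    last_dt = None
    t_prev = 0.0
    eps_end = None
    for t in times:
        dt = t - t_prev
        t_prev = t
        if lu is None or abs(dt - last_dt) > 1e-14 * max(dt, 1e-30):
            A = K - C + Ct + S + dt * H
            A = proj @ A @ proj + pin
            lu = spla.splu(A.tocsc())
            last_dt = dt
        lam = min(t / ramp, 1.0) if load_shape == "ramp" else 1.0
        rhs = f_full * lam + Ct @ u + S @ u
        rhs[fixed] = 0.0
        u = lu.solve(rhs)

        eps = np.einsum("egik,ek->egi", ws.B, u[ws.edof])  # (ne, gp, ns)
        ed = _octahedral_from_voigt(eps, ws.axi).mean(axis=1)
        peak_eps_dev = np.maximum(peak_eps_dev, ed)
        gradp = np.einsum("egai,ea->egi", ws.dNdx, u[ws.pdof]).mean(axis=1)
        wf = (
            np.linalg.norm(gradp, axis=1)
            * mats["k_mm"] / np.maximum(mats["porosity"], 1e-6)
            * 1e3
        )  # um/s
        peak_wf = np.maximum(peak_wf, wf)
        eps_end = eps

    # end-of-step effective stress, energy
    D = ws.elastic_D(mats["E"], mats["nu"])
    sig = np.einsum("eij,egj->egi", D, eps_end)
    energy = 0.5 * np.einsum(
        "eg,egi,egi->e", ws.weight, sig, eps_end
    ) / ws.weight.sum(axis=1)
    vm = _von_mises_from_voigt(sig, mats["nu"], ws.axi).mean(axis=1)

    if rho is None:
        rho_arr = np.ones(ne)
    else:
        rho_arr = np.asarray(rho, dtype=float)
        if np.any(rho_arr <= 0):
            raise ValueError("rho must be positive")
    psi = energy / rho_arr

    # reaction at the fixed end from the unconstrained operators
    resid = (K - C) @ u - f_full
    react = 0.0
    for n in np.asarray(fix_nodes, dtype=int):
        react += resid[2 * n + 1]
    if mesh.axisymmetric:
        react *= 2 * np.pi

    disp = np.column_stack([u[0:2 * nn:2], u[1:2 * nn:2]])
    press = u[2 * nn:]
    return FieldSnapshot(
        eps_dev=peak_eps_dev,
        wf_mag=peak_wf,
        sigma=vm,
        energy=energy,
        psi=psi,
        displacement=disp,
        pressure=press,
        reaction=float(react),
        applied=float(total_force),
    )


def _octahedral_from_voigt(eps: np.ndarray, axi: bool) -> np.ndarray:
    """Octahedral strain at each gauss point from Voigt strain components."""
    if axi:
        err, ezz, ett, grz = (eps[..., i] for i in range(4))
    else:
        err, ezz, grz = eps[..., 0], eps[..., 1], eps[..., 2]
        ett = np.zeros_like(err)
    # principal strains of the in-plane block plus the hoop strain
    mean = 0.5 * (err + ezz)
    rad = np.sqrt((0.5 * (err - ezz)) ** 2 + (0.5 * grz) ** 2)
    return deviatoric_strain(mean + rad, mean - rad, ett)


def _von_mises_from_voigt(sig: np.ndarray, nu: np.ndarray, axi: bool) -> np.ndarray:
    if axi:
        s11, s22, s33, s12 = (sig[..., i] for i in range(4))
    else:
        s11, s22, s12 = sig[..., 0], sig[..., 1], sig[..., 2]
        s33 = nu[:, None] * (s11 + s22)  # plane-strain out-of-plane stress
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * s12 ** 2
    )
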