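"""MSC infiltration: diffusion on the callus with a saturating boundary ramp.

The boundary (source-surface) concentration follows the discrete update
c_b <- c_b + D (c_max - c_b) dt, i.e. the exponential ramp 1 - exp(-D t)
in the small-step limit, which removes the start-up artifact of applying
full concentration at t = 0.  The interior obeys dc/dt = D lap(c), solved
implicitly with a lumped mass matrix on the shared simulation mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CALLUS_REGIONS, MeshModel

__all__ = ["DiffusionState", "update_boundary_concentration", "diffuse_step"]


@dataclass
class DiffusionState:
    """Nodal MSC concentration field plus the boundary ramp value."""

    c: np.ndarray              # (n_nodes,) relative concentration in [0, 1]
    c_b: float = 0.0           # current boundary concentration
    D: float = 0.1             # diffusion coefficient, mm^2/day
    c_max: float = 1.0         # saturation concentration

    @classmethod
    def initial(cls, mesh: MeshModel, D: float = 0.1) -> "DiffusionState":
        return cls(c=np.zeros(mesh.n_nodes), c_b=0.0, D=D)

    def element_concentration(self, mesh: MeshModel) -> np.ndarray:
        """Integration-point concentration: interpolated nodal values."""
        return self.c[mesh.elements].mean(axis=1)


def update_boundary_concentration(state: DiffusionState, dt: float) -> DiffusionState:
    """Advance the boundary ramp by one increment (no overshoot of c_max)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    c_b = state.c_b + state.D * (state.c_max - state.c_b) * dt
    c_b = min(c_b, state.c_max)
    return replace(state, c_b=c_b)


def _diffusion_operator(mesh: MeshModel):
    """Lumped mass and stiffness over callus elements (cached per mesh)."""
    cached = getattr(mesh, "_diffusion_operator", None)
    if cached is not None:
        return cached

    from .poroelastic import _workspace

    ws = _workspace(mesh)
    sel = np.isin(mesh.region, CALLUS_REGIONS)
    w = ws.weight[sel]
    dNdx = ws.dNdx[sel]
    conn = mesh.elements[sel]
    nn = mesh.n_nodes

    He = np.einsum("eg,egai,egbi->eab", w, dNdx, dNdx)
    # row-sum (lumped) mass
    Me = np.einsum("eg,ga->ea", w, ws.N)
    rows = np.repeat(conn[:, :, None], 4, axis=2).ravel()
    cols = np.repeat(conn[:, None, :], 4, axis=1).ravel()
    Kd = sp.coo_matrix((He.ravel(), (rows, cols)), shape=(nn, nn)).tocsr()
    Ml = np.zeros(nn)
    np.add.at(Ml, conn.ravel(), Me.ravel())

    active = np.zeros(nn, dtype=bool)
    active[np.unique(conn)] = True
    source = np.asarray(mesh.boundary_nodes.get("msc_source", []), dtype=int)
    if source.size == 0:
        raise ValueError("mesh has no MSC source boundary set")
    op = (Kd, Ml, active, source)
    mesh._diffusion_operator = op
    return op


def diffuse_step(mesh: MeshModel, state: DiffusionState, dt: float) -> DiffusionState:
    """Implicit diffusion update over one increment of ``dt`` days.

    The source surface carries the Dirichlet value c_b(t); concentrations
    are clipped to [0, c_b] (discrete maximum principle).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    Kd, Ml, active, source = _diffusion_operator(mesh)
    nn = mesh.n_nodes

    act = np.flatnonzero(active)
    interior = np.setdiff1d(act, source, assume_unique=False)
    c_new = state.c.copy()
    c_new[source] = state.c_b

    # (M/dt + D K) c = M/dt c_old, Dirichlet columns folded into the rhs
    Aint = (sp.diags(Ml[interior] / dt)
            + state.D * Kd[interior][:, interior]).tocsc()
    rint = (Ml[interior] / dt) * state.c[interior] \
        - state.D * (Kd[interior][:, source] @ np.full(source.size, state.c_b))
    c_new[interior] = spla.spsolve(Aint, rint)
    np.clip(c_new, 0.0, max(state.c_b, 0.0), out=c_new)
    c_new[~active] = 0.0
    return replace(state, c=c_new)
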