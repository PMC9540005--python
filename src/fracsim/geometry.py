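"""Idealized fracture geometries as labelled structured quad meshes.

Unplated and calibration variants are 2D axisymmetric (coordinates (r, z));
the plated variant is a plane-strain full cross-section (coordinates (x, z))
with a bonded plate strip on the +x side spanning the fracture gap.

All dimensions are in mm and configurable; the default cross-section
(outer radius 10 mm, wall 5 mm) follows the common idealized-tibia
convention and is overridable through :class:`GeometrySpec`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np

from .materials import DEFAULT_MATERIALS, PoroMaterial

__all__ = [
    "GeometrySpec",
    "MeshModel",
    "build_fracture_model",
    "assign_region_materials",
    "spanning_path_exists",
    "REGION_LABELS",
]

REGION_LABELS = (
    "cortex",
    "marrow",
    "inner_callus",
    "callus_focus",
    "outer_callus",
    "plate",
)
CALLUS_REGIONS = ("inner_callus", "callus_focus", "outer_callus")

#: region -> material-table key at t = 0 (callus starts as granulation tissue)
REGION_MATERIAL_KEY = {
    "cortex": "cortex",
    "marrow": "marrow",
    "inner_callus": "granulation",
    "callus_focus": "granulation",
    "outer_callus": "granulation",
    "plate": "plate",
}


@dataclass
class GeometrySpec:
    """Parametric description of an idealized fracture model."""

    variant: str = "unplated"            # unplated | plated | calibration
    fracture_gap: float = 3.0            # mm
    cortex_outer_radius: float = 10.0    # mm
    cortex_inner_radius: float = 5.0     # mm
    callus_extent: float = 10.0          # axial half-extent of the callus, mm
    callus_thickness: float = 6.0        # radial thickness of the outer callus, mm
    half_length: float = 18.0            # axial half-length of the model, mm
    plate_thickness: float = 4.0         # mm
    plate_half_span: float = 13.0        # axial half-span of the plate, mm
    plate_modulus: float = 110_000.0     # MPa
    mesh_target_size: float = 1.0        # mm

    def __post_init__(self) -> None:
        if self.variant not in ("unplated", "plated", "calibration"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.fracture_gap > 0:
            raise ValueError("fracture_gap must be positive")
        if not self.cortex_inner_radius < self.cortex_outer_radius:
            raise ValueError("cortex_inner_radius must be < cortex_outer_radius")
        if not self.mesh_target_size > 0:
            raise ValueError("mesh_target_size must be positive")
        if self.fracture_gap / 2.0 >= self.callus_extent:
            raise ValueError("fracture gap exceeds callus axial extent")
        if self.callus_extent >= self.half_length:
            raise ValueError("callus_extent must be < half_length")
        if self.variant == "plated" and self.plate_half_span >= self.half_length:
            raise ValueError("plate_half_span must be < half_length")

    @classmethod
    def calibration_defaults(cls, **overrides) -> "GeometrySpec":
        """Ovine-metatarsus-proportioned osteotomy model (3 mm gap).

        Dimensions are reconstructions of the calibration geometry and are
        fully overridable.
        """
        base = dict(
            variant="calibration",
            fracture_gap=3.0,
            cortex_outer_radius=7.0,
            cortex_inner_radius=4.0,
            callus_extent=8.0,
            callus_thickness=4.0,
            half_length=16.0,
            mesh_target_size=1.0,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MeshModel:
    """Labelled structured quad mesh with region and boundary metadata.

    ``nodes`` holds (r, z) for axisymmetric variants or (x, z) for the
    plane-strain plated variant.  Boundary sets are node-index arrays;
    boundary faces are (element, node_a, node_b) triples used for traction
    assembly.
    """

    nodes: np.ndarray                       # (n_nodes, 2) float
    elements: np.ndarray                    # (n_elems, 4) int, CCW quads
    region: np.ndarray                      # (n_elems,) str
    axisymmetric: bool
    boundary_nodes: dict[str, np.ndarray] = field(default_factory=dict)
    boundary_faces: dict[str, np.ndarray] = field(default_factory=dict)
    spec: GeometrySpec | None = None

    _adjacency: list[list[int]] | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_centers(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        """Plain (meridional/in-plane) quad areas via the shoelace formula."""
        quad = self.nodes[self.elements]                     # (ne, 4, 2)
        x, y = quad[..., 0], quad[..., 1]
        xs, ys = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.abs(np.sum(x * ys - xs * y, axis=1))

    def region_areas(self) -> dict[str, float]:
        areas = self.element_areas()
        return {
            lab: float(areas[self.region == lab].sum())
            for lab in np.unique(self.region)
        }

    def adjacency(self) -> list[list[int]]:
        """Symmetric element adjacency through shared edges (cached)."""
        if self._adjacency is None:
            edge_map: dict[tuple[int, int], int] = {}
            adj: list[list[int]] = [[] for _ in range(self.n_elements)]
            for e, conn in enumerate(self.elements):
                for i in range(4):
                    a, b = conn[i], conn[(i + 1) % 4]
                    key = (a, b) if a < b else (b, a)
                    other = edge_map.pop(key, None)
                    if other is None:
                        edge_map[key] = e
                    else:
                        adj[e].append(other)
                        adj[other].append(e)
            self._adjacency = adj
        return self._adjacency

    def elements_in(self, *labels: str) -> np.ndarray:
        mask = np.isin(self.region, labels)
        return np.flatnonzero(mask)


def _segment_coords(breaks: list[float], target: float) -> np.ndarray:
    """1D coordinates covering each [b_i, b_i+1] with ~target-sized cells.

    Every break is an exact grid coordinate so region interfaces are
    resolved identically at any resolution.
    """
    coords = [breaks[0]]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(round((hi - lo) / target)))
        coords.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(coords)


def _classify(spec: GeometrySpec, xc: float, zc: float) -> str | None:
    """Region label for a cell centred at (xc, zc); None means no material."""
    g2 = spec.fracture_gap / 2.0
    ri, ro = spec.cortex_inner_radius, spec.cortex_outer_radius
    ce, ct = spec.callus_extent, spec.callus_thickness
    r = abs(xc)
    if spec.variant == "plated":
        pt, ps = spec.plate_thickness, spec.plate_half_span
        if xc > ro and xc < ro + pt:
            return "plate" if abs(zc) < ps else None
        callus_outer_hi = ro + pt + ct
        if xc >= ro + pt:
            if xc < callus_outer_hi and abs(zc) < ce:
                return "outer_callus"
            return None
        if xc < -ro:
            if xc > -(ro + ct) and abs(zc) < ce:
                return "outer_callus"
            return None
    else:
        if r > ro:
            if r < ro + ct and abs(zc) < ce:
                return "outer_callus"
            return None
    if r > ri:  # cortical wall band
        return "callus_focus" if abs(zc) < g2 else "cortex"
    return "inner_callus" if abs(zc) < ce else "marrow"


def build_fracture_model(spec: GeometrySpec) -> MeshModel:
    """Build the labelled mesh for the given geometry specification."""
    g2 = spec.fracture_gap / 2.0
    ri, ro = spec.cortex_inner_radius, spec.cortex_outer_radius
    ce, ct, L = spec.callus_extent, spec.callus_thickness, spec.half_length
    h = spec.mesh_target_size

    z_breaks = sorted({-L, -ce, -g2, g2, ce, L})
    if spec.variant == "plated":
        ps, pt = spec.plate_half_span, spec.plate_thickness
        z_breaks = sorted(set(z_breaks) | {-ps, ps})
        x_breaks = sorted(
            {-(ro + ct), -ro, -ri, 0.0, ri, ro, ro + pt, ro + pt + ct}
        )
        axisymmetric = False
    else:
        x_breaks = [0.0, ri, ro, ro + ct]
        axisymmetric = True

    xs = _segment_coords(x_breaks, h)
    zs = _segment_coords(z_breaks, h)
    nx, nz = len(xs) - 1, len(zs) - 1

    # classify cells on the tensor grid, drop void cells
    xc = 0.5 * (xs[:-1] + xs[1:])
    zc = 0.5 * (zs[:-1] + zs[1:])
    labels = []
    cells = []
    node_id = -np.ones((len(xs), len(zs)), dtype=int)
    for j in range(nz):
        for i in range(nx):
            lab = _classify(spec, xc[i], zc[j])
            if lab is None:
                continue
            labels.append(lab)
            cells.append((i, j))

    # number only the nodes actually referenced
    for (i, j) in cells:
        for di, dj in ((0, 0), (1, 0), (1, 1), (0, 1)):
            node_id[i + di, j + dj] = 0
    used = np.argwhere(node_id == 0)
    for k, (i, j) in enumerate(used):
        node_id[i, j] = k
    nodes = np.column_stack([xs[used[:, 0]], zs[used[:, 1]]])

    elements = np.empty((len(cells), 4), dtype=int)
    for e, (i, j) in enumerate(cells):
        elements[e] = (
            node_id[i, j], node_id[i + 1, j],
            node_id[i + 1, j + 1], node_id[i, j + 1],
        )
    region = np.asarray(labels, dtype=object)

    areas = _quad_areas(nodes, elements)
    if np.any(areas <= 0):
        raise ValueError("degenerate mesh: inverted or zero-area elements")

    mesh = MeshModel(nodes, elements, region, axisymmetric, spec=spec)
    _build_boundary_sets(mesh)
    return mesh


def _quad_areas(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    quad = nodes[elements]
    x, y = quad[..., 0], quad[..., 1]
    xs, ys = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
    return 0.5 * np.sum(x * ys - xs * y, axis=1)


def _build_boundary_sets(mesh: MeshModel) -> None:
    """Populate loaded/fixed end, drainage surface and MSC source sets."""
    spec = mesh.spec
    nodes, elements, region = mesh.nodes, mesh.elements, mesh.region
    zmax, zmin = nodes[:, 1].max(), nodes[:, 1].min()
    tol = 1e-9
    ro = spec.cortex_outer_radius
    g2 = spec.fracture_gap / 2.0
    ri = spec.cortex_inner_radius

    on_top = np.abs(nodes[:, 1] - zmax) < tol
    on_bot = np.abs(nodes[:, 1] - zmin) < tol
    mesh.boundary_nodes["loaded_end"] = np.flatnonzero(on_top)
    mesh.boundary_nodes["fixed_end"] = np.flatnonzero(on_bot)

    # exterior edges: edges referenced by exactly one element
    edge_owner: dict[tuple[int, int], tuple[int, int, int]] = {}
    for e, conn in enumerate(elements):
        for i in range(4):
            a, b = conn[i], conn[(i + 1) % 4]
            key = (a, b) if a < b else (b, a)
            if key in edge_owner:
                del edge_owner[key]
            else:
                edge_owner[key] = (e, a, b)
    exterior = list(edge_owner.values())

    is_callus = np.isin(region, CALLUS_REGIONS)
    callus_nodes = np.zeros(mesh.n_nodes, dtype=bool)
    callus_nodes[np.unique(elements[is_callus])] = True

    # loaded-end faces restricted to bone + marrow + (plate) cross-section
    loaded, drainage_faces = [], []
    exterior_node = np.zeros(mesh.n_nodes, dtype=bool)
    for e, a, b in exterior:
        za, zb = nodes[a, 1], nodes[b, 1]
        on_axis = mesh.axisymmetric and (
            abs(nodes[a, 0]) < tol and abs(nodes[b, 0]) < tol
        )
        if not on_axis:
            exterior_node[a] = exterior_node[b] = True
        if abs(za - zmax) < tol and abs(zb - zmax) < tol:
            loaded.append((e, a, b))
        elif (
            is_callus[e]
            and not on_axis
            and not (abs(za - zmin) < tol and abs(zb - zmin) < tol)
        ):
            drainage_faces.append((e, a, b))
    mesh.boundary_faces["loaded_end"] = np.asarray(loaded, dtype=int)
    mesh.boundary_faces["drainage"] = (
        np.asarray(drainage_faces, dtype=int)
        if drainage_faces else np.empty((0, 3), dtype=int)
    )
    if drainage_faces:
        dn = np.unique(np.asarray(drainage_faces, dtype=int)[:, 1:])
    else:
        dn = np.empty(0, dtype=int)
    mesh.boundary_nodes["drainage"] = dn

    # MSC source surface: callus nodes on the exterior or shared with
    # marrow/cortex (periosteal + marrow + soft-tissue interfaces), except
    # the transverse cortical fracture faces at |z| = gap/2, ri <= r <= ro.
    other_nodes = np.zeros(mesh.n_nodes, dtype=bool)
    for lab in ("marrow", "cortex"):
        sel = elements[region == lab]
        if len(sel):
            other_nodes[np.unique(sel)] = True
    candidate = callus_nodes & (exterior_node | other_nodes)
    r = np.abs(nodes[:, 0])
    on_fracture_face = (
        (np.abs(np.abs(nodes[:, 1]) - g2) < tol)
        & (r >= ri - tol)
        & (r <= ro + tol)
    )
    mesh.boundary_nodes["msc_source"] = np.flatnonzero(
        candidate & ~on_fracture_face
    )


def assign_region_materials(
    mesh: MeshModel,
    material_table: dict[str, PoroMaterial] | None = None,
) -> list[PoroMaterial]:
    """Per-element initial materials from a region -> material table.

    The table is keyed by tissue name (see :data:`REGION_MATERIAL_KEY`);
    callus regions start as granulation tissue.  Raises ``KeyError`` for a
    region without a table entry.
    """
    table = dict(DEFAULT_MATERIALS)
    if material_table:
        table.update(material_table)
    out: list[PoroMaterial] = []
    for lab in mesh.region:
        key = REGION_MATERIAL_KEY.get(lab)
        if key is None or key not in table:
            raise KeyError(f"no material for region {lab!r}")
        mat = table[key]
        if lab == "plate" and mesh.spec is not None:
            mat = mat.with_modulus(mesh.spec.plate_modulus)
        out.append(mat)
    return out


def spanning_path_exists(mesh: MeshModel, element_predicate) -> bool:
    """True iff predicate-true callus-focus elements form an adjacency-
    connected chain linking the two cortical fracture faces.

    ``element_predicate`` is a callable on global element indices or a
    boolean array over all elements.
    """
    focus = mesh.elements_in("callus_focus")
    if focus.size == 0:
        return False
    if callable(element_predicate):
        ok = {int(e) for e in focus if element_predicate(int(e))}
    else:
        pred = np.asarray(element_predicate, dtype=bool)
        ok = {int(e) for e in focus if pred[e]}
    if not ok:
        return False

    adj = mesh.adjacency()
    centers = mesh.element_centers()
    is_cortex = mesh.region == "cortex"
    start, goal = set(), set()
    for e in focus:
        for nb in adj[e]:
            if is_cortex[nb]:
                if centers[nb, 1] > 0:
                    start.add(int(e))
                else:
                    goal.add(int(e))
    start &= ok
    goal &= ok
    if not start or not goal:
        return False

    seen = set(start)
    queue = deque(start)
    while queue:
        e = queue.popleft()
        if e in goal:
            return True
        for nb in adj[e]:
            if nb in ok and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return False
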