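"""Mesh construction, region labelling, materials and path queries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracsim import (
    GeometrySpec,
    assign_region_materials,
    build_fracture_model,
    spanning_path_exists,
)
from fracsim.geometry import CALLUS_REGIONS
from fracsim.materials import PoroMaterial


def test_unplated_regions_no_plate():
    mesh = build_fracture_model(GeometrySpec(fracture_gap=3.0,
                                             mesh_target_size=1.5))
    labels = set(mesh.region)
    assert labels == {"cortex", "marrow", "inner_callus", "callus_focus",
                      "outer_callus"}


def test_plated_has_plate_with_titanium_modulus():
    spec = GeometrySpec(variant="plated", mesh_target_size=1.5)
    mesh = build_fracture_model(spec)
    assert "plate" in set(mesh.region)
    # bone/callus regions unchanged relative to the unplated variant
    assert set(mesh.region) - {"plate"} == {
        "cortex", "marrow", "inner_callus", "callus_focus", "outer_callus"}
    mats = assign_region_materials(mesh)
    plate_E = {mats[e].E for e in mesh.elements_in("plate")}
    assert plate_E == {110_000.0}


def test_refinement_grows_elements_and_conserves_areas():
    coarse = build_fracture_model(GeometrySpec(mesh_target_size=2.0))
    fine = build_fracture_model(GeometrySpec(mesh_target_size=1.0))
    ratio = fine.n_elements / coarse.n_elements
    assert 3.0 < ratio < 5.0
    a0, a1 = coarse.region_areas(), fine.region_areas()
    for lab in a0:
        assert abs(a1[lab] - a0[lab]) / a0[lab] < 0.01


def test_mirror_symmetry_about_gap_midplane():
    mesh = build_fracture_model(GeometrySpec(mesh_target_size=1.5))
    centers = mesh.element_centers()
    key = {tuple(np.round([c[0], c[1]], 6)): r
           for c, r in zip(centers, mesh.region)}
    for c, r in zip(centers, mesh.region):
        assert key[tuple(np.round([c[0], -c[1]], 6))] == r


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="gap"):
        GeometrySpec(fracture_gap=25.0)
    with pytest.raises(ValueError):
        GeometrySpec(fracture_gap=-1.0)
    with pytest.raises(ValueError):
        GeometrySpec(cortex_inner_radius=11.0)
    with pytest.raises(ValueError):
        GeometrySpec(mesh_target_size=0.0)


def test_boundary_sets_reference_existing_nodes():
    mesh = build_fracture_model(GeometrySpec(mesh_target_size=1.5))
    for name in ("loaded_end", "fixed_end", "drainage", "msc_source"):
        nodes = mesh.boundary_nodes[name]
        assert len(nodes) > 0
        assert nodes.max() < mesh.n_nodes


def test_msc_source_excludes_fracture_faces():
    spec = GeometrySpec(mesh_target_size=1.0)
    mesh = build_fracture_model(spec)
    src = mesh.boundary_nodes["msc_source"]
    g2 = spec.fracture_gap / 2.0
    ri, ro = spec.cortex_inner_radius, spec.cortex_outer_radius
    r, z = np.abs(mesh.nodes[src, 0]), mesh.nodes[src, 1]
    on_face = (np.abs(np.abs(z) - g2) < 1e-9) & (r >= ri) & (r <= ro)
    assert not on_face.any()


def test_adjacency_symmetric(default_mesh):
    adj = default_mesh.adjacency()
    for e, nbs in enumerate(adj):
        for nb in nbs:
            assert e in adj[nb]


def test_assign_materials_table_values(default_mesh):
    mats = assign_region_materials(default_mesh)
    cortex = default_mesh.elements_in("cortex")[0]
    m = mats[cortex]
    assert (m.E, m.permeability, m.nu, m.porosity) == (17_000.0, 1e-17, 0.37, 0.04)
    callus = default_mesh.elements_in("callus_focus")[0]
    assert mats[callus].porosity == 0.8
    assert mats[callus].E == 0.001  # granulation at t = 0


def test_assign_materials_missing_region(default_mesh):
    import copy
    mesh = copy.copy(default_mesh)
    mesh.region = default_mesh.region.copy()
    mesh.region[0] = "cartilage_x"
    with pytest.raises(KeyError):
        assign_region_materials(mesh)


def test_poromaterial_invariants():
    with pytest.raises(ValueError):
        PoroMaterial(E=-1.0, nu=0.3, permeability=1e-14, porosity=0.5)
    with pytest.raises(ValueError):
        PoroMaterial(E=1.0, nu=0.6, permeability=1e-14, porosity=0.5)
    m = PoroMaterial(E=1.0, nu=0.1, permeability=1e-14, porosity=0.3)
    assert m.solid_fraction + m.porosity == 1.0


# ----------------------------------------------------------- path queries

def test_spanning_path_trivial(default_mesh):
    assert spanning_path_exists(default_mesh, lambda e: True)
    assert not spanning_path_exists(default_mesh, lambda e: False)


def _bfs_oracle(mesh, ok_set):
    """Independent oracle: brute-force reachability via edge sets."""
    import itertools
    focus = list(mesh.elements_in("callus_focus"))
    edges = {}
    for e in focus:
        edges[e] = set()
    node_sets = {e: set(mesh.elements[e]) for e in range(mesh.n_elements)}
    for a, b in itertools.combinations(focus, 2):
        if len(node_sets[a] & node_sets[b]) == 2:
            edges[a].add(b)
            edges[b].add(a)
    centers = mesh.element_centers()
    cortex = [e for e in range(mesh.n_elements) if mesh.region[e] == "cortex"]
    starts, goals = set(), set()
    for e in focus:
        for c in cortex:
            if len(node_sets[e] & node_sets[c]) == 2:
                (starts if centers[c, 1] > 0 else goals).add(e)
    starts &= ok_set
    goals &= ok_set
    frontier = set(starts)
    seen = set(starts)
    while frontier:
        nxt = set()
        for e in frontier:
            for nb in edges[e]:
                if nb in ok_set and nb not in seen:
                    nxt.add(nb)
                    seen.add(nb)
        frontier = nxt
    return bool(seen & goals)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_spanning_path_matches_oracle(seed):
    mesh = build_fracture_model(GeometrySpec(mesh_target_size=1.0))
    rng = np.random.default_rng(seed)
    pred = rng.random(mesh.n_elements) < 0.55
    ok = {int(e) for e in mesh.elements_in("callus_focus") if pred[e]}
    assert spanning_path_exists(mesh, pred) == _bfs_oracle(mesh, ok)
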