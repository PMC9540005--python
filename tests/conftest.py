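"""Shared fixtures; expensive coupled-simulation scenarios are session-scoped."""

from __future__ import annotations

import pytest

from fracsim import (
    GeometrySpec,
    RemodelParams,
    Simulation,
    SimulationConfig,
    build_fracture_model,
    run_simulation,
)

# coarse desk-scale discretization used for all scenario runs
SCEN_H = 1.2


def scen_spec(**kw) -> GeometrySpec:
    kw.setdefault("mesh_target_size", SCEN_H)
    return GeometrySpec(**kw)


def scen_config(**kw) -> SimulationConfig:
    kw.setdefault("geometry", scen_spec())
    return SimulationConfig(**kw)


def run_until_union(cfg: SimulationConfig) -> Simulation:
    """Advance until union or the non-union deadline (cheap partial run)."""
    sim = Simulation(cfg)
    while sim.t < min(cfg.duration, cfg.nonunion_deadline) and not sim.union:
        sim.step()
    return sim


@pytest.fixture(scope="session")
def default_mesh():
    return build_fracture_model(scen_spec())


@pytest.fixture(scope="session")
def union_days_by_condition():
    out = {}
    for cond in ["LC_A", "LC_B", "LC_C", "LC_D", "LC_E"]:
        sim = run_until_union(scen_config(condition=cond))
        out[cond] = sim.union_day
    return out


@pytest.fixture(scope="session")
def union_days_by_gap():
    out = {}
    for gap in [3.0, 4.0, 6.0, 8.0]:
        cfg = scen_config(geometry=scen_spec(fracture_gap=gap))
        out[gap] = run_until_union(cfg).union_day
    return out


@pytest.fixture(scope="session")
def plated_union_days():
    out = {}
    for cond in ["LC_C", "LC_D", "LC_E"]:
        cfg = scen_config(geometry=scen_spec(variant="plated"), condition=cond)
        out[cond] = run_until_union(cfg).union_day
    return out


@pytest.fixture(scope="session")
def year_unplated():
    return run_simulation(scen_config(condition="LC_A"))


@pytest.fixture(scope="session")
def year_plated():
    cfg = scen_config(geometry=scen_spec(variant="plated"), condition="LC_A")
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def year_plated_damage_pair():
    """Plated LC_A full-year runs with and without fatigue damage.

    Run with a physiological daily cycle count so that damage accumulation
    is non-negligible at desk scale (1 cycle/day leaves the fatigue terms
    orders of magnitude below threshold on a 2D bonded-plate model).
    """
    out = {}
    for damage in (True, False):
        cfg = scen_config(
            geometry=scen_spec(variant="plated"), condition="LC_A",
            damage=damage, remodelling=RemodelParams(cycles_per_day=5000.0),
        )
        out["D" if damage else "ND"] = run_simulation(cfg)
    return out
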