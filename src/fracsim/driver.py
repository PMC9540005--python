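"""Coupled simulation driver: staged loading, adaptive time stepping,
union detection and the healing -> remodelling phase transition.

Each increment performs, in order: one daily-loading mechanics solve,
healing updates on callus elements (while in the healing phase),
SED/damage remodelling on cortical elements (always) and on callus
elements (after the global transition), the three time-step controls, and
the MSC boundary ramp + diffusion step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import (
    CALLUS_REGIONS,
    GeometrySpec,
    MeshModel,
    assign_region_materials,
    build_fracture_model,
    spanning_path_exists,
)
from .materials import DEFAULT_MATERIALS
from .poroelastic import material_arrays, solve_daily_loading
from .diffusion import DiffusionState, diffuse_step, update_boundary_concentration
from .healing import (
    MechanoRegParams,
    TissueState,
    biophysical_stimulus,
    healing_time_scale,
    tissue_membership,
)
from .remodelling import (
    BoneState,
    RemodelParams,
    damage_resorption_rate,
    damage_update,
    density_modulus_law,
    inverse_density_modulus_law,
    remodel_time_scales,
    sed_remodelling_rate,
)

__all__ = [
    "LoadSchedule",
    "SimulationConfig",
    "SimulationResult",
    "TimeStepController",
    "applied_load",
    "union_check",
    "transition_check",
    "advance_increment",
    "run_simulation",
    "Simulation",
]

#: initial-phase loads in N for the unplated conditions (10-20% of a 700 N
#: body weight) and initial-phase applied stresses in MPa for the plated
#: conditions (reconstructed; the text anchors only LC(H) at 6.6 MPa).
UNPLATED_INITIAL_N = {"LC_A": 70.0, "LC_B": 87.5, "LC_C": 105.0,
                      "LC_D": 122.5, "LC_E": 140.0}
PLATED_INITIAL_MPA = {"LC_F": 1.1, "LC_G": 2.7, "LC_H": 6.6}


@dataclass
class LoadSchedule:
    """Piecewise post-operative loading: indirect loading to day 28, ramped
    gait recovery to day 112, then full gait (300% body weight)."""

    condition: str = "LC_A"
    body_weight_N: float = 700.0
    breakpoints: tuple = (28.0, 56.0, 112.0)
    cross_section_area: float = math.pi * 100.0   # mm^2
    duration: float = 365.0
    crutch_fraction_bw: float = 0.3               # partial weight bearing at day 56
    initial_load_N: float | None = None           # override; else per condition

    def __post_init__(self) -> None:
        cond = self.condition
        if self.initial_load_N is None:
            if cond in UNPLATED_INITIAL_N:
                self.initial_load_N = UNPLATED_INITIAL_N[cond]
            elif cond in PLATED_INITIAL_MPA:
                self.initial_load_N = (
                    PLATED_INITIAL_MPA[cond] * self.cross_section_area
                )
            else:
                raise ValueError(f"unknown loading condition {cond!r}")

    @property
    def final_load_N(self) -> float:
        return 3.0 * self.body_weight_N

    def to_dict(self) -> dict:
        return asdict(self)


def applied_load(schedule: LoadSchedule, t: float) -> float:
    """Axial load magnitude (N) at day ``t``; linear ramps between phases."""
    if t < 0 or t > schedule.duration:
        raise ValueError(f"t={t} outside [0, {schedule.duration}]")
    t0, t1, t2 = schedule.breakpoints
    l0, l2 = schedule.initial_load_N, schedule.final_load_N
    # conditions keep their relative severity through the crutch phase:
    # the day-56 plateau scales with the initial load (LC_A -> 30% BW)
    factor = l0 / UNPLATED_INITIAL_N["LC_A"]
    l1 = max(l0, factor * schedule.crutch_fraction_bw * schedule.body_weight_N)
    if t <= t0:
        return l0
    if t <= t1:
        return l0 + (l1 - l0) * (t - t0) / (t1 - t0)
    if t >= t2:
        return l2
    return l1 + (l2 - l1) * (t - t1) / (t2 - t1)


@dataclass
class TimeStepController:
    dt: float
    dt_min: float = 1e-3
    dt_max: float = 1.0
    growth: float = 1.2
    last_factors: dict = field(default_factory=dict)

    def accept(self, factors: dict[str, float]) -> float:
        """Scaled increment honouring the smallest control factor."""
        self.last_factors = dict(factors)
        f = min(1.0, *factors.values()) if factors else 1.0
        dt_acc = max(self.dt * f, self.dt_min)
        self.dt = min(dt_acc * self.growth, self.dt_max)
        return dt_acc


@dataclass
class SimulationConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    condition: str = "LC_A"
    healing: MechanoRegParams = field(default_factory=MechanoRegParams)
    remodelling: RemodelParams = field(default_factory=RemodelParams)
    diffusion_coefficient: float = 0.15      # mm^2/day (literature range 0.1-0.3)
    damage: bool = True                      # D vs ND run switch
    duration: float = 365.0
    dt_initial: float = 0.25
    dt_min: float = 0.05
    dt_max: float = 1.0
    dt_growth: float = 1.2
    mech_duration_s: float = 86400.0     # daily event: quasi-static ramp over the day
    mech_ramp_s: float = 86400.0
    mech_steps: int = 5
    union_bone_threshold: float = 0.5
    nonunion_deadline: float = 172.0         # day 112 + 60
    confluence_level: float = 0.95
    modulus_floor: float = 0.01              # MPa, numerical floor
    fixed_load_N: float | None = None        # constant-load override (calibration)
    seed: int = 0                            # reserved; algorithms deterministic

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def schedule(self) -> LoadSchedule:
        area = math.pi * self.geometry.cortex_outer_radius ** 2
        return LoadSchedule(
            condition=self.condition,
            cross_section_area=area,
            duration=max(self.duration, 365.0),
        )

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "condition": self.condition,
            "healing": self.healing.to_dict(),
            "remodelling": self.remodelling.to_dict(),
            "diffusion_coefficient": self.diffusion_coefficient,
            "damage": self.damage,
            "duration": self.duration,
            "dt_initial": self.dt_initial,
            "dt_min": self.dt_min,
            "dt_max": self.dt_max,
            "dt_growth": self.dt_growth,
            "mech_duration_s": self.mech_duration_s,
            "mech_ramp_s": self.mech_ramp_s,
            "mech_steps": self.mech_steps,
            "union_bone_threshold": self.union_bone_threshold,
            "nonunion_deadline": self.nonunion_deadline,
            "confluence_level": self.confluence_level,
            "modulus_floor": self.modulus_floor,
            "fixed_load_N": self.fixed_load_N,
            "seed": self.seed,
        }


@dataclass
class SimulationResult:
    series: "object"                  # pandas DataFrame of the time series
    union_day: float | None
    transition_day: float | None
    status: str                       # healed | non_union | running
    snapshot: dict
    config: SimulationConfig
    dt_log: list

    @property
    def final_focus_modulus(self) -> float:
        return float(self.series["E_focus"].iloc[-1])


# per-tissue poroelastic mixture properties, ordered (gran, f, c, ib, mb)
_MIX_NU = np.array([0.167, 0.167, 0.167, 0.3, 0.3])
_MIX_LOGK = np.log10(np.array([1e-14, 1e-14, 5e-15, 1e-13, 3.7e-13]) * 1e12)
_MIX_KF = np.array([2300.0, 2300.0, 13_920.0, 13_920.0, 13_920.0])
_MIX_POROSITY = 0.8
_KS = 2300.0


class Simulation:
    """Mutable simulation state plus the per-increment update rule."""

    def __init__(self, config: SimulationConfig, mesh: MeshModel | None = None):
        self.config = config
        self.mesh = mesh if mesh is not None else build_fracture_model(config.geometry)
        self.sched = config.schedule()

        region = self.mesh.region
        self.callus_els = self.mesh.elements_in(*CALLUS_REGIONS)
        self.focus_els = self.mesh.elements_in("callus_focus")
        self.cortex_els = self.mesh.elements_in("cortex")
        self.marrow_els = self.mesh.elements_in("marrow")
        self.plate_els = self.mesh.elements_in("plate")
        # positions of focus elements within the callus ordering
        self._focus_in_callus = np.searchsorted(self.callus_els, self.focus_els)

        self.tissue = TissueState(n=self.callus_els.size, params=config.healing)
        self.cortex_bone = BoneState(
            rho=np.full(self.cortex_els.size, config.remodelling.rho_U)
        )
        self.callus_bone: BoneState | None = None
        self.diff = DiffusionState.initial(self.mesh, config.diffusion_coefficient)
        self.controller = TimeStepController(
            dt=config.dt_initial, dt_min=config.dt_min,
            dt_max=config.dt_max, growth=config.dt_growth,
        )

        self.t = 0.0
        self.increment = 0
        self.union = False
        self.union_day: float | None = None
        self.transitioned = False
        self.transition_day: float | None = None
        self.confluence_day: float | None = None
        self.series: list[dict] = []
        self.dt_log: list[tuple[float, float]] = []
        self._rate_history: list[tuple[float, float, float, float]] = []
        self._last_snapshot = None

        self._base = material_arrays(
            assign_region_materials(self.mesh), self.mesh.n_elements
        )

    # ---------------------------------------------------------- materials
    def _current_materials(self) -> dict[str, np.ndarray]:
        cfg = self.config
        mats = {k: v.copy() for k, v in self._base.items()}
        # cortical bone follows its remodelled density
        mats["E"][self.cortex_els] = density_modulus_law(self.cortex_bone.rho)
        ce = self.callus_els
        if self.transitioned:
            E = np.maximum(self.tissue.E_smoothed, cfg.modulus_floor)
            mats["E"][ce] = E
            mats["nu"][ce] = 0.3
            mats["k_mm"][ce] = 3.7e-13 * 1e12
            mats["porosity"][ce] = _MIX_POROSITY
            kf = np.full(ce.size, 13_920.0)
        else:
            ts = self.tissue
            frac = np.stack([ts.m_gran, ts.m_f, ts.m_c, ts.m_ib, ts.m_mb])
            E = np.maximum(ts.E_smoothed, cfg.modulus_floor)
            mats["E"][ce] = E
            mats["nu"][ce] = _MIX_NU @ frac
            mats["k_mm"][ce] = 10.0 ** (_MIX_LOGK @ frac)
            mats["porosity"][ce] = _MIX_POROSITY
            kf = _MIX_KF @ frac
        nu = mats["nu"][ce]
        kd = mats["E"][ce] / (3.0 * (1.0 - 2.0 * nu))
        alpha = np.clip(1.0 - kd / _KS, 0.0, 1.0)
        n = mats["porosity"][ce]
        mats["alpha"][ce] = alpha
        mats["invQ"][ce] = n / kf + np.maximum(alpha - n, 0.0) / _KS
        return mats

    def _element_rho(self) -> np.ndarray:
        """Apparent density per element for the SED stimulus."""
        cfg = self.config
        rho = np.full(self.mesh.n_elements, 1.0)
        rho[self.cortex_els] = self.cortex_bone.rho
        rho[self.marrow_els] = 1.0
        if self.callus_bone is not None:
            rho[self.callus_els] = self.callus_bone.rho
        else:
            e = np.maximum(self.tissue.E_smoothed, cfg.modulus_floor)
            rho[self.callus_els] = np.clip(
                inverse_density_modulus_law(e),
                cfg.remodelling.rho_min, cfg.remodelling.rho_max,
            )
        return rho

    # ------------------------------------------------------------- checks
    def check_union(self) -> bool:
        bone = np.zeros(self.mesh.n_elements)
        if self.callus_bone is not None:
            return True
        bone[self.callus_els] = self.tissue.bone_fraction
        return union_check(self.mesh, bone, self.config.union_bone_threshold)

    def _check_transition(self) -> bool:
        window = self.config.healing.averaging_window
        lo = self.t - window
        rel = [r for r in self._rate_history if r[0] > lo]
        if not rel:
            return False
        mean_sed = float(np.mean([r[1] for r in rel]))
        mean_heal = float(np.mean([r[2] for r in rel]))
        return transition_check(mean_sed, mean_heal, self.union)

    # --------------------------------------------------------------- step
    def step(self) -> None:
        cfg = self.config
        t, dt_trial = self.t, self.controller.dt
        if cfg.fixed_load_N is not None:
            load_N = cfg.fixed_load_N
        else:
            load_N = applied_load(self.sched, min(t, self.sched.duration))
        stress = load_N / self.sched.cross_section_area

        rho_el = self._element_rho()
        mech = solve_daily_loading(
            self.mesh, self._current_materials(), stress,
            duration=cfg.mech_duration_s, n_steps=cfg.mech_steps,
            ramp_time=cfg.mech_ramp_s, load_kind="stress", rho=rho_el,
        )

        factors: dict[str, float] = {}
        rem = cfg.remodelling

        # --- healing rates on callus elements (healing phase only)
        if not self.transitioned:
            eps = mech.eps_dev[self.callus_els]
            wf = mech.wf_mag[self.callus_els]
            S = biophysical_stimulus(eps, wf, cfg.healing)
            tm = tissue_membership(S, cfg.healing)
            dc, dm = self.tissue.rates(tm)
            max_dm = max(float(np.max(np.abs(d))) for d in dm) * dt_trial
            factors["fracture"] = healing_time_scale(max_dm, cfg.healing)
            self._S_callus = S
        else:
            dc = dm = None
            self._S_callus = biophysical_stimulus(
                mech.eps_dev[self.callus_els], mech.wf_mag[self.callus_els],
                cfg.healing,
            )

        # --- remodelling rates (cortex always; callus after transition).
        # The per-month density cap is enforced directly on each element's
        # rate (a persistently over-cap stimulus must not shrink dt without
        # bound); the dt controls then see already-admissible rates.
        cap_rate = rem.drho_max / rem.month_days   # g/cm^3 per day
        sed_rates = {}
        dmg_rates = {}
        for name, els, bone in self._remodel_groups():
            psi = mech.psi[els]
            r_sed = sed_remodelling_rate(psi, bone.rho, rem)
            r_sed = np.clip(r_sed, -cap_rate, cap_rate)
            r_dmg = np.zeros_like(r_sed)
            if cfg.damage:
                damage_update(bone, mech.sigma[els], bone.rho,
                              rem.cycles_per_day, dt_trial, rem)
                r_dmg = damage_resorption_rate(bone, bone.rho,
                                               rem.cycles_per_day, rem)
                r_dmg = np.clip(r_dmg, -rem.damage_step / dt_trial, 0.0)
            sed_rates[name] = r_sed
            dmg_rates[name] = r_dmg
        all_sed = np.concatenate(list(sed_rates.values())) if sed_rates else np.zeros(0)
        all_dmg = np.concatenate(list(dmg_rates.values())) if dmg_rates else np.zeros(0)
        f_sed, f_dmg = remodel_time_scales(all_sed, all_dmg, dt_trial, rem)
        factors["sed"] = f_sed
        factors["damage"] = f_dmg

        dt = self.controller.accept(factors)

        # --- MSC boundary ramp + diffusion (frozen after the transition)
        if not self.transitioned:
            self.diff = update_boundary_concentration(self.diff, dt)
            self.diff = diffuse_step(self.mesh, self.diff, dt)
            self.tissue.c_m = self.diff.element_concentration(self.mesh)[self.callus_els]
            if self.confluence_day is None:
                cal = self.diff.c[np.unique(self.mesh.elements[self.callus_els])]
                if cal.min() >= cfg.confluence_level:
                    self.confluence_day = self.t + dt

        # --- apply state updates with the accepted increment
        E_focus_before = self.tissue.E_smoothed[self._focus_in_callus].mean()
        if not self.transitioned:
            self.tissue.apply_rates(dc, dm, dt)
        for name, els, bone in self._remodel_groups():
            rate = sed_rates[name] + dmg_rates[name]
            bone.rho = np.clip(bone.rho + rate * dt, rem.rho_min, rem.rho_max)

        self.t += dt
        self.increment += 1
        self.dt_log.append((self.t, dt))

        if self.callus_bone is not None:
            # post-transition: raw modulus tracks the remodelled density
            self.tissue.E_raw = density_modulus_law(self.callus_bone.rho)
            self.tissue.history.append((self.t, dt, self.tissue.E_raw))
            while len(self.tissue.history) > 1 and \
                    self.tissue.history[0][0] <= self.t - cfg.healing.averaging_window:
                self.tissue.history.pop(0)
            from .healing import smoothed_modulus
            self.tissue.E_smoothed = smoothed_modulus(
                self.tissue.history, cfg.healing.averaging_window)
        else:
            self.tissue.push_modulus(self.t, dt)

        # --- transition bookkeeping
        E_focus_after = self.tissue.E_smoothed[self._focus_in_callus].mean()
        dE_heal = abs(E_focus_after - E_focus_before)
        rho_cand = np.clip(
            inverse_density_modulus_law(
                np.maximum(self.tissue.E_smoothed[self._focus_in_callus],
                           cfg.modulus_floor)),
            rem.rho_min, rem.rho_max)
        psi_focus = mech.psi[self.focus_els]
        cand = sed_remodelling_rate(psi_focus, rho_cand, rem)
        dE_sed = float(np.mean(np.abs(3.0 * 3790.0 * rho_cand ** 2 * cand))) * dt
        self._rate_history.append((self.t, dE_sed, dE_heal, dt))
        lo = self.t - cfg.healing.averaging_window
        while len(self._rate_history) > 1 and self._rate_history[0][0] <= lo:
            self._rate_history.pop(0)

        if not self.union and self.check_union():
            self.union = True
            self.union_day = self.t
        if self.union and not self.transitioned and self._check_transition():
            self._enter_remodelling_phase()

        self._last_snapshot = mech
        self._record(load_N, dt)

    def _remodel_groups(self):
        groups = [("cortex", self.cortex_els, self.cortex_bone)]
        if self.callus_bone is not None:
            groups.append(("callus", self.callus_els, self.callus_bone))
        return groups

    def _enter_remodelling_phase(self) -> None:
        cfg = self.config
        self.transitioned = True
        self.transition_day = self.t
        rho0 = np.clip(
            inverse_density_modulus_law(
                np.maximum(self.tissue.E_smoothed, cfg.modulus_floor)),
            cfg.remodelling.rho_min, cfg.remodelling.rho_max,
        )
        self.callus_bone = BoneState(rho=rho0)

    def _record(self, load_N: float, dt: float) -> None:
        fi = self._focus_in_callus
        self.series.append({
            "t": self.t,
            "dt": dt,
            "load_N": load_N,
            "E_focus": float(self.tissue.E_smoothed[fi].mean()),
            "E_callus": float(self.tissue.E_smoothed.mean()),
            "rho_cortex": float(self.cortex_bone.rho.mean()),
            "bone_fraction_focus": float(self.tissue.bone_fraction[fi].mean()),
            "c_m_mean": float(self.tissue.c_m.mean()),
            "union": self.union,
            "transitioned": self.transitioned,
        })

    # -------------------------------------------------------------- runs
    def snapshot_arrays(self) -> dict[str, np.ndarray]:
        ne = self.mesh.n_elements
        out = {"region": self.mesh.region.astype(str)}
        rho = self._element_rho()
        E = np.zeros(ne)
        E[self.cortex_els] = density_modulus_law(self.cortex_bone.rho)
        E[self.marrow_els] = DEFAULT_MATERIALS["marrow"].E
        if self.plate_els.size:
            E[self.plate_els] = self.mesh.spec.plate_modulus
        E[self.callus_els] = self.tissue.E_smoothed
        out["E_smoothed"] = E
        out["rho"] = rho
        for name in ("m_f", "m_c", "m_ib", "m_mb"):
            arr = np.zeros(ne)
            arr[self.callus_els] = getattr(self.tissue, name)
            out[name] = arr
        m_gran = np.zeros(ne)
        m_gran[self.callus_els] = self.tissue.m_gran
        out["m_gran"] = m_gran
        for name in ("c_m", "c_f", "c_c", "c_ib", "c_mb"):
            arr = np.zeros(ne)
            arr[self.callus_els] = getattr(self.tissue, name)
            out[name] = arr
        S = np.zeros(ne)
        if getattr(self, "_S_callus", None) is not None:
            S[self.callus_els] = self._S_callus
        out["stimulus"] = S
        omega = np.zeros(ne)
        domega = np.zeros(ne)
        omega[self.cortex_els] = self.cortex_bone.omega
        domega[self.cortex_els] = self.cortex_bone.delta_omega
        if self.callus_bone is not None:
            omega[self.callus_els] = self.callus_bone.omega
            domega[self.callus_els] = self.callus_bone.delta_omega
        out["omega"] = omega
        out["delta_omega"] = domega
        if self._last_snapshot is not None:
            out["E_raw"] = np.zeros(ne)
            out["E_raw"][self.callus_els] = self.tissue.E_raw
            out["psi"] = self._last_snapshot.psi
        return out

    def result(self, status: str) -> SimulationResult:
        import pandas as pd

        return SimulationResult(
            series=pd.DataFrame(self.series),
            union_day=self.union_day,
            transition_day=self.transition_day,
            status=status,
            snapshot=self.snapshot_arrays(),
            config=self.config,
            dt_log=self.dt_log,
        )


def union_check(mesh: MeshModel, bone_fraction, threshold: float = 0.5) -> bool:
    """True iff ossified focus elements bridge the cortical fragments."""
    bone = np.asarray(bone_fraction, dtype=float)
    return spanning_path_exists(mesh, bone >= threshold)


def transition_check(mean_dE_sed: float, mean_dE_healing: float,
                     union: bool) -> bool:
    """Remodelling takes over once union exists and the SED-driven modulus
    change outpaces the healing-driven change (caller latches the result)."""
    if not union:
        return False
    return mean_dE_sed > mean_dE_healing


def advance_increment(sim: Simulation) -> Simulation:
    """Advance the coupled simulation by one accepted increment."""
    sim.step()
    return sim


def run_simulation(config: SimulationConfig,
                   mesh: MeshModel | None = None,
                   progress=None) -> SimulationResult:
    """Integrate the coupled model to ``config.duration`` days.

    Declares non-union (and stops early) if no bony bridge exists by the
    non-union deadline.
    """
    sim = Simulation(config, mesh=mesh)
    status = "running"
    while sim.t < config.duration:
        sim.step()
        if progress is not None:
            progress(sim)
        if (not sim.union) and sim.t >= config.nonunion_deadline:
            status = "non_union"
            break
    if status == "running":
        status = "healed" if sim.union else "non_union"
    return sim.result(status)
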