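"""Coupled strain-energy-density and fatigue-damage bone remodelling.

Site-specific scheme: every bone element remodels its apparent density
toward a homeostatic SED window [psi_L, psi_U] built around the modified
reference stimulus, with rates scaled by the internal free-surface-area
density a(rho).  Fatigue damage accumulates by Miner's rule against a
repair rate tied to the homeostatic stress, and drives rapid resorption
once the accumulated stimulus exceeds a critical threshold.

The S-N (cycles-to-failure) constants are not tabulated anywhere; the
shipped defaults are a least-squares fit of log10(Nf) = H log10(sigma)
+ J T + K rho + M to the bundled fatigue-life fixture table
(data/fatigue_life.csv) and are fully overridable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

__all__ = [
    "RemodelParams",
    "BoneState",
    "reference_energies",
    "density_modulus_law",
    "inverse_density_modulus_law",
    "surface_area_density",
    "sed_remodelling_rate",
    "cycles_to_failure",
    "damage_update",
    "damage_resorption_rate",
    "remodel_time_scales",
    "critical_damage_threshold",
    "fit_fatigue_constants",
    "load_fatigue_table",
]

# a(rho) expressed in normalized porosity p = (rho_max - rho)/(rho_max - rho_min);
# Martin-style specific-surface quintic with a small linear correction so the
# curve vanishes exactly at both density bounds (mm^2/mm^3).
_SURFACE_POLY_P = (0.0, 32.1, -93.9, 134.0, -101.0, 28.8)

_MODULUS_COEFF = 3790.0  # E = 3790 rho^3 (MPa, rho in g/cm^3)


def load_fatigue_table() -> np.ndarray:
    """Bundled fatigue-life table: columns (sigma, T, rho, Nf)."""
    with resources.files("fracsim.data").joinpath("fatigue_life.csv").open() as f:
        reader = csv.reader(f)
        next(reader)
        rows = [[float(v) for v in row] for row in reader if row]
    return np.asarray(rows)


def fit_fatigue_constants(table: np.ndarray | None = None) -> tuple[float, float, float, float]:
    """Least-squares (H, J, K, M) for log10 Nf = H log10 sigma + J T + K rho + M."""
    if table is None:
        table = load_fatigue_table()
    sigma, T, rho, nf = table.T
    A = np.column_stack([np.log10(sigma), T, rho, np.ones_like(T)])
    coef, *_ = np.linalg.lstsq(A, np.log10(nf), rcond=None)
    return tuple(float(c) for c in coef)


_DEFAULT_SN = None


def _default_sn_constants():
    global _DEFAULT_SN
    if _DEFAULT_SN is None:
        _DEFAULT_SN = fit_fatigue_constants()
    return _DEFAULT_SN


@dataclass(frozen=True)
class RemodelParams:
    """Remodelling constants (homeostatic references, rates, damage law)."""

    sigma_U: float = 6.6            # homeostatic stress, MPa
    E_U: float = 17_000.0           # homeostatic modulus, MPa
    rho_U: float = 1.649            # homeostatic density, g/cm^3
    width: float = 0.35             # lazy-zone half-width factor w
    tau: float = 130.0              # SED rate constant, per month
    drho_max: float = 0.175         # max density change, g/cm^3 per month
    rho_min: float = 0.01           # g/cm^3
    rho_max: float = 1.73           # g/cm^3
    C_d: float = 0.1e8              # damage resorption rate constant
    damage_step: float = 0.00625    # max density change per damage increment
    sn_constants: tuple | None = None   # (H, J, K, M); fitted default if None
    temperature: float = 37.0       # deg C
    cycles_per_day: float = 1.0
    critical_strain: float = 3500e-6    # critical damage strain
    month_days: float = 30.0
    surface_poly: tuple = _SURFACE_POLY_P

    def __post_init__(self) -> None:
        if not 0.0 < self.width < 1.0:
            raise ValueError("width must lie in (0, 1)")
        if not self.rho_min < self.rho_U < self.rho_max:
            raise ValueError("need rho_min < rho_U < rho_max")
        if self.tau <= 0 or self.C_d <= 0:
            raise ValueError("tau and C_d must be positive")

    @property
    def sn(self) -> tuple[float, float, float, float]:
        return self.sn_constants or _default_sn_constants()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sn_constants"] = list(self.sn)
        d["surface_poly"] = list(self.surface_poly)
        return d


def reference_energies(params: RemodelParams) -> tuple[float, float, float]:
    """(psi_ref, psi_U, psi_L) in MPa cm^3/g.

    psi_U = sigma_U^2 / (2 E_U rho_U) regardless of the lazy-zone width;
    the width only moves psi_ref and psi_L.
    """
    w = params.width
    if w >= 1.0:
        raise ValueError("width must be < 1")
    psi_u = params.sigma_U ** 2 / (2.0 * params.E_U * params.rho_U)
    psi_ref = psi_u / (1.0 + w)
    psi_l = psi_ref * (1.0 - w)
    return psi_ref, psi_u, psi_l


def density_modulus_law(rho):
    """Cubic density-modulus law E = 3790 rho^3 (MPa)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    out = _MODULUS_COEFF * rho ** 3
    return float(out) if out.ndim == 0 else out


def inverse_density_modulus_law(E):
    """Density from modulus: rho = (E / 3790)^(1/3)."""
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("E must be positive")
    out = (E / _MODULUS_COEFF) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def surface_area_density(rho, params: RemodelParams | None = None):
    """Internal free surface area per unit volume a(rho), mm^2/mm^3.

    Vanishes at rho_min and rho_max, positive between.
    """
    params = params or RemodelParams()
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < params.rho_min - 1e-12) or np.any(rho > params.rho_max + 1e-12):
        raise ValueError("rho outside [rho_min, rho_max]")
    p = (params.rho_max - rho) / (params.rho_max - params.rho_min)
    p = np.clip(p, 0.0, 1.0)
    out = np.polyval(params.surface_poly[::-1], p)
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def sed_remodelling_rate(psi, rho, params: RemodelParams):
    """Site-specific SED remodelling rate drho/dt in g/cm^3 per day.

    Formation above psi_U, resorption below psi_L, zero inside the lazy
    zone; linear in the stimulus excess and scaled by a(rho).
    """
    psi = np.asarray(psi, dtype=float)
    rho = np.asarray(rho, dtype=float)
    _, psi_u, psi_l = reference_energies(params)
    a = surface_area_density(np.clip(rho, params.rho_min, params.rho_max), params)
    tau_day = params.tau / params.month_days
    rate = np.where(
        psi > psi_u, a * tau_day * (psi - psi_u),
        np.where(psi < psi_l, a * tau_day * (psi - psi_l), 0.0),
    )
    return float(rate) if rate.ndim == 0 else rate


def cycles_to_failure(sigma, rho, params: RemodelParams):
    """Nf = 10^(H log10 sigma + J T + K rho + M)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    H, J, K, M = params.sn
    lognf = H * np.log10(sigma) + J * params.temperature \
        + K * np.asarray(rho, dtype=float) + M
    out = 10.0 ** lognf
    return float(out) if out.ndim == 0 else out


def critical_damage_threshold(rho, params: RemodelParams):
    """Damage stimulus accumulated by one month of daily loading at the
    critical-strain stress for the local density (repair subtracted)."""
    rho = np.asarray(rho, dtype=float)
    sigma_crit = density_modulus_law(np.maximum(rho, 1e-6)) * params.critical_strain
    sigma_crit = np.maximum(sigma_crit, 1e-12)
    rate = params.cycles_per_day * (
        1.0 / cycles_to_failure(sigma_crit, rho, params)
        - 1.0 / cycles_to_failure(params.sigma_U, rho, params)
    )
    out = np.maximum(rate, 0.0) * params.month_days
    return float(out) if out.ndim == 0 else out


@dataclass
class BoneState:
    """Per-element remodelling state."""

    rho: np.ndarray                 # apparent density, g/cm^3
    omega: np.ndarray = None        # gross accumulated damage in [0, 1]
    delta_omega: np.ndarray = None  # net damage stimulus, >= 0

    def __post_init__(self):
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if self.omega is None:
            self.omega = np.zeros_like(self.rho)
        if self.delta_omega is None:
            self.delta_omega = np.zeros_like(self.rho)

    @property
    def E(self) -> np.ndarray:
        return density_modulus_law(self.rho)


def damage_update(state: BoneState, sigma, rho, N: float, dt: float,
                  params: RemodelParams) -> BoneState:
    """Miner's-rule damage accumulation against homeostatic repair.

    Formation rate N/Nf(sigma, rho) per day; repair rate N/Nf(sigma_U, rho)
    so that homeostatic loading accumulates no stimulus.  The net stimulus
    delta_omega is floored at zero; gross damage omega is capped at 1.
    """
    sigma = np.maximum(np.asarray(sigma, dtype=float), 1e-12)
    form = N / cycles_to_failure(sigma, rho, params)
    repair = N / cycles_to_failure(params.sigma_U, rho, params)
    state.delta_omega = np.maximum(state.delta_omega + (form - repair) * dt, 0.0)
    state.omega = np.minimum(state.omega + form * dt, 1.0)
    return state


def damage_resorption_rate(state: BoneState, rho, N: float,
                           params: RemodelParams):
    """Damage-driven density loss rate (g/cm^3 per day, <= 0).

    Zero until the net damage stimulus exceeds the critical threshold for
    the local density; above it, proportional to a(rho) C_d N delta_omega.
    """
    rho = np.asarray(rho, dtype=float)
    a = surface_area_density(np.clip(rho, params.rho_min, params.rho_max), params)
    crit = critical_damage_threshold(rho, params)
    active = state.delta_omega > crit
    rate = np.where(active, -a * params.C_d * N * state.delta_omega, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def remodel_time_scales(sed_rate_per_day, damage_rate_per_day, dt: float,
                        params: RemodelParams) -> tuple[float, float]:
    """(SED factor, damage factor), each <= 1, for the current increment.

    The SED factor keeps the month-equivalent density change below
    drho_max; the damage factor keeps the per-increment damage resorption
    below ``damage_step``.
    """
    sed = np.max(np.abs(np.atleast_1d(sed_rate_per_day))) if np.size(sed_rate_per_day) else 0.0
    dmg = np.max(np.abs(np.atleast_1d(damage_rate_per_day))) if np.size(damage_rate_per_day) else 0.0
    cap_per_day = params.drho_max / params.month_days
    f_sed = 1.0 if sed <= cap_per_day else cap_per_day / sed
    f_dmg = 1.0 if dmg * dt <= params.damage_step else \
        params.damage_step / (dmg * dt)
    return f_sed, f_dmg
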