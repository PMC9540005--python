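"""Mechano-regulated tissue differentiation in the fracture callus.

Per-element pipeline: biophysical stimulus from deviatoric strain and fluid
velocity, fuzzy tissue membership around the band thresholds, coupled cell
differentiation / tissue production ODEs with a strict differentiation
hierarchy (MSC -> fibroblast -> chondrocyte -> immature -> mature bone),
rule-of-mixtures stiffness with maturation interpolation, and trailing
time-averaged smoothing of the modulus.

All rate functions are vectorized over elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .materials import TISSUE_MODULUS_RANGE

__all__ = [
    "MechanoRegParams",
    "TissueMembership",
    "TissueState",
    "biophysical_stimulus",
    "tissue_membership",
    "cell_density_rates",
    "tissue_fraction_rates",
    "healing_time_scale",
    "mixture_modulus",
    "smoothed_modulus",
]

_MTOT_GUARD = 1e-9


@dataclass(frozen=True)
class MechanoRegParams:
    """Calibrated constants of the mechano-regulation algorithm."""

    a: float = 0.0375                  # strain normalizer
    b: float = 3.0                     # velocity normalizer, um/s
    thresholds: tuple = (0.01, 0.2667, 1.0, 3.0)
    fuzzy_fraction: float = 0.10       # total fuzzy-zone width / threshold
    F_f: float = 0.02                  # differentiation rates, 1/day
    F_c: float = 0.3
    F_ib: float = 0.15
    F_mb: float = 0.15
    Q_f: float = 0.12                  # tissue production rates, 1/day
    Q_c: float = 0.2
    Q_ib: float = 0.1
    Q_mb: float = 0.1
    dm_max: float = 0.05               # max fraction change per increment
    averaging_window: float = 10.0     # days

    def __post_init__(self) -> None:
        t = self.thresholds
        if not all(t[i] < t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("thresholds must be strictly increasing")
        if not 0.0 < self.fuzzy_fraction < 1.0:
            raise ValueError("fuzzy_fraction must lie in (0, 1)")
        for name in ("F_f", "F_c", "F_ib", "F_mb",
                     "Q_f", "Q_c", "Q_ib", "Q_mb", "dm_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


@dataclass
class TissueMembership:
    """Fuzzy memberships; at most two adjacent entries are non-zero."""

    f: np.ndarray          # fibrous
    c: np.ndarray          # cartilage
    ib: np.ndarray         # immature bone
    mb: np.ndarray         # mature (woven) bone
    resorb: np.ndarray     # resorption band

    def total(self) -> np.ndarray:
        return self.f + self.c + self.ib + self.mb + self.resorb


def biophysical_stimulus(eps_dev, wf_mag, params: MechanoRegParams):
    """S = eps_dev / a + wf / b (dimensionless)."""
    eps_dev = np.asarray(eps_dev, dtype=float)
    wf_mag = np.asarray(wf_mag, dtype=float)
    if np.any(eps_dev < 0) or np.any(wf_mag < 0):
        raise ValueError("stimulus inputs must be non-negative")
    return eps_dev / params.a + wf_mag / params.b


def _ramp_up(S, threshold, frac):
    half = 0.5 * frac * threshold
    return np.clip((S - (threshold - half)) / (2.0 * half), 0.0, 1.0)


def tissue_membership(S, params: MechanoRegParams) -> TissueMembership:
    """Crisp band membership with linear crossfades in the fuzzy zones.

    Bands, low to high stimulus: resorption, mature/woven bone, immature
    bone, cartilage, fibrous tissue.  Each fuzzy zone has total width
    ``fuzzy_fraction`` of its threshold, centred on the threshold.
    """
    S = np.asarray(S, dtype=float)
    t = params.thresholds
    u = [_ramp_up(S, ti, params.fuzzy_fraction) for ti in t]
    return TissueMembership(
        resorb=1.0 - u[0],
        mb=u[0] * (1.0 - u[1]),
        ib=u[1] * (1.0 - u[2]),
        c=u[2] * (1.0 - u[3]),
        f=u[3],
    )


def cell_density_rates(c_m, c_f, c_c, c_ib, c_mb,
                       tm: TissueMembership, params: MechanoRegParams):
    """Time derivatives of the normalized cell densities (1/day).

    Cells differentiate only toward phenotypes of lower differential
    potential; each target density saturates logistically at 1.
    """
    p = params
    dc_f = (p.F_f * tm.f * (1 - c_f) * c_m
            - p.F_c * tm.c * (1 - c_c) * c_f
            - p.F_ib * tm.ib * (1 - c_ib) * c_f
            - p.F_mb * tm.mb * (1 - c_mb) * c_f)
    dc_c = (p.F_c * tm.c * (1 - c_c) * (c_m + c_f)
            - p.F_ib * tm.ib * (1 - c_ib) * c_c
            - p.F_mb * tm.mb * (1 - c_mb) * c_c)
    dc_ib = (p.F_ib * tm.ib * (1 - c_ib) * (c_m + c_f + c_c)
             - p.F_mb * tm.mb * (1 - c_mb) * c_ib)
    dc_mb = p.F_mb * tm.mb * (1 - c_mb) * (c_m + c_f + c_c + c_ib)
    return dc_f, dc_c, dc_ib, dc_mb


def tissue_fraction_rates(m_f, m_c, m_ib, m_mb, c_f, c_c, c_ib, c_mb,
                          tm: TissueMembership, params: MechanoRegParams):
    """Time derivatives of the tissue volume fractions (1/day).

    Higher-priority tissue replaces lower-priority tissue proportionally
    through the m_x/m_tot terms; in the resorption band the bone fractions
    decay back toward granulation tissue at their production rate scaled by
    the resorption membership.
    """
    p = params
    m_tot = np.maximum(m_f + m_c + m_ib + m_mb, _MTOT_GUARD)
    repl_mb = tm.mb * p.Q_mb * c_mb
    repl_ib = tm.ib * p.Q_ib * c_ib
    repl_c = tm.c * p.Q_c * c_c

    dm_mb = p.Q_mb * tm.mb * (1 - m_mb) * c_mb
    dm_ib = p.Q_ib * tm.ib * (1 - m_ib - m_mb) * c_ib \
        - repl_mb * m_ib / m_tot
    dm_c = p.Q_c * tm.c * (1 - m_c - m_ib - m_mb) * c_c \
        - (repl_mb + repl_ib) * m_c / m_tot
    dm_f = p.Q_f * tm.f * (1 - m_f - m_c - m_ib - m_mb) * c_f \
        - (repl_mb + repl_ib + repl_c) * m_f / m_tot

    # osteoclastic removal of unloaded bone
    dm_ib = dm_ib - p.Q_ib * tm.resorb * m_ib
    dm_mb = dm_mb - p.Q_mb * tm.resorb * m_mb
    return dm_f, dm_c, dm_ib, dm_mb


def healing_time_scale(max_dm_per_increment, params: MechanoRegParams) -> float:
    """Time-increment scale factor keeping every fraction change <= dm_max."""
    m = float(np.max(max_dm_per_increment)) if np.ndim(max_dm_per_increment) \
        else float(max_dm_per_increment)
    if m < 0:
        raise ValueError("max_dm must be non-negative")
    if m > params.dm_max:
        return params.dm_max / m
    return 1.0


def _tissue_modulus(key: str, maturity, ranges) -> np.ndarray:
    lo, hi = ranges[key]
    return lo + (hi - lo) * np.clip(maturity, 0.0, 1.0)


def mixture_modulus(m_gran, m_f, m_c, m_ib, m_mb,
                    c_m, c_f, c_c, c_ib, c_mb,
                    ranges: dict | None = None):
    """Rule-of-mixtures element modulus (MPa).

    Each constituent modulus is interpolated within its material-table
    range by the matching normalized cell density (maturation); granulation
    tissue matures with the MSC concentration.
    """
    ranges = ranges or TISSUE_MODULUS_RANGE
    return (
        m_gran * _tissue_modulus("granulation", c_m, ranges)
        + m_f * _tissue_modulus("fibrous", c_f, ranges)
        + m_c * _tissue_modulus("cartilage", c_c, ranges)
        + m_ib * _tissue_modulus("immature_bone", c_ib, ranges)
        + m_mb * _tissue_modulus("mature_bone", c_mb, ranges)
    )


def smoothed_modulus(history, window: float = 10.0):
    """dt-weighted trailing average of the raw modulus.

    ``history`` is a sequence of (t_end, dt, E_raw) entries with variable
    dt; entries are weighted by their overlap with [t_now - window, t_now].
    If the elapsed time is shorter than the window the available history is
    averaged.
    """
    if not history:
        raise ValueError("empty modulus history")
    t_now = history[-1][0]
    lo = t_now - window
    acc = None
    wsum = 0.0
    for t_end, dt, e in history:
        w = min(t_end, t_now) - max(t_end - dt, lo)
        if w <= 0:
            continue
        contrib = w * np.asarray(e, dtype=float)
        acc = contrib if acc is None else acc + contrib
        wsum += w
    if acc is None or wsum <= 0:  # degenerate: fall back to the last entry
        return np.asarray(history[-1][2], dtype=float)
    return acc / wsum


@dataclass
class TissueState:
    """Healing state arrays for a set of callus elements."""

    n: int
    params: MechanoRegParams = field(default_factory=MechanoRegParams)
    c_m: np.ndarray = None
    c_f: np.ndarray = None
    c_c: np.ndarray = None
    c_ib: np.ndarray = None
    c_mb: np.ndarray = None
    m_f: np.ndarray = None
    m_c: np.ndarray = None
    m_ib: np.ndarray = None
    m_mb: np.ndarray = None
    E_raw: np.ndarray = None
    E_smoothed: np.ndarray = None
    history: list = field(default_factory=list)

    def __post_init__(self):
        z = lambda: np.zeros(self.n)
        for name in ("c_m", "c_f", "c_c", "c_ib", "c_mb",
                     "m_f", "m_c", "m_ib", "m_mb"):
            if getattr(self, name) is None:
                setattr(self, name, z())
        if self.E_raw is None:
            self.E_raw = self.modulus()
        if self.E_smoothed is None:
            self.E_smoothed = self.E_raw.copy()

    @property
    def m_gran(self) -> np.ndarray:
        return 1.0 - (self.m_f + self.m_c + self.m_ib + self.m_mb)

    @property
    def bone_fraction(self) -> np.ndarray:
        return self.m_ib + self.m_mb

    def modulus(self) -> np.ndarray:
        return mixture_modulus(
            self.m_gran, self.m_f, self.m_c, self.m_ib, self.m_mb,
            self.c_m, self.c_f, self.c_c, self.c_ib, self.c_mb,
        )

    def rates(self, tm: TissueMembership):
        dc = cell_density_rates(
            self.c_m, self.c_f, self.c_c, self.c_ib, self.c_mb,
            tm, self.params,
        )
        dm = tissue_fraction_rates(
            self.m_f, self.m_c, self.m_ib, self.m_mb,
            self.c_f, self.c_c, self.c_ib, self.c_mb,
            tm, self.params,
        )
        return dc, dm

    def apply_rates(self, dc, dm, dt: float) -> None:
        """Explicit update; clips states to [0, 1] and keeps sum(m) <= 1."""
        for name, d in zip(("c_f", "c_c", "c_ib", "c_mb"), dc):
            setattr(self, name, np.clip(getattr(self, name) + d * dt, 0.0, 1.0))
        for name, d in zip(("m_f", "m_c", "m_ib", "m_mb"), dm):
            setattr(self, name, np.clip(getattr(self, name) + d * dt, 0.0, 1.0))
        tot = self.m_f + self.m_c + self.m_ib + self.m_mb
        over = tot > 1.0
        if np.any(over):
            scale = np.where(over, 1.0 / np.maximum(tot, 1.0), 1.0)
            for name in ("m_f", "m_c", "m_ib", "m_mb"):
                setattr(self, name, getattr(self, name) * scale)

    def push_modulus(self, t: float, dt: float) -> None:
        self.E_raw = self.modulus()
        self.history.append((t, dt, self.E_raw))
        window = self.params.averaging_window
        # drop entries that end before the trailing window starts
        while len(self.history) > 1 and self.history[0][0] <= t - window:
            self.history.pop(0)
        self.E_smoothed = smoothed_modulus(self.history, window)
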