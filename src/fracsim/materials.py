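"""Poroelastic material definitions and the default tissue material table.

Units: elastic moduli in MPa, permeability in m^4/(N s) as conventionally
tabulated (converted to mm^2/(MPa s) internally), density in g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "PoroMaterial",
    "DEFAULT_MATERIALS",
    "TISSUE_MODULUS_RANGE",
    "PERMEABILITY_SI_TO_MM",
]

# 1 m^2/(Pa s) == 1e12 mm^2/(MPa s)
PERMEABILITY_SI_TO_MM = 1.0e12


@dataclass(frozen=True)
class PoroMaterial:
    """Isotropic linear biphasic (poroelastic) material.

    ``permeability`` is stored in m^4/(N s); use :attr:`k_mm` for the
    mm-MPa-s value used by the solver.
    """

    E: float                    # drained Young's modulus, MPa
    nu: float                   # drained Poisson's ratio
    permeability: float         # m^4/(N s)
    porosity: float             # fluid volume fraction Vf
    solid_bulk_modulus: float = 2300.0   # MPa
    fluid_bulk_modulus: float = 2300.0   # MPa

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not -1.0 < self.nu < 0.5:
            raise ValueError(f"nu must lie in (-1, 0.5), got {self.nu}")
        if not 0.0 <= self.porosity <= 1.0:
            raise ValueError(f"porosity must lie in [0, 1], got {self.porosity}")
        if self.permeability < 0:
            raise ValueError("permeability must be non-negative")

    @property
    def solid_fraction(self) -> float:
        """Vs = 1 - Vf (saturated mixture)."""
        return 1.0 - self.porosity

    @property
    def k_mm(self) -> float:
        """Permeability in mm^2/(MPa s)."""
        return self.permeability * PERMEABILITY_SI_TO_MM

    @property
    def drained_bulk_modulus(self) -> float:
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def biot_alpha(self) -> float:
        """Biot coefficient, clipped to [0, 1].

        The tabulated solid bulk modulus of stiff tissues (cortical bone)
        is below the drained bulk modulus, which classical Biot theory does
        not admit; such materials are treated as effectively uncoupled
        (alpha = 0).
        """
        a = 1.0 - self.drained_bulk_modulus / self.solid_bulk_modulus
        return min(max(a, 0.0), 1.0)

    @property
    def storage_compressibility(self) -> float:
        """Specific storage 1/Q in 1/MPa (never negative)."""
        a = self.biot_alpha
        n = self.porosity
        return n / self.fluid_bulk_modulus + max(a - n, 0.0) / self.solid_bulk_modulus

    def with_modulus(self, E: float, nu: float | None = None) -> "PoroMaterial":
        if nu is None:
            return replace(self, E=E)
        return replace(self, E=E, nu=nu)


# Default material table (elastic modulus MPa, permeability m^4/Ns, Poisson
# ratio, initial porosity, solid/fluid bulk moduli MPa).  Tissues with a
# modulus range are entered at their lower (least mature) bound; maturation
# interpolation happens in the healing module.
DEFAULT_MATERIALS: dict[str, PoroMaterial] = {
    "cortex": PoroMaterial(17_000.0, 0.37, 1e-17, 0.04, 2300.0, 2300.0),
    "marrow": PoroMaterial(0.0247, 0.167, 1e-14, 0.8, 2300.0, 2300.0),
    "granulation": PoroMaterial(0.001, 0.167, 1e-14, 0.8, 2300.0, 2300.0),
    "fibrous": PoroMaterial(0.2, 0.167, 1e-14, 0.8, 2300.0, 2300.0),
    "cartilage": PoroMaterial(5.0, 0.167, 5e-15, 0.8, 2300.0, 13_920.0),
    "immature_bone": PoroMaterial(500.0, 0.3, 1e-13, 0.8, 2300.0, 13_920.0),
    "intermediate_bone": PoroMaterial(1000.0, 0.3, 3.7e-13, 0.8, 2300.0, 13_920.0),
    "mature_bone": PoroMaterial(2000.0, 0.3, 3.7e-13, 0.8, 2300.0, 13_920.0),
    # Titanium plate: elastic only; pore phase effectively disabled.
    "plate": PoroMaterial(110_000.0, 0.3, 1e-20, 0.01, 1e9, 1e9),
}

# (E_min, E_max) in MPa; effective tissue modulus is interpolated within its
# range by the matching normalized cell density.
TISSUE_MODULUS_RANGE: dict[str, tuple[float, float]] = {
    "granulation": (0.001, 2.0),
    "fibrous": (0.2, 5.0),
    "cartilage": (5.0, 500.0),
    "immature_bone": (500.0, 1000.0),
    "mature_bone": (2000.0, 6000.0),
}
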