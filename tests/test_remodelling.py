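"""SED/damage remodelling: references, laws, rates, time controls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracsim import (
    BoneState,
    RemodelParams,
    cycles_to_failure,
    damage_resorption_rate,
    damage_update,
    density_modulus_law,
    inverse_density_modulus_law,
    reference_energies,
    remodel_time_scales,
    sed_remodelling_rate,
    surface_area_density,
)
from fracsim.fixtures import SingleElementRig
from fracsim.remodelling import critical_damage_threshold, fit_fatigue_constants

P = RemodelParams()


# --------------------------------------------------------- SED references

def test_psi_u_worked_value():
    _, psi_u, _ = reference_energies(P)
    assert psi_u == pytest.approx(7.7694e-4, rel=1e-4)


def test_psi_u_independent_of_width():
    u1 = reference_energies(RemodelParams(width=0.2))[1]
    u2 = reference_energies(RemodelParams(width=0.5))[1]
    assert u1 == pytest.approx(u2)


def test_width_zero_degenerate():
    # construct without validation shortcut: width must be > 0, so probe
    # the algebraic limit through a tiny width
    ref, u, lo = reference_energies(RemodelParams(width=1e-9))
    assert ref == pytest.approx(u, rel=1e-6)
    assert lo == pytest.approx(u, rel=1e-6)


def test_width_shrinks_resorption_region():
    lo_narrow = reference_energies(RemodelParams(width=0.2))[2]
    lo_wide = reference_energies(RemodelParams(width=0.5))[2]
    assert lo_wide < lo_narrow  # larger w pushes psi_L down


# ------------------------------------------------------------- cubic law

def test_density_modulus_law_unit():
    assert density_modulus_law(1.0) == pytest.approx(3790.0)


def test_density_modulus_law_homeostatic():
    assert density_modulus_law(1.649) == pytest.approx(16_996, rel=1e-3)


def test_density_modulus_round_trip():
    assert inverse_density_modulus_law(3790.0) == pytest.approx(1.0)
    for rho in (0.3, 1.0, 1.7):
        assert inverse_density_modulus_law(density_modulus_law(rho)) == \
            pytest.approx(rho)


def test_density_modulus_rejects_nonpositive():
    with pytest.raises(ValueError):
        density_modulus_law(0.0)
    with pytest.raises(ValueError):
        inverse_density_modulus_law(-1.0)


# -------------------------------------------------------- surface density

def test_surface_area_density_vanishes_at_bounds():
    assert surface_area_density(P.rho_max, P) == pytest.approx(0.0, abs=1e-9)
    assert surface_area_density(P.rho_min, P) == pytest.approx(0.0, abs=1e-9)


def test_surface_area_density_positive_midrange():
    rho = np.linspace(0.05, 1.7, 100)
    assert (surface_area_density(rho, P) > 0).all()


def test_surface_area_density_out_of_range():
    with pytest.raises(ValueError):
        surface_area_density(2.0, P)


# ---------------------------------------------------------------- SED rate

def test_lazy_zone_inert():
    _, psi_u, psi_l = reference_energies(P)
    psi = 0.5 * (psi_u + psi_l)
    assert sed_remodelling_rate(psi, 1.0, P) == 0.0


def test_rate_zero_at_density_bounds():
    _, psi_u, _ = reference_energies(P)
    assert sed_remodelling_rate(10 * psi_u, P.rho_max, P) == pytest.approx(0.0, abs=1e-12)


def test_rate_linear_in_excess():
    _, psi_u, _ = reference_energies(P)
    r1 = sed_remodelling_rate(psi_u + 1e-5, 1.0, P)
    r2 = sed_remodelling_rate(psi_u + 2e-5, 1.0, P)
    assert r1 > 0
    assert r2 == pytest.approx(2 * r1, rel=1e-9)


def test_resorption_below_lazy_zone():
    _, _, psi_l = reference_energies(P)
    assert sed_remodelling_rate(0.5 * psi_l, 1.0, P) < 0


# ----------------------------------------------------------------- damage

def test_cycles_to_failure_monotonicities():
    H, J, K, M = P.sn
    assert H < 0 and K > 0
    assert cycles_to_failure(20.0, 1.6, P) < cycles_to_failure(10.0, 1.6, P)
    assert cycles_to_failure(20.0, 1.7, P) > cycles_to_failure(20.0, 1.4, P)
    ratio = cycles_to_failure(20.0, 1.6, P) / cycles_to_failure(10.0, 1.6, P)
    assert ratio == pytest.approx(2.0 ** H, rel=1e-9)


def test_cycles_to_failure_rejects_nonpositive():
    with pytest.raises(ValueError):
        cycles_to_failure(0.0, 1.6, P)


def test_fatigue_fit_reproduces_table():
    from fracsim.remodelling import load_fatigue_table
    table = load_fatigue_table()
    H, J, K, M = fit_fatigue_constants(table)
    sigma, T, rho, nf = table.T
    pred = H * np.log10(sigma) + J * T + K * rho + M
    assert np.max(np.abs(pred - np.log10(nf))) < 0.01


def test_damage_equilibrium_at_homeostatic_stress():
    s = BoneState(rho=np.array([1.649]))
    for _ in range(50):
        damage_update(s, P.sigma_U, s.rho, 1.0, 1.0, P)
    assert s.delta_omega[0] == pytest.approx(0.0, abs=1e-15)


def test_damage_accumulates_above_homeostatic():
    s = BoneState(rho=np.array([1.649]))
    prev = 0.0
    for _ in range(5):
        damage_update(s, 30.0, s.rho, 1.0, 1.0, P)
        assert s.delta_omega[0] > prev
        prev = s.delta_omega[0]


def test_damage_decays_under_unloading():
    s = BoneState(rho=np.array([1.649]),
                  delta_omega=np.array([1e-6]))
    damage_update(s, 1e-9, s.rho, 1.0, 1e9, P)
    assert s.delta_omega[0] == 0.0


def test_damage_resorption_gating():
    s = BoneState(rho=np.array([1.0]))
    assert damage_resorption_rate(s, s.rho, 1.0, P)[0] == 0.0
    crit = critical_damage_threshold(1.649, P)
    s2 = BoneState(rho=np.array([1.649]),
                   delta_omega=np.array([crit * 10]))
    assert damage_resorption_rate(s2, s2.rho, 1.0, P)[0] < 0.0
    s3 = BoneState(rho=np.array([P.rho_min]),
                   delta_omega=np.array([1.0]))
    assert damage_resorption_rate(s3, s3.rho, 1.0, P)[0] == pytest.approx(0.0, abs=1e-9)


def test_damage_resorption_faster_than_sed_resorption():
    # at a documented reference state the damage pathway outpaces negative
    # SED remodelling for comparable drivers
    rho = 1.4
    crit = critical_damage_threshold(rho, P)
    s = BoneState(rho=np.array([rho]), delta_omega=np.array([2 * crit]))
    r_dmg = abs(damage_resorption_rate(s, s.rho, 1.0, P)[0])
    _, _, psi_l = reference_energies(P)
    r_sed = abs(sed_remodelling_rate(0.0, rho, P))
    assert r_dmg > r_sed


# ------------------------------------------------------------ time scales

def test_remodel_time_scale_sed_factor():
    # 0.35 g/cm^3 per month attempted -> factor 0.5
    rate = 0.35 / P.month_days
    f_sed, _ = remodel_time_scales(rate, 0.0, 1.0, P)
    assert f_sed == pytest.approx(0.5)


def test_remodel_time_scale_at_cap():
    rate = 0.175 / P.month_days
    f_sed, f_dmg = remodel_time_scales(rate, 0.0, 1.0, P)
    assert f_sed == 1.0
    assert f_dmg == 1.0


def test_remodel_time_scale_damage():
    f_sed, f_dmg = remodel_time_scales(0.0, 2 * P.damage_step, 1.0, P)
    assert f_dmg == pytest.approx(0.5)


# ------------------------------------------------------------- fixed point

@pytest.mark.parametrize("rho0", [0.5, 1.0, 1.5])
def test_homeostatic_fixed_point_from_below(rho0):
    rig = SingleElementRig(rho=rho0)
    _, rs = rig.run(6.6, days=3000)
    assert rs[-1] == pytest.approx(1.649, abs=2e-3)
    assert density_modulus_law(rs[-1]) == pytest.approx(17_000, rel=5e-3)
    # monotone approach outside the lazy zone
    assert (np.diff(rs) >= -1e-12).all()


def test_lazy_zone_stalls_from_above():
    # starting above the homeostatic density the stimulus sits inside the
    # lazy zone, so the state is (by construction) stationary
    rig = SingleElementRig(rho=1.7)
    _, rs = rig.run(6.6, days=200)
    assert rs[-1] == pytest.approx(1.7, abs=1e-9)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 9999))
def test_density_bounds_under_random_stimuli(seed):
    rng = np.random.default_rng(seed)
    rig = SingleElementRig(rho=float(rng.uniform(0.2, 1.7)), damage=True)
    for _ in range(100):
        rig.step(float(rng.lognormal(1.5, 1.0)))
        assert P.rho_min - 1e-12 <= rig.state.rho[0] <= P.rho_max + 1e-12


def test_params_validation():
    with pytest.raises(ValueError):
        RemodelParams(width=1.5)
    with pytest.raises(ValueError):
        RemodelParams(rho_min=2.0)
    with pytest.raises(ValueError):
        RemodelParams(tau=-1.0)
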