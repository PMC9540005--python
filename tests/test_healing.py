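"""Mechano-regulation: stimulus, fuzzy membership, ODE rates, mixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fracsim import (
    MechanoRegParams,
    TissueState,
    biophysical_stimulus,
    cell_density_rates,
    healing_time_scale,
    mixture_modulus,
    smoothed_modulus,
    tissue_fraction_rates,
    tissue_membership,
)

P = MechanoRegParams()


# ---------------------------------------------------------------- stimulus

def test_stimulus_one_strain_unit():
    assert biophysical_stimulus(0.0375, 0.0, P) == pytest.approx(1.0)


def test_stimulus_fibrous_band_edge():
    assert biophysical_stimulus(0.1125, 0.0, P) == pytest.approx(3.0)


def test_stimulus_resorption_band_edge():
    assert biophysical_stimulus(0.0, 0.03, P) == pytest.approx(0.01)


def test_stimulus_rejects_negative():
    with pytest.raises(ValueError):
        biophysical_stimulus(-0.1, 0.0, P)


# -------------------------------------------------------------- membership

def test_membership_crisp_cartilage():
    tm = tissue_membership(2.0, P)
    assert tm.c == pytest.approx(1.0)
    assert tm.f == tm.ib == tm.mb == tm.resorb == 0.0


def test_membership_midpoint_crossfade():
    tm = tissue_membership(1.0, P)
    assert tm.c == pytest.approx(0.5)
    assert tm.ib == pytest.approx(0.5)


def test_membership_outside_fuzzy_zone():
    # the zone around S = 3 spans [2.85, 3.15]
    tm = tissue_membership(3.2, P)
    assert tm.f == pytest.approx(1.0)
    tm = tissue_membership(2.84, P)
    assert tm.c == pytest.approx(1.0)


@settings(max_examples=200, deadline=None)
@given(st.floats(0.0, 10.0))
def test_membership_partition_of_unity(S):
    tm = tissue_membership(S, P)
    vals = [tm.resorb, tm.mb, tm.ib, tm.c, tm.f]
    assert all(0.0 <= v <= 1.0 for v in vals)
    assert sum(vals) == pytest.approx(1.0, abs=1e-12)
    nz = [i for i, v in enumerate(vals) if v > 0]
    assert len(nz) <= 2
    if len(nz) == 2:   # only adjacent bands crossfade
        assert nz[1] - nz[0] == 1


# --------------------------------------------------------------- ODE rates

def _tm(S):
    return tissue_membership(np.asarray([S]), P)


def test_cell_rates_direct_mb_differentiation():
    one, zero = np.ones(1), np.zeros(1)
    dc = cell_density_rates(one, zero, zero, zero, zero, _tm(0.1), P)
    # only mature-bone cells appear, at rate F_mb
    assert dc[3][0] == pytest.approx(0.15)
    assert dc[0][0] == dc[1][0] == dc[2][0] == 0.0


def test_cell_rates_zero_membership():
    one = np.ones(1)
    tm = tissue_membership(np.asarray([0.005]), P)  # pure resorption band
    dc = cell_density_rates(one, one, one, one, one, tm, P)
    assert all(abs(d[0]) < 1e-15 for d in dc)


def test_cell_rates_logistic_saturation():
    one, zero = np.ones(1), np.zeros(1)
    dc = cell_density_rates(one, zero, zero, zero, one, _tm(0.1), P)
    assert dc[3][0] == 0.0


def test_tissue_rates_mb_production():
    one, zero = np.ones(1), np.zeros(1)
    dm = tissue_fraction_rates(zero, zero, zero, zero,
                               zero, zero, zero, one, _tm(0.1), P)
    assert dm[3][0] == pytest.approx(0.1)   # Q_mb


def test_tissue_rates_saturation():
    one, zero = np.ones(1), np.zeros(1)
    dm = tissue_fraction_rates(zero, zero, zero, one,
                               zero, zero, zero, one, _tm(0.1), P)
    assert dm[3][0] == 0.0


def test_granulation_closure():
    s = TissueState(n=1)
    s.m_f[:], s.m_c[:], s.m_ib[:] = 0.2, 0.3, 0.1
    assert s.m_gran[0] == pytest.approx(0.4)


# ------------------------------------------------------------ time control

def test_healing_time_scale():
    assert healing_time_scale(0.1, P) == pytest.approx(0.5)
    assert healing_time_scale(0.05, P) == 1.0
    assert healing_time_scale(0.0, P) == 1.0


# ----------------------------------------------------------------- modulus

def test_mixture_single_phase():
    E = mixture_modulus(1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 0, 0, 0)
    assert E == pytest.approx(0.001)


def test_mixture_cartilage_mature_blend():
    E = mixture_modulus(0.0, 0.0, 0.5, 0.0, 0.5, 0, 0, 1.0, 0, 1.0)
    assert E == pytest.approx(3250.0)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=9, max_size=9))
def test_mixture_convexity(vals):
    m = np.asarray(vals[:4])
    tot = m.sum()
    if tot > 1:
        m = m / tot
    m_gran = 1 - m.sum()
    c = vals[4:9]
    E = mixture_modulus(m_gran, *m, c[0], c[1], c[2], c[3], c[4])
    assert 0.001 - 1e-12 <= E <= 6000.0 + 1e-9


def test_smoothed_modulus_constant():
    hist = [(float(t), 1.0, 100.0) for t in range(1, 11)]
    assert smoothed_modulus(hist, 10.0) == pytest.approx(100.0)


def test_smoothed_modulus_linear_ramp_midpoint():
    hist = [(t, 0.1, 10.0 * t) for t in np.arange(0.1, 10.05, 0.1)]
    assert smoothed_modulus(hist, 10.0) == pytest.approx(50.0, rel=1e-2)


def test_smoothed_modulus_single_entry_and_empty():
    assert smoothed_modulus([(1.0, 1.0, 42.0)], 10.0) == pytest.approx(42.0)
    with pytest.raises(ValueError):
        smoothed_modulus([], 10.0)


# -------------------------------------------------- trajectory properties

@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_conservation_and_bounds_under_random_stimuli(seed):
    rng = np.random.default_rng(seed)
    n = 8
    state = TissueState(n=n)
    state.c_m = rng.random(n)
    for _ in range(60):
        S = rng.lognormal(mean=0.0, sigma=1.5, size=n)
        tm = tissue_membership(S, P)
        dc, dm = state.rates(tm)
        dt = 1.0 * healing_time_scale(
            max(float(np.max(np.abs(d))) for d in dm) * 1.0, P)
        before = {k: getattr(state, k).copy()
                  for k in ("m_f", "m_c", "m_ib", "m_mb")}
        state.apply_rates(dc, dm, dt)
        for name in ("c_f", "c_c", "c_ib", "c_mb",
                     "m_f", "m_c", "m_ib", "m_mb"):
            arr = getattr(state, name)
            assert (arr >= -1e-12).all() and (arr <= 1 + 1e-12).all()
        total = state.m_gran + state.m_f + state.m_c + state.m_ib + state.m_mb
        assert np.allclose(total, 1.0, atol=1e-9)
        for k, old in before.items():
            assert np.max(np.abs(getattr(state, k) - old)) <= P.dm_max + 1e-12


def test_hierarchy_no_mature_bone_without_membership():
    rng = np.random.default_rng(0)
    n = 5
    state = TissueState(n=n)
    state.c_m = np.ones(n)
    for _ in range(200):
        S = rng.uniform(0.3, 0.94, size=n)  # immature band only, TM_mb = 0
        tm = tissue_membership(S, P)
        assert np.all(tm.mb == 0)
        dc, dm = state.rates(tm)
        state.apply_rates(dc, dm, 0.5)
    assert np.all(state.c_mb == 0)
    assert np.all(state.m_mb == 0)


def test_smoothness_of_time_average():
    # successive smoothed values are window averages of the raw modulus, so
    # each change is bounded by the raw range over the (joint) window, and
    # the smoothed value always lies inside the raw envelope
    state = TissueState(n=1)
    rng = np.random.default_rng(1)
    prev_sm = state.E_smoothed.copy()
    t = 0.0
    raws = [(0.0, state.E_raw[0])]
    win = state.params.averaging_window
    for _ in range(100):
        dt = float(rng.uniform(0.2, 1.0))
        t += dt
        state.m_ib[:] = min(1.0, state.m_ib[0] + rng.uniform(0, 0.05))
        state.c_ib[:] = min(1.0, state.c_ib[0] + rng.uniform(0, 0.05))
        state.push_modulus(t, dt)
        raws.append((t, state.E_raw[0]))
        joint = [r for (tt, r) in raws if tt >= t - win - dt - 1e-9]
        rng_raw = max(joint) - min(joint)
        assert abs(state.E_smoothed[0] - prev_sm[0]) <= rng_raw + 1e-9
        assert min(joint) - 1e-9 <= state.E_smoothed[0] <= max(joint) + 1e-9
        prev_sm = state.E_smoothed.copy()


def test_params_validation():
    with pytest.raises(ValueError):
        MechanoRegParams(thresholds=(0.2, 0.1, 1.0, 3.0))
    with pytest.raises(ValueError):
        MechanoRegParams(fuzzy_fraction=0.0)
    with pytest.raises(ValueError):
        MechanoRegParams(Q_mb=-0.1)
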