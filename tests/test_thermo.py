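"""Unfolding thermodynamics and the coupled ligand-binding equilibrium.

The closed-form coupled solver is checked against two independent
oracles: a damped fixed-point iteration on the free-ligand concentration,
and a brute-force temperature scan for the predicted midpoint shift.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meltshift.thermo import (
    CELSIUS,
    LigandCoupling,
    R_KJ,
    SpeciesThermo,
    calibrate_kd,
    fraction_unfolded,
    melting_midpoint,
    predicted_tm_shift,
    solve_equilibrium,
    unfolding_free_energy,
)

KINASE = SpeciesThermo("kinase", 49.0, 420.0, dcp=6.0)
SIMPLE = SpeciesThermo("simple", 49.0, 400.0)  # ΔCp = 0


def fixed_point_free_ligand(t_k, thermo, coupling, p_total, l_total, tol=1e-12):
    """Independent oracle: damped fixed-point iteration on [L]free."""
    ku = math.exp(-unfolding_free_energy(t_k, thermo) / (R_KJ * t_k))
    kd = coupling.kd_at(t_k)
    l = l_total
    for _ in range(100000):
        bound = p_total * (l / kd) / (1.0 + ku + l / kd)
        l_new = 0.5 * l + 0.5 * max(l_total - bound, 0.0)
        if abs(l_new - l) < tol:
            return l_new
        l = l_new
    raise AssertionError("fixed point did not converge")


def test_free_energy_zero_at_midpoint():
    assert unfolding_free_energy(KINASE.tm_k, KINASE) == pytest.approx(0.0, abs=1e-12)


def test_free_energy_closed_form_value():
    # ΔHm·(1 − T/Tm) with ΔHm=400, Tm=322.15 K at T=312.15 K
    val = unfolding_free_energy(312.15, SpeciesThermo("x", 49.0, 400.0))
    assert val == pytest.approx(400.0 * (1.0 - 312.15 / 322.15), rel=1e-12)
    assert val == pytest.approx(12.4166, abs=1e-3)


def test_free_energy_monotone_and_negative_past_tm():
    ts = np.linspace(280.0, 360.0, 200)
    gs = [unfolding_free_energy(t, SIMPLE) for t in ts]
    assert all(b < a for a, b in zip(gs, gs[1:]))
    assert unfolding_free_energy(SIMPLE.tm_k + 5.0, SIMPLE) < 0


def test_fraction_unfolded_half_at_apo_midpoint():
    assert fraction_unfolded(KINASE.tm_k, KINASE, p_total=5.0) == pytest.approx(0.5)


@pytest.mark.parametrize("t_c", [20.0, 40.0, 49.0, 60.0, 80.0])
def test_fraction_unfolded_in_unit_interval(t_c):
    for coupling, l in [(None, 0.0), (LigandCoupling("L", "kinase", 10.0), 100.0)]:
        fu = fraction_unfolded(t_c + CELSIUS, KINASE, coupling, 5.0, l)
        assert 0.0 <= fu <= 1.0


def test_ligand_limits_reduce_to_apo():
    apo = fraction_unfolded(322.15, KINASE, p_total=5.0)
    weak = LigandCoupling("L", "kinase", 1e9)
    none_left = LigandCoupling("L", "kinase", 10.0)
    assert fraction_unfolded(322.15, KINASE, weak, 5.0, 100.0) == pytest.approx(apo, abs=1e-6)
    assert fraction_unfolded(322.15, KINASE, none_left, 5.0, 1e-12) == pytest.approx(apo, abs=1e-6)


@pytest.mark.parametrize("kd,l_total,dhb", [(10.0, 100.0, 0.0), (1.0, 3.0, 0.0), (50.0, 20.0, -40.0), (0.2, 8.0, 60.0)])
def test_closed_form_agrees_with_fixed_point_oracle(kd, l_total, dhb):
    coupling = LigandCoupling("L", "kinase", kd, dhb)
    for t_k in (300.15, 322.15, 330.15):
        st_ = solve_equilibrium(t_k, KINASE, coupling, 5.0, l_total)
        l_oracle = fixed_point_free_ligand(t_k, KINASE, coupling, 5.0, l_total)
        assert st_.l_free == pytest.approx(l_oracle, abs=1e-8)


@pytest.mark.parametrize("kd,l_total", [(10.0, 100.0), (1.0, 3.0), (200.0, 500.0)])
def test_conservation_laws_hold(kd, l_total):
    coupling = LigandCoupling("L", "kinase", kd)
    p_total = 5.0
    for t_k in np.linspace(290.0, 345.0, 12):
        s = solve_equilibrium(t_k, KINASE, coupling, p_total, l_total)
        protein = (s.f_native_free + s.f_bound + s.f_unfolded) * p_total
        ligand = s.l_free + s.f_bound * p_total
        assert protein == pytest.approx(p_total, abs=1e-8)
        assert ligand == pytest.approx(l_total, abs=1e-8)


def test_predicted_shift_zero_without_ligand():
    c = LigandCoupling("L", "kinase", 10.0)
    assert predicted_tm_shift(KINASE, c, 5.0, 0.0) == 0.0


def test_predicted_shift_matches_brute_force_scan():
    """Bisection midpoint vs a 0.001 °C grid scan of fraction_unfolded."""
    coupling = LigandCoupling("L", "kinase", 10.0, dhb=20.0)
    shift = predicted_tm_shift(KINASE, coupling, 5.0, 100.0)
    ts = KINASE.tm_c + np.arange(0.0, 25.0, 0.001)
    fus = np.array([fraction_unfolded(t + CELSIUS, KINASE, coupling, 5.0, 100.0) for t in ts])
    scan_mid = ts[int(np.argmin(np.abs(fus - 0.5)))]
    assert shift == pytest.approx(scan_mid - KINASE.tm_c, abs=0.002)


@settings(max_examples=25, deadline=None)
@given(
    l1=st.floats(min_value=0.5, max_value=400.0),
    factor=st.floats(min_value=1.1, max_value=4.0),
)
def test_shift_monotone_in_ligand_and_kd(l1, factor):
    tight = LigandCoupling("L", "kinase", 5.0)
    loose = LigandCoupling("L", "kinase", 5.0 * factor)
    s_l1 = predicted_tm_shift(KINASE, tight, 5.0, l1)
    s_l2 = predicted_tm_shift(KINASE, tight, 5.0, l1 * factor)
    assert s_l2 >= s_l1 - 1e-9  # non-decreasing in dose
    assert predicted_tm_shift(KINASE, loose, 5.0, l1) <= s_l1 + 1e-9  # non-increasing in Kd


def test_calibrate_kd_inverts_shift():
    c = calibrate_kd(KINASE, 5.0, 50.0, 6.7, ligand="cmpd")
    assert predicted_tm_shift(KINASE, c, 5.0, 50.0) == pytest.approx(6.7, abs=1e-6)


def test_invalid_species_parameters_rejected():
    with pytest.raises(ValueError):
        SpeciesThermo("bad", 49.0, -1.0)
    with pytest.raises(ValueError):
        SpeciesThermo("bad", 49.0, 400.0, k_agg=-0.1)
    with pytest.raises(ValueError):
        LigandCoupling("L", "x", 0.0)


def test_apo_midpoint_is_tm():
    assert melting_midpoint(KINASE) == KINASE.tm_c
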