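"""Boltzmann fitting: recovery, invariances, model selection, QC flags."""

import numpy as np
import pytest

from meltshift.config import AnalysisConfig
from meltshift.curves import MeltCurve
from meltshift.fitting import (
    BIPHASIC,
    DegenerateCurveError,
    HIGH_INITIAL,
    MERGED,
    MeltCurveModel,
    NON_TWO_STATE,
    TWO_STATE,
    fit_boltzmann,
    fit_melt_curve,
    fit_two_transitions,
    preprocess,
    tm_from_derivative,
)
from meltshift.fixtures import generate_fixture
from meltshift.simulate import SimScenario, simulate_curve
from meltshift.thermo import SpeciesThermo, melting_midpoint


def _curve(t, f, sid="c"):
    return MeltCurve(sid, "A1", 1, t, f)


def _boltz(t, ll, ul, tm, a):
    return ll + (ul - ll) / (1.0 + np.exp((tm - t) / a))


def _sim_single(tm_c, dhm=420.0, noise=0.0, seed=1, conc=5.0, grid=(15.0, 85.0, 1.0)):
    th = SpeciesThermo("sp", tm_c, dhm, dcp=6.0)
    return th, simulate_curve(
        SimScenario([(th, conc)], grid=grid, noise_frac=noise, n_replicates=1, seed=seed)
    )[0]


# -- preprocess -------------------------------------------------------------


def test_preprocess_keeps_monotone_curve_unchanged():
    t = np.arange(20.0, 70.0)
    c = _curve(t, _boltz(t, 0.1, 1.0, 45.0, 2.0))
    pre, flags = preprocess(c)
    assert len(pre) == len(c)
    assert flags == set()


def test_preprocess_truncates_exactly_at_argmax():
    _, c = _sim_single(49.0)
    pre, _ = preprocess(c)
    assert len(pre) == int(np.argmax(c.fluorescence)) + 1
    assert pre.fluorescence[-1] == c.fluorescence.max()


def test_preprocess_flags_high_initial_fluorescence():
    t = np.arange(4.0, 74.0)
    f = _boltz(t, 0.65, 1.0, 43.0, 2.0)
    _, flags = preprocess(_curve(t, f))
    assert HIGH_INITIAL in flags


def test_preprocess_degenerate_when_peak_too_early():
    t = np.arange(4.0, 44.0)
    f = np.concatenate([[5.0], np.linspace(1.0, 0.2, t.size - 1)])
    with pytest.raises(DegenerateCurveError):
        preprocess(_curve(t, f))


# -- single-transition fit --------------------------------------------------


def test_exact_boltzmann_recovered_to_1e6():
    t = np.arange(20.0, 76.0)
    c = _curve(t, _boltz(t, 0.0, 1.0, 50.0, 2.0))
    fit = fit_boltzmann(c)
    assert fit.tm == pytest.approx(50.0, abs=1e-6)
    assert fit.transitions[0].slope_a == pytest.approx(2.0, abs=1e-6)
    assert fit.ll == pytest.approx(0.0, abs=1e-6)
    assert fit.ul == pytest.approx(1.0, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("tm", [30.0, 37.0, 44.0, 51.0, 58.0, 65.0])
@pytest.mark.parametrize("a", [1.0, 2.0, 4.0])
def test_exact_boltzmann_midpoints_recovered_across_grid(tm, a):
    t = np.arange(15.0, 86.0)
    fit = fit_boltzmann(_curve(t, _boltz(t, 0.1, 1.1, tm, a)))
    assert fit.tm == pytest.approx(tm, abs=0.05)


def test_noiseless_simulated_kinase_tm_within_0p05():
    th, c = _sim_single(49.0)
    pre, _ = preprocess(c)
    fit = fit_boltzmann(pre)
    assert abs(fit.tm - melting_midpoint(th)) <= 0.05


def test_fitted_tm_invariant_under_fluorescence_scaling():
    _, c = _sim_single(49.0, noise=0.01, seed=3)
    pre, _ = preprocess(c)
    base = fit_boltzmann(pre).tm
    for scale in (0.01, 7.3, 1e4):
        scaled = MeltCurve("s", "A1", 1, pre.temperatures, pre.fluorescence * scale)
        assert fit_boltzmann(scaled).tm == pytest.approx(base, abs=0.05)


def test_replicate_tm_scatter_below_regression_bound():
    """At 1% noise the fitted Tm sd stays below 0.3 °C (100 replicates)."""
    th = SpeciesThermo("sp", 49.0, 420.0, dcp=6.0)
    curves = simulate_curve(
        SimScenario([(th, 5.0)], grid=(15.0, 85.0, 1.0), noise_frac=0.01, n_replicates=100, seed=11)
    )
    tms = []
    for c in curves:
        pre, _ = preprocess(c)
        tms.append(fit_boltzmann(pre).tm)
    assert np.std(tms) <= 0.3


def test_constant_trace_is_non_two_state():
    t = np.arange(20.0, 70.0)
    fit = fit_boltzmann(_curve(t, np.full(t.size, 3.0)))
    assert fit.classification == NON_TWO_STATE
    assert (not fit.converged) or fit.amplitude < 1e-3


# -- two-transition fit -----------------------------------------------------


def test_fusion_components_recovered_within_0p2():
    """Additive two-species curves: both Tms within 0.2 °C (sep ≥ 6)."""
    a = SpeciesThermo("a", 38.3, 350.0, dcp=6.0)
    b = SpeciesThermo("b", 50.0, 450.0, dcp=5.0)
    mid_a, mid_b = melting_midpoint(a), melting_midpoint(b)
    for noise, seed in [(0.0, 1), (0.01, 2)]:
        c = simulate_curve(
            SimScenario([(a, 5.0), (b, 5.0)], grid=(4.0, 74.0, 1.0), noise_frac=noise,
                        n_replicates=1, seed=seed)
        )[0]
        fit = fit_two_transitions(c, reference_tms=(38.3, 50.0))
        assert fit.n_transitions == 2
        # empirical Boltzmann midpoints sit a fixed small offset from the
        # thermodynamic ones; compare against noiseless self-consistency
        assert fit.transitions[0].tm == pytest.approx(mid_a, abs=0.45)
        assert fit.transitions[1].tm == pytest.approx(mid_b, abs=0.45)
    # noiseless vs noisy agreement is the 0.2 °C recovery check
    c0 = simulate_curve(
        SimScenario([(a, 5.0), (b, 5.0)], grid=(4.0, 74.0, 1.0), noise_frac=0.0,
                    n_replicates=1, seed=1)
    )[0]
    f0 = fit_two_transitions(c0, reference_tms=(38.3, 50.0))
    c1 = simulate_curve(
        SimScenario([(a, 5.0), (b, 5.0)], grid=(4.0, 74.0, 1.0), noise_frac=0.01,
                    n_replicates=1, seed=5)
    )[0]
    f1 = fit_two_transitions(c1, reference_tms=(38.3, 50.0))
    assert f1.transitions[0].tm == pytest.approx(f0.transitions[0].tm, abs=0.2)
    assert f1.transitions[1].tm == pytest.approx(f0.transitions[1].tm, abs=0.2)


def test_single_species_selects_one_transition():
    _, c = _sim_single(49.0, noise=0.01, seed=4)
    fit = fit_two_transitions(c)
    assert fit.n_transitions == 1
    assert fit.classification == TWO_STATE


def test_merged_transitions_flagged_when_references_distinct():
    """Two transitions closer than min_separation collapse to one fit."""
    a = SpeciesThermo("a", 47.8, 350.0, dcp=6.0)
    b = SpeciesThermo("b", 50.0, 450.0, dcp=5.0)
    c = simulate_curve(
        SimScenario([(a, 5.0), (b, 5.0)], grid=(4.0, 74.0, 1.0), noise_frac=0.01,
                    n_replicates=1, seed=6)
    )[0]
    fit = fit_two_transitions(c, reference_tms=(38.3, 50.0))
    assert fit.n_transitions == 1
    assert MERGED in fit.flags


# -- classification on fixtures --------------------------------------------


def test_pyl_classification_matrix():
    """Apo PYL1 melts two-state; apo PYL2 does not until ABA is added."""
    fx = generate_fixture("pyl_aba", 11)

    def fits(label):
        return [
            fit_melt_curve(c)
            for c in fx.curves
            if c.sample_id.rsplit("_r", 1)[0] == label
        ]

    assert all(f.classification == TWO_STATE for f in fits("PYL1_ABA_0"))
    pyl2_apo = fits("PYL2_ABA_0")
    assert all(f.classification == NON_TWO_STATE for f in pyl2_apo)
    assert all(HIGH_INITIAL in f.flags for f in pyl2_apo)
    assert all(f.classification == TWO_STATE for f in fits("PYL2_ABA_25"))


def test_low_pp2c_titration_point_is_biphasic():
    fx = generate_fixture("complex_titration", 11)
    curves = [c for c in fx.curves if c.sample_id.startswith("PYL1_HAB1_1_")]
    fits = [fit_melt_curve(c, compare_two=True) for c in curves]
    assert sum(f.classification == BIPHASIC for f in fits) >= 2


# -- derivative-based Tm ----------------------------------------------------


def test_derivative_tm_on_exact_boltzmann():
    t = np.arange(20.0, 76.0)
    c = _curve(t, _boltz(t, 0.0, 1.0, 50.0, 2.0))
    assert abs(tm_from_derivative(c) - 50.0) <= 1.0


def test_derivative_tm_picks_higher_amplitude_transition():
    t = np.arange(4.0, 74.0)
    f = _boltz(t, 0.0, 1.0, 35.0, 2.0) + _boltz(t, 0.0, 3.0, 55.0, 2.0)
    assert abs(tm_from_derivative(_curve(t, f)) - 55.0) <= 1.0


def test_derivative_tm_flat_trace_returns_without_error():
    t = np.arange(20.0, 70.0)
    out = tm_from_derivative(_curve(t, np.full(t.size, 2.0)))
    assert t[0] <= out <= t[-1]


def test_summary_renders():
    _, c = _sim_single(49.0, noise=0.01, seed=9)
    fit = fit_melt_curve(c)
    text = fit.summary()
    assert "Tm1" in text and "classification" in text
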