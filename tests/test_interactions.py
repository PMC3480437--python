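"""Complex detection, stoichiometry inference, concentration independence."""

import numpy as np
import pytest

from meltshift.fitting import fit_group, fit_melt_curve
from meltshift.fixtures import PP2C_TITRATION, generate_fixture
from meltshift.interactions import (
    InteractionInputError,
    analyze_titration,
    check_concentration_independence,
    detect_complex,
)
from meltshift.simulate import SimScenario, simulate_curve
from meltshift.thermo import SpeciesThermo


def _complex_fixture_fits(seed=11, pp2c="HAB1"):
    fx = generate_fixture("complex_titration", seed)

    def sel(label, **kw):
        curves = [c for c in fx.curves if c.sample_id.rsplit("_r", 1)[0] == label]
        return fit_group(curves, **kw)

    series = {
        conc / 10.0: sel(f"PYL1_{pp2c}_{conc:g}", compare_two=True)
        for conc in PP2C_TITRATION
    }
    return series, sel("PYL1_ABA_ref"), sel(f"{pp2c}_ref")


def test_equimolar_mixture_detected_as_cooperative_complex():
    series, ref_r, ref_p = _complex_fixture_fits()
    detected, tm_mix = detect_complex(ref_r[0], ref_p[0], series[1.0][0])
    assert detected
    assert tm_mix > max(ref_r[0].tm, ref_p[0].tm) + 1.0


def test_noninteracting_mixture_not_detected():
    a = SpeciesThermo("a", 41.0, 380.0, dcp=5.0)
    b = SpeciesThermo("b", 49.0, 420.0, dcp=6.0)
    mk = lambda sp, seed: fit_melt_curve(
        simulate_curve(SimScenario([(s, 10.0) for s in sp], grid=(4.0, 74.0, 1.0),
                                   noise_frac=0.01, n_replicates=1, seed=seed))[0],
        compare_two=True,
    )
    fit_a, fit_b = mk([a], 1), mk([b], 2)
    fit_mix = mk([a, b], 3)
    detected, _ = detect_complex(fit_a, fit_b, fit_mix)
    assert not detected
    assert fit_mix.n_transitions == 2


def test_boundary_margin_blocks_detection():
    """A mixture Tm equal to the best component Tm fails the +1 °C rule."""
    th = SpeciesThermo("x", 49.0, 420.0, dcp=6.0)
    mk = lambda seed: fit_melt_curve(
        simulate_curve(SimScenario([(th, 10.0)], grid=(4.0, 74.0, 1.0), noise_frac=0.01,
                                   n_replicates=1, seed=seed))[0], compare_two=True)
    detected, _ = detect_complex(mk(1), mk(2), mk(3))
    assert not detected


def test_non_two_state_reference_raises():
    fx = generate_fixture("pyl_aba", 11)
    bad = [fit_melt_curve(c) for c in fx.curves if c.sample_id.startswith("PYL2_ABA_0_")]
    good = [fit_melt_curve(c) for c in fx.curves if c.sample_id.startswith("PYL1_ABA_0_")]
    with pytest.raises(InteractionInputError):
        detect_complex(bad[0], good[0], good[0])


@pytest.mark.parametrize("pp2c", ["HAB1", "ABI2"])
def test_titration_phase_calls_and_stoichiometry(pp2c):
    series, ref_r, ref_p = _complex_fixture_fits(pp2c=pp2c)
    res = analyze_titration(series, ("PYL1", ref_r), (pp2c, ref_p))
    assert res.stoichiometry == 1.0
    assert res.phase_calls[0.1] == "biphasic_excess_PYL1"
    assert res.phase_calls[0.5] == "biphasic_excess_PYL1"
    assert res.phase_calls[1.0] == "monophasic"
    assert res.phase_calls[2.0] == f"biphasic_excess_{pp2c}"
    assert res.cooperative


def test_phase_calls_invariant_under_component_relabel():
    series, ref_r, ref_p = _complex_fixture_fits()
    a = analyze_titration(series, ("PYL1", ref_r), ("HAB1", ref_p))
    b = analyze_titration(series, ("receptor", ref_r), ("phosphatase", ref_p))
    rename = lambda s: s.replace("PYL1", "receptor").replace("HAB1", "phosphatase")
    assert {r: rename(c) for r, c in a.phase_calls.items()} == b.phase_calls
    assert a.stoichiometry == b.stoichiometry


def test_secondary_transition_matches_excess_component():
    """Biphasic secondary Tm sits within 0.5 °C of the excess species'."""
    series, ref_r, ref_p = _complex_fixture_fits()
    res = analyze_titration(series, ("PYL1", ref_r), ("HAB1", ref_p))
    ref_tm_r = np.mean([f.tm for f in ref_r])
    ref_tm_p = np.mean([f.tm for f in ref_p])
    assert res.secondary_tms[0.5] == pytest.approx(ref_tm_r, abs=0.5)
    assert res.secondary_tms[2.0] == pytest.approx(ref_tm_p, abs=0.5)


def test_stoichiometry_needs_bracketing_biphasic_ratios():
    series, ref_r, ref_p = _complex_fixture_fits()
    partial = {r: f for r, f in series.items() if r >= 1.0}
    partial[3.0] = series[2.0]
    res = analyze_titration(partial, ("PYL1", ref_r), ("HAB1", ref_p))
    assert res.stoichiometry is None
    assert "no_monophasic_ratio" in res.flags or res.phase_calls[1.0] == "monophasic"


def test_all_biphasic_titration_yields_none():
    series, ref_r, ref_p = _complex_fixture_fits()
    bi = {r: series[r] for r in (0.1, 0.5)}
    bi[2.0] = series[2.0]
    res = analyze_titration(bi, ("PYL1", ref_r), ("HAB1", ref_p))
    assert res.stoichiometry is None


def test_concentration_independence_passes_on_abi2_ladder():
    fx = generate_fixture("abi2_concentration", 11)
    series = {
        conc: fit_group([c for c in fx.curves if c.sample_id.startswith(f"ABI2_{conc:g}uM")])
        for conc in (2.5, 5.0, 10.0, 20.0)
    }
    rep = check_concentration_independence(series)
    assert rep.passed
    assert rep.tm_sd <= 0.3
    amps = [rep.amplitude_by_conc[c] for c in sorted(rep.amplitude_by_conc)]
    assert all(b > a for a, b in zip(amps, amps[1:]))


def test_concentration_independence_fails_on_flat_amplitude():
    fx = generate_fixture("abi2_concentration", 11)
    fits = fit_group([c for c in fx.curves if c.sample_id.startswith("ABI2_5uM")])
    series = {2.5: fits, 5.0: fits, 10.0: fits}
    rep = check_concentration_independence(series)
    assert not rep.passed
    assert not rep.amplitude_pass


def test_concentration_independence_fails_on_tm_outlier():
    fx = generate_fixture("abi2_concentration", 11)
    series = {
        conc: fit_group([c for c in fx.curves if c.sample_id.startswith(f"ABI2_{conc:g}uM")])
        for conc in (2.5, 5.0, 10.0)
    }
    shifted = SpeciesThermo("ABI2", 46.0, 380.0, dcp=5.0)
    outlier = simulate_curve(
        SimScenario([(shifted, 20.0)], grid=(4.0, 74.0, 1.0), noise_frac=0.01,
                    n_replicates=3, seed=77)
    )
    series[20.0] = fit_group(outlier)
    rep = check_concentration_independence(series)
    assert not rep.tm_pass
    assert not rep.passed
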