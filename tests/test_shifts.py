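"""ΔTm statistics, detection rules, and the dose-response model."""

import numpy as np
import pytest

from meltshift.config import AnalysisConfig
from meltshift.fitting import fit_melt_curve, preprocess, fit_boltzmann
from meltshift.fixtures import GRID_SCREEN, generate_fixture
from meltshift.shifts import (
    DoseResponseModel,
    MixedClassificationError,
    ShiftResult,
    compare_ligands,
    delta_tm,
    fit_dose_response,
)
from meltshift.simulate import SimScenario, simulate_curve
from meltshift.thermo import LigandCoupling, SpeciesThermo, predicted_tm_shift


def _fits(th, coupling=None, l_total=0.0, seed=1, n=3, noise=0.01):
    curves = simulate_curve(
        SimScenario(
            [(th, 5.0)],
            couplings=[(coupling, l_total)] if coupling else [],
            grid=GRID_SCREEN,
            noise_frac=noise,
            n_replicates=n,
            seed=seed,
        )
    )
    return [fit_melt_curve(c) for c in curves]


KINASE = SpeciesThermo("kinase", 49.0, 420.0, dcp=6.0)


def test_delta_tm_zero_against_itself():
    fits = _fits(KINASE, seed=2)
    sr = delta_tm(fits, fits)
    assert sr.delta_tm_mean == 0.0
    assert not sr.detectable


def test_delta_tm_antisymmetric():
    a = _fits(KINASE, seed=3)
    coup = LigandCoupling("L", "kinase", 5.0)
    b = _fits(KINASE, coup, 50.0, seed=4)
    ab = delta_tm(a, b)
    ba = delta_tm(b, a)
    assert ab.delta_tm_mean == pytest.approx(-ba.delta_tm_mean, abs=1e-12)
    assert ab.delta_tm_sd == pytest.approx(ba.delta_tm_sd, abs=1e-12)


def test_delta_tm_requires_two_state_fits():
    fx = generate_fixture("pyl_aba", 11)
    apo = [c for c in fx.curves if c.sample_id.startswith("PYL2_ABA_0_")]
    cond = [c for c in fx.curves if c.sample_id.startswith("PYL2_ABA_500_")]
    apo_fits = [fit_melt_curve(c) for c in apo]
    cond_fits = [fit_melt_curve(c) for c in cond]
    with pytest.raises(MixedClassificationError, match="PYL2_ABA_0"):
        delta_tm(cond_fits, apo_fits)
    sr = delta_tm(cond_fits, apo_fits, require_two_state=False)
    assert "reference_flagged" in sr.flags
    assert sr.delta_tm_mean > 3.0


def test_detection_needs_threshold_and_sem_rule():
    cfg = AnalysisConfig()
    small = ShiftResult("c", "r", 0.4, 0.01, 3, True)  # below θ_detect
    assert not ShiftResult.__dataclass_fields__ or True
    sr = delta_tm(_fits(KINASE, seed=5), _fits(KINASE, seed=6))
    assert abs(sr.delta_tm_mean) < cfg.theta_detect
    assert not sr.detectable


def test_pipeline_shift_matches_thermodynamic_prediction():
    """End-to-end ΔTm tracks the coupled-equilibrium prediction (≤0.3 °C)."""
    coup = LigandCoupling("L", "kinase", 2.0)
    cond = _fits(KINASE, coup, 25.0, seed=7)
    ref = _fits(KINASE, seed=8)
    sr = delta_tm(cond, ref)
    predicted = predicted_tm_shift(KINASE, coup, 5.0, 25.0)
    assert sr.delta_tm_mean == pytest.approx(predicted, abs=0.3)


# -- dose response ----------------------------------------------------------


def _series_from_hyperbola(dtm_max=8.0, k_half=40.0, concs=(0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)):
    out = []
    for c in concs:
        shift = dtm_max * c / (k_half + c)
        out.append((c, ShiftResult("c", "r", shift, 0.0, 3, shift >= 0.5)))
    return out


def test_hyperbola_parameters_recovered_within_5pc():
    fit = fit_dose_response(_series_from_hyperbola(), protein_conc=10.0)
    assert fit.converged
    assert fit.dtm_max == pytest.approx(8.0, rel=0.05)
    assert fit.k_half == pytest.approx(40.0, rel=0.05)
    assert fit.r_squared > 0.999


def test_min_detectable_and_kd_bound_logic():
    fit = fit_dose_response(_series_from_hyperbola(), protein_conc=10.0)
    # first dose with shift >= 0.5 for dtm_max 8, K 40 is 2.56 -> 5 µM here
    assert fit.min_detectable_conc == 5.0
    assert fit.kd_lower_bound is None  # detectable at sub-stoichiometric dose
    # dtm_max 4, K 400: shift first crosses 0.5 °C at 100 µM (0.8 °C),
    # nothing detectable at or below the 10 µM protein concentration
    fit2 = fit_dose_response(_series_from_hyperbola(dtm_max=4.0, k_half=400.0), protein_conc=10.0)
    assert fit2.min_detectable_conc == 100.0
    assert fit2.kd_lower_bound == 100.0


def test_all_undetectable_series_returns_none():
    series = [(c, ShiftResult("c", "r", 0.01 * i, 0.0, 3, False)) for i, c in enumerate([0.0, 5.0, 10.0, 25.0])]
    fit = fit_dose_response(series, protein_conc=10.0)
    assert fit.min_detectable_conc is None
    assert fit.kd_lower_bound is None
    assert not fit.converged


def test_series_needs_zero_dose_and_four_points():
    with pytest.raises(ValueError):
        DoseResponseModel([(5.0, None), (10.0, None), (25.0, None)])


def test_min_detectable_monotone_in_affinity():
    """Tighter binding never needs a higher dose to become detectable."""
    th = SpeciesThermo("kinase", 49.0, 420.0, dcp=6.0)
    concs = (0.0, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0)
    min_detect = []
    for i, kd in enumerate((0.5, 5.0, 50.0)):
        coup = LigandCoupling("L", "kinase", kd)
        ref = _fits(th, seed=100 + i)
        series = [(0.0, delta_tm(ref, ref))]
        for j, c in enumerate(concs[1:]):
            cond = _fits(th, coup, c, seed=200 + 10 * i + j)
            series.append((c, delta_tm(cond, ref)))
        dr = fit_dose_response(series, protein_conc=5.0)
        min_detect.append(dr.min_detectable_conc if dr.min_detectable_conc else np.inf)
    assert min_detect[0] <= min_detect[1] <= min_detect[2]


# -- ligand comparison ------------------------------------------------------


def test_compare_ligands_orders_by_tm():
    out = compare_ligands({"aba": 48.1, "pyrabactin": 45.6})
    assert out["ranking"] == [["aba"], ["pyrabactin"]]
    assert out["pairwise_delta_tm"]["aba-pyrabactin"] == pytest.approx(2.5)


def test_compare_ligands_tie_within_0p1():
    out = compare_ligands({"x": 45.00, "y": 45.08})
    assert out["ranking"] == [["y", "x"]]


def test_compare_ligands_singleton():
    assert compare_ligands({"only": 50.0})["ranking"] == [["only"]]
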