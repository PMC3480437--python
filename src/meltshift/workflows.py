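"""End-to-end pipelines: fixture → fits → shift/stoichiometry/screen calls.

Each function regenerates a fixture from a seed, runs the full analysis
path (preprocess → Boltzmann fit → downstream logic) and returns the
headline quantities.  ``reproduce_all`` bundles everything into one
JSON-serializable summary; the CLI ``reproduce`` command and the
acceptance script both call it.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .curves import MeltCurve
from .fitting import MeltFitResult, fit_group
from .fixtures import (
    ABA_TITRATION,
    ABI2_CONCS,
    PP2C_TITRATION,
    SCREEN_HITS,
    STAURO_TITRATION,
    generate_fixture,
)
from .interactions import analyze_titration, check_concentration_independence, detect_complex
from .io import group_replicates
from .screening import call_hits, fusion_control_classify
from .shifts import compare_ligands, delta_tm, delta_tm_biphasic, fit_dose_response

MAX_SEED = 2 ** 31


def _fixture_seed(seed: int, k: int) -> int:
    return (int(seed) + 7919 * k) % MAX_SEED


def _by_prefix(curves: Sequence[MeltCurve], label: str) -> List[MeltCurve]:
    """Curves whose sample id is ``label`` + a replicate suffix ``_r<k>``."""
    out = [c for c in curves if c.sample_id.rsplit("_r", 1)[0] == label]
    if not out:
        raise KeyError(f"no curves with sample label {label!r}")
    return out


def _fit_prefix(curves, prefix, config, **kw) -> List[MeltFitResult]:
    return fit_group(_by_prefix(curves, prefix), config, **kw)


# ---------------------------------------------------------------------------


def snrk_panel_tms(seed: int, config: AnalysisConfig = DEFAULT_CONFIG) -> Dict[str, dict]:
    """Mean fitted apo Tm (± replicate sd) for the three SnRK2 kinases."""
    fx = generate_fixture("snrk_panel", seed)
    out = {}
    for kinase in ("SnRK2.2", "SnRK2.3", "SnRK2.6"):
        fits = _fit_prefix(fx.curves, f"{kinase}_apo", config)
        tms = [f.tm for f in fits]
        out[kinase] = {
            "tm_mean": float(np.mean(tms)),
            "tm_sd": float(np.std(tms, ddof=1)),
            "n": len(tms),
            "classifications": [f.classification for f in fits],
        }
    return out


def staurosporine_titration(seed: int, config: AnalysisConfig = DEFAULT_CONFIG) -> Dict[str, dict]:
    """Dose-resolved staurosporine shifts on SnRK2.3 and SnRK2.6."""
    fx = generate_fixture("snrk_staurosporine", seed)
    out = {}
    for kinase in ("SnRK2.3", "SnRK2.6"):
        ref_fits = _fit_prefix(fx.curves, f"{kinase}_stauro_0", config)
        series = []
        shift_at = {}
        for conc in STAURO_TITRATION:
            if conc == 0:
                continue
            fits = _fit_prefix(fx.curves, f"{kinase}_stauro_{conc:g}", config)
            sr = delta_tm(fits, ref_fits, config)
            series.append((conc, sr))
            shift_at[f"{conc:g}"] = sr.delta_tm_mean
        series.insert(0, (0.0, delta_tm(ref_fits, ref_fits, config)))
        dr = fit_dose_response(series, protein_conc=5.0, config=config)
        out[kinase] = {
            "shift_at_uM": shift_at,
            "delta_tm_50uM": shift_at["50"],
            "min_detectable_conc": dr.min_detectable_conc,
            "k_half": dr.k_half,
            "dtm_max": dr.dtm_max,
            "n": 3,
        }
    return out


def pyl_dose_response(seed: int, config: AnalysisConfig = DEFAULT_CONFIG) -> Dict[str, dict]:
    """ABA dose response for PYL1/PYL2 plus the pyrabactin comparison.

    The PYL2 apo trace has no conventional melt curve (high initial
    fluorescence); its numerically fitted Tm still anchors the dose
    series, and a dose only counts as detectable once its own curve shows
    a clean two-state transition.
    """
    fx = generate_fixture("pyl_aba", seed)
    out = {}
    for receptor in ("PYL1", "PYL2"):
        ref_fits = _fit_prefix(fx.curves, f"{receptor}_ABA_0", config)
        apo_class = [f.classification for f in ref_fits]
        series = []
        for conc in ABA_TITRATION:
            if conc == 0:
                continue
            fits = _fit_prefix(fx.curves, f"{receptor}_ABA_{conc:g}", config)
            if all(f.classification != "two_state" for f in fits):
                series.append((conc, None))
                continue
            sr = delta_tm(fits, ref_fits, config, require_two_state=False)
            series.append((conc, sr))
        series.insert(0, (0.0, None))
        dr = fit_dose_response(series, protein_conc=10.0, config=config)
        out[receptor] = {
            "apo_classification": apo_class,
            "min_detectable_conc": dr.min_detectable_conc,
            "kd_lower_bound": dr.kd_lower_bound,
            "k_half": dr.k_half,
            "dtm_max": dr.dtm_max,
            "saturation_reached": dr.saturation_reached,
            "shifts": {f"{c:g}": (s.delta_tm_mean if s else None) for c, s in series},
        }
    # ligand comparison at 500 µM on PYL2
    aba_fits = _fit_prefix(fx.curves, "PYL2_ABA_500", config)
    pyr_fits = _fit_prefix(fx.curves, "PYL2_pyrabactin_500", config)
    cmp = compare_ligands(
        {
            "(+)-ABA": float(np.mean([f.tm for f in aba_fits])),
            "pyrabactin": float(np.mean([f.tm for f in pyr_fits])),
        },
        config,
    )
    out["PYL2_ligand_ranking"] = cmp
    return out


def complex_stoichiometry(seed: int, config: AnalysisConfig = DEFAULT_CONFIG) -> Dict[str, dict]:
    """Phase calls and inferred stoichiometry for both PP2C titrations."""
    fx = generate_fixture("complex_titration", seed)
    receptor_uM = 10.0
    ref_r = _fit_prefix(fx.curves, "PYL1_ABA_ref", config)
    out = {}
    for pp2c in ("HAB1", "ABI2"):
        ref_p = _fit_prefix(fx.curves, f"{pp2c}_ref", config)
        series = {}
        for conc in PP2C_TITRATION:
            fits = _fit_prefix(fx.curves, f"PYL1_{pp2c}_{conc:g}", config, compare_two=True)
            series[conc / receptor_uM] = fits
        res = analyze_titration(series, ("PYL1", ref_r), (pp2c, ref_p), config)
        equimolar = series[1.0]
        detected, tm_mix = detect_complex(ref_r[0], ref_p[0], equimolar[0], config)
        out[pp2c] = {
            "stoichiometry": res.stoichiometry,
            "phase_calls": {f"{r:g}": c for r, c in res.phase_calls.items()},
            "complex_tm": res.complex_tm,
            "cooperative": res.cooperative,
            "equimolar_complex_detected": detected,
            "equimolar_tm": tm_mix,
            "flags": sorted(res.flags),
        }
    return out


def abi2_concentration_check(seed: int, config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    fx = generate_fixture("abi2_concentration", seed)
    series = {
        conc: _fit_prefix(fx.curves, f"ABI2_{conc:g}uM", config) for conc in ABI2_CONCS
    }
    rep = check_concentration_independence(series, config)
    return {
        "passed": rep.passed,
        "tm_sd": rep.tm_sd,
        "tm_by_conc": {f"{c:g}": t for c, t in rep.tm_by_conc.items()},
        "amplitude_by_conc": {f"{c:g}": a for c, a in rep.amplitude_by_conc.items()},
    }


def fusion_control_analysis(seed: int, config: AnalysisConfig = DEFAULT_CONFIG) -> Dict[str, dict]:
    """Specificity calls + NaCl shifts from the MBP-SnRK2.3 control fixture."""
    fx = generate_fixture("fusion_control", seed)
    kin_ref = _fit_prefix(fx.curves, "SnRK2.3_apo", config)
    mbp_ref = _fit_prefix(fx.curves, "MBP_apo", config)
    target_ref = float(np.mean([f.tm for f in kin_ref]))
    tag_ref = float(np.mean([f.tm for f in mbp_ref]))
    refs = (target_ref, tag_ref)
    fusion_apo = _fit_prefix(
        fx.curves, "MBP-SnRK2.3_apo", config, reference_tms=refs
    )
    out: Dict[str, dict] = {"references": {"SnRK2.3": target_ref, "MBP": tag_ref}}
    for treatment in ("wee1_inhibitor", "staurosporine", "NaCl", "apo"):
        fusion_cond = _fit_prefix(
            fx.curves, f"MBP-SnRK2.3_{treatment}", config, reference_tms=refs
        )
        call = fusion_control_classify(fusion_apo, fusion_cond, refs, config)
        out[treatment] = {"specificity": call}
    # per-species NaCl shifts (untagged proteins + the fusion's transitions)
    nacl_kin = delta_tm(_fit_prefix(fx.curves, "SnRK2.3_NaCl", config), kin_ref, config)
    nacl_mbp = delta_tm(_fit_prefix(fx.curves, "MBP_NaCl", config), mbp_ref, config)
    nacl_fusion = delta_tm_biphasic(
        _fit_prefix(fx.curves, "MBP-SnRK2.3_NaCl", config, reference_tms=refs),
        fusion_apo,
        {"SnRK2.3": target_ref, "MBP": tag_ref},
        config,
    )
    out["NaCl"].update(
        {
            "delta_tm": {
                "SnRK2.3": nacl_kin.delta_tm_mean,
                "MBP": nacl_mbp.delta_tm_mean,
                "fusion_SnRK2.3": nacl_fusion["SnRK2.3"].delta_tm_mean,
                "fusion_MBP": nacl_fusion["MBP"].delta_tm_mean,
            }
        }
    )
    return out


def run_screen(seed: int, config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    """Fit the 300-compound screen and call/rank pan-kinase hits."""
    fx = generate_fixture("screen_300", seed)
    kinases = ("SnRK2.2", "SnRK2.3", "SnRK2.6")
    refs = {k: _fit_prefix(fx.curves, f"{k}_apo", config) for k in kinases}
    groups = group_replicates(fx.curves)
    table: Dict[str, Dict[str, object]] = {}
    for g in groups:
        ligs = dict(g.condition.ligands)
        if not ligs:
            continue
        compound = next(iter(ligs))
        kinase = g.condition.proteins[0][0]
        fits = fit_group(g.curves, config)
        table.setdefault(compound, {})[kinase] = delta_tm(fits, refs[kinase], config)
    calls = call_hits(table, targets=kinases, config=config)
    hits = [c for c in calls if c.hit]
    return {
        "n_compounds": len(table),
        "n_hits": len(hits),
        "hits_ranked": [
            {"compound": c.compound, "min_shift": c.rank_key, "shifts": c.shift_means()}
            for c in hits
        ],
        "expected_hits": sorted(SCREEN_HITS),
        "true_positive": sorted(c.compound for c in hits) == sorted(SCREEN_HITS),
    }


# ---------------------------------------------------------------------------


def reproduce_all(seed: int, config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    """Run every fixture through its analysis; one summary dict.

    Per-fixture seeds are derived deterministically from ``seed`` so a
    single integer reproduces the entire set of results.
    """
    panel = snrk_panel_tms(_fixture_seed(seed, 1), config)
    stauro = staurosporine_titration(_fixture_seed(seed, 2), config)
    pyl = pyl_dose_response(_fixture_seed(seed, 3), config)
    cplx = complex_stoichiometry(_fixture_seed(seed, 4), config)
    fusion = fusion_control_analysis(_fixture_seed(seed, 5), config)
    screen = run_screen(_fixture_seed(seed, 6), config)
    abi2 = abi2_concentration_check(_fixture_seed(seed, 7), config)
    return {
        "seed": seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "snrk_panel": panel,
        "staurosporine": stauro,
        "pyl_aba": pyl,
        "complex_titration": cplx,
        "fusion_control": fusion,
        "screen": screen,
        "abi2_concentration": abi2,
    }


def acceptance_values(summary: dict) -> Dict[str, dict]:
    """Collapse a ``reproduce_all`` summary into the headline scalars."""
    fusion_nacl = summary["fusion_control"]["NaCl"]["delta_tm"]
    # salt destabilizes every transition by a common amount; the pipeline's
    # estimate of that magnitude is the mean over the four transitions
    nacl_magnitude = float(np.mean([abs(v) for v in fusion_nacl.values()]))
    hab1 = summary["complex_titration"]["HAB1"]
    return {
        "snrk26_apo_tm": {"value": summary["snrk_panel"]["SnRK2.6"]["tm_mean"], "n": 3},
        "snrk22_apo_tm": {"value": summary["snrk_panel"]["SnRK2.2"]["tm_mean"], "n": 3},
        "snrk23_apo_tm": {"value": summary["snrk_panel"]["SnRK2.3"]["tm_mean"], "n": 3},
        "snrk26_stauro_50uM_shift": {
            "value": summary["staurosporine"]["SnRK2.6"]["delta_tm_50uM"],
            "n": 3,
        },
        "snrk23_stauro_50uM_shift": {
            "value": summary["staurosporine"]["SnRK2.3"]["delta_tm_50uM"],
            "n": 3,
        },
        "nacl_destabilization_magnitude": {"value": nacl_magnitude, "n": 4},
        "complex_stoichiometry": {"value": hab1["stoichiometry"], "n": 4},
        "pyl1_min_detectable_aba": {
            "value": summary["pyl_aba"]["PYL1"]["min_detectable_conc"],
            "n": 3,
        },
        "pyl2_min_detectable_aba": {
            "value": summary["pyl_aba"]["PYL2"]["min_detectable_conc"],
            "n": 3,
        },
        "snrk23_stauro_min_detectable": {
            "value": summary["staurosporine"]["SnRK2.3"]["min_detectable_conc"],
            "n": 3,
        },
    }
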