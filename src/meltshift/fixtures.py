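"""Fixture registry: every experimental scenario, regenerated from seed.

Each fixture returns simulated melt curves plus a ground-truth manifest
(species thermodynamics, calibrated couplings, true shifts).  Printed
melting temperatures (SnRK2.2 36.2 °C, SnRK2.3 38.3 °C, SnRK2.6 49.0 °C)
and printed shift/detection values are encoded directly; binding
parameters that were never printed are obtained by numerically inverting
the pipeline-measured noiseless shift so the fixture reproduces the
printed observable (see docs/methods.md for the calibration procedure).

Registry
--------
snrk_panel          apo SnRK2.2/2.3/2.6 triplicates
snrk_staurosporine  staurosporine titrations on SnRK2.3 and SnRK2.6
screen_300          300-compound inhibitor screen on all three kinases
pyl_aba             ABA dose series on PYL1/PYL2 (+ pyrabactin on PYL2)
complex_titration   receptor + PP2C titration under saturating ABA
fusion_control      MBP-SnRK2.3 internal-specificity-control scenarios
abi2_concentration  ABI2 concentration ladder (Tm concentration-invariance)
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from functools import lru_cache
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq, root

from .curves import ConditionMeta, MeltCurve
from .fitting import fit_boltzmann, preprocess
from .simulate import MAX_SEED, SimScenario, noiseless_trace, simulate_curve
from .thermo import LigandCoupling, SpeciesThermo, predicted_tm_shift

GRID_SCREEN = (15.0, 85.0, 1.0)   # kinase-screen instrument range
GRID_STANDARD = (4.0, 74.0, 1.0)  # all other experiments
NOISE = 0.01
DETECT_SUB = 0.35  # °C pinned at the dose just below the detection point (0.7 × θ_detect)


# ---------------------------------------------------------------------------
# coupling calibration
#
# Printed ΔTm and detection-dose values are Boltzmann-fit readouts, so the
# fixtures are calibrated end to end: the coupling parameters are found by
# inverting the *measured* noiseless shift (simulate → preprocess →
# Boltzmann fit) rather than the bare thermodynamic midpoint shift, which
# the empirical fit reproduces only up to a model-mismatch bias of a few
# tenths of a °C.


def _noiseless_fit_tm(
    species: SpeciesThermo,
    coupling: Optional[LigandCoupling],
    p_total: float,
    l_total: float,
    grid,
) -> float:
    sc = SimScenario(
        [(species, p_total)],
        couplings=[(coupling, l_total)] if coupling is not None and l_total > 0 else [],
        grid=grid,
        noise_frac=0.0,
        n_replicates=1,
        sample_id="calibration",
    )
    pre, _ = preprocess(simulate_curve(sc)[0])
    return fit_boltzmann(pre).tm


def empirical_shift(
    species: SpeciesThermo,
    coupling: LigandCoupling,
    p_total: float,
    l_total: float,
    grid,
) -> float:
    """Pipeline-measured noiseless ΔTm for one coupled condition."""
    return _noiseless_fit_tm(species, coupling, p_total, l_total, grid) - _noiseless_fit_tm(
        species, None, p_total, 0.0, grid
    )


@lru_cache(maxsize=None)
def _calibrate(
    species_key: str,
    p_total: float,
    anchors: tuple,
    ligand: str,
    grid: tuple,
) -> LigandCoupling:
    """Invert the empirical shift for (Kd, ΔHb) through the anchor points.

    One anchor → temperature-independent Kd by bracketed root-finding; two
    anchors → simultaneous (log Kd, ΔHb) solve.  Cached: calibrations are
    seed-independent.
    """
    species = _SPECIES_REGISTRY[species_key]

    def shift(kd: float, dhb: float, l_total: float) -> float:
        c = LigandCoupling(ligand, species.name, kd, dhb)
        return empirical_shift(species, c, p_total, l_total, grid)

    if len(anchors) == 1:
        (l_a, s_a), = anchors
        x = brentq(lambda lg: shift(10.0 ** lg, 0.0, l_a) - s_a, -4.0, 6.0, xtol=1e-9)
        return LigandCoupling(ligand, species.name, 10.0 ** x, 0.0)

    (l_a, s_a), (l_b, s_b) = anchors

    def resid(x):
        kd, dhb = 10.0 ** x[0], 100.0 * x[1]
        return [shift(kd, dhb, l_a) - s_a, shift(kd, dhb, l_b) - s_b]

    x0 = brentq(lambda lg: shift(10.0 ** lg, 0.0, l_a) - s_a, -4.0, 6.0, xtol=1e-6)
    sol = root(resid, x0=[x0, 0.0], method="hybr", tol=1e-10)
    r = resid(sol.x)
    if max(abs(r[0]), abs(r[1])) > 5e-4:
        raise RuntimeError(
            f"empirical calibration failed for {ligand}/{species.name}: residual {r}"
        )
    return LigandCoupling(ligand, species.name, 10.0 ** sol.x[0], 100.0 * sol.x[1])

SNRK22 = SpeciesThermo("SnRK2.2", 36.2, 350.0, dcp=6.0)
SNRK23 = SpeciesThermo("SnRK2.3", 38.3, 350.0, dcp=6.0)
SNRK26 = SpeciesThermo("SnRK2.6", 49.0, 420.0, dcp=6.0)
PYL1 = SpeciesThermo("PYL1", 45.0, 400.0, dcp=4.0)
# HAB1 sits well below the ABA-loaded receptor (~48.6 °C) so the excess-
# phosphatase transition stays resolvable from excess holo-receptor
HAB1 = SpeciesThermo("HAB1", 41.0, 380.0, dcp=5.0)
ABI2 = SpeciesThermo("ABI2", 44.0, 380.0, dcp=5.0)
MBP = SpeciesThermo("MBP", 50.0, 450.0, dcp=5.0)
PYL2_BASE = SpeciesThermo("PYL2", 43.0, 400.0, dcp=4.0)

#: species resolvable by the (cached) calibration machinery
_SPECIES_REGISTRY: Dict[str, SpeciesThermo] = {
    "SnRK2.2": SNRK22,
    "SnRK2.3": SNRK23,
    "SnRK2.6": SNRK26,
    "PYL1": PYL1,
    "PYL2": PYL2_BASE,
}

STAURO_TITRATION = (0.0, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0)
ABA_TITRATION = (0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)
PP2C_TITRATION = (1.0, 5.0, 10.0, 20.0)
NACL_DESTAB = -1.6  # °C, uniform nonspecific destabilization at 500 mM NaCl


@dataclass
class Fixture:
    fixture_id: str
    seed: int
    curves: List[MeltCurve]
    manifest: dict


def _cond_seed(seed: int, index: int) -> int:
    return (seed + 1000 * index) % MAX_SEED


def _species_dict(th: SpeciesThermo) -> dict:
    return asdict(th)


def _coupling_dict(c: LigandCoupling) -> dict:
    return asdict(c)


class _Builder:
    """Accumulates conditions, assigns wells/seeds deterministically."""

    def __init__(self, seed: int, grid, noise: float = NOISE):
        self.seed = seed % MAX_SEED
        self.grid = grid
        self.noise = noise
        self.curves: List[MeltCurve] = []
        self.conditions: List[dict] = []
        self._idx = 0
        self._well = 0

    def add(
        self,
        sample_id: str,
        species: List[Tuple[SpeciesThermo, float]],
        couplings: Optional[List[Tuple[LigandCoupling, float]]] = None,
        complex_spec=None,
        condition: Optional[ConditionMeta] = None,
        n_replicates: int = 3,
        noise: Optional[float] = None,
    ) -> SimScenario:
        wells = []
        for _ in range(n_replicates):
            self._well += 1
            wells.append(f"W{self._well:04d}")
        scenario = SimScenario(
            species_list=species,
            couplings=couplings or [],
            complex_spec=complex_spec,
            grid=self.grid,
            noise_frac=self.noise if noise is None else noise,
            n_replicates=n_replicates,
            seed=_cond_seed(self.seed, self._idx),
            condition=condition,
            sample_id=sample_id,
            wells=wells,
        )
        self.curves.extend(simulate_curve(scenario))
        self.conditions.append(
            {
                "sample_id": sample_id,
                "wells": wells,
                "seed": scenario.seed,
                "n_replicates": n_replicates,
            }
        )
        self._idx += 1
        return scenario


def _kinase_condition(kinase: str, ligand: Optional[str] = None, conc: float = 0.0,
                      protein_conc: float = 5.0) -> ConditionMeta:
    return ConditionMeta(
        proteins=((kinase, protein_conc),),
        ligands=((ligand, conc),) if ligand and conc > 0 else (),
    )


# ---------------------------------------------------------------------------
# snrk_panel


def build_snrk_panel(seed: int) -> Fixture:
    b = _Builder(seed, GRID_SCREEN)
    for th in (SNRK22, SNRK23, SNRK26):
        b.add(f"{th.name}_apo", [(th, 5.0)], condition=_kinase_condition(th.name))
    manifest = {
        "fixture_id": "snrk_panel",
        "seed": seed,
        "species": {th.name: _species_dict(th) for th in (SNRK22, SNRK23, SNRK26)},
        "true_tm": {"SnRK2.2": 36.2, "SnRK2.3": 38.3, "SnRK2.6": 49.0},
        "conditions": b.conditions,
    }
    return Fixture("snrk_panel", seed, b.curves, manifest)


# ---------------------------------------------------------------------------
# snrk_staurosporine


def _stauro_couplings() -> Dict[str, LigandCoupling]:
    # anchors: the printed 50 µM shift, plus the 1 µM dose pinned below the
    # detection threshold so 2.5 µM is the first detectable titration point
    return {
        "SnRK2.3": _calibrate(
            "SnRK2.3", 5.0, ((50.0, 9.5), (1.0, DETECT_SUB)), "staurosporine", GRID_SCREEN
        ),
        "SnRK2.6": _calibrate(
            "SnRK2.6", 5.0, ((50.0, 6.7), (1.0, DETECT_SUB)), "staurosporine", GRID_SCREEN
        ),
    }


def build_snrk_staurosporine(seed: int) -> Fixture:
    couplings = _stauro_couplings()
    b = _Builder(seed, GRID_SCREEN)
    true_shifts: Dict[str, Dict[str, float]] = {}
    for th in (SNRK23, SNRK26):
        coup = couplings[th.name]
        shifts = {}
        for conc in STAURO_TITRATION:
            label = f"{th.name}_stauro_{conc:g}"
            cpl = [(coup, conc)] if conc > 0 else []
            b.add(
                label,
                [(th, 5.0)],
                couplings=cpl,
                condition=_kinase_condition(th.name, "staurosporine", conc),
            )
            shifts[f"{conc:g}"] = predicted_tm_shift(th, coup, 5.0, conc)
        true_shifts[th.name] = shifts
    manifest = {
        "fixture_id": "snrk_staurosporine",
        "seed": seed,
        "species": {th.name: _species_dict(th) for th in (SNRK23, SNRK26)},
        "couplings": {k: _coupling_dict(v) for k, v in couplings.items()},
        "titration_uM": list(STAURO_TITRATION),
        "true_shifts": true_shifts,
        "calibration": {
            "SnRK2.3": {"anchors_uM_degC": [[50.0, 9.5], [1.0, DETECT_SUB]]},
            "SnRK2.6": {"anchors_uM_degC": [[50.0, 6.7], [1.0, DETECT_SUB]]},
        },
        "conditions": b.conditions,
    }
    return Fixture("snrk_staurosporine", seed, b.curves, manifest)


# ---------------------------------------------------------------------------
# screen_300

SCREEN_HITS = {
    # per-kinase true shifts (°C) for the three pan-kinase stabilizers
    "staurosporine": {"SnRK2.2": 9.5, "SnRK2.3": 9.6, "SnRK2.6": 6.7},
    "K-252a": {"SnRK2.2": 5.2, "SnRK2.3": 4.8, "SnRK2.6": 4.1},
    "wee1_inhibitor": {"SnRK2.2": 4.0, "SnRK2.3": 4.2, "SnRK2.6": 3.5},
}
N_SCREEN = 300
N_SINGLE_KINASE = 5


def screen_true_shifts(seed: int) -> Dict[str, Dict[str, float]]:
    """Ground-truth ΔTm table for the 300-compound screen.

    297 library compounds draw shifts from N(0, 0.3 °C) clipped to ±2 °C;
    five of them additionally stabilize exactly one kinase by 3.5-6 °C.
    The three pan-kinase stabilizers carry their printed shifts.
    """
    rng = np.random.default_rng(seed % MAX_SEED)
    kinases = ["SnRK2.2", "SnRK2.3", "SnRK2.6"]
    shifts: Dict[str, Dict[str, float]] = {}
    n_library = N_SCREEN - len(SCREEN_HITS)
    single_idx = set(rng.choice(n_library, size=N_SINGLE_KINASE, replace=False).tolist())
    for i in range(n_library):
        cid = f"cmpd_{i + 1:03d}"
        row = {k: float(np.clip(rng.normal(0.0, 0.3), -2.0, 2.0)) for k in kinases}
        if i in single_idx:
            row[kinases[int(rng.integers(3))]] = float(rng.uniform(3.5, 6.0))
        shifts[cid] = row
    for cid, row in SCREEN_HITS.items():
        shifts[cid] = dict(row)
    return shifts


def build_screen_300(seed: int) -> Fixture:
    kin = {t.name: t for t in (SNRK22, SNRK23, SNRK26)}
    shifts = screen_true_shifts(seed)
    b = _Builder(seed, GRID_SCREEN)
    for name, th in kin.items():
        b.add(f"{name}_apo", [(th, 5.0)], condition=_kinase_condition(name))
    for cid, row in shifts.items():
        for name, th in kin.items():
            b.add(
                f"{name}__{cid}",
                [(th.shifted(row[name]), 5.0)],
                condition=_kinase_condition(name, cid, 50.0),
                n_replicates=1,  # the library screen is unreplicated
            )
    single_kinase = sorted(
        cid
        for cid, row in shifts.items()
        if cid not in SCREEN_HITS and max(row.values()) >= 3.0
    )
    manifest = {
        "fixture_id": "screen_300",
        "seed": seed,
        "species": {n: _species_dict(t) for n, t in kin.items()},
        "true_shifts": shifts,
        "pan_kinase_hits": sorted(SCREEN_HITS),
        "single_kinase_stabilizers": single_kinase,
        "screen_concentration_uM": 50.0,
        "conditions": b.conditions,
    }
    return Fixture("screen_300", seed, b.curves, manifest)


# ---------------------------------------------------------------------------
# pyl_aba


def _pyl_couplings() -> Dict[str, LigandCoupling]:
    """ABA/pyrabactin couplings reproducing the printed detection doses.

    PYL1: detectable first at 50 µM → the 25 and 50 µM shifts straddle
    the 0.5 °C detection threshold symmetrically.  PYL2: detectable at
    25 µM → the 10/25 µM shifts straddle it.  Pyrabactin binds PYL2 more
    weakly than ABA (4× the Kd), giving the lower 500 µM Tm the melt
    curves show.
    """
    aba_pyl1 = _calibrate(
        "PYL1", 10.0, ((25.0, 0.345), (50.0, 0.66)), "(+)-ABA", GRID_STANDARD
    )
    # PYL2 keeps a temperature-independent Kd: its apo-baseline story needs
    # weak binding at the low end of the ramp, which a large |ΔHb| would break
    aba_pyl2 = _calibrate("PYL2", 10.0, ((25.0, 0.69),), "(+)-ABA", GRID_STANDARD)
    pyr_pyl2 = LigandCoupling("pyrabactin", "PYL2", 4.0 * aba_pyl2.kd, aba_pyl2.dhb)
    return {"PYL1": aba_pyl1, "PYL2": aba_pyl2, "PYL2:pyrabactin": pyr_pyl2}


@lru_cache(maxsize=None)
def _pyl2_species() -> SpeciesThermo:
    """PYL2 with its apo native baseline calibrated for the flag boundary.

    The apo form's anomalously high initial fluorescence must persist at
    10 µM ABA and clear at 25 µM, so the elevated apo baseline is placed
    where the high-initial-fluorescence criterion (F(T0) > 0.5 F_max)
    flips exactly midway between those two doses.
    """
    aba = _pyl_couplings()["PYL2"]

    def margin(a: float, l_total: float) -> float:
        th = SpeciesThermo("PYL2", 43.0, 400.0, dcp=4.0, apo_native_intercept=a)
        sc = SimScenario(
            [(th, 10.0)],
            couplings=[(aba, l_total)] if l_total > 0 else [],
            grid=GRID_STANDARD,
            noise_frac=0.0,
            n_replicates=1,
        )
        f = noiseless_trace(sc)
        return float(f[0] - 0.5 * f.max())

    a_star = brentq(lambda a: margin(a, 10.0) + margin(a, 25.0), 0.3, 0.95, xtol=1e-10)
    return SpeciesThermo("PYL2", 43.0, 400.0, dcp=4.0, apo_native_intercept=a_star)


def build_pyl_aba(seed: int) -> Fixture:
    couplings = _pyl_couplings()
    pyl2 = _pyl2_species()
    b = _Builder(seed, GRID_STANDARD)
    true_shifts: Dict[str, Dict[str, float]] = {}
    for th, coup in ((PYL1, couplings["PYL1"]), (pyl2, couplings["PYL2"])):
        shifts = {}
        for conc in ABA_TITRATION:
            cpl = [(coup, conc)] if conc > 0 else []
            b.add(
                f"{th.name}_ABA_{conc:g}",
                [(th, 10.0)],
                couplings=cpl,
                condition=ConditionMeta(
                    proteins=((th.name, 10.0),),
                    ligands=(((coup.ligand, conc),) if conc > 0 else ()),
                ),
            )
            shifts[f"{conc:g}"] = predicted_tm_shift(th, coup, 10.0, conc)
        true_shifts[th.name] = shifts
    pyr = couplings["PYL2:pyrabactin"]
    b.add(
        "PYL2_pyrabactin_500",
        [(pyl2, 10.0)],
        couplings=[(pyr, 500.0)],
        condition=ConditionMeta(proteins=(("PYL2", 10.0),), ligands=(("pyrabactin", 500.0),)),
    )
    manifest = {
        "fixture_id": "pyl_aba",
        "seed": seed,
        "species": {"PYL1": _species_dict(PYL1), "PYL2": _species_dict(pyl2)},
        "couplings": {k: _coupling_dict(v) for k, v in couplings.items()},
        "titration_uM": list(ABA_TITRATION),
        "true_shifts": true_shifts,
        "true_pyrabactin_shift_500": predicted_tm_shift(pyl2, pyr, 10.0, 500.0),
        "detection_targets_uM": {"PYL1": 50.0, "PYL2": 25.0},
        "conditions": b.conditions,
    }
    return Fixture("pyl_aba", seed, b.curves, manifest)


# ---------------------------------------------------------------------------
# complex_titration


def _complex_species(holo_tm: float, pp2c: SpeciesThermo) -> SpeciesThermo:
    """Cooperative 1:1 pseudo-species.

    Native baseline sums over the two folded partners; the unfolded signal
    exceeds the component sum by 30% because cooperative unfolding also
    exposes the buried protein-protein interface to the dye.
    """
    return SpeciesThermo(
        name=f"PYL1:{pp2c.name}",
        tm_c=max(holo_tm, pp2c.tm_c) + 5.0,
        dhm=PYL1.dhm + pp2c.dhm,
        dcp=PYL1.dcp + pp2c.dcp,
        native_intercept=2 * 0.08,
        native_slope=2 * 0.0002,
        unfolded_intercept=2.6,
        unfolded_slope=-0.0005,
    )


def build_complex_titration(seed: int) -> Fixture:
    # saturating ABA: a temperature-independent coupling matched to the same
    # 500 µM shift keeps the holo-receptor reference a clean two-state
    # sigmoid (the receptor's excess-ligand regime hides any ΔHb shape)
    aba = _calibrate("PYL1", 10.0, ((500.0, 3.6),), "(+)-ABA", GRID_STANDARD)
    holo_tm = PYL1.tm_c + predicted_tm_shift(PYL1, aba, 10.0, 500.0)
    b = _Builder(seed, GRID_STANDARD)
    complexes = {}
    for pp2c in (HAB1, ABI2):
        cplx = _complex_species(holo_tm, pp2c)
        complexes[pp2c.name] = cplx
        for conc in PP2C_TITRATION:
            b.add(
                f"PYL1_{pp2c.name}_{conc:g}",
                [(PYL1, 10.0), (pp2c, conc)],
                couplings=[(aba, 500.0)],
                complex_spec=("PYL1", pp2c.name, cplx),
                condition=ConditionMeta(
                    proteins=(("PYL1", 10.0), (pp2c.name, conc)),
                    ligands=(("(+)-ABA", 500.0),),
                ),
            )
    b.add(
        "PYL1_ABA_ref",
        [(PYL1, 10.0)],
        couplings=[(aba, 500.0)],
        condition=ConditionMeta(proteins=(("PYL1", 10.0),), ligands=(("(+)-ABA", 500.0),)),
    )
    for pp2c in (HAB1, ABI2):
        b.add(
            f"{pp2c.name}_ref",
            [(pp2c, 10.0)],
            condition=ConditionMeta(proteins=((pp2c.name, 10.0),)),
        )
    manifest = {
        "fixture_id": "complex_titration",
        "seed": seed,
        "species": {
            "PYL1": _species_dict(PYL1),
            "HAB1": _species_dict(HAB1),
            "ABI2": _species_dict(ABI2),
            **{f"PYL1:{n}": _species_dict(c) for n, c in complexes.items()},
        },
        "coupling": _coupling_dict(aba),
        "holo_receptor_tm": holo_tm,
        "titration_uM": list(PP2C_TITRATION),
        "receptor_uM": 10.0,
        "true_stoichiometry": 1.0,
        "conditions": b.conditions,
    }
    return Fixture("complex_titration", seed, b.curves, manifest)


# ---------------------------------------------------------------------------
# fusion_control


def _fusion_couplings() -> Dict[str, LigandCoupling]:
    return {
        "wee1_inhibitor": _calibrate(
            "SnRK2.3", 5.0, ((50.0, 4.0),), "wee1_inhibitor", GRID_STANDARD
        ),
        "staurosporine": _stauro_couplings()["SnRK2.3"],
    }


def build_fusion_control(seed: int) -> Fixture:
    couplings = _fusion_couplings()
    b = _Builder(seed, GRID_STANDARD)
    species_sets = {
        "SnRK2.3": [(SNRK23, 5.0)],
        "MBP": [(MBP, 5.0)],
        "MBP-SnRK2.3": [(SNRK23, 5.0), (MBP, 5.0)],
    }
    treatments = ["apo", "wee1_inhibitor", "staurosporine", "NaCl"]
    for set_name, species in species_sets.items():
        fusion = set_name == "MBP-SnRK2.3"
        for treatment in treatments:
            if treatment == "NaCl":
                sp = [(th.shifted(NACL_DESTAB), c) for th, c in species]
                cpl, ligands, additives = [], (), (("NaCl", 500.0),)
            elif treatment == "apo":
                sp, cpl, ligands, additives = species, [], (), ()
            else:
                coup = couplings[treatment]
                sp = species
                cpl = [(coup, 50.0)]
                ligands, additives = ((treatment, 50.0),), ()
            b.add(
                f"{set_name}_{treatment}",
                sp,
                couplings=cpl,
                condition=ConditionMeta(
                    proteins=tuple((th.name, c) for th, c in species),
                    ligands=ligands,
                    additives=additives,
                    tag_fusion=("MBP", "SnRK2.3") if fusion else None,
                ),
            )
    manifest = {
        "fixture_id": "fusion_control",
        "seed": seed,
        "species": {"SnRK2.3": _species_dict(SNRK23), "MBP": _species_dict(MBP)},
        "couplings": {k: _coupling_dict(v) for k, v in couplings.items()},
        "true_shifts": {
            "wee1_inhibitor": predicted_tm_shift(SNRK23, couplings["wee1_inhibitor"], 5.0, 50.0),
            "staurosporine": predicted_tm_shift(SNRK23, couplings["staurosporine"], 5.0, 50.0),
            "NaCl": NACL_DESTAB,
        },
        "conditions": b.conditions,
    }
    return Fixture("fusion_control", seed, b.curves, manifest)


# ---------------------------------------------------------------------------
# abi2_concentration

ABI2_CONCS = (2.5, 5.0, 10.0, 20.0)


def build_abi2_concentration(seed: int) -> Fixture:
    b = _Builder(seed, GRID_STANDARD)
    for conc in ABI2_CONCS:
        b.add(
            f"ABI2_{conc:g}uM",
            [(ABI2, conc)],
            condition=ConditionMeta(proteins=(("ABI2", conc),)),
        )
    manifest = {
        "fixture_id": "abi2_concentration",
        "seed": seed,
        "species": {"ABI2": _species_dict(ABI2)},
        "concentrations_uM": list(ABI2_CONCS),
        "conditions": b.conditions,
    }
    return Fixture("abi2_concentration", seed, b.curves, manifest)


# ---------------------------------------------------------------------------

FIXTURES: Dict[str, Callable[[int], Fixture]] = {
    "snrk_panel": build_snrk_panel,
    "snrk_staurosporine": build_snrk_staurosporine,
    "screen_300": build_screen_300,
    "pyl_aba": build_pyl_aba,
    "complex_titration": build_complex_titration,
    "fusion_control": build_fusion_control,
    "abi2_concentration": build_abi2_concentration,
}


def generate_fixture(fixture_id: str, seed: int) -> Fixture:
    """Build a registered fixture; identical (id, seed) → identical bits."""
    try:
        builder = FIXTURES[fixture_id]
    except KeyError:
        raise KeyError(
            f"unknown fixture {fixture_id!r}; known: {sorted(FIXTURES)}"
        ) from None
    return builder(int(seed))
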