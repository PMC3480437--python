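"""Ligand-induced complex detection and stoichiometry from titrations.

A cooperative 1:1 protein-protein complex melts as a single transition
whose Tm exceeds both components' reference Tms; mixing the partners off
the stoichiometric ratio leaves the excess partner free, producing a
biphasic profile whose secondary transition matches the excess component's
reference Tm.  Scanning the titrant:fixed molar ratio and classifying each
profile as monophasic or biphasic therefore reads the binding
stoichiometry directly off the melt curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .fitting import BIPHASIC, MeltFitResult, TWO_STATE

MONOPHASIC = "monophasic"


class InteractionInputError(ValueError):
    """Reference or mixture fits unusable for complex analysis."""


def _mean_tm(fits: Sequence[MeltFitResult], which: int = 0) -> float:
    return float(np.mean([f.transitions[which].tm for f in fits]))


def detect_complex(
    fit_a: MeltFitResult,
    fit_b: MeltFitResult,
    fit_mix: MeltFitResult,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Tuple[bool, Optional[float]]:
    """Is an equimolar mixture a cooperative complex?

    Detected iff the mixture melts as a single transition with a Tm above
    both component references by the cooperativity margin (+1 °C default).
    Returns (detected, mixture Tm).
    """
    for f, label in ((fit_a, "component A"), (fit_b, "component B")):
        if f.classification != TWO_STATE:
            raise InteractionInputError(
                f"{label} reference fit {f.sample_id} is {f.classification}, need two_state"
            )
    if fit_mix.n_transitions != 1 or fit_mix.classification != TWO_STATE:
        return False, None
    tm_mix = fit_mix.tm
    detected = tm_mix > max(fit_a.tm, fit_b.tm) + config.coop_margin
    return detected, tm_mix


@dataclass
class StoichiometryResult:
    component_a: str                       # fixed component
    component_b: str                       # titrant
    ratios_tested: List[float]             # titrant:fixed molar ratios
    phase_calls: Dict[float, str]
    stoichiometry: Optional[float]
    complex_tm: Optional[float]
    cooperative: bool
    flags: set = field(default_factory=set)
    secondary_tms: Dict[float, Optional[float]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Titration of {self.component_b} (titrant) against {self.component_a} (fixed)",
            f"  phase calls: "
            + ", ".join(f"{r:g}: {c}" for r, c in sorted(self.phase_calls.items())),
            f"  stoichiometry (titrant:fixed): {self.stoichiometry}",
            f"  complex Tm: {self.complex_tm}",
            f"  cooperative: {self.cooperative}",
        ]
        if self.flags:
            lines.append(f"  flags: {sorted(self.flags)}")
        return "\n".join(lines)


def _majority_phase(fits: Sequence[MeltFitResult]) -> str:
    n_bi = sum(1 for f in fits if f.n_transitions == 2 and f.classification == BIPHASIC)
    return BIPHASIC if n_bi > len(fits) / 2 else MONOPHASIC


def analyze_titration(
    series: Dict[float, Sequence[MeltFitResult]],
    ref_a: Tuple[str, Sequence[MeltFitResult]],
    ref_b: Tuple[str, Sequence[MeltFitResult]],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> StoichiometryResult:
    """Infer binding stoichiometry from a titration of melt-curve fits.

    ``series`` maps titrant:fixed molar ratio → replicate fits of the
    mixture; ``ref_a``/``ref_b`` are (name, replicate fits) for the fixed
    component and the titrant measured alone.  The stoichiometry is the
    tested ratio whose profile is monophasic while at least one smaller
    and one larger tested ratio are biphasic; biphasic secondary
    transitions are assigned to the excess component by nearest reference
    Tm (within the acceptance window, else flagged unassigned).
    """
    if len(series) < 3:
        raise ValueError("titration needs >= 3 ratios")
    ratios = sorted(series)
    if not (min(ratios) < 1.0 < max(ratios) or 1.0 in ratios):
        raise ValueError("titration must span ratios below and above 1")
    name_a, fits_a = ref_a
    name_b, fits_b = ref_b
    tm_a, tm_b = _mean_tm(fits_a), _mean_tm(fits_b)
    flags: set = set()
    phase_calls: Dict[float, str] = {}
    secondary: Dict[float, Optional[float]] = {}
    complex_tms: List[float] = []
    for r in ratios:
        fits = series[r]
        phase = _majority_phase(fits)
        if phase == MONOPHASIC:
            phase_calls[r] = MONOPHASIC
            complex_tms.append(
                float(np.mean([f.tm for f in fits if f.n_transitions == 1]))
            )
            continue
        bi = [f for f in fits if f.n_transitions == 2]
        # the complex is the most stable species: highest transition;
        # the secondary (lower) transition belongs to the excess partner
        sec_tm = float(np.mean([f.transitions[0].tm for f in bi]))
        complex_tms.append(float(np.mean([f.transitions[1].tm for f in bi])))
        secondary[r] = sec_tm
        d_a, d_b = abs(sec_tm - tm_a), abs(sec_tm - tm_b)
        if min(d_a, d_b) > config.assign_window:
            phase_calls[r] = "biphasic_unassigned"
            flags.add("unassigned_secondary_transition")
        elif d_a <= d_b:
            phase_calls[r] = f"biphasic_excess_{name_a}"
        else:
            phase_calls[r] = f"biphasic_excess_{name_b}"

    stoich = None
    for i, r in enumerate(ratios):
        if phase_calls[r] != MONOPHASIC:
            continue
        smaller_bi = any(phase_calls[q].startswith("biphasic") for q in ratios[:i])
        larger_bi = any(phase_calls[q].startswith("biphasic") for q in ratios[i + 1:])
        if smaller_bi and larger_bi:
            stoich = r
            break
    if stoich is None:
        if all(c == MONOPHASIC for c in phase_calls.values()):
            flags.add("all_monophasic_indistinguishable_components")
        else:
            flags.add("no_monophasic_ratio")
    complex_tm = float(np.mean(complex_tms)) if complex_tms else None
    cooperative = (
        complex_tm is not None and complex_tm > max(tm_a, tm_b) + config.coop_margin
    )
    return StoichiometryResult(
        component_a=name_a,
        component_b=name_b,
        ratios_tested=ratios,
        phase_calls=phase_calls,
        stoichiometry=stoich,
        complex_tm=complex_tm,
        cooperative=cooperative,
        flags=flags,
        secondary_tms=secondary,
    )


@dataclass
class ConcentrationIndependenceReport:
    passed: bool
    tm_by_conc: Dict[float, float]
    amplitude_by_conc: Dict[float, float]
    tm_sd: float
    tm_pass: bool
    amplitude_pass: bool

    def summary(self) -> str:
        rows = ", ".join(
            f"{c:g} µM: Tm {t:.2f} °C / amp {self.amplitude_by_conc[c]:.3g}"
            for c, t in sorted(self.tm_by_conc.items())
        )
        return (
            f"Concentration independence: {'PASS' if self.passed else 'FAIL'}\n"
            f"  sd(Tm) = {self.tm_sd:.3f} °C (Tm {'ok' if self.tm_pass else 'VARIES'}; "
            f"amplitude {'increases' if self.amplitude_pass else 'NOT increasing'})\n"
            f"  {rows}"
        )


def check_concentration_independence(
    series: Dict[float, Sequence[MeltFitResult]],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> ConcentrationIndependenceReport:
    """Tm must be invariant while amplitude grows with concentration.

    The melting midpoint of a (non-self-associating) species is an
    intensive property: fluorescence scales with how much protein is in
    the well, the Tm does not.  Requires >= 3 concentrations.
    """
    if len(series) < 3:
        raise ValueError("need >= 3 concentrations")
    tm_by_conc = {float(c): _mean_tm(fits) for c, fits in series.items()}
    amp_by_conc = {
        float(c): float(np.mean([f.amplitude for f in fits]))
        for c, fits in series.items()
    }
    concs = sorted(tm_by_conc)
    tm_sd = float(np.std([tm_by_conc[c] for c in concs], ddof=1))
    tm_ok = tm_sd <= config.tm_spread_tol
    amps = [amp_by_conc[c] for c in concs]
    amp_ok = all(b > a for a, b in zip(amps, amps[1:]))
    return ConcentrationIndependenceReport(
        passed=tm_ok and amp_ok,
        tm_by_conc=tm_by_conc,
        amplitude_by_conc=amp_by_conc,
        tm_sd=tm_sd,
        tm_pass=tm_ok,
        amplitude_pass=amp_ok,
    )
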