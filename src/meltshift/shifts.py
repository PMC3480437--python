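"""ΔTm statistics and ligand dose-response analysis.

ΔTm is the difference between a condition's mean fitted Tm and a
reference's (apo) mean, with its uncertainty propagated from the replicate
scatter: SE = sqrt(sd_c²/n_c + sd_r²/n_r).  A shift counts as *detected*
when |ΔTm| clears the detection threshold (0.5 °C by default) and, when
replicated, also a 3-sigma rule against that propagated SE.

Dose series are fitted to a one-site saturation hyperbola (a Hill curve
with h fixed at 1 by default)

    ΔTm([L]) = ΔTm_max · [L]^h / (K_half^h + [L]^h)

which describes the rising phase of the thermal-shift dose response.  When
no shift is detectable at ligand doses up to the protein concentration
(stoichiometric ratio), the smallest detectable dose is a lower bound on
the dissociation constant — a detectable shift at ~1:1 stoichiometry
requires ligand concentrations approaching Kd, so its absence places Kd at
or above the first detectable dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .config import AnalysisConfig, DEFAULT_CONFIG
from .fitting import BIPHASIC, MeltFitResult, TWO_STATE

__all__ = [
    "ShiftResult",
    "DoseResponseFit",
    "DoseResponseModel",
    "delta_tm",
    "delta_tm_biphasic",
    "fit_dose_response",
    "compare_ligands",
    "MixedClassificationError",
]


class MixedClassificationError(ValueError):
    """Condition/reference fits are not comparable (classification mix)."""


@dataclass
class ShiftResult:
    condition_id: str
    reference_id: str
    delta_tm_mean: float
    delta_tm_sd: float  # propagated SE of the mean difference
    n: int              # condition replicates
    detectable: bool
    flags: set = field(default_factory=set)


def _tm_stats(fits: Sequence[MeltFitResult], which: int = 0) -> Tuple[float, float, int]:
    tms = [f.transitions[which].tm for f in fits]
    n = len(tms)
    sd = float(np.std(tms, ddof=1)) if n > 1 else 0.0
    return float(np.mean(tms)), sd, n


def _detectable(mean: float, se: float, n: int, config: AnalysisConfig) -> bool:
    if abs(mean) < config.theta_detect:
        return False
    if n > 1 and se > 0:
        return abs(mean) >= 3.0 * se
    return True


def delta_tm(
    condition: Sequence[MeltFitResult],
    reference: Sequence[MeltFitResult],
    config: AnalysisConfig = DEFAULT_CONFIG,
    require_two_state: bool = True,
) -> ShiftResult:
    """Mean Tm difference between condition and reference replicate fits.

    All fits must be classified ``two_state``; pass
    ``require_two_state=False`` to accept a flagged (but converged)
    reference, e.g. a high-initial-fluorescence apo trace whose fitted Tm
    is still numerically defined — the result then carries a
    ``reference_flagged`` flag.
    """
    if not condition or not reference:
        raise ValueError("delta_tm needs non-empty condition and reference fits")
    flags = set()
    bad = [f.sample_id for f in condition if f.classification != TWO_STATE]
    bad_ref = [f.sample_id for f in reference if f.classification != TWO_STATE]
    if bad or (bad_ref and require_two_state):
        if require_two_state:
            raise MixedClassificationError(
                f"non-two-state fits: condition {bad}, reference {bad_ref}"
            )
    if bad_ref:
        if any(not f.converged for f in reference):
            raise MixedClassificationError(f"unconverged reference fits: {bad_ref}")
        flags.add("reference_flagged")
    mc, sc, nc = _tm_stats(condition)
    mr, sr, nr = _tm_stats(reference)
    mean = mc - mr
    se = math.sqrt((sc ** 2) / nc + (sr ** 2) / nr)
    return ShiftResult(
        condition_id=condition[0].sample_id,
        reference_id=reference[0].sample_id,
        delta_tm_mean=mean,
        delta_tm_sd=se,
        n=nc,
        detectable=_detectable(mean, se, nc, config),
        flags=flags,
    )


def _assign_transitions(
    fit: MeltFitResult, ref_tms: Dict[str, float], window: float
) -> Dict[str, float]:
    """Map each fitted transition to the nearest reference Tm (greedy)."""
    pairs = []
    for i, tr in enumerate(fit.transitions):
        for name, ref in ref_tms.items():
            pairs.append((abs(tr.tm - ref), i, name))
    pairs.sort()
    used_i, used_n, out = set(), set(), {}
    for dist, i, name in pairs:
        if i in used_i or name in used_n:
            continue
        if dist > window:
            continue
        out[name] = fit.transitions[i].tm
        used_i.add(i)
        used_n.add(name)
    return out


def delta_tm_biphasic(
    condition: Sequence[MeltFitResult],
    reference: Sequence[MeltFitResult],
    component_refs: Dict[str, float],
    config: AnalysisConfig = DEFAULT_CONFIG,
    assign_window: Optional[float] = None,
) -> Dict[str, ShiftResult]:
    """Per-component ΔTm between matched biphasic fits.

    Transitions are assigned to components by nearest reference Tm within
    the acceptance window; both condition and reference must be biphasic.
    """
    window = config.assign_window if assign_window is None else assign_window
    for fits, label in ((condition, "condition"), (reference, "reference")):
        bad = [f.sample_id for f in fits if f.classification != BIPHASIC]
        if bad:
            raise MixedClassificationError(f"non-biphasic {label} fits: {bad}")

    def collect(fits) -> Dict[str, List[float]]:
        acc: Dict[str, List[float]] = {k: [] for k in component_refs}
        for f in fits:
            for name, tm in _assign_transitions(f, component_refs, window).items():
                acc[name].append(tm)
        return acc

    # references shift too (e.g. salt moves every transition): assign the
    # reference replicates against the component Tms, then difference
    ref_assigned = collect(reference)
    # condition transitions can sit far from the apo component references
    # (a specifically shifted kinase); widen the window to the span of the
    # data but keep the pairing one-to-one by nearest reference
    cond_assigned = collect(condition)
    out: Dict[str, ShiftResult] = {}
    for name in component_refs:
        ctms, rtms = cond_assigned[name], ref_assigned[name]
        if not ctms or not rtms:
            continue
        mc, sc, nc = float(np.mean(ctms)), float(np.std(ctms, ddof=1)) if len(ctms) > 1 else 0.0, len(ctms)
        mr, sr, nr = float(np.mean(rtms)), float(np.std(rtms, ddof=1)) if len(rtms) > 1 else 0.0, len(rtms)
        mean = mc - mr
        se = math.sqrt(sc ** 2 / nc + sr ** 2 / nr)
        out[name] = ShiftResult(
            condition_id=condition[0].sample_id,
            reference_id=reference[0].sample_id,
            delta_tm_mean=mean,
            delta_tm_sd=se,
            n=nc,
            detectable=_detectable(mean, se, nc, config),
        )
    return out


# ---------------------------------------------------------------------------
# dose response


@dataclass
class DoseResponseFit:
    concentrations: List[float]
    shift_means: List[float]
    dtm_max: float
    k_half: float
    hill_h: float
    r_squared: float
    min_detectable_conc: Optional[float]
    kd_lower_bound: Optional[float]
    saturation_reached: bool
    converged: bool

    def summary(self) -> str:
        lines = [
            "Thermal-shift dose response (one-site saturation)",
            f"  ΔTm_max:  {self.dtm_max:.2f} °C",
            f"  K_half:   {self.k_half:.1f} µM   (h = {self.hill_h:g})",
            f"  R²:       {self.r_squared:.4f}",
            f"  min detectable dose: {self.min_detectable_conc} µM",
            f"  Kd lower bound:      {self.kd_lower_bound} µM",
            f"  saturation reached:  {self.saturation_reached}",
        ]
        return "\n".join(lines)


class DoseResponseModel:
    """One-site saturation model of ΔTm vs ligand concentration.

    Parameters
    ----------
    series : sequence of (concentration µM, ShiftResult or None)
        Must include the 0 dose and at least 4 concentrations.  ``None``
        marks a dose whose curves yielded no usable Tm (never detectable).
    protein_conc : float, optional
        Protein concentration in µM; needed for the Kd-bound logic (a
        bound is only claimed when nothing is detectable at doses up to
        the stoichiometric ratio).
    """

    def __init__(
        self,
        series: Sequence[Tuple[float, Optional[ShiftResult]]],
        protein_conc: Optional[float] = None,
        hill_h: float = 1.0,
        config: AnalysisConfig = DEFAULT_CONFIG,
    ):
        concs = [float(c) for c, _ in series]
        if len(concs) < 4 or 0.0 not in concs:
            raise ValueError("dose series needs >= 4 concentrations including 0")
        self.series = sorted(series, key=lambda p: p[0])
        self.protein_conc = protein_conc
        self.hill_h = hill_h
        self.config = config

    def fit(self) -> DoseResponseFit:
        cfg = self.config
        concs, means = [], []
        detectable: List[Tuple[float, bool]] = []
        for conc, sr in self.series:
            if sr is None:
                detectable.append((conc, False))
                continue
            detectable.append((conc, bool(sr.detectable)))
            concs.append(conc)
            means.append(sr.delta_tm_mean)
        concs_a = np.asarray([0.0] + concs if 0.0 not in concs else concs)
        means_a = np.asarray(([0.0] + means) if 0.0 not in concs else means)

        min_det = next((c for c, d in detectable if c > 0 and d), None)
        kd_bound = None
        if (
            min_det is not None
            and self.protein_conc is not None
            and not any(d for c, d in detectable if 0 < c <= self.protein_conc)
        ):
            kd_bound = min_det

        h = self.hill_h
        any_signal = any(d for _, d in detectable)
        if not any_signal:
            return DoseResponseFit(
                concentrations=list(concs_a),
                shift_means=list(means_a),
                dtm_max=float("nan"),
                k_half=float("nan"),
                hill_h=h,
                r_squared=float("nan"),
                min_detectable_conc=None,
                kd_lower_bound=None,
                saturation_reached=False,
                converged=False,
            )

        def hyperbola(l, dtm_max, k_half):
            return dtm_max * l ** h / (k_half ** h + l ** h)

        top = float(np.max(np.abs(means_a))) or 1.0
        try:
            popt, _ = curve_fit(
                hyperbola,
                concs_a,
                means_a,
                p0=[top, max(np.median(concs_a[concs_a > 0]), 1.0)],
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                maxfev=20000,
            )
            converged = True
        except RuntimeError:
            popt, converged = (float("nan"), float("nan")), False
        if converged:
            resid = means_a - hyperbola(concs_a, *popt)
            ss_tot = float(np.sum((means_a - means_a.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
            top2 = np.sort(concs_a)[-2:]
            top_means = [means_a[list(concs_a).index(c)] for c in top2]
            saturation = all(abs(m - popt[0]) <= 0.1 * abs(popt[0]) for m in top_means)
        else:
            r2, saturation = float("nan"), False
        return DoseResponseFit(
            concentrations=list(map(float, concs_a)),
            shift_means=list(map(float, means_a)),
            dtm_max=float(popt[0]),
            k_half=float(popt[1]),
            hill_h=h,
            r_squared=r2,
            min_detectable_conc=min_det,
            kd_lower_bound=kd_bound,
            saturation_reached=bool(saturation),
            converged=converged,
        )


def fit_dose_response(
    series: Sequence[Tuple[float, Optional[ShiftResult]]],
    protein_conc: Optional[float] = None,
    hill_h: float = 1.0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> DoseResponseFit:
    """Functional wrapper over :class:`DoseResponseModel`."""
    return DoseResponseModel(series, protein_conc, hill_h, config).fit()


# ---------------------------------------------------------------------------
# ligand comparison


def compare_ligands(
    tm_by_ligand: Dict[str, float], config: AnalysisConfig = DEFAULT_CONFIG
) -> dict:
    """Rank ligands by the Tm they confer at a fixed concentration.

    Returns a ranking (groups of ligands tied within ``tie_tol``) plus the
    pairwise Tm differences.
    """
    items = sorted(tm_by_ligand.items(), key=lambda kv: (-kv[1], kv[0]))
    groups: List[List[str]] = []
    for name, tm in items:
        if groups and abs(tm_by_ligand[groups[-1][-1]] - tm) <= config.tie_tol:
            groups[-1].append(name)
        else:
            groups.append([name])
    pairwise = {
        f"{a}-{b}": tm_by_ligand[a] - tm_by_ligand[b]
        for a in tm_by_ligand
        for b in tm_by_ligand
        if a < b
    }
    return {"ranking": groups, "pairwise_delta_tm": pairwise}
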