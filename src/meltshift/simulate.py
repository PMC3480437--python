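"""Render melt curves from the thermodynamic model.

The fluorescence of a well is the sum over species s of

    F_s(T) = c_s · [ f_native(T)·B_nat(T) + f_unfolded(T)·B_unf(T)·D_s(T) ]

where the baselines B are linear in temperature (per-µM units), the native
term splits into ligand-free and ligand-bound sub-states (they may carry
different baselines), and D_s(T) = exp(−k_agg·max(0, T − (Tm + onset)))
models the post-transition fluorescence decay caused by aggregation burying
the dye-binding hydrophobic surface.  Gaussian noise with standard
deviation ``noise_frac`` × (full noiseless amplitude) is added per
replicate; replicate r of a scenario uses seed ``seed + r``.

A cooperative 1:1 complex is modelled as a pseudo-species: ``complex_spec``
replaces min(c_A, c_B) of each named component with the complex, leaving
the excess of the more abundant component free — valid under saturating
ligand, which is how such complexes are measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .curves import ConditionMeta, MeltCurve
from .thermo import (
    CELSIUS,
    LigandCoupling,
    SpeciesThermo,
    melting_midpoint,
    solve_equilibrium,
)

MAX_SEED = 2 ** 31


@dataclass
class SimScenario:
    """Everything needed to simulate one condition's replicate curves."""

    species_list: List[Tuple[SpeciesThermo, float]]          # (thermo, µM)
    couplings: List[Tuple[LigandCoupling, float]] = field(default_factory=list)  # (coupling, L_total µM)
    complex_spec: Optional[Tuple[str, str, SpeciesThermo]] = None
    grid: Tuple[float, float, float] = (15.0, 85.0, 1.0)
    noise_frac: float = 0.01
    n_replicates: int = 3
    seed: int = 0
    condition: Optional[ConditionMeta] = None
    sample_id: str = "sim"
    wells: Optional[Sequence[str]] = None

    def __post_init__(self):
        t0, t1, dt = self.grid
        if dt <= 0 or t1 <= t0:
            raise ValueError("grid must have positive step and span")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def temperatures(self) -> np.ndarray:
        t0, t1, dt = (float(x) for x in self.grid)
        n = int(round((t1 - t0) / dt)) + 1
        return t0 + dt * np.arange(n, dtype=float)


def effective_species(scenario: SimScenario) -> List[Tuple[SpeciesThermo, float]]:
    """Apply the complex-pseudo-species substitution to the species list."""
    species = [(th, float(c)) for th, c in scenario.species_list]
    if scenario.complex_spec is None:
        return species
    name_a, name_b, cplx = scenario.complex_spec
    concs = {th.name: c for th, c in species}
    if name_a not in concs or name_b not in concs:
        raise ValueError(f"complex components {name_a}/{name_b} not in species list")
    m = min(concs[name_a], concs[name_b])
    out = []
    for th, c in species:
        if th.name in (name_a, name_b):
            c = c - m
        if c > 0:
            out.append((th, c))
    if m > 0:
        out.append((cplx, m))
    return out


def _species_trace(
    t_c: np.ndarray,
    thermo: SpeciesThermo,
    conc: float,
    coupling: Optional[LigandCoupling],
    l_total: float,
) -> np.ndarray:
    native = thermo.native_intercept + thermo.native_slope * t_c
    apo_native = native
    if thermo.apo_native_intercept is not None:
        apo_native = thermo.apo_native_intercept + thermo.native_slope * t_c
    unfolded = thermo.unfolded_intercept + thermo.unfolded_slope * t_c
    # aggregation follows unfolding: its onset tracks the apparent melting
    # midpoint (ligand-shifted when a coupling is present), not the apo Tm
    apparent_tm = melting_midpoint(thermo, coupling, conc, l_total)
    decay = np.exp(-thermo.k_agg * np.maximum(0.0, t_c - (apparent_tm + thermo.agg_onset_offset)))
    f = np.empty_like(t_c)
    for i, t in enumerate(t_c):
        st = solve_equilibrium(t + CELSIUS, thermo, coupling, conc, l_total)
        f[i] = (
            st.f_native_free * apo_native[i]
            + st.f_bound * native[i]
            + st.f_unfolded * unfolded[i] * decay[i]
        )
    return conc * f


def noiseless_trace(scenario: SimScenario) -> np.ndarray:
    """The deterministic total fluorescence over the scenario grid."""
    t_c = scenario.temperatures
    by_species = {c.species: (c, lt) for c, lt in scenario.couplings}
    total = np.zeros_like(t_c)
    for thermo, conc in effective_species(scenario):
        coupling, l_total = by_species.get(thermo.name, (None, 0.0))
        total += _species_trace(t_c, thermo, conc, coupling, l_total)
    return total


def simulate_curve(scenario: SimScenario) -> List[MeltCurve]:
    """Simulate ``n_replicates`` noisy MeltCurves for one condition."""
    t_c = scenario.temperatures
    clean = noiseless_trace(scenario)
    sd = scenario.noise_frac * float(clean.max() - clean.min())
    cond = scenario.condition
    if cond is None:
        cond = ConditionMeta(
            proteins=tuple((th.name, c) for th, c in scenario.species_list),
            ligands=tuple((c.ligand, lt) for c, lt in scenario.couplings),
        )
    curves = []
    for r in range(1, scenario.n_replicates + 1):
        rng = np.random.default_rng((scenario.seed + r) % MAX_SEED)
        f = clean + (rng.normal(0.0, sd, size=t_c.size) if sd > 0 else 0.0)
        well = (
            scenario.wells[r - 1]
            if scenario.wells is not None
            else f"{scenario.sample_id}:{r}"
        )
        curves.append(
            MeltCurve(
                sample_id=f"{scenario.sample_id}_r{r}",
                well=well,
                replicate=r,
                temperatures=t_c.copy(),
                fluorescence=np.maximum(f, 0.0),
                condition=cond,
            )
        )
    return curves
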