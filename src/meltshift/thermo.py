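"""Two-state unfolding thermodynamics with native-state ligand coupling.

The simulator's physical model.  A protein unfolds in a single cooperative
N ⇌ U equilibrium whose free energy follows the Gibbs-Helmholtz relation

    ΔGu(T) = ΔHm·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm)),        T, Tm in K

with ΔHm the van't Hoff unfolding enthalpy at the midpoint Tm and ΔCp the
unfolding heat-capacity change.  A ligand L binds the native state only,

    N + L ⇌ NL,   Kd(T) = Kd(T_ref)·exp[(ΔHb/R)(1/T − 1/T_ref)]

so ligand binding raises the temperature at which half the protein is
unfolded — the basis of the thermal-shift readout.  The coupled system is
solved under full mass conservation (ligand depletion included):

    P_total = [N] + [NL] + [U],      L_total = [L] + [NL].

Free-ligand concentration has a stable quadratic closed form, used
throughout; the root-finding/fixed-point formulations exist only as
independent oracles in the test-suite.

Units: temperatures °C at the API surface and K internally; energies
kJ/mol; concentrations µM; R = 8.3145 J/(mol·K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

from scipy.optimize import brentq, root

#: gas constant, kJ/(mol·K)
R_KJ = 8.3145e-3
#: reference temperature for Kd, K (25 °C)
T_REF = 298.15
CELSIUS = 273.15


@dataclass(frozen=True)
class SpeciesThermo:
    """Unfolding thermodynamics and fluorescence baselines of one species.

    Baselines are in fluorescence units per µM of species; the unfolded
    baseline must exceed the native one (the dye fluoresces on unfolding).
    ``apo_native_intercept``, when set, is the native baseline of the
    *unbound* native state — used for proteins whose apo form shows
    anomalously high initial fluorescence that clears upon ligand binding.
    Post-transition aggregation quenches the unfolded signal at rate
    ``k_agg`` (1/°C) beyond ``Tm + agg_onset_offset``.
    """

    name: str
    tm_c: float                      # apo midpoint, °C
    dhm: float                      # van't Hoff unfolding enthalpy at Tm, kJ/mol
    dcp: float = 0.0                # unfolding heat-capacity change, kJ/(mol·K)
    native_intercept: float = 0.08
    native_slope: float = 0.0002
    unfolded_intercept: float = 1.0
    unfolded_slope: float = -0.00025
    k_agg: float = 0.08             # 1/°C
    agg_onset_offset: float = 6.0   # °C past Tm
    apo_native_intercept: Optional[float] = None

    def __post_init__(self):
        if self.dhm <= 0:
            raise ValueError(f"{self.name}: unfolding enthalpy must be > 0")
        if self.dcp < 0:
            raise ValueError(f"{self.name}: ΔCp must be >= 0")
        if self.k_agg < 0:
            raise ValueError(f"{self.name}: k_agg must be >= 0")
        if self.unfolded_intercept <= self.native_intercept:
            raise ValueError(f"{self.name}: unfolded baseline must exceed native baseline")

    @property
    def tm_k(self) -> float:
        return self.tm_c + CELSIUS

    def shifted(self, delta_tm_c: float) -> "SpeciesThermo":
        """Copy with the true midpoint offset by ``delta_tm_c`` °C."""
        return replace(self, tm_c=self.tm_c + delta_tm_c)


@dataclass(frozen=True)
class LigandCoupling:
    """One ligand binding the native state of one species.

    ``kd`` is the dissociation constant (µM) at 25 °C; ``dhb`` the binding
    enthalpy (kJ/mol) that carries Kd across temperature by van't Hoff
    (0 = temperature-independent binding).
    """

    ligand: str
    species: str
    kd: float
    dhb: float = 0.0

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError(f"{self.ligand}: Kd must be > 0")

    def kd_at(self, t_k: float) -> float:
        return self.kd * math.exp((self.dhb / R_KJ) * (1.0 / t_k - 1.0 / T_REF))


def unfolding_free_energy(t_k: float, thermo: SpeciesThermo) -> float:
    """ΔGu(T) in kJ/mol by Gibbs-Helmholtz; zero at the midpoint."""
    if t_k <= 0:
        raise ValueError("absolute temperature must be positive")
    tm = thermo.tm_k
    dg = thermo.dhm * (1.0 - t_k / tm)
    if thermo.dcp:
        dg += thermo.dcp * (t_k - tm - t_k * math.log(t_k / tm))
    return dg


def unfolding_equilibrium_constant(t_k: float, thermo: SpeciesThermo) -> float:
    """Ku = [U]/[N] = exp(−ΔGu/RT), clipped against overflow."""
    x = -unfolding_free_energy(t_k, thermo) / (R_KJ * t_k)
    return math.exp(min(max(x, -500.0), 500.0))


class EquilibriumState(NamedTuple):
    """Fractions of total protein in each state plus free ligand (µM)."""

    f_native_free: float
    f_bound: float
    f_unfolded: float
    l_free: float


def solve_equilibrium(
    t_k: float,
    thermo: SpeciesThermo,
    coupling: Optional[LigandCoupling] = None,
    p_total: float = 1.0,
    l_total: float = 0.0,
) -> EquilibriumState:
    """Solve the coupled N ⇌ U / N + L ⇌ NL system with ligand depletion.

    Free ligand follows from the quadratic
    ``[L]² + [L]·((1+Ku)·Kd + P − L_tot) − L_tot·(1+Ku)·Kd = 0``
    evaluated in its cancellation-safe form.
    """
    if p_total <= 0:
        raise ValueError("p_total must be > 0")
    ku = unfolding_equilibrium_constant(t_k, thermo)
    a = 1.0 + ku
    if coupling is None or l_total <= 0:
        return EquilibriumState(1.0 / a, 0.0, ku / a, max(l_total, 0.0))
    kd = coupling.kd_at(t_k)
    b = a * kd + p_total - l_total
    disc = math.sqrt(b * b + 4.0 * l_total * a * kd)
    if b <= 0:
        l_free = 0.5 * (-b + disc)
    else:
        l_free = 2.0 * l_total * a * kd / (b + disc)
    denom = a + l_free / kd
    return EquilibriumState(1.0 / denom, (l_free / kd) / denom, ku / denom, l_free)


def fraction_unfolded(
    t_k: float,
    thermo: SpeciesThermo,
    coupling: Optional[LigandCoupling] = None,
    p_total: float = 1.0,
    l_total: float = 0.0,
) -> float:
    """[U]/P_total in [0, 1]; exactly 0.5 at the apo midpoint."""
    return solve_equilibrium(t_k, thermo, coupling, p_total, l_total).f_unfolded


class MidpointNotBracketedError(RuntimeError):
    """The half-unfolded temperature does not lie in the search range."""


def melting_midpoint(
    thermo: SpeciesThermo,
    coupling: Optional[LigandCoupling] = None,
    p_total: float = 1.0,
    l_total: float = 0.0,
    span_c: float = 120.0,
) -> float:
    """Temperature (°C) at which half the protein is unfolded."""
    if coupling is None or l_total <= 0:
        return thermo.tm_c

    def g(t_k: float) -> float:
        return fraction_unfolded(t_k, thermo, coupling, p_total, l_total) - 0.5

    lo = thermo.tm_k - 1.0
    hi = thermo.tm_k + span_c
    if g(lo) >= 0 or g(hi) <= 0:
        raise MidpointNotBracketedError(
            f"{thermo.name}: no unfolding midpoint within {span_c} °C of Tm"
        )
    return brentq(g, lo, hi, xtol=1e-9) - CELSIUS


def predicted_tm_shift(
    thermo: SpeciesThermo,
    coupling: LigandCoupling,
    p_total: float,
    l_total: float,
) -> float:
    """ΔTm (°C) induced by the ligand at the given totals; 0 at L_total = 0."""
    if l_total < 0:
        raise ValueError("l_total must be >= 0")
    if l_total == 0:
        return 0.0
    return melting_midpoint(thermo, coupling, p_total, l_total) - thermo.tm_c


def calibrate_kd(
    thermo: SpeciesThermo,
    p_total: float,
    l_total: float,
    target_shift: float,
    ligand: str = "ligand",
    dhb: float = 0.0,
    log10_kd_bounds=(-5.0, 7.0),
) -> LigandCoupling:
    """Invert predicted_tm_shift for the reference Kd at fixed ΔHb.

    Used by the fixture builders: when the ground truth is a printed ΔTm
    rather than a binding constant, the Kd reproducing that shift is found
    numerically (the shift is strictly decreasing in Kd).
    """

    def g(log10_kd: float) -> float:
        c = LigandCoupling(ligand, thermo.name, 10.0 ** log10_kd, dhb)
        return predicted_tm_shift(thermo, c, p_total, l_total) - target_shift

    lo, hi = log10_kd_bounds
    x = brentq(g, lo, hi, xtol=1e-10)
    return LigandCoupling(ligand, thermo.name, 10.0 ** x, dhb)


def calibrate_kd_two_point(
    thermo: SpeciesThermo,
    p_total: float,
    point_a: tuple,
    point_b: tuple,
    ligand: str = "ligand",
) -> LigandCoupling:
    """Solve (Kd_ref, ΔHb) so the shift curve passes through two points.

    ``point_a``/``point_b`` are (L_total µM, ΔTm °C) anchors, e.g. the
    printed shift at the screening concentration plus the sub-threshold
    shift that pins the detection boundary between two tested doses.
    """
    (l_a, s_a), (l_b, s_b) = point_a, point_b

    def resid(x):
        log10_kd, dhb_scaled = x
        c = LigandCoupling(ligand, thermo.name, 10.0 ** log10_kd, 100.0 * dhb_scaled)
        return [
            predicted_tm_shift(thermo, c, p_total, l_a) - s_a,
            predicted_tm_shift(thermo, c, p_total, l_b) - s_b,
        ]

    guess = calibrate_kd(thermo, p_total, l_b, s_b, ligand=ligand)
    sol = root(resid, x0=[math.log10(guess.kd), 0.0], method="hybr", tol=1e-12)
    r = resid(sol.x)
    if not sol.success or max(abs(r[0]), abs(r[1])) > 1e-6:
        raise RuntimeError(
            f"coupling calibration failed for {ligand}/{thermo.name}: residual {r}"
        )
    return LigandCoupling(ligand, thermo.name, 10.0 ** sol.x[0], 100.0 * sol.x[1])
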