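# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `meltshift`, in the spirit of a package methods
appendix.  Nothing here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Forward model: two-state unfolding with ligand coupling

Each protein species unfolds in a single cooperative equilibrium N ⇌ U
with Gibbs–Helmholtz free energy

    ΔGu(T) = ΔHm·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm)),   T, Tm in kelvin,

parameterised by the midpoint `Tm` (°C at the API surface), the van't Hoff
unfolding enthalpy `ΔHm` (kJ/mol, sets transition sharpness: the
effective Boltzmann slope is a ≈ R·Tm²/ΔHm, about 1–2.5 °C here) and the
heat-capacity change `ΔCp` (kJ/mol/K, curves the stability profile).
R = 8.3145 J/(mol·K); all thermodynamics are computed in kelvin, all I/O
is °C.

A ligand binds the native state only: N + L ⇌ NL with
`Kd(T) = Kd(Tref)·exp[(ΔHb/R)(1/T − 1/Tref)]`, Tref = 25 °C.  The coupled
system is solved under both conservation laws (protein and ligand;
ligand depletion is therefore exact, which matters at the stoichiometric
doses where detection thresholds live).  Free ligand has a closed
quadratic solution, evaluated in its cancellation-safe form; the
test-suite checks it against an independent damped fixed-point iteration
to 1e-8 µM and verifies both conservation laws at the same tolerance.
The ligand-shifted melting midpoint (fraction unfolded = ½) is found by
bracketed root-finding and is verified against a brute-force 0.001 °C
temperature scan to within 0.002 °C.

Unfolded-state binding, receptor oligomerisation and three-state
intermediates are not modelled.  Ternary receptor–hormone–phosphatase
complexes are represented as a single cooperative pseudo-species that
replaces the limiting component (valid only under saturating hormone,
which is how such complexes are measured); the excess partner remains
free.  Scan-rate (kinetic) effects are outside the model: curves are
equilibrium snapshots on the temperature grid.

## Fluorescence model

Per species, `F(T) = c·[f_N·B_nat(T) + f_NL·B_nat(T) + f_U·B_unf(T)·D(T)]`
with linear baselines in fluorescence-units per µM.  Defaults: native
intercept 0.08, unfolded intercept 1.0, slopes +0.0002 and −0.00025 per
°C — small but non-zero, so the flat-plateau empirical fit stays an
approximation of the data rather than its mirror image.  The aggregation
factor `D(T) = exp(−k_agg·max(0, T − (Tm_app + onset)))` with defaults
k_agg = 0.08 /°C and onset = +6 °C produces the canonical rise-then-fall
profile.  `Tm_app` is the *apparent* (ligand-shifted) midpoint: aggregation
follows actual unfolding, so a stabilized protein also aggregates later —
tying the onset to the apo midpoint would quench a strongly shifted
transition before it occurs.

A species may carry a distinct `apo_native_intercept`: the baseline of its
*unbound* native state.  This reproduces receptors whose apo form shows
anomalously high initial fluorescence (partially exposed hydrophobic
surface) that clears as ligand binds and orders the protein.

Noise is Gaussian with sd = noise_frac × (max − min of the noiseless
trace), default 1%; replicate r of a scenario uses seed + r, so every
fixture is bit-reproducible from (fixture_id, seed).

## Empirical fitting

**Single-transition Tm** uses the classic DSF protocol: truncate the trace
at its global fluorescence maximum (the aggregation decline carries no
midpoint information), then least-squares fit
`F = LL + (UL−LL)/(1+exp((Tm−T)/a))` with flat plateaus.  Initial values:
Tm from the smoothed-derivative maximum, plateaus from the first/last
deciles, a = 2 °C.  On noiseless simulated single-species curves the
fitted Tm is within 0.05 °C of the thermodynamic midpoint; at 1% noise the
replicate sd is ≲ 0.1 °C (the suite asserts ≤ 0.3 °C over 100
replicates).  Fitted Tm is invariant under uniform scaling of the
fluorescence.

**Mono- vs biphasic classification** cannot use the truncated window: in
a mixture the minority species' transition may ride the major species'
aggregation decline as a mere shoulder with no fluorescence peak at all
(the 1 µM phosphatase titration point).  Model comparison therefore runs
on the full trace with decay-aware variants in which each transition's
native floor vanishes across its sigmoid and its unfolded signal then
decays past its own apex:

    F(T) = Σ_i [ LLi·(1−sig_i) + (LLi+A_i)·sig_i·exp(−k·max(0, T−Tm_i−onset)) ]

(one or two transitions; per-transition floors split the fitted LL in
proportion to amplitude).  This mirrors the generative structure —
including the decline to zero once everything is aggregated — so the fit
is well-conditioned.  Numerical choices that matter:

* the decay rate k is **held fixed** at the canonical 0.08 /°C
  (configurable): freeing it creates a flat (k, Tm) ridge whose local
  minima flip with the noise seed;
* transition slopes are bounded at 8 °C, well above any genuine transition
  here (a ≈ 1–5 °C) but low enough that a maximally broad sigmoid cannot
  impersonate a sloped baseline;
* multi-start initialisation over derivative-peak pairs, caller-supplied
  reference Tms, ±(min_separation+1) offsets around the main transition,
  and two amplitude splits (50/50, 80/20); the best SSR wins;
* the two-transition model is accepted only if ΔBIC ≥ 10, each amplitude
  carries ≥ 15% of the total, and the fitted separation exceeds
  min_separation = 4 °C without sitting on that bound (a pinned
  separation means the optimizer wanted the transitions closer: merged);
* when caller-supplied reference Tms are distinct and the two-transition
  model is rejected, the single fit carries a `merged_transitions` flag —
  this is how a very strong stabilizer that pushes the target transition
  into the tag's is recognised.

**Quality control**: `two_state` requires convergence, R² ≥ 0.99,
relative amplitude ≥ 20% of the trace maximum, a midpoint ≥ 2 °C from the
window edge, and no high-initial-fluorescence flag (first point > half
the trace maximum).  `biphasic` applies the same gates to the selected
two-transition model.  R² is always evaluated over the protocol window
(up to the fluorescence maximum): the decay tail informs the full-trace
fit but not the quality gate.

## Shift statistics and dose response

ΔTm = mean(condition Tms) − mean(reference Tms); its uncertainty is the
propagated standard error √(sd_c²/n_c + sd_r²/n_r).  A shift is
*detected* when |ΔTm| ≥ θ_detect = 0.5 °C and, when replicated, |ΔTm| ≥ 3×
that standard error.  The 0.5 °C threshold makes the qualitative notion of
a "noticeable" shift explicit and is configurable.

Dose series fit `ΔTm([L]) = ΔTm_max·[L]^h/(K_half^h + [L]^h)` with h fixed
at 1 (one-site saturation; h is exposed but not fitted by default).  The
rising phase alone cannot identify Kd when solubility truncates the
series, so no Kd estimate is attempted — instead, when nothing is
detectable at doses up to the protein concentration, the smallest
detectable dose is reported as a *lower bound* on Kd (a detectable shift
at ~1:1 stoichiometry requires free-ligand levels approaching Kd).
Thermodynamic (enthalpy-coupled) ΔTm→Kd conversion is deliberately out of
scope.

A reference whose curve is flagged (e.g. a high-baseline apo receptor) can
still anchor a dose series through its numerically converged fitted Tm;
the resulting shifts carry a `reference_flagged` marker, and a dose only
counts as detectable once its own curve is clean two-state.

## Titrations, screens, fusion control

Complex detection: an equimolar mixture is a cooperative complex iff it
melts as a single transition more than 1 °C above both component
references.  In titrations, each ratio is called monophasic/biphasic by
replicate majority; the lower transition of a biphasic profile is assigned
to the excess component by nearest reference Tm within a 2 °C window
(else flagged unassigned).  The stoichiometry is the tested ratio that is
monophasic while flanked by biphasic ratios on both sides; no
interpolation between tested ratios is attempted.

Hit calling uses the all-targets rule: a compound is a hit iff its mean
ΔTm meets the 3 °C threshold on *every* target.  Ranking is by minimum
shift across targets (an affinity proxy for inhibitors of comparable
binding enthalpy, not an IC50 prediction), ties broken by compound id.
Screens are treated as unreplicated (n = 1, SEM rule disabled), matching
common practice for library passes; references stay in triplicate.

The fusion-tag control classifies a condition from the two transitions of
a tag–target fusion: `specific` (target moves ≥ 3 °C, tag stays within
1 °C), `nonspecific_stabilizer`/`_destabilizer` (both move ≥ 1 °C the same
way), `no_effect`, `specific_merged` (condition collapses to a single
transition at the tag's position but ≥ 3 °C above the target reference),
else `indeterminate`.

## Fixture calibration

The fixtures regenerate a complete receptor/phosphatase/kinase study.
Printed quantities are encoded directly (kinase Tms 36.2/38.3/49.0 °C;
staurosporine shifts ≈ 9.5 °C on SnRK2.3 and 6.7 °C on SnRK2.6 at 50 µM;
detection doses 2.5 µM for staurosporine titrations, 50 µM ABA on PYL1,
25 µM on PYL2; the 3-of-300 screen outcome; 1:1 complex stoichiometry; a
1.6 °C salt destabilization from the reported 1.5–1.6 °C range).  Binding
parameters were never printed, so each coupling's (Kd, ΔHb) is found by
numerically inverting the *measured* shift — simulate noiselessly,
preprocess, Boltzmann-fit, difference — through one or two anchor points.
The empirical route matters: the published numbers are themselves
Boltzmann-fit readouts, and the fit reproduces the thermodynamic midpoint
shift only up to a model-mismatch bias of a few tenths of a °C.

Detection-dose calibrations use two anchors that straddle the 0.5 °C
threshold symmetrically (e.g. 0.35 °C at the last sub-threshold dose),
placing the detection boundary robustly between the two tested
concentrations rather than at a knife edge.  PYL2 keeps a
temperature-independent Kd because its apo-baseline behaviour requires
weak binding at the low end of the ramp; its elevated apo baseline is
itself calibrated so the high-initial-fluorescence flag clears between 10
and 25 µM ABA.  The complex-titration fixture likewise uses a
temperature-independent hormone coupling matched to the same 500 µM
shift, keeping the saturating-hormone receptor a clean two-state
reference.  All calibrated values ship in each fixture's manifest.

Never-printed absolute Tms (receptors, phosphatases, MBP, complexes) are
package choices: PYL1 45, PYL2 43, ABI2 44, HAB1 41 (placed well below
the ~48.6 °C hormone-loaded receptor so the excess-phosphatase transition
stays resolvable), MBP 50 (so a > 9 °C kinase stabilization genuinely
merges with the tag transition at the 4 °C resolvability limit, while a
~4 °C one stays resolved), complex Tm = hormone-loaded-receptor Tm + 5.
The complex's unfolded brightness exceeds its components' sum by 30%
(cooperative unfolding also exposes the buried interface), which keeps
the 1 µM titration point's minority transition above the 15% amplitude
gate.

## What passing tests do and do not show

The simulator produces idealised plate data: Gaussian homoscedastic
noise, exact grid temperatures, no well-to-well optical variation, no
evaporation or drift, mild linear baselines, a single shared aggregation
law.  Pipeline accuracy quoted here (Tm recovery to ≲ 0.1 °C, detection
boundaries resolved between adjacent doses, zero false-positive hits) is
accuracy *under this generative model*; instrument data with uncorrected
optical artefacts, drifting baselines or protein-specific aggregation
kinetics will degrade all of these, and the configurable gates
(R², amplitude, ΔBIC, thresholds) are the intended adjustment points.

## Problem sizes

Default analyses fit 9–60 curves per fixture of 71 points each; the
screen fits ~900.  The full reproduction (`meltshift reproduce`,
`scripts/acceptance.py`) runs in well under a minute on one CPU.
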