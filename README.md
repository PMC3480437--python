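# meltshift

Thermal stability shift assay (TSA / DSF / thermofluor) analysis in Python:
melt-curve simulation from unfolding thermodynamics, Boltzmann Tm fitting,
ligand-shift dose response with Kd bounds, protein-complex stoichiometry
from titration profiles, and internally controlled inhibitor screening.

## Who this is for

A thermal shift assay follows protein unfolding in a real-time PCR machine
with an environment-sensitive dye (e.g. SYPRO Orange): the dye is quenched
in water and fluoresces on the hydrophobic surface a protein exposes as it
unfolds, so fluorescence rises through the melting transition and falls
again once aggregation buries that surface.  Ligands that bind the native
state raise the melting temperature Tm; the shift ΔTm reads out binding —
down to interactions far too weak (Kd ≥ 50 µM) for radioligand or SPR
assays.  This package is for people analysing such plate-reader exports:
it fits per-well melt curves, aggregates replicates into ΔTm statistics,
interprets dose series, titrations, and compound screens, and ships a
thermodynamic simulator so every analysis stage can be exercised and
validated without instrument data.

The bundled fixtures emulate a complete study of the abscisic-acid (ABA)
signalling pathway of *Arabidopsis*: PYL1/PYL2 hormone receptors, HAB1 and
ABI2 phosphatases (PP2Cs), and the SnRK2 kinases, including a ~300-compound
kinase-inhibitor screen and an MBP-fusion specificity control.

## Models

**Simulator (forward model).**  Two-state unfolding N ⇌ U with
Gibbs–Helmholtz free energy

    ΔGu(T) = ΔHm·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm))

and optional native-state ligand binding N + L ⇌ NL with a van't Hoff
temperature-dependent Kd, solved under full mass conservation (ligand
depletion included; the free-ligand concentration has a closed quadratic
form).  The fluorescence of a well sums per-species contributions
`c·[f_native·B_nat(T) + f_unfolded·B_unf(T)·D(T)]` with linear baselines
and an exponential aggregation decay D past each transition.  Cooperative
1:1 complexes are pseudo-species replacing the limiting component.

**Empirical fits (inverse model).**  Per-curve Tm estimation uses the
standard DSF Boltzmann sigmoid `F = LL + (UL−LL)/(1+exp((Tm−T)/a))` fitted
over the window ending at the fluorescence maximum
(`MeltCurveModel(curve).fit(n_transitions=1)`).  Monophasic-vs-biphasic
classification fits one- and two-transition decay-aware variants on the
full trace and chooses by BIC with explicit amplitude/separation gates.
Dose series are fitted to a one-site saturation curve
`ΔTm([L]) = ΔTm_max·[L]/(K_half + [L])` (`DoseResponseModel`); when no
shift is detectable at doses up to the protein concentration, the first
detectable dose is reported as a lower bound on Kd.

## Worked example

Measure the staurosporine-induced stabilization of the SnRK2.6 kinase at
50 µM compound:

```python
from meltshift import generate_fixture, delta_tm
from meltshift.fitting import fit_group

fx = generate_fixture("snrk_staurosporine", seed=11)
sel = lambda label: [c for c in fx.curves if c.sample_id.startswith(label)]

cond = fit_group(sel("SnRK2.6_stauro_50_"))   # 50 µM staurosporine, 3 wells
apo  = fit_group(sel("SnRK2.6_stauro_0_"))    # no compound, 3 wells

print(cond[0].summary())
shift = delta_tm(cond, apo)
print(f"ΔTm = {shift.delta_tm_mean:.2f} ± {shift.delta_tm_sd:.2f} °C,"
      f" detectable: {shift.detectable}")
```

prints

```
Melt-curve fit: SnRK2.6_stauro_50_r1
  model:          1-transition Boltzmann
  window:         15.0-62.0 °C (48 pts)
  classification: two_state
  R²:             0.99901
  flags:          -
  Tm1: 55.72 ± 0.085 °C   slope a: 2.45 °C   amplitude: 4.51
ΔTm = 6.79 ± 0.05 °C, detectable: True
```

The well melts as a clean two-state transition (R² > 0.99) at 55.7 °C —
6.8 °C above the 49.0 °C apo kinase — a detectable stabilization far above
the 0.5 °C detection threshold, consistent with tight staurosporine
binding.

The same objects drive the command line:

```bash
meltshift simulate --fixture snrk_panel --seed 11 --out out/
meltshift fit out/curves.csv --layout out/layout.yaml --out out/fits.csv
meltshift reproduce --seed 11 --out out/   # every fixture + analysis
```

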