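# voclift

Quantitative machinery for studying how a cell-wall lipid-transfer protein
(nsLTP) carries volatile organic compounds (VOCs) from the plasma membrane
to the cuticle of flower epidermal cells. The package is aimed at plant
biochemists and modellers who want to (i) simulate carrier-facilitated
diffusion across the hydrophilic cell wall, (ii) process fluorescent-probe
(TNS) displacement assays into binding constants with nested model
selection, and (iii) convert emission/pool time courses into biosynthetic
fluxes and volatile emission factors. A seeded synthetic-data module
generates every input with known ground truth, so the whole pipeline is
testable without any measured dataset.

## The models

**Transport.** At steady state, the flux of a VOC across a wall slab of
thickness *L* decomposes into free (Fickian) and carrier-borne terms:

    J = (D_s / L)(S₀ − S_L) + (D_c C_T / L)[y(S₀) − y(S_L)],
    y(s) = Σᵢ s / (K_dᵢ + s)

with *S₀*, *S_L* the free VOC concentrations at the membrane- and
cuticle-facing boundaries, *C_T* the total carrier concentration, and
*D_s*, *D_c* the diffusivities of free VOC and carrier·VOC complex. The
extent of enhanced flux E = J / J_free is ≥ 1, linear in *C_T*, and
maximised over the dissociation constant at K_d = √(S₀·S_L) — a bell-shaped
optimum balancing ligand capture against release. A full reaction–diffusion
two-point boundary-value solver (`bvp_oracle`) validates the closed form
independently.

**Binding.** Displacement titrations are calibrated well-by-well
(solvent ratios R = F^sol/F⁰, percent of protein-bound probe signal) and
the rising displacement curve is fit to one- and two-site mass-action
hyperbolas, Bmax·L/(K_d + L) (+ a second site). Model selection uses the
extra-sum-of-squares F ratio

    F = ((SS1 − SS2)/SS2) / ((DF1 − DF2)/DF2)

with a p-value from F(DF1−DF2, DF2); the two-site model is preferred at
p < 0.05.

**Emission flux.** The internal pool obeys dC/dt = v_syn − v_emi; the pool
slope over an evening window (OLS) plus the hourly emission rate gives the
biosynthetic flux, and VEF = v_emi / v_syn. Cuticle partition follows from
a brief hexane dip: cuticular fraction = (C_hex / C_total) / R with R the
wax recovery.

## Worked example

```python
>>> from voclift import calibrate_reference_scenario, steady_state_flux, \
...     optimal_kd, predict_knockdown
>>> sc = calibrate_reference_scenario()      # 1 mM carrier, 0.25 nM gradient
>>> kd_mb = sc.kd_by_compound["methylbenzoate"]
>>> round(optimal_kd(sc.boundary_conditions, sc.carrier_params(kd_mb)), 1)
24.4
>>> round(steady_state_flux(sc.carrier_params(kd_mb),
...                         sc.boundary_conditions).enhancement, 2)
1.67
>>> round(steady_state_flux(sc.carrier_params(sc.methylbenzoate_two_site),
...                         sc.boundary_conditions).enhancement, 2)
1.98
>>> round(predict_knockdown(sc.carrier_params(kd_mb), sc.boundary_conditions,
...       0.6, [(kd, 1.0) for kd in sc.kd_by_compound.values()]), 1)
18.0
```

The calibrated scenario says: with 1 mM carrier and a 0.25 nM concentration
difference across the wall, carrier affinity is most effective at
K_d = 24.4 μM; methylbenzoate flux is enhanced 1.67-fold by a single
binding site and 1.98-fold by two independent sites; and scaling the
carrier to 60% (a 40% transcript knockdown) cuts the six-compound total
flux by 18%.

The same stages run from the shell:

```sh
voclift simulate assay --seed 4 --out sim/
voclift binding quench --in sim/plate.csv --out quench.csv
voclift binding fit --in quench.csv --alpha 0.05 --out fits.json
voclift transport calibrate
voclift vef --in series.csv --window 17:19 --out vef.tsv
voclift cuticle --in dips.csv --out fractions.tsv
```

## Layout

- `src/voclift/transport.py` — facilitated-diffusion model, sweeps,
  optimal-K_d search, knockdown prediction, BVP oracle, reference-scenario
  calibration
- `src/voclift/binding.py` — assay calibration, one-/two-site fits, F-test
- `src/voclift/emission.py` — pool-rate regression, VEF, cuticle partition
- `src/voclift/simulate.py` — seeded synthetic-data generators
- `src/voclift/io.py`, `src/voclift/cli.py` — validated table/parameter I/O
  and the `voclift` command
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details, and known limitations
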