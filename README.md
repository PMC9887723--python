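# formadose

Tissue dosimetry of endogenous and exogenous formaldehyde DNA adducts in rat
nasal mucosa.

Inhaled formaldehyde causes nasal tumors in F344 rats at high concentrations,
but formaldehyde is also produced continuously inside cells by 1-carbon
metabolism. Risk analysis therefore hinges on a quantitative question: at what
inhaled concentration does the *exogenous* DNA damage overtake the ever-present
*endogenous* background? `formadose` answers it with a nine-state kinetic model
of the nasal mucosa that links CFD-predicted site-specific uptake of inhaled
formaldehyde, glutathione conjugation with saturable
formaldehyde-dehydrogenase clearance, and the formation and repair of two DNA
lesions: deoxyguanosine (DG) monoadducts and DNA–protein crosslinks (DPX),
each split into endogenous and exogenous pools.

The package is for toxicokinetic modellers and risk analysts: it ships the
published kinetic parameter set and the measured adduct dataset, simulates the
published inhalation protocols, calibrates parameters by bounded Nelder–Mead
against that dataset, and reproduces the headline dose–response analyses
(crossover concentrations, DPX:DG ratios, multi-week time courses).

## Model

For each origin (endo/exo), free formaldehyde F obeys

    dF/dt = source − k21·F − k23·F·GSH + k32·F_GSH − (kDNA_DG + kDNA_DPX)·F

where the source is either the zero-order metabolic production kp or the
flux-derived uptake `flux·ppm/thick`. The S-hydroxymethylglutathione complexes
compete for one formaldehyde-dehydrogenase pool
(`ox = Vmax·C/(Km + C_total)`), oxidation regenerates free GSH (the
glutathione moiety is conserved), and each adduct pool forms first-order in F
and repairs first-order in itself:

    dDPX/dt = kDNA_DPX·F − krep_DPX·DPX        dDG/dt = kDNA_DG·F − krep_DG·DG

Units: hours and pmol/mm³ (= µM) throughout. See `docs/methods.md` for the
full equation set, the reconstruction choices behind it, and the numerics.

## Worked example

```python
import numpy as np
import formadose as fd

params = fd.KineticParameters()            # published parameter set
steady = fd.endogenous_steady_state(params)
print(f"endoF={steady.endoF:.1f}  endoDG={steady.endoDG:.3g}  endoDPX={steady.endoDPX:.4g}")

# chronic DPX protocol: 6 h/day, 5 d/wk, 11 wk + 4 d, final 3 h at 15.8 ppm
sched = fd.casanova_schedule(15.8)
traj = fd.integrate(params, fd.DPX_SITE, sched, steady, [1947.0])
print(f"exogDPX(15.8 ppm, 1947 h) = {traj.value_at(1947.0, 'exogDPX'):.3g}")

# dose-response and crossovers over the measured range
curve = fd.dose_response(params, np.geomspace(0.7, 15.0, 9))
for pair in ("DPX", "DG"):
    res = fd.find_crossover(curve, pair, params=params)
    print(f"exog/endo {pair} crossover: {res.ppm:.2f} ppm")
print("min DPX:DG ratios:", {k: round(v, 1) for k, v in fd.dpx_dg_ratio(curve).items()})
```

prints

```
endoF=46.8  endoDG=0.000707  endoDPX=0.02182
exogDPX(15.8 ppm, 1947 h) = 1.25
exog/endo DPX crossover: 2.06 ppm
exog/endo DG crossover: 3.98 ppm
min DPX:DG ratios: {'endo': 32.1, 'exo': 84.5}
```

Read: at the endogenous steady state the mucosa carries ~0.022 pmol/mm³ of
endogenous DPX and ~7e−4 pmol/mm³ of endogenous DG adducts. A 12-week
15.8-ppm exposure drives exogenous DPX to ~1.25 pmol/mm³ (measured: 1.14).
Exogenous DPX overtakes the endogenous background near 2 ppm and exogenous DG
near 4 ppm — below those concentrations the endogenous adducts dominate — and
DPX concentrations stay more than 10-fold above their DG counterparts
everywhere in the measured range.

The same computations are available from the shell:

```sh
formadose steady-state
formadose simulate --protocol casanova --ppm 15.8 --site dpx --out traj.csv
formadose dose-response --ppm-min 0.7 --ppm-max 15 --out curve.csv
formadose convert --value 1 --basis 1e7 --direction to-conc   # 5.49e-4 pmol/mm^3
```

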