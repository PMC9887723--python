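# Methods

`formadose` models the tissue dosimetry of formaldehyde in the nasal mucosa of
the F344 rat: the balance between endogenous formaldehyde produced by
1-carbon metabolism and exogenous formaldehyde absorbed from inhaled air, and
the resulting burden of two DNA lesions — N2-hydroxymethyl-deoxyguanosine
monoadducts (DG) and DNA–protein crosslinks (DPX). The model's purpose is to
predict, per anatomical sampling site, the concentrations of endogenous and
exogenous adducts as functions of the inhaled concentration and exposure
schedule.

## Model structure

The mucosa is a single well-mixed slab of thickness `thick` (mm). Nine state
variables (pmol/mm³ ≡ µM) track free formaldehyde, free glutathione, the
S-hydroxymethylglutathione complex, DG adducts and DPX, with the
formaldehyde-derived pools split by origin (endogenous vs. exogenous):

```
d endoF/dt = kp            − k21·endoF − k23·endoF·GSH + k32·endoF_GSH − (kDNA_DG + kDNA_DPX)·endoF
d exogF/dt = uptake − EC(exogF) − k21·exogF − k23·exogF·GSH + k32·exogF_GSH − (kDNA_DG + kDNA_DPX)·exogF
d endoF_GSH/dt = k23·endoF·GSH − k32·endoF_GSH − ox_endo
d exogF_GSH/dt = k23·exogF·GSH − k32·exogF_GSH − ox_exog
d GSH/dt   = −k23·(endoF + exogF)·GSH + k32·(endoF_GSH + exogF_GSH) + ox_endo + ox_exog
d endoDG/dt  = kDNA_DG·endoF  − krep_DG·endoDG        (exogDG analogous)
d endoDPX/dt = kDNA_DPX·endoF − krep_DPX·endoDPX      (exogDPX analogous)
```

with `ox_endo = Vmax·endoF_GSH / (Km + endoF_GSH + exogF_GSH)` and `ox_exog`
analogous. Exogenous uptake is driven by the CFD-predicted wall mass flux of
the sampling site, linear in the inhaled concentration:
`uptake = flux_per_ppm · ppm / thick` (pmol/mm³/h). Two sites are built in:
the anterior "high tumor" DPX site (800.3 pmol/mm²/h per ppm, 171.6 mm²) and
the larger DG monoadduct site (776.6 pmol/mm²/h per ppm, 419.9 mm²). The CFD
simulation itself is out of scope; its outputs enter only as these two
constants.

### Reconstructed companion equations

Only the free-formaldehyde and DPX balances of this model family are printed;
the glutathione, complex and DG-pool equations are reconstructed here from
the coupling terms those balances contain, and the reconstruction embodies
two explicit choices:

1. **Shared-enzyme competition.** Both complexes are oxidized by one
   formaldehyde-dehydrogenase pool, so each Michaelis–Menten rate carries the
   *total* complex concentration in its denominator. Splitting the enzyme
   into independent pools would let a 15-ppm exposure more than double the
   total oxidation capacity, which has no biochemical basis.
2. **Glutathione conservation.** Oxidation of S-hydroxymethylglutathione
   regenerates free GSH (the enzyme's product is S-formylglutathione, whose
   hydrolysis returns GSH); no synthesis or turnover term is included. The
   moiety total `GSH + endoF_GSH + exogF_GSH` is therefore a conserved
   quantity, which doubles as an integration-accuracy check (drift ≤ 1e−6
   relative in the test suite).

A consistency check supports the reconstruction: the model's endogenous fixed
point is endoF ≈ 46.8, GSH ≈ 4322, endoF_GSH ≈ 304, endoDG ≈ 7.1e−4 and
endoDPX ≈ 0.0219 pmol/mm³ — the endoDG value reproduces both the tabulated
initial value (7.42e−4) and the measured endogenous DG plateau (≈7–9e−4),
none of which were fitted by this package.

### Extracellular clearance variants

`ec_mode` selects an optional clearance of exogenous free formaldehyde:
`zero_order` (rate `ec_rate`, tapered linearly below 1e−6 pmol/mm³ so it can
never drive the pool negative — the behavior at vanishing concentration is
unspecified in the source model) or `saturable`
(`ec_Vmax·exogF/(ec_Km + exogF)`, parameters user-supplied; no quantitative
claims are made for this variant).

With `ec_rate = 2.02e3` pmol/mm³/h the 0.3-ppm repeated-exposure prediction
falls from ≈3.2e−5 to ≈4.1e−7 pmol/mm³ — on the scale of, and here slightly
below, the 5.26e−7 detection limit. Because the clearance nearly cancels the
0.3-ppm uptake (2.047e3 pmol/mm³/h), which side of the detection limit the
prediction lands on is exquisitely sensitive to the reconstructed exogenous
sink terms; the package asserts only the order-of-magnitude suppression.

## Parameters

Defaults are the published calibrated set (units in
`formadose.parameters`): kp = 10 835 pmol/mm³/h, k21 = 16.57 /h,
k23 = 0.35 mm³/pmol/h, k32 = 200 /h, kDNA_DG = 9.5183e−8 /h,
kDNA_DPX = 1.8183e−4 /h, krep_DG = 0.0063 /h, krep_DPX = 0.39 /h,
Vmax = 74 156 pmol/mm³/h, Km = 1935 pmol/mm³, thick = 0.1138 mm. The tabulated
initial concentrations are approximate; simulations therefore start from the
model's own endogenous fixed point (below), with the literal published
initialization available as `burn_in=False`.

## Numerics

* **Fixed point.** The zero-exposure steady state reduces to a single scalar
  root problem: summing the formaldehyde and complex balances shows the
  oxidation flux must equal `kp − (k21 + kDNA_DG + kDNA_DPX)·F`, which fixes
  the complex concentration, and the complex balance then closes one equation
  in F, solved by bracketed bisection (`brentq`). An ODE burn-in fallback
  covers parameter sets where the bracket fails, and the two routes agree to
  1e−4 relative in the tests. Adduct fixed points follow algebraically
  (`endoDG = kDNA_DG·F/krep_DG`, etc.), so the result is independent of the
  starting adduct burden.
* **Integration.** Exposure is a square wave, so every episode edge is an
  integration restart; each constant-uptake segment is solved with LSODA
  (stiff-capable; the rate constants span nine orders of magnitude) at
  rtol = 1e−8, atol = 1e−12 pmol/mm³. Solver noise below 1e−9 pmol/mm³ is
  clipped to zero; more negative states raise an error. A fixed-step
  classical RK4 integrator (`integrate_rk4`) serves as a brute-force oracle:
  on a 24-h, 2-ppm run the two agree within 0.1% relative above an absolute
  floor of 1e−9 pmol/mm³ (below the floor the exogenous pools are physically
  zero and relative error is meaningless).
* **Fitting.** Cost is relative least squares,
  `Σ((pred−obs)/obs)²` — the observations span four orders of magnitude, so
  absolute least squares would fit only the top decade. A log-residual
  variant (`residual="log"`) is provided; the exact weighting used for the
  published fit is not recoverable. Non-detects and the dG-specific
  crosslink (DPC) rows never enter the cost. Bounds are enforced by the sine
  transform `x = lo + (hi−lo)(sin u + 1)/2` around Nelder–Mead (simplex
  tolerances 1e−4 on size, 1e−6 relative on cost spread, 2000 iterations
  max; hitting the cap flags `converged=False`). The two-stage procedure
  first fits `thick` separately against the DG-site and DPX-site datasets
  with their own fluxes, then refits jointly with one shared `thick`
  initialized at the geometric mean of the stage-1 values.

## Exposure protocols

Three published protocols are built in, and their printed sampling times are
reproduced exactly:

* `single_exposure(ppm)` — 6 h at `ppm` from t = 0, sampled at 7 h (1 h
  post-exposure).
* `daily_schedule(ppm, n_exposure_days=28, ...)` — 6 h/day consecutive days;
  day *n* occupies [24·n, 24·n + 6) h, i.e. t = 0 sits one day before the
  first exposure, which is the origin that reproduces the published sampling
  times (175 = 24·7 + 7, …, 679 = 24·28 + 7; post-exposure 684–846 h).
* `casanova_schedule(ppm)` — 6 h/day, 5 days/week for 11 weeks and 4 days
  (59 six-hour episodes), then 3 h on the 5th day of week 12 with sampling
  immediately after. Published times for this protocol are counted from the
  start of the first exposure, so calendar day *d* occupies
  [24·(d−1), 24·(d−1)+6) and the final episode is [1944, 1947) h.
* `leng_schedule(ppm)` — 28 consecutive 6-h/day exposures from t = 0,
  sampled at 672 h.

Square waves with instantaneous on/off are used throughout; no chamber ramp
or breathing-cycle resolution (site fluxes are breath-averaged).

## Dose-response conventions

Each adduct class is evaluated under the protocol of the study that measured
it: DPX under the chronic schedule (sampled at 1947 h), DG by default under
the repeated daily schedule at its quasi-plateau (sampled at 679 h of a
28-day course). This pairing is what makes the two crossovers mutually
consistent — fast-repaired DPX (t½ = ln 2/0.39 ≈ 1.78 h) tracks the
concurrent exposure while slowly repaired DG (t½ ≈ 110 h) integrates the
exposure history. With it, the exogenous DPX curve crosses the endogenous one
at ≈2.1 ppm and the exogenous DG curve at ≈4.0 ppm. Under the alternative
single-exposure DG mode (`dg_protocol="single"`) the DG crossover moves to
≈9–10 ppm because a single 6-h dose accumulates far less DG than a month of
repeated exposures. Crossovers are located by bisection on log-ppm to 1%
relative precision, re-simulating at each midpoint.

## Units conversion

Monoadduct data reported as adducts per 10⁷ dG (DPC: per 10⁸ dG) convert to
pmol/mm³ via `x · (ploidy · genome_bp · g_fraction / basis) / cell_volume /
N_A · 1e12`, with genome_bp = 3.024e9, g_fraction = 0.41,
cell_volume = 7.5e−7 mm³. The ploidy convention of the original conversion is
not visible in the source material, so ploidy is an explicit, auditable
constant (default 2, diploid nucleus); with it 1 adduct/10⁷ dG ↔ 5.49e−4
pmol/mm³, and the round trip is exact to machine precision.

## Synthetic data and what recovery tests show

`generate_synthetic_observations` simulates a protocol battery at a known
parameter set and applies multiplicative lognormal noise
(`value = pred·exp(σZ)`, `σ² = ln(1 + cv²)`, median-unbiased), emulating the
between-animal scatter of the measured dataset at a default CV of 20%. The
default recovery battery uses single 6-h exposures at 2 and 15 ppm sampled at
1–10 h on both sites — cheap to simulate while exercising endogenous
production, uptake, conjugation saturation and both adduct channels. A
zero-noise refit started at 1.5× truth recovers (kp, k21, Vmax, Km, thick)
to well under 5%; at 20% noise the median recovery error of kp and thick
stays under 25% across replicate datasets (the identifiable pair; Vmax/Km
are mutually correlated below saturation and are reported, not asserted
tight). What these tests do *not* show: identifiability under the real
studies' sparse designs, robustness to structural error in the reconstructed
companion equations, or anything about inter-animal kinetic variability —
the generator reproduces the model's own kinetics by construction.

## Problem sizes

The packaged analyses use a 9-point log-spaced grid over the measured
0.7–15 ppm range for dose-response curves (each grid point runs one chronic
and one 28-day simulation), bisection refinement to 1% for crossovers, and
9 replicate datasets in the noisy-recovery experiment — the package's chosen
balance of resolution against simulation cost; all are parameters.

## Known limitations

* The companion equations are a documented reconstruction; absolute adduct
  predictions inherit that structural uncertainty (the worked-example checks
  use factor-2–3 tolerances for this reason, while ratio, conservation and
  timing properties are tested tightly).
* Single well-mixed slab: no mucus layer, no intracellular
  compartmentalization of 1-carbon metabolism, uniform enzyme activity and
  thickness across the mucosa.
* The model cannot reproduce the reported low-dose DG non-detects and the
  positive 0.32-ppm DPX measurement with one parameter set (the published
  analysis reached the same conclusion); the clearance variants are
  structural probes, not calibrated claims.
* DPC (dG-specific crosslink) data are carried as fixtures only and never
  modelled.
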