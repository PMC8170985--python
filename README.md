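# myofoam

A desk-scale re-implementation of the computational machinery used to study
how muscle-tissue stiffness affects occupant response in crash simulation:

* **material model** — a hyperelastic, compressible, Ogden-type foam
  material evaluated from principal stretches, driven by engineering
  stress–strain curves with an ordinate scale factor (SFO) and optional
  strain-rate tables; curve-to-constants fitting by linear least squares;
* **explicit FE mini-solver** — trilinear hex8 elements with full 2×2×2
  Gauss quadrature, lumped mass, central-difference time integration under
  the CFL critical step, selective mass scaling to a target step (dt2ms),
  and rigid-plane penalty contact with an energy audit;
* **metrics** — effective (von Mises) stress, effective strain, accumulated
  effective plastic strain, spatial logarithmic strain, and linear-fit
  Young's-modulus estimation over the high-load window;
* **injury post-processing** — threshold-based failed-element volume, the
  cumulative strain damage measure (CSDM, default threshold 59% = 95% mean
  failure elongation minus one 36% s.d.), peak contact-force extraction, and
  pluggable force→probability risk curves;
* **fixtures** — deterministic generators for the 8-element 1 mm cuboid
  model, a unit uniaxial coupon, a drop-impact block, and synthetic element
  histories with closed-form expected outputs;
* **I/O and CLI** — a keyword-deck subset reader/writer (`*NODE`,
  `*ELEMENT_SOLID`, `*PART`, `*MAT_SIMPLIFIED_RUBBER/FOAM`,
  `*DEFINE_CURVE`, `*DEFINE_TABLE`, `*CONTROL_TIMESTEP`,
  `*CONTROL_TERMINATION`; comma and fixed-width dialects), CSV history
  files with a JSON run manifest, and a `myofoam` command line.

Everything runs in SI units internally; decks default to the mm–ms–kg
system (stresses in GPa). No external dataset is required — all inputs are
generated by the fixtures module.

## Command line

```bash
# generate a fixture deck (and optionally simulate it in one go)
myofoam fixture cuboid8 --sfo 2.0 --out out/cuboid8 --run

# simulate a deck
myofoam simulate out/cuboid8/deck.k --units mm_ms_kg --seed 1 --out out/hist

# fit material constants to a 2-column strain,stress CSV
myofoam fit curve.csv --nu 0.3 --out constants.json

# effective-field peaks and stiffness fits from histories
myofoam metrics out/hist

# failed-element volume, CSDM and force-based risk
myofoam injury out/hist --field effective_plastic_strain --threshold 0.015 \
    --csdm-threshold 0.59 --risk-curve hip_risk.csv --out report.json
```

## Notes on conventions

* The volumetric penalty exponent defaults to the standard compressible-foam
  relation `n = nu / (1 - 2 nu)`, under which uniaxial lateral contraction
  follows `l_lat = l_axial^-nu`; the sign-flipped printed variant is
  available as `convention="paper"`.
* `KM` feeds only the wave-speed/time-step estimate and contact stiffness;
  `MU` and `SIGF` are parsed and stored without constitutive effect.
* The von Mises formula is implemented with all three principal-difference
  terms squared (`sqrt(3 J2)` of the deviator).
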