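# kinpot — kinetic potentiometry of peroxyl-radical inhibition

`kinpot` is a toolkit for the potentiometric study of antioxidants in
azo-initiator radical-generating systems.  It is aimed at analytical and
redox-biochemistry groups who run (or model) AAPH-based assays in which a
platinum electrode tracks the peroxyl-radical population, and who want both
the **thermodynamic** side of inhibition (how many radicals an antioxidant
scavenges) and the **kinetic** side (how fast it reacts).

## The chemistry and the measurements

A thermally unstable initiator I (AAPH, typically 0.1 M at 37 °C)
decomposes first-order and generates peroxyl radicals at rate
*W*ᵢ = 2 *k*ᵢ [I]; the radicals recombine (lumped constant 2*k*₂) or are
scavenged by an antioxidant InH (constant *k*ᵢₙₕ, stoichiometry *q*):

    I → 2 RO₂•                       Wᵢ = 2 kᵢ [I]
    RO₂• + RO₂• → products           (2k₂)
    RO₂• + InH → RO₂⁻ + products     (kinh, q radicals per molecule)

The electrode potential follows the radical population Nernstian-ly,
E(t) = E₀ + (RT/F)·ln([RO₂•]/c_ref).  From a recorded trace the package
extracts:

* **Antiradical capacity** ARC = *W*ᵢ·τ, with the induction period τ read
  at the maximum of the smoothed derivative (dE/dt)ₘₐₓ;
* **Inhibition rate constants** from residual-concentration kinetics:
  aliquots are quenched into a K₃[Fe(CN)₆]/K₄[Fe(CN)₆] cell whose
  potential shift returns the residual concentration
  (C_AO = n·(C_Ox − αC_Red)/(1+α), α = (C_Ox/C_Red)·10^((E₂−E₁)F/2.303RT));
  the initial semilog slopes a = kinh·[RO₂•]ₛₛ measured at several starting
  concentrations are extrapolated to zero load, where
  kinh = a₀ / √(Wᵢ/2k₂);
* **Area-above-Exp(ΔE)** capacity statistics ("initial-rate" and
  "fixed-time" conventions), the robust choice for slow antioxidants and
  mixtures that show no usable inflection.

A first-class synthetic-data module simulates the whole measurement chain
(stiff ODE kinetics, electrode law, mediator cell, electrode noise and
drift) so every estimator is testable end to end without instrument data.

## Worked example

Recover an inhibition rate constant from a simulated three-concentration
experiment (0.05/0.1/0.2 mM antioxidant in 0.1 M AAPH, aliquots every
120 s through the 1 mM/0.01 mM ferri/ferrocyanide cell):

```python
from kinpot import AntioxidantSpec, RateParameters
from kinpot.rate_constant import full_recovery_pipeline

params = RateParameters()            # 0.1 M AAPH, ki=1e-6 s^-1 -> Wi=2e-7 M/s
truth = AntioxidantSpec("ascorbic", 1e-4, 3.95e3, q=2.0)
res = full_recovery_pipeline(truth, [5e-5, 1e-4, 2e-4], params)
print(res.summary())
```

```
Inhibition rate-constant estimation
===================================================
estimator:            kinetic_slope
n series / n samples: 3 / 31
Wi:                   2e-07 M/s
2k2:                  5e+04 1/(M s)
sqrt(Wi/2k2):         2e-06 M
---------------------------------------------------
   c0 (mM)     a (1/s)       SE          R^2
   0.05       0.0023374     0.00017     0.99487  [window extended]
   0.1        0.0011085     4.4e-05     0.99843  [window extended]
   0.2        0.00054685    1.2e-05     0.99909
---------------------------------------------------
a0 (c0 -> 0):         0.0079 1/s (SE 7e-10)
kinh:                 3950 M^-1 s^-1 (SE 0.00035)
kinh (printed scale): 3.950 x10^3 M^-1 s^-1
```

The slopes fall steeply with concentration (radical competition), and the
kinetic-form fit recovers the generating constant exactly; a straight-line
extrapolation of the same three points would return ≈1.3×10³ — see
`docs/methods.md` for why the default estimator fits the kinetic curve
instead of a line.

The same experiment from the shell:

```bash
kinpot simulate --config experiment.yaml --out run1
kinpot arc --trace run1_trace.csv --wi 2e-7
```

```json
{
  "tau_s": 601.0,
  "inflection_t_s": 901.0,
  "arc_M_eq": 0.0001202,
  "arc_mM_eq": 0.1202
}
```

A 0.075 mM fast antioxidant (q = 2) absorbs ≈0.12 mM-eq of radicals before
the potential inflects; the value sits below the naive capacity q·c₀ =
0.15 mM-eq because the inflection fires when a residual concentration
c* ≈ 0.78·2√(2k₂Wᵢ)/(q·kinh) is still unscavenged (`docs/methods.md`).
Traces of "slow" antioxidants (kinh ≲ 8×10²) have no interior derivative
maximum; `kinpot arc` then exits with error class `no_inflection` and the
area statistics (`kinpot area`) are the appropriate measure.

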