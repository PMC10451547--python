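# Methods

This note documents the model, the numerical choices, and the design
decisions behind `kinpot`, including what the synthetic-data generator does
and does not emulate.

## Kinetic scheme

The simulator integrates

    d[I]/dt    = −kᵢ[I]
    d[RO₂•]/dt = 2ε·kᵢ[I] − 2k₂[RO₂•]² − Σⱼ sⱼ·kinhⱼ·[RO₂•][InHⱼ]
    d[InHⱼ]/dt = −kinhⱼ·[RO₂•][InHⱼ]

with running integrals of generated, recombined and scavenged radicals
carried as extra states so mass balance is available to solver precision
(measured residual ~1e-15 relative; the tested invariant is ≤1e-3).

Parameters and defaults, with rationale:

| parameter | default | units | note |
|---|---|---|---|
| kᵢ | 1×10⁻⁶ | s⁻¹ | AAPH decomposition at 37 °C; gives Wᵢ = 2×10⁻⁷ M/s at 0.1 M |
| 2k₂ | 5×10⁴ | M⁻¹s⁻¹ | lumped recombination; 2.6×10⁴ is a defensible alternative and is configurable |
| [I]₀ | 0.1 | M | standard initiator load |
| ε (efficiency) | 1.0 | – | cage-escape efficiency, configurable |
| q | 2 | – | radicals scavenged per antioxidant molecule; per-species override |
| sⱼ | qⱼ | – | radical consumption per inhibition event; a variant with sⱼ=1 (q only in capacity accounting) is selectable |

Antioxidant rate constants are second-order (M⁻¹s⁻¹); the conventional
"fast" group spans (1.05–9.25)×10³ and the "slow" group (4.0–8.5)×10².
A pseudo-first-order loss of radicals to ferrocyanide can be enabled
(`ferrocyanide_side_reaction=True`); it is off by default because at assay
concentrations its flux share is negligible.

The solver is LSODA at rtol 1e-8 / atol 1e-12.  Antioxidant addition at
t_add splits the integration into an inert phase and an active phase, so
the addition discontinuity never passes through the stiff solver.

**QSSA mode** replaces the radical ODE by the non-negative root of
2k₂x² + Lx − Wᵢ = 0 (L = Σ sⱼkinhⱼ[InHⱼ]), computed in a cancellation-free
form.  It is accepted only when the radical relaxation rate
(2·2k₂x + L) times the grid spacing exceeds 10.  Full-vs-QSSA inhibitor
curves agree to ≤0.7% of c₀ across the tested grid; the deviation is
quoted relative to c₀ because any finite transient offset diverges in
pointwise relative terms as c→0.

## Electrode model and Exp(ΔE)

E(t) = E₀ + (RT/F)·ln(max([RO₂•], 10⁻¹⁵ M)/c_ref) at 310.15 K (the floor
keeps the pre-initiation trace finite).  Exp(ΔE) = exp((E−E_baseline)/E_s)
with the baseline averaged over the 30 s before addition.  E_s is the one
deliberately loose constant of the method: with E_s = RT/F the series is
exactly a radical-concentration ratio; the default E_s = 1 V matches the
magnitude convention of published area tables.  Areas integrate
max(0, 1−Exp(ΔE)) trapezoidally; the initial-rate variant stops at the
return to within 10⁻³ of unity (an exact crossing of 1.0 never occurs on
noise-free traces because initiator depletion leaves the recovered
potential a fraction of a millivolt low), the fixed-time variant uses a
1200 s window.

The mediator cell (1 mM K₃[Fe(CN)₆] / 0.01 mM K₄[Fe(CN)₆], 25 °C) is
modelled stoichiometrically: a spike x converts Ox→Ox−x, Red→Red+x, and
the inverse formula C_AO = n·(C_Ox−αC_Red)/(1+α) recovers the sample
concentration, with n the sample dilution into the cell (the forward spike
is c/n).  Forward/inverse round trips are exact to 1e-10 relative and the
delta-method error propagation
sd(C_AO) = n(C_Ox+C_Red)·α/(1+α)²·(F/RT)·√2·σ_E is validated against
Monte Carlo.

## Induction period and ARC

τ is read at the maximum of the Savitzky–Golay first derivative of the
post-addition segment (polyorder 3).  The generic derivative operator
defaults to a 31-point window at 1 Hz; inflection *detection* uses an
adaptive window of ~10% of the post-addition segment (clipped to
[31, 241] points), because the inflection hump is several hundred seconds
wide and the wider window buys a ~10× reduction in derivative noise
without shifting the peak.  Pre- and post-addition segments are filtered
separately so the sharp addition drop cannot leak into either.

A trace is classified "inflection present" only if the derivative maximum
is (1) an interior maximum of the search region (t ≥ t_add + max(60 s,
gap + half-window)), (2) at least 8× the pre-addition derivative floor,
and (3) at least 8 standard deviations above the derivative noise
propagated from the trace's own high-frequency potential residual.  The
shape criterion is not heuristic: under the log-radical electrode law the
derivative peaks exactly when the dimensionless load
u = q·kinh·c/(2√(2k₂Wᵢ)) falls through u* = 0.782 (root of
u(2+u²) = (1+u²)^{3/2}).  Antioxidants whose initial load u₀ ≤ u* produce
a monotonically decaying derivative — no interior maximum, hence "no
inflection".  At c₀ = 0.1 mM and q = 2 the boundary sits at
kinh ≈ 7.8×10², which reproduces the empirical fast(≥1.05×10³)/slow
(≤8.5×10²) split.  At 0.5 mV noise the detector is calibrated to 30/30
detection for kinh = 3.95×10³ and 0/30 false positives for slow and
inert-control traces; borderline compounds (kinh ≈ 1×10³) are resolved
noise-free but not reliably under noise — consistent with the induction
method being ill-suited to slow antioxidants.

**Known bias.** Because the detection concentration c* =
u*·2√(2k₂Wᵢ)/(q·kinh) is still unscavenged at the inflection, ARC = Wᵢ·τ
systematically undershoots the capacity q·c₀ (by ~20% for 0.075 mM of a
3.95×10³ antioxidant).  The inflection time itself matches the c* crossing
of the simulated trajectory to ±2 s, and d(ARC)/d(c₀) ≈ q within 5% (c*
only shifts the intercept).  Experimental traces show sharper inflections
than the idealized Nernstian-log response, so measured capacities can sit
closer to q·c₀ than this model predicts.

**Mixtures.** With a fast and a slow antioxidant both at 0.075 mM
(kinh = 3.95×10³/7.5×10², q = 2) the slow component takes a growing share
of the radical flux, delaying the fast component's depletion: the
simulated inflection moves ~20–30% later and the mixture ARC exceeds the
fast-alone ARC.  The experimental observation that the inflection barely
moves implies the slow species scavenges a negligible flux share in
reality (e.g. aggregation-limited accessibility of tocopherol in water) —
a feature outside this kinetic scheme.  The fixed-time area, by contrast,
robustly increases upon adding the slow component, here and
experimentally.

## Rate-constant estimation

The measured statistic per series is the initial semilog slope: an OLS fit
of ln c vs t over samples with c ≥ 0.8·c₀ (≥3 points; with 120 s aliquots
and fast antioxidants fewer than 3 samples stay inside that window, in
which case the window widens to the first three positive samples and the
fit is flagged).  Estimators, in `InhibitionRateModel.fit(method=...)`:

* `kinetic_slope` (default): 1-D least squares of measured vs model
  slopes over log₁₀kinh, the model slopes produced by applying the
  identical extraction procedure to simulated curves.  Exact on
  noise-free data by construction.
* `trajectory`: weighted least squares of the full aliquot concentration
  curves, weights 1/sd² from the mediator-cell delta method.
  Recommended under noise: at 0.5 mV electrode noise the median recovery
  error over kinh ∈ [4×10², 10⁴] is ~2%, versus ~20% for the slope
  statistic alone (initial slopes saturate at high load:
  d ln a/d ln kinh = 1 − u/√(1+u²) ≈ 0.02 at u ≈ 5).
* `linear` / `quadratic`: the classical graphical extrapolation of a(c₀)
  to c₀ = 0.  Retained for comparability, but strongly biased low
  whenever the load rivals recombination: a(c₀) = kinh·x_ss(c₀) follows
  the root of the balance quadratic and is far from affine over
  0.05–0.2 mM (a straight line through the ascorbate-class design
  recovers ~⅓ of the true constant).

All estimators report kinh = a₀/√(Wᵢ/2k₂) with a₀ the zero-load limit of
the slope; uncertainty comes from the objective curvature at the optimum
(approximate, reported as such).  `build_surface()` precomputes model
responses on a log-kinh grid for fast refitting of many replicates of the
same design.  Species flagged `mediator_compatible=False`
(thiadiazine-like transformation kinetics) are refused with a
`not_applicable` error rather than a number.

## Synthetic data

The generator emulates: the 0.1 M AAPH / 37 °C generation cell,
antioxidant addition at 300 s into an 1800 s, 1 Hz trace; additive
Gaussian electrode noise (σ = 0.5 mV) plus Wiener drift (0.02 mV/√s);
aliquot sampling every 120 s through the 25 °C mediator cell with noise on
both potential readings (so series carry measurement error, not truth).
PRNG: `numpy.random.default_rng` (PCG64) with an explicit seed recorded in
every truth record; identical seeds reproduce outputs byte-for-byte.

It does **not** emulate: temperature drift between cells, electrode
double-layer/junction effects, activity corrections, oxygen depletion,
co-oxidizable substrates, or any sharpening of the inflection beyond the
Nernstian-log response.  Passing tests therefore demonstrate the internal
consistency and statistical performance of the estimators under the
stated model, not instrument-level accuracy on real traces.

## Problem sizes used in tests and the acceptance script

Rate-constant recoveries use the three-concentration design
(0.05/0.1/0.2 mM) with 120 s aliquots over the capacity time q·c₀/Wᵢ
(5–17 samples per series).  The recovery grid spans 10 log-spaced kinh
values in [4×10², 10⁴] with 50 noise replicates each, fitted through a
shared 50-point response surface.  Traces are 1800–3000 s at 1 Hz.  These
sizes keep the full suite around ten seconds on one CPU while leaving all
tolerances comfortably resolved.

## Known limitations

* ARC from (dE/dt)ₘₐₓ inherits the c* bias described above; comparisons
  across instruments should calibrate against a known antioxidant.
* Area statistics depend on the Exp(ΔE) scale E_s, which published tables
  do not pin down; only orderings and concentration-monotonicity are
  scale-free.
* The stoichiometric factor q is assumed, not estimated; mis-specifying q
  rescales capacities and (weakly) the recovered kinh.
* The estimation of kinh for very fast antioxidants (u ≫ 1 at the lowest
  design concentration) is intrinsically ill-conditioned from slopes
  alone; prefer the trajectory estimator or extend the design downward in
  concentration.
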