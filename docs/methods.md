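# Methods

## Decay chain and nuclear data

The ²¹³Bi chain is modelled as
²¹³Bi → (β⁻, b = 0.9791) ²¹³Po → (α) ²⁰⁹Pb and
²¹³Bi → (α, b = 0.0209) ²⁰⁹Tl → (β⁻) ²⁰⁹Pb → (β⁻) ²⁰⁹Bi, with ²⁰⁹Bi as
a stable sink. Half-lives: ²¹³Bi 45.6 min, ²¹³Po 4.2 μs, ²⁰⁹Tl 2.16 min,
²⁰⁹Pb 3.25 h; the daughter half-lives come from standard decay tables
and are overridable through `load_chain(half_life_overrides=...)` or the
YAML chain file, since they enter the Bateman solution directly.

Emission data per decay: α lines 5.87 MeV (y = 0.0209, ²¹³Bi) and
8.38 MeV (y = 1.0, ²¹³Po) with SRIM CSDA ranges 46.47 and 81.75 μm in
water; β⁻ spectra with endpoints 1.422 / 1.944 / 0.644 MeV and tabulated
mean energies 0.434 / 0.655 / 0.197 MeV (ESTAR ranges at both energies).
Some published tabulations print 1.94 %/decay for the ²¹³Bi α abundance;
that number is consistent only with the α S-value at 10 μL, not with the
decay scheme, so 2.09 % is used. The 440 keV γ of the ²¹³Bi branch
carries its measured yield (0.261); all other γ and the conversion/Auger
electrons are folded into minimal *effective* lines flagged
`approximate=True` — they contribute ≲ 4 % of any dose quantity here,
and the flag is honest about their provenance. α-recoil nuclei (112 and
160 keV) are stored but excluded from S-values by default; their sub-μm
ranges would deposit locally, and the published reference S-values are
reproduced without them (an `include_recoils` flag adds them).

## Bateman kinetics

Activities follow closed-form branching Bateman solutions from a
pure-²¹³Bi start. The 4.2 μs ²¹³Po half-life makes the textbook
coefficients ill-conditioned (λ_Po/λ_Bi ≈ 7·10⁸), so ²¹³Po uses the
transient-equilibrium form A_Po = b_β·A_Bi·(1 − e^(−λ_Po t)), and ²⁰⁹Pb
ingrowth treats ²¹³Po as an instantaneous pass-through; both carry a
relative error of order λ_Bi/λ_Po ≈ 10⁻⁹. Time-integrated activities are
analytic integrals of the same exponential sums. The default time grid
(600 points, logarithmic to 60 s then linear) resolves the 2.16 min
²⁰⁹Tl ingrowth without large grids. Correctness is checked against an
independent fixed-step (1 ms) linear-propagator integration of the chain
ODEs, which agrees to better than 10⁻⁶ relative over 10 min.

## Vial geometry

The 1 mL vial is a full cone, apex at the origin, height 20 mm, with the
half-angle fixed by capacity: (π/3)h³tan²θ = 1000 mm³ gives
tanθ = 0.3455 (θ ≈ 19.1°). Both parameters are configurable; at the
relevant particle ranges the absorbed fractions are controlled by the
fluid surface-to-volume ratio, which this parameterization sets. Fill
height follows h(V) = (3V/(π tan²θ))^(1/3). Source points are sampled
uniformly in the fluid by inverse CDF in cone coordinates with isotropic
directions; boundary distances are exact ray–cone / ray–plane
intersections. The polyethylene wall (0.65 mm, 0.9 g/mL) and the air
above the fluid are non-scoring absorbers: energy crossing the fluid
boundary is "escaped", and backscatter is neglected — expected to bias
β absorbed fractions low by a few percent relative to a full transport
code.

## Particle transport

Charged particles travel in straight lines under the continuous-slowing-
down approximation. The range–energy relation is piecewise log-log
(locally R = k·Eᵖ) through the calibration points — exact at SRIM/ESTAR
values, power-law extrapolated beyond; a single global power law misfits
the electron points by up to 9.5 %, which is why the piecewise form is
used. Deposited energy per history is E − E(R(E) − d) with d the
boundary distance and E(·) the inverse range model; electrons with
residual energy below 1 keV deposit locally. β⁻ energies are rejection-
sampled from the allowed shape p·W·(E_max−E)² times the **relativistic**
point-charge Fermi function (γ₀ = √(1−(αZ)²), |Γ(γ₀+iη)|²); at Z ≈ 83
the non-relativistic correction underweights the low-energy end and
misses the tabulated mean β energies by > 20 %, while the relativistic
form lands within 14 % (the residual bias comes from unresolved branches
to excited daughter states — the model uses a single endpoint per
spectrum). γ-rays use a single-interaction model: mean first-interaction
probability inside the fluid times μ_en/μ at the line energy (NIST water
coefficients, log-interpolated); this is adequate for a component that
never exceeds ~0.1 % of the total S-value and is flagged approximate.

S-values are S(V) = Σᵢ yᵢ·Eᵢ·φᵢ(V)·C/m(V) with
C = 1.602·10⁻¹³ J/MeV × 10⁶ decays/(MBq·s), E the mean energy for
spectra, and m(V) the fluid mass. Each (nuclide, line, volume) task
draws from an independent stream derived from one master seed, so a
fixed seed yields bit-identical tables; standard errors come from
20-batch statistics. Default histories: 10⁶ per task (seconds per table
on one core; standard errors of φ are well below 1 %), configurable
upward.

**Validation route, independent of any reference numbers:** α absorbed
fractions from the cone engine are compared with a deterministic
chord-length quadrature for a uniform source in a sphere of equal
volume. The sphere has slightly less surface than the cone, so the
oracle brackets the engine within 1 % absolute at α ranges ≪ vial size;
the suite enforces that band before any comparison to published values.

**Known bias:** replacing condensed-history electron physics with
straight-line CSDA overestimates electron escape (real electrons
scatter, shortening their displacement). β⁻ absorbed fractions at the
smallest fill volume sit ≈ 19 % below the published MCNP values, within
the ±20 % band expected for this simplification; at 800 μL the deviation
is < 2 %. All headline dose quantities are α-dominated, and the α
results agree with published values to ≲ 1 %.

## Dose and molar-energy metrics

D(t) = Σ_n S_n·A_n(t), tracked per component and nuclide. Cumulative
dose integrates the total rate by trapezoid with grid-doubling
refinement until the end-point changes by < 0.1 %; it cross-checks
against the closed form Σ_n S_n·Ã_n(T). The "initial" dose rate is
evaluated with ²¹³Po at instantaneous equilibrium and ²⁰⁹Tl/²⁰⁹Pb at
zero — the only physically meaningful t = 0⁺ state for this chain.
Absorbed power is dose rate × fluid mass; the molar energy rate divides
by the compound amount, and the time to reach a molar-energy threshold
(e.g. the ~65 kJ/mol DOTA ring-inversion activation energy) treats the
rate as constant over the first seconds (error < 0.1 % for a 45.6 min
parent). Dose is the bulk average over the fluid; no microdosimetry.

## Chemistry calculators

Carrier-free specific activity is λ·N_A per mole (152.6 GBq/nmol for
T½ = 45.6 min), scaled linearly by the metal:chelator mole ratio.
Osmolarity counts fully dissociated NaI and HCl twice and TRIS/ascorbic
acid once; the peptide and DTPA (≲ 10⁻⁴ Osmol/L) are neglected. This
simple model reproduces both the standard (0.71) and optimized (0.45
Osmol/L) recipe values. Dilution scales every component by
aliquot/final volume; for the clonogenic-assay dilution (400 μL into
8.4 mL) the computed DTPA concentration is 3.0·10⁻³ mmol/L — the
published figure of 6.1·10⁻³ is consistent instead with DTPA dissolved
in the 400 μL aliquot; the calculator reports the computed value and
leaves the discrepancy visible rather than patching it.

The incorporation curve is a logistic
I(m) = asymptote/(1 + e^(−(m−m₅₀)/s)) fitted by `scipy.optimize.curve_fit`
with the asymptote bounded at 100 %; with fewer than five distinct
peptide amounts the asymptote is fixed to the plateau mean (the
3-parameter fit is unstable on sparse designs). The functional form is a
choice — the underlying data are only described as S-shaped — and probit
would fit comparably; logistic is standard for dose–response work.
Standard errors come from the fit covariance; non-increasing data raise
a `FitError` with diagnostics instead of silently converging. The
ascorbic-acid requirement uses the empirical anchor 0.9 mmol/L at
~200 Gy in 800 μL, constant below and linear in dose above; the linear
extrapolation is a modelling choice and results above the anchor carry
an `extrapolated` flag.

## Synthetic data

`gen_incorporation` draws replicate ITLC yields from the logistic truth
(m₅₀ = 2.4 nmol, s = 0.25 nmol, asymptote 99 %) plus Gaussian noise
(σ = 3 % default) clamped to [0, 100]; the default design covers the
measured amounts (1.7, 3.5, 7.0 nmol, n = 3) plus transition points
around the midpoint, without which the slope would be unidentifiable.
`gen_stability` models RCP(t) = RCP₀(c)·e^(−k(c)t) with baseline RCP₀
taken from the measured post-labelling values per quencher level and a
decay rate falling linearly to zero at 0.9 mmol/L ascorbic acid. The
exponential decay and the k(c) form are modelling choices — the real
curves are shown but not parameterized — so passing recovery tests
demonstrates that the fitting pipeline is consistent with its own model
class, not that real radiolysis follows an exponential. Truth parameters
are always attached to the generated frames. Clamping biases values near
the bounds slightly; recovery tests use interior design points.
Calibration: the logistic fit recovers m₅₀ within 3 SE in ≥ 95 % of 200
seeded replicate datasets.

## Problem sizes

Monte Carlo defaults are 10⁶ histories per emission and volume — at the
vectorized engine's throughput this keeps a full six-volume table under
a minute while holding Monte Carlo standard errors far below the physics
bias of the transport model; 10⁷ is available via configuration when
tighter statistics are wanted. The fixed-step kinetics oracle uses 1 ms
steps over 10 min via matrix powers.

## Limitations

* Straight-line CSDA electron transport (no lateral scattering, no
  backscatter from the wall): β⁻ quantities carry up to ~20 % relative
  bias at small fill volumes.
* Single-endpoint β spectra; branches to excited states unresolved.
* Effective single-line γ and conversion/Auger bundles, order-of-
  magnitude faithful only (flagged in the data).
* The exact vial shape is a parameterized cone; real conical vials have
  a cylindrical upper section, which matters only through the
  surface-to-volume ratio at these particle ranges.
* No microdosimetry: doses are bulk averages over the fluid, while
  radiolysis chemistry happens along α tracks.
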