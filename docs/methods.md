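# Methods

This note documents the models, estimators, numerical choices and
limitations behind `aspdyn`, and what the synthetic-data tests do and do
not establish about real data.

## Biosensor time courses

The ratiometric aspartate sensor reports as GFP/RFP per well. RFP comes
from a constitutively expressed nuclear protein, so the ratio cancels
expression and cell-number effects; nuclei counts are normalized to the
pre-treatment scan. Dividing the ratio itself by its pre-treatment value
is optional but on by default: panels from wells with different sensor
expression become comparable, and the operation is invertible. Sensor
output is *not* converted to millimolar — no sensor calibration is
assumed — so rebound descriptors operate on ratio units and are invariant
to positive rescaling.

Proliferation rates use the two-point doubling formula
`log2(final/initial)/days`, matching the counting practice the data come
from; windowed rates tile the trace from the pre-treatment scan (default
6 h windows) and use each window's first and last counts. A regression
variant (`regression=True`, OLS on log2 counts) is available for noisy
counts; on exact exponentials the two agree to machine precision.

Nadir detection smooths with a centered moving average (default width 3
samples — scans arrive several times a day, so this suppresses scan noise
without displacing a 24 h-scale feature) and takes the global minimum
after the first sample. The rebound fraction is
`(final - nadir)/(initial - nadir)` clipped to [0, 1]; traces whose dip is
below 1e-9 of the trace scale are classified flat (monotonic), and a
configurable threshold (default 0.05) separates monotonic declines from
rebounds.

## Exchange fluxes

Evaporation concentrates the medium, so concentrations are not conserved;
amounts are. With `A(t) = c(t) V_media(t)` and exponential cell growth
`V(t) = V0 e^{mu t}`, the net exchange flux (uptake positive) is

    F = -[A(t1) - A(t0)] / \int_{t0}^{t1} V0 e^{mu t} dt      [mM/h]

with the integral in closed form and the `mu -> 0` limit handled
analytically (`expm1`). When only initial and residual media volumes are
measured, intermediate volumes are interpolated linearly — adequate for
steady evaporation. For metabolites absent from fresh media, an
initial-rate option restricts the estimate to the first sampling interval,
before the medium conditions.

The asparagine partition takes the net influx of labeled asparagine
`J_in`, the net efflux of unlabeled asparagine `J_out`, and the
intracellular unlabeled-to-labeled ratio `r`, and returns
`J_prot = J_in (1 + r)` with `J_syn` closing the stationary balance
`J_in + J_syn = J_prot + J_out`. This algebra treats efflux as drawing on
the unlabeled (synthesized) pool only; the implementation keeps that
assumption explicit rather than resolving it, and the round-trip property
(implied label ratio inverts to the input whenever `J_syn > J_out`) is
enforced by tests.

## Fate budget

For a cell at constant composition doubling at rate `K` (doublings/h),
maintaining total concentration `C_i` requires `F_i = K ln(2) C_i`.
Acid hydrolysis merges Asn into Asp (and Gln into Glu), so the table
carries a combined Asp+Asn pool; the aspartate-to-protein term is the
combined-pool flux minus the separately measured asparagine-to-protein
flux. Because asparagine synthesis consumes aspartate 1:1 (the carbon
skeleton is retained), both asparagine terms are added back to total
aspartate demand — the subtraction only prevents double-counting within
the combined pool.

Purines do not survive hot acid, so purine demand is estimated from
pyrimidines: with purine molar demand equal to pyrimidine demand and AMP
and GMP synthesis fluxes equal, de novo purine synthesis costs one
aspartate per IMP plus one more per AMP — `1 + 1/2 = 1.5x` the pyrimidine
cost (one aspartate per pyrimidine ring). The rule is on by default and
toggleable. Arginine demand defaults to zero (standard media carry excess
arginine and tumor lines suppress synthesis). Free and polymer pools are
not separated; `C_i` is the combined total, as the flux equation assumes.

## Isotopologue bookkeeping

**Natural-abundance correction.** Measured intensities are modeled as
`measured = C @ true`, where column `j` of `C` spreads a species with `j`
tracer atoms binomially over the remaining `n - j` positions at the
natural heavy-isotope abundance (13C 0.0107, 15N 0.00364). The inverse
problem is solved by non-negative least squares and renormalized, which
truncates the small negative components an unconstrained inverse would
produce. This is a deliberate single-element simplification — tracer
purity 1.0, no resolution-dependent isobaric overlap, one element at a
time — sufficient for the synthetic test surface; it is not a
reimplementation of production correction software. Matrices beyond 60
atoms are refused as numerically meaningless.

**Salvage fractions.** Under amide-15N glutamine at isotopic steady state,
de novo GTP carries three glutamine-amide nitrogens and salvaged GTP none,
so guanine salvage is `m0/(m0+m3)`; de novo ATP carries two (ring N3 and
N9), giving `m0/(m0+m2)` by default, with a strict-`m0` variant that
instead counts intermediate isotopologues as de novo. Intermediate
isotopologues from incomplete precursor labeling are excluded from the
denominators; this follows the estimator's definition rather than a
resolved mixing model, and the generators emulate the same two-source
structure. Adenine's direct contribution reads from the
aspartate-donated `m+1` of ATP relative to aspartate under alpha-15N
glutamine, clipped to [0, 1] with a warning on clipping.

**Isotope-dilution quantification.** Response ratios (area over labeled
internal standard) are mapped through a calibration curve fitted to a
12-point 2-fold dilution series (500 µM top, three replicates — the
standard design the generator reproduces). Three families are fitted:
linear, power, quadratic. LC-MS response noise is multiplicative, so
linear and quadratic are fitted by relative-error (1/y-weighted) least
squares and the power model in log-log space, and selection uses
small-sample-corrected AIC on the *relative* residuals of all three —
putting the families on a common likelihood scale. (Selecting on raw
residuals for the polynomial families against log residuals for power was
tried first and systematically favored power under multiplicative noise,
including on quadratic-truth data where its predictions were off by tens
of percent; the weighted scheme is also what quantitative LC-MS practice
uses.) Candidates that are not strictly monotonic over the dilution range
— including degenerate flat fits — are discarded before selection; exact
ties resolve linear, then power, then quadratic. Curves invert by Brent's
method within the fitted range; response ratios outside the calibrated
response range are flagged discarded (`in_range=False`) rather than
raised, and intracellular concentration is
`vial_uM x V_reconstitution / V_cells / 1000` (mM).

## The rebound model

Three concentration pools — aspartate, succinate, UTP — in mM, plus
relative cell volume, with growth diluting every pool at `mu` (1/h):

    dAsp/dt  = J_asp f(s) + [J_alt if CI] + uptake - v_atc - mu c_asp - mu Asp
    dSucc/dt = P_succ g(CI) + supplement - k_sdh s Succ - mu Succ
    dUTP/dt  = v_atc + [salvage if uridine] - mu c_utp - mu UTP

    v_atc = Vmax Asp / (Km (1 + Succ/Ki) + Asp) * 1/(1 + UTP/Kfb)
    mu    = mu_max min(Asp/(Asp+Ka), UTP/(UTP+Ku))

`s` is residual SDH activity; `f(s) = f0 + (1-f0)s` (oxidative synthesis
lost with SDH block, a residual fraction `f0` remains — pyruvate-supported
alternative routes); `g(CI) < 1` under complex-I inhibition (slowed
alpha-ketoglutarate dehydrogenase cuts succinate production, while `J_alt`
adds alternative aspartate synthesis). ATCase carries the standard
competitive-inhibition law — succinate raises the apparent Km by
`(1 + Succ/Ki)` without touching Vmax, so the block is surmountable by
aspartate — times a phenomenological `1/(1 + UTP/Kfb)` feedback (the
feedback on carbamoyl-aspartate synthesis is documented; its functional
form is not, so the simplest saturating form is used). Growth is a Monod
minimum: whichever of aspartate (biosynthesis at large) or UTP
(replication/transcription) is scarcer limits proliferation. Each
functional form is isolated inside `derivatives` so alternates can be
swapped.

These are phenomenological whole-cell balances, not an enzyme-level
reconstruction: one lumped aspartate pool (no compartments), UTP standing
in for the whole pyrimidine pathway (no carbamoyl-aspartate or
dihydroorotate states), no purine branch, no NAD+/NADH state, no
replication-stress signaling. Supplement arms use constant influxes
(aspartate uptake in particular is low-permeability and not saturable
here); rotenone's magnitudes (`J_alt`, `g`) are calibration choices, as no
quantitative values exist for them.

### Calibration (frozen, version 1.0)

Step 1 pins the vehicle fixed point to measured medians in untreated
cells — aspartate 1.7 mM, succinate 0.2 mM — plus UTP 1.0 mM and a growth
rate near one doubling/day; `J_asp`, `P_succ`, `Vmax_atc`, `c_utp` then
follow in closed form from the steady-state balances (see
`src/aspdyn/_calibration.py`). Step 2 takes `Km = 2 mM`, `Ki = 0.75 mM`,
inside the ranges established for bacterial ATCase (Km 0.5–5 mM aspartate,
Ki 0.5–1 mM succinate). Step 3 tuned the remaining free parameters once —
`f0 = 0.32`, `Ku = 0.4 mM`, `k_sdh = 1.2/h`, vehicle ATCase flux
0.08 mM/h, `c_asp = 6 mM` — so that under full SDH inhibition the
aspartate minimum falls near 24 h with a substantial rebound and
succinate approaches ~14 mM (~70-fold) by 72 h, and the supplement arms
reproduce the observed shape grammar: uridine abolishes the rebound,
complex-I co-inhibition attenuates it and is overtaken by the
SDH-inhibition arm late (a finite crossover), succinate supplementation
restores it, and uridine abolishes it again. The resulting set is frozen
and versioned; the nadir-timing check in the test suite is a regression
test of the dynamics against this frozen set (25.0 h on the 0.5 h grid),
not a fit to data.

Note the model's fluxes are an order of magnitude below the measured
whole-cell aspartate demand (~10 mM/h): with millimolar pools and
10 mM/h turnover the intracellular relaxation time would be minutes, and
the observed day-scale kinetics could not emerge from a three-pool model.
The calibration trades absolute flux magnitude for faithful time scales —
a known limitation of lumping every downstream reservoir into three
pools.

### Numerics

LSODA (stiff-capable) with rtol 1e-8 / atol 1e-10; the reporting grid
(default 0.5 h) is decoupled from solver steps. Non-negativity is enforced
by projection: the right-hand side always evaluates on the non-negative
part of the state, so numerical undershoots cannot feed back, and reported
states are clipped at zero. The model contains no randomness; fixed
tolerances make trajectories reproducible to the bit. Fixed points are
located with `scipy.optimize.root` (hybr, tol 1e-12). Crossover times
interpolate the first sign change linearly, treating differences below
1e-9 of the variable's scale as ties so integrator round-off cannot
fabricate a crossing.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible
under identical specs. Noise models follow the measurement physics at the
level the estimators are sensitive to: lognormal (multiplicative,
unit-median) noise for fluorescence and concentrations, multinomial ion
sampling for isotopologue fractions, Poisson counts for nuclei. The
biosensor generator drives GFP/RFP through a saturating Hill transfer
function (coefficient 1, apparent Kd 0.9 mM) of the simulated aspartate
trajectory — only monotonicity matters downstream, since sensor
calibration is out of scope. Media series integrate the exponential
cell-volume curve exactly and shrink media volume exponentially at the
evaporation rate; the composition generator constructs tables whose budget
reproduces a chosen total demand exactly (flux shares 0.65 combined
Asp+Asn, 0.10 asparagine efflux, 0.10 pyrimidine, purine rule adding
0.15).

What passing these tests shows: the estimators invert their own generative
models correctly at realistic noise levels (2–3% CV, 1e3–1e6 ions), and
the ODE reproduces the qualitative phenotype grammar under the frozen
calibration. What they do not show: robustness to chromatographic
artifacts, batch and plate-position effects, drifting sensor expression,
media degradation, or model misspecification of real cellular kinetics —
none of which the generators emulate.

## Degenerate inputs and edge policies

Zero RFP, zero pre-treatment nuclei, non-positive counts or volumes, and
all-zero intensity vectors raise errors naming the offending well or
input. Flat value traces classify as monotonic with rebound fraction 0.
Quantification out of calibrated range flags rather than raises (the
measurement is to be discarded, not the batch). `denovo_fraction` clips
ratios above 1 with a warning. The asparagine partition requires
`J_in > 0` — the label ratio is undefined without labeled influx.
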