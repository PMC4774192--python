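# Methods

## Scope and model structure

`hepatokin` implements a kinetic model of carbohydrate metabolism in a
rat hepatocyte: glycolysis, gluconeogenesis, and glycogen turnover,
distributed over four compartments (cytosol, mitochondrion, ER lumen,
external space).  The model contains 32 reactions and transporters:

* plasma-membrane transport: GlcT (GLUT2), LacT (monocarboxylate
  transporter);
* glucose phosphorylation/dephosphorylation: GK, and the ER route
  G6PT_ER → G6P (glucose-6-phosphatase) → GlcT_ER;
* upper glycolysis/gluconeogenesis: GPI, PFK1, FBP1 and the
  fructose-2,6-bisphosphate signal couple PFK2/FBP2;
* the near-equilibrium triose backbone ALD, TPI, GAPDH, PGK, PGM, EN;
* lower glycolysis and anaplerosis: PK, LDH, PyrT, PC, MDH, MDH_mito,
  PyrMalT, PEPCK, PEPCK_mito, PEPT;
* nucleotide bookkeeping on clamped pools: NDK_GTP, NDK_mito_GTP,
  NDK_UTP;
* glycogen turnover: GS, GP.

The cofactor pools (ATP/ADP, NAD/NADH, GTP/GDP, UTP/UDP, phosphate,
pyrophosphate, CO2) are clamped constants: energy and redox metabolism
are outside the model's scope, so their concentrations enter the rate
laws as fixed numbers.  The near-equilibrium steps
phosphoglucomutase and UDP-glucose pyrophosphorylase of the glycogen-
synthesis branch are folded into the GS step; Glc1P and UDP-glucose are
carried as clamped quasi-equilibrium species so the metabolite roster
is complete without orphaned state variables.  Citrate inhibition of
PFK1 and all other cofactor-mediated allosteric effects are deliberately
not included.

Units: concentrations in mM, fluxes in umol per g wet tissue per hour,
time in hours, hormones in pM.  Fluxes convert to concentration
derivatives through the cell-water content of liver tissue
(0.46 mL/g) corrected for liver density (1.067 g/mL), i.e.
d[c]/dt = 2.3196 x flux.  A single conversion factor is used for all
compartments; compartment volume ratios are absorbed into the Vmax
values.

## Rate laws

Rate equations are composed from a small modular library:

* a generalized reversible Michaelis-Menten core,
  v = Vmax (prod_s (S/K_s)^h - (1/keq) prod_p (P/K_p)^h) / D with the
  standard denominator D = prod_s(1 + (S/K_s)^h) + prod_p(1 + (P/K_p)^h) - 1.
  `keq` is an apparent constant on Km-scaled concentrations (clamped
  cofactors folded in).  Irreversible laws omit the reverse numerator;
  listed products still bind competitively.  Product binding provides
  the physiological feedbacks of the anaplerotic limb (oxaloacetate on
  PC, PEP on the PEPCK isoforms) and the glucose product inhibition of
  glucose-6-phosphatase, without which the clamped-cofactor design
  would let these steps pump against an infinitely absorbing pool;
* a carrier law for facilitated transport,
  v = Vmax (prod S_i/K_i - prod P_i/K_i)/prod(1 + S_i/K_i + P_i/K_i),
  pairing the two membrane faces (antiport for PyrMalT);
* multiplicative allosteric saturation factors per effector, functions
  of X = E/p only: activators (a0 + X^h)/(1 + X^h), inhibitors
  (1 + a0 X^h)/(1 + X^h).  Because the factor depends on the effector
  concentration and its binding constant only through their ratio, the
  elasticity with respect to the binding constant is exactly the
  negative of the elasticity with respect to the effector;
* phospho-pair composition for the five interconvertible enzymes
  (GP, GS, PK, PFK2, FBP2): v = gamma v_phospho + (1-gamma) v_dephospho,
  where each form scales the shared core by a vmax factor (and
  optionally a Km factor).  GP and FBP2 are active when phosphorylated,
  GS, PK and PFK2 when dephosphorylated;
* a structural store factor for GS, max(0, 1 - (Glyc/C)^4) with storage
  capacity C = 500 mM glucosyl units, so synthesis stalls only near a
  full store; GP sees the store through an ordinary Km term in Glyc.
  "Filling state" is Glyc/C in [0, 1].

## Parameter provenance and calibration

The binding constants are order-of-magnitude literature values for the
rat liver enzymes (e.g. GLUT2 Km ~ 11 mM, glucokinase S0.5 in the
high-mM range with sigmoidal kinetics, FBP1 Km for Fru16P2 in the uM
range).  Regulatory saturation terms (the glucose switches of GP and
GS, the Fru26P2 control of FBP1) carry calibrated Hill exponents well
above their microscopic binding cooperativity: they lump the steepness
of entire signaling layers that the model does not resolve
mechanistically.  The maximal rates of the fed reference state and the sharpness
parameters of the regulatory terms are not directly measurable in vivo;
they were calibrated, once, against published stationary anchors of
perfused rat liver and hepatocytes:

* net glucose release of -64 umol/g/h for fasted hepatocytes at 4 mM
  plasma glucose (low glycogen store) and net uptake of +81 umol/g/h
  for fed hepatocytes at 10 mM (high store);
* glucose set points (zero exchange flux) near 6.5 / 7.5 / 9 mM for
  fed / normal / fasted livers at half-filled store, with the fasted
  set point ranging over [8.0, 9.2] mM and the fed one over
  [5.9, 6.6] mM as the store goes from empty to full, and a diabetic
  set point right-shifted to ~15-16 mM;
* maximal gluconeogenesis from lactate of 60-70 umol/g/h, saturating
  above ~5 mM external lactate, in a perfusion setting without glucose
  and hormones;
* the flux-control structure at the two canonical states (see below):
  control concentrated on a handful of enzymes, near-equilibrium steps
  carrying none.

The canonical "low" and "high" glycogen stores of the two reference
states are taken as filling fractions 0.15 and 0.80.

## Physiological states and hormonal control

Four states differ only in (a) enzyme abundances and (b) the
glucose-hormone transfer (GHT) curves.  Abundance ratios
alpha = <E>_state/<E>_fed scale Vmax linearly; the embedded table holds
the reported means and min-max ranges for the normal, fasted, and
diabetic liver (fed = 1 by definition).  The printed normal-liver
column is used verbatim.

The GHT functions are Hill curves: insulin rises with glucose,
glucagon falls; the diabetic variant scales insulin to 10 % and
glucagon to 200 % of normal.  The phosphorylated fraction gamma of all
interconvertible enzymes follows one empirical signal function
gamma(I, G) = [g0 + (1-g0) X_G/(1+X_G)] / (1 + (I/K_I)^2) with
X_G = (G/K_G)^2, saturating to 1 at 1e5 pM glucagon and 0 at 1e5 pM
insulin.  The hormone-free basal value g0 = 0.38 reflects the
substantial phosphorylation state of perfused liver without hormones.  The function
is calibrated so that gamma evaluates to 0.32 at the hormone levels
belonging to the normal-state set point.  A single gamma is shared by
all five interconvertible enzymes; no intracellular signaling cascade
is modeled, and hormones act instantaneously (no hormone kinetics).

## Simulation engine

Steady states are found by Newton iteration (scipy `root`, hybr) on
log-concentrations, warm-started where possible and falling back to
stiff integration (LSODA) when the initial guess is outside the Newton
basin.  A state is accepted when max |dc/dt| < 1e-6 mM/h.  Glucose set
points are located by bracketing bisection on [3, 20] mM to 1e-3 mM,
seeded by a coarse scan; the exchange flux is monotone in glucose over
the physiological band, so the root is unique.  For store-clamped
scans, glycogen is removed from the dynamic state vector.  Diurnal
simulations interpolate the glucose profile with a monotone cubic
(PCHIP) scheme, recompute hormones and gamma instantaneously at every
step, and integrate with LSODA; one burn-in day with the periodically
extended profile is integrated and discarded so the reported day is
free of initial-condition transients (the initial store filling of the
recorded day is therefore an emergent property, not an input).
Replicate ensembles draw abundance ratios independently and uniformly
within the reported ranges (enzymes without a range keep their mean);
one seed governs the whole ensemble through a single generator, making
ensembles bit-reproducible.

## Regulation-mode dissection

The reference state is the converged steady state at the normal-state
set point (half-filled store).  Freezing a mode constructs a variant
that reproduces the reference fluxes exactly:

* abundance: all alpha pinned to the normal-state means, whatever the
  nominal state;
* phosphorylation: gamma pinned to its reference value for all hormone
  levels;
* allosteric: each effector saturation factor replaced by the number it
  attains at the reference concentrations.  Only effector terms are
  frozen; substrate and product terms of the same law stay live, which
  is the narrower of the two possible readings and the one implemented.

The loss of regulation over a 24-h profile is
Delta = int |v_full - v_depleted| dt / int |v_full| dt, computed by
trapezoidal quadrature on the simulation grid (97 points over 24 h in
the shipped analysis; the measure is invariant to uniform rescaling of
time or flux).

## Metabolic control analysis

Flux control coefficients are computed by symmetric 5 % variation of
each enzyme amount with full steady-state re-solves (a 0.5 % mode is
available as a cross-check); the summation theorem (sum C_i = 1) is
recovered to well within 0.02 and serves as the internal accuracy
check.  Coefficients diverge by definition where v_ex -> 0, so
references with |v_ex| < 1 umol/g/h are rejected, and diurnal control
series flag such time points instead of reporting values.
pi-elasticities are central differences on the isolated rate law
(relative step 1e-4); the elasticity with respect to the enzyme's own
abundance is exactly 1, so the response coefficient R_ik = C_i pi_ik
reduces to C_i for abundance changes.  Relative elasticities normalize
|pi| per enzyme to unit sum.  "Key regulatory enzymes" are those with
|C_i| > 0.1 in at least one of the two canonical states (fasted at
4 mM, fed at 10 mM).

## Synthetic driving data

Measured diurnal plasma-glucose profiles are replaced by synthetic
surrogates: a baseline with slow sinusoidal modulation plus Gaussian
meal pulses (fed: baseline 5.8 mM with three nocturnal-feeding pulses
reaching ~8.5 mM, crossing the fed set point in both directions;
fasted: flat 4.2 +/- 0.4 mM; diabetic: baseline 16.5 mM with blunted
pulses, never below 14 mM).  Optional smooth noise comes from three
random Fourier modes.  The surrogates reproduce the qualitative
features that drive the analysis (range, set-point crossings,
persistence), not the measured traces, so quantities that depend on the
exact measured profiles (e.g. the precise Delta table) are reproduced
in ordering and magnitude class rather than digit-by-digit.  The bolus
scenario adds a smooth pulse inside hours 12-16 of the fasted profile,
peaking at 10 mM.

GHT scatter fixtures place points on a known Hill curve with
multiplicative Gaussian noise; the fitting routine (nonlinear least
squares, five deterministic multi-starts, ties broken by residual then
by lower Hill exponent) recovers noiseless parameters to well below
1 %.

## Numerical choices and degenerate inputs

* Steady-state tolerance 1e-6 mM/h; set-point tolerance 1e-3 mM;
  integrator tolerances rtol 1e-7 / atol 1e-9 (diurnal) and
  1e-8 / 1e-10 (phase protocols).
* Root solves clip log-concentrations to [-34, 8.5] to keep iterates
  finite; the acceptance check is always on the unclipped residual.
* Concentrations are floored at 1e-12 mM inside the ODE right-hand
  side to protect fractional powers during transients.
* gamma outside [0, 1], negative concentrations, negative hormone
  levels, non-bracketing set-point intervals, and zero reference
  curves in Delta all raise with explicit messages.
* Problem sizes of the shipped analyses: 5-point glycogen-filling
  scans, 10-point lactate titrations, 49-97-point diurnal grids,
  10-50-replicate ensembles.  These reproduce the reported quantities
  to the stated tolerances; finer grids change results well below
  those tolerances.

## SBML exchange

Models export as SBML L3V2 with clamped species as boundary species and
the complete rate law emitted as each reaction's kinetic-law math with
local parameters.  The modular composition is encoded in a
local-parameter naming convention that the importer inverts, giving a
bit-exact round trip; foreign kinetic conventions are reported as
unsupported rather than silently dropped.  Level 2 files are accepted
on import for species/stoichiometry.

## Known limitations

* Fixed cofactor pools understate allosteric regulation (no energy
  charge feedback, no citrate inhibition of PFK1).
* One shared gamma function for all interconvertible enzymes; enzyme-
  specific phosphorylation kinetics are not resolved.
* The rate laws are phenomenological modular forms calibrated to
  system-level anchors, not transcriptions of individual in vitro
  enzyme studies; parameter values should not be quoted as measured
  kinetic constants.
* Plasma glucose is always an input; there is no whole-body feedback,
  so the model cannot be used to predict plasma glucose dynamics, only
  the hepatic response to them.
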