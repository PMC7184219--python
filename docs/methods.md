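# Methods

`cofactorkit` models the computational workflow of a metabolic-cofactor
supplementation study in healthy subjects: predicting long-term plasma
levels of orally supplemented compounds (L-serine, L-carnitine,
N-acetyl-L-cysteine; nicotinamide riboside is dosed from literature and
not modeled), conditioning a liver metabolic network on plasma
metabolite fold changes, and testing longitudinal metabolomics/protein
panels. Everything is exercisable on synthetic data with a known ground
truth.

## Oral pharmacokinetic model

The plasma response to an oral bolus is a linear three-compartment
cascade: stomach `A`, small intestine `B`, and the plasma increment
`dC` above the endogenous baseline `C0`:

    dA/dt  = -k1 A              A(0) = F * dose
    dB/dt  =  k1 A - k1 B       B(0) = 0
    ddC/dt =  s k1 B - k2 dC    dC(0) = 0
    C(t)   =  C0 + dC(t)

One transfer constant `k1` (1/h) serves both gut compartments — the
two-stage cascade supplies the observed absorption delay with one fewer
parameter — and `k2` (1/h) is central clearance. Two quantities close
the unit system: oral bioavailability `F` (fraction, default 1.0 with a
configuration override per compound, since literature values vary by
compound and salt form) and `s` ("scale", assay units per gram reaching
circulation), which absorbs the volume of distribution. `s` is a fitted
parameter; nothing else in the model maps grams to concentration units.

A clearance law of the form `dC/dt = k1 B - k2 C - C0` was considered
and rejected as the default: its drug-free steady state is `-C0/k2`,
i.e. the curve neither starts nor ends at baseline. The
baseline-reverting form above reproduces the physiologically described
behaviour (baseline before dosing, return to baseline after washout).
The affine variant remains available via `solve_single_dose(...,
literal_form=True)` for comparison.

Numerics: the constant-coefficient system is propagated with the matrix
exponential of one grid step (exact at grid points to float precision;
default step 0.05 h). Multi-dose regimens use superposition of the
single-dose response, valid because the system is linear; event times
are snapped to the grid. Tests verify the solver against an
independently derived analytic solution of the repeated-eigenvalue
cascade, the increment AUC identity `F * dose * s / k2`, and gut
mass accounting.

### Long-term increase and dose search

"Long term" means the steady-state 24-h mean of the plasma increment
under a daily-periodic regimen, relative to baseline. Linearity gives
the closed form

    increase% = 100 * F * s * D_daily / (24 * k2 * C0)

which the simulation path (>= 14 simulated days, trailing 24-h moving
average over the final fully dosed day) matches to < 0.5%. The moving
average uses a half-open trailing window containing exactly
`window/step` samples so that a window-periodic signal averages to its
period mean exactly. `find_dose` inverts the closed form for a target
increase (default 100%), splits the daily dose into two equal
administrations 12 h apart (administration times are a convention, not
data), and truncates at per-compound daily safety caps (defaults:
serine 25.5 g/day, L-carnitine 7 g/day, NAC 6 g/day) reporting the
achieved increase and a `capped` flag.

### Pooled fitting

Per-subject series are interpolated with monotone shape-preserving
cubics (PCHIP; no overshoot between sparse concentration samples, no
extrapolation outside the observed span) on a uniform grid, averaged
pointwise into a target curve, and the model is fitted once to that
pooled mean (no between-subject variability is estimated). Free
parameters are `(k1, k2, s)` in log space (positivity by construction);
`C0` is fixed to the observed t = 0 value by default, with a fit-C0
option. Optimization is trust-region least squares from a coarse
log-spaced multi-start (default 5^3 starts; `k1` in [0.03, 10], `k2` in
[0.1, 100], scale anchored to the curve's AUC via `AUC*k2/(F*dose)`),
ties on RSS broken by lowest `k1` — the absorption/elimination
"flip-flop" ambiguity makes the global search necessary. Relative
standard errors come from the Jacobian covariance at the optimum;
log-space standard deviations are relative errors to first order.
Replicate simulations show the reported RSE tracks the empirical
dispersion within a factor of two in well-conditioned regimes; in
fast-elimination regimes (k2 >> k1) individual replicates can sit near a
flat direction and report very large RSEs, which is informative rather
than wrong.

## Network conditioning on plasma fold changes

The liver network is conditioned in the relative-metabolic-difference
style: (1) sample a reference flux space, (2) remap measured exchange
bounds around the reference flux magnitudes according to plasma fold
changes, (3) re-sample and compare.

* **Default bounds.** Internal reversible reactions get (-inf, +inf),
  irreversible (0, +inf); a finite cap (1000) stands in for infinity
  when sampling, which requires a bounded polytope. Exchanges default to
  uptake/secretion magnitude 1 except unlimited species (O2, H2O, CO2)
  and the cocktail substances, whose uptake is forced into [0.1, 1];
  nicotinamide and cysteine are uptake-only.
* **ATP maintenance.** Resting hepatic energy expenditure (default
  15 kcal/liver/h) floors an ATP-hydrolysis reaction at
  `energy * 4.184 / deltaG * 1000` mmol/h; with deltaG = 51.77 kJ/mol
  this is ~1,212 mmol/h. The deltaG default is back-solved from that
  printed bound and should be confirmed against a concrete model's
  units before reuse (flux units of published liver models differ:
  mmol/h/liver vs mmol/gDW/h).
* **Objective.** Mitochondrial fatty-acid-oxidation reactions (selected
  by subsystem tag and compartment), each weighted by the FADH2 + NADH
  it produces (consumption counts zero). During sampling the objective
  is constrained to >= gamma times its optimum (default gamma = 0.9,
  gamma in [0, 1]; gamma = 0 recovers unconstrained sampling) — the
  near-optimal restriction stands in for "reduce the solution space",
  since fixing at exactly the optimum would collapse most of the
  polytope.
* **Sampling.** Artificially centered hit-and-run (ACHR, via cobrapy)
  with thinning 100; 1,000 samples averaged into the reference state.
  Seeded and deterministic; every sample satisfies steady state (tol
  1e-6 relative) and bounds, asserted in tests. Validated against
  interval midpoints and vertex enumeration on low-dimensional toys.
* **Fold-change rules.** For reference magnitude `v` and fold change
  `f >= 1` (direction carries the sign): uptake+decreased -> uptake in
  `[v, f v]`; secretion+decreased -> `[v/f, v]`; uptake+increased ->
  `[v/f, v]`; secretion+increased -> `[v, f v]`. The two "increased"
  cases are the mirror images of the first two and are flagged as an
  extrapolation of the stated rule. All arithmetic is on magnitudes
  (uptake is negative flux internally); `f = 1` is the identity. A
  near-zero reference flux degenerates to `[0, eps * default_bound]`
  (eps = 1e-3) with a warning. Infeasible record combinations raise,
  with a greedy bound-relaxation diagnosis; nothing is silently relaxed.
* **Summaries.** Per-metabolite turnover is half the summed absolute
  carried flux per compartment (production = consumption at steady
  state), summed over compartments; `halved=False` gives the literal
  double-counting reading. Pathway aggregates are sums of member
  reaction means.

## Longitudinal panel statistics

Panels are long-format (subject, arm, analyte, time, value; NaN =
missing). Every trajectory is normalized to its subject/analyte t = 0
baseline (pairs with missing/zero baseline are dropped with a warning).
Per analyte and time point, a one-way ANOVA with two groups — literally
the squared pooled two-sample t test — compares fold changes either
against baseline or between arms; missing values are removed pairwise.
Benjamini–Hochberg FDR is applied within each time point across
analytes by default (matching per-timepoint reporting), with a
study-wide pooled option. Analytes significant (q < 0.05) at >= k time
points are summarized with their counts. Spearman correlations relate
every analyte to the supplemented cofactors across all subject-time
records (pairwise-complete, >= 4 pairs, BH across pairs). A detection
filter retains analytes observed in strictly more than 80% of samples.

Two caveats are intentional consequences of the literal procedure: the
baseline "group" of fold changes is identically 1, so the
baseline-comparison F test inherits pooled degrees of freedom from a
zero-variance group and is mildly anti-conservative for skewed data
(the paired option avoids this); and the type-I calibration test
therefore exercises the between-arm comparison, where both groups are
sampled. The baseline comparison is unpaired by default because the
procedure specifies a one-way ANOVA; a paired variant (one-sample t on
per-subject fold-change differences) is exposed.

## Synthetic data

The generators produce the study conditions the analyses assume, fixed
up front: nine supplementation-arm subjects (ten in the water-only
control arm), a single oral bolus at t = 0 (20 g serine, 3 g carnitine,
5 g NAC, 1 g NR), eight draws on the grid {0, 1, 2, 3, 4, 6, 8, 24} h
(a configurable stand-in; the study's exact draw times are not
tabulated), multiplicative lognormal measurement noise (unit mean;
default CV 10% for targeted PK assays, 20% for untargeted omics),
lognormal inter-subject baselines (CV 15%), 5% missingness plus
detection-floor censoring, and omics values
`baseline * exp(shared fasting drift + arm-specific effect) * noise`.
Baseline records are never censored so the normalization contract
holds. Each dataset ships with a ground-truth manifest; identical seeds
reproduce outputs bit-identically.

The toy liver network is hand-written (not sampled) so flux
expectations are stable: ~65 reactions over extracellular/cytosol/
mitochondrion covering glycolysis, beta-oxidation behind a carnitine
shuttle, serine -> glycine -> glutathione with NAC-derived cysteine,
BCAA oxidation, NAD salvage, an ATP-maintenance sink and a lipoprotein
proxy, mass-balanced on toy formulas (C/N/S only; cofactor pairs share
a formula). One deliberate capacity choice makes the fixture
informative: the TCA acetyl-CoA sink is capped, so oxidation beyond it
must export acetyl-carnitine, making carnitine availability limiting
for fat oxidation — closing the carnitine exchange lowers the FAO
optimum, and supplementation-style conditioning raises mean FAO,
glutathione-synthesis and BCAA fluxes while glycolysis does not rise.

What passing synthetic tests do *not* show: real LC-MS/PEA artifacts
(batch effects, drift, correlated missingness), between-subject
kinetic variability (the pooled fit ignores it by design), or the
behaviour of a genome-scale model with thousands of reactions, where
sampling mixes far more slowly than on the toy fixture.

## Reproducibility and scale choices

A single run seed fans out to per-stage seeds by stable hashing
(SHA-256 of `"{seed}:{stage}"`, reduced below 2^31), so stages can be
rerun independently. Every artifact directory carries the
configuration hash, stage seed and package versions. Default problem
sizes — 1,000 flux samples, 200 fitting replicates, 1,000-analyte null
panels, 14–21 simulated dosing days at 0.05 h resolution — are the
package's demonstration scale, chosen so the full pipeline and test
suite run on a laptop-class single core in minutes.

## Known limitations

* Population (mixed-effects) PK, between-subject variability prediction
  and NR kinetics are out of scope.
* Dose linearity is exact in the model; saturation of absorption or
  clearance at supplementation doses would break the closed form.
* The conditioning rules act on exchange bounds only; intracellular
  regulation, gene-protein-reaction rules and thermodynamically
  infeasible loops are not modeled (loop flux in the toy fixture is
  kept small by explicit capacity bounds).
* FDR scope (per time point vs pooled) changes which analytes clear
  q < 0.05; both are implemented and the default is per time point.
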