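# Methods

## Assay model and normalisation

The package models a 96-well endpoint fluorometric inhibition assay: a
recombinant CYP isozyme converts a fluorogenic substrate to a fluorescent
product; inhibitors reduce product formation and hence the endpoint RFU.
Each plate carries test wells (8-point two-fold dilution series in
duplicate), solvent-control wells (uninhibited reaction, reference A),
positive-inhibitor wells (full inhibition, reference B), a fluorescent
standard column for calibration, and buffer blanks.

Percent inhibition is `(1 − (X−B)/(A−B))·100`.  Three normalisation
choices are deliberate:

* **Controls are averaged at the RFU level** before the formula is applied
  (the formula takes a single A and B), matching plate-reader convention.
* **Values outside [0, 100] are preserved.**  Noise around the asymptotes
  produces slightly negative or >100% inhibition; clipping before fitting
  would bias the asymptote estimates, so clipping exists only as a
  reporting helper.
* **The solvent-control reaction, not the fluorescent standard, is A.**
  Assay write-ups sometimes conflate the two; the formula requires an
  uninhibited-reaction reference, so the standard is kept as a separate
  calibration role.

Equality of A and B (zero assay window) is a hard error in the
percent-inhibition path and a flag (`degenerate`/`inverted`) in the QC
path, so screening runs can skip bad plates rather than crash.

## Units

The canonical kinetic unit is µM.  µg/mL is accepted at every boundary
and converted through the compound's molecular weight
(`µM = µg/mL · 1000 / MW`); nM standards are converted by 1/1000.  The
packaged constants table carries free-base molecular weights for the five
PPIs and ticlopidine.  The static-model ratio is always formed in µM/µM —
mixed-unit division is a classic source of inconsistent published ratio
columns, and the report surfaces such inconsistencies rather than
reproducing them.

## Dose-response fitting

Four-parameter logistic, fitted with `scipy.optimize.least_squares`
(trust-region reflective) on log10 concentration.  Defaults: bottom = 0
and top = 100 fixed (responses are control-normalised), Hill slope
bounded to [0.1, 10], log10(IC50) bounded to the tested range ± 2
decades.  Five starts spaced across the tested range guard against local
minima; ties resolve by lowest SSE then lowest Hill slope.  A fit is
reported **non-converged** when the optimiser fails or when the fitted
IC50 falls more than one decade outside the tested range — a flat or
saturated curve can reach near-zero SSE with an arbitrary far-away
midpoint, and such midpoints are not identified by the data.  An
unconstrained mode (bottom/top free) exists for QC of incompletely
normalised data.

Because published dose-response spreads rarely state their estimator, the
IC50 SD here is defined explicitly as a **case-bootstrap SD**.  Two
levels exist:

* point-level (`dose_response.bootstrap_ic50_sd`): resamples the
  (concentration, %I) wells — the textbook case bootstrap;
* plate-level (`pipeline.bootstrap_plate_ic50`, used by the pipeline):
  additionally resamples the control wells and renormalises per resample.
  The controls are shared by every point on the curve, so their noise
  shifts the whole curve coherently; ignoring it underestimates the
  plate-to-plate IC50 SD by roughly a factor of two at the default layout
  (4 solvent / 3 positive control wells).  The plate-level estimator is
  the honest one for endpoint plates and is what the analysis pipeline
  reports.

Both are deterministic given a seed.

## IVIVE chain and risk call

`IC50,u = IC50/fu_inc` with fu_inc = 0.02 (regulatory default for highly
bound drugs in microsomal/recombinant incubations); `Cmax,u = Cmax·fu`
with fu = 0.01.  Two Ki conventions are implemented and never mixed
silently: exact Cheng–Prusoff `IC50,u/(1+S/Km)` (requires S and Km), and
the regulatory shortcut `IC50,u/2`, which equals Cheng–Prusoff at
S = Km and is the default because it is what published PPI summary
tables use.  Note the tension: under the assays' stated S ≪ Km the
rigorous correction would be ≈1, making /2 conservative by up to 2×; the
package implements both and leaves the choice to configuration.  The
cutoff (default 0.02) is inclusive (≥) and configurable — guidance
revisions move cutoffs, constants should not be hard-coded.

## Simulator

Competitive-inhibition Michaelis–Menten with linear product accumulation
(endpoint assays operate in the kit's linear window; substrate depletion
is out of scope): `v = Vmax·S/(Km(1+I/Ki)+S)`, product `v·t`,
`RFU = background + gain·product`, multiplied by `(1+ε)`,
ε ~ N(0, CV²) independently per well, drawn in row-major well order so a
single seed reproduces a plate bit-for-bit.  Defaults: Km = 10 µM,
S = 1 µM (substrate well below Km, the regime the /2 shortcut is applied
in; `paper_mode` enforces S ≤ Km), Vmax and gain sized to give ~1 kRFU of
uninhibited signal over the 10-min reaction, background 50 RFU, CV 5%,
positive controls at zero residual activity (the positive inhibitor is
treated as complete, so B ≈ background).

Under this model the noiseless inhibition curve is **exactly**
`%I(I) = 100·I/(I + Ki(1+S/Km))` — a Hill-1 logistic — which provides a
closed-form oracle: the fitter must recover `Ki(1+S/Km)` to ≤0.1% on
noiseless plates, and does so to ~1e-12 in practice.

What the simulator does *not* emulate: optical cross-talk and edge
effects, inner-filter/quenching, time-dependent (mechanism-based)
inactivation, NADPH-regeneration kinetics, and non-Gaussian outliers.
Passing recovery tests therefore demonstrates correctness of the
analysis chain under idealised measurement noise, not robustness to
every real-plate artefact.

The default test-range layout is an 8-point two-fold series from a
configurable top (12.8 µM default, spanning 128-fold); a 4-point preset
covers the 0.8–6.4 µg/mL range sometimes quoted for PPI screens, since an
8-point two-fold series cannot span only 8-fold.

## Problem sizes and determinism

The stochastic validation study uses 50 simulated single-compound plates
at CV 5% (median relative IC50 error, observed ≈5–6%, asserted <10%) and
a 300-resample plate bootstrap compared against the Monte-Carlo SD of the
50 fitted IC50s (asserted within 2×; observed ratio ≈0.5–1.2 across
seeds).  These sizes give stable medians while keeping the whole
validation run in seconds.  All randomness flows from
`numpy.random.default_rng` seeds; simulation and bootstrap are
bit-reproducible given a seed, and every pipeline run emits a provenance
block (config SHA-256, seed, version).

## Known limitations

* The constrained 4PL assumes complete inhibition at saturation; partial
  inhibitors need the unconstrained mode and interpretation care.
* The Ki conventions assume competitive, reversible inhibition.
* Replay mode can only be as consistent as its inputs; when a published
  ratio column disagrees with its own Cmax,u and Ki,u columns, the
  package recomputes from the stated formula and reports the discrepancy
  rather than choosing a side silently.
* Ilaprazole's packaged total Cmax is back-derived from a published
  unbound value (no labelled source exists) and flagged in the constants
  table.
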