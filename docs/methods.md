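# Methods

## Scope and data model

The package analyzes a two-group rodent intervention study (labels "Ctrl"
and "Cvs" by default) from four input kinds: OCR plate tables (wells ×
measurement ticks with injection-phase labels and per-well normalizers),
metabolic-cage traces (30-min bins of VO₂, VCO₂, activity, food, body
weight under a 12 h/12 h light schedule), protein-abundance tables
(proteins × samples, linear intensities, plus GMT gene sets), and qPCR Ct
tables (Nd1/Lpl triplicates).  Every stage is a pure function from a
validated container to a results table; group statistics are always
delegated to the shared gated test chooser so the same selection rules
apply everywhere.

## Respiration states from plate traces

Coupling protocols carry the phase sequence basal → ADP (state 3) →
oligomycin (state 4o) → FCCP (state 3u) → antimycin A (residual);
electron-flow protocols carry FCCP-uncoupled basal → complex inhibitor →
complex substrate → antimycin → TMPD/ascorbate.  Two equilibration cycles
precede every run and are excluded from all states.  The basal state is
the *second* basal tick (the first only verifies that the preparation has
reached steady state); this rule is applied to the uncoupled basal of
electron-flow runs as well, since the instrument logic is identical.
Every other state defaults to the mean of its phase's ticks; a "last tick"
statistic is available for plateau-seeking protocols.  The choice matters
only under within-phase drift and is recorded in the result metadata.

Technical replicate wells are averaged per animal *after* state
extraction, because all cohort statistics run on animals, not wells.
Normalization divides each state by (protein loaded / 2.5 µg reference)
and then by citrate-synthase activity; protein loading is normally
equalized, but keeping the division explicit makes the operation total
rather than assumed.  No automatic post-antimycin (non-mitochondrial)
subtraction is applied by default — raw plate exports can carry negative
state-4o readings, and the downstream offset rule is designed to handle
them; subtraction is exposed as an option and recorded when used.

## Coupling degree, efficiency, set points

The two-flow converter mapping lives in one function each:
q = √(1 − state4o/state3) and η_opt = q²/(1+√(1−q²))², so a corrected
state→flow identification would be a one-line change.  Samples with
state4o > state3 (RCR < 1) have no defined q; the default policy clamps
q to 0 with a per-sample warning record so cohort statistics stay
computable, and a strict policy raises instead.

The RCR offset rule is made deterministic: c = 0 when every state-4o
reading is positive, otherwise c = −min(state4o) + ε with ε defaulting to
1% of the median state 3, added uniformly to *all* state-3 and state-4o
readings of the batch.  The offset is reported alongside the results, and
q is computed from the offset-adjusted states so q and RCR always describe
the same numbers (q = √(1 − 1/RCR) exactly).

The four set points are derived at run time by bounded scalar maximization
(Brent-style, xatol 1e-8) of F_n(q) = qⁿ·s/(1+s)ⁿ on (0, 1), n = 1…4,
with an interior-optimum guard, cached after first derivation, and
compared against the printed constants (0.786, 0.910, 0.953, 0.972) plus a
1e-6-step grid argmax in the test suite rather than hard-coded.
Classification bands are half-open [lower, upper).

## Indirect calorimetry

RER = VCO₂/VO₂ per bin; bins with VO₂ = 0 are masked, never silently
dropped.  EE is the mass-exponent-normalized VO₂/BW^0.75 in
ml/min/g^0.75 — deliberately *not* converted to calories, because the
printed unit is the contract for this analysis; total body weight (the
per-animal mean over the analysis window) is used in the exponent, as the
choice of weight snapshot is otherwise arbitrary, and lean mass is not
part of the trace.  Substrate oxidation uses the protein-free
Péronnet–Massicotte equations, whose coefficients are quarantined in one
constants block (CHO = 4.585·VCO₂ − 3.2255·VO₂; FAO = 1.6946·VO₂ −
1.7012·VCO₂; L/min in, g/min out).  These place CHO = 0 at RER ≈ 0.7035
and FAO = 0 at RER ≈ 0.9961 — the standard fat/carbohydrate threshold
lines.  Under measurement noise RER can stray slightly outside that band;
negative oxidation rates are clamped to zero with per-bin flags and the
raw values kept in debug columns.

The circadian summary uses exactly the first two complete light+dark
cycles: the window opens at the first bin at/after the configured light
onset (a bin exactly at onset belongs to light) and spans 48 h — 96 bins
at 30-min width; shorter traces are an error stating the shortfall, longer
traces do not change the result.  Intake metrics are total food × diet
energy density (default 12.8 kJ/g metabolizable energy, standard chow) per
gram of mean body weight, and weight change in mg per kJ consumed.

## Proteome statistics

Differential abundance tests run on log2-transformed intensities (the
field norm for label-free quantification); fold changes are reported on
the linear scale.  A protein is called regulated iff p < α (default 0.05,
raw by default — BH-adjusted gating is available) *and* its ratio passes
the symmetric 1.5-fold gate.  Zero-variance-in-both-groups proteins are
excluded with a reason code.  Note the fold gate dominates the null
behavior: with no true effects the p-gate alone fires at ≈ α per protein,
while the combined default gate fires orders of magnitude more rarely.

Enrichment is the one-sided hypergeometric upper tail with the EASE-style
penalization: the observed overlap k is replaced by max(k−1, 0) before
taking P(X ≥ k), so single-protein overlaps can never drive a call.  The
unmodified tail is available as `variant="classic"`, and the test suite
checks EASE ≥ classic exhaustively over all margins N ≤ 12 against a
rational-arithmetic oracle.  BH correction is applied across pathways.

Pathway effect sizes follow the estimation-plot scheme: each protein is
z-scored across all samples pooled (the overall experimental mean and
population SD), per-group protein means are averaged into a pathway mean z
per group, and the group difference carries a 95% t-interval whose unit of
replication is the member protein.  Singleton pathways are reported with a
NaN-width CI and a flag.

mtDNA copy number is 2^(mean Ct(Lpl) − mean Ct(Nd1)) per animal,
replicate means first, reported relative (no diploid ×2), so only group
contrasts are interpreted.

## Test selection

Two groups: Shapiro–Wilk per group at α = 0.05 (the conventional level);
both must pass for the unpaired two-tailed Student t-test (Welch off by
default, switchable), otherwise Mann–Whitney U — exact when both n ≤ 8 and
no ties, normal approximation with tie correction above.  Groups below
n = 3 or with zero variance skip the gate and force the nonparametric
branch with the reason recorded.  A fully tied pooled sample short-circuits
to p = 1.  More than two groups: one-way ANOVA with Tukey HSD.  BH is the
standard step-up with monotone enforcement, input order preserved.
Correlations are Pearson, reported as R² with the two-sided zero-slope p.

## Synthetic cohorts

The generators define the study conditions: n = 6 animals/group, technical
triplicates, 5% tick noise CV and 5% between-animal CV for flux plates;
72-h cage traces in 30-min bins starting at the 06:00 light onset; 1090
proteins with 73 up- and 13 down-regulated at two-fold across 5
samples/group; qPCR triplicates from 5 animals/group.

Flux-plate defaults encode the anticipated contrasts: state 2 down
40%/36%, state 3 down 55%/56%, state 3u down 42%/47% (complex I/II), an
unaltered complex-I RCR, and a complex-II leak collapse that moves the
stressed group's coupling degree past the economic-power set point
(q ≈ 0.975 vs 0.856).  Tick dynamics are an instantaneous step at each
injection plus optional linear within-phase drift — per-measurement OCR
points are all an instrument exports, so nothing finer is modelled.  Two
mechanisms can push state-4o ticks negative (negative drift, or
subtraction of the non-mitochondrial signal); both are options rather than
a single asserted cause, and both exercise the offset rule.

Cage traces use a light/dark square wave for EE and RER plus a 12-h
sinusoidal ripple with zero phase-mean (so configured phase means are
exactly recoverable), multiplicative EE noise (CV 5%), additive RER noise
(SD 0.02), Poisson activity and dark-biased food intake.  Default phase
means give total EE 7.2 vs 6.3 ml/min/g^0.75 with the decrease carried by
the dark phase, and RER 0.95 vs 0.89; per-phase values (Ctrl 6.3/8.1, Cvs
5.9/6.7) were chosen to honor those totals and the dark-driven structure,
which cannot be reconciled simultaneously with every printed per-phase
range under equal-phase weighting.  VCO₂ is constructed as RER(t)·VO₂(t)
exactly, so RER noise lives in the ratio, not independently in both gases.

Every generator draws from `default_rng([master_seed, stream_id])` so
streams are independent and adding a generator never shifts another's
draws; identical seed and config give bit-identical outputs.  Each
generator returns a ground-truth sidecar (configured means, per-animal
factors, planted DE sets, true ratios) sufficient to score recovery;
analysis code never reads sidecars — the pipeline writes them to disk for
audit but no reader exists inside the analysis modules.

What the generator does *not* emulate: instrument-level oxygen-diffusion
kinetics, pharmacokinetics of the injected compounds, mass spectra or
protein inference, behavioral feeding structure, or realistic inter-animal
covariance between data kinds.  Passing recovery tests therefore
demonstrates the correctness of the estimators under the stated noise
model, not robustness to every artifact of real instruments.

## Problem sizes and numerical choices

Recovery checks run 100 seeded cohorts at the default sizes above (~20 s
total); the set-point optimizer tolerance is 1e-8 with a 1e-6-step grid
cross-check; BH and Tukey come from statsmodels, Shapiro/t/Mann–Whitney/
hypergeometric from scipy.  Summary JSON rounds floats to 10 decimals and
sorts keys, which is what makes rerun outputs byte-identical.  Degenerate
inputs are handled explicitly rather than propagated: empty abundance
tables return zero counts, zero-intake animals get NaN weight-change
ratios with a warning, fully tied comparisons return p = 1, and a failed
offset (any state-4o still nonpositive after c) is an internal error
because the rule makes it impossible.

## Configuration

Pipeline runs are configured in YAML (schema version 1); exactly one data
source — simulation block or input paths — per data kind.  The output
directory receives per-stage CSVs (self-describing headers), truth
sidecars when simulating, `summary.json`, and `manifest.json` with the
SHA-256 of the canonical config, the seed and library versions.

## Known limitations

The q/η_opt mapping assumes state 4o is a pure leak measurement and state
3 a fully loaded flow; partial oligomycin inhibition or ADP limitation
biases q upward.  The batch offset rule shifts ratios for *all* samples
whenever one state-4o reading is negative, so RCRs from offset batches are
not comparable across batches with different offsets (the offset is
reported for exactly this reason).  The estimation-plot CI treats member
proteins as independent replicates, which overstates precision for
co-regulated pathways.  No repeated-measures or mixed models: each phase
summary value enters group tests as one independent observation per
animal.
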