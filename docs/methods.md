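# Methods

## The AHP stage

A screen compares k alternatives of one factor on four criteria: biomass
(OD600), protein concentration (g/L), surface tension (mN/m) and
clear-zone diameter (cm). The hierarchy is goal → criteria → alternatives.

**Criteria weights.** The four criteria carry importance ranks
(biomass 1, protein 2, surface tension 3, clear zone 4; larger = more
important). The criteria judgment matrix is reconstructed from these ranks
by the *ceiling-of-ratio* rule: for ranks `s_i ≥ s_j`,
`a_ij = min(9, ceil(s_i/s_j))`, reciprocals below the diagonal. This rule
was chosen because it is the one reconstruction that reproduces the
published criteria weights (0.10, 0.18, 0.29, 0.43) and criteria
consistency ratio (0.017) exactly; it is pluggable (`nearest`, `log`, or
any callable) for sensitivity analysis.

**Alternative weights.** Each criterion's measured values generate a
judgment matrix the same way, after converting to effective values
(`v` for benefits, `1/v` for the surface-tension cost). Zero measurements
(non-producing alternatives: no clear zone) cannot enter a ratio; a
positive-vs-zero comparison maps to the scale maximum 9 and zero-vs-zero
to indifference 1, which keeps every matrix on the Saaty scale instead of
producing infinities.

**Prioritization and consistency.** Weights are geometric means of matrix
rows, computed in log space (a 60-item matrix with extreme entries would
otherwise overflow the row product), normalized to sum 1. The default
`λ_max` estimator is the row-ratio average `(1/n)Σ(Aw)_i/w_i`, which is
the arithmetic that matches the published per-matrix diagnostics; an exact
principal-eigenvalue estimator (power iteration, relative tolerance 1e-10)
is available via `lambda_method="eigen"`. `CI = (λ_max−n)/(n−1)`,
`CR = CI/RI(n)` with Saaty's RI table (n ≤ 10), acceptable below 0.1. For
n ≤ 2 a reciprocal matrix is always consistent and RI = 0, so CI = CR = 0
by definition rather than dividing by zero. An inconsistent matrix does
not abort the analysis: the ranking is produced and flagged, because in
practice the flag is what prompts re-elicitation.

**Synthesis.** Overall weight of alternative j is
`Σ_c w_c · w_{c,j}`; mass is conserved (overall sums to 1). Ties at the
top break to the earliest row with a warning.

**Composite CCD response.** To score designed-experiment runs on all four
indices at once, `composite_response` computes
`Y_k = Σ_c w_c · sign_c · x_{c,k} / Σ_k x_{c,k}` — column-sum
normalization of each index across runs, signed by direction (surface
tension −1), weighted by the criteria weights; `max` and `minmax`
normalizations are selectable. The construction behind the response
column printed with the packaged 20-run table is not fully recoverable
(for the zero-clear-zone run the default formula gives −0.0116 against a
printed −0.0134; the two columns correlate at 0.9998), so the fitting
stage always prefers an explicitly supplied response column, and the
packaged analysis uses the printed responses verbatim.

## The RSM stage

**Design.** `generate_ccd(k, alpha, n_center)` builds 2^k factorial ±1
points, 2k axial points at ±alpha and n_center centers, in canonical
order with an optional seeded shuffle. Alpha defaults to the exact
rotatable value 2^(k/4). For k = 3 this is 1.68179…, conventionally
printed as 1.682 — the packaged run table stores the printed levels and
the loader restores the axial entries to full precision by default, which
is what reproduces the published ANOVA to the printed digit.

**Fit.** The full 10-term second-order model is fitted by QR-based least
squares; no stepwise selection is performed, since the reference ANOVA
reports all nine non-intercept terms. Rank-deficient designs are rejected
with the collinear columns named. Leverages come from the thin-QR factor;
`PRESS = Σ (e_i/(1−h_ii))²` gives predicted R² without explicit
leave-one-out refits (their equivalence is property-tested).

**ANOVA.** Term sums of squares are partial (drop-one), computed in
whatever units the design was supplied; in a CCD the linear terms are
orthogonal to the rest, so partial and sequential SS coincide for them.
Pure error pools squared deviations within groups of exactly identical
design rows; lack of fit is the residual remainder. Lack-of-fit rows are
emitted only when replicates exist. p-values are upper-tail F
probabilities and are never used for control flow.

**Units.** The full quadratic model space is closed under affine maps, so
R², F statistics and predictions are identical in coded and actual units
(tested). The default coded↔actual mapping uses centers lactose 5,
yeast extract 6, NaCl 20 g/L and steps 2, 3, 10 g/L per coded unit. The
steps are not printed anywhere in the source study; they were recovered
with `infer_steps`, which exploits `β_coded,ii = β_actual,ii · step_i²`
— the published actual-units equation and the coded refit agree with
these steps to ~0.5%, i.e. exactly, to printed precision.

**Optimum.** `stationary_point` solves `∇Y = 0` (optionally with some
factors frozen) and classifies by Hessian eigenvalue signs.
`constrained_optimum` returns the interior stationary point when it is a
maximum inside the box, and otherwise evaluates a dense grid (default
101 per axis over [−1.682, 1.682]^k) followed by a bounded L-BFGS-B
polish; both paths are deterministic. On the packaged data the surface
has no interior maximum — production keeps increasing with yeast extract
— so the optimum lies on the design-region boundary.

## Synthetic data

`simulate_screen` draws a screen with a known latent utility per
alternative: each index is a linear monotone transform of normalized
utility into plausible instrument ranges (OD600 0–1.2, protein 0–7 g/L,
surface tension 55 down to 30 mN/m — decreasing in utility — clear zone
0–7.5 cm) plus independent Gaussian noise scaled as a fraction of the
range and truncated at zero (surface tension clipped into (0, 100]).
Gaussian-with-truncation was preferred over a lognormal because realistic
index values sit far from zero except for designed dropouts, which are
injectable explicitly (`dropouts` forces zero clear zones, emulating
non-producing carbon sources). One `SeedSequence` substream per index
means adding an index never perturbs the others, and equal seeds give
byte-identical tables.

`simulate_ccd` evaluates a known 10-term coded-unit β on the CCD points
and adds N(0, σ²) noise. At σ equal to the packaged fit's residual
standard error the median refit R² over seeded replicates stays within
0.05 of 0.97, and fitted coefficients fall within three sampling standard
errors (σ·√((X'X)⁻¹)_jj, using the generator's known σ) of the generating
β in ≥ 99% of coefficient draws — the nominal three-sigma rate is 99.7%.
With the model-estimated σ̂ instead, the pivot is t-distributed with 10
degrees of freedom and the nominal 3-SE coverage drops to 98.7%; the
known-σ form is therefore the calibrated check.

What the simulator does *not* emulate: correlated noise across indices
(in real broths biomass and protein are strongly coupled), run-order
drift, heteroscedasticity, and any mechanistic growth dynamics. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to real-world measurement
structure.

## Numerical and design choices

- Displayed report values are rounded to 4 decimals, mirroring the source
  tables; all internal arithmetic is double precision.
- `consistency_index` clamps λ_max estimates up to 1e-6 below n (rounding
  artifacts) to zero and rejects anything lower.
- The CR threshold 0.1 and the RI table are configurable only through the
  pipeline configuration file, not per call.
- Ties in ranking break to the earliest row, with a warning, so results
  are deterministic under permutation.
- Configuration is schema-validated (unknown keys rejected) before any
  computation; CSV is UTF-8, comma-separated, `.` decimal, headers
  required.

## Known limitations

- The value→comparison quantizer used to build the published per-screen
  alternative matrices is unstated in the source study, and none of the
  implemented quantizers reproduces its printed per-matrix λ_max values;
  those are treated as descriptive. With the default ceiling quantizer
  the pipeline reproduces five of the seven published screen winners; the
  liquid-volume and carbon-source screens rank the published winner
  second and third respectively (both near-ties), which the
  characterization test surfaces as a quantizer-review warning rather
  than a failure.
- The AHP stage assumes criteria independence; interactions among indices
  are only captured later, by the response-surface stage.
- The composite response construction is an approximation of the source
  study's (unstated) one; supplied response columns always take
  precedence.
- Only full second-order models are supported (no stepwise selection,
  Box–Behnken designs, or multi-response desirability optimization).
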