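# Methods

## The model

The package analyses factorial optimisation experiments in which a
culture response — here the percentage of *n*-dodecane mineralised after
incubation, measured by GC-FID and averaged over triplicate flasks — is
modelled as a quadratic function of k coded culture factors.  Coding maps
an actual setting x to (x − centre)/step, so a factor's five design
levels are the integers −2…+2; the four packaged factors are pH
(centre 7.25, step 0.75), temperature (20 °C, 10 °C), diesel
concentration (2.5 % v/v, 1.5), and NaCl (1.0 % w/v, 1.0).  Two of these
decode to negative concentrations at the −2 level; a `clamp_floor` of 0
is applied only when producing bench run sheets.  The regression always
uses the planned coded levels, never the clamped actuals: the clamp is an
execution convenience and using it in the model would distort the design
geometry (the published predicted values are consistent with the planned
levels).

The full second-order polynomial (intercept, k linear, k squared,
k(k−1)/2 interaction terms; p = 15 for k = 4) is estimated by ordinary
least squares (via statsmodels) on the central composite design: 2^k
factorial points at ±1, 2k axial points at ±α, and replicated centre
points.  α defaults to 2, matching the ±2 coded span of the factor
table.  Responses are treated as single observations per run (triplicate
means); replicate-level variance is not modelled because per-run SDs are
not available in the packaged tables.

## ANOVA and diagnostics

Per-term sums of squares follow the extra-sum-of-squares (partial,
Type-III-style) principle: SS(term) = SSE(model without the term) −
SSE(full model), each tested as F = SS/MSE on (1, n−p) df.  The CCD's
linear and interaction columns are mutually orthogonal, so for those
terms partial and sequential SS coincide; the squared terms are
non-orthogonal to the intercept and to each other, and there the partial
convention is the one that reproduces the published tables.  The
lack-of-fit split identifies replicate groups by exact equality of coded
rows (tolerance 1e-9): pure-error SS is the within-group squared
deviation (df = Σ(group−1)), lack-of-fit the remainder of the residual,
tested as an F ratio of their mean squares.  With no replicated runs the
split is omitted with a warning.

Fit statistics: SD = √MSE; CV% = 100·SD/ȳ; R² = 1 − SSE/SST;
adjusted R² = 1 − (SSE/df_res)/(SST/(n−1)); PRESS = Σ(eᵢ/(1−hᵢᵢ))² from
the hat diagonals, which is algebraically identical to explicit
leave-one-out refitting (asserted in tests to 1e-8 relative); predicted
R² = 1 − PRESS/SST; adequate precision = (max ŷ − min ŷ over the design
points)/√(p·MSE/n), the signal-to-noise definition used by the classical
RSM software.  If any leverage reaches 1, PRESS is undefined and reported
as missing.  p-values come from the F distribution; report writers render
p < 1e-4 as "< 0.0001" while storing exact values.  Displays round to
2 decimals (4 for the R² family); all arithmetic is full precision.

## Optimisation

A quadratic restricted to a box attains its maximum at the interior
stationary point or on a face, so `maximize_box` enumerates all 3^k
configurations (each coordinate free, at the lower, or at the upper
bound), solves the reduced stationary system on each face, keeps feasible
candidates (vertices are the all-fixed configurations), and returns the
best — exact and deterministic, with ties broken toward lexicographically
smallest coded coordinates.  The default region is the factorial cube
[−1,+1]^k: the axial points exist to estimate curvature, not to be
operating conditions, and the cube is the region over which the fitted
optimum of the ADL15 surface equals the published predicted value; the
region is an explicit argument (and CLI flag) because that choice is a
modelling judgement, not a property of the data.  Stationary-point nature
comes from Hessian eigenvalue signs (tolerance 1e-10); a singular Hessian
raises rather than silently entering ridge analysis, which is out of
scope.  Desirability is the single-response "maximize" ramp — 0 at or
below `low` (default 0), 1 at or above `target` (default 100%), linear
between — sufficient for a single response; multi-response desirability
is not implemented.

## Biodegradation efficiency

Peak tables are matched to a C8–C20 *n*-alkane standard ladder by
retention time: candidate (peak, standard) pairs within `rt_tol`
(default 0.05 min) are assigned globally nearest-first, each alkane label
used at most once, exact-distance ties resolved toward the earlier
eluting peak with a warning.  BE(%) = 100 − A_s·100/A_ac per alkane;
alkanes missing from the sample score 100, alkanes missing from the
control are excluded with a warning, and negative BE (peak growth) is
reported with a flag rather than clipped, since it is a useful
abiotic-control quality signal.  The total BE pools areas over the
control's alkanes (100 − 100·ΣA_s/ΣA_ac), reading "total peak area" as
the sum over matched n-alkanes.  Raw chromatogram processing (baseline,
peak picking, integration, vendor formats) is out of scope; inputs are
integrated peak tables as CSV.

## Synthetic data

`simulate_ccd_response` evaluates a known quadratic truth over the CCD
and adds iid homoscedastic Gaussian noise.  The truths of interest are
the two packaged published surfaces, and the matching noise scales are
their residual SDs — 4.17 (ADL15) and 7.50 (ADL36) percentage points;
`noise_sd` is a required argument rather than a hidden default.  The
generator emulates the mean structure and residual scale of the real
experiment but not heteroscedasticity, run-order drift, replicate-level
variation, or response bounding at 0/100%, so simulation-based tests
establish estimator correctness and calibration under the stated model,
not robustness to those features.  `simulate_chromatograms` builds
control/sample/standard peak tables with specified per-alkane fractional
reductions, optional relative area noise (clipped at −0.99 to keep areas
positive), and retention times linear in carbon number (2.0 min +
0.9 min/C — an arbitrary but documented convention, since no retention
times are published for this system).  All generators take an explicit
seed and are byte-reproducible; design noise and chromatogram noise use
independent `numpy` Generator streams.

Design generation is implemented directly: the CCD by enumeration of its
three blocks, and Plackett–Burman designs by the classical cyclic
first-row generators for n ∈ {8, 12, 16, 20} (each subsequent row a
cyclic shift, closed by an all-minus row), validated by the XᵀX = nI
orthogonality property.  PB main effects are mean(+1) − mean(−1) per
column; unused columns become dummy factors whose apparent effects
estimate noise, giving a pseudo standard error √(mean(dummy effect²)) and
a t test on n_dummy df.  No published PB matrix or effect table exists
for this study, so PB support is validated by construction properties and
simulated responses only.

## Packaged tables and reproduction accuracy

The two 30-run CCD response tables, the factor-coding table, and the two
published coded-unit regression equations ship as CSV/JSON package data
with a SHA-256 manifest checked at load time; the published randomised
run order and sign conventions are preserved (U+2212 minus normalised to
ASCII on parse).  Refitting those tables reproduces every published
coefficient to ±0.01, the predicted columns to ±0.02 per run, F
statistics to ±0.01–0.04, and the R² family to ±0.0002.  The published
responses are printed to two decimals, and propagating that ±0.005
rounding through the quadratic forms moves SS-scale outputs (PRESS,
per-term SS) by a few tenths and large F ratios by ~0.01; tests therefore
assert SS-scale quantities at 0.1% relative and F ratios at
max(0.01, 0.1%), the precision the printed inputs support.  Observed
agreement is ~0.03% on every SS-scale quantity.

## Problem sizes

All computations are desk scale: 30-run fits (p = 15), 3^4 = 81 face
systems per optimisation, 500-replicate calibration checks — the full
test suite and the acceptance script each run in seconds on one CPU.

## Known limitations

No model reduction (all 14 non-intercept terms are kept, as in the
published equations, even where individually non-significant); no
Box–Cox transformation, mixed models, blocking, Box–Behnken or D-optimal
designs; no multi-response desirability or ridge analysis; no
chromatogram signal processing.  Whether the original analysis used peak
areas or heights, and its exact optimisation region and desirability
weights, are not recoverable from the published record; the defaults here
(areas; factorial cube; 0–100% ramp) are stated choices validated against
the published optima.
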