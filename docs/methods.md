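# Methods

## The design and the coded scale

The supported design is the three-factor Box–Behnken design: the 12 edge
midpoints of the factor cube — every (±1, ±1, 0) pattern over the three
factor pairs — plus `n_center` replicated centre points (default 5, which
gives the 4 pure-error degrees of freedom of a 17-run study). Runs are
emitted in a fixed canonical order (pairs (A,B), (A,C), (B,C), each in
(−,−), (−,+), (+,−), (+,+) order, centres last); bench randomisation of run
order affects no statistic computed here and is out of scope. Factor levels
are coded by the affine map `coded = (actual − centre)/half-range`, and only
symmetric codings (centre = midpoint of low and high) are accepted — an
asymmetric triple would silently distort every quadratic coefficient, so it
is an error rather than a warning. Points beyond |coded| > 1.2 are flagged
as extrapolation.

On this design each linear column satisfies Σx = 0, Σx² = 8; interaction
columns have Σ(xᵢxⱼ)² = 4; and the quadratic block of (XᵀX) is the symmetric
matrix [[17,8,8,8],[8,8,4,4],[8,4,8,4],[8,4,4,8]] whose inverse has diagonal
0.2375 for the quadratic terms — the constants behind the ANOVA below.

## Model fitting and ANOVA

The response — the count of analytes with mean recovery inside the
compliance window — is modelled as a continuous quantity by the full
ten-term second-order polynomial, fitted by ordinary least squares through a
QR factorisation (rank detected on singular values with relative tolerance
1e-10; a deficient design raises rather than pseudo-inverts).

The variance decomposition follows standard DoE practice:

* **Per-term SS** are Type-III (partial): `SSⱼ = βⱼ² / [(XᵀX)⁻¹]ⱼⱼ`, i.e.
  8β² for linear terms, 4β² for interactions and β²/0.2375 for quadratics on
  BBD(3)+5 centres. Type-III was chosen over sequential SS because the
  quadratic columns are mutually correlated, so sequential SS would depend
  on term order. Note a consequence worth stating explicitly: the per-term
  Type-III SS of the quadratic block do **not** sum to the model SS; the
  model row is computed from the dispersion of the fitted values, and only
  the first-order (linear + interaction) block is additive.
* **Pure error** is the within-group SS of replicated design points (the
  centres); **lack of fit** is the remainder of the residual, tested against
  pure error with an F ratio. An unreplicated design degenerates to
  lack-of-fit = residual with a warning.
* **F tests** use the residual mean square; p-values come from the upper
  tail of the F distribution, rendered `<0.0001` below 1e-4. Significance
  flags are `**` for p < 0.01 and `*` for 0.01 ≤ p < 0.05.

Because every per-term SS and the model SS are functions of the
coefficients and the design only, a printed ANOVA table can be reproduced
from a published regression equation plus the aggregate residual and
pure-error SS (`ResponseSurfaceResults.from_aggregates`) without the raw
runs.

### Adequacy statistics

R² = 1 − SSres/SStot; adjusted R² uses the df-corrected ratio; PRESS is the
leave-one-out sum Σ(eᵢ/(1−hᵢ))², giving predicted R² = 1 − PRESS/SStot;
adequate precision is (max ŷ − min ŷ over the design points) / √(p·MSres/n)
with p = 10 and n the run count, with > 4 as the usual usability threshold.
PRESS and predicted R² require the raw residuals and are reported as
unavailable (None) in the aggregate-only path.

One non-obvious property of BBD(3): the leverage is constant within point
classes (0.75 at edges, 0.2 at centres), the pure-error subspace is
supported on the centres and the lack-of-fit subspace on the edges. PRESS
of any response consistent with given aggregates therefore equals
SS_lof/(1−0.75)² + SS_pe/(1−0.2)² = 16·SS_lof + 1.5625·SS_pe,
independent of the noise direction — so predicted R² is itself recoverable
from a published table, and the package's constructed-response round trip
reproduces it exactly.

## Optimisation over the design region

A quadratic in three variables is maximised over the coded cube exactly:
the 27 coordinate patterns {free, −1, +1}³ enumerate the cube's interior,
faces, edges and vertices; on each, the restricted stationary system (a
≤3×3 linear solve) yields a candidate if it lands inside the face; the best
candidate is the global maximum. Restrictions with singular Hessians are
skipped — their optima lie on lower-dimensional faces, which are enumerated
anyway. Ties break to the lexicographically smallest coded point. No
iterative optimiser and no convergence tolerance are involved; agreement
with a dense 0.01-step grid is asserted in the tests.

The stationary point solves H x = −b with H_ii = 2b_ii, H_ij = b_ij, and is
classified by eigenvalue signs with a relative zero tolerance of 1e-8; a
singular Hessian raises an error carrying the flat direction.

The predicted response at the optimum is a real number; because the response
is a count of whole analytes, the default rounding policy truncates toward
zero (a surface value of 42.55 compliant drugs is reported as 42 — the 43rd
drug does not pass because the surface says "42.55"), with `nearest` and
`none` selectable.

## Validation statistics

* **Compliant count**: recovery per record is 100·measured/spike; the
  per-analyte mean is compared with the window with *inclusive* endpoints —
  inclusivity makes the boundary case deterministic, and the convention is
  stated rather than left to float comparison accidents. The window is
  applied at all spike levels by default; the concentration clause
  (spikes above 10 µg/kg) is available as configuration
  (`enforce_spike_threshold`).
* **CCα/CCβ**: `CCα = 0.2·VL + 1.64·SD`, `CCβ = CCα + 1.64·SD`, with SD the
  sample standard deviation of measured concentrations at the 0.2×VL spike
  pooled across days (the pooling convention is a package choice; day-mean
  alternatives are easy to compute from the same records). The algebraic
  identity CCβ = 2·CCα − 0.2·VL holds exactly and is property-tested.
* **Matrix effect**: slope ratio of matrix-matched vs solvent calibration
  minus one, in percent; |ME| ≤ 50 (boundary included) is "mild_or_medium",
  beyond is "strong". Calibrations are OLS straight lines on
  (level, response); weighted schemes are out of scope.
* **LOQ**: the stated operational definition — concentration at
  signal-to-noise 10 — is implemented as `10·conc_ref/SN` under local
  linearity of S/N in concentration. (The compact formula "LOQ = 10 × S/N"
  sometimes quoted is dimensionally inconsistent; the concentration form is
  what is computed.)
* **Precision**: intra-day RSD pools per-day RSDs by root mean square over
  days with ≥ 2 replicates; inter-day RSD is the RSD of all replicates
  across days pooled together (computing it from day means instead is a
  known alternative; the all-replicates convention is used and stated).

## The synthetic generator

`SyntheticTruth` emulates the spiked-recovery study: each analyte has a
quadratic recovery surface in the coded factors (baseline at the centre,
linear, interaction and curvature terms), measurement noise is
multiplicative Gaussian — analytical CVs scale with level — with CV
defaulting to 8 % (mid-range of typical intra-day RSDs for this kind of
method), and per-analyte matrix/solvent slope pairs carry the true matrix
effects. The default panel is 43 analytes with baselines in 88–106 %,
curvatures in −14…−4 per coded unit² and small linear/interaction terms,
which makes the expected count surface span roughly 20–42 across the cube —
the scale of a three-sorbent clean-up pushed away from its optimum — and
the SD at the 0.2×VL spike defaults to 0.549 µg/kg, i.e. a CCα of
10.9 µg/kg at VL = 50 µg/kg. Replicate structure follows the validation
scheme: 6 parallel determinations × 3 days at 0.2×VL, triplicates across
the design.

All generators are pure functions of (parameters, seed).

Two points about what the simulations do and do not show:

* **Recovery of the optimum.** The expected compliant count saturates near
  the centre (nearly every analyte passes with probability ≈ 1), so the
  count surface has a flat plateau and its raw argmax is not a stable
  target. The well-posed estimand is the maximiser of the quadratic
  projection of the noise-free expected count at the design runs — the
  infinite-replicate limit of the estimator itself
  (`SyntheticTruth.surrogate_maximizer`). Parameter-recovery tests measure
  the distance of fitted maximisers to that target (≤ 0.15 coded units
  across 20 seeds under the default conditions).
* **CCα calibration.** The estimator uses the plain sample SD, whose
  small-sample bias at n = 18 (c₄ ≈ 0.9854) shifts the mean CCα by about
  −0.013 µg/kg; the Monte-Carlo acceptance band (±0.05) covers bias plus
  simulation error. The estimator is deliberately not c₄-corrected because
  published limits are computed with the plain SD.

The generator emulates the statistical structure of the experiment, not its
chemistry: no chromatograms, retention times, carry-over, heteroscedastic
calibration error beyond the multiplicative model, or analyte-analyte
correlation (co-eluting drugs would fail together in real data). Passing
tests therefore demonstrate the correctness of the computational chain
under the assumed noise model, not method performance on real extracts.

### Constructed-consistent responses

`construct_consistent_response` builds `y = Xβ + e` with `e` orthogonal to
the model space, its centre-contrast component scaled to the requested
pure-error SS and the remaining (lack-of-fit) component to the remainder of
the residual SS; the direction within each subspace is seed-randomised.
Refitting any such vector returns the input coefficients to machine
precision and reproduces every ANOVA entry — the round trip that anchors the
aggregate-reproduction path.

## Numerical choices

* OLS via QR, never normal equations; rank tolerance 1e-10 (relative).
* Hessian eigenvalue zero-tolerance 1e-8·max|λ|.
* Optimiser tie tolerance 1e-12 on response values.
* ANOVA internal consistency asserted at 1e-6 relative on construction.
* Delimited files: comma-separated UTF-8, one header row, decimal point
  only. Concentrations in µg/kg for sample quantities and µg/L for
  calibration levels, with unit-suffixed column names where confusion is
  plausible.

## Known limitations

* Only the 3-factor Box–Behnken family is implemented — no central
  composite, D-optimal or blocked designs, and no run randomisation.
* No stepwise term selection, transformations, or weighted least squares.
* Desirability-style multi-response optimisation and confidence regions
  around the optimum are out of scope.
* The actual mg levels of the reference study's factors were not published;
  `datasets.reference_design` therefore carries placeholder mass ranges, and
  results tied to the coded scale are unaffected while actual-unit optima
  for that study cannot be reproduced.
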