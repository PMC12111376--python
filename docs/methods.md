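# Methods

This note documents the models, conventions, numerical choices and known
limitations of `hygrostab`.

## Moisture conventions

All model-facing moisture is dry basis (g water / g dry solids); wet-basis
percentages (as a gravimetric oven assay reports them) are converted at
ingestion via M_db = (M_wb/100)/(1 − M_wb/100). The water mass fraction
used by the Gordon–Taylor rule is total-mass based, W = M_db/(1 + M_db).
Mixing bases silently is a common source of inconsistency in the
literature; here every `MoistureValue` carries its basis and conversion is
an exact involution.

## GAB isotherm

M(a_w) = m0·b·C·a_w / [(1 − b·a_w)(1 − b·a_w + C·b·a_w)], with m0 the
monolayer moisture (g/g db), C an energy constant and b a correction
factor. The model has a pole at a_w = 1/b, so b is bounded in (0, 0.9999]
during fitting and evaluation is restricted to a_w ∈ [0, 0.95]. Fitting is
bounded trust-region least squares (scipy `curve_fit`) with deterministic
perturbed restarts; initialisation m0 = mid-grid moisture, C = 1, b = 0.9.
GAB is notoriously ill-conditioned near b → 1, hence tight optimizer
tolerances (1e-14) so noiseless round trips recover parameters to better
than 1e-3 relative.

The monolayer activity a_w0 solves M(a_w) = m0 by bisection (derivative
free, deterministic; bracket (0, 0.95], tolerance 1e-9 on a_w). Isotherm
inversion uses tolerance 1e-12 so the moisture round-trip error stays
below 1e-6 even where the isotherm is steep. With the published rounded
parameters (m0 = 0.06, C = 1.10, b = 0.99) the computed a_w0 is 0.493;
the study's own readout of 0.48 came from the unrounded fit, which is not
recoverable from the printed values, so this package always reports the
value computed from the parameters at hand rather than hard-coding a
literature number. The same applies to state-diagram readouts
(T_g ≈ 15.6 °C at a_w 0.32 and ≈ −33.8 °C at 0.65 from the printed
parameters, versus 14 / −41 °C printed from the unrounded fit).

## DVS equilibrium rule

A sorption step counts as equilibrated at the earliest sample time t such
that (max − min)/mass(t) over the inclusive window [t, t + 8.5 h] is below
1e-4 (0.01 %). The right window edge is linearly interpolated because the
instrument samples every 20 min and the window end rarely falls on a
sample. Both conventions (inclusive endpoints, interpolation) are explicit
because the rule is otherwise ambiguous at the edges.

## Gordon–Taylor and the state diagram

T_g(W) = ((1−W)·T_gi + ε·W·T_gw)/((1−W) + ε·W), with T_gw fixed at −135 °C
(amorphous water; overridable in the fit signature only). Only T_gi and ε
are free. The literature on this system reports the fitted pair as
"T_gi and k"; since Eq.-level k denotes the solids fraction, the second
fitted quantity is interpreted as the Gordon–Taylor parameter ε — the only
free interaction parameter the model has.

The modified state diagram chains T_g through the isotherm:
a_w → M_db → W → T_g. The chained curve is strictly decreasing, so the
critical a_w (where T_g equals the storage temperature) is a unique
bisection root. Storage at an ERH is mapped to a_w = ERH/100 (equilibrium
assumption, consistent with salt-solution conditioning). State labels use
ΔT = T − T_g with a closed transition band: glassy for ΔT < 0, transition
for 0 ≤ ΔT ≤ 5 °C (a ΔT this small is not enough for a complete
glass–rubber transition), rubbery beyond; the band width is configurable.

## Storage kinetics

Moisture (wet %, days) and dissolution absorbance (420 nm, seconds) follow
the asymptotic first-order law Y(t) = Y∞ − (Y∞ − Y0)·e^(−kt); Y∞ < Y0
covers the drying observed at 11 % ERH. Equation-text in the source
literature swaps the labels of Y0 and Y∞; the implementation follows the
algebra (Y(0) = Y0), which also matches the tabulated values. Brew pH
follows pH(t) = pH0·e^(−kt), fitted on the original scale (not
log-linearised, so the implied error model stays additive Gaussian).

Initial guesses: Y0 = first observation, Y∞ = last, k = ln 2 / (time of
the first half-range crossing); pH rate seeded by the log-linear slope.
Time units are per-series and fixed per response (days for storage
responses, seconds for dissolution); mixing units is a hard error rather
than a silent conversion.

The published pH rate constants (0.38–2.11, printed unitless) are
physically consistent with the observed ~0.1 pH drop over 180 days only on
a 1e-4 day⁻¹ scale. The package therefore stores fitted rates in day⁻¹,
generates long-horizon study series on the physical scale, and reports
both the raw fitted k and its table-unit magnitude (k / 1e-4); the display
scale is never silently applied to arithmetic. Parameter-recovery targets
exercise the printed magnitudes as-is on correspondingly short time grids.

Times-to-threshold are closed form
(t = −ln((Y∞ − level)/(Y∞ − Y0))/k and t = ln(pH0/level)/k) and
cross-checked against numeric root-finding. A level outside the open
response interval raises "never reached"; a pH threshold already passed at
t = 0 returns 0 with a warning, by convention.

## Freshness imaging

Membership in the fresh RGB box is inclusive on both bounds and requires
all three channels simultaneously — the most literal reading of
"within the selected ranges". The index is 100·(in-range count)/(baseline
in-range count), deliberately not clamped above 100. Automatic calibration
replaces manual screening with symmetric per-channel quantile intervals
(coverage 0.99 by default, rounded outward to integers) and asserts the
reference's own in-range fraction is at least coverage − 0.03. Images are
converted to 8-bit RGB on load; ICC profiles, illumination correction and
colorimeter emulation are out of scope (L\*a\*b\* data are tabular inputs).

## Group statistics

Both ANOVA partitions are computed from explicit sums of squares (the
repeated-measures F is MS_time / MS_subject×time with the subject effect
removed). No sphericity correction is applied — none is used in the
emulated analysis — and reported df are uncorrected. Tukey HSD uses the
Tukey–Kramer statistic with critical values from scipy's numerically
integrated studentized-range distribution (no table lookup). Letter
displays use insert-and-absorb and re-verify the share-a-letter ⇔
not-significant equivalence exhaustively on every call, raising rather
than emitting an inconsistent display. Letters are assigned in descending
order of group means, ties broken lexicographically.

## Synthetic-data generator

The generator reproduces the emulated study's structure, not its raw data
(which exist only as figures): 3 ERH conditions (11/32/65 %) at 20 °C,
triplicate series per response, a 0–0.9 isotherm grid in 0.1 steps, T_g
points at the seven salt-conditioned ERH levels (1, 11, 23, 32, 43, 54,
65 %), and powder image series. Generating parameters default to the
published fitted values; noise is additive Gaussian, independent across
points and replicates, at the printed measurement-SD scale (isotherm
0.002 g/g; T_g 1 °C; moisture 0.11 %; absorbance 0.004; pH 0.03). Default
time grids are dense regular grids over the printed observation spans
(0–19/0–30 days moisture, 3–120 s dissolution, 0–180 days pH at 15-day
intervals) because exact sampling times are not published.

Image degradation uses exact pixel-count replacement: image t contains
round(fraction_t · n_pixels) pixels drawn uniformly inside the fresh RGB
box and the rest brightened out of range, making the freshness index
analytically known (100·fraction_t). The fraction is tied to the simulated
wet-basis moisture through a logistic link f(M) = 1/(1 + e^{0.8(M−9.7)}),
chosen so the 65 % ERH condition loses about 70 % of its fresh pixels
within one week while the 11/32 % conditions stay near 100 % — the
qualitative pattern of the emulated study. No residual autocorrelation,
illumination drift or packaging physics is simulated; passing tests
demonstrate estimator correctness and pipeline plumbing under the study's
statistical structure, not robustness to real-world imaging or sorption
artefacts.

Every generator is a pure function of (parameters, seed); reruns are
byte-identical, and `gen_study` manifests record the seed, config hash and
per-file SHA-256.

## Pipeline

Stages run isolated: a failure (e.g. a corrupt CSV) marks the report
partial and records the error without aborting other stages. Kinetic fits
in the pipeline use the replicate-mean trajectory per condition; per-
replicate fits remain available through the library/CLI. Determinism is
end-to-end: identical inputs and config give an identical report.
Problem sizes throughout (triplicates, ≤31 time points, 64×64 images,
2000-replicate null simulations) match the emulated study design and keep
the full suite fast on a laptop.

## Known limitations

Single temperature only (no Arrhenius/WLF extrapolation); adsorption
branch only (no hysteresis, no BET comparison); no mechanistic sorption
models (Fickian, Peleg, Weibull); no DSC thermogram processing (T_g onset
values are inputs); no Couchman–Karasz alternative mixing rule; freshness
imaging assumes comparable illumination between baseline and follow-up
photographs.
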