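# Methods

This note documents the models implemented in `synucalc`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Multi-ligand binding model (nmr_csp)

The titration model treats L calcium ions as binding one protein molecule
as a single unit: P + Ca_L ⇌ P·Ca_L with dissociation constant
K_D = [P][Ca_L]/[P·Ca_L]. Conservation of protein and of calcium
([Ca²⁺]_total = L([Ca_L] + [P·Ca_L])) reduces the equilibrium to a
quadratic in the bound-protein concentration, giving the closed form for
the bound fraction χ_B used as the fitting function (see README). The
closed form was cross-checked against direct root-finding on the
mass-action system to 1e-6 over random parameter draws; that oracle is kept
in the test suite. χ_B is monotone nondecreasing in total calcium and tends
to 1 at excess calcium. With K_D ≪ [P] the curve is nearly stoichiometric:
an almost linear rise that breaks at [Ca²⁺] = L·[P], which is what makes L
identifiable separately from K_D.

**Global fit.** Observed weighted CSPs Δδ_obs(r, C) of the selected
residues are fitted jointly to χ_B(C; K_D, L)·Δδ_sat,r by bounded
nonlinear least squares (scipy `least_squares`, trf). Fitting in shift
space rather than dividing by Δδ_sat first is algebraically the same
residual up to per-residue weighting and avoids dividing by a parameter
that is itself being estimated. Defaults: init K_D = 100 µM, L = 5,
Δδ_sat initialised at the top-concentration CSP; bounds
K_D ∈ (0, 10⁴] µM, L ∈ (0, 50]. Standard errors come from the Jacobian
(s²(JᵀJ)⁻¹). Δδ_sat is fitted per residue rather than fixed to the last
titration point because the top concentration need not fully saturate
the sites; initialising at the last point makes the choice cheap.

**Residue selection.** Residues whose CSP at the top concentration exceeds
mean + 2 SD of all residues form the default "major perturbation" set;
an explicit list can be supplied. Bound fractions computed from noisy
shifts can exceed 1; `chi_B` clips them to 1 and logs the event.

**Broadening.** Exchange broadening is flagged as intensity ratio
I(C_max)/I(0) below a threshold (default 0.7) for residues whose CSP stays
below a shift cut (default 0.05 ppm), separating residues that broaden
from residues that shift.

## CEST scoring (cest)

Measured profiles are intensities I_sat/I_ref per residue over the offset
schedule ±(1.5–9) kHz plus 0, with the reference saturated at −100 kHz.
The scalar score 1 − mean(I, |Ω| ≤ 4 kHz)/mean(I, |Ω| ≥ 7 kHz) contrasts
the near-resonance dip with the far-offset shoulder; the 4/7 kHz split is
chosen from the gap in the acquisition schedule. No exchange rates or
bound-state populations are extracted — comparisons between conditions are
ordinal by design. Region comparisons bootstrap the per-residue score
differences (1000 resamples, seed 42, percentile CI).

## Cluster radius from localisation data (smlm)

Per ROI, all pairwise distances are binned (default 10 nm up to the region
diameter) and divided by the mean histogram of `n_rand` = 50 uniform
placements of the same number of points in the same region (Monte-Carlo
CSR correction, seeded; this handles arbitrary ROI shapes and boundary
effects without analytic edge terms). ROI segmentation is single-linkage
connectivity at 200 nm with a minimum of 50 localisations, the ROI region
being the centroid disc padded 10%.

For any unimodal cluster the per-bin ratio obs/CSR is maximal in the first
bin and decays outward — its argmax carries no size information. The
radius is therefore read from the decay edge: the largest distance at
which the CSR excess (ratio − 1) still exceeds half its peak
(`method="half_max"`, default). For a Gaussian cluster of scale σ this
crossing sits at 2σ√(ln 2) ≈ 1.7σ, is monotone in σ, and lands at ~45 nm
for σ = 30 nm. The literal argmax (ties toward smaller distance) and the
largest-distance-above-1 reading are available via `method="argmax"` and
`"gt1"` for comparison. A pattern is flagged unreliable when the
normalised histogram is statistically flat: max/median < 1.2 over
well-sampled bins (≥ 5 expected pairs), or a peak excess within 3
Monte-Carlo SDs of 1. Group comparisons use Welch's two-tailed t-test on
per-ROI radii with a Welch-df confidence interval; unbalanced groups are
accepted as-is.

## Vesicle classification (vesicles)

Vesicle centres within 250 nm are linked; connected components define
clusters, so a chain A–B–C is one cluster of three even when A–C exceeds
250 nm (transitive linkage — the natural graph reading of "number of
vesicles within a 250 nm radius"). Percentages are reported over vesicles
(share of vesicles in components of size 1, 2, ≥ 3), matching how the
condition percentages are quoted; component-based percentages are also
computed since the denominator convention for pair percentages is
ambiguous. Exact duplicates (within 1 nm) are merged with a warning.
Condition comparisons run a per-category one-way F test plus Tukey-HSD
adjusted pairwise differences; zero-variance layouts short-circuit to the
degenerate answers (all p = 1 if everything is identical; perfect
separation if replicates are constant within conditions but differ between
them).

## Aggregation kinetics (tht)

`fw_model` implements the two-step logistic with exponent (k₁ + k₂A₀)·t;
B(0) = 0 holds algebraically and is asserted to machine precision. The fit
estimates (A₀, k₁, k₂) plus a baseline offset jointly — subtracting a
pre-estimated baseline instead biases k₁ noticeably because the model's
slow early growth leaks into any fixed pre-transition window. Rates are
reported per hour throughout.

The tangent lag uses baseline = median of the pre-transition samples
(first 10% of points, capped at the last sample below 10% amplitude), an
elongation line fitted over the 20–80% amplitude window of the rising
flank, and the line/baseline intersection as the lag; step-like
transitions with no in-window samples fall back to the two samples
bracketing the jump. The 20–80% chord slope underestimates the true
inflection tangent by ~10%, so chord and tangent lags agree (within 2%)
only when the lag is long relative to the transition width — the
slow-nucleation regime k₁ ≪ k₂A₀ typical of amyloid self-assembly, which
is where the closed-form comparison is made in the tests. Lag times from
replicate experiments are computed on the averaged curve per condition.

SEC monomer quantification is an ordinary least-squares line through the
(area, concentration) calibration points; queries outside the calibrated
range are flagged as extrapolated.

## MS stoichiometry (ms)

Adduct masses use the charge-balanced convention: each bound Ca²⁺
displaces two protons, net +38.063 Da per calcium (average masses —
appropriate for the intact-protein, non-isotope-resolved regime; the
convention is declared in output metadata). Deconvolution scans a
zero-charge mass grid (0.2 Da step), summing spectrum intensity within
0.05 Th of each candidate's protonated m/z across charges 9–19; local
maxima above max(3× median score, 1% of peak score) that are supported by
at least 3 charge states become species. The support and relative-floor
filters remove single-charge coincidence artefacts; the grid step bounds
the mass error at half a step. The protein's average mass is a required
input — no sequence database is embedded.

## Synthetic-data generators (simulate)

Generator defaults mirror the study conditions: titrations at 200 µM
protein over 0–3.6 mM calcium (16-point grid concentrated around the
stoichiometric break), the 13 C-terminal perturbation sites, saturation
CSPs drawn in 0.05–0.25 ppm, 1% multiplicative shift noise; CEST tables
simulated by two-state Bloch–McConnell evolution under 400 Hz
continuous-wave saturation at the printed offsets (bound state broadened
to R₂ = 2·10⁴ s⁻¹, exchange 50 s⁻¹, 0.4 s saturation) with 2% noise;
vesicle fields of ~300 vesicles in 20×20 µm (~0.75 µm⁻²) with single
fractions 88/84/81% for the EGTA, calcium and protein+calcium presets
(the split of the clustered remainder between pairs and triples is a
modelling choice — only the single fraction is quoted per condition);
plate-reader traces on the 16-min × 300-cycle grid with 18 wells and 2%
noise; electrospray envelopes over charges 9–19 with geometric adduct
decay. Vesicle entities are placed by rejection sampling with a 320 nm
inter-entity exclusion so the realised composition is exact by
construction; chain members are spaced 40–200 nm.

What the generators do *not* emulate: peak overlap and assignment errors
in spectra, spectral folding or detector saturation, localisation drift
and multi-blinking artefacts, secondary nucleation or fibril
fragmentation, isotope structure and adduct heterogeneity beyond calcium.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated statistical structure, not robustness to every
instrument artefact.

The ThT condition presets place lag times in the published order
(calcium ≪ calcium-depleted) inside the 80 h observation window; the
published per-second rate-constant units could not be reconciled with the
16-min cycle time, so rates are parameterised per hour and the printed
rate values are treated as reference output only, not as recomputable
targets.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed and draws from its own
`numpy.random.default_rng`; fixed seed and config give byte-identical CSV
output. Replicated analyses use 20 seeded replicates (titration recovery,
vesicle fields), 50–100 CSR randomisations, 1000 bootstrap resamples —
sizes at which the Monte-Carlo error is comfortably below the decision
thresholds while the full test suite runs in well under a minute.
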