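# Methods

## Exact-mass arithmetic

All masses derive from one constants table of NIST/CODATA monoisotopic
atomic masses (¹H 1.00782503207, ²H 2.01410177785, ¹²C 12 exactly,
¹³C 13.00335483507, ¹⁴N 14.00307400443, ¹⁵N 15.00010889888,
¹⁶O 15.99491461957, ³²S 31.9720711744, ³¹P 30.97376199842 Da). Ion m/z for
the singly charged ±H adducts uses the bare-proton mass 1.007276 Da, i.e.
the electron mass is accounted for; this is what reproduces
instrument-reported values (glutamate [M−H]⁻ 146.0459, its dual-label
isotopologue 152.0597, glutathione 306.0765) at 4-decimal precision.
Reported m/z are rounded half-up to 4 decimals; internal arithmetic is
full double precision. Only C, H, N, O, S, P and charge ±1 are supported —
multiply charged species are rejected rather than silently mishandled.

Labels are tracked as substitution counts (n¹³C, n¹⁵N, nD), not atom
positions. The single position-specific fact the chemistry needs — that
one deuterium may sit on the α-carbon and is lost on deamination — is a
boolean flag. Measured values in the source data that disagree with theory
by ≤ 1 mDa (e.g. a printed D₄ shift of 4.0256 Da vs the theoretical
4.0251, or a dipeptide m/z of 275.0886 vs 275.0885) are treated as
instrument readings; the package always computes theoretical values.

## Transaminase futile-cycle model

**Reaction.** Glu + OAA ⇌ αKG + Asp under mass action, with a
dimensionless enzyme-activity factor E multiplying both rate constants.
The network is expanded over a restricted isotopologue space (amino acids:
n¹³C ∈ {0,5}, n¹⁵N ∈ {0,1}, nD ∈ {0,4,5}; ketoacids carry no ¹⁵N and no
α-D) with three transfer rules: ¹⁵N follows the amine, ¹³C₅ follows the
C5 skeleton, the α-deuterium is lost to solvent on deamination and
reamination installs ¹H. These rules make two conservation laws hold by
construction — total ¹³C₅ skeletons (Glu+αKG) and total ¹⁵N (Glu+Asp) —
and make total α-deuterium non-increasing. The integrator preserves the
linear conservation laws to floating-point error (~1e-15 relative).

**Assumptions.** Deterministic ODEs (pool sizes are µM-scale; stochastic
fluctuations are irrelevant); a single transaminase couple (Glu/Asp) with
OAA as the only amine acceptor; no enzyme saturation (effective
bimolecular constants); no other glutathione/protein reactions (generic
sink terms are out of scope by default).

**Default study conditions.** 82 µM doubly labeled [¹³C₅,¹⁵N]-glutamate
and 82 µM D₅-glutamate spiked at resuspension into an extract with 82 µM
endogenous unlabeled glutamate, a 250 µM endogenous aspartate pool, and
2.5 µM each αKG and OAA (≈1:100 ketoacid:glutamate). The large aspartate
pool is required for the amine nitrogen to exchange out of glutamate in
quantity; without it the doubly labeled tracer cannot fall below ~40% of
its input and the tens-of-µM ¹⁵N-aspartate seen experimentally is
unreachable. OAA defaults to the αKG-sized pool.

**Rate constants.** k_fwd = k_rev = 0.05 µM⁻¹ hr⁻¹. These are documented
defaults, not fits: they were calibrated once so that the doubly labeled
tracer is ~80–90% consumed by 24 h in the active scenario, and then
frozen. Under them the 24 h state mirrors the experimental picture:
~80% of the dual tracer consumed, an approximately equimolar gain of
[¹³C₅]-only glutamate, ~41 µM ¹⁵N in aspartate, and <1 µM ¹³C₅ retained
in αKG (the small ketoacid pool turns over fast).

**Interventions.** `filtered` (3 kDa protein removal) sets E = 0;
`aoa` (aminooxyacetic acid) decays activity as E₀·exp(−t/τ) with
τ = 0.01 hr by default, leaving a brief window of catalysis before
inhibition takes hold; `active` leaves E = 1.

**Integration.** Fixed-step classical RK4 with h = 0.01 hr by default; the
step is shrunk uniformly inside each save interval so grid points are hit
exactly, keeping runs bit-reproducible. Any concentration falling below
−1e-9 µM aborts with an instruction to reduce the step. On an exactly
linear two-pool exchange the solver tracks the closed-form solution to
<1e-6 µM at the default step. A cumulative integral of the forward
(Glu → αKG) flux is carried alongside the state as the ground-truth event
counter; the label-based cycle estimate (final [¹³C₅]-only + [¹⁵N]-only
glutamate) is never allowed to exceed it, and strictly under-counts
whenever reverse flux exists, because regenerated doubly labeled
glutamate is indistinguishable from the input tracer.

## LC-MS observation model

Each isotopologue pool becomes one feature. Peak area =
concentration × response factor × area scale × multiplicative lognormal
noise with the configured CV (unit mean; CV = 0 gives exact
proportionality). Response factors are drawn per *metabolite*, not per
isotopologue — co-eluting isotopologues ionize identically, which is the
physical basis of label-ratio quantitation. Observed m/z gets a
Normal(0, sd) ppm error (default 1 ppm) and retention time a Gaussian
jitter (default 0.02 min) around a canonical per-metabolite RT. Injections
are equally spaced (default 25 over 0–84 hr). All draws come from one
seeded generator; identical seeds give identical tables.

Twenty "inert" features emulate the non-reacting metabolome. They carry a
slow protein-independent monotone drift (log-scale change over the series
drawn with sd 0.35) present in *every* scenario, reflecting the
solubilization/oxidation drift that real extracts show even after
filtration; without it, autoscaled PCA of the filtered group would be
dominated by injection noise rather than smooth low-rank structure, which
is not what repeat-injection data look like.

MS2 fixtures plant a configurable number of precursors carrying the
glutathione-diagnostic fragment (m/z 308.0912 within ±2 ppm by default,
precursors spaced >10 ppm apart so isobaric grouping resolves them) among
decoys whose fragments are kept ≥10 ppm away; ground truth is stored per
record.

**What the generator does not emulate** — chromatographic peak shapes
beyond Gaussians, ion suppression and matrix effects, missing values,
saturation, natural-abundance isotope envelopes, and enzyme reactions
beyond the single transaminase couple. Tests passing on these fixtures
therefore demonstrate correctness of the statistics and bookkeeping, not
robustness to every artifact of real data.

## Quantitation

Calibration is unweighted OLS of area ratio on known concentration
(weighted 1/x and 1/x² variants available but off by default, since no
weighting scheme is canonical here); R² is reported and interpolation
inverts the line, flagging extrapolation beyond the standards and
clamping negative concentrations to zero with a warning rather than
dropping them. When the internal standard itself interconverts, the
label-ratio route multiplies the labeled/unlabeled area ratio by an
independently determined endogenous concentration; it is scale-invariant
in the areas. Mole balance sums *skeleton equivalents* — a whole ¹³C₅
backbone counts once, a ¹⁵N once, and a doubly labeled molecule counts
once per element — per replicate, reporting totals and the deviation from
the spiked input both per replicate and on the group mean (the
conservation claim is checked both ways because either reading is
defensible). A helper converts µM in the resuspension to per-mg-tissue
amounts via the extraction volume rule (sample mg / 40 mg × mL solvent).

## Drift statistics

**Trend test.** Natural cubic regression spline with df = 4 (boundary
knots at the series range, interior knots at equally spaced quantiles) fit
to log₁₀(area+1) versus time, F-tested against the intercept-only model.
A fixed-df spline was chosen over a penalized smoother because it is
transparent, dependency-light and exactly calibrated (null p-values are
uniform by construction); df is configurable. The basis was cross-checked
against R's `splines::ns` + `lm` F-test (identical F and p on frozen
fixtures). Constant series return p = 1 with a flag; series shorter than
df+2 points are rejected. Significance defaults to raw p < 0.05 per group;
a Benjamini–Hochberg FDR column is always emitted alongside.

**PCA.** log₁₀(x+1), per-feature mean-centering and unit-variance
autoscaling, each independently switchable; zero-variance features are
dropped with a warning; SVD-based. Drift magnitude is the accumulated
Euclidean distance between consecutive injections in the first two PCs
(dims exposed). The path length is invariant to rotation and shift of the
scores and scales linearly with them, so only within-analysis comparisons
are meaningful; absolute published path values from other pipelines cannot
be matched without knowing their exact scaling.

**Deduplication.** For compounds measured by several chromatographic
methods, the row with the lowest pooled-QC CV is kept; ties break by
lexicographic method name, which is arbitrary but deterministic.

**Intersections.** UpSet semantics: every feature in the union is
assigned to the exclusive region given by the exact set of groups calling
it significant.

**LogP correlation.** Log₂ fold change uses the ratio of replicate means
(not the mean of per-replicate ratios), with an optional pseudocount for
zero means; Spearman correlation with average-rank ties and the two-sided
t approximation for p.

## Screening

Chromatographic peaks are local maxima delimited at flanking minima;
base width is valley-to-valley (FWHM was considered and rejected as the
default because the width filter is phrased as a base-width cut; the
valley definition is the simplest contract consistent with it). Filters:
base width > 6 s AND apex ≥ 1e5 counts. Fragment screening selects MS2
records containing the diagnostic fragment within 10 ppm (separate,
looser than grouping because fragment mass accuracy is worse at MS2
resolution), then groups precursors by single-linkage within ±2 ppm.
Label-pair finding reports ordered (light, heavy) pairs whose m/z gap
matches a label shift within a ppm tolerance of the heavy mass and whose
RT difference is within a coelution window (defaults 5 ppm, 0.1 min).
Blank filtering keeps features with sample mean ≥ 3× blank mean
(inclusive boundary; a zero blank keeps any detected feature); the factor
3 is a convention, exposed as a parameter.

## Problem sizes and numerical choices in the test suite

Simulation-based checks use the default 13-species network: conservation
over the full 0–84 hr grid; 50 random-rate runs (rates log-uniform in
[0.005, 0.2] µM⁻¹hr⁻¹) over 24 h for the cycle-estimate contract; 20
seeded replicates with technical triplicates for the intervention
ordering; 20 seeded 25-injection series for the drift-path ordering; 2000
simulated null features for trend-test calibration; 14 planted + 50 decoy
spectra for screening. These sizes were chosen so every property is
exercised at the study's stated scale while the whole suite stays fast
enough to run routinely.

## Known limitations

* One transaminase couple only; real extracts contain many
  donor/acceptor pairs and additional enzyme classes (glutathione
  reductase, transferases, proteases) that this model represents at most
  as drift in inert features.
* Effective mass-action kinetics: no PLP ping-pong mechanism, no enzyme
  saturation, no temperature/pH dependence.
* The acceptor pool composition of real extracts is unknown; the default
  aspartate/ketoacid pools are plausibility choices documented above, and
  conclusions that depend on absolute pool sizes should be re-derived
  with measured values.
* Fixed-step RK4 is not suited to stiff parameter regimes
  (k·pool ≫ 100 hr⁻¹); the solver detects failure rather than adapting.
* The drift path length depends on the PCA scaling convention; only
  relative comparisons under one convention are supported.
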