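# Methods

## Two-state duplex melting model

The core model treats a non-self-complementary duplex (two distinct
strands mixed equimolar, total strand concentration C_T) as populating
exactly two states, with temperature-independent formation enthalpy ΔH°
(kcal/mol) and entropy ΔS° (cal mol⁻¹ K⁻¹). The dissociation constant
follows the van't Hoff form K_D = exp(ΔH°/(RT) − ΔS°/R) with
R = 1.987 cal mol⁻¹ K⁻¹; the fraction of strands in duplex form solves
K_D = C_T(1−f)²/(2f), taken as the unique root of the quadratic in
(0, 1) and evaluated in a rationalised form that is stable for K_D many
orders of magnitude above or below C_T. Observed absorbance is a
baseline-weighted mixture of two straight lines in temperature (the
duplex and single-strand signals); the temperature dependence of
single-strand extinction coefficients is absorbed into those sloping
baselines rather than modelled separately.

Assumptions and scope: equilibrium melting only (no heating-rate or
cuvette effects), a single transition, bimolecular stoichiometry with
the C_T/4 concentration term throughout. Self-complementary duplexes,
multi-state transitions, nearest-neighbour ΔG prediction and salt
corrections are out of scope. Internally all temperatures are Kelvin;
I/O uses °C. ΔH° is stored in kcal/mol and ΔS° in cal/(mol·K) so that
published tables can be used directly as inputs; unit conversion is
confined to the ΔG°₃₇ and T_m formulas.

## Curve fitting

`fit_two_state` minimises Σ(A_obs − A_model)² with
`scipy.optimize.least_squares` (Levenberg–Marquardt) over six
parameters: ΔH°, T_m, and the four baseline coefficients. ΔS° is not a
free parameter — it is derived from (ΔH°, T_m, C_T) through the T_m
relation. The (ΔH°, T_m) parameterisation is used because ΔH° and ΔS°
are nearly collinear in a direct fit, while T_m is pinned by the data;
this is standard practice for melt fitting. Convergence tolerances are
1e-10 on the relative change of cost, parameters and gradient, with at
most 2000 model evaluations; a fit that fails the optimiser's test is
returned flagged (`converged=False`), never silently.

Initialisation: baselines are least-squares lines through the first and
last 15% of the temperature range; T_m₀ is the peak of the smoothed
(boxcar, ~1/15 of the grid) numerical derivative dA/dT, with the
smoothing-biased edge points excluded from the peak search; ΔH°₀ comes
from the derivative peak height via the bimolecular two-state slope
relation df/dT|_Tm = ΔH°/(6 R T_m²), falling back to −50 kcal/mol when
the estimate is implausible (outside −400…−10 kcal/mol). A trace is
rejected as transition-free ("flat curve") when the separation of the
two edge baselines at the derivative peak does not exceed
max(8 × baseline residual SD, 1e-4 AU). These are stated conventions:
the initialisation of the legacy desktop software used for such fits is
unpublished, so no attempt is made to reproduce it beyond the model
itself.

Replicate aggregation is the unweighted mean ± SD of per-curve
parameters over converged fits (non-converged fits are excluded and
counted), matching the convention of averaging independently fitted
curves rather than fitting globally. Because ΔG°₃₇ is linear in
(ΔH°, ΔS°), the mean ΔG°₃₇ is identical to the parameter-averaged
value.

## Van't Hoff analysis

`vant_hoff_fit` is an ordinary least-squares regression of 1/T_m on
ln(C_T/4) (no errors-in-variables correction), requiring ≥ 3 points
spanning ≥ 2-fold in concentration; ΔH° = R/slope and
ΔS° = intercept·ΔH°. The two-state check is the symmetric percent
difference 100·|ΔH°₁ − ΔH°₂| / mean(|ΔH°₁|, |ΔH°₂|) with a 10% pass
threshold; the symmetric denominator avoids an arbitrary choice of
reference method. Both ΔH° values are always reported.

A note on error propagation: a 5–20 μM series spans only ln 4 ≈ 1.39 in
the regressor, so T_m scatter of SD σ maps to a ΔH° relative error of
roughly σ·T_m²·√2/(span·|ΔH°|/R) — about 12% per 0.3 K at
ΔH° ≈ −97 kcal/mol. Curve fits at the default noise level determine T_m
to ~0.03 K, which is why the full-pipeline consistency simulation
passes the 10% criterion with a large margin (median ≈ 2%), while
artificially large 0.3 K T_m scatter would not. The property test uses
0.1 K scatter, the scale the fits actually deliver.

## Extinction coefficients and concentration

Single-strand ε₂₆₀ uses the nearest-neighbour formula
ε = Σ 2·ε_dimer − Σ ε_mono over a bundled literature table
(`data/extinction_nn_260.tsv`, versioned; these constants are inputs,
not results of this package). Duplex ε is the sum of the two strand
values; strand concentration follows Beer–Lambert from the
high-temperature absorbance.

## Motif template and isostericity

The motif is a fixed 13-position template (left strand 1–7, right
strand 8–13, 5′→3′) with an invariant slot list: cWW(1,13), tSH(2,12)
"lower", tHH(3,11), cSH(4,5) bulge-to-triple, tWH(5,10), tHS(6,9)
"upper", cWW(7,8). Families are conserved across variants; only the
sequence varies. Position 5 belongs to two slots (the base triple).
Variants are named by mutation tokens against the prototype sequence
CUAGUAG/CGAACG (e.g. "U2G/C12A"); S/R-like architectures missing a pair
are represented by slot masks on the same template.

Isostericity matrices ship as a human-readable data file
(`data/isostericity_sr.txt`), one 4×4 grid per family, with cells from
{i1…i6, combined i-groups, near:iN, modeled:iN, "-"}. Reversed-order
families (tSH, cHS, tHW) are derived by transposition, so
classify(tHS, x, y) ≡ classify(tSH, y, x) by construction, and
symmetric families (tHH, cWW) are validated to have symmetric tables at
load time. The matrices are curated: group assignments come from the
base combinations explicitly documented as observed (or excluded) in
surveys of S/R instances in atomic-resolution structures, interpreted
against the published isostericity classification of non-Watson–Crick
families; combinations with no such evidence are conservatively marked
not-a-pair rather than guessed, and each grid carries a provenance
comment. Near-isosteric status is an explicit annotation, not computed
from geometry (IsoDiscrepancy-style computation is out of scope).
Substitution classes: forbidden (target cell empty), isosteric (group
overlap, no near annotation), near_isosteric (group overlap with a near
annotation), non_isosteric (disjoint groups).

## Temperature survey

Organisms are classed by optimal growth temperature with boundaries
<20 °C (psychrophile), 20–<50 (mesophile), 50–<70 (thermophile),
≥70 (hyperthermophile). One representative per species is kept: the
sequence with the most unambiguous A/C/G/U characters (i.e. fewest gaps
and ambiguity codes — the most complete sequence), ties broken by
smallest id so selection is order-independent.

Alignment columns are correlated with structure residue numbers by
degapping each candidate reference row, globally aligning it to the
ungapped structure sequence (Biopython PairwiseAligner; match +1,
mismatch −1, gap open −5, extend −1 — near-identical sequences, so the
scoring only needs to be pinned for determinism), choosing the row with
the most identically aligned non-gap positions, and threading the
residue-to-residue map back through that row's gap structure. Both
coordinate systems are 1-based. A best row under 90% identity to the
structure is an error: the mapping would be unreliable. Columns where
the reference row has a gap, and structure residues absent from the
alignment, are simply unmapped.

Frequency tables count base combinations per slot per temperature
class. Records with a gap or ambiguity at a slot's columns are excluded
from that slot's denominator only, and the exclusion count is reported
(how the original tabulations handled such records is not documented;
this convention makes the denominators explicit). An optional
deduplicated mode counts identical motif strings once per class — the
strict reading of "unique sequences" — and both modes are available.
Phylum stratification is reported for inspection but never used to
filter. Trends are descriptive (per-class fractions plus a
non-decreasing flag); no hypothesis test is attached, since class
counts at the realistic scale are too small for one to be meaningful.

## Synthetic data

The melting-curve generator evaluates the closed-form model on the
instrument grid (15–90 °C every 0.5 °C, 151 points) and adds iid
Gaussian absorbance noise, default SD 0.002 AU against a ~0.2 AU
transition amplitude — a convention chosen so that fits typically reach
R² ≥ 0.99 as real fits of good data do; the true instrument noise is
not published. Default baselines are A_DS = 5e-4·T + 0.70 and
A_SS = 1e-3·T + 0.86 (AU, T in °C), a typical hyperchromic geometry.
Replicates and concentration series derive per-curve sub-seeds from the
master seed via `numpy.random.SeedSequence`, so all generators are pure
functions of their spec.

The alignment generator plants the 13 motif columns inside a conserved
random background (default 120 nt, class counts 82/328/108/44 for
psychro/meso/thermo/hyper — the composition of a realistic curated 16S
dataset), drawing each sequence's motif from a class-conditional
per-slot composition. The default composition encodes the qualitative
survey picture: the upper tHS pair shifts from AA toward AG with rising
growth temperature (AG fraction 0.30/0.50/0.80/0.95) and the bulged G
leaks to U/A/C mostly in cold classes; all other slots stay prototype.
Within a class, growth temperatures are drawn uniformly (hyper capped
at 95 °C) — only the class label matters downstream. Deletions ('-')
and ambiguities ('N') hit survey rows at configurable rates, insertion
columns (gap in the reference) at the gap rate; reference rows
reproduce the structure sequence exactly so the ground-truth mapping is
well defined. What the generator does *not* emulate: phylogenetic
correlation between sequences, covariation between slots, alignment
errors, chimeric or misannotated sequences. Passing recovery tests
therefore demonstrates correctness of the pipeline's bookkeeping and
estimators under the stated statistical model, not robustness to the
messiness of real curated alignments.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses 5 replicate curves per duplex at
C_T = 100 μM, 500 repetitions of the four-concentration (5–20 μM)
Van't Hoff simulation, and 100 curves spanning ΔH° ∈ [−120, −40]
kcal/mol, T_m ∈ [30, 80] °C for the fit-quality sweep. The duplex used
for the Van't Hoff series is the double-mutant whose ΔG°₃₇ is
−15.9 kcal/mol; its entropy is not tabulated, so a prototype-scale
ΔS° = −250 e.u. is used, which sets the simulated T_m range
(≈ 61–64 °C across the series). Each target derives an independent
sub-seed from the master `--seed`.

## Known limitations

* The fitter assumes a single bimolecular transition; hairpin
  contributions, sequential transitions and aggregation are not
  detected beyond a poor R².
* Isostericity cells without explicit documentary evidence are marked
  not-a-pair; a combination genuinely observed elsewhere would be
  misreported as forbidden until the curated file is extended.
* The survey's column mapping assumes the reference organism's rows are
  nearly identical to the structure sequence; distant references fail
  loudly rather than degrade quietly.
* Melting in the presence of Mg²⁺ is treated identically to Na⁺-only
  data; ion-specific folding effects enter only through the measured
  parameters, not the model.
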