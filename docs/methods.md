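# Methods

## Carbonate-system solver

The CO₂ system in seawater is fully determined by any two of (DIC, TA, pH,
pCO₂) at known temperature, salinity and pressure. This package solves the
(DIC, TA) pair, the combination produced by a VINDTA-style coulometric/
potentiometric analysis. The alkalinity balance is the minimal carbonate +
borate + water form,

TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]_F − [HSO₄⁻] − [HF],

with optional phosphate (H₃PO₄/HPO₄²⁻/PO₄³⁻) and silicate terms for
nutrient-enriched culture media. The residual TA(pH) − TA_measured is
strictly increasing in pH; the solver runs safeguarded Newton iterations
(numerical derivative) bracketed on pH ∈ [2, 12], falling back to bisection
when a step leaves the bracket, to a tolerance of 1e−8 pH units. A plain
bisection oracle in the test suite agrees to 1e−6 pH units over random
seawater-range inputs.

Constant choices (all at 0 dbar, concentrations in mol kg-SW⁻¹): K₀ Weiss
1974; K₁/K₂ Mehrbach 1973 as refit by Dickson & Millero 1987, defined on the
seawater scale and converted to the total scale through the Dickson 1990
bisulfate and Dickson & Riley 1979 fluoride equilibria; K_B Dickson 1990;
K_W Millero 1995 (converted likewise); calcite solubility Mucci 1983;
borate, sulfate, fluoride and calcium totals proportional to salinity
(Uppström; Morris & Riley; Riley; Riley & Tongudai). This is the standard
companion set used by CO2SYS for the Mehrbach-refit K₁/K₂ option.

Salinity is an explicit input everywhere with default 35 (open-ocean English
Channel water); the culture experiments the package mirrors never report
salinity, so this is a documented assumption. pCO₂ is reported as an
uncorrected partial pressure in µatm (the quantity the source tables label
p.p.m.v.); no fugacity correction is applied.

**Known limitation.** The published end-state table this solver is validated
against is internally inconsistent in one row: its printed pH is lower than
the pH implied by its own printed species ratios by almost exactly
log₁₀(1 + S_T/K_S) ≈ 0.105 in both CO₂ treatments, i.e. a free/total scale
conversion appears to have been applied in the wrong direction in the
original processing. The package reproduces the printed species, pCO₂ and
Ω within ~2% but the printed pH only to ~0.1; we deliberately do not
replicate the inconsistent transformation. Related: the spec-level claim
that phosphate contributes < 1 µmol kg⁻¹ to TA at culture-media
concentrations is incorrect (HPO₄²⁻ contributes ≈ 1 µmol per µmol phosphate
at pH 8), so the validation solves with the measured end-point phosphate
(3.3 µmol kg⁻¹) included; the package default remains the minimal TA form.

## Physiology

µ = ln(C₁/C₀)/Δt over a user-chosen exponential-phase window (default: the
full observed span); g = log₂(N₁/N₀); production = quota × µ, the steady-
state per-cell synthesis rate in exponential growth — this identity
reproduces the published production values from the published quotas and
growth rates within last-digit rounding (±0.02 pmol cell⁻¹ day⁻¹).

The two-sample test is the unpaired pooled-variance t (df = n₁+n₂−2), not
Welch: the published degrees of freedom (4 for n = 3+3; 195 for n = 115+82)
force the pooled form, and published "±" values are treated as sample
standard deviations because that convention reproduces the published
t statistics (e.g. t(4) = 3.55 vs printed 3.556 from unrounded data).
No multiple-testing correction is applied, matching the source analysis.
The CaCO₃ quota blank correction uses an oceanic Ca/Na molar ratio of
0.0219 by default; it is a parameter because the original value is
unpublished.

## iTRAQ quantification

Reporter ratios are formed per PSM and replicate pair (high:ambient);
non-positive channels exclude the peptide from that pair. Ratios are
median-normalized across each whole replicate pair — this absorbs channel
loading bias under the assumption that most proteins are unchanged, which
holds in the motivating experiment (4 of ~46 quantified groups regulated).
Peptide weighting is the summed reporter intensity of the channel pair
(option: unweighted); the commercial engine's weighting is undocumented, so
this is an explicit stand-in. Outliers are removed by an iterated two-sided
Grubbs test at α = 0.05 on natural-log ratios, capped at 20% of a protein's
peptides. Identifications with a single peptide, or with exactly two
peptides of which one is erroneous (ratio outside [0.1, 10] or a
non-positive intensity), are not evaluable.

Across replicate pairs, G = exp(mean ln r) with a 95% CI of
exp(mean ± 1.96·sd(ln r)/√n). The normal z is used rather than Student t
(which with df = 2 gives far wider intervals): z = 1.96 exactly reproduces
the published interval bounds from the published replicate triples, so the
convention is reverse-engineered from the reference tables and stated here
openly. Thresholds are inclusive: down iff CI_upper ≤ 0.67, up iff
CI_lower ≥ 1.5.

From the printed (2-dp rounded) replicate triples, 68% of recomputed CI
bounds agree with the printed ranges at 2 dp exactly and 99% within ±0.01;
the residual spread is what input rounding alone produces. The four
down-regulated groups' primary rows agree exactly.

## Protein inference

ESTs are translated in all six frames (stops break segments); peptides map
by exact substring match (I/L distinct by default, mergeable); the
two-distinct-peptide rule drops weak identifications. Pairwise similarity is
Smith–Waterman local alignment (BLOSUM62, gap open 11 / extend 1 — the
BLASTP defaults) with an ungapped Karlin–Altschul e-value
(λ = 0.3176, K = 0.134) over the summed residue count of the clustered set;
single-linkage clustering links pairs passing BOTH e ≤ 1e−10 and identity
> 5%. The 5% identity floor is implemented literally as published despite
being permissive, and is a parameter. The e-value calibration is
deliberately conservative (ungapped parameters applied to gapped scores)
but reproducible without external search binaries; at the 1e−10 threshold
the decision boundary is far from both random-pair scores (e ≫ 1e−10 at
length ~50) and true-family scores (e ≪ 1e−10), so the conservatism does
not move cluster boundaries in practice. Representative = longest member,
ties broken by id.

## Synthetic data

The generator emulates the motivating experiment's design: three replicate
high:ambient channel pairs (114:113, 116:115, 118:117; 119/121 excluded as
the abandoned fourth replicate), ~46 quantified proteins with 4 regulated at
a true fold change of 0.4, 5 tryptic peptides per protein, log-normal base
intensities (ln-mean ln 10⁴, ln-sd 0.5), per-channel noise exp(N(0, 0.15)),
and ±20% channel loading biases to exercise normalization. Reporter noise is
log-normal on intensities — equivalently additive Gaussian on log ratios —
matching the geometric-mean statistics downstream; the real instrument's
spectrum-level effects (co-isolation interference, isotope impurity,
intensity-dependent variance) are not modelled, so passing recovery tests
demonstrates correctness of the statistical pipeline, not robustness to
those artefacts.

Cultures grow exponentially from 5×10³ cells mL⁻¹ for 4 generations at
µ = 1.29 (ambient) / 1.05 (high) day⁻¹ — the published end-point rates —
with 3% log-normal counting noise, sampled daily plus once at the exact
harvest time; bottle DIC at harvest is (1 − 0.04) × blank DIC, inside the
< 5% semi-constant-chemistry criterion. Quota means/sds follow the
published POC values; PON uses a Redfield-like C:N of 6.6 and CaCO₃ a
PIC:POC of 1 (the strain is heavily calcified and its published PIC:POC is
≈ 1 and CO₂-insensitive). All randomness derives from one seed through
named substreams; fixed seed ⇒ byte-identical files.

**Recovery-experiment design.** Call-recovery is validated on 200 proteins
with a 20% regulated fraction (40 at fold change 0.4, σ = 0.15), plus an
all-null 200-protein run. A 50% regulated fraction would break global
median normalization by construction (the median lands between the two
populations), so the recovery experiment keeps the regulated fraction in
the regime where the normalization assumption holds — as in the motivating
data, where < 10% of quantified groups were regulated. Measured this way,
down-call sensitivity exceeds 0.9 with zero false up-calls and the null run
makes no calls in either direction.

## Numerical choices and degenerate inputs

Speciation at fixed pH is closed-form, so the species sum to DIC
analytically; DIC = 0 speciates to (0, 0, 0). Zero-variance ratio triples
give a degenerate CI equal to G. A zero pooled variance with unequal means
reports an infinite t (flagged, p = 0). Grubbs removal needs n ≥ 3.
Blank-dominated CaCO₃ samples (correction > measured Ca) floor at 0 with a
logged warning. Unsolvable bottle samples (no TA root in pH [2, 12]) raise
a domain error naming the sample, and pipeline stages fail fast rather than
skipping downstream work.

## Problem sizes in the shipped validation

The test suite runs the solver oracle on dozens of random bottle pairs, the
recovery simulations on 200 proteins × 5 peptides × 8 channels, and HPG
recovery on 5–6 families × 3 members; the full pipeline demonstration uses
16 families. These sizes give stable pass/fail behaviour for every property
tested while keeping the whole suite fast enough to run on every commit.
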