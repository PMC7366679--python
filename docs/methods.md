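# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions and the design choices behind `mlproteo`, and
what the test suite does and does not establish about real data.

## Scope and inputs

The package starts where spectral search and scoring end. SAINT scores,
CRAPome-style contaminant frequencies, xQuest-style ld scores, integrated
PRM transition areas, DIA m-scores, decoy flags and phosphosite
localization calls are consumed as inputs; none of the upstream scoring
models are re-implemented. All tables are long-format TSV (UTF-8), one
measured intensity per analyte × condition × replicate. A missing intensity
is an empty cell or `NA`, never 0 — downstream missing-not-at-random
imputation must distinguish absence from small values, and a literal 0 is
rejected as invalid.

## Differential testing (all layers)

Per analyte and mutant-vs-reference contrast, the two-sided unpaired
Student's *t*-test with pooled variance is applied to log2 intensities;
Welch's correction is deliberately not used because the procedure is
defined as the classical equal-variance test. Degenerate inputs follow a
documented convention: zero pooled variance with equal means gives p = 1,
with unequal means p = 0. Benjamini–Hochberg adjustment is applied within
each contrast (not pooled across mutants), because regulation counts are
reported per mutant. Regulation calls use |log2FC| > 1 and adj. p ≤ 0.05 by
default; the network-integration criteria use the strict form adj. p <
0.05, and a second, stricter profile (adj. p ≤ 0.01, |log2FC| > 0.5) is
available for heatmap-style inclusion. Analytes with fewer than two finite
observations on either side of a contrast are excluded and logged rather
than tested.

The phospho/total-proteome group comparison is a deliberate surrogate: the
Bayesian group-comparison model of mapDIA-style tools is *not*
re-implemented. The surrogate (peptide-level log2 t-test + BH) keeps the
same thresholds and directions and is prominently documented here; its
p-values are not expected to match a Bayesian model's numerically.

## Imputation

*Interaction layer.* Missing log2 intensities are drawn from
Normal(μ = 5th percentile of observed log2 intensities, σ = 0.3 × observed
SD), truncated below at the observed minimum minus three observed SDs.
"A distribution based on the 5th lowest quantile" admits several readings;
this down-shifted normal is the standard MNAR imputation consistent with
it. Imputation is global (not per-run), seeded, and applied only to
analytes detected in ≥ 50 % of the runs of at least one condition; analytes
below that floor are reported but not tested. At least 20 observed values
are required to anchor the percentile.

*Cross-linking layer.* Missing normalized abundances take the global
minimum observed value (per the stated procedure); per-cross-link minima
are a configurable alternative reading.

Down-shift imputation under MNAR missingness is known to distort null
calibration near the detection limit: an analyte missing at random in one
condition gets a low imputed value and can produce a spurious call. The
calibration tests therefore feed complete planted-null data to the
differential stages; the imputation policy is tested separately for its
distributional properties (seeded determinism, Monte-Carlo mean at the
anchor percentile, observed values untouched).

## Cross-link quantification and geometry

Peak acceptance automates three manual review criteria: apex retention
time within ±2 min of the library value; light/heavy co-elution within
0.2 min; Pearson correlation ≥ 0.8 between the paired light/heavy
transition areas. The ±2 min window is the layer's stated criterion; the
co-elution and shape thresholds are this package's choices for the two
criteria that manual review applies qualitatively. Runs failing any
criterion are rejected with reason codes; fewer than three finite
transition pairs rejects with `insufficient transitions`. Flat (zero
variance) transition patterns correlate 1.0 when both channels are flat.

Abundance sums up to twelve transition areas (six per isotope channel)
after excluding transitions with SNR < 5 (SNR exactly 5 is kept, per
"< 5 were filtered out"); if nothing survives the value is missing, never
0. Normalization divides by the mean of the two non-cross-linked reference
peptides of the same run (mean vs sum is not determined by the procedure's
wording; mean is the default, sum is a switch).

Distance restraints use Cα–Cα Euclidean distance with an inclusive ≤ 30 Å
threshold (the DSS spacer implies "~30 Å", so the cut-off is
configurable). Residues outside the structure's covered range, or lacking
a Cα, classify as `unmappable` rather than violated. Because construct and
deposited-structure numbering can differ, an integer offset parameter
reconciles cross-link positions with author residue numbering. PDB
alternate locations resolve to the highest-occupancy conformer, ties to
the first in file.

PCA of runs over log2 cross-link abundances centers features and
eigendecomposes the sample covariance; component signs are fixed by making
each component's largest-magnitude loading positive, so scores are
reproducible up to that convention.

## DIA layer conventions

The detection filter is inclusive ("at least 30 %") with the denominator
equal to all runs across all conditions. Fragment selection correlates each
fragment's run profile with the peptide's mean fragment profile (the
reference profile is ambiguous in the source procedure; the mean profile is
this package's choice), drops r < 0.1, keeps the top six by total
intensity and requires at least three survivors. The FFT-scaled FDR is the
exact linear form FDR = FFT · n_decoy / n_target. Non-localized
phosphopeptides are carried with `localized = False`; motif analysis uses
localized peptides only, since the motif needs a site. The regulated-
fraction denominators use the significant set (adj. p ≤ 0.05), which is
configurable.

The motif R/K-x-x(-x)-S/T-P is matched as: phosphoacceptor in {S, T},
proline at +1, and R or K at −3 or −4; positions beyond either terminus
never match. The matcher is verified exhaustively against an independent
regular-language oracle for all sequences of length ≤ 6 over
{A,R,K,S,T,P}.

## Network integration

Node selection requires Cancer-Gene-Census membership (the CDP list is a
user-supplied input; no catalogue version is assumed) and regulation in at
least one layer under the strict criteria. Edges come from a user-supplied
reference interactome and, by default, must be experimentally validated
with at least one PubMed id. The EASE variant of over-representation
reduces the in-term hit count by one (floored at zero) before an upper-tail
hypergeometric test, which is never more significant than the plain
one-sided test. Grouping of related terms by shared ontology parents is
out of scope; an optional user-supplied term→group mapping can be applied
downstream.

## Synthetic-data model

The generators emulate the study design the pipeline targets: a wild-type
reference plus six mutant conditions, three biological replicates,
log-normal intensity noise (σ = 0.3 log2 units by default) and logistic
MNAR missingness P(missing) = 1/(1 + exp(slope · (log2 I − midpoint))) with
midpoint 17 and slope 1.2, giving a few percent missingness in the
abundant interactome range and ~20 % in the lower phospho range. One RNG
stream per generator call, seeded from the config seed plus a
stage-specific offset, makes stages independently reproducible and outputs
byte-identical under an identical config.

Deterministic id schemes (preys `P0001`…, cross-links `XL01`…,
phosphopeptides `PP0001`…, proteins `PR0001`…) let planted effects be
addressed by id. Analytes carrying planted effects draw their base
intensity from the abundant range, emulating core-complex subunits and
direct substrates: the quantified changes the pipeline targets concern
well-detected species, and planting a −3 effect on an analyte at the
detection limit would instead probe the imputation policy. Low-SNR
transitions are declared per trace (cross-link × channel × transition) and
applied in every run — a weak fragment ion is weak everywhere — which also
makes zero-noise fold-change recovery exact. The toy structure is a
straight Cα trace (3.8 Å per residue), so pairwise distances are controlled
exactly by residue separation; declared subsets of cross-links satisfy,
violate, or fall outside the covered range. The default planted-effect map
(`default_study_effects`) reproduces the qualitative mutant-panel pattern:
the truncation and kinase-dead mutants remodel the interactome and
phosphoproteome most, with motif-bearing downregulated sites; the mild
mutants mostly gain motif-free phosphosites; the total proteome changes
little.

What the generators do **not** emulate: retention-time drift,
chromatographic interference, correlated (batch) noise, peptide-level
missingness shared across charge states, sequence-dependent ionization,
or SAINT's internal statistics (scores are drawn from separated
distributions for true interactors vs contaminants). Passing
parameter-recovery tests therefore shows the downstream arithmetic and
calls are correct under the stated noise model, not that the pipeline is
robust to every artefact of real acquisitions.

## Problem sizes and defaults

Defaults: 200 preys, 300 phosphopeptides, 300 proteins, 14 cross-links
(plus three identifications built to fail the ld/length filter), 7
conditions × 3 replicates. The acceptance script uses 1,000 planted-null
analytes for calibration, 1,000 random vectors for the BH oracle and all
2×2 tables with margins ≤ 10 for the Fisher oracle; the test suite extends
the Fisher sweep to margins ≤ 12. These sizes give binomial standard
errors small enough for 3-SE acceptance bands while keeping the full suite
around ten seconds.

## Known limitations

- The t-test surrogate for the Bayesian DIA group comparison shares
  thresholds, not posterior probabilities.
- Imputation-induced calibration distortion near the detection limit is
  inherent to down-shift MNAR imputation (see above).
- Replicate correlation and PCA assume complete matrices; impute first.
- With three replicates, per-analyte fold-change estimates carry a
  standard error of σ·√(2/3); single-analyte reports at default noise are
  accurate to roughly ±0.5 log2 units at 2 SE.
- Fisher enrichment p-values depend on the background definition; the
  package requires the caller to provide the measured background
  explicitly rather than assuming one.
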