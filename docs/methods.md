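# Methods

## Site occupancy from peptide areas

A PTM site is a biological modification at an absolute residue of a specific
histone protein (H3K14ac = acetylation of lysine 14 of H3). Peptide-level
quantification exports give one normalized area per (peptide form, sample,
digest), where a form is a stripped sequence plus bracketed integer mass
shifts. For a site *s*, a localized form *covers* *s* when its protein span
includes the site residue; it is *modified* when it carries the site's
modification at exactly that residue. Carrying the same mark elsewhere, or
any other mark (including unresolved ones), leaves a covering form in the
unmodified partition — "unmodified" always means "lacking this mark at this
residue".

Per digest *d* and sample *j*:

    RA_d(s, j) = 100 · Σ_{modified covering forms} area / Σ_{all covering forms} area

with RA missing when the denominator is zero (no covering signal in that
digest). The three digests are parallel preparations covering the same sites
with different peptides; their RAs are averaged **unweighted over the
non-missing digests**, regardless of how many forms each contributes. A
profile is missing only when all three digests are; missing profiles are
counted and logged, never imputed. Averaging over available digests (rather
than dropping the profile when one digest lacks coverage) maximizes usable
data without inventing signal; it is the one place the averaging rule needed
a decision for partially covered sites.

β = RA/100 is clamped into [ε, 1−ε] with ε = 1e-4 so that 0% and 100%
occupancies — common in sparse samples — keep finite M-values; the M-value is
the base-2 logit, M = log2(β/(1−β)), following the β/M convention of the
DNA-methylation literature. The log base only rescales M by a constant and is
configurable (it cannot change any test decision).

Nominal (integer) masses are used throughout because that is what the
quantification exports print. At integer resolution +42 is ambiguous between
acetylation and trimethylation; the shipped table resolves +42 to acetyl on
K/S/T/peptide-N-term and can be overridden per residue (a +42→trimethyl
table is one YAML entry). A shift at peptide position 1 that matches no
direct (mass, residue) entry is decomposed into an N-terminus-allowed plus a
residue-allowed mass when exactly one such pair exists — +112 on an
N-terminal lysine becomes N-terminal propionyl (+56) plus side-chain
propionyl (+56). Propionylation is flagged `lab_introduced` and can never
define a biological site. A +57 shift on lysine, which appears in some
exports, matches no standard histone mark at nominal resolution; it is
reported as unresolved (and may be added to the table) rather than guessed,
and an unresolved mark does not remove a form from coverage.

Ambiguously localized peptides (multiple exact-substring hits, e.g. shared
histone-variant sequences) are excluded from quantification by default to
avoid double counting; a "count in all hits" policy is available.

## Differential model

Within one tissue and experiment, two treatment groups are compared across
the panel: Welch's unequal-variance t-test on M-values per site (group
variances of occupancy are routinely heterogeneous; Student's pooled test is
available by config), with a variance floor of 1e-12 per group so constant
groups remain testable (equal constant groups give p = 1). Sites with fewer
than two non-missing values in either group are untestable: excluded from
the family with the realized hypothesis count m reported. Fold changes are
computed on mean relative abundance (percent scale), treatment over
reference, with means clamped below at 0.01% so empty groups give large but
finite values; the volcano fold-change threshold defaults to |log2 FC| > 1
and is configuration, as is the q threshold (default 0.1).

Multiple testing uses FDR regression: for each λ in 0.05, 0.10, …, 0.95 the
indicator 1(p_i > λ) is regressed on the covariate design (intercept +
one-hot modification class, logistic link by default; a linear-probability
fit is available). The fitted probability divided by (1−λ) estimates
π₀(x_i; λ). Per covariate class the λ-profile is smoothed with a cubic
smoothing spline and evaluated at the largest λ, then clipped into [0, 1].
The spline uses inverse-standard-deviation weights — sd(π̂₀(λ)) grows like
sqrt(λ/(n(1−λ))) for a binomial indicator mean, so the noisy right end of
the grid is down-weighted rather than allowed to tilt the fit. Covariate
levels with fewer than two tests merge into the reference class; separation
or non-convergence of the logistic fit falls back to the intercept-only fit
for that λ (both logged). With a single λ configured, smoothing is skipped.

Conditioned q-values are q_i = π̂₀(x_i) · BH(p_i), monotonized
(non-decreasing in p by a running maximum) and capped at 1. With π̂₀ ≡ 1 this
is exactly Benjamini–Hochberg. Responsive means q < 0.1; the volcano class is
red (q- and FC-significant), blue (q only), green (FC only) or gray.

Each (tissue, experiment, group pair) is its own correction family. The
standard pairs are SW vs FW, SW/FW vs FW, SW vs SW/FW (short-term transfer
experiment) and S1 vs S0, S3 vs S0, S3 vs S1 (long-term salinity-pulse
experiment); families with insufficient samples in a group are skipped with
a logged reason.

## Homology mapping

Cross-species analogs are determined by the package's own global pairwise
aligner (Needleman–Wunsch with affine gaps, Gotoh recurrences): only
pairwise position projection is needed, so a self-contained aligner replaces
a progressive multiple-alignment tool; three-sequence comparisons are two
pairwise alignments against the common target. Defaults are BLOSUM62, gap
open 10, gap extend 1, with a gap of length L costing open + extend·L;
letters outside the matrix alphabet score 0 (neutral). Traceback is
deterministic: aligned pair over gap-in-query over gap-in-target at equal
score. The modification's allowed-residue set is the sole arbiter of the
"incompatible residue" verdict (e.g. lysine-ubiquitylation projecting onto
an arginine → no analog); a site inside a target deletion is `no_analog_gap`,
and analog calls also report residue conservation. N-terminal numbering
follows the input FASTA as given — whether an initiator methionine is
included is the caller's convention and is not second-guessed.

## Synthetic-data generator

The generator emulates the structure of a deposited quantification export:
per (site, digest) a set of covering peptide windows on a synthetic protein,
split into modified forms (carrying the site's mark at the site residue) and
unmodified forms (some decorated with a propionyl mark elsewhere, exercising
the covering-form rules). Per fish the occupancy is logit-normal around the
group truth, θ_i = expit(logit θ + N(0, σ_bio)); per digest the total
covering abundance is log-normal; the modified forms share θ_i of it and the
unmodified forms 1−θ_i, with symmetric Dirichlet(1) weights re-drawn per
fish; every area is finally multiplied by exp(N(0, σ_tech)). All randomness
derives from one integer seed; equal seeds give bit-identical tables. With
σ_bio = σ_tech = 0 the pipeline recovers RA = 100·θ exactly, which anchors
the closure tests.

Defaults are declared study conditions, not estimates: sample sizes follow
the study design (short-term: n = 6 gills and kidney, n = 3 testes per
group; long-term: n = 8 gills, n = 6 kidney and testes per group); noise
defaults σ_bio = 0.15 (natural-logit) and σ_tech = 0.1 (natural-log) are
moderate values at which effects of the reported size are detectable at
those n; between-fish occupancy variance is not recoverable from published
summaries, so these are assumptions. Covering-form counts default to 2–6
modified and 5–12 unmodified forms per site per digest — real sites span
roughly 2–10 modified and 7–39 unmodified forms, and the defaults sit in the
central range so a 221-site, three-digest, up-to-105-sample run stays
desk-scale. Null panels cycle modification identities (acetyl, methyl,
dimethyl, GG) so the Unimod covariate has several levels.

The `paper_replay_config` preset plants the four reported salinity effects
at their published group-mean occupancies among 217 group-constant nulls:
H1K16ub 2.03% (FW) → 3.78% (SW), 3.33% (SW/FW); H1S1ac 5.59% (S0) → 3.33%
(S1); H3K14ac 27.5% → 15.3%, 16.0% (S3); H3K18ub 5.0% → 2.2%, 2.6% (S3). The
H1S1ac S3 mean is not published; the preset uses 4.5%, an intermediate value
consistent with the qualitative account (reduced, not significantly
different from either group). Planted occupancies are group-level, so a
planted short-term effect is present in every tissue of that experiment —
detection checks therefore name the (tissue, pair) family they score.

What the generator does **not** emulate: chromatograms and retention times,
interference between co-eluting peptides, missingness beyond zero-coverage,
shared peptides between real histone variants, or correlated occupancies
across sites. Passing tests therefore demonstrate correctness of the
estimator and the statistical machinery under the declared noise model, not
robustness to every pathology of real LC-MS data.

## Numerical choices and degenerate inputs

- β clamp ε = 1e-4; fold-change clamp 0.01%; variance floor 1e-12.
- The simulator's window length is at least 8 residues so random-sequence
  windows cannot collide across synthetic proteins.
- Duplicate (form, sample, digest) records, negative areas, unknown digest
  labels, group/experiment mismatches and ambiguous mass tables are
  construction-time errors, not silent repairs.
- Problem sizes used by the stochastic checks: the global-null control runs
  100 seeds of a 221-site, one-tissue (gills, n = 6 per short-term group)
  simulation; effect recovery runs 50 seeds of the replay preset over the
  three families that carry the planted effects (kidney samples contribute
  nothing to those families and are omitted from that preset run).

## Known limitations

- Nominal-mass classification cannot distinguish isobaric marks (+42
  acetyl/trimethyl); the table is configuration, not inference.
- π̂₀ regression with small covariate classes is noisy; classes can clip to
  0 or 1 and q-values inherit that (the global-null error rate remains
  controlled in aggregate, as the null-control check verifies).
- The aligner is strictly pairwise and global; distant homologs with large
  rearrangements are out of scope.
- No between-sample normalization or imputation: inputs are assumed already
  normalized, and missingness propagates to the family sizes.
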