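# Methods

This note documents the statistical model, the defaults and the design
choices behind phosphopipe, and what the synthetic-data validation does and
does not establish about real data.

## Data model and filtering

Input is a modification-specific peptide table: one row per (sequence,
modification-set) species with one raw MS1 intensity per run.  Raw
intensity 0 (MaxQuant's "not quantified") and absent cells are missing
values; everything else is log2-transformed.  Decoy and contaminant rows
are dropped first, then non-phosphorylated peptides.

Missingness in MS1 quantification is missing-not-at-random: the
probability of dropout rises as intensity falls, and the value that went
missing tends to lie below the mean of its observed replicates.  Because
reconstructing a triplet from a single observation is error prone enough
to inflate false positives, a peptide is retained only if **every**
(strain, treatment) triplet has at most one missing value.  The phrase
"no more than one missing value in three replicates of any sample" is
ambiguous between "every sample" and "at least one sample"; the strict
reading is the default and a `scope="any"` flag exposes the permissive
one.  At the defaults this retains about two thirds of phospho-peptides.

## Sibling-peptide error model

Two peptides are siblings when one sequence is an N- or C-terminal
extension of the other with a tryptic junction (they differ by missed
cleavage) and both carry identical modifications on the shared residues,
the extension being unmodified.  Trypsin efficiency should not depend on
the biological condition, so siblings share an expression profile; a fully
observed sibling therefore reveals what the missing replicate of its
partner would have been.

For each peptide P with exactly one missing value (sample S, replicate i)
and each sibling P′ complete in S, the difference
`I_{P′,S,i} − α_{P′,S,i}` (α = mean of P′ at the two replicates where P is
observed) is one draw from the imputation error distribution.  μ and σ are
the sample mean and SD (ddof = 1) of all pooled draws — one global model,
no per-strain stratification, no outlier trimming.  A one-sample two-sided
t test of the draws against 0 reports the dropout bias (`bias_t`,
`bias_p`).  With fewer than `min_sibling_obs` (default 30) draws the model
falls back to μ = 0 and σ = the median within-triplet SD of complete
triplets, with a logged warning.

Imputation itself never copies sibling values: the missing cell becomes
`α_{P,S,i} + N(μ, σ)`.  Draws are keyed by (seed, peptide id, run id)
through a counter-based seed sequence, so imputing a subset of rows yields
bit-identical values for the rows shared with a full run, and observed
cells are never touched.  The sibling search accepts one extra missed
cleavage by default (`max_missed_gap=1`); junction residues must be K/R.

## Normalization, linear model, moderated t

Quantile normalization forces every run to the common per-rank mean
distribution (ties receive the mean of their rank-range targets).  It is
the method that literally equalizes the log2-intensity distributions of
all runs; note that with strongly asymmetric regulation it shifts
unaffected peptides slightly in the opposite direction — visible as a mild
positive logFC bias of null peptides when many peptides are
down-regulated.

One global OLS fit per peptide uses indicators for all (strain, treatment)
groups (no intercept) plus a batch factor with the reference level
dropped.  Batch defaults to the replicate index, the plausible blocking
factor of a 10-sample × 3-replicate acquisition; `--batch-column` changes
it.  Residual df is n_runs − rank(X) (18 for the full 30-run design).

The empirical-Bayes prior (d0, s0²) is estimated by moment matching on
log s²: with e = log s² − ψ(d/2) + log(d/2), the excess of var(e) over
ψ′(d/2) determines d0 via trigamma inversion (Newton, tolerance 1e-8);
s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)).  No positive excess means d0 = ∞
with s0² = the pooled mean variance.  The moderated t for the
drug-minus-mock contrast of each strain uses the posterior variance
(d0·s0² + d·s²)/(d0 + d) on d0 + d degrees of freedom; d0 = 0 reduces to
the classical t (verified against scipy), d0 = ∞ to a fixed-variance
z statistic, and the full path is cross-checked against R/limma
(`lmFit`/`eBayes`) in the test suite.  BH adjustment is applied per strain
over all retained peptides; α = 0.05 everywhere downstream.

## Sites, motifs, logos

Peptides are located in their leading (razor) protein by first exact
substring occurrence; protein position = peptide start + in-peptide
phospho position − 1, 1-based throughout.  Duplicate (protein, position)
entries collapse to the representative with the highest localization
score (ties: lowest peptide id).  Windows span −5..+5 with `_` padding
beyond protein ends; a padded position never satisfies an R requirement
(conservative).  Motif flags obey the implication lattice RRxS/T ⇒ RxxS/T,
RxRxxS/T ⇒ RxxS/T and RxRRxS/T ⇔ (RRxS/T ∧ RxRxxS/T), verified by
exhaustive enumeration.

The logo foreground is the site set of significantly regulated peptides in
a chosen direction (a site inherits significance from any significant
source peptide); the background is all quantified sites.  Each (residue,
position) cell scores the exact binomial tail probability of the
foreground count given the background frequency, as signed −log10(p) with
0 at exact expectation; the significance line is drawn at raw p = 0.05
(a Bonferroni line is available behind a flag).  Overlap reports count
every Venn cell over named site or peptide sets, optionally restricted to
a motif class; the known-target report tallies curated (kinase, protein,
position) rows as known / detected / significantly hypo-phosphorylated.

## Synthetic data

The generator builds proteins from planned tryptic segments (interior
residues from an 18-letter alphabet without K/R, yeast-like frequencies;
K/R terminal), so digestion recovers the planned peptides exactly, and
arginine motif anchors are realized as the short segments and forced R
terminals that basic motifs actually produce under tryptic digestion.
Defaults emulate the study conditions: 5 strains × 2 treatments × 3
replicates, ~3800 base peptides (75% phosphorylated once), motif mix 6%
RRxS/T, 6% RxRxxS/T, 1% RxRRxS/T, planted effect −1.0 log2 in the drug
condition of the responsible strain (PKA/Sch9-type kinases target RRxS/T,
the Ypk1-type targets RxRxxS/T, both target RxRRxS/T), log2 baselines
N(23, 2), replicate noise SD 0.25, batch shifts (0, +0.3, −0.2), sibling
fraction 0.35 with a −1.5 log2 offset for the longer (dimmer) form.

Missingness is Bernoulli with probability logistic(intercept − slope ·
intensity); slope 0.8 per log2 unit and intercept 15.6 give a mean
per-cell rate near 11%, which under the ≤1-missing filter leaves about two
thirds of peptides — the retention regime the analysis targets.  The
dropout bias (mu_miss = −0.15, sigma_miss = 0.4) is injected at the
sibling-family level: when a flagged cell is the single missing value of a
member's triplet, one shared N(mu_miss, sigma_miss) draw replaces the
replicate deviation of every family member at that (sample, replicate),
anchored at each member's mean of its other two replicates.  This is what
makes the planted bias recoverable — the calibration never sees the
deleted value, only the sibling, which must carry the same deviation — and
it makes the deleted value follow the imputation model exactly.  Triplets
losing two or more values are deleted without injection; the filter
discards them and no estimator ever sees them.

What the generator does **not** emulate: peptide-specific ionization
efficiency trends, co-eluting interference, localization ambiguity across
neighboring residues (each planted peptide carries one phospho with a
known position), shared peptides between proteins, and run-order drift.
Passing the recovery tests therefore shows the estimators are correct
under the stated MNAR model, not that real data meet that model.

## Validation scale and determinism

The repeated-simulation checks run at reduced scale chosen for tight
sampling error at interactive runtimes: the null false-positive rate uses
ten ~3000-peptide single-strain datasets; the bias-calibration uniformity
check uses 200 datasets of ~640 peptides; end-to-end recovery uses one
full-scale 5-strain dataset.  All randomness flows from explicit integer
seeds; generation is byte-identical per (config, seed), and imputation
draws are cell-keyed.

## Kinetics

Trehalose degraded is (glucose − blank)/2, floored at 0 (amounts are
physical).  Activity is the least-squares slope through the origin,
Σ(t·y)/Σ(t²) — the reaction starts at zero product, so a free intercept
would only fit blank error.  Group comparisons use the pooled-variance
Student t (Welch behind a flag); relative activity is the ratio of treated
to mock group means (per-replicate ratios behind `pairwise=True`).  Zero
pooled variance yields p = 1 for equal means and p = 0 otherwise — the
natural limit, stated explicitly because assays with identical readouts do
occur in fixtures.

## Known limitations

- The moderated test assumes exchangeable variances after imputation;
  imputed cells add N(μ, σ) noise that thickens the tails, so the realized
  false-discovery fraction among discoveries can exceed the nominal 5%
  (the synthetic end-to-end run shows ~15–20% at default noise), while the
  null false-positive *rate* stays far below 0.4%.
- Site positions come from exact substring search in the leading protein;
  peptides occurring multiple times in a protein map to the first
  occurrence.
- The sibling definition requires exact modification identity; positional
  phospho-isoforms of the same peptide are distinct species and never
  siblings.
- Logo scores use per-position binomial tails without multiplicity
  correction by default, matching the raw p = 0.05 significance line.
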