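# Methods

`cystomics` implements the post-identification half of a label-free
mass-spectrometry study of pancreatic cyst fluid (PCF): it starts from a
peptide identification table and a feature × sample intensity matrix and
carries them through normalization, protein inference and roll-up,
differential testing, multivariate supergrouping, degradome-specific
analytics, marker diagnostics and term overrepresentation. Because the raw
LC-MS data of such studies are not reproducible at desk scale, the package
ships a ground-truthed generator that emulates the statistical structure of
PCF degradomes; every downstream claim the test suite makes is made against
that generator's known truth or against closed-form/brute-force oracles.

## The biological setting

PCFs aspirated by EUS-FNA are dominated by blood proteins and by pancreatic
and blood peptidases. The low-molecular-weight (<5 kDa) fraction — the
*degradome* — consists of proteolytic fragments of those proteins and is
analysed without enzymatic digestion ("none" cleavage specificity), while
the *proteome* is measured conventionally after trypsin digestion. Cyst
types (pseudocyst PC, serous SCN, mucinous MCN, IPMN, carcinoma CA, plus
unclassified UNC) differ both in protein abundance and in inherent
proteolytic activity; empirically the types separate along the first
principal component into an amylase-rich supergroup {PC, IPMN} and a
{CA, SCN, MCN} supergroup with heavy exopeptidase laddering.

## Synthetic data generator

The generator (`cystomics.simulate`) is first-class, tested code, and its
defaults are the study conditions used throughout the test suite.

**Proteome.** `n_proteins` (default 30) random sequences, residues i.i.d.
uniform over the 20 canonical letters, lengths uniform in `length_range`
(default 120–400). Uniform residue usage slightly exaggerates cleavage-site
entropy relative to real proteins but keeps the logo null distribution
exactly computable.

**Digestion.** Endoprotease specificity is modelled at P1 only: a cut after
residue `r` occurs with probability `cleavage_probability · w(r)/max(w)`.
Each cyst type has its own profile; by default PC/IPMN are
trypsin-dominant (K/R weight 1.0, F/W/Y 0.3, cleavage probability 0.8,
light trimming) and CA/SCN/MCN chymotrypsin-dominant (F/W/Y 1.0, K/R 0.3)
with heavy exopeptidase trimming (per-terminus probability 0.5, depth up to
4, every intermediate rung emitted). The weaker shared specificity ensures a
sizable common peptide core across all types, as in real fluids. Richer
P4–P4′ context is deliberately out of scope: the logos *measure* flanking
context, the generator does not *generate* beyond P1, so logo tests are
honest recovery tests rather than self-fulfilling.

**Detection structure.** Real PCF degradomes are extremely sparse (most
peptides are absent from at least one cyst type). Two mechanisms produce
this: (1) a *repertoire* decision — for each peptide a type's protease did
not produce, the type's fluid contains it with probability 0.5 if the type
belongs to the same supergroup as a producing type, 0.05 otherwise (drawn
once per peptide × type, so missingness is group-structured); and (2) a
per-cell logistic detection model, `P(detected) = logistic(slope · (log2
abundance − mid))` with mid = 16 and slope = 1 against a protein base level
of 20 ± 2 log2 units, mimicking an MS detection limit. A constant-probability
and an always-detected mode exist for clean unit tests. Unclassified samples
carry a latent cyst type drawn within their latent supergroup and follow its
repertoire — recovering that latent supergroup is exactly the projection
task the multivariate stage is asked to solve.

**Abundances.** log2 abundance = protein base level + peptide offset
(SD 1.0) + group effect + N(0, `sigma_within`) noise; `diff_fraction`
(default 5%) of the *shared-core* peptides receive ±`effect_log2fc`/2
(default 2.0, i.e. a 4-fold supergroup ratio) with random direction.
Effects are spiked on the shared core because an effect on a peptide one
supergroup never produces is already expressed as presence/absence, not
abundance. The matrix is emitted on the linear scale (2^x) so the pipeline's
own log transform is exercised.

**Markers.** Per-sample CEA (ng/mL) and amylase (IU/L) are log-normal with
group-specific medians chosen to match the clinical pattern of each cyst
type (pseudocysts amylase-rich/CEA-poor, median 40 000 IU/L and 27.5 ng/mL;
serous cysts low in both; IPMN 2 891 IU/L and 236 ng/mL; MCN CEA-rich at
2 931 ng/mL; unclassified heterogeneous). No clinical table for malignant
cysts is available at this granularity; CA is modelled mucinous-like (CEA
median 1 500 ng/mL, σ_ln 1.2; amylase 400 IU/L) since most malignant cysts
arise from mucinous lesions. Log-SDs approximate the min–median–max spread
of the corresponding clinical ranges.

**What the generator does not emulate:** spectrum-level noise, retention
time, isotope patterns, shared tryptic peptides between homologous real
proteins (random sequences essentially never share peptides, so metaprotein
merging is exercised by dedicated unit fixtures instead), correlated
peptide behaviour within a protein beyond the shared base level, and
covariates such as cyst size or patient age. Passing tests therefore
demonstrate correctness of the algorithms under a realistic sparsity and
effect structure, not clinical performance on real fluids.

## Normalization

Intensities are log2-transformed (zero/negative present values are an
error; no silent pseudocount). Each sample is then regressed against the
*median pseudosample* (per-feature median over samples, ignoring missing;
features missing in >50% of samples are excluded from the pseudosample but
remain correctable): a robust LOESS (statsmodels `lowess`, bisquare, 3
robustifying iterations) of (sample − pseudosample) vs pseudosample is
fitted on *anchor features* — the lowest-variance quarter
(`anchor_fraction` = 0.25) of features present in ≥80% of samples
(`min_present`) — and the fitted curve, linearly interpolated between fit
points and constant beyond the anchor range, is subtracted from every
feature of that sample. The span (0.3), anchor fraction and robustness
scheme are package choices (exposed in config) since only "robust LOESS
against a median pseudosample fitted on low-variance features" is specified
by the underlying method. Evaluating the correction at the feature's
pseudosample value makes the correction per-feature-constant within a
sample, which removes any per-sample multiplicative (linear-scale) artifact
exactly in the constant-offset limit, is idempotent there, and never
creates or removes missing values.

## Protein inference and roll-up

Proteome-mode reporting applies the conventional post-search rules:
proteins matched by identical peptide sets merge into a *metaprotein*
(id = sorted accessions joined by `|`); peptides matching more than one
metaprotein are then discarded — the order matters, and merging first
preserves peptides shared only among indistinguishable proteins; finally
metaproteins with fewer than two peptides are dropped (two-peptide rule).
Decoy-based score thresholding (`threshold_decoy_fdr`) selects the smallest
observed score `t` with #decoys(≥t)/#targets(≥t) ≤ the target FDR.

Quantitative roll-up shifts each member peptide's log2 profile so its
across-sample median equals the metaprotein reference level (the median of
member-peptide medians) and takes the per-sample median of shifted values;
samples with no member peptide present stay missing. Because the reference
level itself is a function of the peptide medians, absolute protein levels
shift by a common constant when per-peptide offsets change; the *relative*
profile (differences between samples) is exactly invariant to per-peptide
constant offsets, which is the meaningful guarantee for relative
quantitation and the one the tests assert. The degradome branch of the
pipeline bypasses this module entirely — endogenous peptides are the
analyte and are quantified at peptide level.

## Differential testing

Per feature, a one-way F statistic is computed on present values over
groups with ≥2 present values (`min_per_group`); unclassified samples are
excluded. The null is built by permuting group labels over that feature's
present samples, preserving the missingness pattern. When the number of
distinct label assignments is ≤ `exhaustive_limit` (20 000) the null is
enumerated completely and p = #{F* ≥ F}/N is exact; otherwise `n_perm`
(default 9 999) Monte-Carlo permutations are drawn and
p = (1 + #{F* ≥ F})/(1 + n_perm), which is a valid test (p > 0, uniform
under the null on achievable quantiles). Permuted F values are compared
against the observed one with a 1e-9 absolute slack so that ties produced
by floating-point noise count as exceedances. Degenerate features (no
variance at all) get F = 0, p = 1; zero within-group variance with
between-group spread gives F = ∞, which orders correctly under comparison.

P-values are adjusted by Benjamini–Hochberg step-up (own implementation —
monotone cumulative minimum of p·m/rank, clipped at 1 — cross-checked
against statsmodels in the tests). The fold change of a multi-group feature
is the maximal pairwise linear ratio of group means, `2^(max−min)` of the
log2 group means (group means over present values, i.e. geometric means of
intensities). A feature is significant iff adjusted p ≤ 0.05 AND FC ≥ 1.5;
both boundaries inclusive.

## PCA and supergroup assignment

PCA is computed by SVD of the feature-centered matrix (no unit-variance
scaling — log2 abundances are already commensurate). Scores, orthonormal
loadings, and variance fractions σ_k²/Σσ² are returned with a
deterministic sign convention (largest-magnitude loading entry positive) so
results are invariant to sample order. Two missingness policies exist:
complete-features-only, and per-feature-mean imputation optionally
restricted to features present in ≥ `min_present_frac` of samples. The
*pipeline* default is mean-imputation over ≥80%-present features: at
realistic degradome sparsity the number of fully complete features can fall
below a handful, making complete-case PCA degenerate, while the
80%-present core is stable; complete-case remains the library default of
`pca_fit` for dense matrices.

Unclassified samples are projected onto the fitted components
((values − centering offsets) · loadings) and assigned to the supergroup
({PC, IPMN} vs {CA, SCN, MCN}, configurable) whose labeled-sample centroid
on PC1 is nearer; the distance margin is reported and exact ties are
flagged as unassigned. Nearest-centroid on PC1 is an explicit
operationalization of what is visually evident in 1-D score plots; a
multi-component variant is available through `SupergroupClassifier`.

## Degradome analytics

**Flank windows and logos.** A peptide at protein positions [start, end]
witnesses a cleavage at each terminus; in protease nomenclature the cut
lies between P1 and P1′, so the N-terminal window covers protein positions
start−4 … start+3 and the C-terminal window end−3 … end+4 (width
configurable). Positions past the protein ends are gap-filled and excluded
from frequency normalization (gaps are not a 21st symbol). Logos are
count-based — each detected peptide terminus counts once, with an
abundance-weighted mode available — and per-position information content is
log2(20) − H with H the Shannon entropy of the residue distribution, no
small-sample correction. Group logos are compared per position by
Jensen–Shannon divergence (base 2). Peptides matching multiple proteins
contribute one window per match by default; a unique-match-only mode is
used for specificity tests.

**Ladders.** Peptide matches of one protein are grouped by shared start
(nested C-terminal trimming) and by shared end (N-terminal trimming);
groups with ≥ `min_rungs` (3) distinct lengths are reported longest-first
with step sizes. Every member is by construction an anchored substring of
the longest member.

**Uniqueness census.** A feature is detected in a cyst type iff present in
≥1 of its samples; the census reports per-type detected and unique counts,
the shared-in-all count and the full Venn partition, optionally rolled up
to proteins via the feature → protein map.

## Marker diagnostics

For a binary class defined by cyst-type membership (mucinous = {IPMN, MCN}
for CEA at 192 ng/mL; duct-communicating = {PC, IPMN} for amylase at
250 IU/L; both configurable), a sample is test-positive iff its marker
value ≥ cutoff (boundary positive). Sensitivity, specificity and accuracy
follow from the confusion counts; missing marker values are excluded with a
logged count. AUC is P(value_pos > value_neg) + ½P(tie), computed by
average ranks (Mann–Whitney form) and, as an independent route, by
trapezoidal integration of the ROC curve; both are exposed and agree to
floating-point precision.

## Overrepresentation

For each term with background frequency p0, the over tail P(X ≥ k) and
under tail P(X ≤ k) of Binomial(|query|, p0) are computed; the smaller tail
is reported with its direction (no doubling), Bonferroni-corrected by the
number of terms actually tested; terms with zero background count are
skipped. Annotations come from a user-supplied feature → term table; no
live ontology service is queried, and the pipeline's synthetic runs use a
random annotation table explicitly labelled synthetic.

## Determinism and problem sizes

One global seed drives zlib-CRC-keyed per-stage substreams
(`stage_rng(seed, stage_name)`), so adding a stage never perturbs earlier
stages and any stage can be regenerated in isolation. Re-running the
pipeline with an identical config + seed reproduces byte-identical tables;
each run directory carries a manifest with the config SHA-256, seed and
package version. Floats are written in shortest-roundtrip representation so
TSV round-trips are exact.

The test suite and `scripts/acceptance.py` use deliberately scaled
problem sizes chosen as the package's own balance of statistical resolution
and turnaround: 1 000 features × 30 samples × 999 permutations for null
calibration (3 seeds), 1 000 features × 40 samples for spiked-effect
recovery (50 spiked features; with permutation resolution 1e-3, BH at 5%
comfortably separates them), 20–60 random proteins per simulated study, and
9 999 permutations wherever a single feature's p-value is examined closely.

## Known limitations

- The P1-only generative model cannot produce (and therefore cannot test
  recovery of) extended-context specificity such as P2/P1′ preferences.
- Random protein sequences make cross-protein shared peptides vanishingly
  rare, so metaprotein merging is exercised on constructed fixtures only.
- Permutation tests at small group sizes have coarse attainable p-values;
  features testable in only two small groups cannot reach stringent
  adjusted significance, mirroring the behaviour of the original analysis.
- The nearest-centroid supergroup rule assumes the dichotomy is expressed
  on PC1; if group structure rotated into later components the assignment
  would need the multi-component variant.
- Marker diagnostics treat class definitions as configuration; they do not
  model within-type heterogeneity (e.g. malignant mucinous cysts) beyond
  the group label.
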