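# Methods

## The prediction problem

Lysine succinylation is a post-translational modification in which a
succinyl group is attached to a lysine side chain, changing its charge
from +1 to −1 and perturbing protein structure and function.
Experimentally mapped succinylation sites are scarce relative to the
number of lysines in a proteome, so sequence-based predictors are used
to prioritise candidates. `gpsuc` implements a two-stage ensemble
predictor over fixed sequence windows: five per-encoding random forests
whose scores are fused by a logistic regression.

## Windows and profiles

Each candidate site is the 41-residue fragment centred on a lysine
(±20 flank). Fragments that overhang a protein terminus are padded with
`-`; the unknown residue `X` is legal and is treated like a gap by every
encoder (it contributes zeros and is excluded from composition
denominators). All public coordinates are 1-based.

Evolutionary information enters through an L×20 position-specific
scoring matrix (PSSM) per protein. The package parses the ASCII PSSM
dialect written by PSI-BLAST (`-out_ascii_pssm`; the reference search
settings are an e-value cutoff of 1e-4 and 3 iterations against a
non-redundant protein database) but never runs the search itself. Only
the 20 log-odds columns are used; the file's native column order is
remapped to the canonical alphabet `ACDEFGHIKLMNPQRSTVWY`. Profile rows
for padded window positions are zero-filled — the padding convention is
our documented choice. When no search profile is available, a
deterministic pseudo-profile is substituted: row r holds the BLOSUM62
substitution scores of `sequence[r]` against the 20 residues (`X` rows
are zero). This mimics the single-sequence profile of a query with no
homologs and keeps the entire pipeline runnable offline.

## Feature encodings

Five fixed-width blocks per site (4152 features in total by default):

| block   | width | content |
|---------|-------|---------|
| AAC     | 20    | residue frequencies in the window, centre excluded; the denominator counts only observed (non-gap, non-X) flank residues |
| BE      | 820   | one-hot encoding of each window position (41×20) |
| AAindex | 492   | per-position physicochemical property values for 12 amino-acid index scales (41×12) |
| PSSM    | 820   | the flattened 41×20 profile window |
| pCKSAAP | 2000  | profile-based composition of k-spaced amino-acid pairs, k ∈ {0..4} |

For pCKSAAP, the score of ordered pair (a, b) at spacing k is

    S_ab(k) = Σ_{r=1}^{L−k−1} max( min(P[r,a], P[r+k+1,b]), 0 ) / (L−k−1),

with L = 41. Summing the clipped minimum over *all* row pairs (r, r+k+1)
for a fixed ordered pair reproduces the stated dimensionality
5 × 20 × 20 = 2000 exactly; the per-k blocks are ordered k-major, then
pair-lexicographically in the canonical alphabet, and every value is
non-negative by construction. Feature names are stable and
self-describing (`pCKSAAP:k2:AC`, `BE:pos-7:R`, `AAindex:pos+3:TSAJ990101`,
`PSSM:pos0:K`, `AAC:L`), with window positions written relative to the
centre (−20..+20).

The 12 bundled property scales are keyed by their AAindex accessions
(TSAJ990101, MAXF760101, NAKH920108, BLAM930101, BIOV880101, CEDJ970104,
NOZY710101, KLEP840101, NAKH900109, LIFS790101, HUTJ700103, MIYS990104);
`NA` entries are stored as 0. The packaged numeric values are offline
transcriptions of AAindex 9.1 and may be replaced wholesale by a user
table — no test or result in this repository depends on the specific
numbers, only on the lookup semantics.

## Feature screening

Each feature column is scored by a two-sample Wilcoxon rank-sum test
between positive and negative windows, with mid-ranks for ties. The
statistic W is the rank sum of the positive group. The permutation
p-value is exact whenever C(r+s, r) ≤ 2·10⁵: rather than literally
enumerating rank assignments, the exact null distribution of W is built
by a subset-sum dynamic programme over the doubled mid-ranks
(mathematically identical to full enumeration, and feasible at any
sample size when forced). Otherwise a tie-corrected normal approximation
with continuity correction is used. The reported p is two-sided,
`min(1, 2·min(P_upper, P_lower))`: screening must catch depletion as
well as enrichment, and a one-tailed rule would make "top features"
direction-dependent. "Most discriminative first" is implemented as
ascending p with ties broken by original column index, which makes
rankings deterministic and row-order invariant; constant columns get
p = 1 and sort last.

Selection retains a per-encoding top-N for the two high-dimensional
blocks — generic preset pCKSAAP 390 and AAindex 250, plus nine
species-specific presets (e.g. human: AAindex 260 / pCKSAAP 440) — and
keeps AAC, BE and PSSM at full width. During cross-validation the plan
is rebuilt inside every training fold, so held-out labels can never leak
into selection; this is the defensible default and a possible source of
divergence from evaluations that select once on the full data.

## Channels, fusion, cutoff

One random forest per encoding block (default 500 trees,
√p features per split, no class weighting; a tuning grid
{100, 300, 500, 1000} over 10-fold CV is available). The channel score
S_n of a window is the fraction of trees voting the positive class.

The five channel scores are combined by logistic regression,

    log(P / (1 − P)) = Σ_{n=1}^{5} β_n S_n + α,

fitted by maximum likelihood on stratified *out-of-fold* channel scores
(never on resubstitution scores, which would make the fusion
optimistic; a resubstitution mode exists for comparison). The constant
term α is clamped to zero by default, matching the published per-species
coefficient sets, which ship as presets (channel order AAC, AAindex, BE,
PSSM, pCKSAAP; e.g. human: 0.142, 1.566, 0.665, 0.342, 0.667). One
published set (house mouse) prints only four of the five coefficients
and is therefore not shipped.

Two numerical choices matter here:

* **Non-negative coefficients.** Each S_n is a probability of the
  positive class, so a channel can only add evidence *for*
  modification; all published coefficient sets are positive. The ML fit
  is therefore constrained to β ≥ 0 (L-BFGS-B on the exact likelihood).
  Unconstrained ML on the five strongly correlated channel scores is
  quasi-separated on clean data and produces large mixed-sign
  coefficients that invert predictions outside the training score
  distribution. Standard errors come from the observed information and
  are reported when the solution is interior. If even the constrained
  fit diverges (clean separation), a ridge-penalised fit (C = 1) is
  substituted with a warning.
* **Cutoff selection.** With α = 0 and β ≥ 0 the fused probability is
  bounded below by 0.5, so a fixed 0.5 threshold would call every site
  positive. The default decision cutoff is therefore the smallest value
  reaching 90% specificity on the out-of-fold fused scores (the
  method's reported operating point is Sp ≈ 0.89–0.90); a fixed-value
  mode is available.

Training data are assembled at a 1:2 positive:negative ratio by
sampling negatives without replacement (all negatives, with a warning,
when fewer are available). Homology reduction of input sequences (e.g.
CD-HIT at 30% identity) is an external preprocessing step, not
re-implemented.

## Evaluation

Standard confusion-matrix definitions give Ac, Sp, Sn and MCC, with any
zero denominator mapping the metric to 0 and score ties at the cutoff
counting as positive calls. ROC curves sweep the unique scores
(simultaneous steps at ties); the trapezoidal AUC equals the
Mann-Whitney concordance U/(n₊·n₋), which the tests verify to 1e-12.
`cross_validated_report` refits the entire chain — selection, channels,
fusion — inside each of 10 stratified folds and averages the fold
metrics.

## Compositional statistics

Per-position summaries over aligned windows: amino-acid frequencies
(AAF; denominators exclude gaps), mean profile value of the observed
residue (MPV), and mean property value under one AAindex scale (MPP;
default NAKH920108). Group differences are tested per position with the
Kruskal-Wallis test — which for two groups reduces to the Wilcoxon
rank-sum test and is implemented once, in the screening module — or per
(position, residue) with 2×2 chi-square tests of occurrence counts
restricted to the central positions (−5..+5 by default; the centre is
excluded because it is K in both groups by construction). All p-values
are Bonferroni-corrected with the family size m equal to the number of
tests actually run, which every report records explicitly. Degenerate
chi-square margins (a residue absent from both groups at a position)
are pooled out with a warning. Signed AAF differences (positive =
enriched around modified sites) provide the numbers a two-sample logo
would render; image generation is out of scope.

## Synthetic data

The generator emulates the statistical structure of succinylation
training sets without emulating any real species: background sequences
(uniform residue composition by default; a Swiss-Prot-like composition
is bundled), lysines designated positive with probability 1/3, and
flanking offsets ±1..±8 of positive sites rewritten from a
charged-residue preference (E 0.35, K 0.25, R 0.20, D 0.20) with
probability `effect_size` — charged-residue enrichment being the
hallmark compositional bias around real succinylation sites.
`effect_size = 0` is an exact null: positives and negatives are
exchangeable, which the calibration tests exploit. Defaults (160
proteins, lengths 80–160) yield roughly 950 labelled lysines and a
~900-window training set at the 1:2 ratio.

What the generator does *not* emulate: homology between proteins, real
PSSMs (pseudo-profiles are deterministic functions of the sequence, so
the PSSM and pCKSAAP blocks carry sequence information only),
species-specific composition, and long-range sequence structure. One
consequence worth knowing: because positives are dense (a third of all
lysines), negative windows overlap positive flanks, and the
position-agnostic blocks (AAC, pCKSAAP) lose most of their margin while
the position-aware blocks (AAindex, BE, PSSM) stay strongly
discriminative. Passing end-to-end tests therefore demonstrate that the
pipeline learns and fuses positional motif signal correctly — not that
every channel is individually informative on real data, where positives
are sparse.

`generate_channel_scores` draws i.i.d. uniform channel scores and
labels from the fusion model itself, for coefficient-recovery checks.

## Problem sizes and tolerances

The test suite and the acceptance script run the full 10-fold
cross-validation on the generator's default ~900-window datasets with
100 trees per channel and 3 inner folds for the fusion fit — sizes
chosen to exercise the complete nested pipeline at desk scale. Oracle
comparisons use 100 random profiles (pCKSAAP), all group sizes with
r+s ≤ 10 plus 30+30 draws (rank-sum test), and 1,000 random confusion
tables; equality tolerances are 1e-12 except exact-vs-normal p-value
agreement (0.01, the approximation's design tolerance). Null
calibration uses 100 seeded datasets of 15 proteins each.

## Known limitations

* The vendored AAindex values are offline transcriptions (see above);
  supply your own table via `AAIndexTable.from_tsv` for
  publication-grade property analyses.
* The pseudo-profile is a stand-in, not an approximation of a real
  PSI-BLAST profile; PSSM-derived features computed from it are
  sequence-determined.
* Retention presets are taken as given; the package does not re-derive
  per-species top-N values.
* With α = 0, fused probabilities live in [0.5, 1); they are ranking
  scores relative to the chosen cutoff, not calibrated probabilities.
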