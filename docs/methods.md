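# Methods

`metox` implements a chain of analyses linking the oxidation of
protein-bound methionine to its structural context, centred on one
geometric feature: the **S-aromatic motif**, a methionine whose SD sulphur
lies within 7 Å of the geometric centre of an aromatic ring (Phe, Tyr,
Trp). This note records the models, the conventions chosen where the
design was genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## Methionine-content bootstrap

`met_content` is the fraction of residues that are methionine, computed
after removing position 1 (the initiator methionine) by default — the
initiator is near-universal and would otherwise bias short sequences.
`bootstrap_content_null` draws `n_samples` protein samples of size
`sample_size` uniformly **without replacement** (independently across
samples; defaults 10⁴ samples of 1646 proteins) and records each sample's
mean content. `empirical_pvalue` uses the add-one estimator
`(1 + #{means ≥ observed}) / (1 + n_samples)`, which can never return 0;
when no bootstrap mean reaches the observed value the report carries an
explicit "below resolution" flag and prints `p < 1/n_samples`.

## Sequence-environment z-scores

For every methionine with at least ten neighbours on **both** sides
(windows truncated by protein ends are excluded entirely, not padded), the
residues at offsets −10..−1 and +1..+10 are tallied into a 20 × 20
relative-frequency matrix; `X` (unknown) residues are excluded from both
numerator and denominator. Each oxidation-prone site is paired with a
uniformly chosen oxidation-resistant methionine of the same protein, so
protein-level composition cancels. Partners are drawn **without
replacement** within a protein: reusing a resistant methionine duplicates
its entire window in the resistant matrix, and simulation shows this
inflates the null variance of the statistic (pooled variance ≈ 1.25 with
replacement vs ≈ 1.0 without at ~1000 pairs).

The differential statistic is the standardized two-proportion difference

    Z_ij = (f_ij^ox − f_ij^res) / sqrt[(f^ox(1−f^ox) + f^res(1−f^res)) / n]

with n the number of pairs and 0/0 defined as 0. Under the null of
identical environments each cell is approximately standard normal;
positive values mean residue *i* is over-represented at offset *j* near
oxidation-prone methionines. Diagnostics: `interval_counts` (cells outside
±b with the sign breakdown), `expected_outside` (the analytic null count,
400·2·Φ̄(b): ≈ 18.2 for b = 2, ≈ 1.08 for b = 3) and
`aa_aggregate_scores` (Σ_j |Z_ij| per residue). The z formula is a
reconstruction constrained by the stated requirements (mean 0 / variance 1
under the null, sign convention, dependence on n only); it is documented
here because the source rendering of the defining equation is not
machine-readable.

## Distance features and the random-forest protocol

For each methionine, 40 predictors: `NT_X`/`CT_X` = residue count to the
nearest occurrence of amino acid X toward the N-/C-terminus, with the
protein length as the default when X is absent in that direction.
`train_rf` follows the fixed protocol: stratified 75/25 train/test split,
random forest of 1000 trees with 6 candidate predictors per split
(⌊√40⌋), 10-fold cross-validation with 5 repetitions (50 resamplings,
metrics averaged) on the training part, final refit scored on the held-out
quarter. The positive class is "oxidized"; out-of-bag accuracy is exposed
as a secondary output. `rfe_select` ranks features by recursive
elimination under random-forest importances, scores every candidate subset
size (default 1..40) by cross-validated AUC on the training part, and
breaks ties toward fewer features. Tree count and CV shape are keyword
arguments so examples and tests can run reduced forests; the defaults are
the protocol.

## Motif geometry

Ring definitions: Phe/Tyr use the six-membered ring (CG, CD1, CD2, CE1,
CE2, CZ); Trp contributes **two** rings (pyrrole CG, CD1, CD2, NE1, CE2
and benzene CD2, CE2, CE3, CZ2, CZ3, CH2), with the nearer of the two
governing the motif call — a conservative superset of either single-ring
convention, since the literature does not fix which ring (or the 9-atom
centroid) to use. Centroids are unweighted means of the member atoms;
incomplete rings are skipped with a warning. Distances are measured from
the SD atom (SE for selenomethionine); methionines without a resolved
sulphur are skipped, never guessed. Contacts are collected across chains —
inter-chain motifs in oligomers are real — but cross-chain pairs are
excluded from primary-structure separation summaries, where no linear
distance is defined. `dedup_chains` keeps one chain per identical
one-letter sequence (lowest identifier) so crystallographic copies do not
multiply observations. The nearest-ring distance feeds the histogram whose
first local minimum (reported as the centre of a flat valley) motivates
the 7.0 Å cutoff; the cutoff is strict ≤, and raising it can only turn
non-motif calls into motif calls (tested monotonicity).

## Solvent accessibility

An internal Shrake–Rupley implementation replaces the POPS program used in
the original workflow: a deterministic golden-spiral lattice of `n_points`
(default 960) points on each heavy atom's solvent-expanded sphere (van der
Waals radii C 1.70, N 1.55, O 1.52, S 1.80, default 1.80 Å; probe
1.4 Å); a point is accessible when it lies strictly outside every
neighbour's expanded sphere, with a 10⁻⁹ Å² slack so exactly coincident
spheres do not occlude each other. Hydrogens are ignored, matching
crystal-structure practice. Per-residue SASA (sum over heavy atoms) agrees
with an independent implementation (biotite) to well under 1% on test
structures, and the isolated-atom area matches 4π(r+w)² to float
precision. Relative accessibility divides by the theoretical Gly-X-Gly
maximum per residue type (MET 224.0 Å²; full table packaged).
"Exposed at t" is a strict inequality; the analysis uses the two extreme
thresholds 0.05 and 0.20. Whether the original accessibility was
whole-residue or side-chain-only is not recorded; this package uses
whole-residue.

## Exact inference

`fisher_exact` evaluates the hypergeometric likelihood of every 2×2 table
compatible with the observed margins — log-space (`lgamma`) by default,
exact rational arithmetic on request. One-sided p is the tail in the
observed direction (enrichment/depletion of the first cell relative to its
margin expectation); two-sided p follows the minimum-likelihood convention
(sum over tables no more likely than observed), matching
`scipy.stats.fisher_exact`. Both sidedness conventions are always
reported, because published headline values mix them: on the
oxidation-by-motif counts (39, 97 / 561, 421) the two-sided value is
4.09 × 10⁻¹⁰ and the one-sided depletion tail 2.96 × 10⁻¹⁰; on the
reactivity benchmark (17, 3 / 2, 13) the one-sided tail is exactly
98 056⁄3 247 943 160 ≈ 3.0 × 10⁻⁵. A degenerate margin admits a single
table and returns p = 1. Note the minimum-likelihood two-sided p is *not*
bounded by twice the one-sided p; the opposite tail can hold many tables
only slightly less likely than the observed one. `binomial_tail` is an
exact rational upper-tail sum; for 13 of 15 correct rule assignments
against a fair-coin null it gives 121/2¹⁵ = 0.003693 (commonly printed
truncated as 0.003).

## The reactivity rule and its benchmark

The classifier is a single geometric rule: motif ⇒ low reactivity toward
peroxide, no motif ⇒ high. The in-vitro benchmark fixture transcribes the
published low/high labels for 35 methionines of 8 therapeutic proteins
together with per-protein confusion counts; the aggregate matrix is
TP 17, TN 13, FP 2, FN 3 with **low reactivity as the positive class**
(the only convention that reproduces sensitivity 17/20 = 85% and
specificity 13/15 = 86.7%). `median_split_labels` converts ordered
empirical reactivities into low/high labels by a per-protein median split;
residues exactly at the median join the group of the nearest non-tied
residue (equidistant → low), except when that would empty a class — the
benchmark construction requires both classes inhabited — in which case
they join the empty class. Benchmark positions are sequence positions;
`ResidueMap` (global alignment, match +1/mismatch −1/gap −2, ≥ 90%
identity over aligned columns required) translates them onto author
numbering, and records whose methionine is unresolved raise rather than
being silently assigned.

## Synthetic data: what it emulates, and what it does not

The generator produces i.i.d.-residue proteomes (human-like composition,
Met pinned at 0.023; Poisson lengths, mean 400, minimum 25, forced leading
M), oxidation labels with a planted flanking bias (default: glutamate
+0.20 at offsets −3..−1 around oxidized sites, half of eligible sites
labelled oxidized), toy lattice structures in which a configurable
fraction of methionines receives a phenylalanine ring centroid at
4.5–6.5 Å (others ≥ 9.5 Å, lattice spacing 30 Å, so the 7 Å call recovers
the construction with margin on both sides), and logistic oxidation labels
`P(ox) = σ(β₀ + β_motif·motif + β_acc·acc)`. Defaults mirror the scale of
the structural study: 1118 methionines, motif fraction 600/1118, β₀ =
logit(97/518) (the non-oxidized-motif stratum's oxidation odds) and
β_motif = ln 0.3, the conditional odds ratio matching the marginal odds
ratio of the published count table (0.302). β_acc defaults to 0; setting
it positive builds in the burial confound deliberately, so the
exposure-stratified analysis can be exercised against a known truth.

Every generator is a pure function of (config, seed); generators that
could plausibly share an integer seed draw from distinct RNG streams
(`default_rng([seed, stream_key])`) so that reusing a seed across
generators cannot couple their outputs.

Limitations worth keeping in mind: sequences are i.i.d. — no domain
structure, no compositional autocorrelation, no homology; toy structures
have no packing, so every residue is fully exposed and accessibilities
used in stratified simulations are drawn, not computed; flank resampling
around oxidized sites can overwrite or create methionines, so the site
list is rebuilt after mutation and unlabeled methionines may exist (as in
real data). Passing the synthetic benchmarks therefore demonstrates
correctness of the machinery and calibration of the statistics under the
stated model — not that real proteomes satisfy that model.

## Numerical and protocol choices

- Positions are 1-based everywhere (UniProt convention); structure author
  numbering is never assumed to equal sequence numbering.
- Alternate locations: highest occupancy wins, ties toward altloc 'A';
  model 1 only; waters dropped.
- PDB round trips preserve coordinates to the format's 3-decimal
  precision.
- Site eligibility for the environment analysis is applied to the stored
  sequence as-is (a site at position ≤ 10 is excluded even though the
  initiator could in principle be dropped first).
- Problem sizes in tests and the acceptance script: the null calibration
  pools 20 seeds × (300-protein proteomes, ≥ 500 retained pairs each,
  measured ≥ 1100); power uses the same 20-seed design; odds-ratio
  recovery uses 200 simulations of 1118 methionines; the type-I
  calibration uses 500 such simulations; the Fisher oracle comparison is
  exhaustive for small totals plus 500 random tables with totals ≤ 60;
  the feature oracle checks 1000 random sequences. These sizes make the
  Monte-Carlo bands in the tests comfortably tight while keeping the
  default suite in the minutes range on one CPU.
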