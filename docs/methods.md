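# Methods

This note documents the models, statistics and numerical choices behind
coevokit, and what the synthetic benchmarks do and do not establish.

## Distances and rates

**p-distance and Poisson correction.** Protein distances are the fraction of
differing residues over mutually comparable columns (gap and unknown symbols
removed pairwise by default; a complete-deletion mode removes any column
with a gap in any sequence). The Poisson correction d = −ln(1 − p) accounts
for multiple hits; p ≥ 1 raises a saturation error, and a pair with zero
comparable columns is flagged missing rather than reported as 0. Percent
identity is the mean of (1 − p) over all unordered pairs, ×100.

**Kimura two-parameter distance.** For nucleotide data,
d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q) with P and Q the observed transition
and transversion proportions. In the equal-rate limit (Q = 2P) this equals
the Jukes–Cantor correction exactly, which the tests verify to 1e−12.

**dN/dS.** Implemented as modified Nei–Gojobori counting with a K2P-style
correction: potential synonymous/nonsynonymous sites are counted per codon
position with transitions weighted by the transition/transversion rate ratio
R (estimated from the pair via the K2P rate decomposition, R = α/2β, unless
supplied); changes to stop codons are excluded from the weighting.
Differences between codons are averaged with equal weights over all
shortest substitution paths, discarding paths through stop codons unless
every path passes one. The K2P correction is applied separately to the
synonymous (Ps, Qs) and nonsynonymous (Pn, Qn) transition/transversion
proportions. A saturated dS flags ω as undefined rather than erroring, and
family-level ω is the mean over pairs with defined ω (undefined pairs
counted). The plain-NG86 mode of the same counting code (R = 1,
Jukes–Cantor correction) reproduces Biopython's `cal_dn_ds` NG86 values to
1e−12 on stop-free codons, which serves as the independent cross-check.

**Z comparison.** Family rate contrasts use a two-sample Z on means with
per-sample standard errors. Pairwise distances are not independent
observations, so the normal-tail p-value is labeled approximate and should
be read as descriptive, not inferential.

## Tol-MirrorTree

Distance matrices for the two families are expanded over the pairing table:
an organism with m family-A members and n family-B members contributes m·n
index rows, so paralogs appear as duplicated labels. The speciation signal
is removed by regressing the off-diagonal family distances on the
neutral-marker distances and subtracting β·S (slope with intercept, so the
residuals are exactly uncorrelated with S); element-wise subtraction is
available behind a flag, but the regression form is the default because
protein and rRNA distances live on different scales. Same-organism cells
(S = 0) pass through unchanged, and a constant marker skips the correction
with a warning.

The Mantel test correlates off-diagonal upper-triangle cells and builds its
null by jointly permuting the row/column labels of one matrix
(paralog-duplicated labels are permuted like any other, as no special
treatment is defensible without more assumptions). The test is one-sided
for positive association by default; p = (1 + #{R_perm ≥ R}) / (1 + n_perm).
Default n_perm = 9999, so the smallest reportable p is 1e−4. The permutation
loop is vectorized; calibration (rejection rate at α = 0.05 on independent
random matrices) is checked in the acceptance suite.

## Correlated-mutation detection

For each usable alignment column (≤50% gaps, non-constant), the site profile
is θ_k = B(a_i, a_j)/t_ij over sequence pairs k, with B the substitution
matrix score (BLOSUM62 by default, configurable) and t_ij the
Poisson-corrected distance from the family's own MSA. Sequence pairs come
from unordered combinations of pairing rows, so pair k in family A
corresponds to pair k in family B; zero-divergence pairs keep their index
position as NaN to preserve that alignment.

Every raw profile contains a large shared component — approximately
(diagonal score)/t_ij — which correlates any two sites at about 0.6
regardless of co-evolution. Each profile is therefore regressed on the
family's mean profile (the mean variability per sequence pair) and replaced
by its residuals before correlating; this is the package's reading of
"correlation relative to the mean variability", and without it the
site-specific signal is swamped. The significance null shuffles one
family's site labels: it draws random (site_A, site_B) re-pairings of the
same residual profiles, so a pair is significant only when its ρ exceeds
the (1 − α) quantile of what random site pairings achieve. This is a
resampling null rather than the original CAPS simulation null — a
documented deviation. Significant pairs are grouped as connected components
of the bipartite residue graph, numbered deterministically by smallest
family-A site; per group, mean ρ and mean Dc (the mean per-site variance of
the raw θ profiles — one reading of an ambiguous quantity, labeled as such)
are reported. Region overlap percentages are rounded to one decimal,
matching the 36/46 = 78.3 reporting convention.

## Clade-specific residues

A column is called when a pair of clades is mutually diagnostic: each clade
uniform (strict rule: one residue; class rule: one of the five
physicochemical classes — small-nonpolar GAST, hydrophobic CVILPFYMW, polar
NQH, negative DE, positive KR) and the clades' residue sets disjoint. The
class rule relaxes uniformity but keeps residue-level disjointness, so
strict calls are a subset of class calls. Gaps or unknowns disqualify a
clade at that column; clades below the minimum size (default 2 sequences)
never qualify. The default contrast is pairwise (any qualifying clade pair
calls the column); an all-clades mode requires every eligible clade to be
uniform and mutually disjoint. Whether the original figure logic required
fixation in all clades or only the contrasted pair is not formalized
anywhere, hence both modes.

## Ancestral-state tracing

Parsimony uses unit-cost Sankoff (min-plus dynamic programming) with a
down-pass and an outside up-pass, returning per node the exact set of
states realized in at least one most-parsimonious reconstruction plus the
minimum change count. This is exact on polytomies too, so no arbitrary
resolution is performed. The likelihood model is the symmetric two-state
Markov (Mk2) chain, P(stay over t) = ½ + ½e^(−2μt), with an equal root
prior; marginal posteriors come from the standard inside/outside message
passing, verified against hand-computed pruning and brute-force enumeration
over internal labelings. The rate is either fixed or optimized by bounded
1-D search on the log-likelihood (log-rate in [ln 1e−4, ln 50]). A single
binary character often has a degenerate (boundary) MLE — with one
discordant tip the likelihood can plateau at the saturation value — so
fixing a biologically sensible rate is recommended for single-trait use.
Cladograms default to unit branch lengths.

## Synthetic data

The generator emulates exactly the structure the detectors assume, on a
pure-birth (Yule) tree rescaled to root-to-tip depth 1.0 (defaults:
30 organisms, birth rate 1).

- **Substitution process**: uniform exchange — an event replaces a residue
  with any of the other 19 (marker: other 3 nucleotides) uniformly. This
  keeps every expectation analyzable; realism of the exchangeabilities is
  deliberately not modeled, since the detectors, not the process, are under
  test.
- **Rates**: family defaults 0.25 substitutions/site per unit depth, chosen
  so pairwise identities land in the 60–85% band typical of conserved
  interacting families; per-branch lognormal multipliers (σ = 0.6, mean 1)
  are correlated between families A and B with configurable ρ (the
  MirrorTree signal) and independent for the decoy. The marker is strictly
  clock-like (rate 0.5/site, length 1500 by default), giving p-distances
  that rank-correlate > 0.9 with true patristic distances.
- **Compensation**: when a substitution lands on a coupled family-A site on
  a branch, the partnered family-B site substitutes on the same branch with
  the configured probability. The default target choice is the most drastic
  BLOSUM62 change from the current residue (the favorable case for a
  BLOSUM-based detector, documented as such); a random-target mode provides
  the hard case.
- **Paralogs**: a duplication splits at the start of the organism's terminal
  branch and the copy evolves independently (without coupling) thereafter;
  the pairing table enumerates all m·n member combinations per organism.
- **Clades**: the bipartition induced by the internal node whose subtree is
  closest to half the organisms — the raw root split of a Yule tree is often
  a singleton and would be unusable for clade contrasts.
- **Neutral codon fixtures** for the dN/dS check evolve codon pairs under a
  κ-biased (default 2) mutation process at 0.4 substitutions/site total
  divergence, rejecting events that create stops — the only departure from
  strict neutrality, and the reason estimated mean ω sits slightly below 1.

What passing on these fixtures does **not** show: robustness to alignment
error, indels (the simulator produces gap-free alignments), heterotachy
beyond lognormal branch rates, non-BLOSUM-like compensatory preferences, or
codon-level selection. Results on real families additionally depend on the
user-supplied organism mapping and alignment quality.

## Problem sizes and benchmarks

The test and acceptance runs use the study conditions stated above:
30 organisms × 200 columns for detector benchmarks (100 seeds for
MirrorTree discrimination, 50 for planted-pair enrichment in the tests;
the acceptance script uses 50/25 seeds for the same quantities), 10×10
matrices × 999 permutations × 1000 replicates for Mantel calibration,
20 pairs × 300 codons for the neutral dN/dS check, and the complete sweep of
105 rooted 5-tip topologies × 32 tip assignments against a brute-force
oracle for parsimony. All randomness flows from explicit seeds; reports log
seed, substitution matrix and permutation counts.

## Known limitations

- The correlated-mutation significance threshold is a background-relative
  resampling quantile, not a familywise-error control; with ~200×200 site
  pairs, α = 0.05 admits thousands of background pairs, and connectivity
  grouping then tends to merge them into few large components. Planted-pair
  recovery is therefore assessed by enrichment, not exact identification.
- The Z comparison treats pairwise values as a sample; its p-values are
  approximate (dependence ignored).
- The Mk2 rate is unidentifiable from a single invariant character; the
  optimizer then returns the lower search bound, which is the intended
  consensus-limit behavior.
- dN/dS assumes codon-aligned, stop-free input; frameshifted data must be
  cleaned upstream.
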