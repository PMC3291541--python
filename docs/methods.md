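# Methods

This note documents the models implemented in `pepself`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the design decisions taken where the procedure was
genuinely open.

## The overlap question

Let S be the set of unique self (host) 9mers presented on one MHC class I
allele and N the corresponding set for a pathogen species. A nonself
peptide n ∈ N *overlaps* self when at least one s ∈ S is recognised as
"the same" under a recognition model. The self/nonself overlap of a
kingdom (virus or bacterium) is pooled: total overlapping nonself peptides
divided by total nonself peptides across all species of that kingdom, and
the headline figure is the unweighted mean of the two kingdom fractions.
All counting is per unique peptide — duplicates within a proteome count
once. Overlap is directional (nonself queried against self), which matters
only for asymmetric similarity rules; every rule constructed here is
symmetric.

## Presentation model

Binding predictors are behind a minimal contract: `score(peptide)` returns
a predicted IC50 in nM (lower = stronger). Two implementations ship:

* **MotifBindingModel** — a 9×20 table of additive log-IC50 contributions,
  `IC50 = exp(Σ_p w[p, aa_p])`. This is a simulation device with plantable
  anchor positions, not a trained predictor.
* **TableBindingModel** — a lookup over an imported TSV of precomputed
  scores (peptide, allele, ic50_nm), for use with external NetMHC-style
  predictions. Conflicting duplicate rows are an error; querying an
  unscored peptide is an error rather than a default.

The processing stage (proteasomal C-terminal cleavage + TAP transport) is
a second contract, `passes(peptide)`, pass-through by default; a toy
C-terminal residue-preference filter is provided for pipeline realism. There is no settled convention for thresholding and combining
cleavage and TAP scores, so no particular combination is baked in behind
the contract.

Two threshold modes select the presented set, with **inclusive**
comparison (score ≤ threshold is a binder, so a peptide at exactly 500 nM
counts):

* **fixed** — 500 nM, the conventional binder cutoff.
* **scaled** — the empirical quantile of the allele's self-peptide scores
  at a target specificity (default 0.023, the fraction of self 9mers
  HLA-A*0201 presents at 500 nM). The threshold is the k-th smallest self
  score with k = ⌊target·N⌋; all peptides tied at the threshold are
  included and the achieved specificity is reported rather than forced.
  With distinct scores this guarantees |achieved − target| ≤ 1/N. A
  degenerate (all-equal) score distribution has no usable quantile and is
  an error directing the caller to fixed mode. If target < 1/N the
  calibration returns a threshold below the minimum score (empty set,
  achieved 0) rather than presenting a too-large fraction.

## Recognition models

A `RecognitionModel` is (recognised positions; fixed positions that must
match exactly; a partition of the remaining recognised positions into
regions, each with a mismatch budget; a similarity rule). A mismatch is
tolerated only if (a) its region still has budget and (b) the residue pair
is in the similarity rule. Exact position-mask models (complete P1–9,
middle P3–8, non-anchor P1+P3–8) are the special case where every
recognised position is fixed.

The default **degenerate** model encodes how TCRs read a presented 9mer:
only P3–8 are visible (P2/P9 are buried anchors, P1 barely matters), P5 is
read most stringently (no mismatch), and at most one conservative mismatch
is tolerated N-terminal of P5 (P3–4) and one C-terminal (P6–8). A variant
with a single region {P3,P4,P6,P7,P8} of budget 2 allows the two
mismatches to sit next to each other; an allele-specific variant applies
the same anatomy (fix the most selective recognised position, split the
rest around it) to an allele's six least-specific positions as measured by
positional entropy.

**Similarity rules** are derived from a symmetric 20×20 matrix by one of
three criteria: `abs_covariance_gt` (|M(a,b)| > cutoff, the PMBEC
convention at 0.05), `value_gt` (signed), and `positive_score` (M(a,b) >
0, the BLOSUM convention). The absolute-value form is the documented PMBEC
usage and is the default even though negative covariance arguably signals
dissimilarity; the signed form is available for that reading. The PMBEC
matrix itself is not bundled — its published values must be supplied as a
matrix file (first row the 20 amino-acid letters, then 20 rows of 20
numbers). BLOSUM45/50/62/80/90 are available by name via Biopython;
BLOSUM35 (the customary matrix for the similarity-score method below) is
likewise supplied as a file, since fabricating matrix values in-repo is
worse than requiring the real ones.

**Key index.** Degenerate overlap at scale uses an index: self peptides
are keyed by their recognised-position projection, and each nonself
peptide enumerates the set of projections its T-cell would accept
(own-residue or similar-residue substitutions within each region's
budget). The key-set size has the closed form Π_regions Σ_{|T|≤budget}
Π_{i∈T} s_i (s_i = similar-set size of the residue at position i; for
budget 1 this is 1 + Σ s_i), ~25 keys under a PMBEC-regime rule. Index
membership is provably equivalent to the pairwise definition for
symmetric rules, and the test suite asserts that equivalence directly
against the O(n²) evaluation.

**Peptide similarity score.** For query q against reference r:
raw = Σ_i M(r_i, q_i), scaled to score = (raw − min)/(max − min) where
min/max are the extreme achievable raw scores against r (worked example:
raw 3 with bounds [1, 11] gives 0.2). Two peptides overlap when the score
exceeds 0.85. When screening nonself against self, the nonself peptide is
the reference (its intrinsic similarity normalises the scale); this choice
is configurable since the convention is ambiguous.

## Cross-reactivity footprint

For a T-cell defined by the middle-region residues, the number of *other*
recognised combinations is the key-count closed form minus 1. Averaged
over independent uniform residues the expectation factorises over regions;
for the default model mean = (1 + 2·E[s])(1 + 3·E[s]) − 1 with E[s] the
mean similar-set size. The reciprocal is reported as 20⁶ / mean — the
"1 in N" cross-reactivity — using the count of *other* combinations
(consistent with 20⁶/24 ≈ 2.7 million in the PMBEC regime); an inclusive
variant (divide by mean + 1) is also carried. The closed form is validated
against exhaustive enumeration of the full middle-region space on reduced
alphabets, where that space is enumerable.

## Statistics

* **Chi-square, 2×2**: statistic n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)], 1 df,
  *no* Yates continuity correction by default — the uncorrected statistic
  reproduces all four published p-values (0.027, 0.29, 0.066, 0.0038) on
  the printed tables; the corrected form is behind a flag. Zero marginals
  are an error naming the degenerate margin.
* **Permutation enrichment**: with global per-residue rate
  λ = Σ counts / Σ lengths, protein i draws Binomial(n_species,
  min(1, λ·L_i/n_species)) per permutation; flagged iff the observed
  species count strictly exceeds all n_perm = 1000 draws (empirical
  p < 1/1001). The binomial-over-species null is the minimal distribution
  consistent with "drawn from the expected fraction given protein length";
  the flagging criterion follows the all-permutations form. The construction
  is scale-invariant: doubling every length and count leaves λ·L/n and
  the flags unchanged in distribution.
* **Positional entropy / anchors**: Shannon entropy per position (bits)
  over presented peptides. Selectivity is *information content*
  (log₂20 − H), not raw entropy: high entropy means low selectivity, so a
  literal entropy sum cannot flag restricted positions in the stated
  direction (a literal mode is provided, and a test demonstrates the
  wrong-direction behaviour). An allele has *additional anchors* when the
  non-anchor (P1, P3–8) selectivity sum exceeds 25% of the all-position
  sum. The six least-specific positions (highest entropy, ties toward the
  N-terminus) define the allele-specific recognition mask.
* **Spearman rank** with tie-aware ranks, p from the t approximation
  (delegated to scipy).

## TCR contacts

For each peptide position of a 9mer in a pMHC–TCR structure, the contact
count is the number of distinct TCR *residues* (not atoms) with at least
one non-hydrogen atom strictly within 5.0 Å of any non-hydrogen atom of
that peptide residue; per-structure fractions normalise by the structure's
total contacts. Chain identity (peptide/TCR/MHC) is explicit annotation,
never guessed from the file — a helper suggests the unique 9-residue chain
if one exists. Altlocs keep the highest-occupancy conformer. Group
comparisons (e.g. P4–8 vs P1–3+P9) pool per-structure fractions into a
two-sided Wilcoxon rank-sums test.

## Synthetic data: what it emulates, what it does not

`make_proteomes` plants homology by overwriting one contiguous chunk of
each pathogen protein with a copied self subsequence, sized so the planted
fraction of 9mer windows equals the requested rate (rate 1 copies whole
proteins and therefore requires nonself no longer than the longest self
protein). Residues are otherwise i.i.d. — uniform by default, matching the
random-peptide convention for entropy calibration. This captures the
set-overlap structure the pipeline measures, but not proteome-scale
composition bias, repeat families, or phylogenetic correlation between
pathogen species; passing tests demonstrate correctness of the overlap
machinery and recoverability of planted signal, not the numerical overlap
levels of real proteomes, which additionally depend on the binding
predictor used. Default problem sizes in tests and the acceptance script
(~100–150 self proteins of 200–500 residues, 4–6 species, 10 proteins
each) were chosen as the smallest runs at which the planted rate of 0.05
sits well clear of its binomial noise floor.

`make_allele` gives anchors a per-residue weight spread (`anchor_strength`,
default 2.0 log-units vs 0.05 background) so presented sets show the low
anchor entropy of real alleles. `make_immunogenicity_labels` draws
immunogenicity with log-odds logit(base_rate) + log(OR)·(1 − overlap); OR
3.5 at base rate 0.25 roughly matches the published effect direction and
magnitude. `make_similarity_matrix` selects round(mean·10) random residue
pairs to exceed the 0.05 cutoff, so achievable mean similar-set sizes are
multiples of 0.1 (requested means are matched within ±0.2; the
PMBEC-regime default 1.6 yields a footprint mean of 23.36 and reciprocal
2.74 million). `make_toy_structure` realises requested contact distances
exactly, with peptide residues 12 Å apart so a placed TCR residue can
contact only its target position; "within 5.0 Å" is strict less-than,
consistently in the generator and the counter.

## Degenerate inputs and tie-breaks

* k-mers: windows containing non-canonical residues (X, B, Z, U, J, O, *)
  are skipped; the protein itself is kept. k longer than every sequence
  yields an empty set, and a length-scan entry with an empty denominator
  is reported absent rather than as 0/0.
* Redundancy reduction visits proteomes in descending size (ties by id)
  and discards a candidate whose shared unique-9mer fraction — normalised
  by the smaller proteome of the pair — exceeds the cutoff against any
  retained proteome. The shared-9mer criterion replaces an all-to-all
  alignment-based similarity with the same normalisation direction; it is
  idempotent by construction.
* Empty self sets yield overlap 0 with a warning (not an error), so
  screens over many alleles do not abort on one empty presented set.
* Matrix symmetry is enforced at 1e-9; similarity rules are validated to
  be symmetric and irreflexive at construction.

## Known limitations

* Published overlap percentages on real data (0.2% identical 9mers, 0.15%
  complete-pMHC, 2.7% middle-exact, ~29% degenerate) are not reproduced
  here: they require the original proteome snapshots and neural-network
  binding predictors, which are out of scope behind the scoring contract.
  What the package guarantees instead is exact agreement between the
  key-index and brute-force overlap definitions, the monotone ordering of
  the overlap models, and recovery of planted rates.
* The footprint's "~24 other variants / 1 in 2.7 million" depends on the
  PMBEC matrix, which must be user-supplied; the bundled synthetic regime
  (mean set size 1.6) gives 23.4 and 2.7 million.
* The similarity-score overlap is all-pairs (no index) and intended for
  presented-set-sized inputs, not whole proteomes.
* The permutation null treats species as exchangeable and overlap events
  as independent given length; clustered homology (e.g. one gene family
  shared with many related species) inflates apparent enrichment.
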