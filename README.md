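# pepself

**Self/nonself overlap of MHC class I presented peptides under exact and
degenerate T-cell recognition.**

CD8⁺ T-cells survey 9-residue peptides (9mers) presented on MHC class I
molecules (pMHCs) and must decide whether a cell is infected. That decision
is only possible if pathogen-derived presented peptides are distinguishable
from host-derived ones. `pepself` quantifies how often they are not: it
measures the fraction of nonself (viral/bacterial) presented 9mers that are
identical to — or, given the cross-reactive way T-cell receptors read a
peptide, indistinguishable from — presented self 9mers, and tests whether
that self-overlap predicts a peptide's failure to elicit a T-cell response
(a "hole" in the T-cell repertoire).

## What it computes

* **Peptidomes** — unique k-mer sets from protein FASTA files, with
  within-protein shuffled controls and shared-9mer redundancy reduction
  between pathogen proteomes.
* **Presentation** — a pluggable IC50 binding-score contract (a built-in
  position-weight motif model for simulation, or imported NetMHC-style
  score tables), with a *fixed* 500 nM binder threshold or a *scaled*
  threshold calibrated per allele so that a common fraction (2.3%) of self
  9mers is presented.
* **Recognition models** — exact overlap on a position mask (complete
  P1–9, TCR-exposed middle P3–8, non-anchor P1+P3–8); a *degenerate* model
  in which the TCR reads P3–8, demands identity at P5 and tolerates one
  conservative substitution on each side of it (conservative = linked in a
  similarity rule derived from a covariance/substitution matrix, e.g.
  |covariance| > 0.05 or a positive BLOSUM score); and a min–max-scaled
  peptide similarity score with a 0.85 overlap threshold.
* **Overlap enumeration** — per-species overlap counts pooled per kingdom
  (virus/bacterium), the peptide-length scan with shuffled controls, and
  per-self-protein counts of overlapping pathogen species. The degenerate
  overlap uses a recognition-key index (≈25 probes per peptide) that
  exactly matches the all-pairs definition while scaling linearly.
* **Cross-reactivity footprint** — for a T-cell defined by a middle-region
  6mer, the number of *other* middle-region combinations it recognises:
  closed form `Π_regions (1 + Σ s_i) − 1`, its uniform-residue average, and
  the "1 in N" reciprocal against the 20⁶ possible combinations.
* **Statistics** — uncorrected chi-square on 2×2
  immunogenicity × self-overlap tables, a length-normalised permutation
  enrichment test for self proteins overlapping unexpectedly many species,
  per-position Shannon entropy / additional-anchor selectivity (25% rule),
  and Spearman rank correlation.
* **Structures** — per-position TCR contact counts in pMHC–TCR complexes
  (distinct TCR residues with any heavy atom strictly within 5.0 Å).
* **Synthetic data** — generators for all of the above with known ground
  truth: planted shared-9mer rates, planted binding anchors, planted
  immunogenicity odds ratios, calibrated similarity matrices and toy PDB
  structures.

## Worked example

A fully synthetic end-to-end run (the shipped demo configuration plants a
5% shared-9mer rate between host and pathogens and uses a P2/P9-anchored
allele at 10% specificity):

```bash
$ pepself run --config examples/demo.cfg --outdir demo_out
run complete; manifest d89345d59d77 -> demo_out

$ cat demo_out/overlap_summary.tsv
# pepself 0.1.0 | seed=1
model   kingdom_average
complete        0.06350300459526334
middle  0.0681980003029844
nonanchor       0.06350300459526334
degenerate      0.06978740594859364
```

The kingdom-averaged overlap rises monotonically as the T-cell is assumed
to read fewer positions (complete → middle) and to tolerate conservative
mismatches (middle → degenerate): ~6.4% of presented nonself peptides are
identical to a presented self peptide over all nine positions, while ~7.0%
are indistinguishable under the degenerate model. (On real proteomes the
gap is far larger — identity is rare but degenerate overlap is not — the
synthetic demo plants mostly exact homology.)

The cross-reactivity footprint of a single T-cell clone, under a
conservative-substitution rule with a mean of 1.6 interchangeable partners
per residue (the regime of covariance-derived rules like PMBEC at
|cov| > 0.05):

```bash
$ pepself synth matrix --mean-similar 1.6 --seed 11 --out pmbec_like.txt
$ pepself footprint --matrix pmbec_like.txt
mean other recognized middle-region combinations: 23.36
cross-reactivity: 1 in 2,739,726 (2.7 million)
```

i.e. a T-cell recognising one middle-region 6mer also recognises ~23 of
the 20⁶ = 64 million possible other combinations — one pMHC in ~2.7
million — far more specific than experimental cross-reactivity estimates
of ~1 in 10⁵, so degenerate-overlap figures built on it are conservative.

The association between self-overlap and immunogenicity for HIV-1-derived
peptides on HLA-A\*0201 (published counts: 4 of 33 immunogenic vs 18 of 54
non-immunogenic peptides overlap self):

```bash
$ pepself immunotest --table 4,29,18,36
chi2 = 4.878, p = 0.0272
```

Immunogenic peptides overlap self significantly less often — self
tolerance censors T-cell responses to self-like pathogen peptides.

A real PMBEC matrix file (or BLOSUM35 for the similarity-score method) can
be dropped in as a whitespace-delimited 20×20 table (first row: the 20
amino-acid letters) and passed via `--matrix`; BLOSUM45/50/62/80/90 are
available by name.

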