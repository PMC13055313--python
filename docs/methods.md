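# Methods

## Problem setting

An *efp* deletion in *Bacillus subtilis* perturbs translation at
stall-prone diproline sites and, through the resulting shifts in RNA
polymerase subunits and sigma factors, rewires much of the
transcriptome. Distinguishing proteins whose decrease is a *direct*
consequence of losing EF-P from those that merely follow their mRNA
requires paired measurements: transcript fold changes (RNA-seq),
protein fold changes (iTRAQ LC-MS/MS), and the location of XPPX motifs
in the proteome. `xppx` implements that discrimination as a small,
fully tested pipeline.

## Motif model

A stall-prone site is any four-residue window whose middle two residues
are proline. The scanner reports **every** such window, including
overlaps inside polyproline tracts (a run of n ≥ 4 prolines yields n − 3
windows); collapsing to per-protein flags is a view applied downstream.
Conventions:

- `position` is the 1-based index of the window's first residue (the
  leading X). The printed annotations this follows (e.g. an APPV motif
  "at codon 171") quote the four-letter motif starting at the cited
  residue; whether genome annotations count the initiator Met cannot be
  settled without the sequences, so the package simply documents its own
  convention in every output header.
- A proline pair flush against either terminus has no in-sequence flank
  and is not an XPPX hit (the pattern requires four in-bounds residues).
- The unknown residue `X` may occupy flank slots but never counts as P.
- Non-canonical stall triplets (IPI, KPG, DPG by default) are scanned by
  exact 3-mer match and reported with `kind=noncanonical`; they do not
  enter the XPPX flag.

## Differential calling

Counts are scaled to counts-per-million per replicate; replicates are
summarized by the arithmetic mean (the proteome arm of the underlying
design pooled three biological replicates before labelling, the
transcriptome arm sequenced three independently — the mean treats both
shapes uniformly). A pseudocount (default 0.5, configurable, added to
condition means) keeps low-count ratios finite.

Cutoffs are deliberately layer-specific and strict:

- transcripts: up iff log2FC > 1, down iff log2FC < −1 — mirror
  symmetric in the ratio;
- proteins: up iff ratio > 1.5, down iff ratio < 0.7 — *not* mirror
  symmetric (0.7 ≠ 1/1.5), reflecting the compressed dynamic range of
  reporter-ion quantification.

Values exactly at a cutoff are `unchanged`. No dispersion estimation or
hypothesis testing is performed: the published gene lists this mirrors
are fold-change-only, and adding an FDR layer would change the object
being reproduced.

## Regulatory-mode classification

The TE (translational efficiency) ratio is the protein ratio divided by
the mRNA ratio; TE < 1 means less protein made per transcript. Rules
apply in a fixed, tested order (transcriptional before direct): a
protein down at both layers is attributed to its mRNA even when it
carries the motif, because the cross-omics design cannot separate the
two explanations for such genes. The "severely downregulated at the
mRNA level" exclusion is quantified as the same DEG cutoff used
everywhere (log2FC < −1) rather than inventing a second threshold, and
the TE cutoff for the masked class (apparent up, rising mRNA, TE below
cutoff) reuses the protein down-threshold 0.7 for the same reason. Both
are configurable.

Proteins detected in the protein layer but absent from the RNA table are
treated as mRNA-unchanged (ratio 1) with a `no_rna_evidence` flag; they
remain eligible as direct candidates since only a demonstrated mRNA
decrease excludes a protein.

Stall-atlas support: a call gains `stall_support` when the atlas lists a
site within ±1 residue (default) of any XPPX hit in that protein — the
window absorbs ribosome-profiling positional jitter and the ambiguity of
which residue of the motif a stall is assigned to. Atlas rows for
unknown proteins warn and are skipped (the available atlas derives from
a different strain and growth condition).

## Category summaries

Up/down calls are aggregated per functional category (one category per
feature; unmapped features fall into "Unknown or poorly characterized
proteins"). Percentages are shares of the summed Total column of the
produced table — not of the number of detected features — because that
is the denominator the published percentages are arithmetically
consistent with. The printing rule, derived from the same table: round
half away from zero; if the one-decimal rounding is below 1.0, keep one
decimal (0.7, 0.3, 0.2), otherwise print the integer (so 0.99% prints as
1, not 1.0).

## Synthetic data

The generator emulates the quantities the pipeline consumes, not the
instruments that produce them:

- **Sequences**: lengths uniform on 80–600 residues. By default,
  backgrounds are proline-free and exactly the designated fraction of
  genes receives one planted x-P-P-x window, so the motif flag is
  perfectly recoverable by scanning; a `realistic_background` switch
  instead uses a natural proline frequency (4.5%) and rewrites the truth
  flag from an actual scan.
- **Counts**: negative binomial with var = μ + φμ² (φ =
  `nb_dispersion`, default 0.05; φ → 0 degenerates to Poisson), baseline
  means lognormal (median ≈ 245 counts), mutant means scaled by
  2^(planted log2 effect) for DE genes (|log2FC| uniform on 1.5–3).
- **Protein ratios**: true protein abundance per condition is the
  empirical mRNA mean times a baseline translational efficiency, times
  the planted attenuation multiplier in the mutant (uniform on 0.2–0.6
  for targets). The observed mutant/wild ratio applies dynamic-range
  compression as a one-parameter power law, observed = true^c with
  c = 0.6 by default — the simplest monotone shrinkage consistent with
  the qualitative compression of summed-peptide reporter ratios — then
  multiplicative lognormal noise with the configured CV.
- **Defaults as study conditions**: `frac_xppx = 0.22` matches the
  927/4237 motif share of the *B. subtilis* genome; `frac_rna_de = 0.25`
  matches the ~1100 of ~4500 transcripts changed in the mutant;
  `n_replicates = 3` matches the design. Attenuation strength, noise CV
  (0.1) and `frac_translational` (0.3) have no published estimates and
  are fixed, plausible placeholders — sensitivity is explored by passing
  different configs, not by moving the defaults.

The whole dataset is a pure function of (config, seed): one
`numpy.random.Generator` is threaded through all stages in a fixed
order.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: peptide-level iTRAQ artifacts (shared
peptides, ratio estimation from spectra), protein degradation and
turnover, operon structure and correlated regulation, detection dropout
(all genes appear in both layers), and context-dependence of stalling
(every planted motif is fully penetrant).

## Validation studies and their problem sizes

- Planted-target recovery runs at n = 4,000 genes, 22% motif share, half
  of motif genes attenuated (multiplier ≤ 0.5), noise CV 0.05, no
  compression, and — deliberately — no planted mRNA effects: a planted
  translational target whose mRNA also drops is *by design* classified
  `transcriptional` (that is the rule the cross-omics census itself
  applies), so precision/recall of the translational channel is only
  well-posed with the transcriptional channel silenced. Under these
  conditions precision and recall are each ≥ 0.95.
- The compression study compares recall at c = 1 vs c = 0.6 at fixed
  thresholds on otherwise identical draws (same seed), and checks
  |log2 observed| = c·|log2 true| to 1e−9 noise-free. Attenuation
  multipliers up to 0.6 are used here so that compression has cutoff
  crossings to reveal (0.6^0.6 ≈ 0.74 > 0.7).
- The null study (nothing planted, 2,000 genes, low dispersion) bounds
  the direct-candidate false-positive rate at 1%.

These sizes keep the full suite in a few seconds while leaving the
binomial noise on estimated rates well inside the asserted margins.

## Numerical conventions and degenerate inputs

- Percent rounding is decimal-based half-away-from-zero (`decimal`
  quantize), not float banker's rounding.
- A replicate with zero total counts is an error naming the replicate; a
  zero wild-type mean is an error unless a positive pseudocount is set;
  an all-zero category table has no percentage denominator and errors.
- Fold-change records verify log2fc against the ratio to 1e−4 on
  construction; funnel counts verify their nesting invariants on
  construction.
- Duplicate feature ids, invalid residues (with protein and offset),
  negative abundances, and mismatched rna/protein feature ids all fail
  fast with specific messages.

## Known limitations

- Fold-change-only calling cannot reproduce list-level membership of any
  real differential set; only threshold behavior is guaranteed.
- The TE ratio inherits both layers' noise and the compression bias; no
  attempt is made to decompress observed ratios (c is not identifiable
  from a single two-condition experiment).
- The category summary requires a single category per feature;
  multi-category curations must be flattened upstream, which can make
  column sums differ slightly from layer-wide DEG counts.
- With `realistic_background`, motif flags are scan-derived and some
  planted attenuations are dropped to preserve the
  target-implies-motif invariant, so the realized `frac_translational`
  is slightly below the configured value.
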