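# Methods

## Experimental design being modelled

The pipeline assumes a 2×2 gene-level FPKM design: cells transfected with
either the miRNA of interest or a control duplex, each profiled by total
RNA-seq and by Ago2 RIP-seq (sequencing of RISC-co-immunoprecipitated
RNA), optionally with biological replicates. All inference is ratio-based;
no differential-expression testing is performed at the quantification
stage.

## Expression processing

1. **Replicate combining.** Biological replicates are collapsed to one
   pseudo-replicate per condition×assay cell by the arithmetic mean of
   FPKM. The mean is the simplest unbiased pooling; upstream quantifiers
   that already emit a combined FPKM pass through unchanged (a single
   replicate is the identity case).
2. **Hard capping.** Every FPKM below the floor (default 1.0 FPKM) is set
   to the floor *before any ratio is formed*, bounding all ratios to
   [floor/max, max/floor] and removing zero denominators. Capping after
   combining is a deliberate ordering: the cap exists to protect the
   ratios, so it must sit immediately before them.
3. **Ratios.** Repression = control-total / miRNA-total; enrichment =
   (miRNA-RIP / miRNA-total) / (control-RIP / control-total). The two are
   deliberately coupled: real repression shrinks the miRNA-total
   denominator and therefore inflates enrichment, so a noise-free
   simulated target with enrichment effect *E* and repression effect *R*
   measures enrichment *E·R* and repression *R* — a closed form the tests
   rely on.
4. **Score and target set.** score = (enrichment + repression)/2; genes
   with score ≥ 1.75 (boundary inclusive) form the target set, sorted by
   descending score with lexicographic gene-ID tie-breaks for determinism.

Statistical comparisons of gene classes (repression CDFs, box summaries by
pairing type) use two-sided Welch *t*-tests (unequal variance) on log2
ratios; correlations are Pearson on log2 ratios. Ratios are multiplicative,
so the log scale symmetrises up- and down-changes; raw-scale variants would
weight de-repressed outliers asymmetrically.

## Site search

Pairing is Watson–Crick reverse complement on the sense strand of the UTR;
G:U wobble pairs count as mismatches (a flag enables them, default off —
"wobble" in the site definitions below refers to spacer length, not G:U
pairing). Mismatches are Hamming substitutions; no indels inside blocks —
the spacer wobble already absorbs length variation between blocks.

A supplementary site is a perfect match to the reverse complement of the
seed interval (6-mer, miRNA positions 1–6 or 2–7) plus, 5′ of it on the
UTR (antiparallel duplex geometry), a match to the reverse complement of
the 3′ interval (8-mer, positions 11–18 or 13–20) with at most 3
mismatches. The UTR spacer between the blocks must equal the nominal
spacer ±1 nt, where the nominal spacer is the miRNA gap between the two
intervals (e.g. 4 nt for seed 1–6 with 3′ 11–18, 5 nt for seed 2–7 with 3′
13–20). A compensatory site has the same geometry with *exactly one* seed
mismatch; perfect-seed loci are classified supplementary, keeping the two
classes disjoint by construction. Per seed locus, the reported site is the
one with the fewest 3′ mismatches (ties: spacer closest to nominal, then
shorter spacer). Canonical seed matches (default 7-mer, positions 2–8 —
the 7mer-m8 convention) are exact occurrences, overlaps allowed.

Genes are labelled by precedence supplementary > compensatory >
canonical_seed > none, counted once regardless of site multiplicity. For
miR-503-style analyses the seed interval is 1–6 with 3′ 11–18; for
miR-103-style analyses the seed is 2–7 with 3′ 13–20 (supplementary) and
11–18 (compensatory); these parameter sets ship as constants.

The stepwise k-mer scan takes, for each 1-based miRNA offset *p*, the
k-mer at positions *p..p+k−1* (k = 6 by default) and reports the fraction
of target genes whose UTR contains its reverse complement divided by the
same fraction over all genes profiled. The default counts genes with at
least one occurrence; an occurrence-count mode is available. Offsets with
zero background frequency are reported as undefined (NaN), never as 0.

UTR coordinates in outputs are 0-based half-open; miRNA positions are
1-based inclusive. Both conventions are stated in output file headers.

## Synthetic data generator

The generator emulates the design at the gene level, not the read level:

* **Baselines.** Per-gene baseline FPKM is log-normal: log2 baseline ~
  N(5, 2²) by default, i.e. a median of ~32 FPKM with a realistic dynamic
  range; genes in the low tail get capped downstream, exactly as real
  low-expression genes would.
* **Effects.** The first `n_targets` genes are targets: their miRNA-RIP
  FPKM is multiplied by `enrichment_effect` (default 3) and their
  miRNA-total FPKM divided by `repression_effect` (default 2) —
  multiplicative effects on cell means, mirroring fold-change language.
* **Noise.** Each replicate value is its cell mean times 2^N(0, sd²) with
  sd = 0.25 log2 units by default (replicate-level scatter typical of
  well-powered bulk RNA-seq), `n_replicates` = 3.
* **UTRs.** Background is i.i.d. uniform over {A,C,G,U} (a GC-controlled
  alternative exists); lengths are normal with mean 800 nt, sd 150 nt —
  typical human 3′UTR scale. At most one site is planted per gene, never
  crossing UTR boundaries, by inserting the exact reverse-complement
  segment(s): canonical 7-mer (positions 2–8), supplementary (3′ 8-mer
  block + nominal spacer of background sequence + perfect seed 6-mer), or
  compensatory (the same with one random seed substitution). Planted
  coordinates are recorded as ground truth.
* **Site plan.** `site_plan` maps site type → gene count; sites go to the
  lowest-index genes, so counts summing to `n_targets` put a site on every
  expression target and only on them.
* **Determinism.** UTR generation and expression simulation use
  independent child streams of `rng_seed`; identical seeds give
  byte-identical FASTA and FPKM outputs.
* **Clean backgrounds.** Random backgrounds occasionally contain chance
  sites (a chance seed 6-mer occurs at ~0.02% per position, and a
  1-mismatch seed is ~18× likelier than a perfect one), so exact
  label-recovery tests use `clean_background=True`, which re-draws a
  gene's background until its classification equals its plan. This is off
  by default because it biases background k-mer statistics, which null
  calibration checks depend on.

What the generator does **not** model: read-level sampling noise, fragment
and length bias, multi-site genes, dosage-dependent effects, G:U pairing
in planted sites, miRNA co-transfection, and any correlation structure
between genes. Passing tests therefore demonstrate that the pipeline's
logic is correct and calibrated under its stated noise model — not that
the thresholds would achieve the same precision/recall on real
transfection data, where effect sizes are smaller and heterogeneous.

## Numerical and design choices

* Ratios are only computed on capped (strictly positive) inputs; the code
  refuses uncapped zeros rather than emitting infinities.
* Empirical CDFs are right-continuous step functions ending at 1; the last
  ranked group may be smaller than 250 and is reported, preserving the
  invariant that group frequencies, weighted by group size, average to 1.
* Box summaries report quartiles over all values; whiskers exclude points
  beyond 1.5×IQR (outliers are excluded from whiskers only).
* Classes with fewer than two members are summarised but flagged and not
  *t*-tested.
* Genes present in the FPKM table but missing from the UTR FASTA stay in
  expression analyses and are excluded from sequence analyses, with the
  count logged and reported.

## Problem sizes

The validation suite simulates at sizes where the checked signals are
unambiguous while a laptop run stays comfortable: 10,000 genes / 500
planted targets for target recovery, 2,000 genes / 400
supplementary-planted targets for sequence-pattern checks, 500 random
miRNA–UTR pairs (UTRs ≤ 300 nt) for brute-force oracle comparison, and 200
independent null simulations of 100 genes for *t*-test calibration.

In the k-mer pattern check, "peak" offsets are those whose 6-mer lies
fully inside a planted interval; the "flat" set is offsets sharing at most
half the k-mer (3 of 6 positions) with a planted interval, where guaranteed
occupancy is ≤ (1/4)³ ≈ 1.6% absolute. Offsets sharing 4–5 planted bases
sit in neither set: they are genuinely, if mildly, elevated by
construction (an exact planted insert extends into random flanks with
probability 1/4 per base), and belong to neither the peak nor the
chance-level regime.

## Known limitations

* The arithmetic-mean replicate pooling and the capping-after-combining
  order are judgment calls; both are isolated behind single functions and
  easy to swap.
* Site search is exhaustive O(UTR × blocks) per gene — fine for
  transcriptome-scale UTR sets, but no suffix-automaton tricks are
  attempted.
* The thermodynamics of pairing (ΔG), site conservation, and site
  accessibility are out of scope by design; the site definitions are
  purely combinatorial.
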