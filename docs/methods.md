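# Methods

This note documents the models, rules and numerical choices behind `gage`,
and what the synthetic study conditions do and do not establish about real
genomes.

## The identification workflow

Species identification here rests on two ingredients: (i) a *target
sequence* — a 25-bp genome window consisting of a 4-nt protospacer-adjacent
motif (PAM) and a 21-nt protospacer — that is present in the subject
species' genome and absent (to within a mismatch tolerance) from the genomes
of its likely adulterants, and (ii) a CRISPR/Cas12a assay in which a crRNA
matching that target triggers collateral ssDNA cleavage and hence
fluorescence only when subject DNA is present. The package implements the
in-silico half end to end: target enumeration, annotation statistics,
region-restricted extraction, specificity screening, crRNA assembly and
detection calling on fluorescence replicates.

## Target enumeration (`target_library`)

A genome of total length L yields `len - k + 1` sliding windows per contig
(k = 25 by default; windows never span contig boundaries). A window is a
candidate target iff its first 4 nt match the forward PAM pattern or its
last 4 nt match the reverse-end pattern, with IUPAC semantics. Two PAM
conventions are supported:

* **paper** (default): forward `TTTV`, reverse-end `VAAA`, both matched
  literally on the forward-strand string. This is the published rule. Note
  it is *not* strand-symmetric, because the reverse complement of `TTTV` is
  `BAAA`, not `VAAA`.
* **strict**: reverse-end = reverse complement of the forward pattern
  (`BAAA` for `TTTV`), i.e. a true TTTV site on the opposite strand.
  Strand-mirror invariants hold only in this mode.

Both modes are first-class because the literal rule is what the method
describes, while the strict rule is what the enzyme's biochemistry implies;
the default follows the description. Windows containing any non-ACGT letter
are skipped (a probe cannot be synthesised against an ambiguous base), but
the genome length L used for the density statistic is the raw assembly
length including those bases. A window matching both patterns is counted
once with orientation `both` and decomposes on its forward reading.
Deduplication compares k-mer strings literally on the scanned strand, with
no cross-strand canonicalisation — the semantics of a plain k-mer counter.
Copy number is the number of qualifying windows with that exact string;
overlapping windows in tandem repeats each count.

Density is `L / total_count` (bp of genome per candidate target). On an
i.i.d. uniform ACGT genome, P(TTTV prefix) = P(VAAA suffix) =
(1/4)^3 · (3/4) = 3/256, the two events are independent (disjoint window
positions), so the expected density is `1 / (2p − p²) ≈ 42.9 bp`. AT-rich
plant genomes are denser; the generator ships an AT-rich preset
(A,C,G,T = 0.30, 0.185, 0.185, 0.33) that pushes densities toward the
18–30 bp range observed in real plant assemblies. The whole-genome scan on
a 1-Mb genome runs in about a second; the scanner streams PAM matches via
regular-expression lookahead and never materialises all windows.

## Annotation classification (`annotation_classify`)

An occurrence belongs to a class iff its full window is **contained** in a
single feature of that class — a window straddling a boundary is not
"located in" the feature. Classes are: genome (all), annotated (contained
in the merged union of coding-gene and ncRNA intervals, counted once even
under feature overlap), unannotated (the complement; annotated +
unannotated = genome exactly), coding genes (gene-body extent of
protein-coding genes), CDS, and ncRNA (miRNA/rRNA/snRNA/tRNA). Rows other
than the annotated/unannotated partition may overlap, which mirrors how
such tables are tallied in practice. Per-class totals count occurrences; a
deduplicated record counts toward every class in which at least one of its
occurrences lies. Gene CDS coverage is the fraction of coding genes with at
least one target window contained in one of their CDS intervals; gene-body
extent (not mRNA extent) defines the coding-gene row.

## Specificity screening (`specificity`)

The off-target search follows Cas-OFFinder semantics: the PAM must match
its IUPAC pattern exactly and mismatches are counted on the 21-nt
protospacer only. Both strands are scanned; reverse-strand distance is
computed as `hamming(site[:21], revcomp(query))`, which equals the distance
on the opposite-strand reading. Hits are reported in forward-strand
coordinates, totally ordered by (seqid, start0, strand), and a palindromic
window can legitimately yield one hit per strand. The implementation is a
numpy-vectorised position scan (PAM mask + per-candidate Hamming count);
the test suite asserts exact equality with an independent per-position
brute-force oracle, so any faster index-based strategy must preserve this
contract. At the genome sizes used here (≤ 1 Mb) the vectorised scan is
ample; multi-Gb assemblies would want a seed-and-extend index, which is an
engineering extension, not a semantic one.

A candidate *passes* the screen iff every adulterant genome has zero sites
within `max_mm = 3` mismatches — the empirical bound below which Cas12a
off-target activation is reported. Presence in the subject is reported but
not enforced. Final selection ranks passing candidates by copy number
descending (multi-copy targets amplify signal), ties broken
lexicographically by k-mer; failing candidates are retained with the names
of the offending genomes.

## crRNA assembly (`crrna_design`)

The crRNA is `repeat (5') + spacer (3')`. The spacer is the protospacer
transcribed in place (T→U), length k − 4 = 21. The default repeat is the
21-nt mature LbCas12a direct repeat `UAAUUUCUACUAAGUGUAGAU`; vendors ship
variants (e.g. longer precursor repeats), so the repeat is a parameter and
is recorded in every output. Design is a pure function of (protospacer,
repeat): two targets sharing a protospacer yield identical crRNAs, and
reverse-transcribing the spacer recovers the protospacer exactly.

## Detection calling (`assay_detection`)

Groups are replicate fluorescence series on a shared time grid (default
grid 0–60 min with a 25-min plateau read, triplicates). A group is
*detected* vs the no-template control when a two-sided Welch t-test at the
chosen timepoint gives p < α (default 0.01) **and** the group mean exceeds
the control mean; the direction guard turns the two-sided p into the
one-sided "significantly higher than control" call. Welch rather than
pooled variance because equal variances are not guaranteed across
concentrations; the choice is configurable. Degenerate inputs (zero
variance in both groups) are resolved explicitly: p = 1 for equal means,
p = 0 otherwise. The test is run at a single caller-chosen timepoint
(default 25 min); per-timepoint multiplicity correction is deliberately out
of scope since the workflow reports single-threshold calls. The LOD of a
dilution ladder is the smallest detected concentration; the scan also flags
non-monotone ladders (an undetected concentration above a detected one).

## Synthetic study conditions (`synth_data`)

The generator emulates everything the tests need with exact ground truth:

* **Genomes**: i.i.d. background from configurable base frequencies, split
  into equal contigs; planted 25-mer sites (forward-PAM prefix required;
  reverse-strand sites embed the reverse complement) at non-overlapping
  positions, with 0–4 substitutions applied to protospacer positions only,
  never the PAM. After assembly the genome is re-scanned (strict mode, up
  to max(3, planted mismatches)) and regenerated if the background contains
  any accidental exact or near-miss copy of a planted protospacer — truth
  tables are exact, not probabilistic. All randomness flows from one
  integer seed through a named generator; identical spec + seed gives
  byte-identical FASTA.
* **Annotations**: non-overlapping protein-coding genes (gene → mRNA → 1–3
  CDS) and ncRNA features in valid GFF3; the emitted text re-parses to the
  truth features exactly.
* **Adulterants**: per-base i.i.d. substitution of the subject at a given
  divergence (no indels or rearrangements). At 25% divergence a 21-nt
  protospacer expects ~5.25 mismatches, so most subject targets pass the
  ≤3-mismatch screen against such an adulterant.
* **Assays**: plateau gap over baseline follows a Hill curve in substrate
  concentration, `gap(c) = f_max·c^h/(c^h + c_half^h)`, rising as
  `1 − exp(−t/τ)`; readings add Gaussian noise and clip at zero. Defaults
  (f_max = 3000 AU, c_half = 0.005 ng/µL, h = 2, baseline = 300 AU,
  τ = 8 min, σ = 150 AU, triplicates, ten-fold ladder 10 → 0.0001 ng/µL)
  were fixed by an a-priori power analysis: at the 25-min read the
  0.01 ng/µL group sits ~19 noise-sd above background (detected with
  probability ≈ 1 at α = 0.01, n = 3) while 0.001 ng/µL sits below one sd
  (false-detection probability ≈ 2%), so the planted LOD is 0.01 ng/µL and
  the ladder recovers it in ≈ 98% of simulations. The *planted threshold*
  is defined as the smallest ladder concentration whose expected gap at the
  read timepoint is ≥ 6σ, and the generator refuses signal models where
  some sub-threshold concentration exceeds 1σ, keeping the truth
  unambiguous.

What passing these tests does **not** show: real plant genomes are not
i.i.d. — repeat families create correlated near-miss landscapes; real
annotations overlap and nest in ways the toy GFF3 does not; real assay
kinetics can be non-monotone in concentration at the high end (substrate
inhibition), which the Hill model deliberately omits; and adulterant
genomes diverge by indels and rearrangements, not only substitutions. The
synthetic conditions validate the *logic* (containment rules, Hamming
semantics, verdicts, threshold selection), not field performance.

## Problem sizes

Default test and acceptance runs use genomes of 5 kb–1 Mb, 100–200 oracle
instances, and 200 assay simulations — sizes chosen so the full suite
completes in a few minutes on one CPU while still exercising every code
path at meaningful scale. The closed-form density check uses a 1-Mb
genome, where the sampling noise on the density is ≈ 0.7%, comfortably
inside the 5% acceptance band.

## Known limitations

* The off-target scan is O(L) per query; screening thousands of candidates
  against multi-Gb genomes would need the seed-and-extend index noted
  above.
* Paper-mode PAM matching is strand-asymmetric by construction; users
  wanting biochemical symmetry must opt into strict mode.
* No bulge (indel) off-target modelling and no cleavage-efficiency scoring;
  the mismatch count is the only specificity statistic.
* GFF3 writing is out of scope except for the synthetic generator's own
  output.
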