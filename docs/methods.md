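# Methods

## The screening problem

Deep targeted resequencing of a lesion and its matched germline sample
yields thousands of raw allele observations per panel position. Separating
true somatic mutations from (a) inherited variants and (b) sequencing
artifacts concentrated in the terminal bases of reads is a rule-based
screening problem: every rule is simple, but the value of the pipeline is
in applying them in a fixed, auditable order with the evidence preserved.
`ampliqc` implements that cascade for single-end amplicon reads, together
with the simulator needed to test it without patient data.

## Candidate calling

The caller is deliberately permissive; stringency belongs to the filter.

* A pileup column exists for every reference position consumed by a read's
  M or D CIGAR operation. Deletions consume reference without contributing
  a base call: the spanned columns carry a `*` marker in their counts, and
  the deletion allele itself is recorded at its anchor (the last aligned
  base before the event), in the left-anchored VCF representation.
  Insertions likewise anchor at the preceding matched base.
* A candidate is emitted per (site, alt allele) with ≥ `min_alt_reads` (4)
  supporting reads and AF ≥ `min_af` (1%). These defaults sit below the
  filter's 2% regime so that borderline events reach the filter and are
  rejected there, visibly, rather than silently never called.
* Each supporting read contributes its `offset_frac`: the 0-based index of
  the variant base among the read's aligned (soft-clip-excluded) bases
  divided by the aligned length. Soft-clipped bases are excluded
  throughout because they are not aligned evidence. For indel alleles the
  anchor base's offset is used.
* Ties are broken lexicographically by alt allele so output order is
  deterministic.

## The QC cascade

Parameters (`FilterParams`) and their defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `end_frac` | 0.15 | terminal fraction of aligned read bases treated as unreliable |
| `max_alt_alleles` | 2 | maximum distinct variant alleles at a site |
| `min_depth` | 100 | raw coverage floor (reads) |
| `tier_low` | AF 2–5% → ≥ 10 reads | support floor in the low-AF band |
| `tier_high` | AF > 5% → ≥ 25 reads | support floor above it |

Conventions the defaults do not pin down, and the choices made:

* **Terminal window boundaries.** "Within the first 15%" is
  `offset_frac < 0.15`; the last 15% is `offset_frac ≥ 0.85`. Half-open on
  both sides, so for read lengths divisible by 20 exactly 30% of base
  positions are flagged.
* **Re-evaluated AF denominator.** `af_core = ao_core / (depth − removed)`,
  where `removed` counts only the discarded alt-supporting end reads;
  reference reads all stay. This slightly raises AF relative to dividing
  by raw depth; both numerator and denominator are written to the VCF
  (`AO_CORE`, `DP_CORE`) so any consumer can recompute either convention.
  `0/0` is defined as 0.
* **Tier edges.** AF_core exactly 5% belongs to the low tier (the 2–5% band
  is inclusive; "> 5%" is strict). AF_core below 2% fails as `low_af` —
  but only for candidates that still have interior support; an event whose
  support is entirely terminal is fully explained by `end_read` and gets
  that single label.
* **Allele counting.** `multiallelic` counts distinct non-reference alleles
  with ≥ 1 read in the raw tumor pileup at the site (mismatching base
  calls plus anchored indel alleles; `*` spans are not separate alleles —
  their deletion is counted at its anchor). Counting before subtraction
  and before end-read removal makes the rule a property of the site, not
  of the candidate under review. Note the ≥ 1 read convention makes deep
  sites multiallelic under any appreciable error rate; with the default
  terminal error model this is confined to terminal windows, whose
  candidates fail `end_read` anyway.
* **Depth floor.** Applied to raw depth, not end-corrected depth.
* **No short-circuiting.** All rules are evaluated and every failure is
  recorded, in the fixed order `end_read, multiallelic, min_depth, low_af,
  tier_support`, so a verdict is a complete diagnostic. Matched-normal
  removal prepends `in_normal`. PASS/FAIL is unaffected by recording
  everything.
* **Subtraction key.** Exact (contig, pos, ref, alt) on left-normalized
  alleles. Position-only matching would discard a real somatic allele
  arising at a germline-variant site.

### A known non-monotonicity

Relaxing `min_depth`, the tier support floors, or `max_alt_alleles` can
only grow the PASS set (verified by property test). The terminal-window
width is different: shrinking `end_frac` retains more terminal support,
which raises `af_core`, and a candidate crossing the 5% boundary moves from
the 10-read to the 25-read requirement — a PASS can become a FAIL. This is
intrinsic to any AF-tiered support rule and independent of the denominator
convention; the deterministic counterexample is kept as a unit test.
Parameter sweeps over `end_frac` should therefore not assume nestedness of
their PASS sets.

## The simulator

What it emulates: amplicon sequencing of a small panel. Each read spans its
amplicon interval exactly, so a variant's offset within every read equals
its offset within the amplicon — real panel geometry, and the reason
variants near amplicon boundaries produce end-read artifacts. Germline
variants are written into reads of both samples, somatic variants into
tumor reads only, each by an independent Bernoulli(AF) draw per overlapping
read. Substitution errors are drawn per base at `e_interior` (default
0.001) inside the read and `e_end` (default 0.01) within the terminal
`end_frac` (0.15); an erroneous base is replaced by a uniformly chosen
different base. The defaults are tool parameters chosen as plausible for
semiconductor-type platforms, not measured values.

What it does not emulate: base qualities, indel sequencing errors,
homopolymer/flow-space error structure, strand effects, paired ends, GC or
coverage bias, contamination. A green end-to-end test therefore establishes
that the cascade implements its rules correctly on reads with the stated
variant and error structure — not that the thresholds are optimal on any
real platform's error profile.

Reproducibility: one seeded NumPy generator; draw order is tumor then
normal, amplicons in list order, reads in index order, and within a read
the planted-variant Bernoullis (in position order) followed by the per-base
error draws 5'→3'. Identical seeds give byte-identical SAM output.

A `simulate_shotgun` mode (uniform random read starts) exists for property
tests that need variable read offsets, and `plant_end_artifact` builds the
pure artifact case: a variant in an amplicon's terminal 15% whose
supporting reads consequently all carry it in their terminal bases.

### The bundled scenario

Five 200-bp amplicons with 50-bp overlaps at 1000× over a 900-bp synthetic
open reading frame (random stop-free codons behind an ATG, so the panel
doubles as a valid CDS for annotation). Planted: germline heterozygous
SNVs at positions 101 and 251; clean somatic SNVs at 401/551/701 with AF
3%, 8%, 20%; a somatic 1-bp deletion at 271 (AF 15%); an end-artifact SNV
at position 11 (AF 8%, read offset 0.05 in its only covering amplicon).
The error model is zeroed in this scenario so that every verdict is
attributable to exactly one planted cause — with terminal errors on, stray
low-count alleles make deep terminal sites multiallelic under the ≥ 1 read
counting rule and blur that one-to-one mapping. The elevated-terminal
error model is exercised in the simulator's own tests instead.

## Annotation

Codon-level effects against a single transcript model (gene, contig,
strand, ordered CDS intervals; total length must be a multiple of 3).
SNVs: translate the affected codon before and after (standard genetic code
only). Indels: frameshift when the net length change is not a multiple of
3, labeled `Frameshift at <ref_aa><codon>` using the first codon whose
composition changes; in-frame indels are labeled analogously. No
downstream-consequence prediction (no `fs*N` tails), no HGVS compliance,
one transcript per gene. Minus-strand models are handled by reverse
complement; a variant annotated on a minus-strand model equals the
annotation of its reverse complement on the equivalent plus-strand model
(property-tested). Variants outside the CDS or spanning a CDS boundary
return a non-coding marker rather than a guess.

## Statistics

* **E→K fraction**: per gene, 100 × (missense with ref Glu and alt Lys) /
  (all missense). Labels that fail to parse as `<AA><pos><AA>` stay in the
  denominator and are logged — dropping them would inflate the fraction.
* **Fisher's exact test**: two-sided by the sum-of-smaller-probabilities
  convention, conditioning on both margins. Hypergeometric probabilities
  are computed in log space from log-gamma (exact to double precision for
  N ≲ 10⁴); the inclusion comparison `P(k) ≤ P(observed)` uses a 1e−7
  relative tolerance so floating-point representations of exact ties are
  not dropped. Mid-p is not used. Verified against exact rational
  enumeration for every table with N ≤ 30.
* **ΔΔCt**: each group's ΔCt is the mean of (target Ct − reference Ct);
  fold change is 2^−(ΔCt_test − ΔCt_control). Within-group pairing of
  target and reference wells is assumed.

## Limitations

Single-end reads with M/I/D(/S) CIGARs only; SNVs and simple left-anchored
indels (no MNVs, no complex substitutions); one matched normal (no panel of
normals, no contamination model); no base-quality or strand-bias
filtering; annotation against one transcript. The candidate caller is a
transparent stand-in for production somatic callers — it guarantees the
filter cascade the fields it needs, not equivalence with any vendor
caller's internal heuristics.
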