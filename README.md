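# ampliqc

Somatic variant screening for matched tumor–normal deep amplicon sequencing,
with a built-in panel simulator — the setting is targeted (AmpliSeq-style)
resequencing of a small gene panel in paired lesion/germline samples, where
the goal is a short, trustworthy list of somatic mutations and the main
enemies are inherited variants masquerading as somatic and artifacts born in
the error-prone terminal bases of reads.

## What it does

Given aligned reads for a tumor sample and its matched normal, the pipeline

1. builds per-position pileups and calls **low-stringency candidates**
   (every allele with ≥ 4 supporting reads and AF ≥ 1%), keeping, for each
   supporting read, the offset of the variant base within the read;
2. **subtracts the matched normal**: any tumor candidate whose exact
   (contig, pos, ref, alt) allele is also called in the normal is removed as
   germline (`in_normal`);
3. applies the **read-end rule**: supporting reads that place the variant
   within the first or last 15% of their aligned bases are discarded and the
   allele frequency is re-evaluated on what remains,

   AF_core = AO_core / (DP − removed reads);

   a candidate with no interior support left is an end-read artifact
   (`end_read`);
4. applies site-level QC: at most 2 distinct variant alleles per site
   (`multiallelic`), at least 100 reads of coverage (`min_depth`);
5. applies **AF-tiered support**: AF_core in 2–5% needs ≥ 10 alt reads,
   AF_core > 5% needs ≥ 25 (`tier_support`); AF_core below 2% is outside
   the callable regime (`low_af`).

Every rule is evaluated for every candidate, so each verdict carries a
complete ordered trail of failures (empty trail = PASS), written to the VCF
FILTER column with the evidence in INFO (`DP`, `AO`, `AF`, `AO_CORE`,
`DP_CORE`, `AF_CORE`).

Passing variants are annotated at the codon level against a transcript
model (`E20K`-style labels for substitutions, `Frameshift at G488` for
frame-disrupting indels). Companion statistics cover the E→K share of a
gene's missense burden, two-sided Fisher's exact tests for rescue-experiment
2×2 tables, and ΔΔCt relative expression from qPCR cycle thresholds.

Because paired patient sequencing data cannot be bundled, the package
includes a first-class simulator: overlapping amplicons over a synthetic
reference, germline variants planted in both samples and somatic ones in
the tumor only (independent Bernoulli(AF) per read), and a substitution
error model elevated in the terminal 15% of each read. Reads span their
amplicon exactly, so a variant near an amplicon boundary lands near the
read ends — the geometry that makes end artifacts constructible and
testable.

## Worked example

The bundled demo simulates a five-amplicon panel at 1000× with two germline
SNVs (AF 50%), three clean somatic SNVs (AF 3/8/20%), a somatic 1-bp
deletion (AF 15%) and one end-artifact SNV (AF 8%):

```bash
ampliqc demo --out-dir demo_out --seed 7
```

prints `{"pass_count": 4, "out_dir": "demo_out"}` and writes
`demo_out/somatic.vcf`:

```text
#CHROM      POS  REF  ALT  FILTER     INFO
panel_gene  11   G    T    end_read   DP=1000;AO=80;AF=0.08;AO_CORE=0;DP_CORE=920;AF_CORE=0
panel_gene  101  T    A    in_normal  DP=1000;AO=503;AF=0.503;...
panel_gene  251  T    A    in_normal  DP=1000;AO=510;AF=0.51;...
panel_gene  271  GC   G    PASS       DP=1000;AO=131;AF=0.131;AF_CORE=0.131
panel_gene  401  A    C    PASS       DP=1000;AO=32;AF=0.032;AF_CORE=0.032
panel_gene  551  T    A    PASS       DP=1000;AO=92;AF=0.092;AF_CORE=0.092
panel_gene  701  T    A    PASS       DP=1000;AO=169;AF=0.169;AF_CORE=0.169
```

Reading it: the two AF ≈ 50% calls were also called in the normal sample —
germline, removed by subtraction. The AF 8% call at position 11 had all 80
supporting reads placing the variant at read offset 0.05, inside the
terminal window, so after end-read removal `AO_CORE=0`: an artifact. The
four PASS records are exactly the planted clean somatic variants; the AF
3.2% SNV passes the 2–5% tier with 32 ≥ 10 supports, the others clear the
25-read bar of the >5% tier. `demo_out/annotated.tsv` gives their protein
effects on the panel's reading frame:

```text
sample  gene    label              kind
tumor   PANEL1  Frameshift at A91  frameshift
tumor   PANEL1  N134T              missense
tumor   PANEL1  L184*              nonsense
tumor   PANEL1  V234D              missense
```

`demo_out/report.json` records the per-label filter counts and compares the
PASS set against the planted truth manifest.

The same stages are available piecewise (`ampliqc simulate / call / filter
/ annotate`), and the statistics as `ampliqc enrich` (per-gene E→K percent
of missense mutations from a MAF-like TSV), `ampliqc stats fisher --table
3,1,1,3` (prints `p_value 0.485714`) and `ampliqc stats ddct` (fold change
from paired Ct tables).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the bundled scenario end to end under the given seed — simulates
the panel pair, calls, subtracts, filters and annotates — and writes the
results JSON to `--out`.

## Layout

| module | contents |
| --- | --- |
| `ampliqc.io_formats` | FASTA/SAM/VCF/TSV readers and writers, domain records |
| `ampliqc.simulate` | amplicon pair simulator, error model, end-artifact generator |
| `ampliqc.pileup` | pileup construction, low-stringency candidate calling |
| `ampliqc.filters` | normal subtraction, read-end re-evaluation, QC cascade |
| `ampliqc.annotate` | transcript model, codon-level protein effects |
| `ampliqc.stats` | E→K enrichment, Fisher exact, ΔΔCt expression |
| `ampliqc.config` / `ampliqc.demo` / `ampliqc.cli` | YAML config, bundled scenario, CLI |

See `docs/methods.md` for the model, parameter and numerical-convention
details, including what the simulator does and does not emulate.
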