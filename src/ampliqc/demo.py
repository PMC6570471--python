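"""Bundled end-to-end demonstration scenario.

One panel of five overlapping 200-bp amplicons at 1000x over a 900-bp
synthetic coding reference, with planted truth:

* two germline heterozygous SNVs (present in both samples at AF 0.5);
* three clean somatic SNVs at AF 3%, 8% and 20%, each in the interior of
  its amplicon;
* one somatic 1-bp deletion at AF 15%;
* one somatic end-artifact SNV at AF 8%, placed so every supporting read
  carries it within the terminal 15% of its bases;
* zero sequencing error, so the artifact variant is the only terminal-base
  signal and every verdict is exactly attributable to a planted truth.

(The elevated terminal error model is exercised by the simulator's own
tests; leaving it on here would sprinkle stray low-count alleles over
terminal windows and turn deep sites there multiallelic by the >= 1 read
allele-counting rule, muddying the one-cause-per-verdict property this
scenario exists to demonstrate.)

Running the full pipeline on this world must recover exactly the four clean
somatic variants: the germline pair is removed by matched-normal
subtraction and the artifact by the read-end rule.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

from . import __version__
from .annotate import NonCodingMarker, annotate_variant
from .config import PipelineConfig, parse_config
from .filters import IN_NORMAL, FilterParams, run_somatic_pipeline
from .io_formats import write_fasta, write_sam
from .simulate import Amplicon, PlantedVariant, simulate_pair, write_truth_tsv

DEMO_CONFIG: dict = {
    "seed": 7,
    "reference": {"kind": "coding", "name": "panel_gene", "length": 900},
    "amplicons": [
        {"start": 0, "end": 200, "depth": 1000},
        {"start": 150, "end": 350, "depth": 1000},
        {"start": 300, "end": 500, "depth": 1000},
        {"start": 450, "end": 650, "depth": 1000},
        {"start": 600, "end": 800, "depth": 1000},
    ],
    "planted": [
        # germline heterozygous pair, removed at subtraction
        {"pos": 101, "kind": "snv", "af": 0.5, "scope": "germline"},
        {"pos": 251, "kind": "snv", "af": 0.5, "scope": "germline"},
        # clean somatic SNVs in amplicon interiors
        {"pos": 401, "kind": "snv", "af": 0.03, "scope": "somatic"},
        {"pos": 551, "kind": "snv", "af": 0.08, "scope": "somatic"},
        {"pos": 701, "kind": "snv", "af": 0.20, "scope": "somatic"},
        # somatic 1-bp deletion (anchored at pos 271)
        {"pos": 271, "kind": "del", "length": 1, "af": 0.15, "scope": "somatic"},
        # end artifact: offset 10/200 = 0.05 in its only covering amplicon
        {"pos": 11, "kind": "snv", "af": 0.08, "scope": "somatic"},
    ],
    "error_model": {"e_interior": 0.0, "e_end": 0.0, "end_frac": 0.15},
    "caller": {"min_alt_reads": 4, "min_af": 0.01},
    "filters": {},
    "transcript_model": {"gene": "PANEL1", "strand": "+", "cds": [[0, 900]]},
}


def demo_config() -> PipelineConfig:
    return parse_config(json.loads(json.dumps(DEMO_CONFIG)))


def expected_pass_keys(
    planted: list[PlantedVariant],
    amplicons: list[Amplicon],
    params: FilterParams,
) -> set[tuple[str, int, str, str]]:
    """Planted somatic variants the cascade is expected to keep.

    Uses expectations, not draws: a somatic variant passes when it has
    interior support (some covering amplicon places it outside the terminal
    window), its AF reaches the callable regime, and its expected alt-read
    count meets the depth floor and the AF tier minimum.
    """
    expected: set[tuple[str, int, str, str]] = set()
    for var in planted:
        if var.zygosity_scope != "somatic":
            continue
        covering = [
            a
            for a in amplicons
            if a.ref_name == var.ref_name
            and a.start <= var.ref_span[0]
            and var.ref_span[1] <= a.end
        ]
        depth = sum(a.depth for a in covering)
        interior_depth = sum(
            a.depth
            for a in covering
            if params.end_frac <= (var.pos0 - a.start) / len(a) < 1.0 - params.end_frac
        )
        exp_ao_core = var.af * interior_depth
        if exp_ao_core == 0 or depth < params.min_depth or var.af < params.tier_low.af_lo:
            continue
        tier = (
            params.tier_low
            if var.af <= params.tier_low.af_hi
            else params.tier_high
        )
        if exp_ao_core >= tier.min_support:
            expected.add((var.ref_name, var.pos0 + 1, var.ref_allele, var.alt_allele))
    return expected


def run_demo(config: PipelineConfig, seed: int, out_dir: str | os.PathLike) -> dict:
    """Simulate, call, filter and annotate; write artifacts and a JSON report.

    Identical (config, seed) pairs produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reference = config.build_reference(seed)
    amplicons = config.build_amplicons(reference)
    planted = config.build_planted(reference)
    model = config.build_transcript(reference)

    tumor, normal, manifest = simulate_pair(
        [reference], amplicons, planted, config.error_model, seed
    )
    write_fasta([reference], out / "reference.fasta")
    write_sam(tumor, [reference], out / "tumor.sam", sample="tumor")
    write_sam(normal, [reference], out / "normal.sam", sample="normal")
    write_truth_tsv(manifest, out / "truth.tsv")

    verdicts = run_somatic_pipeline(
        tumor,
        normal,
        [reference],
        params=config.filters,
        min_alt_reads=config.caller.min_alt_reads,
        min_af=config.caller.min_af,
        vcf_out=out / "somatic.vcf",
    )

    label_counts: dict[str, int] = {}
    for v in verdicts:
        for label in v.trail:
            label_counts[label] = label_counts.get(label, 0) + 1
    passing = [v for v in verdicts if v.passed]
    pass_keys = {v.candidate.key for v in passing}

    annotations = []
    if model is not None:
        for v in passing:
            effect = annotate_variant(v.to_record(), model, reference)
            annotations.append(
                {
                    "sample": "tumor",
                    "gene": model.gene,
                    "contig": v.candidate.ref_name,
                    "pos": v.candidate.pos,
                    "ref": v.candidate.ref_allele,
                    "alt": v.candidate.alt_allele,
                    "label": "non_coding" if isinstance(effect, NonCodingMarker) else effect.label,
                    "kind": effect.reason if isinstance(effect, NonCodingMarker) else effect.kind,
                }
            )
        with open(out / "annotated.tsv", "w") as fh:
            fh.write("sample\tgene\tlabel\tkind\n")
            for ann in annotations:
                fh.write(f"{ann['sample']}\t{ann['gene']}\t{ann['label']}\t{ann['kind']}\n")

    expected = expected_pass_keys(planted, amplicons, config.filters)
    report = {
        "version": __version__,
        "seed": seed,
        "n_reads_tumor": len(tumor),
        "n_reads_normal": len(normal),
        "n_verdicts": len(verdicts),
        "n_removed_in_normal": sum(1 for v in verdicts if IN_NORMAL in v.trail),
        "filter_label_counts": dict(sorted(label_counts.items())),
        "pass_count": len(passing),
        "pass_variants": sorted([list(k) for k in pass_keys]),
        "annotations": annotations,
        "truth": {
            "expected_pass": sorted([list(k) for k in expected]),
            "recovered": sorted([list(k) for k in expected & pass_keys]),
            "missed": sorted([list(k) for k in expected - pass_keys]),
            "unexpected_pass": sorted([list(k) for k in pass_keys - expected]),
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
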