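"""Readers and writers for the formats the pipeline touches.

FASTA, the single-end SAM text dialect emitted by the simulator, VCF 4.2
and header-bearing TSV tables.  Internal coordinates are 0-based half-open
everywhere; the 1-based conventions of SAM and VCF exist only at the file
boundary, where the conversion is applied symmetrically on read and write.

Standard-format heavy lifting is delegated to Biopython (FASTA) and pysam
(SAM, VCF); this module owns validation and the mapping onto the pipeline's
domain types.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

#: CIGAR operations the pipeline models.  Soft clips (S) are accepted on
#: input but trimmed away: clipped bases are not aligned evidence and do not
#: count toward "the bases of the read" for positional filtering.
SUPPORTED_CIGAR_OPS = frozenset("MIDS")

_PYSAM_OP = {0: "M", 1: "I", 2: "D", 4: "S"}
_OP_TO_PYSAM = {"M": 0, "I": 1, "D": 2, "S": 4}


class FormatError(ValueError):
    """A file violates the dialect this pipeline reads or writes."""


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference contig: identifier plus an upper-case DNA sequence."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("reference sequence with empty name")
        if not self.seq:
            raise FormatError(f"reference sequence {self.name!r} is empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"reference {self.name!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignedRead:
    """A single-end aligned read after soft-clip trimming.

    ``cigar`` holds (length, op) pairs over {M, I, D}; ``seq`` is the aligned
    (clip-trimmed) query sequence, so sum of M+I lengths equals ``len(seq)``.
    ``aligned_length`` is the denominator of the read-end positional rule.
    """

    read_id: str
    ref_name: str
    ref_start: int  # 0-based leftmost aligned reference position
    cigar: list[tuple[int, str]]
    seq: str
    sample: str = "unknown"

    def __post_init__(self) -> None:
        if not self.cigar:
            raise FormatError(f"read {self.read_id!r}: empty CIGAR")
        if self.ref_start < 0:
            raise FormatError(f"read {self.read_id!r}: negative ref_start")
        for length, op in self.cigar:
            if length < 1 or op not in "MID":
                raise FormatError(
                    f"read {self.read_id!r}: bad CIGAR element ({length}, {op!r})"
                )
        query_len = sum(n for n, op in self.cigar if op in "MI")
        if query_len != len(self.seq):
            raise FormatError(
                f"read {self.read_id!r}: CIGAR consumes {query_len} query bases "
                f"but sequence has {len(self.seq)}"
            )

    @property
    def aligned_length(self) -> int:
        """Number of aligned query bases (M+I), soft clips excluded."""
        return len(self.seq)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the reference span (M+D)."""
        return self.ref_start + sum(n for n, op in self.cigar if op in "MD")

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar)


@dataclass
class VariantRecord:
    """A site-level allele call (VCF conventions: 1-based, left-anchored indels)."""

    ref_name: str
    pos: int  # 1-based reference position of the (anchor) base
    ref_allele: str
    alt_allele: str
    depth: int
    alt_reads: int
    filter_trail: list[str] = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= self.depth):
            raise ValueError(
                f"{self.key}: alt_reads {self.alt_reads} outside [0, depth={self.depth}]"
            )
        if len(self.ref_allele) > 1 or len(self.alt_allele) > 1:
            if self.ref_allele[0] != self.alt_allele[0]:
                raise ValueError(f"{self.key}: indel alleles must share their anchor base")

    @property
    def af(self) -> float:
        """Alt-allele frequency alt_reads / depth (0.0 at zero depth)."""
        return self.alt_reads / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.ref_name, self.pos, self.ref_allele, self.alt_allele)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[ReferenceSequence]:
    """Read a FASTA file into :class:`ReferenceSequence` records.

    Sequences are upper-cased.  Empty sequences and duplicate names raise
    :class:`FormatError` naming the offending record.
    """
    records: list[ReferenceSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA record {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: FASTA record {rec.id!r} has an empty sequence")
        seen.add(rec.id)
        records.append(ReferenceSequence(name=rec.id, seq=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ReferenceSequence], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM


def read_sam(path: str | os.PathLike, sample: str | None = None) -> list[AlignedRead]:
    """Read a SAM text file into :class:`AlignedRead` records.

    Unmapped reads (FLAG 0x4) are skipped.  Soft-clipped bases are trimmed
    from the sequence; CIGAR ops outside {M, I, D, S} are rejected.  POS is
    converted from SAM's 1-based convention to internal 0-based.  The sample
    tag is taken from the read group SM field when present, else from the
    ``sample`` argument.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as fh:
        rg_sample = _header_sample(fh.header)
        tag = sample if sample is not None else (rg_sample or "unknown")
        for aln in fh:
            if aln.is_unmapped:
                continue
            cigar: list[tuple[int, str]] = []
            for op_code, length in aln.cigartuples or []:
                op = _PYSAM_OP.get(op_code)
                if op is None:
                    raise FormatError(
                        f"read {aln.query_name!r}: unsupported CIGAR op code {op_code} "
                        f"(only M/I/D/S are modeled)"
                    )
                if op != "S":
                    cigar.append((length, op))
            seq = aln.query_alignment_sequence  # soft clips already removed
            if seq is None:
                raise FormatError(f"read {aln.query_name!r}: missing sequence")
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    ref_name=aln.reference_name,
                    ref_start=aln.reference_start,
                    cigar=cigar,
                    seq=seq.upper(),
                    sample=tag,
                )
            )
    return reads


def _header_sample(header: pysam.AlignmentHeader) -> str | None:
    for rg in header.to_dict().get("RG", []):
        if "SM" in rg:
            return rg["SM"]
    return None


def write_sam(
    reads: list[AlignedRead],
    reference: list[ReferenceSequence],
    path: str | os.PathLike,
    sample: str | None = None,
) -> None:
    """Write reads as SAM text with @SQ lines from the reference."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": len(ref.seq)} for ref in reference],
    }
    if sample is not None:
        header["RG"] = [{"ID": sample, "SM": sample}]
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as fh:
        for read in reads:
            aln = pysam.AlignedSegment(fh.header)
            aln.query_name = read.read_id
            aln.flag = 0
            aln.reference_id = fh.header.get_tid(read.ref_name)
            aln.reference_start = read.ref_start
            aln.mapping_quality = 60
            aln.cigartuples = [(_OP_TO_PYSAM[op], n) for n, op in read.cigar]
            aln.query_sequence = read.seq
            if sample is not None:
                aln.set_tag("RG", sample)
            fh.write(aln)


# ---------------------------------------------------------------------------
# VCF

#: FILTER labels the somatic cascade can assign, with their meanings.
FILTER_DESCRIPTIONS = {
    "in_normal": "Variant also called in the matched normal sample",
    "end_read": "All alt support lies within the terminal 15% of read bases",
    "multiallelic": "Site carries more than 2 distinct variant alleles",
    "min_depth": "Covered by fewer than the minimum required reads",
    "low_af": "Re-evaluated allele frequency below the callable regime",
    "tier_support": "Alt read support below the AF-tier minimum",
}

_INFO_FIELDS = [
    ("DP", 1, "Integer", "Total read depth at the site"),
    ("AO", 1, "Integer", "Reads supporting the alt allele"),
    ("AF", "A", "Float", "Alt allele frequency AO/DP"),
    ("AO_CORE", 1, "Integer", "Alt support after removing terminal-read evidence"),
    ("DP_CORE", 1, "Integer", "Depth after removing flagged alt-supporting end reads"),
    ("AF_CORE", "A", "Float", "Re-evaluated allele frequency AO_CORE/DP_CORE"),
]


def _vcf_header(contigs: list[tuple[str, int]] | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs or []:
        header.contigs.add(name, length=length)
    for key, number, vtype, desc in _INFO_FIELDS:
        header.info.add(key, number, vtype, desc)
    for label, desc in FILTER_DESCRIPTIONS.items():
        header.filters.add(label, None, None, desc)
    return header


def write_vcf(
    records: list[VariantRecord],
    path: str | os.PathLike,
    contigs: list[tuple[str, int]] | None = None,
) -> None:
    """Write records as VCF 4.2.

    FILTER is PASS for an empty ``filter_trail``, else the semicolon-joined
    labels.  INFO carries DP/AO/AF and, when present in ``record.info``, the
    end-corrected AO_CORE/DP_CORE/AF_CORE.  Records must be position-sorted.
    """
    keys = [(r.ref_name, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("write_vcf requires records sorted by (ref_name, pos)")
    if contigs is None:
        contigs = []
        for rec in records:
            if not contigs or contigs[-1][0] != rec.ref_name:
                contigs.append((rec.ref_name, 2**29))
    header = _vcf_header(contigs)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as fh:
        for rec in records:
            out = fh.new_record(
                contig=rec.ref_name,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref_allele),
                alleles=(rec.ref_allele, rec.alt_allele),
            )
            out.info["DP"] = rec.depth
            out.info["AO"] = rec.alt_reads
            out.info["AF"] = rec.af
            for key in ("AO_CORE", "DP_CORE"):
                if key in rec.info:
                    out.info[key] = int(rec.info[key])
            if "AO_CORE" in rec.info and "DP_CORE" in rec.info:
                dp_core = int(rec.info["DP_CORE"])
                out.info["AF_CORE"] = (
                    int(rec.info["AO_CORE"]) / dp_core if dp_core else 0.0
                )
            if rec.filter_trail:
                for label in rec.filter_trail:
                    out.filter.add(label)
            else:
                out.filter.add("PASS")
            fh.write(out)


def read_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    """Read a VCF written by :func:`write_vcf` back into records.

    AF and AF_CORE are recomputed from the integer INFO fields rather than
    trusting the single-precision floats VCF stores, so a write/read
    round-trip reproduces every modeled field exactly.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(path)) as fh:
        for rec in fh:
            trail = [f for f in rec.filter.keys() if f != "PASS"]
            info: dict = {}
            for key in ("AO_CORE", "DP_CORE"):
                if key in rec.info:
                    info[key] = int(rec.info[key])
            records.append(
                VariantRecord(
                    ref_name=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    depth=int(rec.info["DP"]),
                    alt_reads=int(rec.info["AO"]),
                    filter_trail=trail,
                    info=info,
                )
            )
    return records
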