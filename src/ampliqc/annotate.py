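"""Codon-level protein-effect annotation against a transcript model.

Produces the compact clinical-report nomenclature for coding changes:
``E20K`` for a Glu->Lys substitution at codon 20, ``Frameshift at G488``
for a frame-disrupting indel whose first affected codon is a Gly at 488.
Translation uses the standard genetic code (Biopython's table 1); there is
no downstream-consequence prediction, no HGVS c./p. compliance and a single
transcript per gene.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .io_formats import ReferenceSequence, VariantRecord


class ModelConsistencyError(ValueError):
    """Transcript model disagrees with the reference or the variant."""


@dataclass(frozen=True)
class NonCodingMarker:
    """Marker for variants the transcript model cannot interpret in protein."""

    reason: str


@dataclass(frozen=True)
class TranscriptModel:
    """CDS geometry of one transcript.

    ``cds_intervals`` are 0-based half-open genomic intervals, non-
    overlapping, listed 5'->3' in transcript orientation (descending genomic
    coordinates on the minus strand).  Total CDS length must be a multiple
    of three.
    """

    gene: str
    ref_name: str
    strand: str  # "+" | "-"
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelConsistencyError(f"strand must be + or -, got {self.strand!r}")
        length = 0
        for start, end in self.cds_intervals:
            if end <= start:
                raise ModelConsistencyError(f"empty CDS interval ({start}, {end})")
            length += end - start
        if length % 3 != 0:
            raise ModelConsistencyError(f"CDS length {length} not divisible by 3")
        genomic = sorted(self.cds_intervals)
        for (_, a_end), (b_start, _) in zip(genomic, genomic[1:]):
            if b_start < a_end:
                raise ModelConsistencyError("CDS intervals overlap")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != self.cds_intervals:
            raise ModelConsistencyError(
                "CDS intervals must be listed 5'->3' in transcript orientation"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a 0-based genomic position to its 0-based CDS offset, or None."""
        offset = 0
        for start, end in self.cds_intervals:
            if start <= pos0 < end:
                if self.strand == "+":
                    return offset + (pos0 - start)
                return offset + (end - 1 - pos0)
            offset += end - start
        return None

    def cds_sequence(self, reference: ReferenceSequence) -> str:
        if reference.name != self.ref_name:
            raise ModelConsistencyError(
                f"model is on {self.ref_name!r}, reference is {reference.name!r}"
            )
        parts = []
        for start, end in self.cds_intervals:
            if end > len(reference.seq):
                raise ModelConsistencyError("CDS interval exceeds the reference")
            chunk = reference.seq[start:end]
            parts.append(chunk if self.strand == "+" else str(Seq(chunk).reverse_complement()))
        return "".join(parts)


@dataclass(frozen=True)
class ProteinEffect:
    """A coding consequence in compact notation."""

    gene: str
    kind: str  # missense | synonymous | nonsense | frameshift | inframe_indel
    aa_pos: int  # 1-based codon index of the (first) affected codon
    ref_aa: str
    alt_aa: str  # empty for frameshift / inframe_indel
    label: str

    def __post_init__(self) -> None:
        if self.aa_pos < 1:
            raise ValueError("aa_pos must be >= 1")


_SUBST_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*])$")
_FRAMESHIFT_RE = re.compile(r"^Frameshift at ([A-Z])(\d+)$")
_INFRAME_RE = re.compile(r"^Inframe indel at ([A-Z])(\d+)$")


def make_label(kind: str, aa_pos: int, ref_aa: str, alt_aa: str) -> str:
    if kind == "frameshift":
        return f"Frameshift at {ref_aa}{aa_pos}"
    if kind == "inframe_indel":
        return f"Inframe indel at {ref_aa}{aa_pos}"
    return f"{ref_aa}{aa_pos}{alt_aa}"


def parse_label(label: str) -> tuple[str, int, str, str]:
    """Invert :func:`make_label`: label -> (kind, aa_pos, ref_aa, alt_aa)."""
    m = _FRAMESHIFT_RE.match(label)
    if m:
        return ("frameshift", int(m.group(2)), m.group(1), "")
    m = _INFRAME_RE.match(label)
    if m:
        return ("inframe_indel", int(m.group(2)), m.group(1), "")
    m = _SUBST_RE.match(label)
    if m:
        ref_aa, pos, alt_aa = m.group(1), int(m.group(2)), m.group(3)
        if alt_aa == "*":
            kind = "nonsense"
        elif ref_aa == alt_aa:
            kind = "synonymous"
        else:
            kind = "missense"
        return (kind, pos, ref_aa, alt_aa)
    raise ValueError(f"unparseable protein-change label {label!r}")


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_variant(
    variant: VariantRecord,
    model: TranscriptModel,
    reference: list[ReferenceSequence] | ReferenceSequence,
) -> ProteinEffect | NonCodingMarker:
    """Annotate one left-normalized variant with its protein-level effect.

    SNVs inside the CDS are classified by translating the affected codon
    before and after; indels are frameshift when the inserted/deleted length
    is not a multiple of three, labeled by the reference amino acid of the
    first codon whose composition changes.  Variants outside the CDS, on a
    different contig, or spanning a CDS boundary return a
    :class:`NonCodingMarker`.
    """
    if isinstance(reference, list):
        by_name = {r.name: r for r in reference}
        if model.ref_name not in by_name:
            raise ModelConsistencyError(f"reference lacks contig {model.ref_name!r}")
        ref = by_name[model.ref_name]
    else:
        ref = reference
    if variant.ref_name != model.ref_name:
        return NonCodingMarker(reason=f"variant on {variant.ref_name}, model on {model.ref_name}")

    pos0 = variant.pos - 1
    if ref.seq[pos0 : pos0 + len(variant.ref_allele)] != variant.ref_allele:
        raise ModelConsistencyError(
            f"variant {variant.key}: ref allele disagrees with the reference sequence"
        )
    cds = model.cds_sequence(ref)

    if len(variant.ref_allele) == 1 and len(variant.alt_allele) == 1:
        return _annotate_snv(variant, model, cds, pos0)
    return _annotate_indel(variant, model, cds, pos0)


def _annotate_snv(
    variant: VariantRecord, model: TranscriptModel, cds: str, pos0: int
) -> ProteinEffect | NonCodingMarker:
    cds_idx = model.genomic_to_cds(pos0)
    if cds_idx is None:
        return NonCodingMarker(reason="SNV outside the CDS")
    alt = variant.alt_allele
    if model.strand == "-":
        alt = str(Seq(alt).reverse_complement())
    codon_idx = cds_idx // 3
    within = cds_idx % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    mutated = codon[:within] + alt + codon[within + 1 :]
    ref_aa = _translate_codon(codon)
    alt_aa = _translate_codon(mutated)
    if alt_aa == ref_aa:
        kind = "synonymous"
    elif alt_aa == "*":
        kind = "nonsense"
    else:
        kind = "missense"
    return ProteinEffect(
        gene=model.gene,
        kind=kind,
        aa_pos=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        label=make_label(kind, codon_idx + 1, ref_aa, alt_aa),
    )


def _annotate_indel(
    variant: VariantRecord, model: TranscriptModel, cds: str, pos0: int
) -> ProteinEffect | NonCodingMarker:
    # left-anchored: changed reference bases start one past the shared anchor
    ref_len = len(variant.ref_allele)
    alt_len = len(variant.alt_allele)
    if ref_len > 1 and alt_len > 1:
        return NonCodingMarker(reason="complex substitution not modeled")
    if ref_len > 1:  # deletion
        changed = range(pos0 + 1, pos0 + ref_len)
        indel_len = ref_len - 1
    else:  # insertion: the change lands between anchor and the next base
        changed = range(pos0 + 1, pos0 + 2)
        indel_len = alt_len - 1
    cds_indices = [model.genomic_to_cds(p) for p in changed]
    if any(i is None for i in cds_indices):
        if all(i is None for i in cds_indices):
            return NonCodingMarker(reason="indel outside the CDS")
        return NonCodingMarker(reason="indel spans a CDS boundary")
    first_cds = min(cds_indices)
    codon_idx = first_cds // 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    ref_aa = _translate_codon(codon)
    kind = "frameshift" if indel_len % 3 != 0 else "inframe_indel"
    return ProteinEffect(
        gene=model.gene,
        kind=kind,
        aa_pos=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa="",
        label=make_label(kind, codon_idx + 1, ref_aa, ""),
    )


def is_e_to_k(effect: ProteinEffect) -> bool:
    """True iff the effect is a Glu->Lys (E->K) missense substitution."""
    if effect.kind != "missense":
        raise ValueError(f"is_e_to_k requires a missense effect, got {effect.kind!r}")
    return effect.ref_aa == "E" and effect.alt_aa == "K"


# ---------------------------------------------------------------------------
# Model (de)serialization


def read_transcript_model(path: str | os.PathLike) -> TranscriptModel:
    """Load a transcript model from JSON (gene, ref_name, strand, cds_intervals)."""
    with open(path) as fh:
        data = json.load(fh)
    return TranscriptModel(
        gene=data["gene"],
        ref_name=data["ref_name"],
        strand=data["strand"],
        cds_intervals=tuple(tuple(iv) for iv in data["cds_intervals"]),
    )


def write_transcript_model(model: TranscriptModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "gene": model.gene,
                "ref_name": model.ref_name,
                "strand": model.strand,
                "cds_intervals": [list(iv) for iv in model.cds_intervals],
            },
            fh,
            indent=2,
        )
        fh.write("\n")
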