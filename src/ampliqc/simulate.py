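"""Matched tumor/normal amplicon sequencing simulator.

Emulates targeted panel (AmpliSeq-style) sequencing: every read spans its
amplicon interval exactly, so a variant's offset within a read is fixed by
its offset within the amplicon — which is precisely how real panel variants
end up near read ends when they sit near an amplicon boundary.  Germline
variants are planted in both samples, somatic variants in the tumor only,
each written into a read by an independent Bernoulli(af) draw.  Sequencing
errors are base substitutions drawn at an elevated rate within the terminal
fraction of each read (default 15%), the artifact class the positional
filter downstream is designed to remove.

Reproducibility contract: one seeded numpy Generator; draw order is tumor
sample then normal, amplicons in list order, reads in index order, and per
read first the variant Bernoullis (planted list order) then the error draws
(5'->3').  Identical seed implies byte-identical SAM output.

A uniform-random-start "shotgun" mode (``read_length`` shorter than the
amplicon) is available for property tests that need variable offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AlignedRead, ReferenceSequence

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    """Simulation inputs are inconsistent (e.g. variant outside every amplicon)."""


@dataclass(frozen=True)
class Amplicon:
    """A panel interval: reads generated from it span [start, end) exactly."""

    ref_name: str
    start: int
    end: int
    depth: int

    def __post_init__(self) -> None:
        if self.end - self.start < 50:
            raise ConfigurationError(
                f"amplicon {self.ref_name}:{self.start}-{self.end} shorter than 50 bp"
            )
        if self.depth < 1:
            raise ConfigurationError("amplicon depth must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PlantedVariant:
    """A ground-truth variant: germline (both samples) or somatic (tumor only).

    Alleles use the left-anchored VCF representation: for indels ref and alt
    share their first base; ``pos0`` is the 0-based position of that anchor.
    """

    ref_name: str
    pos0: int
    ref_allele: str
    alt_allele: str
    af: float
    zygosity_scope: str  # "germline" | "somatic"

    def __post_init__(self) -> None:
        if not 0.0 < self.af <= 1.0:
            raise ConfigurationError(f"planted af {self.af} outside (0, 1]")
        if self.zygosity_scope not in ("germline", "somatic"):
            raise ConfigurationError(f"unknown scope {self.zygosity_scope!r}")
        if self.ref_allele == self.alt_allele:
            raise ConfigurationError("ref and alt alleles are identical")
        if (len(self.ref_allele) > 1 or len(self.alt_allele) > 1) and (
            self.ref_allele[0] != self.alt_allele[0]
        ):
            raise ConfigurationError("indel alleles must share their anchor base")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open reference interval the variant rewrites."""
        return (self.pos0, self.pos0 + len(self.ref_allele))


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution error rates, elevated in terminal read bases.

    ``end_frac`` is the fraction of each read's bases, at either end, subject
    to ``e_end`` instead of ``e_interior``; default 0.15 mirrors the terminal
    window the positional filter tests.
    """

    e_interior: float = 0.001
    e_end: float = 0.01
    end_frac: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_interior <= self.e_end < 0.5):
            raise ConfigurationError("need 0 <= e_interior <= e_end < 0.5")
        if not (0.0 < self.end_frac < 0.5):
            raise ConfigurationError("need 0 < end_frac < 0.5")


def _check_coverage(amplicons: list[Amplicon], planted: list[PlantedVariant]) -> None:
    for var in planted:
        span = var.ref_span
        if not any(
            amp.ref_name == var.ref_name and amp.start <= span[0] and span[1] <= amp.end
            for amp in amplicons
        ):
            raise ConfigurationError(
                f"planted variant {var.ref_name}:{var.pos0} "
                f"{var.ref_allele}>{var.alt_allele} falls outside every amplicon"
            )


def _mutate_read(
    ref_slice: str, amp_start: int, variants: list[PlantedVariant]
) -> tuple[str, list[tuple[int, str]]]:
    """Apply variants (sorted by pos0) to an amplicon-spanning read.

    Returns the read sequence and its CIGAR.  Variants act on reference
    coordinates; insertions add bases after their anchor, deletions skip
    reference bases (D ops).  Substitution errors are applied later, on the
    final sequence.
    """
    parts: list[str] = []
    cigar: list[tuple[int, str]] = []
    cursor = amp_start

    def emit(n: int, op: str) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][1] == op:
            cigar[-1] = (cigar[-1][0] + n, op)
        else:
            cigar.append((n, op))

    amp_end = amp_start + len(ref_slice)
    for var in variants:
        start, stop = var.ref_span
        if start < cursor:
            raise ConfigurationError("planted variants overlap on the reference")
        match_len = start - cursor
        parts.append(ref_slice[cursor - amp_start : start - amp_start])
        emit(match_len, "M")
        if var.is_snv:
            parts.append(var.alt_allele)
            emit(1, "M")
        else:
            # anchored indel: anchor base aligns as M, then I or D
            parts.append(var.alt_allele)
            emit(1, "M")
            ins = len(var.alt_allele) - 1
            dele = len(var.ref_allele) - 1
            emit(ins, "I")
            emit(dele, "D")
        cursor = stop
    parts.append(ref_slice[cursor - amp_start : amp_end - amp_start])
    emit(amp_end - cursor, "M")
    return "".join(parts), cigar


def _apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Substitute bases at the positional error rates; draw order is 5'->3'.

    Vectorized: per-base uniforms against the position-dependent rate, then
    a uniformly chosen different base at each error position.
    """
    n = len(seq)
    if model.e_end == 0.0 and model.e_interior == 0.0:
        return seq
    idx = np.arange(n)
    terminal = (idx < model.end_frac * n) | (idx >= (1.0 - model.end_frac) * n)
    rates = np.where(terminal, model.e_end, model.e_interior)
    hits = np.flatnonzero(rng.random(n) < rates)
    if hits.size == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _simulate_sample(
    reference: dict[str, ReferenceSequence],
    amplicons: list[Amplicon],
    planted: list[PlantedVariant],
    error_model: ErrorModel,
    rng: np.random.Generator,
    sample: str,
) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    for amp_idx, amp in enumerate(amplicons):
        ref = reference[amp.ref_name]
        if amp.end > len(ref.seq):
            raise ConfigurationError(
                f"amplicon {amp.ref_name}:{amp.start}-{amp.end} exceeds contig length"
            )
        ref_slice = ref.seq[amp.start : amp.end]
        overlapping = sorted(
            (
                v
                for v in planted
                if v.ref_name == amp.ref_name
                and amp.start <= v.ref_span[0]
                and v.ref_span[1] <= amp.end
                and (v.zygosity_scope == "germline" or sample == "tumor")
            ),
            key=lambda v: v.pos0,
        )
        for read_idx in range(amp.depth):
            carried = [v for v in overlapping if rng.random() < v.af]
            seq, cigar = _mutate_read(ref_slice, amp.start, carried)
            seq = _apply_errors(seq, error_model, rng)
            reads.append(
                AlignedRead(
                    read_id=f"{sample}_a{amp_idx}_r{read_idx}",
                    ref_name=amp.ref_name,
                    ref_start=amp.start,
                    cigar=cigar,
                    seq=seq,
                    sample=sample,
                )
            )
    return reads


def simulate_pair(
    reference: list[ReferenceSequence],
    amplicons: list[Amplicon],
    planted: list[PlantedVariant],
    error_model: ErrorModel,
    seed: int,
) -> tuple[list[AlignedRead], list[AlignedRead], pd.DataFrame]:
    """Simulate a matched tumor/normal read pair over the panel.

    Returns (tumor reads, normal reads, truth manifest).  The manifest lists
    every planted variant with its scope and allele fraction; downstream
    tests compare recovered candidates against it.
    """
    _check_coverage(amplicons, planted)
    by_name = {ref.name: ref for ref in reference}
    rng = np.random.default_rng(seed)
    tumor = _simulate_sample(by_name, amplicons, planted, error_model, rng, "tumor")
    normal = _simulate_sample(by_name, amplicons, planted, error_model, rng, "normal")
    manifest = pd.DataFrame(
        [
            {
                "ref_name": v.ref_name,
                "pos": v.pos0 + 1,  # 1-based, VCF convention
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "af": v.af,
                "scope": v.zygosity_scope,
            }
            for v in planted
        ],
        columns=["ref_name", "pos", "ref_allele", "alt_allele", "af", "scope"],
    )
    return tumor, normal, manifest


def plant_end_artifact(
    reference: list[ReferenceSequence],
    amplicon: Amplicon,
    pos0: int,
    af: float,
    seed: int,
    alt_allele: str | None = None,
) -> list[AlignedRead]:
    """Generate tumor reads carrying an end-of-read artifact variant.

    ``pos0`` must fall in the terminal 15% of the amplicon interval; because
    every read spans the amplicon, each alt-supporting read then places the
    variant within the terminal 15% of its aligned bases — the event class
    the positional filter must reject.  Reads are error-free so the artifact
    is the only signal.
    """
    frac = (pos0 - amplicon.start) / len(amplicon)
    if not (0.0 <= frac < 0.15 or frac >= 0.85):
        raise ConfigurationError(
            f"pos0 {pos0} sits at amplicon offset fraction {frac:.3f}; "
            "an end artifact requires the terminal 15%"
        )
    by_name = {ref.name: ref for ref in reference}
    ref_base = by_name[amplicon.ref_name].seq[pos0]
    if alt_allele is None:
        alt_allele = "ACGT"[("ACGT".index(ref_base) + 1) % 4] if ref_base in "ACGT" else "A"
    variant = PlantedVariant(
        ref_name=amplicon.ref_name,
        pos0=pos0,
        ref_allele=ref_base,
        alt_allele=alt_allele,
        af=af,
        zygosity_scope="somatic",
    )
    rng = np.random.default_rng(seed)
    return _simulate_sample(
        by_name, [amplicon], [variant], ErrorModel(0.0, 0.0), rng, "tumor"
    )


# ---------------------------------------------------------------------------
# Shotgun mode: uniform random read starts, used by property tests that need
# variable variant offsets within reads.


def simulate_shotgun(
    reference: ReferenceSequence,
    n_reads: int,
    read_length: int,
    seed: int,
    sample: str = "tumor",
) -> list[AlignedRead]:
    """Error-free reads with uniform random start positions on one contig."""
    if read_length > len(reference.seq):
        raise ConfigurationError("read_length exceeds contig length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(reference.seq) - read_length + 1, size=n_reads)
    return [
        AlignedRead(
            read_id=f"{sample}_s{i}",
            ref_name=reference.name,
            ref_start=int(s),
            cigar=[(read_length, "M")],
            seq=reference.seq[s : s + read_length],
            sample=sample,
        )
        for i, s in enumerate(starts)
    ]


def random_reference(name: str, length: int, seed: int) -> ReferenceSequence:
    """A uniformly random ACGT contig, for panels with no real sequence."""
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    return ReferenceSequence(name=name, seq=seq)


_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def random_coding_reference(name: str, n_codons: int, seed: int) -> ReferenceSequence:
    """A random open reading frame: ATG followed by stop-free random codons.

    Lets a whole simulated panel double as a valid CDS, so passing variants
    can be protein-annotated without internal-stop artifacts.
    """
    if n_codons < 2:
        raise ConfigurationError("need at least 2 codons")
    rng = np.random.default_rng(seed)
    body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)]
    return ReferenceSequence(name=name, seq="ATG" + "".join(body))


def write_truth_tsv(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
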