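"""Pileup construction and low-stringency candidate calling.

Stand-in for the vendor somatic caller: builds per-position pileups from
aligned reads and emits every allele with minimal support as a candidate,
carrying the per-read positional metadata (offset of the variant base within
the read) that the downstream read-end filter consumes.  Thresholds here are
deliberately permissive — the filter cascade owns the real stringency.

Coordinate conventions: pileup columns are 0-based; emitted candidates use
the 1-based, left-anchored VCF representation.  A deletion consumes
reference in its read without contributing a base call: the deleted columns
carry the deletion allele ``*`` in their counts, while the candidate allele
itself is anchored at the last aligned base before the deletion.  Insertions
are likewise anchored at the preceding matched position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AlignedRead, ReferenceSequence, VariantRecord

#: Pileup allele key for "read spans this column inside a deletion".
DELETION_MARKER = "*"


class AlignmentError(ValueError):
    """A read is inconsistent with the reference it claims to align to."""


@dataclass(frozen=True)
class SupportingReadOffset:
    """Positional evidence from one alt-supporting read.

    ``offset_frac`` is the 0-based index of the variant base among the
    read's aligned (soft-clip-excluded) bases, divided by the aligned read
    length; it lies in [0, 1).  For indel alleles the offset of the anchor
    base (the last aligned base before the event) is used.
    """

    read_id: str
    offset_frac: float


@dataclass
class PileupColumn:
    """Allele counts at one reference position.

    ``allele_counts`` maps single-base alleles (plus ``*`` for reads whose
    deletion spans the column) to read counts; anchored indel alleles that
    start at this column are kept separately in ``indel_supports`` keyed by
    their (ref, alt) VCF representation.  ``depth`` is the total number of
    reads whose alignment consumes this reference position.
    """

    ref_name: str
    pos0: int
    ref_base: str
    allele_counts: dict[str, int] = field(default_factory=dict)
    alt_supports: dict[str, list[SupportingReadOffset]] = field(default_factory=dict)
    indel_supports: dict[tuple[str, str], list[SupportingReadOffset]] = field(
        default_factory=dict
    )

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())

    @property
    def n_alt_alleles(self) -> int:
        """Distinct non-reference alleles with >=1 supporting read at the site.

        Counts mismatching base calls and anchored indel alleles; the ``*``
        span marker is excluded (that deletion is counted at its anchor).
        """
        bases = sum(
            1
            for allele, count in self.allele_counts.items()
            if count > 0 and allele not in (self.ref_base, DELETION_MARKER)
        )
        return bases + len(self.indel_supports)


@dataclass
class VariantCandidate(VariantRecord):
    """A variant call plus its per-read positional evidence."""

    supports: list[SupportingReadOffset] = field(default_factory=list)
    n_alt_alleles_at_site: int = 1

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.supports) != self.alt_reads:
            raise ValueError(
                f"{self.key}: {len(self.supports)} supports but alt_reads={self.alt_reads}"
            )


class _ContigPileup:
    """Accumulator for one contig: coverage as diff arrays, alleles sparsely.

    Deep panels make a per-base Python loop prohibitive, so match/deletion
    coverage is accumulated as interval increments and only mismatching
    bases (rare: variants and errors) are handled per event.
    """

    def __init__(self, ref_seq: str):
        self.ref_seq = ref_seq
        self.m_diff = np.zeros(len(ref_seq) + 1, dtype=np.int64)
        self.del_diff = np.zeros(len(ref_seq) + 1, dtype=np.int64)
        # pos0 -> base -> [SupportingReadOffset]
        self.mismatches: dict[int, dict[str, list[SupportingReadOffset]]] = {}
        # pos0 -> (ref, alt) -> [SupportingReadOffset]
        self.indels: dict[int, dict[tuple[str, str], list[SupportingReadOffset]]] = {}


def build_pileup(
    reads: list[AlignedRead], reference: list[ReferenceSequence]
) -> list[PileupColumn]:
    """Build per-position pileup columns from aligned reads.

    Every reference position consumed by at least one M or D op gets a
    column.  Columns are returned sorted by (ref_name, pos0).
    """
    by_name = {ref.name: ref for ref in reference}
    contigs: dict[str, _ContigPileup] = {}

    for read in reads:
        ref = by_name.get(read.ref_name)
        if ref is None:
            raise AlignmentError(f"read {read.read_id!r}: unknown contig {read.ref_name!r}")
        if read.ref_end > len(ref.seq):
            raise AlignmentError(
                f"read {read.read_id!r} extends past the end of {read.ref_name!r}"
            )
        state = contigs.get(read.ref_name)
        if state is None:
            state = contigs[read.ref_name] = _ContigPileup(ref.seq)
        _accumulate(read, state)

    columns: list[PileupColumn] = []
    for name in sorted(contigs):
        columns.extend(_materialize(name, contigs[name]))
    return columns


def _accumulate(read: AlignedRead, state: _ContigPileup) -> None:
    """Walk one read's CIGAR, updating the contig accumulator.

    M consumes both read and reference and contributes a base call; D
    consumes reference only (span marker at each deleted column, anchored
    deletion allele at the preceding matched position); I consumes read only
    (anchored insertion allele at the preceding matched position).
    """
    ref_seq = state.ref_seq
    rpos = read.ref_start
    qpos = 0
    n = read.aligned_length
    last_m = None  # (ref pos, query idx) of last matched base, for anchoring
    for length, op in read.cigar:
        if op == "M":
            state.m_diff[rpos] += 1
            state.m_diff[rpos + length] -= 1
            seg = read.seq[qpos : qpos + length]
            ref_seg = ref_seq[rpos : rpos + length]
            if seg != ref_seg:
                a = np.frombuffer(seg.encode(), dtype="S1")
                b = np.frombuffer(ref_seg.encode(), dtype="S1")
                for i in np.flatnonzero(a != b):
                    i = int(i)
                    site = state.mismatches.setdefault(rpos + i, {})
                    site.setdefault(seg[i], []).append(
                        SupportingReadOffset(read.read_id, (qpos + i) / n)
                    )
            rpos += length
            qpos += length
            last_m = (rpos - 1, qpos - 1)
        elif op == "D":
            if last_m is None:
                raise AlignmentError(
                    f"read {read.read_id!r}: deletion with no preceding match"
                )
            anchor_ref, anchor_q = last_m
            state.del_diff[rpos] += 1
            state.del_diff[rpos + length] -= 1
            ref_allele = ref_seq[anchor_ref : rpos + length]
            alt_allele = ref_seq[anchor_ref]
            site = state.indels.setdefault(anchor_ref, {})
            site.setdefault((ref_allele, alt_allele), []).append(
                SupportingReadOffset(read.read_id, anchor_q / n)
            )
            rpos += length
        elif op == "I":
            if last_m is None:
                raise AlignmentError(
                    f"read {read.read_id!r}: insertion with no preceding match"
                )
            anchor_ref, anchor_q = last_m
            ref_allele = ref_seq[anchor_ref]
            alt_allele = read.seq[anchor_q] + read.seq[qpos : qpos + length]
            site = state.indels.setdefault(anchor_ref, {})
            site.setdefault((ref_allele, alt_allele), []).append(
                SupportingReadOffset(read.read_id, anchor_q / n)
            )
            qpos += length


def _materialize(ref_name: str, state: _ContigPileup) -> list[PileupColumn]:
    m_cov = np.cumsum(state.m_diff)[:-1]
    del_cov = np.cumsum(state.del_diff)[:-1]
    covered = np.flatnonzero((m_cov + del_cov) > 0)
    columns: list[PileupColumn] = []
    for pos0 in covered:
        pos0 = int(pos0)
        ref_base = state.ref_seq[pos0]
        mism = state.mismatches.get(pos0, {})
        counts: dict[str, int] = {}
        ref_count = int(m_cov[pos0]) - sum(len(v) for v in mism.values())
        if ref_count:
            counts[ref_base] = ref_count
        for base, supports in mism.items():
            counts[base] = len(supports)
        if del_cov[pos0]:
            counts[DELETION_MARKER] = int(del_cov[pos0])
        columns.append(
            PileupColumn(
                ref_name=ref_name,
                pos0=pos0,
                ref_base=ref_base,
                allele_counts=counts,
                alt_supports={b: list(s) for b, s in mism.items() if b != ref_base},
                indel_supports={
                    key: list(s) for key, s in state.indels.get(pos0, {}).items()
                },
            )
        )
    return columns


DEFAULT_MIN_ALT_READS = 4
DEFAULT_MIN_AF = 0.01


def call_candidates(
    pileup: list[PileupColumn],
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    min_af: float = DEFAULT_MIN_AF,
) -> list[VariantCandidate]:
    """Emit one candidate per (site, alt allele) meeting the loose thresholds.

    Defaults (4 alt reads, 1% AF) are intentionally below the downstream
    filter's 2% tier so that the filter, not the caller, decides.  Candidates
    are sorted by position, then lexicographically by alt allele.
    """
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    if not 0.0 < min_af < 1.0:
        raise ValueError("min_af must be in (0, 1)")

    candidates: list[VariantCandidate] = []
    for col in pileup:
        depth = col.depth
        if depth == 0:
            continue
        site_alleles = col.n_alt_alleles
        emitted: list[tuple[str, str, list[SupportingReadOffset]]] = []
        for base in sorted(col.alt_supports):
            supports = col.alt_supports[base]
            if len(supports) >= min_alt_reads and len(supports) / depth >= min_af:
                emitted.append((col.ref_base, base, supports))
        for ref_allele, alt_allele in sorted(col.indel_supports):
            supports = col.indel_supports[(ref_allele, alt_allele)]
            if len(supports) >= min_alt_reads and len(supports) / depth >= min_af:
                emitted.append((ref_allele, alt_allele, supports))
        emitted.sort(key=lambda item: item[1])
        for ref_allele, alt_allele, supports in emitted:
            candidates.append(
                VariantCandidate(
                    ref_name=col.ref_name,
                    pos=col.pos0 + 1,
                    ref_allele=ref_allele,
                    alt_allele=alt_allele,
                    depth=depth,
                    alt_reads=len(supports),
                    supports=list(supports),
                    n_alt_alleles_at_site=site_alleles,
                )
            )
    candidates.sort(key=lambda c: (c.ref_name, c.pos, c.alt_allele))
    return candidates


def call_sample(
    reads: list[AlignedRead],
    reference: list[ReferenceSequence],
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    min_af: float = DEFAULT_MIN_AF,
) -> list[VariantCandidate]:
    """Pileup + candidate calling in one step."""
    return call_candidates(build_pileup(reads, reference), min_alt_reads, min_af)
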