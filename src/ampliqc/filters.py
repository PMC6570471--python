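"""The somatic QC cascade for matched tumor-normal amplicon calls.

The screening procedure applied to each tumor/normal pair is:

1. subtract the matched normal's variant calls from the tumor's (exact
   (contig, pos, ref, alt) key match on left-anchored alleles);
2. remove alt-supporting reads that place the variant within the first or
   last 15% of the read's aligned bases and re-evaluate the allele
   frequency on the remaining evidence; a candidate whose support is
   entirely terminal is an end-read event and is excluded outright;
3. exclude sites carrying more than 2 distinct variant alleles;
4. require a minimum raw depth of 100 reads;
5. AF-tiered support: a re-evaluated AF in 2-5% needs at least 10 alt
   reads, an AF above 5% needs at least 25.

Every rule is evaluated for every candidate and each failure is recorded in
an ordered trail, so a verdict is a complete diagnostic, not just a bit.
The one exception is the sub-2% AF rule, which only applies to candidates
retaining interior support: an all-terminal event is already fully explained
by the end-read rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io_formats import (
    AlignedRead,
    ReferenceSequence,
    VariantRecord,
    write_vcf,
)
from .pileup import (
    DEFAULT_MIN_AF,
    DEFAULT_MIN_ALT_READS,
    SupportingReadOffset,
    VariantCandidate,
    call_sample,
)

#: Trail label applied at normal subtraction (recorded on removed records).
IN_NORMAL = "in_normal"

#: Fixed evaluation order of the QC trail labels.
TRAIL_ORDER = ("end_read", "multiallelic", "min_depth", "low_af", "tier_support")


@dataclass(frozen=True)
class SupportTier:
    """Minimum alt-read support required inside an AF band."""

    af_lo: float
    af_hi: float  # inclusive upper bound; use inf for an open tier
    min_support: int


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the somatic QC cascade.

    Defaults are the published screening rules: terminal 15% of read bases,
    at most 2 variant alleles per site, a 100-read depth floor, >=10 alt
    reads when the re-evaluated AF is 2-5% and >=25 when it exceeds 5%.
    """

    end_frac: float = 0.15
    max_alt_alleles: int = 2
    min_depth: int = 100
    tier_low: SupportTier = SupportTier(af_lo=0.02, af_hi=0.05, min_support=10)
    tier_high: SupportTier = SupportTier(af_lo=0.05, af_hi=float("inf"), min_support=25)

    def __post_init__(self) -> None:
        if not 0.0 < self.end_frac < 0.5:
            raise ValueError("end_frac must be in (0, 0.5)")
        if self.min_depth < 1 or self.max_alt_alleles < 1:
            raise ValueError("min_depth and max_alt_alleles must be >= 1")
        for tier in (self.tier_low, self.tier_high):
            if tier.min_support < 1:
                raise ValueError("tier min_support must be >= 1")
        if not (
            0.0 < self.tier_low.af_lo <= self.tier_low.af_hi <= self.tier_high.af_lo
        ):
            raise ValueError("AF tier bounds must be ordered")


@dataclass
class FilterVerdict:
    """One candidate's trip through the cascade.

    ``ao_core`` and ``af_core`` are the alt support and allele frequency
    after terminal-read removal; ``trail`` lists every failed rule in
    evaluation order; ``passed`` iff the trail is empty.
    """

    candidate: VariantCandidate
    ao_core: int
    af_core: float
    end_flagged: list[SupportingReadOffset] = field(default_factory=list)
    trail: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.trail

    def to_record(self) -> VariantRecord:
        """VariantRecord carrying the trail and end-corrected INFO fields."""
        cand = self.candidate
        return VariantRecord(
            ref_name=cand.ref_name,
            pos=cand.pos,
            ref_allele=cand.ref_allele,
            alt_allele=cand.alt_allele,
            depth=cand.depth,
            alt_reads=cand.alt_reads,
            filter_trail=list(self.trail),
            info={
                "AO_CORE": self.ao_core,
                "DP_CORE": cand.depth - len(self.end_flagged),
            },
        )


def subtract_normal(
    tumor: list[VariantCandidate], normal: list[VariantCandidate]
) -> list[VariantCandidate]:
    """Drop tumor candidates whose exact allele is also called in the normal.

    Matching is on the full (contig, pos, ref, alt) key: a different alt
    allele at the same position in the normal does not mask a tumor call.
    Order of surviving candidates is preserved.
    """
    normal_keys = {cand.key for cand in normal}
    return [cand for cand in tumor if cand.key not in normal_keys]


def split_by_normal(
    tumor: list[VariantCandidate], normal: list[VariantCandidate]
) -> tuple[list[VariantCandidate], list[VariantCandidate]]:
    """Like :func:`subtract_normal` but also returns the removed candidates."""
    normal_keys = {cand.key for cand in normal}
    kept = [c for c in tumor if c.key not in normal_keys]
    removed = [c for c in tumor if c.key in normal_keys]
    return kept, removed


def end_read_reeval(
    candidate: VariantCandidate, end_frac: float = 0.15
) -> tuple[int, float, list[SupportingReadOffset]]:
    """Remove terminal-read alt support and re-evaluate the allele frequency.

    A supporting read is flagged when its variant base lies within the first
    or last ``end_frac`` of the read's aligned bases: offset_frac < end_frac
    or offset_frac >= 1 - end_frac (half-open on both sides, so exactly the
    terminal 30% of bases is flagged for read lengths divisible by 20).
    The re-evaluated AF divides the remaining support by the depth minus the
    flagged reads; 0/0 is defined as 0.
    """
    flagged = [
        s
        for s in candidate.supports
        if s.offset_frac < end_frac or s.offset_frac >= 1.0 - end_frac
    ]
    ao_core = candidate.alt_reads - len(flagged)
    denom = candidate.depth - len(flagged)
    af_core = ao_core / denom if denom else 0.0
    return ao_core, af_core, flagged


def evaluate(candidate: VariantCandidate, params: FilterParams) -> FilterVerdict:
    """Run one normal-subtracted candidate through the full QC cascade."""
    ao_core, af_core, flagged = end_read_reeval(candidate, params.end_frac)
    trail: list[str] = []
    if ao_core == 0:
        trail.append("end_read")
    if candidate.n_alt_alleles_at_site > params.max_alt_alleles:
        trail.append("multiallelic")
    if candidate.depth < params.min_depth:
        trail.append("min_depth")
    low, high = params.tier_low, params.tier_high
    if ao_core > 0 and af_core < low.af_lo:
        trail.append("low_af")
    if (low.af_lo <= af_core <= low.af_hi and ao_core < low.min_support) or (
        af_core > high.af_lo and ao_core < high.min_support
    ):
        trail.append("tier_support")
    return FilterVerdict(
        candidate=candidate,
        ao_core=ao_core,
        af_core=af_core,
        end_flagged=flagged,
        trail=trail,
    )


def apply_qc(
    candidates: list[VariantCandidate], params: FilterParams | None = None
) -> list[FilterVerdict]:
    """Apply the QC cascade to already normal-subtracted candidates."""
    params = params or FilterParams()
    return [evaluate(cand, params) for cand in candidates]


def run_somatic_pipeline(
    tumor_reads: list[AlignedRead],
    normal_reads: list[AlignedRead],
    reference: list[ReferenceSequence],
    params: FilterParams | None = None,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    min_af: float = DEFAULT_MIN_AF,
    vcf_out=None,
) -> list[FilterVerdict]:
    """End-to-end screening: pileup, call, subtract, QC.

    Returns a verdict for every tumor candidate: those removed by matched
    normal subtraction carry the trail ``["in_normal"]`` (QC is still
    reported for them diagnostically after that label); the rest carry their
    QC trail.  When ``vcf_out`` is given, all verdicts are written as VCF
    with FILTER PASS or the trail labels.
    """
    params = params or FilterParams()
    tumor_cands = call_sample(tumor_reads, reference, min_alt_reads, min_af)
    normal_cands = call_sample(normal_reads, reference, min_alt_reads, min_af)
    kept, removed = split_by_normal(tumor_cands, normal_cands)

    verdicts = apply_qc(kept, params)
    for cand in removed:
        verdict = evaluate(cand, params)
        verdict.trail.insert(0, IN_NORMAL)
        verdicts.append(verdict)
    verdicts.sort(key=lambda v: (v.candidate.ref_name, v.candidate.pos, v.candidate.alt_allele))

    if vcf_out is not None:
        contigs = [(ref.name, len(ref.seq)) for ref in reference]
        write_vcf([v.to_record() for v in verdicts], vcf_out, contigs=contigs)
    return verdicts


def passing(verdicts: list[FilterVerdict]) -> list[FilterVerdict]:
    return [v for v in verdicts if v.passed]


def relax(params: FilterParams, **changes) -> FilterParams:
    """Convenience for building parameter variants in tests and sweeps."""
    return replace(params, **changes)
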