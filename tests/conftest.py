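from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ampliqc.io_formats import ReferenceSequence
from ampliqc.pileup import SupportingReadOffset, VariantCandidate

# codon -> amino acid choices used to build synthetic CDS fixtures
CODON = {
    "M": "ATG",
    "E": "GAG",
    "K": "AAG",
    "D": "GAT",
    "G": "GGA",
    "A": "GCT",
    "L": "CTT",
    "R": "CGT",
    "Q": "CAA",
    "*": "TAA",
}


def coding_reference(protein: str, name: str = "gene") -> ReferenceSequence:
    """Reference whose sequence is the CDS encoding ``protein`` (one exon)."""
    return ReferenceSequence(name=name, seq="".join(CODON[aa] for aa in protein))


def make_candidate(
    depth: int,
    offsets: list[float],
    n_alt_alleles: int = 1,
    pos: int = 50,
    ref: str = "A",
    alt: str = "C",
) -> VariantCandidate:
    """Candidate with explicit support offsets, for direct filter tests."""
    return VariantCandidate(
        ref_name="chrT",
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        depth=depth,
        alt_reads=len(offsets),
        supports=[SupportingReadOffset(f"r{i}", o) for i, o in enumerate(offsets)],
        n_alt_alleles_at_site=n_alt_alleles,
    )


@pytest.fixture
def small_reference() -> ReferenceSequence:
    return ReferenceSequence(name="chrT", seq="ACGTACGTACGTACGTACGT" * 10)  # 200 bp
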