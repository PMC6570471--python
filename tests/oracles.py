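"""Independent brute-force oracles the test suite checks the package against.

Deliberately naive: exact rational arithmetic for Fisher's test, and a flat
re-statement of the five QC rules as standalone predicates.  Nothing here
imports the code paths under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p-value by exhaustive hypergeometric enumeration.

    Exact rational arithmetic: sums P(k) over every table with the observed
    margins whose probability does not exceed the observed table's.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    total = comb(n, r1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: Fraction(comb(c1, k) * comb(n - c1, r1 - k), total) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def qc_pass_oracle(
    depth: int,
    offsets: list[float],
    n_alt_alleles: int,
    end_frac: float = 0.15,
    max_alt_alleles: int = 2,
    min_depth: int = 100,
    low_af_lo: float = 0.02,
    low_af_hi: float = 0.05,
    low_support: int = 10,
    high_af_gt: float = 0.05,
    high_support: int = 25,
) -> bool:
    """PASS/FAIL of the QC cascade, re-derived rule by rule.

    ``offsets`` are the per-supporting-read variant offsets (fractions of
    aligned read length).
    """
    interior = [o for o in offsets if end_frac <= o < 1.0 - end_frac]
    removed = len(offsets) - len(interior)
    ao = len(interior)
    denom = depth - removed
    af = ao / denom if denom else 0.0

    if ao == 0:
        return False  # all support terminal: an end-read event
    if n_alt_alleles > max_alt_alleles:
        return False
    if depth < min_depth:
        return False
    if af < low_af_lo:
        return False
    if low_af_lo <= af <= low_af_hi and ao < low_support:
        return False
    if af > high_af_gt and ao < high_support:
        return False
    return True
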