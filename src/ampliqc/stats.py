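"""Companion statistics: E->K missense enrichment, Fisher's exact test,
and qPCR relative expression.

The E->K fraction summarizes, per gene, how much of the missense burden is
glutamate-to-lysine substitution — the recurrent change class in CNOT3.
Fisher's exact test (two-sided, sum-of-smaller-probabilities convention)
scores 2x2 rescue-experiment tables.  Relative expression follows the
comparative Ct method: per-group ΔCt against a reference gene, fold change
2^-(ΔCt_test - ΔCt_control).
"""

from __future__ import annotations

import logging
import math
import os
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

_MISSENSE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

#: Relative tolerance when comparing hypergeometric table probabilities to
#: the observed one; guards the two-sided inclusion test against FP ties.
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class MutationRecord:
    """One mutation in a MAF-like table: gene, protein-change label, class."""

    gene: str
    label: str
    kind: str  # "missense" | "other"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = condition, columns = outcome: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class CtMeasurement:
    """Paired cycle thresholds for one well: target gene and reference gene."""

    sample_group: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        if self.target_ct <= 0 or self.reference_ct <= 0:
            raise ValueError("Ct values must be positive")


def ek_fraction(records: list[MutationRecord], gene: str) -> float:
    """Percentage of a gene's missense mutations that are E->K.

    Unparseable missense labels stay in the denominator (and are logged):
    dropping them silently would inflate the fraction.  Raises when the gene
    has no missense records at all.
    """
    missense = [r for r in records if r.gene == gene and r.kind == "missense"]
    if not missense:
        raise ValueError(f"no missense records for gene {gene!r}; fraction undefined")
    n_ek = 0
    for rec in missense:
        m = _MISSENSE_RE.match(rec.label)
        if m is None:
            logger.warning("unparseable missense label %r for %s", rec.label, gene)
            continue
        if m.group(1) == "E" and m.group(3) == "K":
            n_ek += 1
    return 100.0 * n_ek / len(missense)


def ek_fraction_table(records: list[MutationRecord]) -> pd.DataFrame:
    """E->K percentage for every gene with >=1 missense record."""
    genes = sorted({r.gene for r in records if r.kind == "missense"})
    return pd.DataFrame(
        {
            "gene": genes,
            "n_missense": [
                sum(1 for r in records if r.gene == g and r.kind == "missense")
                for g in genes
            ],
            "ek_percent": [ek_fraction(records, g) for g in genes],
        }
    )


def _log_hypergeom_pmf(k: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(N=n, K=c1, draws=r1)."""

    def logc(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return logc(c1, k) + logc(n - c1, r1 - k) - logc(n, r1)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Conditions on both margins and sums the hypergeometric probabilities of
    every table no more likely than the observed one (the classic
    sum-of-small-p two-sided convention).  Probabilities are computed in log
    space from log-gamma, exact to double precision for N up to ~1e4; the
    inclusion comparison uses a 1e-7 relative tolerance so floating-point
    representation of exact ties does not drop symmetric tables.
    """
    r1 = table.a + table.b
    c1 = table.a + table.c
    n = table.n
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    if lo == hi:  # degenerate margins: a single table is possible
        return 1.0
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, c1, n)
    log_obs = float(logp[table.a - lo])
    include = logp <= log_obs + math.log1p(FISHER_REL_TOL)
    p = float(np.exp(logp[include]).sum())
    return min(p, 1.0)


def relative_expression(
    test: list[CtMeasurement], control: list[CtMeasurement]
) -> float:
    """Fold change of the test group over the control by the ΔΔCt method.

    Each group's ΔCt is the mean of (target Ct - reference Ct) over its
    measurements; the fold change is 2^-(ΔCt_test - ΔCt_control), so 1.0
    means no change and values < 1 mean reduced expression in the test
    group.
    """
    if not test or not control:
        raise ValueError("both groups must be non-empty")
    dct_test = sum(m.target_ct - m.reference_ct for m in test) / len(test)
    dct_control = sum(m.target_ct - m.reference_ct for m in control) / len(control)
    return 2.0 ** -(dct_test - dct_control)


# ---------------------------------------------------------------------------
# Tabular front-ends


def read_maf_like(path: str | os.PathLike) -> list[MutationRecord]:
    """MAF-like TSV with columns sample, gene, protein_change, variant_class."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "protein_change", "variant_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        MutationRecord(
            gene=row.gene,
            label=row.protein_change,
            kind="missense" if row.variant_class == "missense" else "other",
        )
        for row in df.itertuples()
    ]


def read_ct_table(path: str | os.PathLike, sample_group: str) -> list[CtMeasurement]:
    """TSV with columns target_ct, reference_ct (one row per well)."""
    df = pd.read_csv(path, sep="\t")
    required = {"target_ct", "reference_ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CtMeasurement(
            sample_group=sample_group,
            target_ct=float(row.target_ct),
            reference_ct=float(row.reference_ct),
        )
        for row in df.itertuples()
    ]
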