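from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliqc.filters import (
    FilterParams,
    SupportTier,
    apply_qc,
    end_read_reeval,
    evaluate,
    run_somatic_pipeline,
    split_by_normal,
    subtract_normal,
)
from ampliqc.pileup import call_sample
from ampliqc.simulate import Amplicon, ErrorModel, PlantedVariant, simulate_pair, random_reference, plant_end_artifact

from conftest import make_candidate
from oracles import qc_pass_oracle


class TestSubtractNormal:
    def test_shared_germline_removed(self):
        tumor = [make_candidate(100, [0.5] * 40)]
        normal = [make_candidate(100, [0.4] * 35)]  # same key, different evidence
        assert subtract_normal(tumor, normal) == []

    def test_tumor_only_retained(self):
        tumor = [make_candidate(100, [0.5] * 40)]
        assert subtract_normal(tumor, []) == tumor

    def test_key_includes_alt_allele(self):
        tumor = [make_candidate(100, [0.5] * 40, alt="C")]
        normal = [make_candidate(100, [0.5] * 40, alt="G")]
        assert subtract_normal(tumor, normal) == tumor

    def test_split_preserves_both_sides(self):
        shared = make_candidate(100, [0.5] * 10, pos=10)
        private = make_candidate(100, [0.5] * 10, pos=20)
        kept, removed = split_by_normal([shared, private], [shared])
        assert kept == [private] and removed == [shared]


class TestEndReadReeval:
    def test_terminal_offset_flagged(self):
        cand = make_candidate(200, [10 / 200] + [0.5] * 9)
        ao_core, af_core, flagged = end_read_reeval(cand, 0.15)
        assert ao_core == 9
        assert len(flagged) == 1
        assert af_core == 9 / 199

    def test_boundary_offset_not_flagged(self):
        # offset exactly at end_frac belongs to the interior (half-open rule)
        cand = make_candidate(100, [15 / 100, 0.5])
        ao_core, af_core, flagged = end_read_reeval(cand, 0.15)
        assert ao_core == 2 and flagged == []

    def test_last_fraction_flagged_from_boundary(self):
        cand = make_candidate(100, [0.85, 0.8499])
        ao_core, _, flagged = end_read_reeval(cand, 0.15)
        assert ao_core == 1 and len(flagged) == 1

    def test_total_removal_gives_zero_af(self):
        cand = make_candidate(500, [0.05] * 40)
        ao_core, af_core, flagged = end_read_reeval(cand, 0.15)
        assert (ao_core, af_core) == (0, 0.0)
        assert len(flagged) == 40


class TestApplyQc:
    """The published threshold rules, exercised at their stated values."""

    def test_low_tier_pass_with_10_reads(self):
        # AF 4% with 12 interior alt reads at depth 300: within 2-5%, >= 10
        cand = make_candidate(300, [0.5] * 12)
        (verdict,) = apply_qc([cand])
        assert verdict.af_core == 12 / 300 == 0.04
        assert verdict.passed

    def test_high_tier_needs_25_reads(self):
        # AF 10% with only 24 supporting reads fails the >5% tier
        cand = make_candidate(240, [0.5] * 24)
        (verdict,) = apply_qc([cand])
        assert verdict.af_core == 0.1
        assert verdict.trail == ["tier_support"]

    def test_depth_floor_100(self):
        cand = make_candidate(99, [0.5] * 50)
        (verdict,) = apply_qc([cand])
        assert verdict.trail == ["min_depth"]

    def test_multiallelic_site_excluded(self):
        cand = make_candidate(1000, [0.5] * 100, n_alt_alleles=3)
        (verdict,) = apply_qc([cand])
        assert "multiallelic" in verdict.trail

    def test_all_terminal_support_is_end_read_only(self):
        cand = make_candidate(500, [0.05] * 40)
        (verdict,) = apply_qc([cand])
        assert verdict.trail == ["end_read"]

    def test_sub_two_percent_rejected(self):
        cand = make_candidate(1000, [0.5] * 15)  # af_core 1.5%
        (verdict,) = apply_qc([cand])
        assert verdict.trail == ["low_af"]

    def test_tier_boundary_five_percent_is_low_tier(self):
        # af_core exactly 5%: the 2-5% band applies, 10 reads suffice
        cand = make_candidate(240, [0.5] * 12)
        (verdict,) = apply_qc([cand])
        assert verdict.af_core == 0.05
        assert verdict.passed

    def test_trail_records_every_failure(self):
        cand = make_candidate(99, [0.5] * 3, n_alt_alleles=4)  # af_core ~3%
        (verdict,) = apply_qc([cand])
        assert verdict.trail == ["multiallelic", "min_depth", "tier_support"]

    def test_idempotent_on_passing_records(self):
        cands = [make_candidate(300, [0.5] * 12), make_candidate(500, [0.4] * 30)]
        first = apply_qc(cands)
        again = apply_qc([v.candidate for v in first if v.passed])
        assert [(v.candidate.key, v.trail) for v in again] == [
            (v.candidate.key, v.trail) for v in first
        ]

    def test_af_core_bounds(self):
        for offsets in ([0.05] * 10, [0.5] * 10, [0.05] * 5 + [0.5] * 5):
            cand = make_candidate(50, offsets)
            (verdict,) = apply_qc([cand], FilterParams(min_depth=1))
            assert verdict.ao_core <= cand.alt_reads
            assert 0.0 <= verdict.af_core <= 1.0


def random_candidate(rng: random.Random, pos: int = 50):
    depth = rng.randint(1, 500)
    n_alt = rng.randint(0, depth)
    offsets = [rng.random() for _ in range(n_alt)]
    return make_candidate(depth, offsets, n_alt_alleles=rng.randint(1, 4), pos=pos)


class TestOracleEquivalence:
    def test_fuzzed_candidates_match_brute_force(self):
        rng = random.Random(20240917)
        params = FilterParams()
        for _ in range(1000):
            cand = random_candidate(rng)
            verdict = evaluate(cand, params)
            expected = qc_pass_oracle(
                cand.depth,
                [s.offset_frac for s in cand.supports],
                cand.n_alt_alleles_at_site,
            )
            assert verdict.passed == expected, (
                cand.depth,
                cand.alt_reads,
                cand.n_alt_alleles_at_site,
            )


def _random_params(rng: random.Random) -> FilterParams:
    af_lo = rng.uniform(0.005, 0.04)
    af_hi = rng.uniform(af_lo, 0.1)
    return FilterParams(
        end_frac=rng.uniform(0.01, 0.45),
        max_alt_alleles=rng.randint(1, 5),
        min_depth=rng.randint(1, 400),
        tier_low=SupportTier(af_lo, af_hi, rng.randint(1, 30)),
        tier_high=SupportTier(af_hi, float("inf"), rng.randint(1, 60)),
    )


def _relax(params: FilterParams, rng: random.Random) -> FilterParams:
    return FilterParams(
        end_frac=rng.uniform(0.01, params.end_frac),
        max_alt_alleles=params.max_alt_alleles + rng.randint(0, 3),
        min_depth=rng.randint(1, params.min_depth),
        tier_low=SupportTier(
            params.tier_low.af_lo,
            params.tier_low.af_hi,
            rng.randint(1, params.tier_low.min_support),
        ),
        tier_high=SupportTier(
            params.tier_high.af_lo,
            float("inf"),
            rng.randint(1, params.tier_high.min_support),
        ),
    )


def _relax_monotone(params: FilterParams, rng: random.Random) -> FilterParams:
    """Relax every axis except end_frac (which is not monotone, see below)."""
    relaxed = _relax(params, rng)
    return FilterParams(
        end_frac=params.end_frac,
        max_alt_alleles=relaxed.max_alt_alleles,
        min_depth=relaxed.min_depth,
        tier_low=relaxed.tier_low,
        tier_high=relaxed.tier_high,
    )


class TestMonotonicity:
    """Depth floor, tier supports and the allele cap are monotone axes.

    The terminal-window width is deliberately excluded: shrinking end_frac
    retains more terminal alt support, which raises the re-evaluated AF and
    can push a candidate across the 5% boundary into the 25-read tier —
    a strictly harder requirement.  The flip is demonstrated below.
    """

    def test_relaxing_monotone_thresholds_never_shrinks_pass_set(self):
        rng = random.Random(7)
        candidates = [random_candidate(rng, pos=i + 1) for i in range(60)]
        for _ in range(200):
            strict = _random_params(rng)
            relaxed = _relax_monotone(strict, rng)
            strict_pass = {
                v.candidate.key for v in apply_qc(candidates, strict) if v.passed
            }
            relaxed_pass = {
                v.candidate.key for v in apply_qc(candidates, relaxed) if v.passed
            }
            assert strict_pass <= relaxed_pass, (strict, relaxed)

    def test_end_frac_relaxation_can_flip_a_pass(self):
        # 12 interior supports + 10 at offset 0.10: under end_frac 0.15 the
        # ten are flagged and af_core = 12/290 ~ 4.1% (low tier, 12 >= 10:
        # PASS); under end_frac 0.05 all 22 count and af_core = 22/300 ~
        # 7.3% (> 5% tier, 22 < 25: FAIL).  The AF-tiered support rule is
        # therefore not monotone in the terminal-window width.
        cand = make_candidate(300, [0.5] * 12 + [0.10] * 10)
        strict = FilterParams()
        relaxed = FilterParams(end_frac=0.05)
        assert evaluate(cand, strict).passed
        verdict = evaluate(cand, relaxed)
        assert verdict.trail == ["tier_support"]


@pytest.fixture(scope="module")
def world():
    reference = random_reference("chrP", 400, seed=3)
    amp = Amplicon("chrP", 0, 400, depth=800)
    ref = reference.seq

    def alt(pos0):
        return "ACGT"[("ACGT".index(ref[pos0]) + 1) % 4]

    planted = [
        PlantedVariant("chrP", 100, ref[100], alt(100), 0.5, "germline"),
        PlantedVariant("chrP", 200, ref[200], alt(200), 0.10, "somatic"),
        PlantedVariant("chrP", 30, ref[30], alt(30), 0.08, "somatic"),  # 30/400 < 15%
    ]
    tumor, normal, _ = simulate_pair(
        [reference], [amp], planted, ErrorModel(0.0, 0.0), seed=41
    )
    return reference, planted, tumor, normal


class TestPipeline:
    def test_composition(self, world):
        reference, planted, tumor, normal = world
        verdicts = run_somatic_pipeline(tumor, normal, [reference])
        by_pos = {v.candidate.pos: v for v in verdicts}
        assert by_pos[101].trail[0] == "in_normal"  # germline subtracted
        assert by_pos[201].passed  # clean somatic at AF 10%
        assert by_pos[31].trail == ["end_read"]  # terminal-window somatic
        assert [v for v in verdicts if v.passed] == [by_pos[201]]

    def test_self_subtraction_leaves_nothing(self, world):
        reference, _, tumor, _ = world
        verdicts = run_somatic_pipeline(tumor, tumor, [reference])
        assert all("in_normal" in v.trail for v in verdicts)

    def test_relaxed_depth_floor_is_superset(self, world):
        reference, _, tumor, normal = world
        default_pass = {
            v.candidate.key
            for v in run_somatic_pipeline(tumor, normal, [reference])
            if v.passed
        }
        relaxed_pass = {
            v.candidate.key
            for v in run_somatic_pipeline(
                tumor, normal, [reference], params=FilterParams(min_depth=1)
            )
            if v.passed
        }
        assert default_pass <= relaxed_pass

    def test_subtraction_soundness(self, world):
        reference, _, tumor, normal = world
        normal_keys = {c.key for c in call_sample(normal, [reference])}
        verdicts = run_somatic_pipeline(tumor, normal, [reference])
        pass_keys = {v.candidate.key for v in verdicts if v.passed}
        assert pass_keys & normal_keys == set()

    def test_end_artifact_never_passes(self):
        reference = random_reference("chrE", 300, seed=13)
        amp = Amplicon("chrE", 0, 200, depth=600)
        for seed in range(5):
            reads = plant_end_artifact([reference], amp, pos0=8, af=0.2, seed=seed)
            verdicts = run_somatic_pipeline(reads, [], [reference])
            assert all(not v.passed for v in verdicts)


@settings(max_examples=50, deadline=None)
@given(
    depth=st.integers(1, 300),
    offsets=st.lists(st.floats(0, 0.999), max_size=50),
    end_frac=st.floats(0.01, 0.49),
)
def test_reeval_invariants(depth, offsets, end_frac):
    """ao_core never exceeds alt support; af_core stays a frequency."""
    offsets = offsets[: depth]
    cand = make_candidate(depth, offsets)
    ao_core, af_core, flagged = end_read_reeval(cand, end_frac)
    assert 0 <= ao_core <= cand.alt_reads
    assert 0.0 <= af_core <= 1.0
    assert len(flagged) + ao_core == cand.alt_reads
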