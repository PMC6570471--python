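"""Pipeline configuration: YAML schema, strict validation, materialization.

Unknown keys are hard errors — in a filtering tool a silently ignored
threshold typo is worse than a crash.  The config describes the whole world
of a run: the reference (generated or loaded), the amplicon panel, the
planted truth variants, the error model, caller and filter parameters, and
an optional transcript model for annotation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .annotate import TranscriptModel
from .filters import FilterParams, SupportTier
from .io_formats import ReferenceSequence, read_fasta
from .simulate import (
    Amplicon,
    ErrorModel,
    PlantedVariant,
    random_coding_reference,
    random_reference,
)


class ConfigError(ValueError):
    """The configuration file is malformed or inconsistent."""


def _require_keys(section: dict, allowed: set[str], required: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    missing = required - set(section)
    if missing:
        raise ConfigError(f"{where}: missing keys {sorted(missing)}")


@dataclass
class ReferenceSpec:
    kind: str  # "coding" | "random" | "fasta"
    name: str = "panel"
    length: int = 900
    path: str | None = None

    def materialize(self, seed: int) -> ReferenceSequence:
        if self.kind == "fasta":
            return read_fasta(self.path)[0]
        if self.kind == "coding":
            if self.length % 3 != 0:
                raise ConfigError("coding reference length must be divisible by 3")
            return random_coding_reference(self.name, self.length // 3, seed)
        if self.kind == "random":
            return random_reference(self.name, self.length, seed)
        raise ConfigError(f"unknown reference kind {self.kind!r}")


@dataclass
class PlantedSpec:
    """A planted variant before the reference sequence is known."""

    pos: int  # 1-based position of the variant (anchor for indels)
    kind: str  # "snv" | "del" | "ins"
    af: float
    scope: str
    alt: str | None = None  # SNV alt base; default: next base in ACGT cycle
    length: int = 1  # deletion length
    bases: str = "A"  # inserted bases

    def materialize(self, reference: ReferenceSequence) -> PlantedVariant:
        pos0 = self.pos - 1
        if not 0 <= pos0 < len(reference.seq):
            raise ConfigError(f"planted pos {self.pos} outside the reference")
        anchor = reference.seq[pos0]
        if self.kind == "snv":
            alt = self.alt
            if alt is None:
                alt = "ACGT"[("ACGT".index(anchor) + 1) % 4] if anchor in "ACGT" else "A"
            if alt == anchor:
                raise ConfigError(f"planted SNV at {self.pos}: alt equals the reference base")
            return PlantedVariant(reference.name, pos0, anchor, alt, self.af, self.scope)
        if self.kind == "del":
            ref_allele = reference.seq[pos0 : pos0 + 1 + self.length]
            if len(ref_allele) != 1 + self.length:
                raise ConfigError(f"planted deletion at {self.pos} runs off the reference")
            return PlantedVariant(reference.name, pos0, ref_allele, anchor, self.af, self.scope)
        if self.kind == "ins":
            return PlantedVariant(
                reference.name, pos0, anchor, anchor + self.bases, self.af, self.scope
            )
        raise ConfigError(f"unknown planted variant kind {self.kind!r}")


@dataclass
class CallerParams:
    min_alt_reads: int = 4
    min_af: float = 0.01


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, short of the seed's final value."""

    seed: int
    reference: ReferenceSpec
    amplicons: list[dict]  # materialized against the reference name later
    planted: list[PlantedSpec]
    error_model: ErrorModel = field(default_factory=ErrorModel)
    caller: CallerParams = field(default_factory=CallerParams)
    filters: FilterParams = field(default_factory=FilterParams)
    transcript: dict | None = None  # gene/strand/cds, bound to the reference contig

    def build_reference(self, seed: int) -> ReferenceSequence:
        return self.reference.materialize(seed)

    def build_amplicons(self, reference: ReferenceSequence) -> list[Amplicon]:
        return [
            Amplicon(
                ref_name=reference.name,
                start=a["start"],
                end=a["end"],
                depth=a["depth"],
            )
            for a in self.amplicons
        ]

    def build_planted(self, reference: ReferenceSequence) -> list[PlantedVariant]:
        return [spec.materialize(reference) for spec in self.planted]

    def build_transcript(self, reference: ReferenceSequence) -> TranscriptModel | None:
        if self.transcript is None:
            return None
        return TranscriptModel(
            gene=self.transcript["gene"],
            ref_name=reference.name,
            strand=self.transcript["strand"],
            cds_intervals=tuple(tuple(iv) for iv in self.transcript["cds"]),
        )


def parse_config(data: dict) -> PipelineConfig:
    """Validate a parsed YAML mapping into a :class:`PipelineConfig`."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _require_keys(
        data,
        allowed={
            "seed",
            "reference",
            "amplicons",
            "planted",
            "error_model",
            "caller",
            "filters",
            "transcript_model",
        },
        required={"seed", "reference", "amplicons"},
        where="config",
    )

    ref = data["reference"]
    _require_keys(
        ref, {"kind", "name", "length", "path"}, {"kind"}, "config.reference"
    )
    reference = ReferenceSpec(
        kind=ref["kind"],
        name=ref.get("name", "panel"),
        length=int(ref.get("length", 900)),
        path=ref.get("path"),
    )

    amplicons = []
    for i, amp in enumerate(data["amplicons"]):
        _require_keys(amp, {"start", "end", "depth"}, {"start", "end", "depth"}, f"config.amplicons[{i}]")
        amplicons.append({k: int(amp[k]) for k in ("start", "end", "depth")})

    planted = []
    for i, var in enumerate(data.get("planted", []) or []):
        _require_keys(
            var,
            {"pos", "kind", "af", "scope", "alt", "length", "bases"},
            {"pos", "kind", "af", "scope"},
            f"config.planted[{i}]",
        )
        planted.append(
            PlantedSpec(
                pos=int(var["pos"]),
                kind=var["kind"],
                af=float(var["af"]),
                scope=var["scope"],
                alt=var.get("alt"),
                length=int(var.get("length", 1)),
                bases=var.get("bases", "A"),
            )
        )

    em = data.get("error_model", {}) or {}
    _require_keys(em, {"e_interior", "e_end", "end_frac"}, set(), "config.error_model")
    error_model = ErrorModel(
        e_interior=float(em.get("e_interior", 0.001)),
        e_end=float(em.get("e_end", 0.01)),
        end_frac=float(em.get("end_frac", 0.15)),
    )

    cp = data.get("caller", {}) or {}
    _require_keys(cp, {"min_alt_reads", "min_af"}, set(), "config.caller")
    caller = CallerParams(
        min_alt_reads=int(cp.get("min_alt_reads", 4)),
        min_af=float(cp.get("min_af", 0.01)),
    )

    filters = parse_filter_params(data.get("filters", {}) or {})

    transcript = data.get("transcript_model")
    if transcript is not None:
        _require_keys(transcript, {"gene", "strand", "cds"}, {"gene", "strand", "cds"}, "config.transcript_model")

    return PipelineConfig(
        seed=int(data["seed"]),
        reference=reference,
        amplicons=amplicons,
        planted=planted,
        error_model=error_model,
        caller=caller,
        filters=filters,
        transcript=transcript,
    )


def parse_filter_params(section: dict) -> FilterParams:
    _require_keys(
        section,
        {"end_frac", "max_alt_alleles", "min_depth", "tier_low", "tier_high"},
        set(),
        "config.filters",
    )
    tl = section.get("tier_low", {}) or {}
    _require_keys(tl, {"af_lo", "af_hi", "min_support"}, set(), "config.filters.tier_low")
    th = section.get("tier_high", {}) or {}
    _require_keys(th, {"af_gt", "min_support"}, set(), "config.filters.tier_high")
    tier_low = SupportTier(
        af_lo=float(tl.get("af_lo", 0.02)),
        af_hi=float(tl.get("af_hi", 0.05)),
        min_support=int(tl.get("min_support", 10)),
    )
    tier_high = SupportTier(
        af_lo=float(th.get("af_gt", 0.05)),
        af_hi=float("inf"),
        min_support=int(th.get("min_support", 25)),
    )
    return FilterParams(
        end_frac=float(section.get("end_frac", 0.15)),
        max_alt_alleles=int(section.get("max_alt_alleles", 2)),
        min_depth=int(section.get("min_depth", 100)),
        tier_low=tier_low,
        tier_high=tier_high,
    )


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data)
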