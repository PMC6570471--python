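from __future__ import annotations

import pytest
from Bio.Seq import Seq

from ampliqc.annotate import (
    ModelConsistencyError,
    NonCodingMarker,
    ProteinEffect,
    TranscriptModel,
    annotate_variant,
    is_e_to_k,
    make_label,
    parse_label,
    read_transcript_model,
    write_transcript_model,
)
from ampliqc.io_formats import ReferenceSequence, VariantRecord

from conftest import coding_reference


def synthetic_gene(n_codons: int = 500) -> ReferenceSequence:
    """Single-exon gene with E at codons 20/70/120, D at 285, K at 286, G at 488."""
    protein = ["L"] * n_codons
    protein[0] = "M"
    for pos, aa in [(20, "E"), (70, "E"), (120, "E"), (285, "D"), (286, "K"), (488, "G")]:
        protein[pos - 1] = aa
    return coding_reference("".join(protein))


@pytest.fixture(scope="module")
def gene() -> ReferenceSequence:
    return synthetic_gene()


@pytest.fixture(scope="module")
def model(gene) -> TranscriptModel:
    return TranscriptModel("GENE1", gene.name, "+", ((0, len(gene.seq)),))


def snv(pos0: int, ref: str, alt: str) -> VariantRecord:
    return VariantRecord("gene", pos0 + 1, ref, alt, depth=100, alt_reads=20)


class TestAnnotateSnv:
    @pytest.mark.parametrize(
        "codon, within, alt, label, kind",
        [
            (20, 0, "A", "E20K", "missense"),  # GAG -> AAG
            (70, 0, "A", "E70K", "missense"),
            (120, 1, "C", "E120A", "missense"),  # GAG -> GCG
            (285, 2, "A", "D285E", "missense"),  # GAT -> GAA
            (286, 0, "G", "K286E", "missense"),  # AAG -> GAG
            (20, 2, "A", "E20E", "synonymous"),  # GAG -> GAA
        ],
    )
    def test_codon_substitutions(self, gene, model, codon, within, alt, label, kind):
        pos0 = (codon - 1) * 3 + within
        effect = annotate_variant(snv(pos0, gene.seq[pos0], alt), model, gene)
        assert isinstance(effect, ProteinEffect)
        assert (effect.label, effect.kind, effect.aa_pos) == (label, kind, codon)

    def test_nonsense(self, gene, model):
        # L (CTT) codon 2 -> stop requires T->A at second position? use CTT->TAA not single;
        # instead mutate codon 2 CTT first base C->? no stop; use A at pos giving TAA via
        # third base: CTT -> CTA is Leu. Take codon 10 CTT: C->T gives TTT (Phe).
        # Simplest real nonsense: make K286 (AAG) -> TAG stop by A->T at first base.
        pos0 = 285 * 3
        effect = annotate_variant(snv(pos0, gene.seq[pos0], "T"), model, gene)
        assert effect.kind == "nonsense"
        assert effect.label == "K286*"

    def test_outside_cds_is_non_coding(self, gene):
        short_model = TranscriptModel("GENE1", gene.name, "+", ((0, 300),))
        effect = annotate_variant(snv(350, gene.seq[350], "A" if gene.seq[350] != "A" else "C"), short_model, gene)
        assert isinstance(effect, NonCodingMarker)

    def test_reference_mismatch_rejected(self, gene, model):
        wrong = "C" if gene.seq[57] != "C" else "G"
        with pytest.raises(ModelConsistencyError):
            annotate_variant(snv(57, wrong, "A"), model, gene)


class TestAnnotateIndel:
    def test_frameshift_label_at_first_affected_codon(self, gene, model):
        # delete the first base of codon 488 (G of GGA): anchored at the
        # preceding base, the first changed codon is 488 with ref Gly
        anchor = 487 * 3 - 1
        var = VariantRecord(
            "gene", anchor + 1, gene.seq[anchor : anchor + 2], gene.seq[anchor],
            depth=100, alt_reads=20,
        )
        effect = annotate_variant(var, model, gene)
        assert effect.kind == "frameshift"
        assert effect.label == "Frameshift at G488"
        assert (effect.aa_pos, effect.ref_aa, effect.alt_aa) == (488, "G", "")

    def test_inframe_deletion(self, gene, model):
        anchor = 487 * 3 - 1
        var = VariantRecord(
            "gene", anchor + 1, gene.seq[anchor : anchor + 4], gene.seq[anchor],
            depth=100, alt_reads=20,
        )
        effect = annotate_variant(var, model, gene)
        assert effect.kind == "inframe_indel"
        assert effect.aa_pos == 488

    def test_frameshift_insertion(self, gene, model):
        anchor = 100
        var = VariantRecord(
            "gene", anchor + 1, gene.seq[anchor], gene.seq[anchor] + "TT",
            depth=100, alt_reads=20,
        )
        effect = annotate_variant(var, model, gene)
        assert effect.kind == "frameshift"
        assert effect.aa_pos == (anchor + 1) // 3 + 1


class TestStrandSymmetry:
    def test_minus_strand_equals_plus_annotation(self, gene, model):
        flipped = ReferenceSequence(
            "gene_rc", str(Seq(gene.seq).reverse_complement())
        )
        minus_model = TranscriptModel(
            "GENE1", "gene_rc", "-", ((0, len(gene.seq)),)
        )
        length = len(gene.seq)
        for codon, within, alt in [(20, 0, "A"), (286, 0, "G"), (120, 1, "C")]:
            pos0 = (codon - 1) * 3 + within
            plus = annotate_variant(snv(pos0, gene.seq[pos0], alt), model, gene)
            rc_pos0 = length - 1 - pos0
            rc_ref = str(Seq(gene.seq[pos0]).reverse_complement())
            rc_alt = str(Seq(alt).reverse_complement())
            minus = annotate_variant(
                VariantRecord("gene_rc", rc_pos0 + 1, rc_ref, rc_alt, 100, 20),
                minus_model,
                flipped,
            )
            assert (minus.label, minus.kind) == (plus.label, plus.kind)


class TestLabels:
    @pytest.mark.parametrize(
        "kind, aa_pos, ref_aa, alt_aa",
        [
            ("missense", 20, "E", "K"),
            ("synonymous", 5, "L", "L"),
            ("nonsense", 30, "K", "*"),
            ("frameshift", 488, "G", ""),
            ("inframe_indel", 10, "A", ""),
        ],
    )
    def test_label_round_trip(self, kind, aa_pos, ref_aa, alt_aa):
        label = make_label(kind, aa_pos, ref_aa, alt_aa)
        assert parse_label(label) == (kind, aa_pos, ref_aa, alt_aa)

    def test_unparseable_label_rejected(self):
        with pytest.raises(ValueError):
            parse_label("p.Glu20Lys")


class TestIsEToK:
    def test_direction_matters(self, gene, model):
        e20k = annotate_variant(snv(57, gene.seq[57], "A"), model, gene)
        k286e = annotate_variant(snv(855, gene.seq[855], "G"), model, gene)
        e120a = annotate_variant(snv(358, gene.seq[358], "C"), model, gene)
        assert is_e_to_k(e20k) is True
        assert is_e_to_k(k286e) is False
        assert is_e_to_k(e120a) is False

    def test_non_missense_rejected(self, gene, model):
        synonymous = annotate_variant(snv(59, gene.seq[59], "A"), model, gene)
        with pytest.raises(ValueError):
            is_e_to_k(synonymous)


class TestModel:
    def test_full_cds_translates_without_internal_stop(self, gene, model):
        protein = str(Seq(model.cds_sequence(gene)).translate())
        assert "*" not in protein

    def test_cds_length_must_be_codon_multiple(self, gene):
        with pytest.raises(ModelConsistencyError):
            TranscriptModel("G", "gene", "+", ((0, 10),))

    def test_split_cds_mapping(self):
        ref = coding_reference("MEKG", name="split")  # 12 bp CDS
        padded = ReferenceSequence("split", ref.seq[:6] + "TTTT" + ref.seq[6:])
        model = TranscriptModel("G", "split", "+", ((0, 6), (10, 16)))
        assert model.cds_sequence(padded) == ref.seq
        assert model.genomic_to_cds(11) == 7
        assert model.genomic_to_cds(7) is None

    def test_json_round_trip(self, tmp_path, model):
        path = tmp_path / "model.json"
        write_transcript_model(model, path)
        assert read_transcript_model(path) == model
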