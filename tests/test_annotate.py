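import pytest

from rnacomposite.annotate import (
    Annotation,
    ModificationMatrix,
    apply_edit,
    differential_duplexes,
    differential_rows,
    load_m6a_matrix,
    matrix_summary,
    mutation_impact,
    parse_edit,
    site_accessibility_delta,
    structural_context,
)
from rnacomposite.composite import DuplexCluster, assemble, cluster_duplexes, accept_duplex
from rnacomposite.core import Helix, Interval, StructureModel, TranscriptSeq, parse_dotbracket
from rnacomposite.probing import DuplexGroup

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


class TestModificationMatrix:
    def test_hek293t_column_counts_all_rows(self):
        m = load_m6a_matrix()
        summary = matrix_summary(m)
        assert summary["n_positions"] == 12
        assert summary["column_counts"]["HEK293T"] == 12

    def test_row_5044_presence_pattern(self):
        m = load_m6a_matrix()
        summary = matrix_summary(m)
        assert summary["row_present"][5044] == ["CD8T", "HEK293T", "Neuro", "A549"]

    def test_differential_rows(self):
        m = load_m6a_matrix()
        rows = differential_rows(m, ["HEK293T"], ["AML", "H1299", "HepG2"])
        assert 5044 in rows
        assert 2611 not in rows  # present everywhere

    def test_empty_matrix_all_zero(self):
        m = ModificationMatrix(positions=[], columns=["X"], cells={})
        summary = matrix_summary(m)
        assert summary["n_positions"] == 0
        assert summary["column_counts"] == {"X": 0}

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            ModificationMatrix(positions=[1, 1], columns=[], cells={})


def _hairpin_model():
    seq = TranscriptSeq(id="t", residues="GGGGGGGGGG" + "A" * 8 + "CCCCCCCCCC")
    return seq, parse_dotbracket("((((((((((........))))))))))", seq)


class TestStructuralContext:
    def test_site_in_stem_structured(self):
        _, model = _hairpin_model()
        ctx = structural_context(
            model, Annotation(kind="protein_site", region=Interval(2, 6), label="s")
        )
        assert ctx.classification == "structured"
        assert ctx.paired_fraction == 1.0

    def test_site_in_loop_unstructured(self):
        _, model = _hairpin_model()
        ctx = structural_context(
            model, Annotation(kind="mirna_site", region=Interval(12, 17), label="s")
        )
        assert ctx.classification == "unstructured"

    def test_loop_site_reports_enclosing_hairpin(self, small_noise_free_bundle):
        b = small_noise_free_bundle
        loop_sites = [a for a in b.annotations if a.label.startswith("loop_site")]
        assert loop_sites
        ann = loop_sites[0]
        ctx = structural_context(b.truth_model, ann)
        assert ctx.classification == "unstructured"
        host = ann.label.split("_")[-1]
        assert host in ctx.elements

    def test_outside_transcript_error(self):
        _, model = _hairpin_model()
        with pytest.raises(ValueError):
            structural_context(
                model, Annotation(kind="snp", region=Interval(100, 120), label="x")
            )


def _cluster(ls, le, rs, re, reads=8):
    return DuplexCluster(
        left=Interval(ls, le),
        right=Interval(rs, re),
        reads_by_dataset={"DS1": reads},
        members=[],
    )


class TestDifferentialDuplexes:
    def test_lost_duplex_with_modification_is_switch(self):
        a = [_cluster(5037, 5063, 6612, 6641)]
        mods = [
            Annotation(
                kind="modification", region=Interval(5044, 5044), label="m6A5044", payload="m6A"
            )
        ]
        out = differential_duplexes(a, [], mods)
        assert len(out) == 1
        assert out[0].is_switch
        assert out[0].modification_overlap == [5044]

    def test_identical_sets_empty(self):
        a = [_cluster(100, 110, 300, 310)]
        assert differential_duplexes(a, a) == []

    def test_lost_without_modification_not_flagged(self):
        a = [_cluster(100, 110, 300, 310)]
        out = differential_duplexes(a, [])
        assert len(out) == 1
        assert not out[0].is_switch

    def test_synthetic_pk7_analog_end_to_end(self):
        left = "GCGAUCGGAUCCGAUGGCAUGCAUGGC"
        right = "".join(COMP[c] for c in reversed(left))
        seq = left + "A" * 120 + right
        dup = lambda ds, reads: DuplexGroup(  # noqa: E731
            dataset_id=ds, left=Interval(1, 27), right=Interval(148, 147 + len(right)), reads=reads
        )
        accepted_a = [
            c for c in cluster_duplexes([dup("DS1", 8)]) if accept_duplex(c)
        ]
        accepted_b = [
            c for c in cluster_duplexes([dup("DS1", 2)]) if accept_duplex(c)
        ]
        assert accepted_a and not accepted_b
        mods = [
            Annotation(kind="modification", region=Interval(8, 8), label="m6A8", payload="m6A")
        ]
        out = differential_duplexes(accepted_a, accepted_b, mods)
        assert len(out) == 1 and out[0].is_switch


class TestEdits:
    def test_parse_substitution(self):
        assert parse_edit("U4056C") == ("sub", 4056, 4056, "U", "C")

    def test_parse_deletion_unicode_and_ascii(self):
        assert parse_edit("ΔAA4040-4041") == ("del", 4040, 4041, "AA", "")
        assert parse_edit("delAA4040-4041") == ("del", 4040, 4041, "AA", "")

    def test_parse_garbage(self):
        with pytest.raises(ValueError):
            parse_edit("banana")

    def test_deletion_span_mismatch(self):
        with pytest.raises(ValueError):
            parse_edit("delAAA4040-4041")

    def test_apply_checks_reference_base(self):
        seq = TranscriptSeq(id="t", residues="AAGAA")
        with pytest.raises(ValueError, match="reference"):
            apply_edit(seq, "U3C")
        out = apply_edit(seq, "G3C")
        assert out.residues == "AACAA"

    def test_apply_deletion(self):
        seq = TranscriptSeq(id="t", residues="AAGGA")
        out = apply_edit(seq, "delGG3-4")
        assert out.residues == "AAA"


class TestMutationImpact:
    def _stem_model(self):
        stem5 = "GCGAUCGGAU"
        stem3 = "".join(COMP[c] for c in reversed(stem5))
        residues = stem5 + "AAAA" + stem3
        seq = TranscriptSeq(id="t", residues=residues)
        model = parse_dotbracket("((((((((((....))))))))))", seq)
        return seq, model

    def test_deletion_destabilizes(self):
        seq, model = self._stem_model()
        bases = seq.residues[2:4]
        ann = Annotation(
            kind="mutation", region=Interval(3, 4), label="d", payload=f"del{bases}3-4"
        )
        impact = mutation_impact(seq, model, ann)
        assert impact.ddg > 0

    def test_gc_to_gu_destabilizes(self):
        seq, model = self._stem_model()
        # pair (1,24) is G-C; make it G-U
        assert seq.base(24) == "C"
        ann = Annotation(kind="mutation", region=Interval(24, 24), label="s", payload="C24U")
        impact = mutation_impact(seq, model, ann)
        assert impact.ddg > 0

    def test_identity_edit_zero(self):
        seq, model = self._stem_model()
        assert seq.base(12) == "A"
        ann = Annotation(kind="mutation", region=Interval(12, 12), label="i", payload="A12A")
        impact = mutation_impact(seq, model, ann)
        assert impact.ddg == 0.0
        assert impact.pairing_diff == []

    def test_edit_outside_transcript(self):
        seq, model = self._stem_model()
        ann = Annotation(kind="mutation", region=Interval(1, 1), label="x", payload="A999C")
        with pytest.raises(ValueError):
            mutation_impact(seq, model, ann)


class TestAccessibility:
    def test_full_flip(self):
        seq = TranscriptSeq(id="t", residues="GGGGAAAACCCC")
        wt = parse_dotbracket("((((....))))", seq)
        mut = parse_dotbracket("............", seq)
        delta = site_accessibility_delta(wt, mut, Interval(1, 4))
        assert delta.delta == 1.0

    def test_identical_zero(self):
        seq = TranscriptSeq(id="t", residues="GGGGAAAACCCC")
        wt = parse_dotbracket("((((....))))", seq)
        delta = site_accessibility_delta(wt, wt, Interval(1, 4))
        assert delta.delta == 0.0

    def test_destabilizing_deletion_increases_accessibility(self):
        from rnacomposite.fold import fold

        stem5 = "GCGAUCGGAU"
        stem3 = "".join(COMP[c] for c in reversed(stem5))
        seq = TranscriptSeq(id="t", residues=stem5 + "AAAA" + stem3)
        wt_res = fold(seq.residues)
        mut_seq = apply_edit(seq, f"del{seq.residues[1:5]}2-5")
        mut_res = fold(mut_seq.residues)

        def model_of(s, res):
            from rnacomposite.core import helices_from_pairs

            return StructureModel(seq=s, helices=helices_from_pairs(res.pairs))

        site = Interval(15, 24)  # the 3' strand in wt coordinates
        delta = site_accessibility_delta(model_of(seq, wt_res), model_of(mut_seq, mut_res), site)
        assert delta.delta > 0
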