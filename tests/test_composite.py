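import pytest

from rnacomposite.classify import NtCall
from rnacomposite.composite import (
    ParisCriteria,
    accept_duplex,
    assemble,
    call_pseudoknots,
    cluster_duplexes,
    duplex_to_pairs,
    loop_distance,
    resolve_nucleotide,
)
from rnacomposite.core import (
    Helix,
    Interval,
    StructureModel,
    TranscriptSeq,
    parse_dotbracket,
    write_dotbracket,
)
from rnacomposite.probing import DuplexGroup
from rnacomposite.simulate import SimConfig, generate, truth_compare


def _groups(reads_by_dataset):
    out = []
    for k, reads in enumerate(reads_by_dataset):
        if reads > 0:
            out.append(
                DuplexGroup(
                    dataset_id=f"DS{k + 1}",
                    left=Interval(100, 110),
                    right=Interval(200, 210),
                    reads=reads,
                )
            )
    return out


class TestAcceptDuplex:
    # strict-inequality boundaries pin the ">3"/">5" reading
    def test_eight_reads_single_dataset_accepted(self):
        assert accept_duplex(_groups([8, 0, 0])) is True

    def test_four_four_accepted(self):
        assert accept_duplex(_groups([4, 4, 0])) is True

    def test_three_three_three_rejected(self):
        assert accept_duplex(_groups([3, 3, 3])) is False

    def test_five_rejected(self):
        assert accept_duplex(_groups([5, 0, 0])) is False

    def test_six_accepted(self):
        assert accept_duplex(_groups([6, 0, 0])) is True

    def test_empty_is_false_not_error(self):
        assert accept_duplex([]) is False

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            ParisCriteria(multi_dataset_min=0)


class TestClusterDuplexes:
    def test_identical_spans_merge_preserving_datasets(self):
        dups = _groups([4, 7])
        clusters = cluster_duplexes(dups)
        assert len(clusters) == 1
        assert clusters[0].reads_by_dataset == {"DS1": 4, "DS2": 7}
        assert clusters[0].left == Interval(100, 110)

    def test_distant_spans_stay_separate(self):
        a = DuplexGroup(dataset_id="X", left=Interval(100, 110), right=Interval(200, 210), reads=4)
        b = DuplexGroup(dataset_id="Y", left=Interval(130, 140), right=Interval(200, 210), reads=4)
        assert len(cluster_duplexes([a, b])) == 2

    def test_jittered_duplexes_cluster_to_truth(self):
        b = generate(
            SimConfig.noise_free(
                seed=21, transcript_len=800, n_helices=8, n_long_range=2, n_pk=1,
                duplex_jitter=2, n_homologs=5,
            )
        )
        clusters = cluster_duplexes(b.duplexes)
        assert len(clusters) == len(b.truth["paris_spans"])


class TestDuplexToPairs:
    def test_perfect_complement(self):
        seq = TranscriptSeq(id="t", residues="GGGGGG" + "A" * 20 + "CCCCCC")
        pairs = duplex_to_pairs(seq, Interval(1, 6), Interval(27, 32))
        assert pairs == [(1, 32), (2, 31), (3, 30), (4, 29), (5, 28), (6, 27)]

    def test_long_designed_duplex(self):
        left = "GCGAUCGGAUCCGAUGGCAUGCAUGGC"
        right = "".join({"A": "U", "U": "A", "G": "C", "C": "G"}[c] for c in reversed(left))
        seq = TranscriptSeq(id="t", residues=left + "A" * 50 + right)
        pairs = duplex_to_pairs(seq, Interval(1, 27), Interval(78, 77 + len(right)))
        assert len(pairs) >= 15

    def test_non_complementary_warns_and_empty(self):
        seq = TranscriptSeq(id="t", residues="AAAAAA" + "G" * 20 + "AAAAAA")
        with pytest.warns(UserWarning, match="complementarity"):
            pairs = duplex_to_pairs(seq, Interval(1, 6), Interval(27, 32))
        assert pairs == []


class TestResolveNucleotide:
    def call(self, pars, dms):
        return NtCall(position=1, pars_call=pars, dms_call=dms)

    def test_agreeing_single(self):
        state, prov = resolve_nucleotide(self.call("single", "unprotected"), False, True)
        assert (state, prov) == ("unpaired", "pars+dms")

    def test_agreeing_double(self):
        state, prov = resolve_nucleotide(self.call("double", "protected"), False, False)
        assert (state, prov) == ("paired", "pars+dms")

    def test_paris_overrides_everything(self):
        state, prov = resolve_nucleotide(self.call("single", "protected"), True, False)
        assert (state, prov) == ("paired", "paris")

    def test_disagreement_goes_to_mfe(self):
        state, prov = resolve_nucleotide(self.call("single", "protected"), False, True)
        assert (state, prov) == ("paired", "mfe_resolved")

    def test_one_channel_only_goes_to_mfe(self):
        state, prov = resolve_nucleotide(self.call("double", "no_data"), False, False)
        assert (state, prov) == ("unpaired", "mfe_resolved")

    def test_no_evidence_defaults_unstructured(self):
        state, prov = resolve_nucleotide(None, False, False, in_probed_region=True)
        assert (state, prov) == ("unpaired", "default_unstructured")

    def test_outside_probed_region_no_data(self):
        state, prov = resolve_nucleotide(None, False, False, in_probed_region=False)
        assert (state, prov) == ("no_data", None)


class TestLoopDistance:
    def test_printed_pk7_coordinates(self):
        # Fig-caption value: spans 5037-5063 / 6612-6641 bridge 1548 nt
        assert loop_distance(Interval(5037, 5063), Interval(6612, 6641)) == 1548

    def test_adjacent_spans_zero(self):
        assert loop_distance(Interval(10, 20), Interval(21, 30)) == 0

    def test_overlap_is_error(self):
        with pytest.raises(ValueError):
            loop_distance(Interval(10, 25), Interval(21, 30))

    def test_planted_long_range_separation(self, small_noise_free_bundle):
        b = small_noise_free_bundle
        for ls, le, rs, re in b.truth["paris_spans"]:
            assert loop_distance(Interval(ls, le), Interval(rs, re)) == rs - le - 1


class TestCallPseudoknots:
    def _seq(self, n=120):
        return TranscriptSeq(id="t", residues="A" * n)

    def test_h_type_geometry(self):
        a = Helix(pairs=[(10 + k, 70 - k) for k in range(5)])
        b = Helix(pairs=[(40 + k, 90 - k) for k in range(5)])
        model = call_pseudoknots(StructureModel(seq=self._seq(), helices=[a, b]))
        by_start = {h.pairs[0][0]: h for h in model.helices}
        assert by_start[10].pk_layer == 0
        assert by_start[40].pk_layer == 1  # tie on size -> the more 5' stays nested

    def test_larger_helix_stays_nested(self):
        a = Helix(pairs=[(10 + k, 70 - k) for k in range(3)])
        b = Helix(pairs=[(40 + k, 90 - k) for k in range(6)])
        model = call_pseudoknots(StructureModel(seq=self._seq(), helices=[a, b]))
        by_start = {h.pairs[0][0]: h for h in model.helices}
        assert by_start[40].pk_layer == 0
        assert by_start[10].pk_layer == 1

    def test_fully_nested_no_pk(self):
        helices = [Helix(pairs=[(1, 100)]), Helix(pairs=[(10, 40)]), Helix(pairs=[(50, 90)])]
        model = call_pseudoknots(StructureModel(seq=self._seq(), helices=helices))
        assert all(h.pk_layer == 0 for h in model.helices)

    def test_planted_crossings_counted(self):
        b = generate(
            SimConfig.noise_free(
                seed=23, transcript_len=900, n_helices=9, n_long_range=0, n_pk=3,
                n_homologs=5,
            )
        )
        pk = [h for h in b.truth_model.helices if h.pk_layer > 0]
        assert len(pk) == 3


class TestAssemble:
    def test_noise_free_recovery_exact(self, small_noise_free_bundle, small_assembly):
        metrics = truth_compare(small_assembly.model, small_noise_free_bundle.truth)
        assert metrics["sensitivity"] == 1.0
        assert metrics["ppv"] == 1.0
        assert metrics["helix_recall"] == 1.0

    def test_paris_pairs_all_in_model(self, small_assembly):
        model_pairs = set(small_assembly.model.pairs)
        assert set(small_assembly.paris_pairs) <= model_pairs

    def test_paris_only_input(self):
        seq = TranscriptSeq(id="t", residues="GGGGGG" + "A" * 50 + "CCCCCC")
        dups = [
            DuplexGroup(dataset_id=f"DS{k}", left=Interval(1, 6), right=Interval(57, 62), reads=8)
            for k in (1, 2)
        ]
        result = assemble([], dups, seq)
        assert set(result.model.pairs) == {(1, 62), (2, 61), (3, 60), (4, 59), (5, 58), (6, 57)}
        assert all(
            result.composite.provenance[p] == "paris"
            for ij in result.model.pairs
            for p in ij
        )

    def test_serialization_roundtrip(self, small_assembly, small_noise_free_bundle):
        text = write_dotbracket(small_assembly.model)
        again = parse_dotbracket(text, small_noise_free_bundle.seq)
        assert set(again.pairs) == set(small_assembly.model.pairs)

    def test_removing_paris_only_shrinks_paris_set(self, small_noise_free_bundle, small_assembly):
        b = small_noise_free_bundle
        without = assemble(b.track, [], b.seq)
        paris_pos = {
            p for p, prov in small_assembly.composite.provenance.items() if prov == "paris"
        }
        paris_pos_without = {
            p for p, prov in without.composite.provenance.items() if prov == "paris"
        }
        assert paris_pos_without == set()
        assert len(paris_pos) > 0

    def test_default_noise_accuracy(self, default_bundle):
        b = default_bundle
        result = assemble(b.track, b.duplexes, b.seq)
        metrics = truth_compare(result.model, b.truth)
        assert metrics["accuracy"] >= 0.90

    def test_bad_uncovered_region_rejected(self, small_noise_free_bundle):
        b = small_noise_free_bundle
        with pytest.raises(ValueError, match="outside"):
            assemble(b.track, [], b.seq, uncovered_regions=[Interval(1, 10_000)])

    def test_deterministic(self, small_noise_free_bundle, small_assembly):
        b = small_noise_free_bundle
        again = assemble(b.track, b.duplexes, b.seq)
        assert again.model.pairs == small_assembly.model.pairs
        assert again.composite.state == small_assembly.composite.state
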