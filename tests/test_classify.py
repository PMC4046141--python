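"""Residue-441 typing, PTS1 detection, prediction rules and tree checks."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aldh10evo.classify import (
    AlignedSequenceSet,
    IsoenzymeRecord,
    SequenceEntry,
    classification_report,
    classify_residue_type,
    detect_pts1,
    extinction_coefficient_280,
    extract_codon441,
    map_reference_position,
    monophyly_check,
    predict_activity,
    predict_gb_phenotype,
    predict_location,
)

from _oracles import oracle_monophyly, random_topology, topology_to_newick


def make_record(type_label="I441", location="peroxisomal") -> IsoenzymeRecord:
    residue = type_label[0] if type_label != "other" else "X"
    act = predict_activity(type_label)
    return IsoenzymeRecord(
        identifier=f"{type_label}-{location}", residue441=residue,
        codon441="?", type_label=type_label,
        pts1="match" if location == "peroxisomal" else "no-match",
        pts1_tripeptide="SKL" if location == "peroxisomal" else None,
        predicted_activity=act.activity, predicted_location=location,
        low_confidence=act.low_confidence)


class TestPositionMapping:
    def test_counts_non_gaps(self):
        aln = AlignedSequenceSet(
            [SequenceEntry("ref", "A-CD"), SequenceEntry("q", "ABCD")], "ref")
        assert map_reference_position(aln, 2) == 3

    def test_gapless_identity(self):
        aln = AlignedSequenceSet([SequenceEntry("ref", "M" * 500)], "ref")
        assert map_reference_position(aln, 441) == 441

    @pytest.mark.parametrize("pos", [0, -3, 5])
    def test_out_of_range(self, pos):
        aln = AlignedSequenceSet([SequenceEntry("ref", "A-CD")], "ref")
        with pytest.raises(ValueError):
            map_reference_position(aln, pos)

    def test_inverse_of_ungapped_count(self):
        ref = "AC--DEF-GH-I"
        aln = AlignedSequenceSet([SequenceEntry("ref", ref)], "ref")
        for col, ch in enumerate(ref, start=1):
            if ch == "-":
                continue
            pos = sum(1 for c in ref[:col] if c != "-")
            assert map_reference_position(aln, pos) == col

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            AlignedSequenceSet(
                [SequenceEntry("ref", "ACD"), SequenceEntry("q", "AC")], "ref")


class TestResidueTyping:
    @pytest.mark.parametrize("residue, label", [
        ("I", "I441"), ("A", "A441"), ("C", "C441"), ("V", "V441"),
        ("T", "T441"), ("S", "S441"), ("F", "F441"),
        ("-", "other"), ("X", "other"), ("L", "other"), ("g", "other"),
    ])
    def test_total_function(self, residue, label):
        assert classify_residue_type(residue) == label


class TestCodonExtraction:
    def _entry(self, cds):
        return SequenceEntry("q", "MI-K", cds=cds)

    def test_direct_readout(self):
        entry = self._entry("ATGATTAAA")
        assert extract_codon441(entry, column=2) == "ATT"

    def test_translation_mismatch(self):
        entry = self._entry("ATGGCTAAA")  # codon 2 is Ala, protein says Ile
        with pytest.raises(ValueError, match="q"):
            extract_codon441(entry, column=2)

    def test_frame_error(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            extract_codon441(self._entry("ATGATTAA"), column=2)

    def test_gap_column(self):
        with pytest.raises(ValueError, match="gap"):
            extract_codon441(self._entry("ATGATTAAA"), column=3)


class TestPTS1:
    @pytest.mark.parametrize("tail, status", [
        ("SKL", "match"), ("SKI", "match"), ("ARM", "match"),
        ("AAA", "no-match"), ("SKP", "no-match"), ("CKL", "no-match"),
    ])
    def test_results_text_preset(self, tail, status):
        got, tri = detect_pts1("MMMM" + tail)
        assert got == status
        assert tri == tail

    def test_figure_legend_preset(self):
        assert detect_pts1("MMMCKL", preset="figure-legend")[0] == "match"
        assert detect_pts1("MMMSKI", preset="figure-legend")[0] == "no-match"

    def test_truncated(self):
        assert detect_pts1("SK") == ("truncated-unknown", None)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            detect_pts1("MSKL", preset="nope")

    @given(prefix=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=30),
           tail=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY",
                        min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_depends_only_on_final_tripeptide(self, prefix, tail):
        base = detect_pts1("MMM" + tail)
        assert detect_pts1("MMM" + prefix + tail) == (base[0], tail)


class TestPredictionRules:
    @pytest.mark.parametrize("label, activity, low_conf", [
        ("I441", "AMADH-only", False), ("V441", "AMADH-only", False),
        ("F441", "AMADH-only", False), ("A441", "AMADH+BADH", False),
        ("C441", "AMADH+BADH", False), ("S441", "AMADH+BADH", False),
        ("T441", "AMADH+BADH", False), ("other", "AMADH-only", True),
    ])
    def test_activity(self, label, activity, low_conf):
        assert predict_activity(label) == (activity, low_conf)

    def test_location_rule(self):
        assert predict_location("match") == "peroxisomal"
        assert predict_location("no-match") == "non-peroxisomal"
        assert predict_location("truncated-unknown") == "non-peroxisomal"

    @pytest.mark.parametrize("records, expected", [
        ([("I441", "peroxisomal")], "non-accumulator"),
        ([("I441", "peroxisomal"), ("A441", "non-peroxisomal")],
         "high-accumulator"),
        ([("C441", "peroxisomal")], "low/moderate-accumulator"),
        ([("C441", "non-peroxisomal")], "high-accumulator"),
        ([("V441", "non-peroxisomal")], "non-accumulator"),
    ])
    def test_gb_phenotype(self, records, expected):
        recs = [make_record(t, loc) for t, loc in records]
        assert predict_gb_phenotype(recs, "sp").gb_class == expected

    def test_gb_phenotype_monotone(self):
        """Adding a non-peroxisomal BADH-active record never lowers the class."""
        order = ["non-accumulator", "low/moderate-accumulator",
                 "high-accumulator"]
        booster = make_record("A441", "non-peroxisomal")
        for combo in [[("I441", "peroxisomal")],
                      [("C441", "peroxisomal")],
                      [("I441", "non-peroxisomal"), ("T441", "peroxisomal")]]:
            recs = [make_record(t, loc) for t, loc in combo]
            before = order.index(predict_gb_phenotype(recs, "sp").gb_class)
            after = order.index(
                predict_gb_phenotype(recs + [booster], "sp").gb_class)
            assert after >= before
            assert order[after] == "high-accumulator"

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            predict_gb_phenotype([], "sp")


class TestExtinctionCoefficient:
    def test_thirteen_trp_ten_tyr(self):
        # 13*5500 + 10*1490 = 86,400, the value used for these enzymes
        assert extinction_coefficient_280("W" * 13 + "Y" * 10) == 86400.0

    @pytest.mark.parametrize("seq, eps", [
        ("GGGG", 0.0), ("W", 5500.0), ("Y", 1490.0)])
    def test_simple_compositions(self, seq, eps):
        assert extinction_coefficient_280(seq) == eps

    def test_cystine_term(self):
        assert extinction_coefficient_280("CCCC", reduced=False) == 250.0
        assert extinction_coefficient_280("CCC", reduced=False) == 125.0
        assert extinction_coefficient_280("CCCC", reduced=True) == 0.0

    def test_additive_over_concatenation(self):
        a, b = "WWYACDE", "YYWMNPQ"
        assert (extinction_coefficient_280(a + b)
                == extinction_coefficient_280(a) + extinction_coefficient_280(b))

    def test_non_standard_residues_listed(self):
        with pytest.raises(ValueError, match="BX"):
            extinction_coefficient_280("WXBY")


class TestMonophyly:
    def test_simple_quartet(self):
        assert monophyly_check("((a,b),(c,d));", {"a", "b"}) == (True, 2)
        assert monophyly_check("((a,b),(c,d));", {"a", "c"}) == (False, 4)

    def test_unknown_tip(self):
        with pytest.raises(ValueError, match="zzz"):
            monophyly_check("((a,b),(c,d));", {"a", "zzz"})

    def test_complement_side_counts(self):
        # {c,d,e} is one side of the central branch: monophyletic even
        # though the Newick happens to be written rooted the other way
        assert monophyly_check("((a,b),(c,(d,e)));", {"c", "d", "e"})[0]

    def test_agrees_with_structural_enumeration(self):
        """Random trees with 4-8 tips vs the nested-tuple clade oracle."""
        rng = random.Random(441)
        for n in range(4, 9):
            for _ in range(20):
                labels = [f"t{i}" for i in range(n)]
                top = random_topology(labels, rng)
                newick = topology_to_newick(top)
                for _ in range(10):
                    k = rng.randint(1, n)
                    subset = set(rng.sample(labels, k))
                    assert monophyly_check(newick, subset) == \
                        oracle_monophyly(top, subset), (newick, subset)


class TestClassificationReport:
    @pytest.fixture()
    def small_alignment(self):
        # template: 6 residues + C-terminal tripeptide
        entries = [SequenceEntry("ref", "MAIWKESKL")]
        specs = [
            ("s1", "I", "SKL", None),
            ("s2", "A", "SKL", None),
            ("s3", "C", "AAA", None),  # signal lost by point change
            ("s4", "I", "SKL", 4),     # C-terminally truncated
            ("s5", "T", "SKI", None),
        ]
        for name, res, tail, trunc in specs:
            seq = "MA" + res + "WKE" + tail
            if trunc:
                seq = seq[:-trunc] + "-" * trunc
            entries.append(SequenceEntry(name, seq, species=f"sp_{name}"))
        return AlignedSequenceSet(entries, "ref")

    def test_round_trip_states(self, small_alignment):
        rep = classification_report(small_alignment, ref_position=3)
        table = rep.table.set_index("identifier")
        assert table.loc["s1", "type"] == "I441"
        assert table.loc["s2", "predicted_activity"] == "AMADH+BADH"
        assert table.loc["s3", "pts1"] == "no-match"
        assert table.loc["s3", "predicted_location"] == "non-peroxisomal"
        assert table.loc["s4", "pts1"] == "truncated-unknown"
        assert table.loc["s5", "pts1"] == "match"  # SKI under default preset

    def test_counts_sum_to_sequences(self, small_alignment):
        rep = classification_report(small_alignment, ref_position=3)
        assert rep.residue_counts["count"].sum() == 5

    def test_phenotypes_per_species(self, small_alignment):
        rep = classification_report(small_alignment, ref_position=3)
        by_sp = {p.species: p.gb_class for p in rep.phenotypes}
        assert by_sp["sp_s1"] == "non-accumulator"
        assert by_sp["sp_s3"] == "high-accumulator"  # non-peroxisomal C441
        assert by_sp["sp_s5"] == "low/moderate-accumulator"  # peroxisomal T441

    def test_monophyly_annotation(self, small_alignment):
        # BADH-active tips are s2, s3, s5
        tree = "((s1,s4),((s2,s3),s5));"
        rep = classification_report(small_alignment, ref_position=3, tree=tree)
        assert rep.badh_monophyletic is True
        tree2 = "((s1,s2),((s4,s3),s5));"
        rep2 = classification_report(small_alignment, ref_position=3, tree=tree2)
        assert rep2.badh_monophyletic is False
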