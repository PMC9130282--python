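"""In-silico PCR, codon substitution calls and resistance flagging."""

import pytest
from hypothesis import given, settings, strategies as st

from weedcomp import fixtures
from weedcomp.markers import (
    FrameError,
    NoAmpliconError,
    call_substitutions,
    find_amplicon,
    flag_resistance,
    revcomp,
    screen_summary,
    screen_template,
)
from weedcomp.simulate import reference_cds, simulate_sequences, template_from_cds

FWD = "TACCCAAACCTACTCTCCCG"
REV = "TGATCAGGCACATTGCACC"

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestRevcomp:
    @given(dna)
    @settings(derandomize=True, max_examples=100)
    def test_involution(self, s):
        assert revcomp(revcomp(s)) == s

    def test_known_value(self):
        assert revcomp("ACGT") == "ACGT"
        assert revcomp("AACCG") == "CGGTT"


class TestFindAmplicon:
    def test_constructed_template(self):
        filler = "AT" * 50
        template = "GGG" + FWD + filler + revcomp(REV) + "CCC"
        amp = find_amplicon(template, FWD, REV)
        assert amp.length == len(FWD) + 100 + len(REV)
        assert amp.start == 3
        assert amp.sequence.startswith(FWD)
        assert amp.sequence.endswith(revcomp(REV))

    def test_absent_primer_is_error(self):
        with pytest.raises(NoAmpliconError):
            find_amplicon("AT" * 200, FWD, REV)

    def test_configured_product_size(self):
        cds, _ = reference_cds("ACCase", seed=5)
        template, _ = template_from_cds(cds, "AGGACACGCAGAGGAACCT",
                                        "GCAGCTGCCTCAGAAGCCAA",
                                        amplicon_bp=2879, seed=5)
        amp = find_amplicon(template, "AGGACACGCAGAGGAACCT",
                            "GCAGCTGCCTCAGAAGCCAA")
        assert amp.length == 2879

    def test_multiple_products_warn_leftmost_shortest(self):
        site = revcomp(REV)
        template = FWD + "A" * 30 + site + "G" * 30 + site
        with pytest.warns(UserWarning, match="multiple candidate"):
            amp = find_amplicon(template, FWD, REV)
        assert amp.length == len(FWD) + 30 + len(site)

    def test_mismatch_tolerance_is_opt_in(self):
        mutated_fwd = "A" + FWD[1:]
        template = mutated_fwd + "C" * 40 + revcomp(REV)
        with pytest.raises(NoAmpliconError):
            find_amplicon(template, FWD, REV)
        amp = find_amplicon(template, FWD, REV, max_mismatches=1)
        assert amp.start == 0

    def test_reverse_complement_mirror(self):
        template = "GGTT" + FWD + "ACAC" * 20 + revcomp(REV) + "AATT"
        amp = find_amplicon(template, FWD, REV)
        mirrored = find_amplicon(revcomp(template), REV, FWD)
        assert mirrored.sequence == revcomp(amp.sequence)
        assert mirrored.start == len(template) - amp.end


class TestCallSubstitutions:
    def test_identical_sequences_give_no_calls(self):
        cds, _ = reference_cds("ALS", seed=1)
        assert call_substitutions(cds, cds) == []

    def test_synonymous_call(self):
        calls = call_substitutions("GGAACC", "GGGACC")
        assert len(calls) == 1
        call = calls[0]
        assert (call.ref_aa, call.alt_aa, call.kind) == ("G", "G", "synonymous")

    def test_trp_to_leu_at_standard_position(self):
        ref = "ATG" * 10 + "TGG" + "ATG" * 5          # Trp at local codon 11
        query = "ATG" * 10 + "TTG" + "ATG" * 5
        calls = call_substitutions(ref, query, numbering_offset=1999 - 11)
        assert len(calls) == 1
        call = calls[0]
        assert call.position_standard == 1999
        assert (call.ref_aa, call.alt_aa, call.kind) == ("W", "L", "nonsynonymous")

    def test_length_mismatch_is_frame_error(self):
        with pytest.raises(FrameError):
            call_substitutions("ATGGCC", "ATG")

    def test_ambiguous_base_marks_indeterminate(self):
        calls = call_substitutions("ATGGCC", "ATGGNC")
        assert calls[0].indeterminate

    @given(dna.filter(lambda s: len(s) % 3 == 0))
    @settings(derandomize=True, max_examples=60)
    def test_self_comparison_empty_and_partition_exhaustive(self, s):
        assert call_substitutions(s, s) == []


class TestFlaggingAndSummary:
    def test_p197a_flagged_on_als(self):
        ref, offset = reference_cds("ALS")
        query, _ = simulate_sequences(ref, 1, 0.0, numbering_offset=offset,
                                      plant=[(197, "A")], seed=3)
        calls = call_substitutions(ref, query, offset)
        flags = flag_resistance(calls, "ALS")
        assert [f.label for f in flags] == ["P197A"]
        assert flags[0].known_resistance

    def test_silent_change_at_known_position_not_flagged(self):
        ref = "CCA" * 200                               # Pro everywhere
        query = ref[: 196 * 3] + "CCG" + ref[197 * 3:]  # silent at codon 197
        calls = call_substitutions(ref, query, 0)
        assert calls[0].kind == "synonymous"
        assert flag_resistance(calls, "ALS") == []

    def test_nonsynonymous_at_unknown_position_reported_unflagged(self):
        ref = "GGA" * 50
        query = "CGA" + ref[3:]
        flags = flag_resistance(call_substitutions(ref, query, 0), "ALS")
        assert len(flags) == 1 and not flags[0].known_resistance

    def test_summary_counts_and_dedup(self):
        ref, offset = reference_cds("ALS", seed=2)
        query, truth = simulate_sequences(ref, 5, 3 / 5,
                                          numbering_offset=offset, seed=9)
        calls = call_substitutions(ref, query, offset)
        summary = screen_summary(calls + calls)   # duplicates collapse
        assert summary["n_synonymous"] == 3
        assert summary["n_nonsynonymous"] == 2
        assert screen_summary([]) == {
            "n_synonymous": 0, "n_nonsynonymous": 0,
            "n_indeterminate": 0, "flagged": [],
        }

    def test_full_screen_on_planted_template(self):
        ref, offset = reference_cds("ACCase", seed=4)
        query, _ = simulate_sequences(ref, 4, 3 / 4, numbering_offset=offset,
                                      plant=[(1999, "L")], seed=11)
        primers = fixtures.primer_table().set_index("gene")
        template, cds_start = template_from_cds(
            query, primers.loc["ACCase", "primer_fwd"],
            primers.loc["ACCase", "primer_rev"], amplicon_bp=2879, seed=4
        )
        result = screen_template(
            "ACCase", template, ref, offset,
            primers.loc["ACCase", "primer_fwd"],
            primers.loc["ACCase", "primer_rev"],
            cds_start_in_amplicon=cds_start,
        )
        assert result["amplicon"].length == 2879
        assert result["summary"]["n_synonymous"] == 3
        assert result["summary"]["n_nonsynonymous"] == 1
        assert result["summary"]["flagged"] == ["W1999L"]
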