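"""Degenerate primers: degeneracy, sites, amplicons, digestion."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from nestscan import (
    A3_F,
    A3_R,
    DegeneratePrimer,
    degeneracy,
    digest,
    evaluate_primer_conditions,
    expand,
    match_sites,
    predict_amplicons,
)
from nestscan.primer_insilico import IUPAC_SETS, PrimerError, find_sites
from nestscan.synthetic_data import make_primer_template

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


def random_primer(rng, length=12, max_degeneracy=4096):
    while True:
        seq = "".join(rng.choice(list(IUPAC_SETS), size=length))
        if degeneracy(seq) <= max_degeneracy:
            return seq


class TestDegeneracy:
    def test_published_primers_have_degeneracy_64(self):
        assert degeneracy(A3_F) == 64
        assert degeneracy(A3_R) == 64

    def test_non_degenerate_primer_is_one(self):
        assert degeneracy("ACGTACGTACGTACGTACGT") == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_exhaustive_expansion_size(self, seed):
        rng = np.random.default_rng(seed)
        p = random_primer(rng)
        exp = expand(p)
        assert degeneracy(p) == len(exp) == len(set(exp))
        assert exp == sorted(exp)

    def test_invalid_code_rejected(self):
        with pytest.raises(PrimerError):
            degeneracy("ACGTZ")


class TestExpand:
    def test_single_twofold_code(self):
        assert expand("ART") == ["AAT", "AGT"]

    def test_reverse_primer_expands_to_64(self):
        assert len(expand(A3_R)) == 64

    def test_refusal_reports_degeneracy(self):
        with pytest.raises(PrimerError, match="1048576"):
            expand("N" * 10, limit=4096)


class TestMatchSites:
    def test_exact_primer_sequence_matches_with_zero_mismatches(self):
        p = DegeneratePrimer("p", "ACGTACGTACGT", "forward")
        sites = match_sites("ACGTACGTACGT", p, 0)
        assert [(s.start, s.end, s.mismatches) for s in sites] == [(0, 12, 0)]

    def test_template_shorter_than_primer(self):
        p = DegeneratePrimer("p", "ACGTACGTACGT", "forward")
        assert match_sites("ACGT", p) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_sliding_window_hamming_oracle(self, seed):
        """Set-membership mismatch counting equals the minimum Hamming
        distance over the exhaustive primer expansion."""
        rng = np.random.default_rng(seed)
        p = random_primer(rng, length=10, max_degeneracy=16)
        template = "".join(rng.choice(list("ACGT"), size=400))
        primer = DegeneratePrimer("p", p, "forward")
        concrete = expand(p)
        for mm in (0, 1, 2):
            got = {(s.start, s.mismatches) for s in match_sites(template, primer, mm)}
            want = set()
            for i in range(len(template) - 10 + 1):
                win = template[i: i + 10]
                d = min(sum(a != b for a, b in zip(win, c)) for c in concrete)
                if d <= mm:
                    want.add((i, d))
            assert got == want

    def test_zero_mismatch_sites_subset_of_one_mismatch(self):
        rng = np.random.default_rng(5)
        template = "".join(rng.choice(list("ACGT"), size=500))
        p = DegeneratePrimer("p", random_primer(rng, 10), "forward")
        s0 = {(s.start, s.end) for s in match_sites(template, p, 0)}
        s1 = {(s.start, s.end) for s in match_sites(template, p, 1)}
        assert s0 <= s1

    def test_iupac_template_matches_on_set_intersection(self):
        p = DegeneratePrimer("p", "ACGTACGTAC", "forward")
        # R = {A,G} intersects A at position 0
        sites = match_sites("RCGTACGTAC", p, 0)
        assert sites and sites[0].mismatches == 0


class TestPredictAmplicons:
    def test_planted_144bp_product(self, a3_primers):
        fwd, rev = a3_primers
        template, truth = make_primer_template(fwd, rev, 144, (0, 0), seed=1)
        amps = predict_amplicons(template, fwd, rev)
        assert len(amps) == 1
        assert amps[0].length == 144
        assert (amps[0].start, amps[0].end) == (
            truth["fwd_site"][0], truth["rev_site"][1]
        )

    def test_wrong_mutual_orientation_gives_no_product(self, a3_primers):
        fwd, rev = a3_primers
        template, _ = make_primer_template(fwd, rev, 144, (0, 0), seed=2)
        # swap roles: both primers now point away from each other
        swapped = predict_amplicons(
            str(Seq(template).reverse_complement()), fwd, rev
        )
        assert [a.length for a in swapped] == [144]  # sanity: rc is fine
        fwd_only = predict_amplicons(template, fwd, fwd)
        assert fwd_only == []

    def test_reverse_complement_template_same_lengths(self, a3_primers):
        fwd, rev = a3_primers
        template, _ = make_primer_template(fwd, rev, 144, (1, 0), seed=3)
        a = predict_amplicons(template, fwd, rev, max_mismatch=1)
        b = predict_amplicons(str(Seq(template).reverse_complement()),
                              fwd, rev, max_mismatch=1)
        assert sorted(x.length for x in a) == sorted(x.length for x in b)

    def test_injected_mismatches_reported(self, a3_primers):
        fwd, rev = a3_primers
        template, truth = make_primer_template(fwd, rev, 144, (2, 1), seed=4)
        amps = predict_amplicons(template, fwd, rev, max_mismatch=2)
        assert len(amps) == 1
        assert amps[0].fwd_mismatches == 2
        assert amps[0].rev_mismatches == 1


class TestDigest:
    def test_one_internal_hindiii_site(self, a3_primers):
        fwd, rev = a3_primers
        template, _ = make_primer_template(fwd, rev, 144, (0, 0), seed=5,
                                           core_insert="AAGCTT")
        (amp,) = predict_amplicons(template, fwd, rev)
        product = template[amp.start: amp.end]
        frags = digest(product, ["HindIII"])
        assert len(frags) == 2 and sum(frags) == 144

    def test_no_sites_returns_whole_sequence(self):
        assert digest("ACGT" * 10, ["HindIII"]) == [40]

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(PrimerError):
            digest("ACGT", ["NoSuchEnzyme"])

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_fragments_sum_to_length(self, s):
        assert sum(digest(s, ["HindIII", "StuI", "EcoRI"])) == len(s)

    @pytest.mark.parametrize("seed", range(10))
    def test_cut_sets_match_biopython_restriction(self, seed):
        """Independent oracle: Bio.Restriction site search."""
        from Bio.Restriction import HindIII, StuI

        rng = np.random.default_rng(seed)
        s = "".join(rng.choice(list("ACGT"), size=600)) + "AAGCTTAGGCCT"
        for enz, name in ((HindIII, "HindIII"), (StuI, "StuI")):
            ours = find_sites(s, name)
            theirs = [p - 1 - enz.charac[0] for p in enz.search(Seq(s))]
            assert ours == sorted(theirs)


class TestPrimerConditions:
    def _target_table(self, a3_primers, mm_by_gene, product_len=144):
        fwd, rev = a3_primers
        table = {}
        for i, (gene, mm) in enumerate(mm_by_gene.items()):
            template, _ = make_primer_template(
                fwd, rev, product_len, mm, seed=10 + i
            )
            table[("chicken", gene)] = (template, gene == "ctnna3")
        return table

    def test_all_three_conditions_pass(self, a3_primers):
        """Target with 0 mismatches, paralog controls with 1 and 2 —
        the published chicken configuration."""
        fwd, rev = a3_primers
        table = self._target_table(
            a3_primers, {"ctnna3": (0, 0), "ctnna1": (1, 0), "ctnna2": (1, 1)}
        )
        report = evaluate_primer_conditions(fwd, rev, table)
        assert report.all_pass

    def test_short_product_fails_geometry_condition(self, a3_primers):
        fwd, rev = a3_primers
        table = self._target_table(a3_primers, {"ctnna3": (0, 0)}, product_len=90)
        report = evaluate_primer_conditions(fwd, rev, table)
        assert not report.product_geometry_ok
        assert report.targets_amplify

    def test_no_amplification_fails_first_condition(self, a3_primers):
        fwd, rev = a3_primers
        table = {("chicken", "ctnna3"): ("ACGT" * 100, True)}
        report = evaluate_primer_conditions(fwd, rev, table)
        assert not report.targets_amplify

    def test_control_as_good_as_target_fails_second(self, a3_primers):
        fwd, rev = a3_primers
        table = self._target_table(
            a3_primers, {"ctnna3": (0, 0), "ctnna1": (0, 0)}
        )
        report = evaluate_primer_conditions(fwd, rev, table)
        assert not report.controls_less_efficient

    def test_empty_table_rejected(self, a3_primers):
        fwd, rev = a3_primers
        with pytest.raises(PrimerError):
            evaluate_primer_conditions(fwd, rev, {})
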