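"""Conservation classification, summaries and synteny blocks."""

import pytest

from nestscan import (
    PresenceMatrix,
    classify_conservation,
    loss_table_matrix,
    summarize,
    synteny_blocks,
)
from nestscan.conservation import ABSENT, PRESENT, UNKNOWN
from nestscan.synthetic_data import make_presence_matrix


class TestClassify:
    def test_published_frog_chicken_losses(self):
        """The transcribed 19-row loss table: every pair lost, with the
        table's categories; CTNNA1/LRRTM2 is a nested-absent-in-frog call."""
        calls = classify_conservation(loss_table_matrix())
        assert all(c.status == "lost" for c in calls)
        by_pair = {c.pair_id: c for c in calls}
        c = by_pair["CTNNA1/LRRTM2"]
        assert c.loss_category == "nested_absent"
        assert "nested absent in frog" in c.evidence
        assert by_pair["CTNNA3/LRRTM3"].loss_category == "host_absent"
        # species-specific double loss: host in frog, nested in chicken
        fyco = by_pair["FYCO1/CXCR6"]
        assert fyco.loss_category == "both_absent"
        assert "host absent in frog" in fyco.evidence
        assert "nested absent in chicken" in fyco.evidence

    def test_all_present_everywhere_is_conserved(self):
        m = PresenceMatrix(
            pairs=[("H", "N", False)],
            species_roles={"coelacanth": "reference", "frog": "test"},
        )
        for sp in m.species_roles:
            for gr in ("host", "nested"):
                m.set_call(0, sp, gr, PRESENT)
        (call,) = classify_conservation(m)
        assert call.status == "conserved"
        assert call.loss_category == "none"

    def test_absent_in_all_references_is_not_assessable(self):
        m = loss_table_matrix()
        for sp in m.reference_species:
            m.set_call(0, sp, "nested", ABSENT)
        calls = classify_conservation(m)
        assert calls[0].status == "not_assessable"

    def test_unknown_in_test_species_flagged_as_unverified(self):
        m = loss_table_matrix()
        m.set_call(0, "frog", "nested", UNKNOWN)
        c = classify_conservation(m)[0]
        assert c.status == "lost"
        assert "(unverified)" in c.evidence

    @pytest.mark.parametrize("seed", range(30))
    def test_recovers_planted_truth(self, seed):
        matrix, truth = make_presence_matrix(n_pairs=25, seed=seed)
        calls = classify_conservation(matrix)
        assert [c.status for c in calls] == truth

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_presence(self, seed):
        """Flipping any absent call to present never turns a conserved
        pair into a lost one."""
        matrix, _ = make_presence_matrix(n_pairs=15, seed=seed)
        before = {c.pair_id: c.status for c in classify_conservation(matrix)}
        absents = [k for k, v in matrix.calls.items() if v == ABSENT]
        for key in absents:
            matrix.set_call(*key, PRESENT)
            after = {c.pair_id: c.status for c in classify_conservation(matrix)}
            for pid, old in before.items():
                if old == "conserved":
                    assert after[pid] != "lost"
            matrix.set_call(*key, ABSENT)

    def test_empty_roles_rejected(self):
        with pytest.raises(ValueError):
            PresenceMatrix(pairs=[("H", "N", False)], species_roles={})

    def test_matrix_tsv_roundtrip(self):
        m = loss_table_matrix()
        again = PresenceMatrix.from_tsv(m.to_tsv())
        assert again.pairs == m.pairs
        assert again.species_roles == m.species_roles
        assert again.calls == m.calls


class TestSummarize:
    def test_published_counts(self):
        summary = summarize(classify_conservation(loss_table_matrix()))
        assert summary["n_lost"] == 19
        assert summary["n_lost_LRR_nested"] == 12

    def test_empty_input_gives_zeros(self):
        s = summarize([])
        assert all(v == 0 for v in s.values())

    def test_additive_and_permutation_invariant(self):
        calls = classify_conservation(loss_table_matrix())
        s_all = summarize(calls)
        s_split = [summarize(calls[:7]), summarize(calls[7:])]
        for k in s_all:
            assert s_all[k] == s_split[0][k] + s_split[1][k]
        assert summarize(list(reversed(calls))) == s_all


class TestSyntenyBlocks:
    # frog scaffold around lrrtm3, vs a human chromosome where the
    # ctnna3/lrrtm3 locus and the tbc1d12/plce1 region are far apart
    FROG = ["sirt1", "herc4", "mypn", "atoh7", "pbld",
            "lrrtm3", "tbc1d12", "plce1"]
    HUMAN = (["SIRT1", "HERC4", "MYPN", "ATOH7", "PBLD", "CTNNA3", "LRRTM3"]
             + [f"FILLER{i}" for i in range(10)] + ["TBC1D12", "PLCE1"])
    ORTHOLOGS = {g: g.upper() for g in FROG}

    def test_two_blocks_flank_the_focal_gene(self):
        """The focal frog lrrtm3 lies between two conserved blocks, one
        syntenic to each human region (the intervening CTNNA3 has no
        frog ortholog)."""
        blocks = synteny_blocks(self.FROG, self.HUMAN, self.ORTHOLOGS,
                                focal_gene="lrrtm3", max_gap=0)
        assert len(blocks) == 2
        assert blocks[0].genes_a == ("sirt1", "herc4", "mypn", "atoh7", "pbld")
        assert blocks[1].genes_a == ("tbc1d12", "plce1")
        assert all(b.flanks_focal for b in blocks)
        assert not any(b.contains_focal for b in blocks)

    def test_gap_allowance_absorbs_interloper(self):
        blocks = synteny_blocks(self.FROG, self.HUMAN, self.ORTHOLOGS,
                                focal_gene="lrrtm3", max_gap=1)
        assert blocks[0].genes_a[-1] == "lrrtm3"
        assert blocks[0].contains_focal

    def test_identical_orders_give_one_spanning_block(self):
        genes = [f"g{i}" for i in range(6)]
        blocks = synteny_blocks(genes, genes, {g: g for g in genes},
                                focal_gene="g2")
        assert len(blocks) == 1
        assert blocks[0].genes_a == tuple(genes)

    def test_shuffled_orthologs_give_no_blocks(self):
        a = [f"g{i}" for i in range(6)]
        b = ["g0", "g3", "g1", "g5", "g2", "g4"]  # no adjacent run survives
        assert synteny_blocks(a, b, {g: g for g in a}, focal_gene="g0") == []

    def test_missing_focal_gene_raises(self):
        with pytest.raises(KeyError):
            synteny_blocks(["a"], ["A"], {"a": "A"}, focal_gene="zzz")

    def test_inverted_segment_detected(self):
        a = [f"g{i}" for i in range(5)]
        b = list(reversed([f"g{i}" for i in range(5)]))
        blocks = synteny_blocks(a, b, {g: g for g in a}, focal_gene="g0")
        assert len(blocks) == 1 and blocks[0].genes_a == tuple(a)
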