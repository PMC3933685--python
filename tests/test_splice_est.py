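"""EST alignment, filtering and AS4 skip/retain calling."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from nestscan import (
    ESTHit,
    SpliceReference,
    align_est,
    call_as4,
    filter_hits,
    skip_fraction,
)
from nestscan.splice_est import GAP_EXTEND, GAP_OPEN
from nestscan.synthetic_data import make_ests, make_splice_reference

AA = "ACDEFGHIKLMNPQRSTVWY"


def smith_waterman_affine(a: str, b: str) -> float:
    """Quadratic Gotoh local alignment score (independent oracle)."""
    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (vertical)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + GAP_OPEN, E[i, j - 1] + GAP_EXTEND)
            F[i, j] = max(H[i - 1, j] + GAP_OPEN, F[i - 1, j] + GAP_EXTEND)
            s = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def _hit(length, identity, ref_interval):
    return ESTHit(est_id="x", ref_interval=ref_interval,
                  est_interval=(0, length), aligned_length=length,
                  identity=identity, score=1.0,
                  ref_blocks=(ref_interval,))


class TestAlign:
    def test_self_alignment_is_identity_one(self, splice_reference):
        hit = align_est(splice_reference.sequence, splice_reference, "self")
        assert hit.identity == 1.0
        assert hit.aligned_length == len(splice_reference.sequence)
        assert hit.ref_interval == (0, len(splice_reference.sequence))

    def test_as4_deletion_produces_gap_spanning_the_segment(self, splice_reference):
        a_s, a_e = splice_reference.as4
        est = (splice_reference.sequence[:a_s]
               + splice_reference.sequence[a_e:])
        hit = align_est(est, splice_reference, "skip")
        assert hit.ref_blocks == ((0, a_s), (a_e, len(splice_reference.sequence)))

    @pytest.mark.parametrize("trial", range(25))
    def test_score_matches_quadratic_dp_oracle(self, trial):
        rng = np.random.default_rng(trial)
        a = "".join(rng.choice(list(AA), size=100))
        # half the trials share a planted common segment so scores are
        # not dominated by noise alignments
        if trial % 2:
            b = a[20:80] + "".join(rng.choice(list(AA), size=40))
        else:
            b = "".join(rng.choice(list(AA), size=100))
        ref = SpliceReference(sequence=a, as4=(40, 60))
        hit = align_est(b, ref, f"t{trial}")
        assert hit.score == pytest.approx(smith_waterman_affine(a, b))

    def test_nucleotide_est_translated_to_best_frame(self, splice_reference):
        from Bio.Seq import Seq
        from Bio.Data.CodonTable import standard_dna_table

        codons = {aa: c for c, aa in standard_dna_table.forward_table.items()}
        prot = splice_reference.sequence[10:120]
        nt = "G" + "".join(codons[aa] for aa in prot)  # frame 2
        hit = align_est(nt, splice_reference, "nt")
        assert hit.frame == 2
        assert hit.identity == 1.0

    def test_empty_sequence_rejected(self, splice_reference):
        with pytest.raises(ValueError):
            align_est("", splice_reference)


class TestFilter:
    @pytest.mark.parametrize(
        "length,identity,interval,kept",
        [
            (79, 0.95, (30, 109), False),   # too short
            (100, 0.29, (30, 130), False),  # identity too low
            (100, 0.50, (30, 130), True),   # all criteria met
            (100, 0.50, (0, 60), False),    # no AS4 overlap (AS4 at 65..95)
            (100, 0.50, (0, 65), True),     # abuts the AS4 junction
        ],
    )
    def test_filter_criteria(self, splice_reference, length, identity,
                             interval, kept):
        hits = [_hit(length, identity, interval)]
        kept_hits, dropped = filter_hits(hits, splice_reference)
        assert bool(kept_hits) is kept
        assert len(kept_hits) + len(dropped) == 1


class TestCall:
    def test_skip_retain_and_indeterminate(self, splice_reference):
        a_s, a_e = splice_reference.as4
        seq = splice_reference.sequence
        skip_est = seq[a_s - 40: a_s] + seq[a_e: a_e + 40]
        full_est = seq
        upstream_only = seq[: a_s]  # ends before AS4
        verdicts = {}
        for name, est in [("skip", skip_est), ("retain", full_est),
                          ("up", upstream_only)]:
            hit = align_est(est, splice_reference, name)
            verdicts[name] = call_as4(hit, splice_reference).verdict
        assert verdicts == {"skip": "skip", "retain": "retain",
                            "up": "indeterminate"}

    def test_counts_partition_input(self, splice_reference):
        ests, _ = make_ests(splice_reference, 0.5, 60, 0.02, seed=9)
        hits = [align_est(s, splice_reference, i) for i, s in ests]
        kept, _ = filter_hits(hits, splice_reference)
        calls = [call_as4(h, splice_reference) for h in kept]
        sf = skip_fraction(calls)
        assert sf["n_skip"] + sf["n_retain"] + sf["n_indeterminate"] == len(calls)

    def test_calls_invariant_under_input_order(self, splice_reference):
        ests, _ = make_ests(splice_reference, 0.5, 30, 0.02, seed=4)
        def run(pool):
            hits = [align_est(s, splice_reference, i) for i, s in pool]
            kept, _ = filter_hits(hits, splice_reference)
            return sorted((c.est_id, c.verdict)
                          for c in (call_as4(h, splice_reference) for h in kept))
        assert run(ests) == run(list(reversed(ests)))


class TestSkipFraction:
    def test_published_style_ratio_rounds_to_39_percent(self):
        from nestscan import SpliceCall

        calls = [SpliceCall(f"e{i}", "skip", "") for i in range(9)] + \
                [SpliceCall(f"r{i}", "retain", "") for i in range(14)]
        sf = skip_fraction(calls)
        assert (sf["n_skip"], sf["n_informative"]) == (9, 23)
        assert sf["percent"] == 39

    def test_all_retain_is_zero_percent(self):
        from nestscan import SpliceCall

        sf = skip_fraction([SpliceCall("a", "retain", "")] * 5)
        assert sf["percent"] == 0

    def test_no_informative_calls_flagged(self):
        from nestscan import SpliceCall

        sf = skip_fraction([SpliceCall("a", "indeterminate", "")])
        assert sf["fraction"] is None and sf["percent"] is None

    def test_estimator_recovers_planted_skip_rate(self, splice_reference):
        p, n = 0.4, 200
        ests, labels = make_ests(splice_reference, p, n, 0.01, seed=3)
        hits = [align_est(s, splice_reference, i) for i, s in ests]
        kept, dropped = filter_hits(hits, splice_reference)
        assert not dropped  # generator windows guarantee informative ESTs
        calls = [call_as4(h, splice_reference) for h in kept]
        sf = skip_fraction(calls)
        se = (p * (1 - p) / n) ** 0.5
        assert abs(float(sf["fraction"]) - p) <= 3 * se
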