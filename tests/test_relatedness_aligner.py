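"""Local alignment: oracle equivalence, screen behaviour, tripartite views."""

import random

import pytest

from oracles import dinucleotide_shuffle, local_alignment_score
from snofrag.relatedness_aligner import (
    ContainmentError,
    RelatednessPolicy,
    local_align,
    render_tripartite,
    screen_catalog_pairs,
)
from snofrag.sequence_io import AlphabetError, SmallRNARead, SnoRNARecord

from conftest import random_dna


class TestLocalAlign:
    def test_identical_sequences_align_fully(self):
        seq = random_dna(random.Random(3), 68)
        res = local_align(seq, seq)
        assert res.identity_pct == 100.0
        assert res.aligned_length == 68
        assert res.n_gap_columns == 0
        assert (res.query_start, res.query_end) == (0, 68)

    def test_85_percent_boundary_case(self):
        """40-nt pair differing at 6 interior positions, gaps forbidden by
        high penalties: exactly 34/40 = 85% identity over 40 columns."""
        rng = random.Random(9)
        a = random_dna(rng, 40)
        b = list(a)
        for pos in (5, 11, 17, 23, 29, 34):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        policy = RelatednessPolicy(gap_open=-100.0, gap_extend=-100.0)
        res = local_align(a + "GG", "CC" + "".join(b), policy)
        # interior mismatches keep the full 40-column alignment optimal
        assert res.aligned_length == 40
        assert res.identity_pct == pytest.approx(85.0)
        assert res.passes(RelatednessPolicy()) is True

    def test_score_equals_recursive_dp_oracle(self):
        rng = random.Random(77)
        for _ in range(200):
            q = random_dna(rng, rng.randint(1, 12))
            s = random_dna(rng, rng.randint(1, 12))
            assert local_align(q, s).score == pytest.approx(
                local_alignment_score(q, s)
            ), (q, s)

    def test_score_equals_biopython_on_longer_pairs(self):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        rng = random.Random(13)
        for _ in range(40):
            q = random_dna(rng, rng.randint(30, 150))
            s = random_dna(rng, rng.randint(30, 150))
            assert local_align(q, s).score == pytest.approx(aligner.score(q, s))

    def test_score_symmetric_for_symmetric_scoring(self):
        rng = random.Random(31)
        for _ in range(50):
            q = random_dna(rng, rng.randint(5, 40))
            s = random_dna(rng, rng.randint(5, 40))
            assert local_align(q, s).score == local_align(s, q).score

    def test_fixing_a_mismatch_never_lowers_the_score(self):
        rng = random.Random(55)
        tested = 0
        while tested < 30:
            q = random_dna(rng, rng.randint(10, 30))
            s = random_dna(rng, rng.randint(10, 30))
            res = local_align(q, s)
            if res.n_gap_columns or res.n_mismatches == 0:
                continue
            # gapless alignment: columns pair q[qs+k] with s[ss+k]
            for k in range(res.aligned_length):
                if q[res.query_start + k] != s[res.subject_start + k]:
                    s2 = (s[: res.subject_start + k]
                          + q[res.query_start + k]
                          + s[res.subject_start + k + 1:])
                    assert local_align(q, s2).score >= res.score
                    tested += 1
                    break

    def test_column_bookkeeping_is_consistent(self):
        rng = random.Random(99)
        for _ in range(50):
            q = random_dna(rng, rng.randint(10, 60))
            s = random_dna(rng, rng.randint(10, 60))
            r = local_align(q, s)
            assert r.n_matches + r.n_mismatches + r.n_gap_columns == r.aligned_length
            if r.aligned_length:
                assert r.identity_pct == pytest.approx(
                    100.0 * r.n_matches / r.aligned_length)

    def test_alphabet_and_empty_inputs_rejected(self):
        with pytest.raises(AlphabetError):
            local_align("ACGX", "ACGT")
        with pytest.raises(ValueError):
            local_align("", "ACGT")


class TestScreen:
    def test_planted_identity_windows_all_pass(self):
        """Hairpins built by copying a 70-nt window from each snoRNA pass
        at 100% identity over (at least) the 70 copied columns."""
        rng = random.Random(2)
        snos = [SnoRNARecord(id=f"sno{i}", sequence=random_dna(rng, 120))
                for i in range(8)]
        hairpins = [SnoRNARecord(id=f"mir{i}", sequence=s.sequence[20:90])
                    for i, s in enumerate(snos)]
        passing, summary = screen_catalog_pairs(snos, hairpins)
        planted = [r for r in passing if r.query_id[3:] == r.subject_id[3:]]
        assert len(planted) == 8
        assert all(r.identity_pct == 100.0 for r in planted)
        assert summary.mean_aligned_length >= 70

    def test_shuffled_catalogs_yield_no_passing_pairs(self):
        """Dinucleotide-shuffled hairpins retain composition but lose the
        planted homology: nothing reaches 85% identity over 40 columns."""
        rng = random.Random(41)
        snos = [SnoRNARecord(id=f"sno{i}", sequence=random_dna(rng, rng.randint(70, 150)))
                for i in range(20)]
        hairpins = []
        for i, s in enumerate(snos):
            shuffled = dinucleotide_shuffle(s.sequence[:90], rng)
            hairpins.append(SnoRNARecord(id=f"mir{i}", sequence=shuffled))
        passing, summary = screen_catalog_pairs(snos, hairpins)
        assert summary.n_passing_pairs == 0
        assert passing == []

    def test_planted_95pct_windows_recovered(self):
        """42 of 60 snoRNAs carry a ~95%-identity 68-nt window planted into a
        hairpin; the screen recovers exactly those 42 snoRNAs and the summary
        means stay near the planted values."""
        rng = random.Random(17)
        snos = [SnoRNARecord(id=f"sno{i:02d}", sequence=random_dna(rng, 160))
                for i in range(60)]
        hairpins = []
        planted_ids = []
        for i in range(42):
            window = list(snos[i].sequence[30:98])  # 68 nt
            # 3 interior substitutions -> 65/68 = 95.6% planted identity
            for pos in (12, 33, 54):
                window[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[pos]]
            hairpins.append(SnoRNARecord(
                id=f"mir{i:02d}",
                sequence=random_dna(rng, 20) + "".join(window) + random_dna(rng, 20),
            ))
            planted_ids.append(snos[i].id)
        for i in range(42, 56):  # unrelated hairpins
            hairpins.append(SnoRNARecord(id=f"mir{i:02d}",
                                         sequence=random_dna(rng, 108)))
        passing, summary = screen_catalog_pairs(snos, hairpins)
        assert {r.query_id for r in passing} == set(planted_ids)
        assert summary.n_queries_passing == 42
        assert summary.mean_identity_pct == pytest.approx(65 / 68 * 100, abs=2.0)
        assert summary.mean_aligned_length == pytest.approx(68, abs=3)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            screen_catalog_pairs([], [])


class TestTripartite:
    def test_identical_trio_marks_every_column(self):
        seq = random_dna(random.Random(8), 30)
        block = render_tripartite(seq, SnoRNARecord(id="s", sequence=seq),
                                  SmallRNARead(id="r", sequence=seq))
        genome, marker, sno, read = block.splitlines()
        assert genome == sno == read == seq
        assert marker == "|" * 30

    def test_internal_read_window_gets_pipes_rest_stars(self):
        seq = random_dna(random.Random(12), 60)
        block = render_tripartite(
            seq, SnoRNARecord(id="s", sequence=seq),
            SmallRNARead(id="r", sequence=seq[20:40]))
        marker = block.splitlines()[1]
        assert marker == "*" * 20 + "|" * 20 + "*" * 20

    def test_genome_snorna_mismatch_in_read_window_unmarked(self):
        rng = random.Random(14)
        sno_seq = random_dna(rng, 50)
        genome = list(sno_seq)
        genome[25] = {"A": "C", "C": "G", "G": "T", "T": "A"}[genome[25]]
        block = render_tripartite(
            "".join(genome), SnoRNARecord(id="s", sequence=sno_seq),
            SmallRNARead(id="r", sequence=sno_seq[18:38]))
        marker = block.splitlines()[1]
        assert marker[25] == " "
        assert set(marker[18:25]) == {"|"} and set(marker[26:38]) == {"|"}

    def test_read_not_contained_raises(self):
        seq = random_dna(random.Random(4), 40)
        with pytest.raises(ContainmentError):
            render_tripartite(seq, SnoRNARecord(id="s", sequence=seq),
                              SmallRNARead(id="r", sequence="T" * 20 + "A"))
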