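"""Perfect-match alignment: policies, hit semantics, brute-force equivalence."""

import random

import pytest

from oracles import brute_force_matches
from snofrag.exact_matcher import (
    CELL_LINE_POLICY,
    SRA_SURVEY_POLICY,
    MatchPolicy,
    PerfectMatcher,
    align_read_set,
    find_perfect_matches,
)
from snofrag.sequence_io import (
    SampleLibrary,
    SmallRNARead,
    SnoRNARecord,
    reverse_complement,
)

from conftest import random_dna


MIMIC = "GCCAAGGATGAGAACTCTAATCTGATTT"          # sense sdRNA mimic, 28 nt
INHIBITOR = "AAATCAGATTAGAGTTCTCATCCTTGGCT"     # antisense inhibitor, 29 nt


def test_mimic_aligns_inside_revcomp_of_inhibitor():
    """The published mimic/inhibitor pair: the mimic must sit at offset 1 of
    the inhibitor's reverse complement (a 28-nt perfect match)."""
    catalog = [SnoRNARecord(id="sd93", sequence=reverse_complement(INHIBITOR))]
    read = SmallRNARead(id="mimic", sequence=MIMIC)
    hits = find_perfect_matches(read, catalog, CELL_LINE_POLICY)
    assert len(hits) == 1
    aln = hits[0]
    assert (aln.start, aln.end, aln.match_length, aln.strand) == (1, 29, 28, "+")


def test_minimum_length_gate():
    ref = SnoRNARecord(id="s", sequence="ACGTACGTACGTACGTACGT")
    short = SmallRNARead(id="r", sequence=ref.sequence[:15])
    assert find_perfect_matches(short, [ref], CELL_LINE_POLICY) == []


def test_policy_contrast_on_30nt_read():
    """A 30-nt full match is rejected by the 16-28 nt cell-line policy but
    accepted by the unbounded SRA-survey policy."""
    ref = SnoRNARecord(id="s", sequence=random_dna(random.Random(1), 60))
    read = SmallRNARead(id="r", sequence=ref.sequence[10:40])
    assert find_perfect_matches(read, [ref], CELL_LINE_POLICY) == []
    hits = find_perfect_matches(read, [ref], SRA_SURVEY_POLICY)
    assert [(h.start, h.end) for h in hits] == [(10, 40)]


def test_reads_with_n_never_match():
    ref = SnoRNARecord(id="s", sequence="ACGT" * 10)
    read = SmallRNARead(id="r", sequence="ACGTACGTACGTACGTN")
    assert find_perfect_matches(read, [ref], CELL_LINE_POLICY) == []


def test_antisense_matching_only_under_both_strands():
    ref = SnoRNARecord(id="s", sequence=random_dna(random.Random(7), 80))
    probe = reverse_complement(ref.sequence[20:42])
    read = SmallRNARead(id="r", sequence=probe)
    assert find_perfect_matches(read, [ref], CELL_LINE_POLICY) == []
    both = MatchPolicy(min_len=16, max_len=28, strands="both")
    hits = find_perfect_matches(read, [ref], both)
    assert [(h.start, h.end, h.strand) for h in hits] == [(20, 42, "-")]


def test_total_hits_semantics_many_copies():
    """1581 copies of one 22-nt reference substring produce 1581 hits on
    that snoRNA (hits count read placements, not distinct sequences)."""
    rng = random.Random(11)
    ref = SnoRNARecord(id="sno-1b", sequence=random_dna(rng, 100))
    frag = ref.sequence[5:27]
    lib = SampleLibrary(
        sample_id="s", total_reads=1581,
        reads=[SmallRNARead(id=f"r{i}", sequence=frag) for i in range(1581)],
    )
    _, counts = align_read_set(lib, [ref], CELL_LINE_POLICY)
    assert counts["sno-1b"] == 1581


def test_no_matching_reads_gives_zero_counts(small_catalog):
    lib = SampleLibrary(
        sample_id="s", total_reads=2,
        reads=[SmallRNARead(id="r1", sequence="A" * 20),
               SmallRNARead(id="r2", sequence="C" * 20)],
    )
    # none of the random references contains a 20-mer homopolymer
    _, counts = align_read_set(lib, small_catalog, CELL_LINE_POLICY)
    assert set(counts.values()) == {0}


def test_empty_catalog_is_a_configuration_error():
    lib = SampleLibrary(sample_id="s", total_reads=0, reads=[])
    with pytest.raises(ValueError, match="catalog"):
        align_read_set(lib, [], CELL_LINE_POLICY)


def test_sampled_reads_recover_their_true_offsets():
    rng = random.Random(23)
    catalog = [SnoRNARecord(id=f"s{i}", sequence=random_dna(rng, 200))
               for i in range(4)]
    matcher = PerfectMatcher(catalog, CELL_LINE_POLICY)
    for trial in range(100):
        ref = catalog[rng.randrange(4)]
        length = rng.randint(16, 28)
        start = rng.randrange(ref.length - length + 1)
        read = SmallRNARead(id=f"t{trial}",
                            sequence=ref.sequence[start : start + length])
        placements = {(h.snorna_id, h.start, h.end) for h in matcher.find(read)}
        assert (ref.id, start, start + length) in placements


@pytest.mark.parametrize("strands", ["sense", "both"])
def test_equivalence_with_brute_force_oracle(strands):
    """Matcher output equals a brute-force scan over every offset of every
    reference, for random catalogs and a mix of planted and random reads."""
    rng = random.Random(97)
    for case in range(60):
        catalog = [
            SnoRNARecord(id=f"c{case}_{i}", sequence=random_dna(
                rng, rng.randint(40, 300)))
            for i in range(rng.randint(1, 10))
        ]
        policy = MatchPolicy(
            min_len=16,
            max_len=rng.choice([28, None]),
            strands=strands,
        )
        matcher = PerfectMatcher(catalog, policy)
        reads = []
        for j in range(10):
            if rng.random() < 0.5:
                ref = rng.choice(catalog)
                ln = rng.randint(14, min(32, ref.length))
                st = rng.randrange(ref.length - ln + 1)
                seq = ref.sequence[st : st + ln]
                if rng.random() < 0.3:
                    seq = reverse_complement(seq)
            else:
                ln = rng.randint(14, 32)
                seq = random_dna(rng, ln)
            reads.append(SmallRNARead(id=f"r{j}", sequence=seq))
        for read in reads:
            got = [(h.snorna_id, h.start, h.end, h.strand)
                   for h in matcher.find(read)]
            expected = brute_force_matches(read.sequence, read.id, catalog, policy)
            assert got == expected


def test_tightening_the_window_never_adds_alignments():
    rng = random.Random(5)
    catalog = [SnoRNARecord(id="s", sequence=random_dna(rng, 250))]
    reads = [
        SmallRNARead(
            id=f"r{i}",
            sequence=catalog[0].sequence[rng.randrange(220): ][: rng.randint(16, 32)],
        )
        for i in range(50)
    ]
    lib = SampleLibrary(sample_id="x", total_reads=50, reads=reads)
    wide, _ = align_read_set(lib, catalog, MatchPolicy(min_len=16, max_len=None))
    narrow, _ = align_read_set(lib, catalog, MatchPolicy(min_len=18, max_len=28))
    assert set(narrow) <= set(wide)


def test_multi_placement_count_all_vs_best_only():
    """A read at k placements yields k alignments under 'all', 1 under 'best'."""
    ref = SnoRNARecord(id="rep", sequence="TTTT" + "ACGTACGTACGTACGTACGT" * 2 + "TTTT")
    read = SmallRNARead(id="r", sequence="ACGTACGTACGTACGT")  # 16-mer, repeated
    lib = SampleLibrary(sample_id="s", total_reads=1, reads=[read])
    all_alns, all_counts = align_read_set(
        lib, [ref], MatchPolicy(min_len=16, max_len=28, multi_reference="all"))
    best_alns, best_counts = align_read_set(
        lib, [ref], MatchPolicy(min_len=16, max_len=28, multi_reference="best"))
    assert len(all_alns) > 1
    assert all_counts["rep"] == len(all_alns)
    assert len(best_alns) == 1
    assert best_counts["rep"] == 1
    # the 'best' placement is the deterministic first one
    assert best_alns[0] == all_alns[0]
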