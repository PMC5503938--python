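"""Generator determinism, planted-truth consistency, recovery properties."""

import pytest

from snofrag.cohort_analyzer import result_from_counts, subtype_prevalence
from snofrag.exact_matcher import (
    CELL_LINE_POLICY,
    SRA_SURVEY_POLICY,
    align_read_set,
    find_perfect_matches,
)
from snofrag.excision_profiler import build_profile, call_sdrna
from snofrag.sequence_io import SmallRNARead
from snofrag.synthetic_data import (
    SimulationConfig,
    SubtypeDesign,
    simulate_catalog,
    simulate_cohort,
    simulate_library,
    write_fastq,
)


class TestCatalog:
    def test_same_seed_is_byte_identical(self, tmp_path):
        runs = []
        for _ in range(2):
            catalog, intervals = simulate_catalog(n_snornas=5, seed=1)
            runs.append([(r.id, r.sequence) for r in catalog] +
                        sorted(intervals.items()))
        assert runs[0] == runs[1]

    def test_degenerate_length_range(self):
        catalog, _ = simulate_catalog(n_snornas=8, length_range=(60, 60), seed=2)
        assert {r.length for r in catalog} == {60}

    def test_planted_fragment_relocates_exactly(self):
        # survey policy: planted fragments may be 29 nt, above the 28 nt
        # cell-line cap
        catalog, intervals = simulate_catalog(n_snornas=10, seed=3)
        for rec in catalog:
            s, e = intervals[rec.id]
            frag = rec.sequence[s:e]
            hits = find_perfect_matches(
                SmallRNARead(id="q", sequence=frag), [rec], SRA_SURVEY_POLICY)
            assert (s, e) in {(h.start, h.end) for h in hits}

    def test_interval_must_fit(self):
        with pytest.raises(ValueError):
            simulate_catalog(length_range=(25, 60), sdrna_length_range=(21, 29))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(background_rate=0.7, offtarget_rate=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(excision_fidelity=1.5)


class TestLibrary:
    def make(self, fidelity, seed, n_reads=2000, background=0.0):
        catalog, intervals = simulate_catalog(
            n_snornas=1, length_range=(120, 120), sdrna_length_range=(22, 22),
            five_prime_anchor_prob=1.0, seed=seed)
        lib, truth = simulate_library(
            catalog, intervals, {catalog[0].id: (1 - background) * 1e6},
            library_size=n_reads, fidelity=fidelity,
            background_rate=background, seed=seed + 100)
        return catalog, intervals, lib, truth

    def test_noiseless_limit_recovers_fraction_one(self):
        catalog, intervals, lib, _ = self.make(fidelity=1.0, seed=4)
        alns, _ = align_read_set(lib, catalog, CELL_LINE_POLICY)
        profile = build_profile(alns, snorna_id=catalog[0].id)
        assert profile.fixed_fraction == 1.0
        assert profile.modal_interval == intervals[catalog[0].id]

    def test_fidelity_095_recovered_within_binomial_tolerance(self):
        """At fidelity 0.95 and 2000 reads the exact-boundary fraction lands
        within +/-0.03 of 0.95 and the modal interval is the planted one."""
        catalog, intervals, lib, truth = self.make(fidelity=0.95, seed=7)
        alns, _ = align_read_set(lib, catalog, CELL_LINE_POLICY)
        profile = build_profile(alns, snorna_id=catalog[0].id,
                                delta5=0, delta3=0)
        assert profile.modal_interval == intervals[catalog[0].id]
        assert profile.fixed_fraction == pytest.approx(0.95, abs=0.03)
        # and the realised fraction agrees with the generator's own tally
        sid = catalog[0].id
        assert profile.modal_family_count == truth.n_fixed[sid]

    def test_background_only_library_yields_no_calls(self):
        catalog, intervals = simulate_catalog(
            n_snornas=3, length_range=(150, 200), seed=11)
        lib, _ = simulate_library(
            catalog, intervals, {}, library_size=3000,
            background_rate=1.0, seed=12)
        alns, _ = align_read_set(lib, catalog, CELL_LINE_POLICY)
        for rec in catalog:
            profile = build_profile(
                [a for a in alns if a.snorna_id == rec.id], snorna_id=rec.id)
            call = call_sdrna(profile, rec)
            assert call.is_fixed_position is False

    def test_same_seed_fastq_byte_identical(self, tmp_path):
        paths = []
        for i in range(2):
            catalog, intervals, lib, _ = self.make(fidelity=0.9, seed=21)
            p = tmp_path / f"run{i}.fastq"
            write_fastq(lib, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_empty_library_warns(self, caplog):
        catalog, intervals = simulate_catalog(n_snornas=1, seed=1)
        with caplog.at_level("WARNING"):
            lib, truth = simulate_library(catalog, intervals, {}, 0)
        assert lib.total_reads == 0 and truth.library_size == 0

    def test_overcommitted_library_rejected(self):
        catalog, intervals = simulate_catalog(n_snornas=1, seed=1)
        with pytest.raises(ValueError, match="exceed"):
            simulate_library(catalog, intervals, {catalog[0].id: 2e6},
                             library_size=1000)

    def test_offtarget_reads_never_hit_the_catalog(self):
        catalog, intervals = simulate_catalog(n_snornas=2, seed=31)
        lib, truth = simulate_library(catalog, intervals, {},
                                      library_size=500, seed=32)
        assert truth.n_offtarget == 500
        _, counts = align_read_set(lib, catalog, CELL_LINE_POLICY)
        assert set(counts.values()) == {0}


class TestCohort:
    DESIGN = [
        SubtypeDesign("TNBC", 29, 12),
        SubtypeDesign("LuminalA", 62, 24),
        SubtypeDesign("LuminalB-HER2pos", 14, 13),
        SubtypeDesign("normal", 11, 0),
    ]

    def test_planted_prevalence_is_reproduced_exactly(self):
        """A cohort planted at the published per-subtype expression counts
        yields exactly 41.4 / 38.7 / 92.9 / 0.0 percent prevalence."""
        truth = simulate_cohort(self.DESIGN, seed=1)
        results = [
            result_from_counts(s.sample_id, s.subtype_label, s.total_reads,
                               s.query_hits)
            for s in truth.samples
        ]
        rows = subtype_prevalence(results)
        assert [(r.subtype_label, r.percentage) for r in rows] == [
            ("TNBC", 41.4), ("LuminalA", 38.7),
            ("LuminalB-HER2pos", 92.9), ("normal", 0.0),
        ]

    def test_flags_match_planted_truth_for_every_sample(self):
        truth = simulate_cohort(self.DESIGN, seed=9)
        for s in truth.samples:
            r = result_from_counts(s.sample_id, s.subtype_label,
                                   s.total_reads, s.query_hits)
            assert r.expressed == s.expressed

    def test_all_expressed_design(self):
        truth = simulate_cohort([SubtypeDesign("X", 5, 5)], seed=2)
        results = [result_from_counts(s.sample_id, s.subtype_label,
                                      s.total_reads, s.query_hits)
                   for s in truth.samples]
        assert subtype_prevalence(results)[0].percentage == 100.0

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort([])
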