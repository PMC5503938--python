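"""End-to-end orchestration of the two analyses.

``run_compare`` is the two-sample differential screen: align both libraries
to the catalog under the cell-line policy, profile excision per snoRNA,
call sdRNAs on the pooled alignments (so both samples are quantified at the
same fragment interval), build snoRNA- and sdRNA-level expression records,
and emit the differential table with fold tiers plus the processing-
preference table.

``run_cohort`` quantifies one query sdRNA across a manifest of labeled
samples and reports per-subtype expression prevalence.

All output files are deterministic for fixed inputs (no timestamps); on any
stage failure the partial outputs written by the run are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import cohort_analyzer as ca
from . import excision_profiler as ep
from . import exact_matcher as em
from . import quantifier as qt
from . import sequence_io as sio
from .config import RunConfig

log = logging.getLogger(__name__)


@dataclass
class CompareResult:
    catalog: list[sio.SnoRNARecord]
    hits_a: dict[str, int]
    hits_b: dict[str, int]
    pooled_calls: dict[str, ep.SdRNACall]
    snorna_differential: list[qt.DifferentialRecord]
    sdrna_differential: list[qt.DifferentialRecord]
    processing: list[qt.ProcessingRecord]
    expression: list[qt.ExpressionRecord]


class _OutputTracker:
    """Removes files written by a failed run so no partial bundle remains."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        return p

    def rollback(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def compare_libraries(
    lib_a: sio.SampleLibrary,
    lib_b: sio.SampleLibrary,
    catalog: Sequence[sio.SnoRNARecord],
    config: RunConfig | None = None,
) -> CompareResult:
    """Two-sample sdRNA screen on in-memory libraries (no file output)."""
    config = config or RunConfig()
    policy = config.match_policy
    aligns_a, hits_a = em.align_read_set(lib_a, catalog, policy)
    aligns_b, hits_b = em.align_read_set(lib_b, catalog, policy)
    by_sno_a: dict[str, list[em.ReadAlignment]] = {r.id: [] for r in catalog}
    by_sno_b: dict[str, list[em.ReadAlignment]] = {r.id: [] for r in catalog}
    for a in aligns_a:
        by_sno_a[a.snorna_id].append(a)
    for a in aligns_b:
        by_sno_b[a.snorna_id].append(a)

    # the sdRNA interval is defined once, on the pooled alignments, so that
    # both samples are counted at the same fragment
    pooled_calls: dict[str, ep.SdRNACall] = {}
    for rec in catalog:
        profile = ep.build_profile(
            by_sno_a[rec.id] + by_sno_b[rec.id], snorna_id=rec.id,
            delta5=config.delta5, delta3=config.delta3,
        )
        pooled_calls[rec.id] = ep.call_sdrna(
            profile, rec, fixed_threshold=config.fixed_threshold,
            min_hits=config.min_hits,
        )

    total_a = config.cpm_total(lib_a)
    total_b = config.cpm_total(lib_b)
    expr: list[qt.ExpressionRecord] = []
    sno_a: list[qt.ExpressionRecord] = []
    sno_b: list[qt.ExpressionRecord] = []
    sd_a: list[qt.ExpressionRecord] = []
    sd_b: list[qt.ExpressionRecord] = []
    for rec in catalog:
        ra = qt.make_expression_record(rec.id, lib_a.sample_id, hits_a[rec.id],
                                       total_a, config.expression_threshold_cpm)
        rb = qt.make_expression_record(rec.id, lib_b.sample_id, hits_b[rec.id],
                                       total_b, config.expression_threshold_cpm)
        sno_a.append(ra)
        sno_b.append(rb)
        expr.extend([ra, rb])
        call = pooled_calls[rec.id]
        if call.is_fixed_position:
            fid = f"sdRNA:{rec.id}"
            fam_a = ep.count_family_hits(by_sno_a[rec.id], (call.start, call.end),
                                         config.delta5, config.delta3)
            fam_b = ep.count_family_hits(by_sno_b[rec.id], (call.start, call.end),
                                         config.delta5, config.delta3)
            da = qt.make_expression_record(fid, lib_a.sample_id, fam_a, total_a,
                                           config.expression_threshold_cpm)
            db = qt.make_expression_record(fid, lib_b.sample_id, fam_b, total_b,
                                           config.expression_threshold_cpm)
            sd_a.append(da)
            sd_b.append(db)
            expr.extend([da, db])

    sno_diff = qt.differential_table(
        sno_a, sno_b, pseudocount=config.pseudocount, min_fold=config.min_fold,
        tiers=config.tiers, expression_threshold=config.expression_threshold_cpm,
    )
    sd_diff = qt.differential_table(
        sd_a, sd_b, pseudocount=config.pseudocount, min_fold=config.min_fold,
        tiers=config.tiers, expression_threshold=config.expression_threshold_cpm,
    )
    sd_cpm_a = {r.feature_id: r.cpm for r in sd_a}
    sd_cpm_b = {r.feature_id: r.cpm for r in sd_b}
    sno_cpm_a = {r.feature_id: r.cpm for r in sno_a}
    sno_cpm_b = {r.feature_id: r.cpm for r in sno_b}
    processing = [
        qt.processing_preference(
            rec.id,
            sd_cpm_a[f"sdRNA:{rec.id}"], sno_cpm_a[rec.id],
            sd_cpm_b[f"sdRNA:{rec.id}"], sno_cpm_b[rec.id],
            pseudocount=config.pseudocount, cutoff=config.preference_cutoff,
        )
        for rec in catalog
        if f"sdRNA:{rec.id}" in sd_cpm_a
    ]
    return CompareResult(
        catalog=list(catalog), hits_a=hits_a, hits_b=hits_b,
        pooled_calls=pooled_calls, snorna_differential=sno_diff,
        sdrna_differential=sd_diff, processing=processing, expression=expr,
    )


def run_compare(
    sample_a: str | Path,
    sample_b: str | Path,
    catalog_path: str | Path,
    outdir: str | Path,
    config: RunConfig | None = None,
) -> CompareResult:
    """File-level two-sample screen; writes the full report bundle."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracker = _OutputTracker(outdir)
    try:
        log.info("stage: ingest")
        catalog = sio.read_fasta(catalog_path)
        if not catalog:
            raise ValueError("catalog is empty")
        lib_a = sio.read_reads(sample_a, config.min_read_len, config.max_read_len)
        lib_b = sio.read_reads(sample_b, config.min_read_len, config.max_read_len)
        log.info("stage: align+profile+quantify")
        result = compare_libraries(lib_a, lib_b, catalog, config)

        log.info("stage: report")
        policy = config.match_policy
        aligns_a, _ = em.align_read_set(lib_a, catalog, policy)
        aligns_b, _ = em.align_read_set(lib_b, catalog, policy)
        em.write_alignments_tsv(aligns_a, tracker.path("alignments_a.tsv"))
        em.write_alignments_tsv(aligns_b, tracker.path("alignments_b.tsv"))
        profiles = [
            ep.build_profile(
                [x for x in aligns_a + aligns_b if x.snorna_id == rec.id],
                snorna_id=rec.id, delta5=config.delta5, delta3=config.delta3,
            )
            for rec in catalog
        ]
        ep.write_profile_tsv(profiles, tracker.path("excision_profiles.tsv"))
        ep.write_calls_tsv(result.pooled_calls.values(),
                           tracker.path("sdrna_calls.tsv"))
        qt.expression_matrix(result.expression).to_csv(
            tracker.path("expression_cpm.tsv"), sep="\t", float_format="%.6f")
        qt.write_differential_tsv(result.snorna_differential,
                                  tracker.path("differential_snorna.tsv"))
        qt.write_differential_tsv(result.sdrna_differential,
                                  tracker.path("differential_sdrna.tsv"))
        qt.write_processing_tsv(result.processing,
                                tracker.path("processing_preference.tsv"))
        config.write_yaml(tracker.path("run_config.yaml"))
        return result
    except Exception:
        tracker.rollback()
        raise


def run_cohort(
    manifest_path: str | Path,
    query_path: str | Path,
    outdir: str | Path,
    config: RunConfig | None = None,
    plot: bool = False,
) -> tuple[list[ca.CohortSampleResult], list[ca.SubtypePrevalence]]:
    """Cohort prevalence analysis; writes per-sample and prevalence reports."""
    config = config or RunConfig(mode="sra_survey")
    if config.mode != "sra_survey":
        log.info("cohort analysis forces the sra_survey policy (>=16 nt)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracker = _OutputTracker(outdir)
    try:
        queries = sio.read_fasta(query_path)
        if len(queries) != 1:
            raise ValueError(
                f"query FASTA must contain exactly one sequence (found "
                f"{len(queries)})"
            )
        manifest = ca.read_manifest(manifest_path)
        results, prevalence, skipped = ca.analyze_cohort(
            manifest, queries[0].sequence,
            policy=em.SRA_SURVEY_POLICY,
            expression_threshold=config.expression_threshold_cpm,
        )
        ca.write_results_tsv(results, tracker.path("cohort_samples.tsv"))
        ca.write_prevalence_tsv(prevalence, tracker.path("prevalence.tsv"))
        ca.write_prevalence_json(prevalence, tracker.path("prevalence.json"))
        if skipped:
            tracker.path("skipped_samples.txt").write_text(
                "\n".join(skipped) + "\n")
        if plot:
            ca.plot_prevalence(prevalence, tracker.path("prevalence.png"))
        config.write_yaml(tracker.path("run_config.yaml"))
        return results, prevalence
    except Exception:
        tracker.rollback()
        raise


__all__ = ["CompareResult", "compare_libraries", "run_compare", "run_cohort"]
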