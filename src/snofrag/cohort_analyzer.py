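"""Cohort-wide quantification of a query sdRNA and subtype prevalence.

Given a manifest of subtype-labelled small RNA-seq samples, quantifies one
query sequence (e.g. an sdRNA) in every sample under the SRA-survey policy
(>=16 nt perfect matches, no upper length bound) and reports, per subtype,
how many samples express the query at >=250 CPM and the corresponding
percentage (half-up rounding to one decimal: 12/29 -> 41.4, 13/14 -> 92.9).

Samples may be supplied either as read files (FASTA/FASTQ) or pre-counted
(total_reads, query_hits) rows, so cohorts of realistic size run at desk
scale.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from .exact_matcher import MatchPolicy, SRA_SURVEY_POLICY, align_read_set
from .quantifier import DEFAULT_EXPRESSION_THRESHOLD_CPM, compute_cpm, flag_expressed
from .sequence_io import SampleLibrary, SnoRNARecord, read_reads

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSampleResult:
    sample_id: str
    subtype_label: str
    total_reads: int
    query_hits: int
    query_cpm: float
    expressed: bool


@dataclass(frozen=True)
class SubtypePrevalence:
    subtype_label: str
    n_expressed: int
    n_total: int
    percentage: float  # half-up rounded to one decimal


@dataclass(frozen=True)
class ManifestRow:
    """One manifest line: either a path to reads or pre-counted totals."""

    sample_id: str
    subtype_label: str
    path: Path | None = None
    total_reads: int | None = None
    query_hits: int | None = None
    exclude: bool = False


def quantify_query_in_sample(
    query: str,
    library: SampleLibrary,
    policy: MatchPolicy = SRA_SURVEY_POLICY,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD_CPM,
) -> CohortSampleResult:
    """Count reads perfectly matching within the query sequence.

    Hits follow the accepted-alignment semantics of the matcher (each
    placement of each read counts once under the default policy); CPM uses
    the library's pre-filter read total as denominator.
    """
    if library.total_reads <= 0:
        raise ValueError(f"library '{library.sample_id}' has no reads")
    if len(query) < policy.min_len:
        raise ValueError(
            f"query length {len(query)} is below the policy minimum "
            f"{policy.min_len}"
        )
    catalog = [SnoRNARecord(id="query", sequence=query)]
    _, counts = align_read_set(library, catalog, policy)
    hits = counts["query"]
    cpm = compute_cpm(hits, library.total_reads)
    return CohortSampleResult(
        sample_id=library.sample_id, subtype_label=library.subtype_label,
        total_reads=library.total_reads, query_hits=hits, query_cpm=cpm,
        expressed=flag_expressed(cpm, expression_threshold),
    )


def result_from_counts(
    sample_id: str,
    subtype_label: str,
    total_reads: int,
    query_hits: int,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD_CPM,
) -> CohortSampleResult:
    """Build a sample result from pre-counted hits (no raw reads needed)."""
    cpm = compute_cpm(query_hits, total_reads)
    return CohortSampleResult(
        sample_id=sample_id, subtype_label=subtype_label,
        total_reads=total_reads, query_hits=query_hits, query_cpm=cpm,
        expressed=flag_expressed(cpm, expression_threshold),
    )


def round_percentage(n_expressed: int, n_total: int) -> float:
    """100*n/total, half-up to one decimal (exact decimal arithmetic)."""
    pct = Decimal(100 * n_expressed) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def subtype_prevalence(
    results: Sequence[CohortSampleResult],
) -> list[SubtypePrevalence]:
    """Per-subtype expressing-sample counts and percentage.

    Subtypes appear in first-seen order; samples without a subtype label
    are skipped with a warning.
    """
    order: list[str] = []
    expressed: dict[str, int] = {}
    total: dict[str, int] = {}
    for r in results:
        if not r.subtype_label:
            log.warning("sample %s has no subtype label; omitted", r.sample_id)
            continue
        if r.subtype_label not in total:
            order.append(r.subtype_label)
            total[r.subtype_label] = 0
            expressed[r.subtype_label] = 0
        total[r.subtype_label] += 1
        if r.expressed:
            expressed[r.subtype_label] += 1
    return [
        SubtypePrevalence(
            subtype_label=s, n_expressed=expressed[s], n_total=total[s],
            percentage=round_percentage(expressed[s], total[s]),
        )
        for s in order
    ]


def read_manifest(path: str | Path) -> list[ManifestRow]:
    """TSV manifest: sample_id, subtype_label, and either a ``path`` column
    or ``total_reads``+``query_hits`` columns; optional ``exclude`` column
    ('1'/'true' drops the row from analysis, mirroring cohort curation)."""
    path = Path(path)
    rows: list[ManifestRow] = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValueError(f"{path}: manifest must have a sample_id column")
        for rec in reader:
            p = rec.get("path") or None
            rows.append(ManifestRow(
                sample_id=rec["sample_id"],
                subtype_label=rec.get("subtype_label", ""),
                path=Path(p) if p else None,
                total_reads=int(rec["total_reads"]) if rec.get("total_reads") else None,
                query_hits=int(rec["query_hits"]) if rec.get("query_hits") else None,
                exclude=str(rec.get("exclude", "")).strip().lower() in ("1", "true", "yes"),
            ))
    return rows


def analyze_cohort(
    manifest: Sequence[ManifestRow],
    query: str,
    policy: MatchPolicy = SRA_SURVEY_POLICY,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD_CPM,
) -> tuple[list[CohortSampleResult], list[SubtypePrevalence], list[str]]:
    """Quantify the query in every manifest sample and compute prevalence.

    Returns (per-sample results, prevalence rows, skipped sample ids).
    Rows flagged exclude are dropped; rows pointing at missing read files
    are skipped with a warning and listed in the third return value.
    """
    results: list[CohortSampleResult] = []
    skipped: list[str] = []
    for row in manifest:
        if row.exclude:
            continue
        if row.total_reads is not None and row.query_hits is not None:
            results.append(result_from_counts(
                row.sample_id, row.subtype_label, row.total_reads,
                row.query_hits, expression_threshold,
            ))
        elif row.path is not None:
            if not row.path.exists():
                log.warning("sample %s: read file %s missing; skipped",
                            row.sample_id, row.path)
                skipped.append(row.sample_id)
                continue
            lib = read_reads(row.path, sample_id=row.sample_id,
                             subtype_label=row.subtype_label)
            results.append(quantify_query_in_sample(
                query, lib, policy, expression_threshold))
        else:
            log.warning("sample %s: neither counts nor path; skipped",
                        row.sample_id)
            skipped.append(row.sample_id)
    return results, subtype_prevalence(results), skipped


def write_results_tsv(
    results: Iterable[CohortSampleResult], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tsubtype_label\ttotal_reads\tquery_hits\t"
                 "query_cpm\texpressed\n")
        for r in results:
            fh.write(
                f"{r.sample_id}\t{r.subtype_label}\t{r.total_reads}\t"
                f"{r.query_hits}\t{r.query_cpm:.6f}\t{str(r.expressed).lower()}\n"
            )


def write_prevalence_tsv(
    prevalence: Iterable[SubtypePrevalence], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("subtype_label\tn_expressed\tn_total\tpercentage\n")
        for p in prevalence:
            fh.write(f"{p.subtype_label}\t{p.n_expressed}\t{p.n_total}\t"
                     f"{p.percentage:.1f}\n")


def write_prevalence_json(
    prevalence: Iterable[SubtypePrevalence], path: str | Path
) -> None:
    path = Path(path)
    path.write_text(json.dumps([asdict(p) for p in prevalence], indent=2) + "\n")


def plot_prevalence(
    prevalence: Sequence[SubtypePrevalence], path: str | Path
) -> None:
    """Bar chart of per-subtype prevalence (percentage, with n labels)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [p.subtype_label for p in prevalence]
    pcts = [p.percentage for p in prevalence]
    fig, ax = plt.subplots(figsize=(1.2 * max(4, len(labels)), 4))
    bars = ax.bar(labels, pcts, color="#4477aa")
    for bar, p in zip(bars, prevalence):
        ax.annotate(
            f"{p.n_expressed}/{p.n_total}",
            (bar.get_x() + bar.get_width() / 2, bar.get_height()),
            ha="center", va="bottom", fontsize=9,
        )
    ax.set_ylabel("samples expressing query (%)")
    ax.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "CohortSampleResult",
    "SubtypePrevalence",
    "ManifestRow",
    "quantify_query_in_sample",
    "result_from_counts",
    "round_percentage",
    "subtype_prevalence",
    "read_manifest",
    "analyze_cohort",
    "write_results_tsv",
    "write_prevalence_tsv",
    "write_prevalence_json",
    "plot_prevalence",
]
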