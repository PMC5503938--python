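"""Expression quantification: CPM, expression flags, fold-change tiers,
and sdRNA processing preference.

All comparisons against thresholds are inclusive (>=). The expression unit
is counts per million (CPM): accepted alignments divided by the library's
total read count, times 1e6. A feature is flagged expressed at >=250 CPM.
Differential overexpression is threshold-based (>=5x), with reporting tiers
at >=5x, >=7.5x and >=75x; ratios are stabilised with a small CPM
pseudocount (default 0.1) so near-zero denominators yield large finite
folds rather than infinities. No statistical testing or normalisation
beyond CPM is performed — the screen is a threshold screen, and treating
its folds as tested effect sizes would be a misuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_EXPRESSION_THRESHOLD_CPM = 250.0
DEFAULT_MIN_FOLD = 5.0
DEFAULT_TIERS = (5.0, 7.5, 75.0)
DEFAULT_PSEUDOCOUNT_CPM = 0.1
DEFAULT_PREFERENCE_CUTOFF = 5.5

TIER_NONE = "none"


def _tier_label(threshold: float) -> str:
    return f">={threshold:g}x"


def compute_cpm(raw_count: int, total_reads: int) -> float:
    """Counts per million: raw_count / total_reads * 1e6, unrounded."""
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive (got {total_reads})")
    if raw_count < 0:
        raise ValueError(f"raw_count must be non-negative (got {raw_count})")
    return raw_count / total_reads * 1e6


def flag_expressed(
    cpm: float, threshold: float = DEFAULT_EXPRESSION_THRESHOLD_CPM
) -> bool:
    """True iff cpm >= threshold (inclusive boundary)."""
    return cpm >= threshold


@dataclass(frozen=True)
class ExpressionRecord:
    feature_id: str
    sample_id: str
    raw_count: int
    cpm: float
    expressed: bool


def make_expression_record(
    feature_id: str,
    sample_id: str,
    raw_count: int,
    total_reads: int,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD_CPM,
) -> ExpressionRecord:
    cpm = compute_cpm(raw_count, total_reads)
    return ExpressionRecord(
        feature_id=feature_id, sample_id=sample_id, raw_count=raw_count,
        cpm=cpm, expressed=flag_expressed(cpm, threshold),
    )


@dataclass(frozen=True)
class DifferentialRecord:
    """Fold change of one feature between sample a and sample b (a over b)."""

    feature_id: str
    cpm_a: float
    cpm_b: float
    fold_change: float
    overexpressed: bool
    tier: str


def fold_change(cpm_a: float, cpm_b: float,
                pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM) -> float:
    return (cpm_a + pseudocount) / (cpm_b + pseudocount)


def differential_table(
    records_a: Sequence[ExpressionRecord],
    records_b: Sequence[ExpressionRecord],
    pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM,
    min_fold: float = DEFAULT_MIN_FOLD,
    tiers: Sequence[float] = DEFAULT_TIERS,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD_CPM,
) -> list[DifferentialRecord]:
    """Per-feature fold change (a over b) with overexpression flag and tier.

    A feature is overexpressed when fold_change >= min_fold AND it reaches
    the expression threshold in at least one of the two samples. The tier is
    the highest tier threshold the fold reaches, reported only for
    overexpressed features. Features seen in only one sample are treated as
    0 CPM in the other, with a warning.
    """
    cpm_a = {r.feature_id: r.cpm for r in records_a}
    cpm_b = {r.feature_id: r.cpm for r in records_b}
    only_a = sorted(set(cpm_a) - set(cpm_b))
    only_b = sorted(set(cpm_b) - set(cpm_a))
    if only_a or only_b:
        log.warning(
            "features missing in one sample treated as 0 CPM "
            "(a-only: %s; b-only: %s)", only_a, only_b,
        )
    out: list[DifferentialRecord] = []
    ordered = list(dict.fromkeys([r.feature_id for r in records_a]
                                 + [r.feature_id for r in records_b]))
    for fid in ordered:
        a = cpm_a.get(fid, 0.0)
        b = cpm_b.get(fid, 0.0)
        fold = fold_change(a, b, pseudocount)
        over = fold >= min_fold and max(a, b) >= expression_threshold
        tier = TIER_NONE
        if over:
            for t in sorted(tiers):
                if fold >= t:
                    tier = _tier_label(t)
        out.append(DifferentialRecord(
            feature_id=fid, cpm_a=a, cpm_b=b, fold_change=fold,
            overexpressed=over, tier=tier,
        ))
    return out


@dataclass(frozen=True)
class ProcessingRecord:
    """Cross-sample comparison of sdRNA:snoRNA processing ratios.

    processing_ratio_a/_b are within-sample (sdRNA CPM + pc)/(snoRNA CPM +
    pc); preference_factor is ratio_a / ratio_b, and the snoRNA is flagged
    preferentially processed in sample a at factor >= 5.5.
    """

    snorna_id: str
    sdrna_cpm_a: float
    snorna_cpm_a: float
    sdrna_cpm_b: float
    snorna_cpm_b: float
    processing_ratio_a: float
    processing_ratio_b: float
    preference_factor: float
    preferential: bool


def processing_preference(
    snorna_id: str,
    sdrna_cpm_a: float,
    snorna_cpm_a: float,
    sdrna_cpm_b: float,
    snorna_cpm_b: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM,
    cutoff: float = DEFAULT_PREFERENCE_CUTOFF,
) -> ProcessingRecord:
    ratio_a = (sdrna_cpm_a + pseudocount) / (snorna_cpm_a + pseudocount)
    ratio_b = (sdrna_cpm_b + pseudocount) / (snorna_cpm_b + pseudocount)
    factor = ratio_a / ratio_b
    return ProcessingRecord(
        snorna_id=snorna_id,
        sdrna_cpm_a=sdrna_cpm_a, snorna_cpm_a=snorna_cpm_a,
        sdrna_cpm_b=sdrna_cpm_b, snorna_cpm_b=snorna_cpm_b,
        processing_ratio_a=ratio_a, processing_ratio_b=ratio_b,
        preference_factor=factor, preferential=factor >= cutoff,
    )


def expression_matrix(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    """Features x samples CPM matrix (row/column order of first appearance)."""
    rows = [(r.feature_id, r.sample_id, r.cpm) for r in records]
    df = pd.DataFrame(rows, columns=["feature_id", "sample_id", "cpm"])
    mat = df.pivot_table(index="feature_id", columns="sample_id", values="cpm",
                         sort=False)
    mat.columns.name = None
    return mat


def write_differential_tsv(
    records: Iterable[DifferentialRecord], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\tcpm_a\tcpm_b\tfold_change\toverexpressed\ttier\n")
        for r in records:
            fh.write(
                f"{r.feature_id}\t{r.cpm_a:.6f}\t{r.cpm_b:.6f}\t"
                f"{r.fold_change:.6f}\t{str(r.overexpressed).lower()}\t{r.tier}\n"
            )


def write_processing_tsv(
    records: Iterable[ProcessingRecord], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "snorna_id\tsdrna_cpm_a\tsnorna_cpm_a\tsdrna_cpm_b\tsnorna_cpm_b\t"
            "ratio_a\tratio_b\tpreference_factor\tpreferential\n"
        )
        for r in records:
            fh.write(
                f"{r.snorna_id}\t{r.sdrna_cpm_a:.6f}\t{r.snorna_cpm_a:.6f}\t"
                f"{r.sdrna_cpm_b:.6f}\t{r.snorna_cpm_b:.6f}\t"
                f"{r.processing_ratio_a:.6f}\t{r.processing_ratio_b:.6f}\t"
                f"{r.preference_factor:.6f}\t{str(r.preferential).lower()}\n"
            )


__all__ = [
    "ExpressionRecord",
    "DifferentialRecord",
    "ProcessingRecord",
    "compute_cpm",
    "flag_expressed",
    "fold_change",
    "make_expression_record",
    "differential_table",
    "processing_preference",
    "expression_matrix",
    "write_differential_tsv",
    "write_processing_tsv",
    "DEFAULT_EXPRESSION_THRESHOLD_CPM",
    "DEFAULT_MIN_FOLD",
    "DEFAULT_TIERS",
    "DEFAULT_PSEUDOCOUNT_CPM",
    "DEFAULT_PREFERENCE_CUTOFF",
    "TIER_NONE",
]
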