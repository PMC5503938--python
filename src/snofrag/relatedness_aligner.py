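"""Local-alignment relatedness screening and tripartite alignment rendering.

Implements Smith-Waterman local alignment with affine gaps (Gotoh) for the
snoRNA vs miRNA-hairpin relatedness screen. Sequence pairs are accepted
when the best local alignment reaches both an identity and an alignment
length floor (defaults: >=85% identity over >=40 alignment columns).

Scoring defaults qualitatively mimic short-sequence blastn (match +2,
mismatch -3, gap open -5, gap extend -2); a gap of length L costs
open + (L-1)*extend, i.e. the opening column already carries the open
penalty. Identity is computed over all alignment columns, gap columns
included (the BLAST convention).

The dynamic-programming fill is numba-compiled; the traceback runs in
Python where the deterministic tie-breaking lives: among co-optimal end
cells the alignment minimising (subject_start, query_start, aligned_length)
is reported, and inside a traceback diagonal moves are preferred over
subject gaps over query gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import isclose, nan
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .sequence_io import AlphabetError, SmallRNARead, SnoRNARecord, VALID_ALPHABET

log = logging.getLogger(__name__)

_NEG_INF = -1e30


@dataclass(frozen=True)
class RelatednessPolicy:
    """Acceptance thresholds and scoring scheme for the relatedness screen."""

    min_identity_pct: float = 85.0
    min_aligned_length: int = 40
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if not 0 < self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in (0, 100]")


@dataclass(frozen=True)
class LocalAlignmentResult:
    """Best local alignment of one (query, subject) pair.

    Coordinates are 0-based half-open; identity_pct is over all alignment
    columns including gap columns. aligned_length == 0 encodes "no
    positive-scoring local alignment" (identity_pct reported as 0).
    """

    query_id: str
    subject_id: str
    score: float
    identity_pct: float
    aligned_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    n_matches: int
    n_mismatches: int
    n_gap_columns: int

    def passes(self, policy: RelatednessPolicy) -> bool:
        return (
            self.identity_pct >= policy.min_identity_pct
            and self.aligned_length >= policy.min_aligned_length
        )


@njit(cache=False)
def _gotoh_fill(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = s.shape[0]
    H = np.zeros((n + 1, m + 1), np.float64)
    E = np.full((n + 1, m + 1), _NEG_INF, np.float64)  # gap in query (consumes subject)
    F = np.full((n + 1, m + 1), _NEG_INF, np.float64)  # gap in subject (consumes query)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            sub = match if q[i - 1] == s[j - 1] else mismatch
            # N (code 4) never counts as a match
            if q[i - 1] == 4 or s[j - 1] == 4:
                sub = mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str, context: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise AlphabetError(f"{context} contains non-nucleotide characters: {sorted(bad)}")
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def local_align(
    query: str,
    subject: str,
    policy: RelatednessPolicy = RelatednessPolicy(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> LocalAlignmentResult:
    """Maximal-scoring Smith-Waterman local alignment of two sequences."""
    if not query or not subject:
        raise ValueError("both sequences must be non-empty")
    q = _encode(query, query_id)
    s = _encode(subject, subject_id)
    H, E, F = _gotoh_fill(
        q, s, policy.match, policy.mismatch, policy.gap_open, policy.gap_extend
    )
    best = float(H.max())
    if best <= 0.0:
        return LocalAlignmentResult(
            query_id=query_id, subject_id=subject_id, score=0.0,
            identity_pct=0.0, aligned_length=0,
            query_start=0, query_end=0, subject_start=0, subject_end=0,
            n_matches=0, n_mismatches=0, n_gap_columns=0,
        )
    end_cells = np.argwhere(np.isclose(H, best, rtol=0.0, atol=1e-9))
    candidates = []
    for i_end, j_end in end_cells:
        cand = _traceback(H, E, F, q, s, int(i_end), int(j_end), policy)
        candidates.append(cand)
    qs, qe, ss, se, n_m, n_x, n_g = min(
        candidates, key=lambda c: (c[2], c[0], (c[1] - c[0]) + (c[3] - c[2]), c[3], c[1])
    )
    cols = n_m + n_x + n_g
    return LocalAlignmentResult(
        query_id=query_id, subject_id=subject_id, score=best,
        identity_pct=100.0 * n_m / cols, aligned_length=cols,
        query_start=qs, query_end=qe, subject_start=ss, subject_end=se,
        n_matches=n_m, n_mismatches=n_x, n_gap_columns=n_g,
    )


def _traceback(H, E, F, q, s, i, j, policy):
    """Greedy traceback from (i, j); diagonal > subject-gap > query-gap."""
    i_end, j_end = i, j
    n_match = n_mismatch = n_gap = 0
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if isclose(h, 0.0, abs_tol=1e-9):
                break
            sub = policy.match if (q[i - 1] == s[j - 1] and q[i - 1] != 4) else policy.mismatch
            if i > 0 and j > 0 and isclose(h, H[i - 1, j - 1] + sub, abs_tol=1e-9):
                if q[i - 1] == s[j - 1] and q[i - 1] != 4:
                    n_match += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif isclose(h, F[i, j], abs_tol=1e-9):
                state = "F"
            else:
                state = "E"
        elif state == "E":  # gap column consuming subject base j
            n_gap += 1
            if isclose(E[i, j], H[i, j - 1] + policy.gap_open, abs_tol=1e-9):
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # "F": gap column consuming query base i
            n_gap += 1
            if isclose(F[i, j], H[i - 1, j] + policy.gap_open, abs_tol=1e-9):
                i -= 1
                state = "H"
            else:
                i -= 1
    return (i, i_end, j, j_end, n_match, n_mismatch, n_gap)


@dataclass(frozen=True)
class ScreenSummary:
    n_pairs_tested: int
    n_passing_pairs: int
    mean_identity_pct: float
    mean_aligned_length: float
    n_queries_passing: int


def screen_catalog_pairs(
    snornas: Sequence[SnoRNARecord],
    hairpins: Sequence[SnoRNARecord],
    policy: RelatednessPolicy = RelatednessPolicy(),
) -> tuple[list[LocalAlignmentResult], ScreenSummary]:
    """All-vs-all relatedness screen of a snoRNA catalog against hairpins.

    Only pairs passing both thresholds are returned; summary means are over
    passing pairs (NaN when nothing passes).
    """
    if not snornas or not hairpins:
        raise ValueError("both catalogs must be non-empty")
    passing: list[LocalAlignmentResult] = []
    for sno in snornas:
        for hp in hairpins:
            res = local_align(
                sno.sequence, hp.sequence, policy,
                query_id=sno.id, subject_id=hp.id,
            )
            if res.passes(policy):
                passing.append(res)
    if passing:
        mean_id = float(np.mean([r.identity_pct for r in passing]))
        mean_len = float(np.mean([r.aligned_length for r in passing]))
    else:
        mean_id = mean_len = nan
    summary = ScreenSummary(
        n_pairs_tested=len(snornas) * len(hairpins),
        n_passing_pairs=len(passing),
        mean_identity_pct=mean_id,
        mean_aligned_length=mean_len,
        n_queries_passing=len({r.query_id for r in passing}),
    )
    return passing, summary


def write_screen_tsv(results: Iterable[LocalAlignmentResult], path: str | Path) -> None:
    """BLAST-tabular-style TSV of screen results."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("qseqid\tsseqid\tpident\tlength\tqstart\tqend\tsstart\tsend\tscore\n")
        for r in results:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.identity_pct:.2f}\t"
                f"{r.aligned_length}\t{r.query_start}\t{r.query_end}\t"
                f"{r.subject_start}\t{r.subject_end}\t{r.score:g}\n"
            )


class ContainmentError(ValueError):
    """Raised when the read is not an exact substring of the snoRNA."""


def render_tripartite(
    genome_window: str,
    snorna: SnoRNARecord,
    read: SmallRNARead,
    policy: RelatednessPolicy = RelatednessPolicy(),
) -> str:
    """Stacked genome / snoRNA / read alignment view.

    Four lines: genome window, a marker row, the snoRNA (placed under its
    genome alignment), and the read (placed under its position inside the
    snoRNA). Marker semantics: '|' where all three sequences agree, '*'
    where genome and snoRNA agree outside (or the read disagrees within)
    the read's columns, blank elsewhere. Only gapless snoRNA::genome
    alignments are rendered.
    """
    aln = local_align(
        snorna.sequence, genome_window, policy,
        query_id=snorna.id, subject_id="genome",
    )
    if aln.aligned_length == 0:
        raise ValueError("snoRNA does not locally align to the genome window")
    if aln.n_gap_columns:
        raise ValueError("gapped genome::snoRNA alignments are not renderable")
    read_off = snorna.sequence.find(read.sequence)
    if read_off == -1:
        raise ContainmentError(
            f"read '{read.id}' is not contained in snoRNA '{snorna.id}'"
        )
    width = len(genome_window)
    sno_line = [" "] * width
    read_line = [" "] * width
    marker = [" "] * width
    for p in range(aln.query_start, aln.query_end):
        col = aln.subject_start + (p - aln.query_start)
        sno_line[col] = snorna.sequence[p]
    read_cols = range(
        aln.subject_start + (read_off - aln.query_start),
        aln.subject_start + (read_off - aln.query_start) + read.length,
    )
    for k, col in enumerate(read_cols):
        if 0 <= col < width:
            read_line[col] = read.sequence[k]
    read_col_set = {c for c in read_cols if 0 <= c < width}
    for col in range(aln.subject_start, aln.subject_end):
        p = aln.query_start + (col - aln.subject_start)
        if genome_window[col] == snorna.sequence[p]:
            marker[col] = "|" if col in read_col_set else "*"
    return "\n".join(
        [genome_window, "".join(marker), "".join(sno_line), "".join(read_line)]
    )


__all__ = [
    "RelatednessPolicy",
    "LocalAlignmentResult",
    "ScreenSummary",
    "ContainmentError",
    "local_align",
    "screen_catalog_pairs",
    "write_screen_tsv",
    "render_tripartite",
]
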