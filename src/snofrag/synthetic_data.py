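"""Synthetic snoRNA catalogs, small RNA-seq libraries and labeled cohorts.

The generator emulates the statistical structure of size-selected small
RNA-seq over a snoRNA catalog:

* reference snoRNAs 60-300 nt with one planted sdRNA interval each
  (fragment length 21-29 nt, anchored at the 5' end of the snoRNA with
  probability 0.5, internal otherwise),
* a dominant fixed-boundary fragment per processed snoRNA: a fraction
  ``fidelity`` of each snoRNA's signal reads reproduce the planted interval
  exactly, the remainder carry a non-zero 3' boundary shift (uniform on
  +/-1..3 nt; the 5' end stays exact, matching the precise 5' processing of
  real sdRNAs),
* a uniform degradation background (random fragments of random snoRNAs),
* off-target reads guaranteed not to share any 16-mer with the catalog on
  either strand, so ground-truth hit counts stay exact,
* read lengths confined to the 17-35 nt size-selection window.

Every sampling decision flows from one integer seed; identical
configuration and seed yield byte-identical FASTA/FASTQ/TSV output.
Sequencing errors default to absent (a perfect-match pipeline discards
erroneous reads anyway); an error rate option exists to probe hit-count
robustness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import SampleLibrary, SmallRNARead, SnoRNARecord, reverse_complement

log = logging.getLogger(__name__)

ALPHABET = "ACGT"

DEFAULT_SNORNA_LENGTH_RANGE = (60, 300)
DEFAULT_SDRNA_LENGTH_RANGE = (21, 29)
DEFAULT_FIDELITY = 0.95
DEFAULT_JITTER3_MAX = 3
READ_LENGTH_WINDOW = (17, 35)
_OFFTARGET_KMER = 16


@dataclass
class SimulationConfig:
    """Bundle of generator parameters (YAML-friendly; see module docstring
    for what each models)."""

    seed: int = 0
    n_snornas: int = 20
    snorna_length_range: tuple[int, int] = DEFAULT_SNORNA_LENGTH_RANGE
    sdrna_length_range: tuple[int, int] = DEFAULT_SDRNA_LENGTH_RANGE
    five_prime_anchor_prob: float = 0.5
    excision_fidelity: float = DEFAULT_FIDELITY
    jitter3_max: int = DEFAULT_JITTER3_MAX
    jitter5_max: int = 0
    background_rate: float = 0.05
    offtarget_rate: float = 0.05
    library_size: int = 50_000
    error_rate: float = 0.0
    expression_cpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("excision_fidelity", "background_rate", "offtarget_rate",
                     "five_prime_anchor_prob", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.background_rate + self.offtarget_rate > 1.0:
            raise ValueError("background_rate + offtarget_rate must be <= 1")


@dataclass(frozen=True)
class LibraryTruth:
    """Ground truth for one simulated library."""

    sample_id: str
    fidelity: float
    planted_intervals: dict[str, tuple[int, int]]
    planted_cpm: dict[str, float]
    n_signal: dict[str, int]
    n_fixed: dict[str, int]
    n_jittered: dict[str, int]
    n_background: int
    n_offtarget: int
    library_size: int


@dataclass(frozen=True)
class CohortSampleTruth:
    sample_id: str
    subtype_label: str
    total_reads: int
    query_hits: int
    planted_cpm: float
    expressed: bool


@dataclass(frozen=True)
class CohortTruth:
    samples: list[CohortSampleTruth]
    prevalence: dict[str, tuple[int, int]]  # subtype -> (n_expressed, n_total)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def simulate_catalog(
    n_snornas: int = 20,
    length_range: tuple[int, int] = DEFAULT_SNORNA_LENGTH_RANGE,
    sdrna_length_range: tuple[int, int] = DEFAULT_SDRNA_LENGTH_RANGE,
    five_prime_anchor_prob: float = 0.5,
    seed: int = 0,
    id_prefix: str = "snoRNA",
) -> tuple[list[SnoRNARecord], dict[str, tuple[int, int]]]:
    """Random snoRNA catalog with one planted sdRNA interval per snoRNA.

    Sequences are i.i.d. uniform over {A,C,G,T}. Planted intervals leave at
    least ``DEFAULT_JITTER3_MAX`` nt of 3' slack so jittered boundaries stay
    on the snoRNA. Returns (catalog, {snorna_id: (start, end)}).
    """
    lo, hi = length_range
    flo, fhi = sdrna_length_range
    if fhi + DEFAULT_JITTER3_MAX > lo:
        raise ValueError(
            f"sdRNA interval (<= {fhi} nt + {DEFAULT_JITTER3_MAX} nt slack) "
            f"does not fit the shortest snoRNA ({lo} nt)"
        )
    rng = np.random.default_rng(seed)
    catalog: list[SnoRNARecord] = []
    intervals: dict[str, tuple[int, int]] = {}
    for i in range(n_snornas):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        frag_len = int(rng.integers(flo, fhi + 1))
        max_start = length - frag_len - DEFAULT_JITTER3_MAX
        if rng.random() < five_prime_anchor_prob:
            start = 0
        else:
            start = int(rng.integers(0, max_start + 1))
        sid = f"{id_prefix}-{i + 1:03d}"
        catalog.append(SnoRNARecord(id=sid, sequence=seq,
                                    description=f"{sid} synthetic"))
        intervals[sid] = (start, start + frag_len)
    return catalog, intervals


def _valid_jitter3(interval: tuple[int, int], sno_len: int,
                   jitter3_max: int) -> list[int]:
    s, e = interval
    lo, hi = READ_LENGTH_WINDOW
    shifts = []
    for d in range(-jitter3_max, jitter3_max + 1):
        if d == 0:
            continue
        new_e = e + d
        if s < new_e <= sno_len and lo <= new_e - s <= hi:
            shifts.append(d)
    return shifts


def simulate_library(
    catalog: Sequence[SnoRNARecord],
    planted_intervals: Mapping[str, tuple[int, int]],
    expression_cpm: Mapping[str, float],
    library_size: int,
    fidelity: float = DEFAULT_FIDELITY,
    jitter3_max: int = DEFAULT_JITTER3_MAX,
    background_rate: float = 0.0,
    offtarget_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
    subtype_label: str = "",
) -> tuple[SampleLibrary, LibraryTruth]:
    """Simulate one small RNA-seq library over a snoRNA catalog.

    Each snoRNA listed in ``expression_cpm`` contributes
    round(cpm * library_size / 1e6) signal reads; each signal read is the
    exact planted fragment with probability ``fidelity``, otherwise its 3'
    boundary is shifted by a non-zero amount up to ``jitter3_max``.
    Degradation background and off-target reads fill ``background_rate`` and
    ``offtarget_rate`` shares of the library; remaining capacity up to
    ``library_size`` is padded with further off-target reads so the library
    total (the CPM denominator) is exact.
    """
    if library_size == 0:
        log.warning("library_size 0 requested; returning empty library")
        empty = SampleLibrary(sample_id=sample_id, total_reads=0, reads=[],
                              subtype_label=subtype_label)
        truth = LibraryTruth(
            sample_id=sample_id, fidelity=fidelity,
            planted_intervals=dict(planted_intervals), planted_cpm={},
            n_signal={}, n_fixed={}, n_jittered={},
            n_background=0, n_offtarget=0, library_size=0,
        )
        return empty, truth
    rng = np.random.default_rng(seed)
    by_id = {r.id: r for r in catalog}
    reads: list[SmallRNARead] = []
    n_signal: dict[str, int] = {}
    n_fixed: dict[str, int] = {}
    n_jittered: dict[str, int] = {}
    counter = 0

    def emit(seq: str) -> None:
        nonlocal counter
        counter += 1
        reads.append(SmallRNARead(id=f"{sample_id}_r{counter:07d}", sequence=seq))

    for sid in expression_cpm:
        if sid not in by_id:
            raise ValueError(f"expression target '{sid}' not in catalog")
    for sid, cpm in expression_cpm.items():
        sno = by_id[sid]
        s, e = planted_intervals[sid]
        n = int(round(cpm * library_size / 1e6))
        n_signal[sid] = n
        shifts = _valid_jitter3((s, e), sno.length, jitter3_max)
        fixed = jittered = 0
        for _ in range(n):
            if rng.random() < fidelity or not shifts:
                emit(sno.sequence[s:e])
                fixed += 1
            else:
                d = shifts[int(rng.integers(0, len(shifts)))]
                emit(sno.sequence[s : e + d])
                jittered += 1
        n_fixed[sid] = fixed
        n_jittered[sid] = jittered

    n_bg = int(round(background_rate * library_size))
    lo, hi = READ_LENGTH_WINDOW
    for _ in range(n_bg):
        sno = catalog[int(rng.integers(0, len(catalog)))]
        max_len = min(hi, sno.length)
        length = int(rng.integers(lo, max_len + 1)) if max_len > lo else max_len
        start = int(rng.integers(0, sno.length - length + 1))
        emit(sno.sequence[start : start + length])

    n_ot_requested = int(round(offtarget_rate * library_size))
    n_emitted = sum(n_signal.values()) + n_bg
    if n_emitted + n_ot_requested > library_size:
        raise ValueError(
            f"requested reads ({n_emitted + n_ot_requested}) exceed "
            f"library_size ({library_size}); lower expression_cpm or rates"
        )
    n_ot = library_size - n_emitted  # requested off-target plus padding
    kmers = _catalog_kmer_set(catalog)
    for _ in range(n_ot):
        emit(_offtarget_read(rng, kmers, lo, hi))

    if error_rate > 0.0:
        reads = [_mutate(rng, r, error_rate) for r in reads]

    library = SampleLibrary(sample_id=sample_id, total_reads=len(reads),
                            reads=list(reads), subtype_label=subtype_label)
    truth = LibraryTruth(
        sample_id=sample_id, fidelity=fidelity,
        planted_intervals=dict(planted_intervals),
        planted_cpm=dict(expression_cpm),
        n_signal=n_signal, n_fixed=n_fixed, n_jittered=n_jittered,
        n_background=n_bg, n_offtarget=n_ot, library_size=len(reads),
    )
    return library, truth


def _catalog_kmer_set(catalog: Sequence[SnoRNARecord],
                      k: int = _OFFTARGET_KMER) -> frozenset[str]:
    kmers: set[str] = set()
    for rec in catalog:
        for seq in (rec.sequence, reverse_complement(rec.sequence)):
            for i in range(len(seq) - k + 1):
                kmers.add(seq[i : i + k])
    return frozenset(kmers)


def _offtarget_read(rng: np.random.Generator, kmers: frozenset[str],
                    lo: int, hi: int, max_tries: int = 1000) -> str:
    """Random read sharing no catalog 16-mer on either strand."""
    k = _OFFTARGET_KMER
    for _ in range(max_tries):
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if not any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1)):
            return seq
    raise RuntimeError("could not sample an off-target read; catalog too dense")


def _mutate(rng: np.random.Generator, read: SmallRNARead,
            error_rate: float) -> SmallRNARead:
    chars = list(read.sequence)
    changed = False
    for i, c in enumerate(chars):
        if rng.random() < error_rate:
            chars[i] = ALPHABET[(ALPHABET.index(c) + int(rng.integers(1, 4))) % 4]
            changed = True
    if not changed:
        return read
    return SmallRNARead(id=read.id, sequence="".join(chars))


def write_fastq(library: SampleLibrary, path: str | Path) -> None:
    """Four-line FASTQ with constant qualities (none are modelled)."""
    path = Path(path)
    with path.open("w") as fh:
        for read in library.reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * read.length}\n")


@dataclass(frozen=True)
class SubtypeDesign:
    """Planted prevalence for one cohort subtype."""

    label: str
    n_total: int
    n_expressed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_expressed <= self.n_total:
            raise ValueError("need 0 <= n_expressed <= n_total")


def simulate_cohort(
    design: Sequence[SubtypeDesign],
    seed: int = 0,
    expressed_cpm: float = 2500.0,
    unexpressed_cpm: float = 25.0,
    library_size_range: tuple[int, int] = (10_000, 1_000_000),
    expression_threshold: float = 250.0,
) -> CohortTruth:
    """Pre-counted cohort with exact planted per-subtype prevalence.

    Which samples express the query is assigned by a seeded permutation
    within each subtype (exactly n_expressed per subtype); expressed and
    silent samples are planted at ``expressed_cpm`` and ``unexpressed_cpm``
    (defaults 10x and 0.1x the 250 CPM flag threshold, far enough from the
    boundary that count rounding cannot flip a flag). Returns per-sample
    (total_reads, query_hits) rows plus the planted prevalence.
    """
    if not design:
        raise ValueError("cohort design is empty")
    rng = np.random.default_rng(seed)
    samples: list[CohortSampleTruth] = []
    prevalence: dict[str, tuple[int, int]] = {}
    lo, hi = library_size_range
    for sub in design:
        flags = np.zeros(sub.n_total, dtype=bool)
        flags[: sub.n_expressed] = True
        rng.shuffle(flags)
        for i, expressed in enumerate(flags):
            total = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            cpm = expressed_cpm if expressed else unexpressed_cpm
            hits = int(round(cpm * total / 1e6))
            realized = hits / total * 1e6
            if (realized >= expression_threshold) != bool(expressed):
                raise RuntimeError(
                    "planted CPM too close to the flag threshold for library "
                    f"size {total}; separate expressed/unexpressed CPM further"
                )
            samples.append(CohortSampleTruth(
                sample_id=f"{_slug(sub.label)}_{i + 1:03d}",
                subtype_label=sub.label, total_reads=total, query_hits=hits,
                planted_cpm=cpm, expressed=bool(expressed),
            ))
        prevalence[sub.label] = (sub.n_expressed, sub.n_total)
    return CohortTruth(samples=samples, prevalence=prevalence)


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label)


def write_cohort_manifest(truth: CohortTruth, path: str | Path) -> None:
    """Pre-counted manifest consumable by the cohort analyzer."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tsubtype_label\ttotal_reads\tquery_hits\texclude\n")
        for s in truth.samples:
            fh.write(f"{s.sample_id}\t{s.subtype_label}\t{s.total_reads}\t"
                     f"{s.query_hits}\t\n")


def write_truth_tsv(truth: LibraryTruth, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("snorna_id\tstart\tend\tplanted_cpm\tn_signal\tn_fixed\t"
                 "n_jittered\n")
        for sid in truth.planted_cpm:
            s, e = truth.planted_intervals[sid]
            fh.write(
                f"{sid}\t{s}\t{e}\t{truth.planted_cpm[sid]:g}\t"
                f"{truth.n_signal[sid]}\t{truth.n_fixed[sid]}\t"
                f"{truth.n_jittered[sid]}\n"
            )


__all__ = [
    "SimulationConfig",
    "LibraryTruth",
    "CohortTruth",
    "CohortSampleTruth",
    "SubtypeDesign",
    "simulate_catalog",
    "simulate_library",
    "simulate_cohort",
    "write_fastq",
    "write_cohort_manifest",
    "write_truth_tsv",
    "READ_LENGTH_WINDOW",
]
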