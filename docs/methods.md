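# Methods

## Problem and model

A snoRNA locus can yield, besides the full-length snoRNA, a short
miRNA-like fragment (an sdRNA). In size-selected small RNA-seq, a genuinely
processed sdRNA appears as a pile-up of reads sharing one fragment interval
on the snoRNA, whereas degradation appears as reads scattered across many
intervals. `snofrag` operationalises that distinction and the downstream
expression questions with threshold rules throughout — no statistical
testing is performed anywhere in the pipeline, and the fold changes it
reports must not be read as tested effect sizes.

## Alignment model

Reads are accepted only as *perfect, full-length matches* to catalog
sequences. This is deliberate: the fragments of interest are exact
subsequences of their precursor, and a mismatch-tolerant mapper would blur
the boundary statistics the excision profiler depends on. Consequences:

* Reads containing `N` can never reach 100% identity and are excluded from
  matching (they still count in the library total).
* Sequencing errors silently remove reads from the aligned set; hit counts
  are therefore conservative.
* Two policy regimes are named in configuration and cannot be mixed
  silently: `cellline` (16–28 nt) for two-sample screens, `sra_survey`
  (≥16 nt, unbounded) for cohort surveys. A biological corollary worth
  knowing: a 29 nt sdRNA is invisible to the 16–28 nt regime.

Coordinates are 0-based half-open internally; report writers use 1-based
inclusive only where a format demands it (SAM). The default strand policy
is sense-only, because small RNA-seq protocols are stranded and sdRNAs are
sense fragments of their precursor; `strands: both` is available, and the
matcher then also places the reverse complement of each read.

Multi-placement reads default to `count all` (each placement is one hit,
matching accepted-alignment counting); `best only` (first placement in
deterministic order) exists for sensitivity analysis. The matcher seeds on
the leading `min_len`-mer of the read via a catalog k-mer index and
verifies the full read; the test suite asserts equivalence with a
brute-force scan over every offset, both strands.

## Excision profiling

Per snoRNA the profiler tallies exact (start, end) intervals, takes the
modal interval (ties broken toward the 5′-most, shortest fragment), and
counts the *modal family*: hits with |start − modal start| ≤ δ5 and
|end − modal end| ≤ δ3. Defaults δ5 = 0, δ3 = 3 encode the observed
biology — precise 5′ processing with modest 3′-length heterogeneity.
Setting δ5 = δ3 = 0 reproduces the strict exact-interval reading. The
*fixed fraction* is family count / total hits; a fixed-position sdRNA is
called when it strictly exceeds 0.90 (the field's ">90% at fixed
positions" convention) **and** the snoRNA has ≥ `min_hits` = 10 aligned
reads. The depth floor is this package's own guard — a 2-read snoRNA
trivially attains fraction 1.0 — and is surfaced in every report. Called
fragments outside 16–35 nt trigger a warning. When two well-separated
fragment clusters exist, only the modal one is called; the runner-up is
available via `secondary_cluster` for inspection, never called.

In the two-sample pipeline the sdRNA interval is defined once on the
pooled alignments of both samples, then per-sample sdRNA counts are the
family hits at that shared interval. This keeps the two samples quantified
at the same fragment; per-sample calls are also written for comparison.

## Quantification

CPM = raw hits / library total × 10⁶, stored unrounded. The denominator is
the *pre-filter* read count of the library by default (`cpm_denominator:
raw`), because the published totals a practitioner will compare against
are whole-file read counts; `filtered` switches to the post-length-filter
count. All threshold comparisons are inclusive (≥): expressed at ≥250 CPM,
overexpressed at fold ≥5 with ≥250 CPM in at least one sample, tiers at
≥5/≥7.5/≥75, processing preference at ≥5.5.

Fold changes use a 0.1-CPM pseudocount on both numerator and denominator:
(a+0.1)/(b+0.1). This is the package's choice for handling near-zero
denominators (a feature absent in one sample yields a large finite fold,
e.g. 300 vs 0 CPM → 3001) and makes fold(a,b)·fold(b,a) = 1 up to float
rounding. Raw CPMs are always reported alongside folds so the pseudocount's
effect is visible; note it pulls marginal folds slightly downward (750 vs
100 CPM gives 7.494, not 7.5).

Because sdRNA family hits are a subset of their snoRNA's hits, the
within-sample processing ratio (sdRNA CPM + 0.1)/(snoRNA CPM + 0.1) is
bounded near 1; the cross-sample *preference factor* (ratio of ratios) is
unaffected by that convention.

Cohort prevalence percentages are computed in exact decimal arithmetic and
rounded half-up to one decimal (12/29 → 41.4, 13/14 → 92.9). Sample
exclusion is a manifest flag, never hard-coded.

## Local alignment (relatedness screen)

Smith–Waterman with affine gaps (Gotoh), scoring match +2, mismatch −3,
gap open −5, gap extend −2 — chosen to mimic short-sequence blastn
qualitatively; the screen's acceptance thresholds (≥85% identity over ≥40
columns), not the scores, carry the decision. A gap of length L costs
open + (L−1)·extend. Identity is computed over all alignment columns
including gaps (BLAST convention); `N` never counts as a match. Only the
single best local alignment per pair is reported (no secondary HSPs, no
E-values).

Determinism: among co-optimal end cells the alignment minimising
(subject start, query start, aligned length) is chosen; within a traceback,
diagonal moves are preferred over subject gaps over query gaps. Co-optimal
*paths from the same end cell* are not enumerated — the guarantee is a
deterministic, reproducible choice, not a canonical enumeration. The DP
fill is numba-compiled; correctness is checked against an independent
recursive DP oracle (≤12 nt pairs) and against Biopython's
`PairwiseAligner` scores on longer pairs.

The tripartite genome/snoRNA/read view renders a gapless genome::snoRNA
local alignment with the read placed inside the snoRNA: `|` marks columns
where all three agree, `*` where genome and snoRNA agree outside the read,
blank where they disagree. Gapped genome alignments are refused rather
than rendered misleadingly.

## Synthetic data

The generator emulates the structure of the real libraries this pipeline
targets, with every draw flowing from one integer seed (identical
config + seed ⇒ byte-identical files):

* snoRNAs 60–300 nt, i.i.d. uniform {A,C,G,T}; one planted sdRNA interval
  each, length 21–29 nt, 5′-anchored with probability 0.5;
* signal reads: a fraction *f* (excision fidelity, default 0.95) reproduce
  the planted interval exactly; the rest shift the 3′ boundary by a
  **non-zero** amount uniform on ±1..3 nt. Zero is excluded by definition:
  a "non-fixed" read is one whose boundary differs, and including zero
  shifts would bias fidelity recovery upward;
* degradation background: uniform random fragments of random snoRNAs
  (default 5% of the library in the analysis scripts);
* off-target reads: random sequences rejection-sampled to share no 16-mer
  with the catalog on either strand, so ground-truth hit counts are exact;
  they also pad the library to its exact nominal size, making planted CPMs
  exact after rounding to integer read counts;
* read lengths confined to 17–35 nt; FASTQ qualities constant (no quality
  model); sequencing errors default to 0 (an error rate option exists to
  probe hit-count robustness).

Planted cohort prevalence is exact by construction: expression flags are
assigned per sample by a seeded permutation, with expressed/silent samples
planted at 10× / 0.1× the 250-CPM threshold so count rounding cannot flip
a flag; library sizes are log-uniform on 10⁴–10⁶ reads.

**Interaction to be aware of:** the profiler's default δ3 = 3 tolerance
absorbs the generator's ±3 nt jitter, so on a background-free library the
default-tolerance fixed fraction is ~1.0 regardless of fidelity; the
fidelity-recovery tests therefore use exact grouping (δ5 = δ3 = 0), which
recovers *f* to binomial accuracy. With degradation background present the
default tolerance behaves as intended, separating planted processing from
background (the analysis scripts show ~0.97 for strongly expressed
snoRNAs over a 5% background, and rejection of snoRNAs whose signal is
comparable to background).

What the simulations do **not** model: sequence composition bias, GC/
ligation bias, quality-dependent errors, true snoRNA secondary structure,
and multi-mapping between homologous snoRNA families (catalog sequences
are random, so cross-mapping is rare). Passing recovery tests on this
generator demonstrates the pipeline's arithmetic and decision rules, not
robustness to those real-data artifacts.

## Problem sizes in tests and scripts

The test suite and analysis scripts run at desk scale by choice: libraries
of 2 000–50 000 reads, catalogs of 1–60 references, a 116-sample
pre-counted cohort. Fidelity recovery uses 4 000-read libraries (binomial
SD ≤ 0.008, comfortably inside the ±0.03 assertion); two-sample screens
use planted CPMs high enough that integer rounding of read counts cannot
move a feature across a tier boundary. Cohorts may be supplied pre-counted
(sample_id, total_reads, query_hits) precisely so realistic cohort sizes
need no raw reads.

## Known limitations

* Perfect matching means error-free reads only; hit counts underestimate
  expression at realistic error rates (conservative, but uncorrected).
* No normalisation beyond CPM (no TMM/size factors) and no multiple-testing
  control — the screen is threshold-based by design.
* The relatedness screen reports one HSP per pair; diverged duplicated
  domains within one pair are not chained.
* Antisense handling is a configuration choice (`sense` default); there is
  no strand inference from the data.
* The 0.1-CPM pseudocount, the min_hits = 10 depth floor, and the pooled
  interval definition in two-sample runs are this package's design
  decisions where the method's published description is silent; all are
  configurable and embedded in every report for auditability.
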