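#!/usr/bin/env python
"""Cohort prevalence of the query sdRNA per breast-cancer subtype.

Two computations: (i) the simulated 116-sample cohort (planted at the
published expressed/total counts) analysed end to end from its manifest,
and (ii) the same prevalence arithmetic applied directly to the published
counts, as a worked example. Both must agree: 41.4 / 38.7 / 92.9 / 0.0
percent for TNBC / Luminal A / Luminal B HER2+ / normal.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _inputs import COHORT_DESIGN, RESULTS, ensure_inputs  # noqa: E402

from snofrag.cohort_analyzer import (  # noqa: E402
    round_percentage,
    write_prevalence_tsv,
)
from snofrag.pipeline import run_cohort  # noqa: E402


def main() -> None:
    paths = ensure_inputs()
    outdir = RESULTS / "cohort"
    _, prevalence = run_cohort(paths["manifest"], paths["query"], outdir)
    print("simulated cohort:")
    for p in prevalence:
        print(f"  {p.subtype_label}: {p.n_expressed}/{p.n_total} "
              f"({p.percentage:.1f}%)")

    print("worked example from the published counts:")
    for d in COHORT_DESIGN:
        pct = round_percentage(d.n_expressed, d.n_total)
        print(f"  {d.label}: {d.n_expressed}/{d.n_total} ({pct:.1f}%)")
    write_prevalence_tsv(prevalence, RESULTS / "prevalence.tsv")
    print(f"prevalence tables -> {outdir} and {RESULTS / 'prevalence.tsv'}")


if __name__ == "__main__":
    main()
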