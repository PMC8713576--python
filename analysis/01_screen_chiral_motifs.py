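"""Massive-parallel chiral-motif screen on synthetic libraries.

Generates all four chirality-encoded substrate pools, digests them with the
planted chirality-gated model, sequences and decodes both gel fractions, and
tests which chiral motifs change abundance in the uncleaved circular fraction.
Writes per-library differential tables and the cross-encoding consistency
calls under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from stereocleave._fastq import write_fastq
from stereocleave.chiral_screen import (
    call_consistent_motifs,
    count_table_from_fastq,
    test_differential,
)
from stereocleave.core_stereo import SCHEMES
from stereocleave.synthetic_data import (
    ReadModel,
    ScreenTruth,
    draw_substrate_pool,
    emit_screen_reads,
    simulate_screen_digestion,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    truth = ScreenTruth()
    rng = np.random.default_rng(seed)
    results = {}
    for lib in ("L1", "L2", "L3", "L4"):
        scheme = SCHEMES[lib]
        s = rng.integers(0, 2**31 - 1, 4)
        pool = draw_substrate_pool(scheme, seed=int(s[0]))
        cleaved = simulate_screen_digestion(pool, truth, seed=int(s[1]))
        print(f"{lib}: {len(pool):,} molecules, {cleaved.mean():.1%} cleaved")
        treated = emit_screen_reads(pool, cleaved, ReadModel(seed=int(s[2])), scheme)
        control = emit_screen_reads(
            pool, np.zeros(len(pool), bool), ReadModel(seed=int(s[3])), scheme
        )
        tables = {}
        for fraction, records in (
            ("circular", treated["uncleaved_circular"]),
            ("no-enzyme", control["uncleaved_circular"]),
        ):
            fq = SCRATCH / f"screen_{lib}_{fraction}.fq"
            write_fastq(fq, records)
            tables[fraction], discards = count_table_from_fastq(fq, scheme, fraction)
            print(f"  {fraction}: retained {tables[fraction].total_nonamers:,} "
                  f"nonamers, discards {dict(discards)}")
        results[lib] = test_differential(tables["circular"], tables["no-enzyme"])
        pd.DataFrame(results[lib]).to_csv(
            RESULTS / f"screen_differential_{lib}.tsv", sep="\t", index=False
        )

    rows = []
    for a, b in (("L1", "L3"), ("L2", "L4")):
        calls = call_consistent_motifs(results[a], SCHEMES[a], results[b], SCHEMES[b])
        for c in calls:
            rows.append(
                {
                    "comparison": f"{a}-vs-{b}",
                    "window": c.window,
                    "chirality_motif": c.motif_str,
                    "consistency": c.consistency,
                    "log2fc_a": c.evidence[0].log2_fold_change,
                    "fdr_a": c.evidence[0].fdr,
                    "log2fc_b": c.evidence[1].log2_fold_change,
                    "fdr_b": c.evidence[1].fdr,
                    "direction": c.evidence[0].direction,
                }
            )
    calls_df = pd.DataFrame(rows)
    calls_df.to_csv(RESULTS / "screen_consistency.tsv", sep="\t", index=False)
    strong = calls_df[calls_df.consistency == "strong"]
    print("\nstrong cross-encoding calls (direction 'up' = enriched uncleaved):")
    print(strong.to_string(index=False))
    sss = strong[strong.chirality_motif == "SpSpSp"]
    print(
        f"\nFinding: SpSpSp is strong-enriched in the uncleaved fraction in "
        f"{len(sss)}/4 window-comparisons — at least one Rp-PS contact is "
        f"needed for efficient cleavage."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
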