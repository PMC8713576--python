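"""Cleavage-site mapping: the chirality walk and the HIF1A-style epimers.

Part 1 — chem walk: for each of the seven walk compounds, predicts cleavage
sites from Rp placement, simulates fragment reads, maps them back through the
length-based pipeline and checks the two-nucleotide offset law.

Part 2 — single stereodefined PS in a gapmer: simulates the PO parent, the
single-Rp and the single-Sp epimer cleavage patterns on the HIF1A-style
construct and quantifies pattern change as total-variation distance.
"""

import sys
from pathlib import Path

import pandas as pd

from stereocleave.cleavage_map import (
    chem_walk_construct,
    compare_profiles,
    hif1a_construct,
    predominant_site,
    profile_from_reads,
)
from stereocleave.core_stereo import build_chem_walk_set, predict_cleavage_sites
from stereocleave.synthetic_data import ReadModel, simulate_cleavage_map_reads

RESULTS = Path(__file__).resolve().parents[1] / "results"


def chem_walk(seed: int) -> None:
    construct = chem_walk_construct()
    rows = []
    for comp in build_chem_walk_set():
        pred = predict_cleavage_sites(comp)
        truth = {
            s.position: (1.0 if s.label == "rp-guided" else 0.5)
            for s in pred.sites
        }
        reads = simulate_cleavage_map_reads(
            construct, truth, ReadModel(n_reads=100_000, seed=seed + comp.compound_id)
        )
        profile = profile_from_reads((s for _t, s, _q in reads), construct)
        site = predominant_site(profile)
        rp = min(comp.rp_positions) if comp.rp_positions else None
        rows.append(
            {
                "compound": comp.compound_id,
                "rp_linkage": rp,
                "predicted_sites": ",".join(map(str, sorted(pred.positions))),
                "recovered_site": site,
                "offset": site - rp if rp is not None else None,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "chem_walk_sites.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    walk = df[df.compound <= 5]
    print(
        f"\nFinding: compounds 1-5 recover a constant offset of "
        f"{sorted(walk.offset.astype(int).unique())} nt between the Rp linkage and the "
        f"cleavage site; compound 6 cleaves only at the control site; "
        f"compound 7 (no Rp) cleaves diffusely."
    )


def hif1a_epimers(seed: int) -> None:
    construct = hif1a_construct()
    native_site = 15
    truths = {
        "HIF1A_O (PO)": {native_site: 1.0},
        "HIF1A_R (single Rp)": {native_site: 1.0, native_site + 4: 0.05},
        "HIF1A_S (single Sp)": {native_site: 0.1, native_site + 4: 0.5,
                                native_site - 4: 0.5},
    }
    profiles = {}
    for name, truth in truths.items():
        reads = simulate_cleavage_map_reads(
            construct, truth, ReadModel(n_reads=50_000, seed=seed + len(profiles))
        )
        profiles[name] = profile_from_reads((s for _t, s, _q in reads), construct)
    rows = []
    po = profiles["HIF1A_O (PO)"]
    for name, prof in profiles.items():
        rows.append(
            {
                "compound": name,
                "predominant_site": predominant_site(prof),
                "tv_distance_to_PO": compare_profiles(po, prof),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "hif1a_profile_comparison.tsv", sep="\t", index=False)
    print("\n" + df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(
        "\nFinding: the single-Rp epimer preserves the PO parent's "
        "predominant site (small TV distance); the single-Sp epimer "
        "drastically changes the pattern and loses the native site."
    )


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    chem_walk(seed)
    hif1a_epimers(seed + 1000)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
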