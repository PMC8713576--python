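"""Decode the massive-parallel chiral-motif screen.

Reads are demultiplexed on exact index match, trimmed against an anchored 5'
adapter and a downstream 3' adapter (substitutions only, cutadapt-style error
rate 0.1), filtered to alphabet-conformant nonamers, and summarised as trimer
counts in the two enzyme-contact windows (insert positions 1-3 and 5-7,
{A,T}-only).  Differential abundance between RNase H-treated fractions and
controls uses an exact conditional binomial test (the Poisson limit of the
negative-binomial exact test) with Benjamini-Hochberg FDR, and motifs are
called chirality-consistent when two libraries with *opposite* encodings
agree — the comparison that cancels base-sequence effects.

The C/G window filter is applied per window independently: a read whose
positions 1-3 contain C or G is excluded from window 1 but can still count
toward window 2.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._fastq import Record, index_of, read_fastq
from .core_stereo import Chirality, EncodingScheme

__all__ = [
    "MotifCountTable",
    "DifferentialResult",
    "ConsistencyCall",
    "WINDOWS",
    "demultiplex",
    "trim_screen_read",
    "filter_and_count",
    "extract_window_trimers",
    "test_differential",
    "estimate_common_dispersion",
    "call_consistent_motifs",
    "count_table_from_fastq",
    "count_table_from_inserts",
]

# (name, python slice) of the two extracted windows on the 9-mer insert
WINDOWS: tuple[tuple[str, slice], ...] = (
    ("pos1-3", slice(0, 3)),
    ("pos5-7", slice(4, 7)),
)

_AT = frozenset("AT")


@dataclass
class MotifCountTable:
    """Counts of {A,T} window trimers for one sample, the screen's ledger.

    ``total_nonamers`` (all retained nonamers, before the per-window C/G
    filter) doubles as the library size for normalization.
    """

    counts: dict[tuple[str, str], int]  # (window, trimer) -> count
    total_nonamers: int
    library_id: str = ""
    fraction: str = ""  # circular | linear | no-enzyme
    replicate: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        for window, _ in WINDOWS:
            wsum = sum(c for (w, _m), c in self.counts.items() if w == window)
            if wsum > self.total_nonamers:
                raise ValueError(f"window {window} counts exceed total nonamers")

    def get(self, window: str, motif: str) -> int:
        return self.counts.get((window, motif), 0)


def demultiplex(
    records: Iterable[Record], index_map: Mapping[str, str]
) -> tuple[dict[str, list[Record]], int]:
    """Route reads to samples on exact index equality.

    ``index_map`` maps sample name -> index sequence (duplicates are a
    configuration error).  Returns per-sample records plus the count of
    discarded (unmatched) reads.
    """
    by_index: dict[str, str] = {}
    for sample, index in index_map.items():
        if index in by_index:
            raise ValueError(
                f"duplicate index {index!r} for samples "
                f"{by_index[index]!r} and {sample!r}"
            )
        by_index[index] = sample
    out: dict[str, list[Record]] = {sample: [] for sample in index_map}
    discarded = 0
    for rec in records:
        sample = by_index.get(index_of(rec[0]))
        if sample is None:
            discarded += 1
        else:
            out[sample].append(rec)
    return out, discarded


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def trim_screen_read(
    read: str, scheme: EncodingScheme, max_error_rate: float = 0.1
) -> tuple[str | None, str]:
    """Extract the insert between the anchored 5' adapter and the 3' adapter.

    The 5' adapter must match at the read start (substitutions only, at most
    floor(rate * len) mismatches); the 3' adapter is searched downstream
    (leftmost match at the same rate).  Returns ``(insert, "ok")`` or
    ``(None, reason)``.
    """
    a5, a3 = scheme.adapter_5p, scheme.adapter_3p
    max_mm5 = int(max_error_rate * len(a5))
    if len(read) < len(a5) or not _hamming_le(read[: len(a5)], a5, max_mm5):
        return None, "no-5p-adapter"
    rest = read[len(a5):]
    pos = rest.find(a3)  # exact fast path
    if pos < 0:
        max_mm3 = int(max_error_rate * len(a3))
        if max_mm3 > 0:
            for start in range(len(rest) - len(a3) + 1):
                if _hamming_le(rest[start : start + len(a3)], a3, max_mm3):
                    pos = start
                    break
    if pos < 0:
        return None, "no-3p-adapter"
    return rest[:pos], "ok"


def filter_and_count(
    inserts: Iterable[str], scheme: EncodingScheme
) -> tuple[Counter, Counter]:
    """Keep length-9, alphabet-conformant inserts; count unique nonamers.

    Returns (nonamer counts, discard tallies by reason).
    """
    alphabet = scheme.alphabet
    counts: Counter = Counter()
    discards: Counter = Counter()
    for insert in inserts:
        if len(insert) != 9:
            discards["length"] += 1
        elif not set(insert) <= alphabet:
            discards["alphabet"] += 1
        else:
            counts[insert] += 1
    return counts, discards


def extract_window_trimers(
    nonamer_counts: Mapping[str, int],
    library_id: str = "",
    fraction: str = "",
    replicate: int = 0,
) -> MotifCountTable:
    """Tally {A,T}-only trimers in windows 1-3 and 5-7, independently.

    A nonamer with C or G inside a window is excluded from that window only;
    the other window is still tallied.
    """
    counts: dict[tuple[str, str], int] = {}
    total = 0
    for nonamer, c in nonamer_counts.items():
        total += c
        for window, sl in WINDOWS:
            trimer = nonamer[sl]
            if set(trimer) <= _AT:
                key = (window, trimer)
                counts[key] = counts.get(key, 0) + c
    return MotifCountTable(counts, total, library_id, fraction, replicate)


def count_table_from_inserts(
    inserts: Iterable[str],
    scheme: EncodingScheme,
    fraction: str = "",
    replicate: int = 0,
) -> tuple[MotifCountTable, Counter]:
    nonamers, discards = filter_and_count(inserts, scheme)
    table = extract_window_trimers(
        nonamers, scheme.library_id, fraction, replicate
    )
    return table, discards


def count_table_from_fastq(
    path, scheme: EncodingScheme, fraction: str = "", replicate: int = 0
) -> tuple[MotifCountTable, Counter]:
    """Full per-sample pipeline: trim every read, filter, count, window."""
    inserts = []
    discards: Counter = Counter()
    for _title, seq, _q in read_fastq(path):
        insert, reason = trim_screen_read(seq, scheme)
        if insert is None:
            discards[reason] += 1
        else:
            inserts.append(insert)
    table, filter_discards = count_table_from_inserts(
        inserts, scheme, fraction, replicate
    )
    discards.update(filter_discards)
    return table, discards


# ---------------------------------------------------------------------------
# differential abundance


@dataclass(frozen=True)
class DifferentialResult:
    window: str
    motif: str
    count_treated: int
    count_control: int
    log2_fold_change: float
    p_value: float
    fdr: float
    direction: str  # "up" (enriched in treated) | "down" | "none"


def _two_sided_exact(k: int, n: int, p0: float, dispersion: float) -> float:
    """Two-sided small-p-values exact test of k successes in n at p0;
    beta-binomial when a common dispersion > 0 is supplied."""
    if n == 0:
        return 1.0
    if dispersion <= 0:
        return stats.binomtest(k, n, p0).pvalue
    rho = dispersion
    a = p0 * (1.0 - rho) / rho
    b = (1.0 - p0) * (1.0 - rho) / rho
    pmf = stats.betabinom.pmf(np.arange(n + 1), n, a, b)
    return float(pmf[pmf <= pmf[k] * (1.0 + 1e-12)].sum())


def test_differential(
    treated: MotifCountTable,
    control: MotifCountTable,
    dispersion: float = 0.0,
) -> list[DifferentialResult]:
    """Per-motif differential abundance, treated vs control.

    log2 fold change uses pseudocount 0.5 after normalization to total
    retained nonamers; the p-value is the exact conditional binomial test of
    the motif's count split given both totals, BH-adjusted across all
    motifs x windows.
    """
    for name, table in (("treated", treated), ("control", control)):
        if table.total_nonamers == 0:
            raise ValueError(
                f"{name} sample "
                f"({table.library_id or 'unnamed'}/{table.fraction or '?'}) "
                "has zero total counts"
            )
    n_t, n_c = treated.total_nonamers, control.total_nonamers
    p0 = n_t / (n_t + n_c)
    keys = sorted(set(treated.counts) | set(control.counts))
    rows = []
    for window, motif in keys:
        k_t, k_c = treated.get(window, motif), control.get(window, motif)
        lfc = math.log2(((k_t + 0.5) / n_t) / ((k_c + 0.5) / n_c))
        p = _two_sided_exact(k_t, k_t + k_c, p0, dispersion)
        rows.append((window, motif, k_t, k_c, lfc, min(p, 1.0)))
    if not rows:
        return []
    fdrs = multipletests([r[5] for r in rows], method="fdr_bh")[1]
    results = []
    for (window, motif, k_t, k_c, lfc, p), fdr in zip(rows, fdrs):
        direction = "up" if lfc > 0 else ("down" if lfc < 0 else "none")
        results.append(
            DifferentialResult(window, motif, k_t, k_c, lfc, p, float(fdr), direction)
        )
    return results


def estimate_common_dispersion(
    replicates: Sequence[MotifCountTable],
) -> float:
    """Moment estimate of a common beta-binomial overdispersion rho.

    Compares the observed squared deviation of per-replicate motif
    proportions with the binomial expectation; the average inflation factor
    phi maps to rho via phi = 1 + (n_mean - 1) * rho.  Clipped at 0.
    """
    if len(replicates) < 2:
        return 0.0
    keys = sorted({k for t in replicates for k in t.counts})
    sizes = np.array([t.total_nonamers for t in replicates], dtype=float)
    phis = []
    for key in keys:
        ks = np.array([t.counts.get(key, 0) for t in replicates], dtype=float)
        p_hat = ks.sum() / sizes.sum()
        if p_hat in (0.0, 1.0):
            continue
        var_binom = sizes * p_hat * (1.0 - p_hat)
        phis.append(float(np.mean((ks - sizes * p_hat) ** 2 / var_binom)))
    if not phis:
        return 0.0
    phi = float(np.mean(phis))
    rho = (phi - 1.0) / (float(np.mean(sizes)) - 1.0)
    return max(0.0, rho)


# ---------------------------------------------------------------------------
# cross-encoding consistency


@dataclass(frozen=True)
class ConsistencyCall:
    chirality_motif: tuple[Chirality, ...]
    window: str
    consistency: str  # "strong" | "moderate" | "none"
    evidence: tuple[DifferentialResult, DifferentialResult]

    @property
    def motif_str(self) -> str:
        return "".join(c.value for c in self.chirality_motif)


def _chirality_key(motif: str, scheme: EncodingScheme) -> tuple[Chirality, ...]:
    return tuple(scheme.base_to_chirality[b] for b in motif)


def call_consistent_motifs(
    results_a: Sequence[DifferentialResult],
    scheme_a: EncodingScheme,
    results_b: Sequence[DifferentialResult],
    scheme_b: EncodingScheme,
    strong_fdr: float = 0.01,
    moderate_fdr: float = 0.05,
) -> list[ConsistencyCall]:
    """Pair motifs across two opposite-encoding libraries in chirality space.

    strong: same effect direction and FDR < 0.01 in both libraries;
    moderate: same direction and FDR < 0.05 (and not strong); otherwise none.
    Libraries sharing an encoding class cannot cancel base-sequence effects,
    which is a configuration error.
    """
    if scheme_a.encoding_class is scheme_b.encoding_class:
        raise ValueError(
            f"libraries {scheme_a.library_id} and {scheme_b.library_id} share "
            f"encoding class {scheme_a.encoding_class.value}; the comparison "
            "would not cancel base-sequence effects"
        )
    index_b = {
        (r.window, _chirality_key(r.motif, scheme_b)): r for r in results_b
    }
    calls = []
    for ra in results_a:
        key = (ra.window, _chirality_key(ra.motif, scheme_a))
        rb = index_b.get(key)
        if rb is None:
            continue
        same_dir = ra.direction == rb.direction and ra.direction != "none"
        if same_dir and ra.fdr < strong_fdr and rb.fdr < strong_fdr:
            consistency = "strong"
        elif same_dir and ra.fdr < moderate_fdr and rb.fdr < moderate_fdr:
            consistency = "moderate"
        else:
            consistency = "none"
        calls.append(ConsistencyCall(key[1], ra.window, consistency, (ra, rb)))
    return calls
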