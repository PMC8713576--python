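"""Map RNase H cleavage sites from fragment-sequencing reads.

The assay is length-based by design: a cleavage fragment's insert length,
measured after 3'-adapter trimming, encodes the cleavage position on the RNA
through a fixed affine map (no alignment involved).  Reads are trimmed with a
cutadapt-style 3' adapter search, validated against a fixed-pattern class
sequence, required to match the construct template exactly, and summarised
into a per-position cleavage profile.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._fastq import read_fastq

__all__ = [
    "PatternSpec",
    "ConstructLayout",
    "CleavageProfile",
    "FRAGMENT_ADAPTER_3P",
    "HIF1A_PATTERN",
    "hif1a_construct",
    "chem_walk_construct",
    "trim_fragment_read",
    "match_pattern",
    "lengths_to_profile",
    "profile_from_reads",
    "profile_from_fastq",
    "predominant_site",
    "compare_profiles",
]

# Small-RNA style 3' sequencing adapter appended to every fragment read.
FRAGMENT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGGC"


@dataclass(frozen=True)
class PatternSpec:
    """Anchored per-position base classes validating an insert's fixed part.

    Each class is a nonempty subset of {A,C,G,T}; an insert matches when its
    first ``len(classes)`` bases each fall in the corresponding class.
    """

    classes: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for i, cls in enumerate(self.classes):
            if not cls or not cls <= frozenset("ACGT"):
                raise ValueError(f"class {i + 1} must be a nonempty subset of ACGT")

    @classmethod
    def from_strings(cls, classes: Sequence[str]) -> "PatternSpec":
        return cls(tuple(frozenset(c) for c in classes))

    def __len__(self) -> int:
        return len(self.classes)


# Default fixed-part pattern for the HIF1A-style construct:
# six free positions, five two-fold degenerate positions, then literal GTT.
HIF1A_PATTERN = PatternSpec.from_strings(
    ["ACGT"] * 6 + ["AT", "CG", "GT", "AC", "AT", "G", "T", "T"]
)

_PERMISSIVE = PatternSpec.from_strings(["ACGT"])


def match_pattern(insert: str, pattern: PatternSpec) -> bool:
    """True iff the insert starts with the pattern's class sequence."""
    if len(insert) < len(pattern):
        return False
    return all(b in cls for b, cls in zip(insert, pattern.classes))


@dataclass(frozen=True)
class ConstructLayout:
    """Geometry shared by the read simulator and the mapper.

    ``template`` is the expected read-side sequence of a full-length
    fragment; every valid insert is a prefix of it.  Insert length ``L`` maps
    to the RNA cleavage position by the 3'-anchored affine rule
    ``position = anchor - L + 1`` (1-based on the RNA).
    """

    rna_id: str
    template: str
    anchor: int
    rna_length: int
    pattern: PatternSpec
    adapter_3p: str = FRAGMENT_ADAPTER_3P
    min_len: int = 14
    max_len: int = 33

    def length_to_position(self, insert_len: int) -> int:
        return self.anchor - insert_len + 1

    def position_to_length(self, position: int) -> int:
        return self.anchor - position + 1


def hif1a_construct() -> ConstructLayout:
    """Synthetic stand-in for the HIF1A cleavage-site construct.

    A synthetic geometry consistent with the 14-33 nt retention window and
    the fixed-part pattern, exposing RNA positions 8..27 to the length
    readout.
    """
    template = "ACGTAC" + "ACGAA" + "GTT" + "ACGTACGTACGTACGTACG"
    assert match_pattern(template, HIF1A_PATTERN)
    return ConstructLayout(
        rna_id="HIF1A_RNA_synthetic",
        template=template,
        anchor=40,
        rna_length=40,
        pattern=HIF1A_PATTERN,
    )


def chem_walk_construct() -> ConstructLayout:
    """Synthetic construct layout for chem-walk fragment reads.

    Positions across the homothymidine tract (duplex positions 5..20) map to
    insert lengths 16..31, inside the default retention window.  The fixed
    part is permissive — the chem-walk design has no class constraints.
    """
    template = "ACGTTGCAGTACGATCGTTACGATGCTAGCATGCA"
    return ConstructLayout(
        rna_id="chem_walk_RNA_synthetic",
        template=template,
        anchor=35,
        rna_length=35,
        pattern=_PERMISSIVE,
    )


def _find_adapter(seq: str, adapter: str, max_error_rate: float) -> int:
    """Leftmost start of ``adapter`` in ``seq`` allowing substitutions only;
    -1 when absent."""
    pos = seq.find(adapter)  # exact fast path
    if pos >= 0:
        return pos
    max_mm = int(max_error_rate * len(adapter))
    if max_mm == 0:
        return -1
    for start in range(0, len(seq) - len(adapter) + 1):
        mm = 0
        for a, b in zip(seq[start : start + len(adapter)], adapter):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return start
    return -1


def trim_fragment_read(
    read: str,
    adapter_3p: str = FRAGMENT_ADAPTER_3P,
    min_len: int = 14,
    max_len: int = 33,
    max_error_rate: float = 0.1,
) -> tuple[str | None, str]:
    """Remove the 3' adapter and apply the insert length window.

    Returns ``(insert, "ok")`` or ``(None, reason)`` with reason one of
    ``no-adapter``, ``too-short``, ``too-long``.  The adapter search allows
    substitutions at the given error rate, no indels.
    """
    if not adapter_3p:
        raise ValueError("adapter_3p must be nonempty")
    pos = _find_adapter(read, adapter_3p, max_error_rate)
    if pos < 0:
        return None, "no-adapter"
    insert = read[:pos]
    if len(insert) < min_len:
        return None, "too-short"
    if len(insert) > max_len:
        return None, "too-long"
    return insert, "ok"


@dataclass
class CleavageProfile:
    """Per-position cleavage read counts on an RNA (1-based positions)."""

    rna_id: str
    counts: np.ndarray  # length = rna_length; counts[i] is position i+1
    total_retained: int
    discards: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if int(self.counts.sum()) != self.total_retained:
            raise ValueError("sum(counts) must equal total_retained")

    @property
    def frequencies(self) -> np.ndarray:
        if self.total_retained == 0:
            raise ValueError("empty profile has no frequencies")
        return self.counts / self.total_retained

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.counts) + 1),
                "count": self.counts,
                "frequency": self.counts / max(self.total_retained, 1),
            }
        )


def lengths_to_profile(
    inserts: Iterable[str], construct: ConstructLayout
) -> CleavageProfile:
    """Summarise template-matching insert lengths into a cleavage profile.

    An insert must equal the expected construct prefix exactly ("perfect
    template match"); mismatching inserts and lengths mapping outside the RNA
    are tallied out, never counted.
    """
    counts = np.zeros(construct.rna_length, dtype=np.int64)
    discards: Counter = Counter()
    retained = 0
    template = construct.template
    for insert in inserts:
        if insert != template[: len(insert)]:
            discards["template-mismatch"] += 1
            continue
        pos = construct.length_to_position(len(insert))
        if not 1 <= pos <= construct.rna_length:
            discards["out-of-range"] += 1
            continue
        counts[pos - 1] += 1
        retained += 1
    return CleavageProfile(construct.rna_id, counts, retained, discards)


def profile_from_reads(
    reads: Iterable[str], construct: ConstructLayout
) -> CleavageProfile:
    """Full fragment pipeline: trim, length window, pattern check, profile."""
    inserts = []
    discards: Counter = Counter()
    for read in reads:
        insert, reason = trim_fragment_read(
            read, construct.adapter_3p, construct.min_len, construct.max_len
        )
        if insert is None:
            discards[reason] += 1
        elif not match_pattern(insert, construct.pattern):
            discards["pattern"] += 1
        else:
            inserts.append(insert)
    profile = lengths_to_profile(inserts, construct)
    profile.discards.update(discards)
    return profile


def profile_from_fastq(path, construct: ConstructLayout) -> CleavageProfile:
    return profile_from_reads((seq for _, seq, _ in read_fastq(path)), construct)


def predominant_site(profile: CleavageProfile) -> int:
    """Position with the highest read count; ties break to the lowest
    position (deterministic)."""
    if profile.total_retained == 0:
        raise ValueError("predominant_site of an empty profile")
    return int(np.argmax(profile.counts)) + 1


def compare_profiles(a: CleavageProfile, b: CleavageProfile) -> float:
    """Total-variation distance between count-normalised profiles, in [0,1]."""
    if a.rna_id != b.rna_id or len(a.counts) != len(b.counts):
        raise ValueError("profiles must describe the same RNA")
    if a.total_retained == 0 or b.total_retained == 0:
        raise ValueError("cannot compare a zero-total profile")
    return 0.5 * float(np.abs(a.frequencies - b.frequencies).sum())
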