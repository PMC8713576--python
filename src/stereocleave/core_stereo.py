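"""Domain types for stereodefined phosphorothioate (PS) oligonucleotides.

A PS linkage replaces one nonbridging phosphate oxygen with sulfur, creating
a chiral center in either the Rp or Sp configuration.  In the chirality-encoded
libraries used by the massive-parallel screen, the *base identity* of a
degenerate DNA position encodes the stereoconfiguration of the PS group on its
3' side, so chirality can be read out by ordinary sequencing.

Coordinates are 1-based throughout: linkage ``i`` sits between bases ``i`` and
``i + 1`` and is said to be 3' of base ``i``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Chirality",
    "StereoOligo",
    "EncodingScheme",
    "ChemWalkCompound",
    "ContactWindow",
    "CleavageSitePrediction",
    "AlphabetError",
    "SCHEMES",
    "encode_chirality",
    "decode_chirality",
    "enumerate_stereo_combinations",
    "build_chem_walk_set",
    "predict_cleavage_sites",
]


class AlphabetError(ValueError):
    """A base falls outside an encoding scheme's degenerate alphabet."""


class Chirality(enum.Enum):
    """Stereoconfiguration of an internucleotide linkage.

    ``PO`` marks an unmodified phosphodiester; ``RANDOM`` a stereorandom PS
    linkage (an unresolved Rp/Sp mixture).  RANDOM is only legal in compound
    *designs* — decoded sequencing output is always a definite Rp or Sp.
    """

    Rp = "Rp"
    Sp = "Sp"
    PO = "PO"
    RANDOM = "RANDOM"

    def __repr__(self) -> str:  # compact in test diffs
        return self.value

    @property
    def symbol(self) -> str:
        return {"Rp": "R", "Sp": "S", "PO": "O", "RANDOM": "X"}[self.value]


_SYMBOL_TO_CHIRALITY = {c.symbol: c for c in Chirality}


@dataclass(frozen=True)
class StereoOligo:
    """A DNA strand with per-linkage chirality annotation.

    An n-base oligo has n - 1 internal linkages.  A fully-PS stereorandom
    oligo of n bases represents 2^(n-1) diastereoisomers.
    """

    bases: str
    linkages: tuple[Chirality, ...]

    def __post_init__(self) -> None:
        if not set(self.bases) <= set("ACGT"):
            raise ValueError(f"non-ACGT base in {self.bases!r}")
        if len(self.linkages) != len(self.bases) - 1:
            raise ValueError(
                f"{len(self.bases)} bases require {len(self.bases) - 1} "
                f"linkages, got {len(self.linkages)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_diastereoisomers(self) -> int:
        """Number of distinct stereoisomers the annotation represents."""
        n_random = sum(1 for c in self.linkages if c is Chirality.RANDOM)
        return 2**n_random

    def to_text(self) -> str:
        """Two-field text form, e.g. ``"TTTTT / SSRS"``."""
        return f"{self.bases} / {''.join(c.symbol for c in self.linkages)}"

    @classmethod
    def from_text(cls, text: str) -> "StereoOligo":
        bases, _, marks = (f.strip() for f in text.partition("/"))
        try:
            linkages = tuple(_SYMBOL_TO_CHIRALITY[m] for m in marks)
        except KeyError as exc:
            raise ValueError(f"unknown chirality symbol {exc.args[0]!r}") from None
        return cls(bases=bases, linkages=linkages)

    def to_fasta(self, name: str) -> str:
        """FASTA-like record with a ``;chirality=`` header extension."""
        marks = "".join(c.symbol for c in self.linkages)
        return f">{name};chirality={marks}\n{self.bases}\n"

    @classmethod
    def from_fasta(cls, record: str) -> tuple[str, "StereoOligo"]:
        header, seq = record.strip().split("\n", 1)
        name, _, marks = header.lstrip(">").partition(";chirality=")
        oligo = cls.from_text(f"{seq.strip()} / {marks}")
        return name, oligo


class EncodingClass(enum.Enum):
    """On the shared {A,T} sub-alphabet, ENC1 and ENC2 assign opposite
    chirality at every position, which lets base-sequence effects cancel when
    the two are compared."""

    ENC1 = "ENC1"  # A -> Rp, T -> Sp
    ENC2 = "ENC2"  # A -> Sp, T -> Rp


@dataclass(frozen=True)
class EncodingScheme:
    """One chirality-encoding library: a 3-letter degenerate alphabet with a
    total base -> {Rp, Sp} map plus the adapters that flank its 9-nt insert."""

    library_id: str
    alphabet: frozenset[str]
    base_to_chirality: Mapping[str, Chirality]
    adapter_5p: str
    adapter_3p: str
    encoding_class: EncodingClass

    def __post_init__(self) -> None:
        if set(self.base_to_chirality) != set(self.alphabet):
            raise ValueError(
                f"{self.library_id}: base_to_chirality must be total on the alphabet"
            )

    def chirality_of(self, base: str) -> Chirality:
        try:
            return self.base_to_chirality[base]
        except KeyError:
            raise AlphabetError(
                f"base {base!r} is outside library {self.library_id}'s "
                f"alphabet {{{','.join(sorted(self.alphabet))}}}"
            ) from None


# Adapter strings as used by the screen's trimming step: the 5' adapter is
# anchored at the read start (distinct for the CS1/CS3 vs CS2/CS4 constructs,
# which is what lets pooled constructs be told apart), the 3' adapter is the
# constant 13-mer that follows the nonamer insert.
_ADAPTER_5P_13 = "TATCTGTGCATCC"  # CS1 / CS3
_ADAPTER_5P_24 = "TATCTGACGTAGG"  # CS2 / CS4
_ADAPTER_3P = "CAGTCAGCTGGAT"

_Rp, _Sp = Chirality.Rp, Chirality.Sp

SCHEMES: dict[str, EncodingScheme] = {
    "L1": EncodingScheme(
        "L1", frozenset("AGT"), {"A": _Rp, "G": _Sp, "T": _Sp},
        _ADAPTER_5P_13, _ADAPTER_3P, EncodingClass.ENC1,
    ),
    "L2": EncodingScheme(
        "L2", frozenset("ACT"), {"A": _Sp, "C": _Sp, "T": _Rp},
        _ADAPTER_5P_24, _ADAPTER_3P, EncodingClass.ENC2,
    ),
    "L3": EncodingScheme(
        "L3", frozenset("AGT"), {"A": _Sp, "G": _Rp, "T": _Rp},
        _ADAPTER_5P_13, _ADAPTER_3P, EncodingClass.ENC2,
    ),
    "L4": EncodingScheme(
        "L4", frozenset("ACT"), {"A": _Rp, "C": _Rp, "T": _Sp},
        _ADAPTER_5P_24, _ADAPTER_3P, EncodingClass.ENC1,
    ),
}


def encode_chirality(bases: str, scheme: EncodingScheme) -> list[Chirality]:
    """Chirality sequence encoded by ``bases`` under ``scheme``.

    Position i (1-based) gives the chirality of the linkage 3' of base i;
    the output therefore has the same length as ``bases``.
    """
    return [scheme.chirality_of(b) for b in bases]


def decode_chirality(bases: str, scheme: EncodingScheme) -> list[Chirality]:
    """Deduce PS stereoconfiguration from sequenced bases.

    The map is the same total function as :func:`encode_chirality`; decoding
    is simply reading it off the sequenced strand.
    """
    return encode_chirality(bases, scheme)


def enumerate_stereo_combinations(n_sites: int) -> list[tuple[Chirality, ...]]:
    """All {Rp, Sp}^n_sites assignments in lexicographic order (Rp < Sp).

    For the three enzyme-contacting linkages (n_sites=3) this is the full set
    of eight stereoconfiguration combinations.
    """
    if n_sites < 0:
        raise ValueError(f"n_sites must be >= 0, got {n_sites}")
    return list(itertools.product((Chirality.Rp, Chirality.Sp), repeat=n_sites))


@dataclass(frozen=True)
class ContactWindow:
    """The three consecutive DNA linkages contacting RNase H.

    ``pocket_index`` is the member bound by the enzyme's phosphate-binding
    pocket; the scissile RNA phosphate sits ``offset_to_scissile`` positions
    from it (magnitude two; the sign is a configurable convention).
    """

    linkage_indices: tuple[int, int, int]
    pocket_index: int
    offset_to_scissile: int = +2

    def __post_init__(self) -> None:
        a, b, c = self.linkage_indices
        if not (b == a + 1 and c == b + 1):
            raise ValueError("linkage_indices must be 3 consecutive indices")
        if self.pocket_index not in self.linkage_indices:
            raise ValueError("pocket_index must lie in linkage_indices")
        if self.offset_to_scissile not in (+2, -2):
            raise ValueError("offset_to_scissile must be +2 or -2")


@dataclass(frozen=True)
class ChemWalkCompound:
    """One member of the chirality walk: identical bases/sugars, differing
    only in which linkages carry the Rp configuration.

    ``tract_linkages`` are the linkage indices internal to the homothymidine
    tract; ``ipccs_site`` is the duplex position of the internal positive
    control cleavage site (IPCCS), a sequence-optimised site present in every
    compound regardless of chirality.
    """

    compound_id: int
    oligo: StereoOligo
    rp_positions: frozenset[int]
    tract_start: int  # 1-based index of the first dT of the tract
    tract_length: int
    ipccs_site: int

    @property
    def tract_linkages(self) -> range:
        # linkages with both flanking bases inside the tract
        return range(self.tract_start, self.tract_start + self.tract_length - 1)


# Synthetic stand-in segments for the chem-walk design.  The IPCCS segment is a
# mixed-base stretch standing in for a sequence-optimised cleavage site; what
# matters structurally is a defined cleavage position followed by a pure
# 11-dT platform over which the single Rp linkage is walked.
_IPCCS_SEGMENT = "CAGCAGTA"  # synthetic stand-in, bases 1..8
_TAIL_SEGMENT = "CAGC"  # synthetic 3' flank
_IPCCS_SITE = 5  # duplex position of the control cleavage site
_DEFAULT_OFFSET = +2


def build_chem_walk_set(tract_length: int = 11) -> list[ChemWalkCompound]:
    """The seven-compound chirality walk over a homothymidine tract.

    Compounds 1-5 carry exactly one Rp linkage walked across the dT tract;
    compound 6 carries a single Rp two linkages from the IPCCS only;
    compound 7 carries no Rp at all (every PS linkage Sp).  All compounds
    share identical bases; only ``rp_positions`` differs.
    """
    if tract_length < 3:
        raise ValueError(f"tract_length must be >= 3, got {tract_length}")
    bases = _IPCCS_SEGMENT + "T" * tract_length + _TAIL_SEGMENT
    tract_start = len(_IPCCS_SEGMENT) + 1
    n_linkages = len(bases) - 1

    tract_linkages = list(range(tract_start, tract_start + tract_length - 1))
    # five walk positions spread across the tract interior
    step = max(1, (len(tract_linkages) - 1) // 4)
    walk = [tract_linkages[min(i * step, len(tract_linkages) - 1)] for i in range(5)]
    if len(set(walk)) < 5:
        walk = tract_linkages[:5]

    ipccs_rp = _IPCCS_SITE - _DEFAULT_OFFSET  # the linkage augmenting the IPCCS

    def compound(cid: int, rp: Iterable[int]) -> ChemWalkCompound:
        rp = frozenset(rp)
        linkages = tuple(
            Chirality.Rp if i in rp else Chirality.Sp
            for i in range(1, n_linkages + 1)
        )
        return ChemWalkCompound(
            compound_id=cid,
            oligo=StereoOligo(bases, linkages),
            rp_positions=rp,
            tract_start=tract_start,
            tract_length=tract_length,
            ipccs_site=_IPCCS_SITE,
        )

    compounds = [compound(i + 1, {walk[i]}) for i in range(5)]
    compounds.append(compound(6, {ipccs_rp}))
    compounds.append(compound(7, set()))
    return compounds


@dataclass(frozen=True)
class CleavageSitePrediction:
    """A predicted RNA cleavage position with a qualitative intensity label."""

    position: int
    label: str  # "rp-guided" | "control" | "diffuse"


@dataclass
class PredictionResult:
    sites: list[CleavageSitePrediction]
    warnings: list[str] = field(default_factory=list)

    @property
    def positions(self) -> set[int]:
        return {s.position for s in self.sites}


def predict_cleavage_sites(
    compound: ChemWalkCompound,
    window: ContactWindow | None = None,
    rna_length: int | None = None,
) -> PredictionResult:
    """Predict RNA cleavage sites from Rp linkage placement.

    Each Rp-PS linkage recruits the phosphate-binding pocket and promotes a
    scissile phosphate ``offset_to_scissile`` positions away (default +2).
    The IPCCS is always emitted (it cleaves on base sequence alone).  A
    compound with no Rp linkage loses positional guidance and yields diffuse
    cleavage across the tract-opposed positions.  Predicted positions falling
    outside the duplex are dropped with a warning record.
    """
    offset = window.offset_to_scissile if window is not None else _DEFAULT_OFFSET
    if rna_length is None:
        rna_length = len(compound.oligo)

    sites: list[CleavageSitePrediction] = []
    warnings: list[str] = []
    sites.append(CleavageSitePrediction(compound.ipccs_site, "control"))
    for p in sorted(compound.rp_positions):
        pos = p + offset
        if 1 <= pos <= rna_length:
            if pos != compound.ipccs_site:
                sites.append(CleavageSitePrediction(pos, "rp-guided"))
        else:
            warnings.append(
                f"compound {compound.compound_id}: Rp at linkage {p} predicts "
                f"position {pos} outside the duplex (1..{rna_length}); dropped"
            )
    if not compound.rp_positions:
        for p in compound.tract_linkages:
            pos = p + offset
            if 1 <= pos <= rna_length and pos != compound.ipccs_site:
                sites.append(CleavageSitePrediction(pos, "diffuse"))
    return PredictionResult(sites=sites, warnings=warnings)
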