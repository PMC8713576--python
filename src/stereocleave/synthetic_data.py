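"""Synthetic inputs with planted, recoverable truths.

Everything the downstream pipelines consume is generated here: pools of
chirality-encoded circular 9-mer substrates, limited-digestion outcomes that
partition molecules into uncleaved-circular and cleaved-linear fractions,
FASTQ reads for the screen and for the fragment-length cleavage assay, kinetic
competition trajectories, and quadruplicate dose-response tables.

The planted truth model for the screen is deliberately minimal: cleavage rate
is a per-window product of a base-sequence weight and a chirality gate that
suppresses molecules whose every enzyme-contact window is all-Sp — the
sequence-independent preference the screen is designed to recover.  The
enzyme is free to choose its register on the 9-mer, modelled as a max over
sliding 3-linkage contact windows.

PCR amplification bias is not modelled; read counts are multinomial draws
over molecules.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._fastq import DEFAULT_QUAL, Record
from .cleavage_map import ConstructLayout
from .core_stereo import Chirality, EncodingScheme, decode_chirality

__all__ = [
    "KineticParams",
    "ScreenTruth",
    "ReadModel",
    "Substrate",
    "CompetitionResult",
    "ConfigurationError",
    "draw_substrate_pool",
    "cleavage_rate",
    "simulate_screen_digestion",
    "simulate_competition",
    "gillespie_competition",
    "emit_screen_reads",
    "simulate_cleavage_map_reads",
    "four_pl",
    "simulate_dose_response",
]


class ConfigurationError(ValueError):
    """A generator was configured inconsistently (e.g. missing motif weight)."""


_BASES = "ACGT"


# ---------------------------------------------------------------------------
# screen substrates and limited digestion


@dataclass(frozen=True)
class Substrate:
    """One circular-substrate molecule: a 9-nt randomized region with the
    chirality decoded from its bases under the library's encoding."""

    bases: str
    chirality: tuple[Chirality, ...]
    library_id: str


class SubstratePool(Sequence):
    """A pool of 9-mer substrates stored column-wise for speed.

    Behaves as a sequence of :class:`Substrate`; bulk operations (digestion,
    nonamer counting, read emission) use the integer-coded base matrix
    directly so synthesis-scale pools stay cheap.
    """

    def __init__(self, codes: np.ndarray, scheme: EncodingScheme) -> None:
        self.codes = np.asarray(codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[1] != 9:
            raise ValueError("codes must be (n_molecules, 9)")
        self.scheme = scheme
        self.alphabet = np.array(sorted(scheme.alphabet))
        # per-base Sp indicator under the scheme, by alphabet code
        sp_by_code = np.array(
            [scheme.base_to_chirality[b] is Chirality.Sp for b in self.alphabet]
        )
        self.is_sp = sp_by_code[self.codes]

    def __len__(self) -> int:
        return self.codes.shape[0]

    def bases_of(self, i: int) -> str:
        return "".join(self.alphabet[self.codes[i]])

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        bases = self.bases_of(int(i))
        return Substrate(
            bases, tuple(decode_chirality(bases, self.scheme)), self.scheme.library_id
        )

    def base_frequencies(self) -> np.ndarray:
        """(9, 3) per-position base frequencies over the sorted alphabet."""
        out = np.empty((9, 3))
        for j in range(9):
            out[j] = np.bincount(self.codes[:, j], minlength=3) / len(self)
        return out

    def nonamer_counts(self, mask: np.ndarray | None = None) -> dict[str, int]:
        """Unique-nonamer counts (optionally of a molecule subset), as fed to
        the screen's counting stage."""
        codes = self.codes if mask is None else self.codes[mask]
        packed = codes.astype(np.int64) @ (3 ** np.arange(8, -1, -1, dtype=np.int64))
        counts = np.bincount(packed, minlength=3**9)
        present = np.flatnonzero(counts)
        digits = (present[:, None] // 3 ** np.arange(8, -1, -1)) % 3
        return {
            "".join(row): int(c)
            for row, c in zip(self.alphabet[digits], counts[present])
        }


@dataclass(frozen=True)
class ScreenTruth:
    """Planted cleavage-rate model for the screen.

    ``seq_weight`` maps base trimers to relative cleavage rates (``None``
    means 1 for every motif — a pure-chirality truth); ``chirality_gate``
    multiplies the rate when all three contact linkages are Sp;
    ``exposure`` scales the overall digestion extent (dimensionless; real
    enzyme-dose-and-time conditions have no fixed mapping to rate units, so
    exposure is a free parameter).
    """

    seq_weight: Mapping[str, float] | None = None
    chirality_gate: float = 0.05
    exposure: float = 6.0

    def __post_init__(self) -> None:
        if not 0 <= self.chirality_gate <= 1:
            raise ValueError("chirality_gate must lie in [0, 1]")
        if self.seq_weight is not None and any(
            w <= 0 for w in self.seq_weight.values()
        ):
            raise ValueError("seq_weight values must be > 0")

    def weight(self, motif: str) -> float:
        if self.seq_weight is None:
            return 1.0
        try:
            return self.seq_weight[motif]
        except KeyError:
            raise ConfigurationError(
                f"motif {motif!r} absent from seq_weight table"
            ) from None


@dataclass(frozen=True)
class ReadModel:
    """Sequencer stand-in: read depth per sample and substitution error."""

    n_reads: int = 50_000
    per_base_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_error <= 1:
            raise ValueError("per_base_error must lie in [0, 1]")


def draw_substrate_pool(
    scheme: EncodingScheme, n_molecules: int = 1_000_000, seed: int = 0
) -> SubstratePool:
    """Draw a pool of 9-mer substrates, each position uniform over the
    library's 3-letter alphabet (the 1:1:1 amidite mix), chirality decoded
    from bases under the scheme.

    The default pool size keeps every one of the 3^9 nonamers represented
    dozens of times, emulating a synthesis-scale library.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=(n_molecules, 9), dtype=np.uint8)
    return SubstratePool(codes, scheme)


def cleavage_rate(substrate: Substrate, truth: ScreenTruth) -> float:
    """Planted per-molecule rate: max over sliding 3-linkage contact windows
    of seq_weight(window bases) x (gate when the window is all-Sp)."""
    best = 0.0
    chir = substrate.chirality
    for i in range(len(substrate.bases) - 2):
        r = truth.weight(substrate.bases[i : i + 3])
        if all(c is Chirality.Sp for c in chir[i : i + 3]):
            r *= truth.chirality_gate
        best = max(best, r)
    return best


def _pool_rates(pool: SubstratePool, truth: ScreenTruth) -> np.ndarray:
    if truth.seq_weight is None:
        # uniform weights: the 7 sliding windows jointly cover all 9
        # positions, so any Rp anywhere puts one window at full rate and the
        # max collapses to gate^[all-Sp molecule]
        return np.where(pool.is_sp.all(axis=1), truth.chirality_gate, 1.0)
    else:
        weight_table = np.empty(27)
        for m in range(27):
            motif = "".join(pool.alphabet[[m // 9, (m // 3) % 3, m % 3]])
            weight_table[m] = truth.weight(motif)
    codes = pool.codes.astype(np.int64)
    best = np.zeros(len(pool))
    for i in range(7):
        motif_idx = codes[:, i] * 9 + codes[:, i + 1] * 3 + codes[:, i + 2]
        r = weight_table[motif_idx]
        all_sp = pool.is_sp[:, i] & pool.is_sp[:, i + 1] & pool.is_sp[:, i + 2]
        r = np.where(all_sp, r * truth.chirality_gate, r)
        np.maximum(best, r, out=best)
    return best


def simulate_screen_digestion(
    pool: Sequence[Substrate], truth: ScreenTruth, seed: int
) -> np.ndarray:
    """Limited-digestion outcome per molecule.

    Returns a boolean array, True = cleaved (linear fraction), with
    P(cleaved) = 1 - exp(-rate x exposure), Bernoulli-drawn under ``seed``.
    """
    if len(pool) == 0:
        raise ValueError("pool must be nonempty")
    rng = np.random.default_rng(seed)
    if isinstance(pool, SubstratePool):
        rates = _pool_rates(pool, truth)
    else:
        rates = np.array([cleavage_rate(s, truth) for s in pool])
    p = 1.0 - np.exp(-rates * truth.exposure)
    return rng.random(len(pool)) < p


# ---------------------------------------------------------------------------
# kinetic competition


@dataclass(frozen=True)
class KineticParams:
    """Mass-action rates for the RNase H catalytic cycle
    E + S <-> ES -> EP -> E + P with optional competitive inhibitor
    E + I <-> EI.

    The chirality of the linkage docked in the phosphate-binding pocket sets
    the association multiplier ``alpha`` (Sp associates weakly) and the
    product off-rate ``k_off_product`` (Rp holds the cleaved duplex, slowing
    enzyme recycling; Sp releases fast).  Units are arbitrary but coherent:
    concentrations in c, time in t, first-order rates 1/t, second-order
    rates 1/(c*t).
    """

    k_on_base: float = 10.0
    alpha: Mapping[Chirality, float] = field(
        default_factory=lambda: {Chirality.Rp: 1.0, Chirality.PO: 1.0, Chirality.Sp: 0.1}
    )
    k_cat: float = 1.0
    k_off_substrate: float = 1.0
    k_off_product: Mapping[Chirality, float] = field(
        default_factory=lambda: {Chirality.Rp: 0.05, Chirality.PO: 0.05, Chirality.Sp: 5.0}
    )
    inhibitor_conc: float = 0.0
    inhibitor_k_on: float = 10.0
    inhibitor_k_off: float = 0.01
    enzyme_total: float = 0.1
    substrate_conc: float = 10.0
    t_end: float = 30.0

    def __post_init__(self) -> None:
        scalars = (
            self.k_on_base, self.k_cat, self.k_off_substrate,
            self.inhibitor_conc, self.inhibitor_k_on, self.inhibitor_k_off,
            self.enzyme_total, self.substrate_conc, self.t_end,
        )
        if any(v < 0 for v in scalars):
            raise ValueError("rates and concentrations must be >= 0")
        if not self.alpha[Chirality.Sp] < self.alpha[Chirality.Rp]:
            raise ValueError("alpha(Sp) must be < alpha(Rp)")
        if not self.k_off_product[Chirality.Sp] > self.k_off_product[Chirality.Rp]:
            raise ValueError("k_off_product(Sp) must be > k_off_product(Rp)")

    def with_inhibitor(self, conc: float = 10.0) -> "KineticParams":
        return replace(self, inhibitor_conc=conc)

    def pocket_rates(self, pocket: Chirality) -> tuple[float, float]:
        """(k_on, k_off_product) for a given pocket-linkage chirality."""
        return self.k_on_base * self.alpha[pocket], self.k_off_product[pocket]


def _class_label(assignment: Sequence[Chirality]) -> str:
    return "".join(c.symbol for c in assignment)


@dataclass
class CompetitionResult:
    """Cleaved-fraction trajectories per stereo class (separate reactions,
    shared parameters)."""

    times: np.ndarray
    cleaved_fraction: np.ndarray  # shape (n_times, n_classes)
    labels: list[str]
    params: KineticParams

    def final_fraction(self, label: str) -> float:
        return float(self.cleaved_fraction[-1, self.labels.index(label)])


def _single_class_rhs(kon: float, koff_s: float, kcat: float, koff_p: float,
                      kon_i: float, koff_i: float):
    def rhs(_t, y):
        e, s, es, ep, p, i, ei = y
        bind = kon * e * s
        bind_i = kon_i * e * i
        return [
            -bind + koff_s * es + koff_p * ep - bind_i + koff_i * ei,
            -bind + koff_s * es,
            bind - (koff_s + kcat) * es,
            kcat * es - koff_p * ep,
            koff_p * ep,
            -bind_i + koff_i * ei,
            bind_i - koff_i * ei,
        ]

    return rhs


def simulate_competition(
    classes: Sequence[Sequence[Chirality]],
    params: KineticParams,
    n_times: int = 101,
) -> CompetitionResult:
    """Integrate the catalytic-cycle ODEs for each contact-window stereo
    class (pocket = first member, 5'-most varied site).

    Each class runs as its own reaction with the full enzyme budget — the
    assay setup is one tube per compound, with the inhibitor (when present)
    competing for the enzyme inside each tube.  Mass balance
    S + ES + EP + P = S_total holds along the trajectory.
    """
    times = np.linspace(0.0, params.t_end, n_times)
    out = np.zeros((n_times, len(classes)))
    labels = []
    for j, assignment in enumerate(classes):
        pocket = assignment[0]
        if pocket is Chirality.RANDOM:
            raise ValueError("RANDOM pocket chirality is not simulatable directly")
        kon, koff_p = params.pocket_rates(pocket)
        rhs = _single_class_rhs(
            kon, params.k_off_substrate, params.k_cat, koff_p,
            params.inhibitor_k_on, params.inhibitor_k_off,
        )
        y0 = [params.enzyme_total, params.substrate_conc, 0.0, 0.0, 0.0,
              params.inhibitor_conc, 0.0]
        sol = solve_ivp(
            rhs, (0.0, params.t_end), y0, t_eval=times,
            method="LSODA", rtol=1e-8, atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(
                f"stiff integration failed for class {_class_label(assignment)} "
                f"with params {params!r}: {sol.message}"
            )
        out[:, j] = sol.y[4] / params.substrate_conc if params.substrate_conc else 0.0
        labels.append(_class_label(assignment))
    return CompetitionResult(times, out, labels, params)


def gillespie_competition(
    assignment: Sequence[Chirality],
    params: KineticParams,
    system_size: float,
    seed: int,
) -> float:
    """Stochastic (Gillespie SSA) cleaved fraction at t_end for one class.

    ``system_size`` converts concentrations to copy numbers (count =
    round(conc * system_size)); second-order rates scale as k/system_size.
    Serves as the stochastic oracle for the deterministic backend.
    """
    rng = np.random.default_rng(seed)
    pocket = assignment[0]
    kon, koff_p = params.pocket_rates(pocket)
    omega = float(system_size)
    e = round(params.enzyme_total * omega)
    s = round(params.substrate_conc * omega)
    i = round(params.inhibitor_conc * omega)
    es = ep = p = ei = 0
    s_total = s
    t = 0.0
    while t < params.t_end:
        props = (
            kon / omega * e * s,
            params.k_off_substrate * es,
            params.k_cat * es,
            koff_p * ep,
            params.inhibitor_k_on / omega * e * i,
            params.inhibitor_k_off * ei,
        )
        total = sum(props)
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= params.t_end:
            break
        r = rng.random() * total
        acc = 0.0
        for idx, a in enumerate(props):
            acc += a
            if r < acc:
                break
        if idx == 0:
            e -= 1; s -= 1; es += 1
        elif idx == 1:
            e += 1; s += 1; es -= 1
        elif idx == 2:
            es -= 1; ep += 1
        elif idx == 3:
            ep -= 1; e += 1; p += 1
        elif idx == 4:
            e -= 1; i -= 1; ei += 1
        else:
            e += 1; i += 1; ei -= 1
        assert s + es + ep + p == s_total
    return p / s_total if s_total else 0.0


# ---------------------------------------------------------------------------
# read emission


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    chars = list(seq)
    for k in np.flatnonzero(rng.random(len(chars)) < rate):
        chars[k] = rng.choice([b for b in _BASES if b != chars[k]])
    return "".join(chars)


_SCREEN_FILLER = "GTCAGTCAGGATCCGA"  # constant downstream filler on screen reads


def emit_screen_reads(
    pool: Sequence[Substrate],
    cleaved: np.ndarray,
    model: ReadModel,
    scheme: EncodingScheme,
    sample_index: str = "ACGTAC",
) -> dict[str, list[Record]]:
    """Sequencing reads for the two gel fractions of one digestion.

    Returns ``{"uncleaved_circular": [...], "cleaved_linear": [...]}``; each
    fraction gets ``model.n_reads`` reads, multinomial over its molecules
    (gel extraction fixes depth per band regardless of band mass).  Read
    layout: 5' adapter + 9-mer insert + 3' adapter + constant filler, with
    the sample index on the title line.
    """
    cleaved = np.asarray(cleaved, dtype=bool)
    if len(cleaved) != len(pool):
        raise ValueError("cleaved mask must align with the pool")
    rng = np.random.default_rng(model.seed)

    def bases_iter(mask: np.ndarray) -> tuple[int, Callable[[int], str]]:
        if isinstance(pool, SubstratePool):
            idx = np.flatnonzero(mask)
            return len(idx), lambda j: pool.bases_of(int(idx[j]))
        molecules = [m for m, keep in zip(pool, mask) if keep]
        return len(molecules), lambda j: molecules[j].bases

    out: dict[str, list[Record]] = {}
    for fraction, mask in (
        ("uncleaved_circular", ~cleaved),
        ("cleaved_linear", cleaved),
    ):
        n_mol, get_bases = bases_iter(mask)
        records: list[Record] = []
        if n_mol:
            counts = rng.multinomial(model.n_reads, np.full(n_mol, 1.0 / n_mol))
            r = 0
            for j in np.flatnonzero(counts):
                seq = (
                    scheme.adapter_5p + get_bases(j) + scheme.adapter_3p + _SCREEN_FILLER
                )
                for _ in range(int(counts[j])):
                    records.append(
                        (
                            f"{scheme.library_id}_{fraction}_{r} 1:N:0:{sample_index}",
                            _apply_errors(seq, model.per_base_error, rng),
                            DEFAULT_QUAL * len(seq),
                        )
                    )
                    r += 1
        out[fraction] = records
    return out


def simulate_cleavage_map_reads(
    construct: ConstructLayout,
    truth: Mapping[int, float],
    model: ReadModel,
) -> list[Record]:
    """Fragment reads whose insert length encodes the cleavage position.

    ``truth`` maps RNA positions to nonnegative intensities; read counts are
    multinomial over positions proportional to intensity.  Each read is the
    construct-template prefix of the encoding length plus the 3' adapter and
    a constant tail.
    """
    positions = sorted(truth)
    intensities = np.array([truth[p] for p in positions], dtype=float)
    if (intensities < 0).any():
        raise ValueError("cleavage intensities must be >= 0")
    if intensities.sum() <= 0:
        raise ValueError("at least one positive intensity required")
    for p in positions:
        if not 1 <= p <= construct.rna_length:
            raise ValueError(
                f"truth position {p} outside RNA 1..{construct.rna_length}"
            )
    rng = np.random.default_rng(model.seed)
    counts = rng.multinomial(model.n_reads, intensities / intensities.sum())
    tail = "ATCTCGTATGCCG"
    records: list[Record] = []
    r = 0
    for pos, c in zip(positions, counts):
        length = construct.position_to_length(pos)
        if not 0 < length <= len(construct.template):
            raise ValueError(
                f"position {pos} maps to insert length {length}, outside the "
                f"template (1..{len(construct.template)})"
            )
        seq = construct.template[:length] + construct.adapter_3p + tail
        for _ in range(int(c)):
            records.append(
                (
                    f"{construct.rna_id}_pos{pos}_{r}",
                    _apply_errors(seq, model.per_base_error, rng),
                    DEFAULT_QUAL * len(seq),
                )
            )
            r += 1
    return records


# ---------------------------------------------------------------------------
# dose-response


def four_pl(x, b: float, c: float, d: float, e: float):
    """Four-parameter log-logistic: f(x) = c + (d - c) / (1 + (x/e)^b)."""
    x = np.asarray(x, dtype=float)
    return c + (d - c) / (1.0 + (x / e) ** b)


def simulate_dose_response(
    params_per_compound: Mapping[str, tuple[float, float, float, float]],
    concentrations: Sequence[float],
    replicates: int = 4,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Quadruplicate %-of-control responses on planted 4PL curves.

    ``params_per_compound`` maps compound name to (b, c, d, e); responses are
    f(conc) + N(0, noise_sd) in percentage points (untreated level = d,
    conventionally 100%).  Returns a long table
    (compound, concentration, response_percent).
    """
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for name, (b, c, d, e) in params_per_compound.items():
        for x in conc:
            mu = float(four_pl(x, b, c, d, e))
            for _ in range(replicates):
                rows.append(
                    (name, x, mu + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
                )
    return pd.DataFrame(rows, columns=["compound", "concentration", "response_percent"])
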