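"""Two-stage generative model for haplotypes and sequencing reads.

The model explains aligned reads from a K-ploid sample (or a mixture of
cell populations) in two stages.  In the *evolution stage* each of the K
hidden consensus haplotypes evolves independently from the reference: every
reference position is kept with probability ``gamma_1``, substituted with
``gamma_2`` (the new base uniform over the three alternatives) or deleted
with ``gamma_3``; every inter-base gap receives a single-base insertion
with probability ``beta``.  In the *sequencing stage* a read is emitted
from a segment of one consensus: each consensus position is sequenced
correctly (``p1``), mismatched (``p2``, emitted base uniform over the three
alternatives) or starts a deletion segment (``p3``) whose length minus one
is Poisson(``lambda_del``); each gap independently receives an insertion
error with probability ``p4``, length minus one Poisson(``lambda_ins``),
inserted bases uniform.

All sequences are indexed against the reference: positions are 1-based
inclusive and gap ``g`` sits between positions ``g`` and ``g+1``.  A ``-``
state marks a deleted reference position; insertions live in a sparse
``{gap: string}`` map.  This module holds the domain types, the event
summaries of consensus-vs-reference and read-vs-consensus comparisons, and
every log-likelihood term.  Inference and simulation are built on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BASES",
    "GAP",
    "ReferenceSequence",
    "ConsensusHaplotype",
    "EvolutionParams",
    "SequencingErrorProfile",
    "AlignedRead",
    "ReadConsensusEvents",
    "ConsensusReferenceEvents",
    "MixtureWeights",
    "summarize_consensus_vs_reference",
    "evolution_log_likelihood",
    "summarize_read_vs_consensus",
    "truncated_poisson_log_pmf",
    "read_log_likelihood",
    "complete_data_log_likelihood",
]

BASES = "ACGT"
GAP = "-"

# integer codes used internally; N (ambiguous reference base) is carried
# through but excluded from event counting
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
_ALPHABET = np.frombuffer(b"ACGT-N", dtype=np.uint8)
_GAP_CODE = 4
_N_CODE = 5

_LOG_THIRD = math.log(1.0 / 3.0)
_LOG_QUARTER = math.log(0.25)

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _ch, _c in _CODE.items():
    _ENCODE_LUT[ord(_ch)] = _c
    _ENCODE_LUT[ord(_ch.lower())] = _c


class ModelError(ValueError):
    """Structural error in model inputs (lengths, alphabets, coordinates)."""


def encode_states(seq: str) -> np.ndarray:
    """Encode a state string over {A,C,G,T,-,N} as uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if np.any(codes == 255):
        bad = seq[int(np.argmax(codes == 255))]
        raise ModelError(f"invalid state character {bad!r}")
    return codes


def decode_states(codes: np.ndarray) -> str:
    return _ALPHABET[codes].tobytes().decode("ascii")


def _run_slices(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) offsets of maximal True runs in a 1-D mask."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = (np.flatnonzero(d == 1) + 1).tolist()
    stops = (np.flatnonzero(d == -1) + 1).tolist()
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(int(mask.size))
    return list(zip(starts, stops))


def _count_log(count: float, prob: float) -> float:
    """count * log(prob) with the conventions 0*log(0)=0, n*log(0)=-inf."""
    if count == 0:
        return 0.0
    if prob <= 0.0:
        return -math.inf
    return count * math.log(prob)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSequence:
    """The genomic backbone of length L0 to which everything is indexed."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        if len(bases) < 2:
            raise ModelError("reference must have at least 2 bases")
        if any(b not in "ACGTN" for b in set(bases)):
            raise ModelError("reference bases must be in {A,C,G,T,N}")

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def n_gaps(self) -> int:
        """Number of inter-base gaps, exactly L0 - 1."""
        return len(self.bases) - 1

    def codes(self) -> np.ndarray:
        return encode_states(self.bases)


@dataclass
class ConsensusHaplotype:
    """One of the K hidden sequences, represented against the reference.

    ``states`` has one entry per reference position over {A,C,G,T,-}
    (plus N carried through at ambiguous reference positions); ``insertions``
    maps a gap index g (1-based, between positions g and g+1) to the
    inserted base string.
    """

    index: int
    states: str
    insertions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        encode_states(self.states)  # alphabet check
        for g, seq in self.insertions.items():
            if not seq:
                raise ModelError(f"empty insertion at gap {g}")
            if g < 1 or g > len(self.states) - 1:
                raise ModelError(f"insertion gap {g} outside [1, L0-1]")
            if any(b not in "ACGTN" for b in seq):
                raise ModelError(f"invalid insertion string {seq!r} at gap {g}")

    def codes(self) -> np.ndarray:
        return encode_states(self.states)

    def literal_sequence(self) -> str:
        """The actual haplotype sequence: '-' removed, insertions spliced in."""
        parts: list[str] = []
        for i, s in enumerate(self.states, start=1):
            if s != GAP:
                parts.append(s)
            if i in self.insertions:
                parts.append(self.insertions[i])
        return "".join(parts)


@dataclass(frozen=True)
class EvolutionParams:
    """Per-haplotype evolution probabilities (gamma_1, gamma_2, gamma_3; beta)."""

    gamma: tuple[float, float, float]
    beta: float

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.gamma)
        object.__setattr__(self, "gamma", g)
        if len(g) != 3 or any(x < 0 or x > 1 for x in g):
            raise ModelError("gamma must be 3 probabilities in [0,1]")
        if abs(sum(g) - 1.0) > 1e-12:
            raise ModelError("gamma components must sum to 1")
        if not (0.0 <= self.beta < 1.0):
            raise ModelError("beta must be in [0,1)")

    @classmethod
    def from_four(cls, values: Sequence[float]) -> "EvolutionParams":
        """Parse a 4-tuple (gamma1, gamma2, gamma3, beta).

        Published parameterizations are often written as four numbers whose
        fourth entry plays the insertion-per-gap role; the first three are
        renormalized to sum to one if needed.
        """
        if len(values) != 4:
            raise ModelError("expected 4 values (gamma1, gamma2, gamma3, beta)")
        g = [float(v) for v in values[:3]]
        total = sum(g)
        if total <= 0:
            raise ModelError("gamma components must be positive overall")
        if abs(total - 1.0) > 1e-12:
            g = [x / total for x in g]
            g[0] = 1.0 - g[1] - g[2]
        return cls(gamma=(g[0], g[1], g[2]), beta=float(values[3]))


@dataclass(frozen=True)
class SequencingErrorProfile:
    """Sequencing-stage error parameters psi = (p1, p2, p3, p4, lambdas).

    ``p1 + p2 + p3 = 1``: at each comparable position the machine either
    emits the correct base, a mismatched base, or starts a deletion segment.
    ``p4`` is the per-gap insertion probability; segment lengths minus one
    follow Poisson(lambda) laws.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    lambda_ins: float
    lambda_del: float

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0 or (name == "p1" and v == 1.0)):
                raise ModelError(f"{name}={v} outside [0,1)")
        if abs(self.p1 + self.p2 + self.p3 - 1.0) > 1e-12:
            raise ModelError("p1 + p2 + p3 must sum to 1")
        if self.lambda_ins <= 0 or self.lambda_del <= 0:
            raise ModelError("lambda_ins and lambda_del must be positive")


@dataclass(frozen=True)
class MixtureWeights:
    """Haplotype mixture weights alpha; P(read drawn from haplotype k) = alpha_k."""

    alpha: tuple[float, ...]

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.alpha)
        object.__setattr__(self, "alpha", a)
        if not a or any(x <= 0 or x > 1 for x in a):
            raise ModelError("alpha components must be in (0,1]")
        if abs(sum(a) - 1.0) > 1e-12:
            raise ModelError("alpha must sum to 1")

    def __len__(self) -> int:
        return len(self.alpha)

    def log(self) -> np.ndarray:
        return np.log(np.asarray(self.alpha))


@dataclass
class AlignedRead:
    """One read's observations over its covered reference interval [start, end].

    ``states`` has one entry per covered reference position (a '-' means the
    read deletes that position); ``insertions`` maps gap g in [start, end-1]
    to the read's inserted string.  ``truth_source`` records the generating
    haplotype in simulations.
    """

    name: str
    start: int
    end: int
    states: str
    insertions: dict[int, str] = field(default_factory=dict)
    truth_source: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ModelError(f"read {self.name}: invalid interval "
                             f"[{self.start}, {self.end}]")
        if len(self.states) != self.end - self.start + 1:
            raise ModelError(f"read {self.name}: states length "
                             f"{len(self.states)} != interval length")
        encode_states(self.states)
        if set(self.states) <= {GAP}:
            raise ModelError(f"read {self.name}: all states deleted")
        for g in self.insertions:
            if g < self.start or g > self.end - 1:
                raise ModelError(f"read {self.name}: insertion gap {g} outside "
                                 f"[{self.start}, {self.end - 1}]")

    @property
    def length(self) -> int:
        """Covered interval length Li = end - start + 1."""
        return self.end - self.start + 1

    def codes(self) -> np.ndarray:
        return encode_states(self.states)


@dataclass(frozen=True)
class ReadConsensusEvents:
    """Event summary of one read compared with one consensus haplotype.

    ``n_correct``/``n_mismatch`` count comparable positions (consensus state
    not '-'); ``del_segments``/``ins_segments`` are the lengths of maximal
    deletion/insertion error segments; ``n_gaps_no_insertion`` is the number
    of gaps without an insertion error, W = (Li - 1) - V.
    """

    n_correct: int
    n_mismatch: int
    del_segments: tuple[int, ...]
    ins_segments: tuple[int, ...]
    n_gaps_no_insertion: int

    def __post_init__(self) -> None:
        if min(self.n_correct, self.n_mismatch, self.n_gaps_no_insertion) < 0:
            raise ModelError("event counts must be non-negative")
        if any(l < 1 for l in self.del_segments + self.ins_segments):
            raise ModelError("segment lengths must be >= 1")

    @property
    def n_del_segments(self) -> int:
        return len(self.del_segments)

    @property
    def n_ins_segments(self) -> int:
        return len(self.ins_segments)

    @property
    def n_deleted_positions(self) -> int:
        return int(sum(self.del_segments))

    @property
    def n_inserted_bases(self) -> int:
        return int(sum(self.ins_segments))


@dataclass(frozen=True)
class ConsensusReferenceEvents:
    """Evolution-stage event counts of one consensus against the reference."""

    n_match: int
    n_substitution: int
    n_deletion: int
    n_insertion: int
    n_inserted_bases: int = -1  # defaults to n_insertion (single-base events)

    def __post_init__(self) -> None:
        if self.n_inserted_bases < 0:
            object.__setattr__(self, "n_inserted_bases", self.n_insertion)
        if min(self.n_match, self.n_substitution, self.n_deletion,
               self.n_insertion) < 0:
            raise ModelError("event counts must be non-negative")


# ---------------------------------------------------------------------------
# event summaries
# ---------------------------------------------------------------------------


def summarize_consensus_vs_reference(
    consensus: ConsensusHaplotype, reference: ReferenceSequence
) -> ConsensusReferenceEvents:
    """Classify every reference position as match / substitution / deletion.

    Ambiguous reference bases (N) count as matches and consensus insertions
    are counted per gap (the number of inserted bases is tracked separately
    for the uniform base-content term).
    """
    cvec = consensus.codes()
    rvec = reference.codes()
    if cvec.size != rvec.size:
        raise ModelError(
            f"consensus length {cvec.size} != reference length {rvec.size}")
    ambiguous = (rvec == _N_CODE) | (cvec == _N_CODE)
    deletion = (cvec == _GAP_CODE) & ~ambiguous
    match = ((cvec == rvec) | ambiguous) & ~deletion
    n_match = int(np.count_nonzero(match))
    n_del = int(np.count_nonzero(deletion))
    n_sub = int(cvec.size) - n_match - n_del
    n_ins = len(consensus.insertions)
    n_ins_bases = sum(len(s) for s in consensus.insertions.values())
    return ConsensusReferenceEvents(n_match, n_sub, n_del, n_ins, n_ins_bases)


def _read_events(
    rvec: np.ndarray,
    start: int,
    end: int,
    read_ins: Mapping[int, str],
    cons_vec: np.ndarray,
    cons_ins: Mapping[int, str],
) -> ReadConsensusEvents:
    """Event summary from encoded arrays; shared by the public API and the
    inference engine (which caches encodings).

    Coordinates are 1-based; ``cons_vec`` spans the whole reference and
    ``rvec`` spans [start, end].
    """
    L0 = cons_vec.size
    if start < 1 or end > L0:
        raise ModelError(f"read interval [{start}, {end}] outside [1, {L0}]")
    window = cons_vec[start - 1:end]
    li = end - start + 1

    excluded = (window == _N_CODE) | (rvec == _N_CODE)
    comparable = (window != _GAP_CODE) & ~excluded
    rcomp = rvec[comparable]
    ccomp = window[comparable]
    has_base = rcomp != _GAP_CODE
    n_correct = int(np.count_nonzero(has_base & (rcomp == ccomp)))
    n_mismatch = int(np.count_nonzero(has_base & (rcomp != ccomp)))
    del_segments = [stop - s for s, stop in _run_slices(~has_base)]

    # read bases over a consensus-deleted run are re-interpreted as an
    # insertion at the gap preceding the run (or following it at the read
    # start); merged with the read's own insertion at that gap if present
    extra_ins: dict[int, int] = {}
    cons_gap = (window == _GAP_CODE) & ~excluded
    for s_off, stop_off in _run_slices(cons_gap):
        n_bases = int(np.count_nonzero(rvec[s_off:stop_off] != _GAP_CODE))
        if n_bases == 0:
            continue
        g = start + s_off - 1  # gap before the run
        if g < start:
            g = start + stop_off - 1  # gap after the run
        if g > end - 1:
            continue  # run spans the whole read; no valid gap to attach to
        extra_ins[g] = extra_ins.get(g, 0) + n_bases

    ins_segments: list[int] = []
    gaps = set(extra_ins)
    gaps.update(g for g in read_ins if start <= g <= end - 1)
    gaps.update(g for g in cons_ins if start <= g <= end - 1)
    for g in sorted(gaps):
        rs = read_ins.get(g, "")
        cs = cons_ins.get(g, "")
        extra = extra_ins.get(g, 0)
        if not cs:
            total = len(rs) + extra
            if total:
                ins_segments.append(total)
        elif not rs and not extra:
            # consensus insertion absent from the read: a deletion segment
            del_segments.append(len(cs))
        else:
            # both have inserted material: differing bases count as
            # mismatch-equivalents; a perfect copy is no event
            k = min(len(rs), len(cs))
            diff = sum(a != b for a, b in zip(rs[:k], cs[:k]))
            diff += abs(len(rs) - len(cs)) + extra
            n_mismatch += diff

    w = (li - 1) - len(ins_segments)
    return ReadConsensusEvents(
        n_correct=n_correct,
        n_mismatch=n_mismatch,
        del_segments=tuple(del_segments),
        ins_segments=tuple(ins_segments),
        n_gaps_no_insertion=w,
    )


def summarize_read_vs_consensus(
    read: AlignedRead, consensus: ConsensusHaplotype
) -> ReadConsensusEvents:
    """Classify every comparable position of ``read`` against ``consensus``.

    Comparable positions are those in [start, end] where the consensus state
    is not '-'; maximal runs of read-deletions form deletion segments (run
    continuity is taken over the comparable subsequence, so a consensus
    deletion inside a read-deletion run does not split it).  Gap events
    follow the insertion-comparison rules documented in the class docstring
    of :class:`ReadConsensusEvents`.
    """
    return _read_events(read.codes(), read.start, read.end, read.insertions,
                        consensus.codes(), consensus.insertions)


# ---------------------------------------------------------------------------
# likelihood terms
# ---------------------------------------------------------------------------


def truncated_poisson_log_pmf(length: int, rate: float) -> float:
    """log P(segment length) under the shifted (truncated) Poisson model.

    Segment lengths are >= 1 and length - 1 ~ Poisson(rate), so the log-pmf
    is (length-1) log(rate) - rate - log((length-1)!).
    """
    if length < 1:
        raise ModelError(f"segment length {length} < 1")
    if rate <= 0:
        raise ModelError(f"rate {rate} must be positive")
    k = length - 1
    return k * math.log(rate) - rate - math.lgamma(k + 1)


def evolution_log_likelihood(
    events: ConsensusReferenceEvents, params: EvolutionParams, L0: int
) -> float:
    """log P(consensus | reference) from evolution-stage event counts.

    Includes the uniform base-content constants: log(1/3) per substituted
    base and log(1/4) per inserted base, so the exponential is the actual
    probability of the consensus sequence.  Returns -inf when a count is
    positive but its probability is zero.
    """
    if events.n_match + events.n_substitution + events.n_deletion != L0:
        raise ModelError("position counts do not sum to L0")
    n_gaps = L0 - 1
    if not (0 <= events.n_insertion <= n_gaps):
        raise ModelError("insertion count outside [0, L0-1]")
    g1, g2, g3 = params.gamma
    ll = _count_log(n_gaps - events.n_insertion, 1.0 - params.beta)
    ll += _count_log(events.n_insertion, params.beta)
    ll += _count_log(events.n_match, g1)
    ll += _count_log(events.n_substitution, g2)
    ll += _count_log(events.n_deletion, g3)
    ll += events.n_substitution * _LOG_THIRD
    ll += events.n_inserted_bases * _LOG_QUARTER
    return ll


def read_log_likelihood(
    events: ReadConsensusEvents, profile: SequencingErrorProfile
) -> float:
    """log P(read | consensus, psi) from sequencing-stage event counts.

    Per-position emissions are categorical over correct/mismatch/deletion
    start; segment lengths carry truncated-Poisson terms; base-content
    constants (log(1/3) per mismatch, log(1/4) per inserted base) are
    included.  Returns -inf on zero-probability events.
    """
    ll = _count_log(events.n_correct, profile.p1)
    ll += _count_log(events.n_mismatch, profile.p2)
    ll += events.n_mismatch * _LOG_THIRD
    for seg in events.del_segments:
        term = _count_log(1, profile.p3)
        ll += term + truncated_poisson_log_pmf(seg, profile.lambda_del)
    ll += _count_log(events.n_gaps_no_insertion, 1.0 - profile.p4)
    for seg in events.ins_segments:
        term = _count_log(1, profile.p4)
        ll += term + truncated_poisson_log_pmf(seg, profile.lambda_ins)
        ll += seg * _LOG_QUARTER
    return ll


def _as_label_array(labels, n: int, K: int) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim == 2:
        if arr.shape != (n, K) or not np.all(arr.sum(axis=1) == 1):
            raise ModelError("one-hot label matrix must be n x K with unit rows")
        arr = arr.argmax(axis=1)
    if arr.shape != (n,):
        raise ModelError("labels must have one entry per read")
    if arr.size and (arr.min() < 0 or arr.max() >= K):
        raise ModelError("labels must be in [0, K)")
    return arr.astype(int)


def complete_data_log_likelihood(
    reads: Sequence[AlignedRead],
    labels,
    consensuses: Sequence[ConsensusHaplotype],
    weights: MixtureWeights,
    profile: SequencingErrorProfile,
    evolution: EvolutionParams | Sequence[EvolutionParams],
    reference: ReferenceSequence,
) -> float:
    """Complete-data log-likelihood of reads, hard labels, and consensuses.

    ``labels`` may be 0-based integers per read or a one-hot n x K matrix;
    ``evolution`` is one parameter set per haplotype or a single shared set.
    """
    K = len(consensuses)
    if len(weights) != K:
        raise ModelError("weights length must equal number of consensuses")
    z = _as_label_array(labels, len(reads), K)
    evo = list(evolution) if isinstance(evolution, (list, tuple)) else [evolution] * K
    if len(evo) != K:
        raise ModelError("need one EvolutionParams per haplotype (or one shared)")
    log_alpha = weights.log()
    total = 0.0
    for read, k in zip(reads, z):
        events = summarize_read_vs_consensus(read, consensuses[k])
        total += log_alpha[k] + read_log_likelihood(events, profile)
    for k, cons in enumerate(consensuses):
        ev = summarize_consensus_vs_reference(cons, reference)
        total += evolution_log_likelihood(ev, evo[k], reference.length)
    return float(total)
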