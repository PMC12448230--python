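"""Read simulator following the model's two-step generative protocol.

Step one evolves K consensus haplotypes from a reference (optionally with
structural variants); step two emits error-bearing reads from the
consensuses under a chosen sequencing error profile.  The generator records
its own injected events so that the event summarizer in
:mod:`haplomix.model` can be cross-checked against ground truth.

Three named error-profile presets reproduce published long-read error
levels (aggregate mismatch / insertion / deletion percentages per base):

====== ========= ========== =========
level  mismatch  insertion  deletion
====== ========= ========== =========
1      1.3000    0.0870     0.3400
2      1.4900    4.0635     1.7500
3      1.6800    8.0400     3.1600
====== ========= ========== =========

Level 2 is the midpoint of levels 1 and 3.  The aggregate indel rates count
inserted/deleted *bases* per position; with the default segment-length
rates lambda_ins = lambda_del = 1 the per-segment probabilities are solved
from p * (1 + lambda) = aggregate rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    GAP,
    AlignedRead,
    ConsensusHaplotype,
    EvolutionParams,
    MixtureWeights,
    ModelError,
    ReadConsensusEvents,
    ReferenceSequence,
    decode_states,
)

__all__ = [
    "LogNormalLengths",
    "EmpiricalLengths",
    "SvConfig",
    "SimulationConfig",
    "SimulatedDataset",
    "error_profile_preset",
    "evolution_preset",
    "weights_preset",
    "simulate_consensus",
    "apply_structural_variants",
    "simulate_read",
    "simulate_dataset",
    "scenario_grid",
    "scenario_config",
]

_GAP_CODE = 4
_N_CODE = 5

#: aggregate per-base error percentages for the three preset levels
PRESET_LEVELS = {
    1: {"mismatch": 1.3000, "insertion": 0.0870, "deletion": 0.3400},
    2: {"mismatch": 1.4900, "insertion": 4.0635, "deletion": 1.7500},
    3: {"mismatch": 1.6800, "insertion": 8.0400, "deletion": 3.1600},
}

SV_TYPES = ("insertion", "deletion", "duplication", "inversion", "translocation")
SV_LENGTHS = (50, 100, 500)


def error_profile_preset(level: int, lambda_ins: float = 1.0,
                         lambda_del: float = 1.0):
    """Sequencing error profile for preset ``level`` in {1, 2, 3}.

    The per-segment probabilities p3 and p4 are solved so that the expected
    number of deleted/inserted bases per position matches the aggregate
    table rate: p * (1 + lambda) = rate.
    """
    from .model import SequencingErrorProfile

    if level not in PRESET_LEVELS:
        raise ModelError(f"unknown error level {level}; choose from 1, 2, 3")
    rates = PRESET_LEVELS[level]
    p2 = rates["mismatch"] / 100.0
    p3 = rates["deletion"] / 100.0 / (1.0 + lambda_del)
    p4 = rates["insertion"] / 100.0 / (1.0 + lambda_ins)
    p1 = 1.0 - p2 - p3
    return SequencingErrorProfile(p1=p1, p2=p2, p3=p3, p4=p4,
                                  lambda_ins=lambda_ins, lambda_del=lambda_del)


def evolution_preset(K: int) -> list[EvolutionParams]:
    """Published evolution parameter presets for K = 2 or 3 haplotypes.

    Both diploid haplotypes use (0.9989, 0.001, 0.0001; beta 0.0001); the
    third (higher-mutation, e.g. disease-associated) haplotype uses
    (0.98572, 0.0139, 0.00038; beta 0.00038).
    """
    base = EvolutionParams.from_four((0.9989, 0.001, 0.0001, 0.0001))
    if K == 2:
        return [base, base]
    if K == 3:
        third = EvolutionParams.from_four((0.98572, 0.0139, 0.00038, 0.00038))
        return [base, base, third]
    raise ModelError(f"no evolution preset for K={K}")


def weights_preset(K: int) -> MixtureWeights:
    """Mixture-weight presets: (0.6, 0.4) for K=2, (0.4, 0.4, 0.2) for K=3."""
    if K == 2:
        return MixtureWeights((0.6, 0.4))
    if K == 3:
        return MixtureWeights((0.4, 0.4, 0.2))
    raise ModelError(f"no weights preset for K={K}")


# ---------------------------------------------------------------------------
# read-length models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogNormalLengths:
    """Log-normal mapping-length model, clipped to [min_length, L0].

    Stands in for an empirical long-read panel length table: ``median`` is
    the median mapped span in bases and ``sigma`` the log-scale spread.
    """

    median: int = 2000
    sigma: float = 0.6
    min_length: int = 500

    def sample(self, rng: np.random.Generator, L0: int) -> int:
        raw = rng.lognormal(mean=math.log(self.median), sigma=self.sigma)
        lo = min(self.min_length, L0)
        return int(np.clip(round(raw), lo, L0))


@dataclass(frozen=True)
class EmpiricalLengths:
    """Empirical length table: lengths with (optional) sampling weights."""

    lengths: tuple[int, ...]
    weights: tuple[float, ...] | None = None

    def sample(self, rng: np.random.Generator, L0: int) -> int:
        p = None
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            p = w / w.sum()
        val = int(rng.choice(np.asarray(self.lengths), p=p))
        return int(np.clip(val, 1, L0))


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SvConfig:
    """Structural-variant injection settings for the evolution step."""

    n_svs: int = 0
    type_probs: dict[str, float] | None = None  # default: uniform over 5 types
    lengths: tuple[int, ...] = SV_LENGTHS

    def probs(self) -> np.ndarray:
        if self.type_probs is None:
            return np.full(len(SV_TYPES), 1.0 / len(SV_TYPES))
        p = np.array([self.type_probs.get(t, 0.0) for t in SV_TYPES], float)
        if p.sum() <= 0 or (set(self.type_probs) - set(SV_TYPES)):
            raise ModelError(f"sv type probabilities must cover {SV_TYPES}")
        return p / p.sum()


@dataclass
class SimulationConfig:
    reference: ReferenceSequence
    K: int
    n_reads: int
    evolution: list[EvolutionParams]
    weights: MixtureWeights
    profile: object  # SequencingErrorProfile or preset level int
    length_model: object = field(default_factory=LogNormalLengths)
    sv_config: SvConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_reads < 1:
            raise ModelError("K and n_reads must be >= 1")
        if len(self.weights) != self.K or len(self.evolution) != self.K:
            raise ModelError("weights/evolution must have one entry per haplotype")
        if isinstance(self.profile, int):
            self.profile = error_profile_preset(self.profile)


@dataclass
class SimulatedDataset:
    reference: ReferenceSequence
    truth_haplotypes: list[ConsensusHaplotype]
    reads: list[AlignedRead]
    truth_snvs: dict[int, list[int]]  # haplotype index (1-based) -> positions
    truth_events: list[ReadConsensusEvents] | None = None
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# evolution step
# ---------------------------------------------------------------------------


def simulate_consensus(
    reference: ReferenceSequence,
    params: EvolutionParams,
    rng: np.random.Generator | int,
    index: int = 1,
) -> ConsensusHaplotype:
    """Evolve one consensus haplotype from the reference.

    Each position is kept / substituted / deleted with probabilities gamma;
    a substituted base is uniform over the three alternatives.  Each gap
    independently receives a single-base insertion with probability beta.
    Ambiguous reference positions (N) are carried through unchanged.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    rvec = reference.codes()
    L0 = rvec.size
    fate = rng.choice(3, size=L0, p=list(params.gamma))
    fate[rvec == _N_CODE] = 0  # N positions: universal match
    out = rvec.copy()
    sub_idx = np.flatnonzero(fate == 1)
    if sub_idx.size:
        # uniform over the 3 alternatives: add 1..3 mod 4 to the base code
        shift = rng.integers(1, 4, size=sub_idx.size)
        out[sub_idx] = (out[sub_idx] + shift) % 4
    out[fate == 2] = _GAP_CODE
    insertions: dict[int, str] = {}
    if params.beta > 0:
        gap_hit = np.flatnonzero(rng.random(L0 - 1) < params.beta)
        for g0 in gap_hit:
            insertions[int(g0) + 1] = "ACGT"[rng.integers(0, 4)]
    return ConsensusHaplotype(index=index, states=decode_states(out),
                              insertions=insertions)


def _sv_span(rng: np.random.Generator, L0: int, length: int,
             states: np.ndarray) -> tuple[int, int]:
    """Uniform 0-based start of a span of ``length`` surviving positions."""
    alive = np.flatnonzero(states != _GAP_CODE)
    if alive.size <= length:
        raise ModelError("sequence shorter than the structural variant")
    i = int(rng.integers(0, alive.size - length))
    return int(alive[i]), int(alive[i + length - 1])


def apply_structural_variants(
    consensus: ConsensusHaplotype,
    sv_config: SvConfig,
    rng: np.random.Generator | int,
) -> ConsensusHaplotype:
    """Inject structural variants (>= 50 bp) into a consensus haplotype.

    Five types are supported: insertion (random bases at a gap), deletion
    (a span set to '-'), duplication (a span re-inserted after itself),
    inversion (a span reverse-complemented in place) and translocation (a
    span deleted and re-inserted at another gap).  Lengths are drawn
    uniformly from ``sv_config.lengths``; loci are uniform.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if sv_config.n_svs == 0:
        return consensus
    states = consensus.codes()
    insertions = dict(consensus.insertions)
    L0 = states.size
    probs = sv_config.probs()
    for _ in range(sv_config.n_svs):
        sv_type = SV_TYPES[int(rng.choice(len(SV_TYPES), p=probs))]
        length = int(rng.choice(np.asarray(sv_config.lengths)))
        if sv_type == "insertion":
            g = int(rng.integers(1, L0))
            seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
            insertions[g] = insertions.get(g, "") + seq
        elif sv_type == "deletion":
            lo, hi = _sv_span(rng, L0, length, states)
            keep = np.flatnonzero(states[lo:hi + 1] != _GAP_CODE) + lo
            states[keep[:length]] = _GAP_CODE
        elif sv_type == "duplication":
            lo, hi = _sv_span(rng, L0, length, states)
            seq = decode_states(states[lo:hi + 1]).replace(GAP, "")[:length]
            g = min(hi + 1, L0 - 1)
            insertions[g] = insertions.get(g, "") + seq
        elif sv_type == "inversion":
            lo, hi = _sv_span(rng, L0, length, states)
            idx = np.flatnonzero(states[lo:hi + 1] != _GAP_CODE) + lo
            idx = idx[:length]
            vals = states[idx][::-1].copy()
            base = vals < 4
            vals[base] = 3 - vals[base]  # A<->T, C<->G under this code
            states[idx] = vals
        else:  # translocation
            lo, hi = _sv_span(rng, L0, length, states)
            idx = np.flatnonzero(states[lo:hi + 1] != _GAP_CODE) + lo
            idx = idx[:length]
            seq = decode_states(states[idx])
            states[idx] = _GAP_CODE
            g = int(rng.integers(1, L0))
            insertions[g] = insertions.get(g, "") + seq
    return ConsensusHaplotype(index=consensus.index,
                              states=decode_states(states),
                              insertions=insertions)


# ---------------------------------------------------------------------------
# sequencing step
# ---------------------------------------------------------------------------


def simulate_read(
    consensus: ConsensusHaplotype,
    profile,
    read_length: int,
    start: int,
    rng: np.random.Generator | int,
    name: str = "read",
    return_events: bool = False,
):
    """Emit one read from ``consensus`` over reference span
    [start, start + read_length - 1].

    Per comparable consensus position the machine draws correct / mismatch /
    deletion-start from (p1, p2, p3); a deletion segment deletes
    1 + Poisson(lambda_del) consensus positions.  Per gap an insertion error
    occurs with probability p4, length 1 + Poisson(lambda_ins), bases
    uniform.  Consensus insertions are copied verbatim.  Leading/trailing
    all-deleted positions are trimmed (an alignment never starts or ends
    with a deletion) and the recorded truth events are adjusted to match.

    With ``return_events=True`` also returns the generator's own event
    record (an independently bookkept :class:`ReadConsensusEvents`).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    cvec = consensus.codes()
    L0 = cvec.size
    if start < 1 or start + read_length - 1 > L0:
        raise ModelError("read span outside the reference")
    end = start + read_length - 1

    window = cvec[start - 1:end]
    out = np.empty(read_length, dtype=np.uint8)
    # raw per-position outcome: 0 skip (consensus '-'/N), 1 correct,
    # 2 mismatch, 3 deletion-start, 4 deletion-continuation
    outcome = np.zeros(read_length, dtype=np.uint8)
    pending_del = 0
    for off in range(read_length):
        c = window[off]
        if c == _GAP_CODE:
            out[off] = _GAP_CODE
            continue
        if c == _N_CODE:
            out[off] = _N_CODE
            continue
        if pending_del > 0:
            out[off] = _GAP_CODE
            outcome[off] = 4
            pending_del -= 1
            continue
        u = rng.random()
        if u < profile.p1:
            out[off] = c
            outcome[off] = 1
        elif u < profile.p1 + profile.p2:
            out[off] = (c + rng.integers(1, 4)) % 4
            outcome[off] = 2
        else:
            seg = 1 + int(rng.poisson(profile.lambda_del))
            out[off] = _GAP_CODE
            outcome[off] = 3
            pending_del = seg - 1

    insertions: dict[int, str] = {}
    ins_events: list[tuple[int, int]] = []  # (gap, length), errors only
    for g in range(start, end):
        cs = consensus.insertions.get(g)
        if cs is not None:
            insertions[g] = cs  # inherited, copied without error
        elif rng.random() < profile.p4:
            seg = 1 + int(rng.poisson(profile.lambda_ins))
            insertions[g] = "".join(
                "ACGT"[c] for c in rng.integers(0, 4, size=seg))
            ins_events.append((g, seg))

    # trim edges so the alignment starts and ends with an observed base
    keep = np.flatnonzero(out != _GAP_CODE)
    if keep.size == 0:
        raise ModelError("simulated read deleted entirely; use a longer span")
    lo, hi = int(keep[0]), int(keep[-1])
    new_start, new_end = start + lo, start + hi
    out = out[lo:hi + 1]
    outcome = outcome[lo:hi + 1]
    insertions = {g: s for g, s in insertions.items()
                  if new_start <= g <= new_end - 1}

    read = AlignedRead(name=name, start=new_start, end=new_end,
                       states=decode_states(out), insertions=insertions)
    if not return_events:
        return read

    # derive the truth record from the raw outcome labels (independent of
    # the model-side summarizer): deletion segments are maximal runs of
    # outcome 3/4, merged across skipped (consensus '-') positions
    n_correct = int(np.count_nonzero(outcome == 1))
    n_mismatch = int(np.count_nonzero(outcome == 2))
    del_segments: list[int] = []
    run = 0
    for off in range(outcome.size):
        oc = outcome[off]
        if oc in (3, 4):
            run += 1
        elif oc == 0:
            continue  # skipped position does not break a run
        else:
            if run:
                del_segments.append(run)
            run = 0
    if run:
        del_segments.append(run)
    kept_ins = [(g, s) for g, s in ins_events
                if new_start <= g <= new_end - 1]
    li = new_end - new_start + 1
    events = ReadConsensusEvents(
        n_correct=n_correct,
        n_mismatch=n_mismatch,
        del_segments=tuple(del_segments),
        ins_segments=tuple(s for _, s in sorted(kept_ins)),
        n_gaps_no_insertion=(li - 1) - len(kept_ins),
    )
    return read, events


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full two-step protocol: evolve K consensuses, then emit reads.

    Read sources are drawn from the mixture weights, spans from the length
    model, starts uniform over feasible positions.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    reference = config.reference
    haps = []
    for k in range(config.K):
        hap = simulate_consensus(reference, config.evolution[k], rng, index=k + 1)
        if config.sv_config is not None and config.sv_config.n_svs:
            hap = apply_structural_variants(hap, config.sv_config, rng)
        haps.append(hap)

    rvec = reference.codes()
    truth_snvs: dict[int, list[int]] = {}
    for hap in haps:
        hvec = hap.codes()
        sub = (hvec != rvec) & (hvec < 4) & (rvec < 4)
        truth_snvs[hap.index] = (np.flatnonzero(sub) + 1).tolist()

    reads: list[AlignedRead] = []
    all_events: list[ReadConsensusEvents] = []
    alpha = np.asarray(config.weights.alpha)
    i = 0
    while len(reads) < config.n_reads:
        k = int(rng.choice(config.K, p=alpha))
        length = config.length_model.sample(rng, reference.length)
        start = int(rng.integers(1, reference.length - length + 2))
        try:
            read, events = simulate_read(
                haps[k], config.profile, length, start, rng,
                name=f"read{i:05d}", return_events=True)
        except ModelError:
            continue  # fully-deleted span; redraw
        read.truth_source = k + 1
        reads.append(read)
        all_events.append(events)
        i += 1
    return SimulatedDataset(reference=reference, truth_haplotypes=haps,
                            reads=reads, truth_snvs=truth_snvs,
                            truth_events=all_events, config=config)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


def scenario_grid() -> list[str]:
    """The full-information simulation design: K in {2,3} x 3 error levels
    x n in {50,100} reads = 12 scenario names."""
    return [f"K{k}-level{lv}-n{n}" for k in (2, 3) for lv in (1, 2, 3)
            for n in (50, 100)]


def scenario_config(name: str, reference: ReferenceSequence,
                    seed: int = 0, n_reads: int | None = None) -> SimulationConfig:
    """Build the SimulationConfig for a named scenario.

    Names follow ``K{2|3}-level{1|2|3}`` with an optional ``-n{reads}``
    suffix; ``n_reads`` overrides the suffix (default 50).
    """
    parts = name.split("-")
    try:
        K = int(parts[0].removeprefix("K"))
        level = int(parts[1].removeprefix("level"))
        n = int(parts[2].removeprefix("n")) if len(parts) > 2 else 50
    except (IndexError, ValueError):
        raise ModelError(
            f"unknown scenario {name!r}; valid names: " + ", ".join(scenario_grid()))
    if K not in (2, 3) or level not in (1, 2, 3):
        raise ModelError(
            f"unknown scenario {name!r}; valid names: " + ", ".join(scenario_grid()))
    if n_reads is not None:
        n = n_reads
    return SimulationConfig(reference=reference, K=K, n_reads=n,
                            evolution=evolution_preset(K),
                            weights=weights_preset(K),
                            profile=error_profile_preset(level), seed=seed)
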