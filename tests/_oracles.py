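"""Independent oracles used by the test suite.

Everything here is written as literal product-form probability walks over
strings — no shared code with the package's numpy event summarizer — so
that exp(log-likelihood) can be checked against brute force on small
instances, and the CAEM fit against exhaustive enumeration of labelings.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from haplomix.inference import FitConfig, _Engine
from haplomix.model import (
    AlignedRead,
    ConsensusHaplotype,
    EvolutionParams,
    MixtureWeights,
    ReferenceSequence,
    SequencingErrorProfile,
)


def poisson_pmf(k: int, lam: float) -> float:
    return lam**k * math.exp(-lam) / math.factorial(k)


def read_probability(read: AlignedRead, cons: ConsensusHaplotype,
                     profile: SequencingErrorProfile) -> float:
    """P(read | consensus, psi) as a literal product over positions/gaps."""
    s, e = read.start, read.end
    # positional emissions over the comparable subsequence
    pairs = []
    for pos in range(s, e + 1):
        c = cons.states[pos - 1]
        r = read.states[pos - s]
        if c in "-N" or r == "N":
            continue
        pairs.append((r, c))
    p = 1.0
    i = 0
    while i < len(pairs):
        r, c = pairs[i]
        if r == "-":
            j = i
            while j < len(pairs) and pairs[j][0] == "-":
                j += 1
            seg = j - i
            p *= profile.p3 * poisson_pmf(seg - 1, profile.lambda_del)
            i = j
        else:
            p *= profile.p1 if r == c else profile.p2 / 3.0
            i += 1
    # read bases over consensus-deleted runs act as insertions at the
    # adjacent gap (before the run, or after it at the read start)
    extra: dict[int, int] = {}
    pos = s
    while pos <= e:
        if cons.states[pos - 1] == "-":
            j = pos
            n_bases = 0
            while j <= e and cons.states[j - 1] == "-":
                if read.states[j - s] not in "-N":
                    n_bases += 1
                j += 1
            if n_bases:
                g = pos - 1 if pos - 1 >= s else j - 1
                if s <= g <= e - 1:
                    extra[g] = extra.get(g, 0) + n_bases
            pos = j
        else:
            pos += 1
    # gap events
    n_ins_segments = 0
    for g in range(s, e):
        rs = read.insertions.get(g, "")
        cs = cons.insertions.get(g, "")
        ex = extra.get(g, 0)
        if not cs:
            seg = len(rs) + ex
            if seg:
                p *= profile.p4 * poisson_pmf(seg - 1, profile.lambda_ins) \
                    * 0.25**seg
                n_ins_segments += 1
        elif not rs and not ex:
            p *= profile.p3 * poisson_pmf(len(cs) - 1, profile.lambda_del)
        else:
            k = min(len(rs), len(cs))
            diff = sum(a != b for a, b in zip(rs[:k], cs[:k]))
            diff += abs(len(rs) - len(cs)) + ex
            p *= (profile.p2 / 3.0) ** diff
    w = (e - s + 1 - 1) - n_ins_segments
    p *= (1.0 - profile.p4) ** w
    return p


def evolution_probability(cons: ConsensusHaplotype, ref: ReferenceSequence,
                          params: EvolutionParams) -> float:
    g1, g2, g3 = params.gamma
    p = 1.0
    for l in range(ref.length):
        r, c = ref.bases[l], cons.states[l]
        if r == "N" or c == "N":
            p *= g1
        elif c == "-":
            p *= g3
        elif c == r:
            p *= g1
        else:
            p *= g2 / 3.0
    for g in range(1, ref.length):
        if g in cons.insertions:
            p *= params.beta * 0.25 ** len(cons.insertions[g])
        else:
            p *= 1.0 - params.beta
    return p


def complete_probability(reads, labels, consensuses, weights, profile,
                         evolution, reference) -> float:
    p = 1.0
    for read, k in zip(reads, labels):
        p *= weights.alpha[k] * read_probability(read, consensuses[k], profile)
    for k, cons in enumerate(consensuses):
        p *= evolution_probability(cons, reference, evolution[k])
    return p


def exhaustive_best_labeling(reads, reference, K: int,
                             config: FitConfig | None = None,
                             n_refine: int = 6) -> tuple[float, tuple[int, ...]]:
    """Best complete-data log-likelihood over every hard labeling.

    For each labeling with no empty component the conditionally optimal
    consensuses and parameters are found by iterating the package's M step
    to a fixed point; the enumeration over all K^n labelings is the
    independent part of the oracle.
    """
    config = config or FitConfig()
    engine = _Engine(reads, reference, config)
    best_obj, best_labels = -math.inf, None
    for labels in itertools.product(range(K), repeat=len(reads)):
        arr = np.asarray(labels)
        if len(set(labels)) < K:
            continue
        state = engine.state_from_labels(arr, K)
        obj = state.objective
        for _ in range(n_refine):
            state = engine.m_step(arr, state, llmat=None)
            new_obj = engine.objective(engine.ll_matrix(state), arr, state)
            if abs(new_obj - obj) < 1e-12:
                obj = new_obj
                break
            obj = new_obj
        if obj > best_obj:
            best_obj, best_labels = obj, labels
    return best_obj, best_labels
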