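"""Classification annealing EM (CAEM) for direct haplotype inference.

The fitting loop alternates three steps.  The *annealed expectation* (AE)
step computes per-read responsibilities proportional to
``(alpha_k P(R_i | C_k, psi))^(1/T)``; the *classification* (C) step hardens
them to labels by per-read argmax; the *maximization* (M) step updates, in
closed form, the mixture weights, the sequencing error profile, the
evolution parameters, and — by exact coordinate ascent — the consensus
sequences themselves.  The temperature follows a geometric cooling schedule
with floor 1; convergence is declared at T = 1 when the relative change of
the complete-data log-likelihood falls below tolerance.  Multiple restarts
are run and the best final objective wins.

The consensus M-step updates each reference position to the state in
{A,C,G,T,-} maximizing the summed read-emission log-likelihood of the
assigned reads plus the evolution log-prior, and accepts a consensus
insertion at a gap when the with-insertion objective beats the
without-insertion one.  Positions with no read coverage revert to the
prior argmax (the reference state).  Only candidate moves are accepted,
never neutral or worsening ones, which preserves the classification-EM
monotonicity of the objective.

Model selection over K uses five-fold cross-validation on the held-out
minimum error correction ratio (MECR), with near-ties (within one standard
error of the minimum) broken toward smaller K.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .metrics import mecr as _mecr
from .model import (
    AlignedRead,
    ConsensusHaplotype,
    EvolutionParams,
    MixtureWeights,
    ModelError,
    ReferenceSequence,
    SequencingErrorProfile,
    _read_events,
    decode_states,
    read_log_likelihood,
    summarize_consensus_vs_reference,
    evolution_log_likelihood,
)

__all__ = [
    "InferenceError",
    "ModelState",
    "FitConfig",
    "CaemResult",
    "SelectKResult",
    "initialize_state",
    "ae_step",
    "c_step",
    "m_step",
    "run_caem",
    "select_k",
]

logger = logging.getLogger(__name__)

_GAP_CODE = 4
_N_CODE = 5
_LOG_THIRD = math.log(1.0 / 3.0)
_LOG_QUARTER = math.log(0.25)
_ACCEPT_TOL = 1e-9  # only strictly improving consensus moves are taken


class InferenceError(RuntimeError):
    pass


@dataclass
class ModelState:
    """All free parameters of the fit plus the current soft assignments."""

    consensuses: list[ConsensusHaplotype]
    weights: MixtureWeights
    profile: SequencingErrorProfile
    evolution: list[EvolutionParams]
    responsibilities: np.ndarray  # n x K, rows on the simplex
    temperature: float = 1.0
    objective: float = -math.inf

    @property
    def K(self) -> int:
        return len(self.consensuses)

    def labels(self) -> np.ndarray:
        """Hard assignment: per-read argmax of the responsibilities."""
        return np.argmax(self.responsibilities, axis=1)


@dataclass(frozen=True)
class FitConfig:
    """CAEM run settings.

    ``T0`` and ``cooling`` define the geometric annealing schedule
    (T floored at 1); ``tol`` is the relative objective tolerance checked at
    T = 1; ``init`` selects restart initialization ("auto" mixes
    variant-column clustering with random partitions, "cluster" and
    "random" force one mode).  Probability estimates are floored
    (``prob_floor`` for the sequencing simplex, ``evo_floor`` for evolution
    rates) so that a zero count cannot freeze later updates at -inf.
    """

    n_restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    T0: float = 10.0
    cooling: float = 0.9
    seed: int = 0
    init: str = "auto"
    tie_evolution: bool = False
    prob_floor: float = 1e-9
    evo_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.T0 < 1 or not (0 < self.cooling < 1) or self.tol <= 0:
            raise ModelError("need T0 >= 1, 0 < cooling < 1, tol > 0")


@dataclass
class CaemResult:
    state: ModelState
    labels: np.ndarray
    diagnostics: dict


@dataclass
class SelectKResult:
    chosen_k: int
    table: pd.DataFrame  # K, mean_mecr, se_mecr, fold scores
    in_sample: bool = False


def _floored_simplex(counts, floor: float) -> np.ndarray:
    """Constrained MLE of a categorical given counts: maximize
    sum n_j log p_j subject to p_j >= floor, sum p_j = 1."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        return np.full(counts.size, 1.0 / counts.size)
    p = counts / counts.sum()
    for _ in range(counts.size):
        low = p < floor
        if not low.any():
            break
        free = ~low
        p[free] *= (1.0 - floor * low.sum()) / p[free].sum()
        p[low] = floor
    return p


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


class _Engine:
    """Cached encodings and fast likelihood / M-step computations."""

    def __init__(self, reads: Sequence[AlignedRead],
                 reference: ReferenceSequence, config: FitConfig):
        self.reads = list(reads)
        self.reference = reference
        self.config = config
        self.refcodes = reference.codes()
        self.L0 = reference.length
        self.n = len(self.reads)
        self.rvecs = [r.codes() for r in self.reads]
        self.starts = np.array([r.start for r in self.reads])  # 1-based
        self.ends = np.array([r.end for r in self.reads])
        self.rins = [dict(r.insertions) for r in self.reads]
        # flattened (position * 5 + code) keys for fast bincount pileups
        self._flat = []
        for i in range(self.n):
            vec = self.rvecs[i]
            pos = np.arange(self.starts[i] - 1, self.ends[i], dtype=np.int64)
            ok = vec != _N_CODE
            self._flat.append(pos[ok] * 5 + vec[ok])

    # -- likelihoods --------------------------------------------------------

    def pair_ll(self, i: int, cons: ConsensusHaplotype,
                cvec: np.ndarray | None, profile) -> float:
        cv = cons.codes() if cvec is None else cvec
        ev = _read_events(self.rvecs[i], int(self.starts[i]), int(self.ends[i]),
                          self.rins[i], cv, cons.insertions)
        return read_log_likelihood(ev, profile)

    def ll_matrix(self, state: ModelState) -> np.ndarray:
        out = np.empty((self.n, state.K))
        for k, cons in enumerate(state.consensuses):
            cvec = cons.codes()
            for i in range(self.n):
                out[i, k] = self.pair_ll(i, cons, cvec, state.profile)
        return out

    def objective(self, llmat: np.ndarray, labels: np.ndarray,
                  state: ModelState) -> float:
        la = state.weights.log()
        total = float(np.sum(la[labels]) + llmat[np.arange(self.n), labels].sum())
        for k, cons in enumerate(state.consensuses):
            ev = summarize_consensus_vs_reference(cons, self.reference)
            total += evolution_log_likelihood(ev, state.evolution[k], self.L0)
        return total

    # -- initialization -----------------------------------------------------

    def _variant_features(self) -> np.ndarray:
        """Per-read allele features at candidate variant columns.

        A column is a candidate when its second-most-common read state is
        supported by at least max(2, 0.15 * coverage) reads; the feature is
        +1 / -1 for the two top states, 0 otherwise or when uncovered.
        """
        counts = self._pileup(np.arange(self.n))
        cov = counts.sum(axis=1)
        order = np.argsort(counts, axis=1)
        top1 = order[:, -1]
        top2 = order[:, -2]
        c2 = counts[np.arange(self.L0), top2]
        thresh = np.maximum(2, np.ceil(0.15 * cov)).astype(int)
        cols = np.flatnonzero((c2 >= thresh) & (cov > 0))
        feats = np.zeros((self.n, cols.size))
        for j, l in enumerate(cols):
            b1, b2 = top1[l], top2[l]
            for i in range(self.n):
                if self.starts[i] - 1 <= l <= self.ends[i] - 1:
                    code = self.rvecs[i][l - (self.starts[i] - 1)]
                    if code == b1:
                        feats[i, j] = 1.0
                    elif code == b2:
                        feats[i, j] = -1.0
        return feats

    def _partition(self, K: int, seed: int, mode: str) -> np.ndarray:
        rng = np.random.default_rng(seed)
        labels = None
        if mode == "cluster" and K > 1:
            feats = self._variant_features()
            if feats.shape[1] > 0:
                from sklearn.cluster import KMeans

                km = KMeans(n_clusters=K, n_init=4,
                            random_state=int(seed % (2**31 - 1)))
                labels = km.fit_predict(feats)
        if labels is None:
            labels = rng.integers(0, K, size=self.n)
        labels = np.asarray(labels, dtype=int)
        # every component needs at least one read
        for k in range(K):
            if not np.any(labels == k):
                donors = np.flatnonzero(
                    np.bincount(labels, minlength=K)[labels] > 1)
                labels[rng.choice(donors)] = k
        return labels

    def plurality_consensus(self, idx: np.ndarray, index: int) -> ConsensusHaplotype:
        """Reference-projected plurality call over the reads in ``idx``."""
        counts = self._pileup(idx)
        counts = counts.astype(float)
        # prefer the reference state on ties / zero coverage
        counts[np.arange(self.L0), np.minimum(self.refcodes, 4)] += 0.1
        states = np.argmax(counts, axis=1).astype(np.uint8)
        states[self.refcodes == _N_CODE] = _N_CODE
        insertions: dict[int, str] = {}
        by_gap: dict[int, list[str]] = {}
        for i in idx:
            for g, s in self.rins[i].items():
                by_gap.setdefault(g, []).append(s)
        for g, strings in by_gap.items():
            covering = int(np.count_nonzero(
                (self.starts[idx] <= g) & (self.ends[idx] - 1 >= g)))
            winner, m = Counter(strings).most_common(1)[0]
            if m * 2 > covering:
                insertions[g] = winner
        return ConsensusHaplotype(index=index, states=decode_states(states),
                                  insertions=insertions)

    def state_from_labels(self, labels: np.ndarray, K: int) -> ModelState:
        """Plurality consensuses and count-based parameters for a given
        hard partition (every component must be non-empty)."""
        labels = np.asarray(labels, dtype=int)
        consensuses = [self.plurality_consensus(np.flatnonzero(labels == k),
                                                index=k + 1)
                       for k in range(K)]
        weights = MixtureWeights(tuple(np.bincount(labels, minlength=K) / self.n))
        profile = self._estimate_profile(labels, consensuses, previous=None)
        evolution = self._estimate_evolution(consensuses)
        resp = np.zeros((self.n, K))
        resp[np.arange(self.n), labels] = 1.0
        state = ModelState(consensuses=consensuses, weights=weights,
                           profile=profile, evolution=evolution,
                           responsibilities=resp,
                           temperature=self.config.T0)
        llmat = self.ll_matrix(state)
        state.objective = self.objective(llmat, labels, state)
        return state

    def initialize(self, K: int, seed: int, mode: str) -> ModelState:
        if self.n < K:
            raise InferenceError(f"need at least K={K} reads, got {self.n}")
        return self.state_from_labels(self._partition(K, seed, mode), K)

    # -- M step -------------------------------------------------------------

    def _pileup(self, idx: np.ndarray) -> np.ndarray:
        if len(idx) == 0:
            return np.zeros((self.L0, 5), dtype=np.int64)
        flat = np.concatenate([self._flat[i] for i in idx])
        return np.bincount(flat, minlength=self.L0 * 5).reshape(self.L0, 5)

    def _covering(self, idx: np.ndarray, l0: int) -> np.ndarray:
        """Assigned read indices covering 0-based reference offset ``l0``."""
        return idx[(self.starts[idx] - 1 <= l0) & (self.ends[idx] - 1 >= l0)]

    def _read_clean_at(self, i: int, l0: int, cvec: np.ndarray,
                       cons_ins: dict[int, str]) -> bool:
        """True when changing the consensus at ``l0`` touches only this
        read's single-position emission (no segment structure nearby)."""
        s0, e0 = self.starts[i] - 1, self.ends[i] - 1
        if l0 - 1 < s0 or l0 + 1 > e0:
            return False
        vec = self.rvecs[i]
        if vec[l0 - 1 - s0] >= 4 or vec[l0 - s0] >= 4 or vec[l0 + 1 - s0] >= 4:
            return False
        if cvec[l0 - 1] >= 4 or cvec[l0 + 1] >= 4:
            return False
        rins = self.rins[i]
        for g in (l0, l0 + 1):  # 1-based gaps adjacent to position l0
            if g in rins or g in cons_ins:
                return False
        return True

    def _exact_delta(self, i: int, l0: int, cand: int, cur: int,
                     cvec: np.ndarray, cons_ins: dict[int, str],
                     profile) -> float:
        """Exact log-likelihood delta for read ``i`` when the consensus state
        at offset ``l0`` changes from ``cur`` to ``cand``.

        Deletion/insertion segment structure is local, so the recomputation
        is restricted to the maximal '-' runs (read or consensus) adjacent
        to ``l0`` plus one anchoring base on each side; both the before and
        after summaries use the same window, so everything outside cancels.
        """
        s0, e0 = int(self.starts[i]) - 1, int(self.ends[i]) - 1
        vec = self.rvecs[i]
        a = b = l0
        while a - 1 >= s0 and (vec[a - 1 - s0] >= 4 or cvec[a - 1] >= 4):
            a -= 1
        while b + 1 <= e0 and (vec[b + 1 - s0] >= 4 or cvec[b + 1] >= 4):
            b += 1
        a, b = max(s0, a - 1), min(e0, b + 1)
        sub = vec[a - s0:b - s0 + 1]
        cvec[l0] = cand
        ev_new = _read_events(sub, a + 1, b + 1, self.rins[i], cvec, cons_ins)
        cvec[l0] = cur
        ev_old = _read_events(sub, a + 1, b + 1, self.rins[i], cvec, cons_ins)
        return (read_log_likelihood(ev_new, profile)
                - read_log_likelihood(ev_old, profile))

    def update_consensus(self, cons: ConsensusHaplotype, idx: np.ndarray,
                         profile: SequencingErrorProfile,
                         evo: EvolutionParams) -> ConsensusHaplotype:
        """Coordinate-ascent update of one consensus given its reads.

        Per-position argmax over {A,C,G,T,-} of assigned-read emission plus
        evolution prior; clean columns (no deletion/insertion structure in
        any covering read) use an O(1) per-read emission delta, others a
        full local recompute.  Insertion calls are made per gap by direct
        likelihood comparison.  Only strictly improving moves are accepted.
        """
        cvec = cons.codes()
        cons_ins = dict(cons.insertions)
        counts = self._pileup(idx)
        g1, g2, g3 = evo.gamma
        lpr = {**{b: math.log(g2 / 3) if g2 > 0 else -math.inf for b in range(4)},
               _GAP_CODE: math.log(g3) if g3 > 0 else -math.inf}
        lp1 = math.log(profile.p1) if profile.p1 > 0 else -math.inf
        lpm = (math.log(profile.p2) + _LOG_THIRD) if profile.p2 > 0 else -math.inf
        gain_match = lp1 - lpm
        pen_sub = (math.log(g1) if g1 > 0 else -math.inf) - lpr[0]
        pen_del = (math.log(g1) if g1 > 0 else -math.inf) - lpr[_GAP_CODE]
        # per-read bounds for the '-' candidate: a deleting read gains at
        # most g_del (its deletion segment shrinks or disappears); a read
        # with a base pays at least lpm - ins_gain (its base becomes an
        # insertion error)
        g_del = max(1.0, -math.log(profile.p3) + profile.lambda_del + 1.0
                    if profile.p3 > 0 else 50.0)
        lp4 = math.log(profile.p4) if profile.p4 > 0 else -math.inf
        lnp4 = math.log1p(-profile.p4)
        ins_gain = lp4 - profile.lambda_ins + _LOG_QUARTER - lnp4

        # best alternative base count per column, excluding the current state
        masked = counts[:, :4].copy()
        rows = np.flatnonzero(cvec < 4)
        masked[rows, cvec[rows]] = -1
        alt_best = masked.max(axis=1)

        base_cov = counts[:, :4].sum(axis=1)
        del_bound = (counts[:, _GAP_CODE] * g_del
                     + base_cov * min(0.0, ins_gain - lpm))
        cand_mask = (cvec != self.refcodes) & (self.refcodes != _N_CODE)
        cand_mask |= (cvec == _GAP_CODE)
        with np.errstate(over="ignore", invalid="ignore"):
            if math.isfinite(gain_match) and math.isfinite(pen_sub):
                cand_mask |= alt_best * gain_match > pen_sub
            else:
                cand_mask |= alt_best > 0
            if math.isfinite(pen_del) and math.isfinite(ins_gain - lpm):
                cand_mask |= del_bound > pen_del
            else:
                cand_mask |= counts[:, _GAP_CODE] > 0
        cand_mask &= self.refcodes != _N_CODE

        def prior(code: int, l0: int) -> float:
            if code == self.refcodes[l0]:
                return math.log(g1) if g1 > 0 else -math.inf
            return lpr[min(code, _GAP_CODE)]

        for l0 in np.flatnonzero(cand_mask):
            l0 = int(l0)
            cur = int(cvec[l0])
            cov = self._covering(idx, l0)
            candidates = {int(self.refcodes[l0])}
            candidates.update(int(b) for b in range(4) if counts[l0, b] > 0)
            if counts[l0, _GAP_CODE] > 0 and (
                    cur == _GAP_CODE or not math.isfinite(pen_del)
                    or del_bound[l0] > pen_del):
                candidates.add(_GAP_CODE)
            candidates.discard(cur)
            best_cand, best_delta = cur, 0.0
            for cand in sorted(candidates):
                delta = prior(cand, l0) - prior(cur, l0)
                if not math.isfinite(delta) and delta < 0:
                    continue
                for i in cov:
                    if cand < 4 and cur < 4 and self._read_clean_at(
                            i, l0, cvec, cons_ins):
                        x = int(self.rvecs[i][l0 - (self.starts[i] - 1)])
                        d = (lp1 if x == cand else lpm) - \
                            (lp1 if x == cur else lpm)
                    else:
                        d = self._exact_delta(i, l0, cand, cur, cvec,
                                              cons_ins, profile)
                    delta += d
                    if delta == -math.inf:
                        break
                if delta > best_delta + _ACCEPT_TOL:
                    best_cand, best_delta = cand, delta
            if best_cand != cur:
                cvec[l0] = best_cand

        self._update_insertions(cvec, cons_ins, idx, profile, evo)
        return ConsensusHaplotype(index=cons.index,
                                  states=decode_states(cvec),
                                  insertions=cons_ins)

    def _update_insertions(self, cvec: np.ndarray, cons_ins: dict[int, str],
                           idx: np.ndarray, profile, evo) -> None:
        """Accept/reject a consensus insertion at each candidate gap by
        comparing the with- and without-insertion local objectives."""
        by_gap: dict[int, Counter] = {}
        for i in idx:
            for g, s in self.rins[i].items():
                by_gap.setdefault(g, Counter())[s] += 1
        gaps = set(cons_ins)
        for g, counter in by_gap.items():
            if counter.most_common(1)[0][1] >= 2:
                gaps.add(g)
        lb = math.log(evo.beta) if evo.beta > 0 else -math.inf
        lnb = math.log1p(-evo.beta)
        lp4 = math.log(profile.p4) if profile.p4 > 0 else -math.inf
        lnp4 = math.log1p(-profile.p4)
        lp3 = math.log(profile.p3) if profile.p3 > 0 else -math.inf
        lpm = (math.log(profile.p2) + _LOG_THIRD) if profile.p2 > 0 else -math.inf

        def seg_ll(length: int, rate: float) -> float:
            k = length - 1
            return k * math.log(rate) - rate - math.lgamma(k + 1)

        for g in sorted(gaps):
            cov = idx[(self.starts[idx] <= g) & (self.ends[idx] - 1 >= g)]
            if cov.size == 0:
                if g in cons_ins:
                    del cons_ins[g]
                continue
            strings = [self.rins[i].get(g, "") for i in cov]
            present = [s for s in strings if s]
            cand = cons_ins.get(g)
            if present:
                top = Counter(present).most_common()
                best_count = top[0][1]
                cand = sorted(s for s, c in top if c == best_count)[0]
            if cand is None:
                continue
            score_with = lb + len(cand) * _LOG_QUARTER
            score_none = lnb
            for s in strings:
                if s == cand:
                    score_with += lnp4
                elif s:
                    k = min(len(s), len(cand))
                    diff = sum(a != b for a, b in zip(s, cand))
                    diff += abs(len(s) - len(cand))
                    score_with += lnp4 + diff * lpm
                else:
                    score_with += lp3 + seg_ll(len(cand), profile.lambda_del)
                if s:
                    score_none += lp4 + seg_ll(len(s), profile.lambda_ins) \
                        + len(s) * _LOG_QUARTER
                else:
                    score_none += lnp4
            if score_with > score_none + _ACCEPT_TOL:
                cons_ins[g] = cand
            else:
                cons_ins.pop(g, None)

    def _estimate_profile(self, labels: np.ndarray,
                          consensuses: list[ConsensusHaplotype],
                          previous: SequencingErrorProfile | None
                          ) -> SequencingErrorProfile:
        """Closed-form sequencing-error MLEs pooled over classified reads."""
        n1 = n2 = n_u = n_v = n_w = 0
        del_len = ins_len = 0
        cvecs = [c.codes() for c in consensuses]
        for i in range(self.n):
            k = labels[i]
            ev = _read_events(self.rvecs[i], int(self.starts[i]),
                              int(self.ends[i]), self.rins[i], cvecs[k],
                              consensuses[k].insertions)
            n1 += ev.n_correct
            n2 += ev.n_mismatch
            n_u += ev.n_del_segments
            del_len += ev.n_deleted_positions
            n_v += ev.n_ins_segments
            ins_len += ev.n_inserted_bases
            n_w += ev.n_gaps_no_insertion
        floor = self.config.prob_floor
        if n1 + n2 + n_u > 0:
            p1, p2, p3 = _floored_simplex([n1, n2, n_u], floor)
        elif previous is not None:
            p1, p2, p3 = previous.p1, previous.p2, previous.p3
        else:
            p1, p2, p3 = 0.98, 0.01, 0.01
        if n_v + n_w > 0:
            p4 = min(max(n_v / (n_v + n_w), floor), 1.0 - floor)
        else:
            p4 = previous.p4 if previous is not None else 0.01
        lam_floor = 1e-6
        if n_u > 0:
            lam_del = max(del_len / n_u - 1.0, lam_floor)
        else:
            lam_del = previous.lambda_del if previous is not None else 1.0
        if n_v > 0:
            lam_ins = max(ins_len / n_v - 1.0, lam_floor)
        else:
            lam_ins = previous.lambda_ins if previous is not None else 1.0
        return SequencingErrorProfile(p1=1.0 - p2 - p3, p2=p2, p3=p3, p4=p4,
                                      lambda_ins=lam_ins, lambda_del=lam_del)

    def _estimate_evolution(self, consensuses: list[ConsensusHaplotype]
                            ) -> list[EvolutionParams]:
        """Per-haplotype evolution MLEs from consensus-vs-reference counts
        (pooled across haplotypes when ``tie_evolution`` is set)."""
        floor = self.config.evo_floor
        events = [summarize_consensus_vs_reference(c, self.reference)
                  for c in consensuses]
        if self.config.tie_evolution:
            tot = [sum(e.n_match for e in events),
                   sum(e.n_substitution for e in events),
                   sum(e.n_deletion for e in events)]
            gamma = _floored_simplex(tot, floor)
            n_ins = sum(e.n_insertion for e in events)
            beta = min(max(n_ins / (len(events) * (self.L0 - 1)), floor),
                       1.0 - floor)
            p = EvolutionParams(gamma=(1.0 - gamma[1] - gamma[2],
                                       gamma[1], gamma[2]), beta=beta)
            return [p] * len(consensuses)
        out = []
        for e in events:
            gamma = _floored_simplex(
                [e.n_match, e.n_substitution, e.n_deletion], floor)
            beta = min(max(e.n_insertion / (self.L0 - 1), floor), 1.0 - floor)
            out.append(EvolutionParams(gamma=(1.0 - gamma[1] - gamma[2],
                                              gamma[1], gamma[2]), beta=beta))
        return out

    def reseed_empty(self, labels: np.ndarray, K: int,
                     llmat: np.ndarray | None) -> np.ndarray:
        """Re-seed empty components with the worst-fitting reads (D-style:
        K stays fixed during a fit)."""
        labels = labels.copy()
        fit = (llmat.max(axis=1) if llmat is not None
               else np.zeros(self.n))
        order = np.argsort(fit)  # worst first
        used = 0
        for k in range(K):
            if np.any(labels == k):
                continue
            for i in order[used:]:
                used += 1
                if np.count_nonzero(labels == labels[i]) > 1:
                    logger.info("component %d empty; re-seeded with read %s",
                                k + 1, self.reads[i].name)
                    labels[i] = k
                    break
        return labels

    def m_step(self, labels: np.ndarray, state: ModelState,
               llmat: np.ndarray | None = None) -> ModelState:
        K = state.K
        labels = self.reseed_empty(labels, K, llmat)
        counts = np.bincount(labels, minlength=K)
        weights = MixtureWeights(tuple(counts / self.n))
        consensuses = []
        for k in range(K):
            idx = np.flatnonzero(labels == k)
            consensuses.append(self.update_consensus(
                state.consensuses[k], idx, state.profile, state.evolution[k]))
        profile = self._estimate_profile(labels, consensuses,
                                         previous=state.profile)
        evolution = self._estimate_evolution(consensuses)
        resp = np.zeros((self.n, K))
        resp[np.arange(self.n), labels] = 1.0
        return ModelState(consensuses=consensuses, weights=weights,
                          profile=profile, evolution=evolution,
                          responsibilities=resp,
                          temperature=state.temperature,
                          objective=state.objective)


# ---------------------------------------------------------------------------
# public steps
# ---------------------------------------------------------------------------


def _anneal(llmat: np.ndarray, log_alpha: np.ndarray, T: float,
            read_names: Sequence[str] | None = None) -> np.ndarray:
    logw = (log_alpha[None, :] + llmat) / T
    norm = logsumexp(logw, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        i = int(np.argmax(bad))
        name = read_names[i] if read_names else f"#{i}"
        raise InferenceError(
            f"read {name} has zero likelihood under every haplotype")
    with np.errstate(invalid="ignore"):
        resp = np.exp(logw - norm[:, None])
    resp[logw == -np.inf] = 0.0
    return resp / resp.sum(axis=1, keepdims=True)


def initialize_state(reads: Sequence[AlignedRead],
                     reference: ReferenceSequence, K: int, seed: int = 0,
                     init: str = "cluster",
                     config: FitConfig | None = None) -> ModelState:
    """Build a starting state: a seeded read partition (variant-column
    clustering by default, ``init="random"`` for a random one), plurality
    consensuses, and parameters from global event counts."""
    config = config or FitConfig(seed=seed, init=init)
    engine = _Engine(reads, reference, config)
    mode = "cluster" if init in ("cluster", "auto") else "random"
    return engine.initialize(K, seed, mode)


def ae_step(reads: Sequence[AlignedRead], state: ModelState) -> np.ndarray:
    """Annealed responsibilities: rows proportional to
    (alpha_k P(R_i|C_k, psi))^(1/T), normalized in log space."""
    llmat = np.empty((len(reads), state.K))
    for k, cons in enumerate(state.consensuses):
        cvec = cons.codes()
        for i, r in enumerate(reads):
            ev = _read_events(r.codes(), r.start, r.end, r.insertions,
                              cvec, cons.insertions)
            llmat[i, k] = read_log_likelihood(ev, state.profile)
    return _anneal(llmat, state.weights.log(), state.temperature,
                   [r.name for r in reads])


def c_step(responsibilities: np.ndarray) -> np.ndarray:
    """Hard classification: per-read argmax, ties to the lowest index."""
    resp = np.asarray(responsibilities)
    if resp.ndim != 2 or np.any(resp < 0):
        raise ModelError("responsibilities must be a non-negative n x K table")
    return np.argmax(resp, axis=1)


def m_step(reads: Sequence[AlignedRead], labels,
           reference: ReferenceSequence, state: ModelState,
           config: FitConfig | None = None) -> ModelState:
    """Closed-form parameter updates and coordinate-ascent consensus update
    given hard labels; empty components are re-seeded with the worst-fitting
    read."""
    config = config or FitConfig()
    engine = _Engine(reads, reference, config)
    labels = np.asarray(labels, dtype=int)
    llmat = engine.ll_matrix(state)
    new = engine.m_step(labels, state, llmat=llmat)
    final_ll = engine.ll_matrix(new)
    new.objective = engine.objective(final_ll, new.labels(), new)
    return new


def run_caem(reads: Sequence[AlignedRead], reference: ReferenceSequence,
             K: int, config: FitConfig | None = None) -> CaemResult:
    """Fit K haplotypes by classification annealing EM with restarts.

    Loops AE -> C -> M with geometric cooling T_{t+1} = max(1, cooling*T_t);
    stops when the relative objective change at T = 1 drops below ``tol`` or
    ``max_iter`` is reached; returns the best restart by final objective
    (ties to the lowest restart index).
    """
    config = config or FitConfig()
    engine = _Engine(reads, reference, config)
    base = np.random.default_rng(config.seed)
    restart_seeds = base.integers(0, 2**31 - 1, size=config.n_restarts)
    best: tuple[float, int, ModelState, np.ndarray, dict] | None = None
    traces = []
    any_converged = False
    for r in range(config.n_restarts):
        if config.init == "auto":
            mode = "cluster" if r < 2 else "random"
        else:
            mode = config.init
        state = engine.initialize(K, int(restart_seeds[r]), mode)
        T = config.T0
        llmat = engine.ll_matrix(state)
        trace: list[float] = []
        prev = None
        converged = False
        labels = state.labels()
        for _ in range(config.max_iter):
            state.temperature = T
            resp = _anneal(llmat, state.weights.log(), T,
                           [rd.name for rd in reads])
            labels = np.argmax(resp, axis=1)
            state = engine.m_step(labels, state, llmat=llmat)
            labels = state.labels()
            llmat = engine.ll_matrix(state)
            obj = engine.objective(llmat, labels, state)
            state.objective = obj
            trace.append(obj)
            if T <= 1.0 and prev is not None and \
                    abs(obj - prev) <= config.tol * max(1.0, abs(prev)):
                converged = True
                break
            prev = obj
            T = max(1.0, config.cooling * T)
        state.temperature = 1.0
        state.responsibilities = _anneal(llmat, state.weights.log(), 1.0,
                                         [rd.name for rd in reads])
        traces.append(trace)
        any_converged |= converged
        if best is None or state.objective > best[0]:
            best = (state.objective, r, state, labels, {"converged": converged})
    assert best is not None
    obj, r, state, labels, extra = best
    if not extra["converged"]:
        logger.warning("CAEM did not converge within max_iter; returning the "
                       "best state found")
    diagnostics = {
        "objective": obj,
        "best_restart": r,
        "converged": extra["converged"],
        "trace": traces[r],
        "traces": traces,
        "n_iter": len(traces[r]),
    }
    return CaemResult(state=state, labels=labels, diagnostics=diagnostics)


def select_k(reads: Sequence[AlignedRead], reference: ReferenceSequence,
             k_values: Sequence[int], config: FitConfig | None = None
             ) -> SelectKResult:
    """Choose K by five-fold cross-validated held-out MECR.

    Reads are partitioned into five seeded folds; for each K the model is
    fitted on four folds and the held-out reads' MECR against the fitted
    haplotypes is recorded.  The chosen K minimizes the mean held-out MECR,
    with near-ties (within one standard error of the minimizer) broken
    toward smaller K.  With fewer than five reads an in-sample MECR is used
    with a warning.
    """
    config = config or FitConfig()
    n = len(reads)
    k_values = sorted(set(int(k) for k in k_values))
    rng = np.random.default_rng(config.seed)
    in_sample = n < 5
    if in_sample:
        logger.warning("fewer than 5 reads; falling back to in-sample MECR")
        folds = [np.array([], dtype=int)]
    else:
        folds = np.array_split(rng.permutation(n), 5)
    rows = []
    for K in k_values:
        scores = []
        for fold in folds:
            test_idx = set(fold.tolist())
            train = [r for i, r in enumerate(reads) if i not in test_idx]
            test = [r for i, r in enumerate(reads) if i in test_idx]
            if not test:
                train, test = list(reads), list(reads)
            if len(train) < K:
                raise InferenceError(
                    f"fold leaves {len(train)} training reads < K={K}")
            res = run_caem(train, reference, K, config)
            scores.append(_mecr(test, res.state.consensuses).mecr)
        scores = np.asarray(scores)
        se = float(scores.std(ddof=1) / math.sqrt(scores.size)) \
            if scores.size > 1 else 0.0
        rows.append((K, float(scores.mean()), se, scores.tolist()))
    table = pd.DataFrame(rows, columns=["K", "mean_mecr", "se_mecr",
                                        "fold_scores"])
    i_min = int(table["mean_mecr"].idxmin())
    threshold = table.loc[i_min, "mean_mecr"] + table.loc[i_min, "se_mecr"]
    chosen = int(table.loc[table["mean_mecr"] <= threshold, "K"].min())
    return SelectKResult(chosen_k=chosen, table=table, in_sample=in_sample)
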