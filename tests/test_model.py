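"""Unit and property tests for the generative-model core."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import haplomix as hx
from haplomix.model import ModelError

from _oracles import complete_probability, evolution_probability, read_probability

LOG3 = math.log(3.0)


# ---------------------------------------------------------------------------
# consensus vs reference
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ref,states,insertions,expected",
    [
        # identity: all matches
        ("ACGT", "ACGT", {}, (4, 0, 0, 0)),
        # hand classification: match, sub, match? A-G sub, G match, T deleted
        ("ACGT", "AGG-", {}, (2, 1, 1, 0)),
        # single insertion event
        ("AC", "AC", {1: "G"}, (2, 0, 0, 1)),
        # N reference positions count as universal matches
        ("ANGT", "ATGT", {}, (4, 0, 0, 0)),
    ],
)
def test_consensus_vs_reference_classification(ref, states, insertions, expected):
    events = hx.summarize_consensus_vs_reference(
        hx.ConsensusHaplotype(1, states, insertions),
        hx.ReferenceSequence("r", ref))
    assert (events.n_match, events.n_substitution, events.n_deletion,
            events.n_insertion) == expected


def test_consensus_length_mismatch_is_structural_error():
    with pytest.raises(ModelError):
        hx.summarize_consensus_vs_reference(
            hx.ConsensusHaplotype(1, "ACG"), hx.ReferenceSequence("r", "ACGT"))


def test_evolution_log_likelihood_values():
    ref = hx.ReferenceSequence("r", "ACGTA")
    cons = hx.ConsensusHaplotype(1, "ACGTA")
    events = hx.summarize_consensus_vs_reference(cons, ref)
    # all probability mass on the observed outcome -> log-likelihood 0
    assert hx.evolution_log_likelihood(
        events, hx.EvolutionParams((1.0, 0.0, 0.0), 0.0), 5) == 0.0
    # the published diploid setting on an identical 5-base consensus
    params = hx.EvolutionParams.from_four((0.9989, 0.001, 0.0001, 0.0001))
    expected = 5 * math.log(0.9989) + 4 * math.log(1 - 0.0001)
    assert hx.evolution_log_likelihood(events, params, 5) == pytest.approx(
        expected, abs=1e-12)


def test_evolution_impossible_event_is_minus_inf():
    ref = hx.ReferenceSequence("r", "ACGT")
    cons = hx.ConsensusHaplotype(1, "AGGT")  # one substitution
    events = hx.summarize_consensus_vs_reference(cons, ref)
    ll = hx.evolution_log_likelihood(
        events, hx.EvolutionParams((0.9, 0.0, 0.1), 0.0), 4)
    assert ll == -math.inf


# ---------------------------------------------------------------------------
# read vs consensus
# ---------------------------------------------------------------------------


def test_read_vs_consensus_identity():
    cons = hx.ConsensusHaplotype(1, "ACGTACGT")
    read = hx.AlignedRead("r", 2, 6, "CGTAC")
    ev = hx.summarize_read_vs_consensus(read, cons)
    assert ev == hx.ReadConsensusEvents(5, 0, (), (), 4)


def test_read_vs_consensus_deletion_run():
    cons = hx.ConsensusHaplotype(1, "ACGTA")
    read = hx.AlignedRead("r", 1, 5, "AC--A")
    ev = hx.summarize_read_vs_consensus(read, cons)
    assert ev == hx.ReadConsensusEvents(3, 0, (2,), (), 4)


def test_consensus_deletion_positions_are_skipped():
    # consensus deletes position 3; the read's base there becomes an
    # insertion at the adjacent gap, and the comparable count drops by one
    cons = hx.ConsensusHaplotype(1, "AC-TA")
    read = hx.AlignedRead("r", 1, 5, "ACGTA")
    ev = hx.summarize_read_vs_consensus(read, cons)
    assert ev.n_correct + ev.n_mismatch + ev.n_deleted_positions == 4
    assert ev.ins_segments == (1,)


def test_matching_insertions_are_no_event():
    cons = hx.ConsensusHaplotype(1, "ACGT", {2: "TT"})
    read = hx.AlignedRead("r", 1, 4, "ACGT", {2: "TT"})
    ev = hx.summarize_read_vs_consensus(read, cons)
    assert ev.ins_segments == () and ev.n_mismatch == 0
    # a missing consensus insertion becomes a deletion segment
    read2 = hx.AlignedRead("r2", 1, 4, "ACGT")
    ev2 = hx.summarize_read_vs_consensus(read2, cons)
    assert ev2.del_segments == (2,)
    # a differing insertion string counts mismatch-equivalents
    read3 = hx.AlignedRead("r3", 1, 4, "ACGT", {2: "TA"})
    ev3 = hx.summarize_read_vs_consensus(read3, cons)
    assert ev3.n_mismatch == 1


def test_read_beyond_reference_is_structural_error():
    cons = hx.ConsensusHaplotype(1, "ACGT")
    with pytest.raises(ModelError):
        hx.summarize_read_vs_consensus(hx.AlignedRead("r", 2, 5, "CGTA"), cons)


# ---------------------------------------------------------------------------
# truncated Poisson
# ---------------------------------------------------------------------------


def test_truncated_poisson_against_scipy():
    for length in (1, 2, 3, 7, 20):
        for rate in (0.3, 1.0, 2.0, 5.5):
            assert hx.truncated_poisson_log_pmf(length, rate) == pytest.approx(
                stats.poisson.logpmf(length - 1, rate), abs=1e-12)


def test_truncated_poisson_values_and_normalization():
    assert hx.truncated_poisson_log_pmf(1, 2.0) == pytest.approx(-2.0)
    assert hx.truncated_poisson_log_pmf(3, 2.0) == pytest.approx(
        2 * math.log(2) - 2 - math.log(2))
    total = sum(math.exp(hx.truncated_poisson_log_pmf(l, 1.7))
                for l in range(1, 201))
    assert total == pytest.approx(1.0, abs=1e-10)
    with pytest.raises(ModelError):
        hx.truncated_poisson_log_pmf(0, 1.0)


# ---------------------------------------------------------------------------
# read log-likelihood
# ---------------------------------------------------------------------------


def test_read_log_likelihood_term_by_term():
    profile = hx.SequencingErrorProfile(p1=0.9, p2=0.05, p3=0.05, p4=0.01,
                                        lambda_ins=1.0, lambda_del=1.0)
    events = hx.ReadConsensusEvents(3, 1, (2,), (), 4)
    # 3 correct + 1 mismatch (with its uniform-base 1/3) + one deletion
    # segment of length 2 + 4 gaps without insertion
    expected = (3 * math.log(0.9)
                + math.log(0.05) - LOG3
                + math.log(0.05) + (1 * math.log(1.0) - 1.0 - 0.0)
                + 4 * math.log(0.99))
    assert hx.read_log_likelihood(events, profile) == pytest.approx(
        expected, abs=1e-12)


def test_read_log_likelihood_degenerate_and_impossible():
    perfect = hx.SequencingErrorProfile(p1=1.0, p2=0.0, p3=0.0, p4=0.0,
                                        lambda_ins=1.0, lambda_del=1.0)
    assert hx.read_log_likelihood(
        hx.ReadConsensusEvents(10, 0, (), (), 9), perfect) == 0.0
    assert hx.read_log_likelihood(
        hx.ReadConsensusEvents(9, 1, (), (), 9), perfect) == -math.inf


# ---------------------------------------------------------------------------
# brute-force product oracles
# ---------------------------------------------------------------------------


@st.composite
def tiny_instance(draw):
    L0 = draw(st.integers(4, 12))
    rng = np.random.default_rng(draw(st.integers(0, 10**6)))
    ref = "".join(rng.choice(list("ACGT"), L0))
    cons_states = "".join(
        rng.choice(list("ACGT-"), L0, p=[0.2, 0.2, 0.2, 0.2, 0.2]))
    cons_ins = {}
    for g in range(1, L0):
        if rng.random() < 0.15:
            cons_ins[g] = "".join(rng.choice(list("ACGT"),
                                             rng.integers(1, 4)))
    s = int(rng.integers(1, L0))
    e = int(rng.integers(s, L0 + 1))
    states = "".join(rng.choice(list("ACGT-"), e - s + 1,
                                p=[0.22, 0.22, 0.22, 0.22, 0.12]))
    if set(states) <= {"-"}:
        states = "A" + states[1:]
    read_ins = {}
    for g in range(s, e):
        if rng.random() < 0.15:
            read_ins[g] = "".join(rng.choice(list("ACGT"),
                                             rng.integers(1, 4)))
    return (hx.ReferenceSequence("r", ref),
            hx.ConsensusHaplotype(1, cons_states, cons_ins),
            hx.AlignedRead("x", s, e, states, read_ins))


PROFILE = hx.SequencingErrorProfile(p1=0.85, p2=0.1, p3=0.05, p4=0.07,
                                    lambda_ins=0.8, lambda_del=1.3)
EVO = hx.EvolutionParams((0.7, 0.2, 0.1), 0.1)


@given(tiny_instance())
def test_read_likelihood_matches_product_oracle(instance):
    """exp(log-likelihood) equals the literal product form computed
    position-by-position by an independent string walk."""
    _, cons, read = instance
    ev = hx.summarize_read_vs_consensus(read, cons)
    ours = math.exp(hx.read_log_likelihood(ev, PROFILE))
    brute = read_probability(read, cons, PROFILE)
    assert ours == pytest.approx(brute, rel=1e-10, abs=1e-300)


@given(tiny_instance())
def test_evolution_likelihood_matches_product_oracle(instance):
    ref, cons, _ = instance
    ev = hx.summarize_consensus_vs_reference(cons, ref)
    ours = math.exp(hx.evolution_log_likelihood(ev, EVO, ref.length))
    brute = evolution_probability(cons, ref, EVO)
    assert ours == pytest.approx(brute, rel=1e-10)


@given(tiny_instance())
def test_position_conservation(instance):
    """Event counts conserve read positions when the consensus carries no
    insertions: correct + mismatch + deleted + consensus-deleted = Li."""
    _, cons, read = instance
    cons = hx.ConsensusHaplotype(1, cons.states, {})
    ev = hx.summarize_read_vs_consensus(read, cons)
    n_cons_del = sum(
        1 for pos in range(read.start, read.end + 1)
        if cons.states[pos - 1] == "-")
    total = ev.n_correct + ev.n_mismatch + ev.n_deleted_positions + n_cons_del
    assert total == read.length


# ---------------------------------------------------------------------------
# complete-data likelihood
# ---------------------------------------------------------------------------


def _tiny_mixture(seed=5):
    rng = np.random.default_rng(seed)
    ref = hx.ReferenceSequence("r", "".join(rng.choice(list("ACGT"), 8)))
    cons = [hx.simulate_consensus(ref, hx.EvolutionParams((0.7, 0.2, 0.1), 0.1),
                                  rng, index=k + 1) for k in range(2)]
    reads = []
    for i in range(4):
        k = int(rng.integers(0, 2))
        r = hx.simulate_read(cons[k], PROFILE, 6, 2, rng, name=f"r{i}")
        reads.append(r)
    labels = [0, 1, 0, 1]
    return ref, cons, reads, labels


def test_complete_likelihood_matches_product_oracle():
    ref, cons, reads, labels = _tiny_mixture()
    weights = hx.MixtureWeights((0.6, 0.4))
    evo = [EVO, EVO]
    ours = hx.complete_data_log_likelihood(reads, labels, cons, weights,
                                           PROFILE, evo, ref)
    brute = complete_probability(reads, labels, cons, weights, PROFILE, evo, ref)
    assert math.exp(ours) == pytest.approx(brute, rel=1e-10)


def test_complete_likelihood_decomposes_and_permutes():
    ref, cons, reads, labels = _tiny_mixture()
    weights = hx.MixtureWeights((0.6, 0.4))
    evo = [EVO, EVO]
    total = hx.complete_data_log_likelihood(reads, labels, cons, weights,
                                            PROFILE, evo, ref)
    # linearity: per-read + per-consensus terms computed independently
    parts = 0.0
    for read, k in zip(reads, labels):
        ev = hx.summarize_read_vs_consensus(read, cons[k])
        parts += math.log(weights.alpha[k]) + hx.read_log_likelihood(ev, PROFILE)
    for k in range(2):
        cev = hx.summarize_consensus_vs_reference(cons[k], ref)
        parts += hx.evolution_log_likelihood(cev, EVO, ref.length)
    assert total == pytest.approx(parts, abs=1e-10)
    # permutation invariance in read order
    perm = [2, 0, 3, 1]
    shuffled = hx.complete_data_log_likelihood(
        [reads[i] for i in perm], [labels[i] for i in perm], cons, weights,
        PROFILE, evo, ref)
    assert shuffled == pytest.approx(total, abs=1e-10)
    # one-hot labels agree with integer labels
    onehot = np.zeros((4, 2), dtype=int)
    onehot[np.arange(4), labels] = 1
    assert hx.complete_data_log_likelihood(
        reads, onehot, cons, weights, PROFILE, evo, ref) == pytest.approx(total)


def test_domain_type_invariants_are_enforced():
    with pytest.raises(ModelError):
        hx.ReferenceSequence("r", "A")  # too short
    with pytest.raises(ModelError):
        hx.EvolutionParams((0.5, 0.5, 0.5), 0.0)  # simplex violated
    with pytest.raises(ModelError):
        hx.SequencingErrorProfile(0.9, 0.05, 0.2, 0.0, 1.0, 1.0)
    with pytest.raises(ModelError):
        hx.MixtureWeights((0.5, 0.6))
    with pytest.raises(ModelError):
        hx.AlignedRead("r", 3, 2, "")  # inverted interval
    with pytest.raises(ModelError):
        hx.AlignedRead("r", 1, 2, "--")  # all deleted
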