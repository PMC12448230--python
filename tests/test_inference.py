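"""CAEM tests: step semantics, M-step optimality on micro instances,
exact recovery on separable data, monotonicity, and model selection."""

import itertools
import math

import numpy as np
import pytest

import haplomix as hx
from haplomix.inference import FitConfig, InferenceError, _Engine
from haplomix.model import ModelError

from conftest import random_reference
from _oracles import exhaustive_best_labeling


def _zero_noise_reads(haps, n_per_hap, length, L0, rng):
    """Error-free reads tiled over each haplotype."""
    profile = hx.SequencingErrorProfile(1.0, 0.0, 0.0, 0.0, 1.0, 1.0)
    reads = []
    for k, hap in enumerate(haps):
        for i in range(n_per_hap):
            start = int(rng.integers(1, L0 - length + 2))
            r = hx.simulate_read(hap, profile, length, start, rng,
                                 name=f"h{k}r{i}")
            r.truth_source = k + 1
            reads.append(r)
    return reads


@pytest.fixture
def distinct_pair(small_reference):
    """Two consensuses 20 substitutions apart, plus zero-noise reads."""
    rng = np.random.default_rng(21)
    ref = small_reference
    states = list(ref.bases)
    hap1 = hx.ConsensusHaplotype(1, "".join(states))
    pos = rng.choice(ref.length, 20, replace=False)
    for p in pos:
        states[p] = "ACGT"[(("ACGT".index(states[p])) + 1) % 4]
    hap2 = hx.ConsensusHaplotype(2, "".join(states))
    reads = _zero_noise_reads([hap1, hap2], 20, 600, ref.length, rng)
    return ref, [hap1, hap2], reads


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def test_initialize_is_deterministic(separable_dataset):
    ds = separable_dataset
    a = hx.initialize_state(ds.reads, ds.reference, K=2, seed=3)
    b = hx.initialize_state(ds.reads, ds.reference, K=2, seed=3)
    assert [c.states for c in a.consensuses] == [c.states for c in b.consensuses]
    assert np.array_equal(a.responsibilities, b.responsibilities)
    assert a.weights.alpha == b.weights.alpha


def test_initialize_k1_is_global_plurality(separable_dataset):
    ds = separable_dataset
    state = hx.initialize_state(ds.reads, ds.reference, K=1, seed=0)
    engine = _Engine(ds.reads, ds.reference, FitConfig())
    expected = engine.plurality_consensus(np.arange(len(ds.reads)), index=1)
    assert state.consensuses[0].states == expected.states


def test_initialize_needs_enough_reads(small_reference):
    read = hx.AlignedRead("r", 1, 4, "ACGT")
    with pytest.raises(InferenceError):
        hx.initialize_state([read], small_reference, K=2, seed=0)


# ---------------------------------------------------------------------------
# AE step
# ---------------------------------------------------------------------------


def _two_component_state(ref, haps, reads, T=1.0, alpha=(0.5, 0.5)):
    profile = hx.error_profile_preset(1)
    evo = [hx.EvolutionParams((0.99, 0.009, 0.001), 0.001)] * 2
    resp = np.full((len(reads), 2), 0.5)
    return hx.ModelState(consensuses=haps, weights=hx.MixtureWeights(alpha),
                         profile=profile, evolution=evo,
                         responsibilities=resp, temperature=T)


def test_ae_step_t1_is_bayes_posterior(distinct_pair):
    ref, haps, reads = distinct_pair
    state = _two_component_state(ref, haps, reads, T=1.0)
    resp = hx.ae_step(reads, state)
    assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-12)
    # closed form for K=2 with equal weights: 1 / (1 + exp(-Delta))
    for i, read in enumerate(reads[:10]):
        ll = [hx.read_log_likelihood(
            hx.summarize_read_vs_consensus(read, h), state.profile)
            for h in haps]
        delta = ll[0] - ll[1]
        if math.isfinite(delta):
            assert resp[i, 0] == pytest.approx(1 / (1 + math.exp(-delta)),
                                               abs=1e-12)


def test_ae_step_high_temperature_flattens(distinct_pair):
    ref, haps, reads = distinct_pair
    state = _two_component_state(ref, haps, reads, T=1e9)
    resp = hx.ae_step(reads, state)
    assert np.allclose(resp, 0.5, atol=1e-3)


def test_ae_step_reports_zero_likelihood_read(distinct_pair):
    ref, haps, reads = distinct_pair
    state = _two_component_state(ref, haps, reads, T=1.0)
    # a profile with p2 = 0 makes any mismatching read impossible
    state.profile = hx.SequencingErrorProfile(1.0, 0.0, 0.0, 0.0, 1.0, 1.0)
    bad = hx.AlignedRead("impossible", 1, 4, "".join(
        "ACGT"[("ACGT".index(b) + 2) % 4] for b in ref.bases[:4]))
    with pytest.raises(InferenceError, match="impossible"):
        hx.ae_step([*reads, bad], state)


def test_c_step_argmax_and_ties():
    resp = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [0.2, 0.8]])
    labels = hx.c_step(resp)
    assert labels.tolist() == [0, 1, 0, 1]  # tie broken to the lowest index
    # invariant under strictly monotone row rescaling
    assert hx.c_step(resp ** 3).tolist() == labels.tolist()


# ---------------------------------------------------------------------------
# M step
# ---------------------------------------------------------------------------


def test_m_step_closed_form_weights_and_lambda(distinct_pair):
    ref, haps, reads = distinct_pair
    engine = _Engine(reads[:3], ref, FitConfig())
    state = engine.state_from_labels(np.array([0, 0, 1]), 2)
    assert state.weights.alpha == pytest.approx((2 / 3, 1 / 3))
    # shifted-Poisson MLE: mean segment length minus one
    ev = hx.ReadConsensusEvents(5, 0, (1, 3), (), 4)
    segs = np.array(ev.del_segments)
    assert segs.mean() - 1 == pytest.approx(1.0)


def test_m_step_consensus_attains_exhaustive_optimum():
    """On a 3-read, L0=6 instance the updated consensus reaches the best
    complete-data log-likelihood over all 5^6 state vectors."""
    rng = np.random.default_rng(77)
    ref = hx.ReferenceSequence("r", "ACGTAC")
    profile = hx.SequencingErrorProfile(0.8, 0.1, 0.1, 0.05, 1.0, 1.0)
    evo = hx.EvolutionParams((0.8, 0.1, 0.1), 0.01)
    reads = [
        hx.AlignedRead("a", 1, 6, "AGGTAC"),
        hx.AlignedRead("b", 1, 6, "AGG-AC"),
        hx.AlignedRead("c", 2, 6, "GGTAC"),
    ]
    engine = _Engine(reads, ref, FitConfig())
    labels = np.zeros(3, dtype=int)
    state = engine.state_from_labels(labels, 1)
    state.profile = profile
    state.evolution = [evo]
    for _ in range(6):
        state = engine.m_step(labels, state)
        state.profile = profile  # hold parameters fixed; optimize consensus
        state.evolution = [evo]
    ours = hx.complete_data_log_likelihood(
        reads, labels, state.consensuses, hx.MixtureWeights((1.0,)),
        profile, [evo], ref)

    best = -math.inf
    for combo in itertools.product("ACGT-", repeat=6):
        cand = "".join(combo)
        if set(cand) <= {"-"}:
            continue
        cons = hx.ConsensusHaplotype(1, cand)
        ll = hx.complete_data_log_likelihood(
            reads, labels, [cons], hx.MixtureWeights((1.0,)), profile,
            [evo], ref)
        best = max(best, ll)
    assert ours == pytest.approx(best, abs=1e-9)


def test_m_step_reseeds_empty_component(distinct_pair):
    ref, haps, reads = distinct_pair
    subset = reads[:6]
    state = hx.initialize_state(subset, ref, K=2, seed=0)
    new = hx.m_step(subset, np.zeros(6, dtype=int), ref, state)
    counts = np.bincount(new.labels(), minlength=2)
    assert counts.min() >= 1  # the empty component was re-seeded


# ---------------------------------------------------------------------------
# full fits
# ---------------------------------------------------------------------------


def test_caem_recovers_distinct_haplotypes_exactly(distinct_pair):
    ref, haps, reads = distinct_pair
    res = hx.run_caem(reads, ref, 2, FitConfig(n_restarts=4, seed=0))
    assert hx.cpr(haps, res.state.consensuses, reference=ref) == 1.0
    recovered = sorted(c.states for c in res.state.consensuses)
    assert recovered == sorted(h.states for h in haps)


def test_caem_objective_trace_is_monotone(separable_dataset):
    ds = separable_dataset
    res = hx.run_caem(ds.reads, ds.reference, 2,
                      FitConfig(n_restarts=3, seed=2))
    for trace in res.diagnostics["traces"]:
        for a, b in zip(trace, trace[1:]):
            assert b >= a - 1e-7 * max(1.0, abs(a))


def test_caem_k1_identical_across_restarts(separable_dataset):
    ds = separable_dataset
    r1 = hx.run_caem(ds.reads, ds.reference, 1, FitConfig(n_restarts=1, seed=0))
    r2 = hx.run_caem(ds.reads, ds.reference, 1, FitConfig(n_restarts=3, seed=5))
    assert r1.state.consensuses[0].states == r2.state.consensuses[0].states


def test_caem_matches_exhaustive_labeling_on_micro_instance():
    """Best-of-restarts CAEM reaches the global optimum over all 2^n
    labelings with conditionally optimal consensuses and parameters."""
    rng = np.random.default_rng(5)
    ref = random_reference(50, 12)
    states = list(ref.bases)
    hap1 = hx.ConsensusHaplotype(1, "".join(states))
    for p in (2, 6, 9):
        states[p] = "ACGT"[("ACGT".index(states[p]) + 1) % 4]
    hap2 = hx.ConsensusHaplotype(2, "".join(states))
    reads = _zero_noise_reads([hap1, hap2], 3, 10, ref.length, rng)[:5]
    config = FitConfig(n_restarts=20, seed=1)
    res = hx.run_caem(reads, ref, 2, config)
    best_obj, _ = exhaustive_best_labeling(reads, ref, 2, config)
    assert res.diagnostics["objective"] == pytest.approx(best_obj, abs=1e-6)


def test_label_permutation_leaves_objective_unchanged(distinct_pair):
    ref, haps, reads = distinct_pair
    engine = _Engine(reads, ref, FitConfig())
    labels = np.array([0 if r.truth_source == 1 else 1 for r in reads])
    s1 = engine.state_from_labels(labels, 2)
    s2 = engine.state_from_labels(1 - labels, 2)
    assert s1.objective == pytest.approx(s2.objective, abs=1e-9)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def _selection_dataset(K, seed, L0=300, n=60):
    ref = random_reference(400 + seed, L0)
    evo = [hx.EvolutionParams((0.969, 0.03, 0.001), 0.001)] * K
    weights = {1: (1.0,), 2: (0.6, 0.4), 3: (0.4, 0.4, 0.2)}[K]
    cfg = hx.SimulationConfig(
        reference=ref, K=K, n_reads=n, evolution=evo,
        weights=hx.MixtureWeights(weights), profile=1, seed=seed,
        length_model=hx.EmpiricalLengths((L0,)))
    return hx.simulate_dataset(cfg), ref


# a short annealing schedule: the hard-label dynamics are invariant to the
# temperature (a monotone power transform does not change the argmax), so
# cross-validation sweeps use a quick warm-up
_CV_CONFIG = dict(n_restarts=2, max_iter=100, T0=1.5, cooling=0.5)


@pytest.mark.parametrize("true_k", [1, 2])
def test_select_k_recovers_generating_k(true_k):
    ds, ref = _selection_dataset(true_k, seed=true_k)
    config = FitConfig(seed=0, **_CV_CONFIG)
    result = hx.select_k(ds.reads, ref, [1, 2, 3], config)
    assert result.chosen_k == true_k
    assert result.table["K"].tolist() == [1, 2, 3]


def test_select_k_fold_partition_deterministic():
    ds, ref = _selection_dataset(2, seed=9)
    config = FitConfig(seed=4, **_CV_CONFIG)
    a = hx.select_k(ds.reads, ref, [1, 2], config)
    b = hx.select_k(ds.reads, ref, [1, 2], config)
    assert a.chosen_k == b.chosen_k
    assert a.table["mean_mecr"].tolist() == b.table["mean_mecr"].tolist()
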