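"""Choose the number of haplotypes K by five-fold cross-validated MECR.

Simulates a well-separated K=2 dataset and sweeps K = 1..4.  The held-out
MECR drops sharply from K=1 to the true K and flattens beyond it; near-ties
within one standard error are broken toward the smaller K.
"""

import numpy as np

import haplomix as hx

rng = np.random.default_rng(1)
reference = hx.ReferenceSequence("demo", "".join(rng.choice(list("ACGT"), 300)))
config = hx.SimulationConfig(
    reference=reference, K=2, n_reads=60,
    evolution=[hx.EvolutionParams((0.969, 0.03, 0.001), 0.001)] * 2,
    weights=hx.MixtureWeights((0.6, 0.4)), profile=1, seed=3,
    length_model=hx.EmpiricalLengths((300,)))
dataset = hx.simulate_dataset(config)

fit_config = hx.FitConfig(n_restarts=2, seed=0, max_iter=100,
                          T0=1.5, cooling=0.5)
result = hx.select_k(dataset.reads, reference, [1, 2, 3, 4], fit_config)

print(result.table[["K", "mean_mecr", "se_mecr"]].to_string(index=False))
print(f"chosen K = {result.chosen_k} (simulated with K = 2)")
print("the mean held-out MECR is the cross-validated per-base inconsistency; "
      "adding components beyond the true ploidy barely improves it.")
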