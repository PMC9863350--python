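"""Optimal-contributions mate selection at a 45-degree balance target.

Builds a structured candidate set (30 genotypes over 10 founder families),
optimizes a 15-mating plan balancing index gain against parental
coancestry, and prints the achieved summary alongside the two frontier
endpoints.
"""

import numpy as np

from breedgain.ocs import CandidateSet, OCSConfig, evaluate_plan, frontier_endpoints, optimize_matings
from breedgain.pedigree import PedigreeRecord, build_additive_matrix

rng = np.random.default_rng(1)
records = [PedigreeRecord(f"F{i}", fgen=2) for i in range(10)]
for i in range(30):
    a, b = rng.choice(10, 2, replace=False)
    records.append(PedigreeRecord(f"C{i}", f"F{a}", f"F{b}"))
rm = build_additive_matrix(records)
ids = [f"C{i}" for i in range(30)]
cand = CandidateSet(ids=ids, index=rng.normal(1000, 50, 30),
                    A=rm.submatrix(ids).a, max_uses=4)

config = OCSConfig(n_matings=15, target_degrees=45.0, population_size=60,
                   generations=150, seed=7)
gain_plan, min_plan = frontier_endpoints(cand, config)
e_gain = evaluate_plan(gain_plan, cand)
e_min = evaluate_plan(min_plan, cand)
print(f"Max-gain endpoint:       index {e_gain.mean_progeny_index:7.1f}, "
      f"coancestry {e_gain.parental_coancestry:.4f}")
print(f"Min-coancestry endpoint: index {e_min.mean_progeny_index:7.1f}, "
      f"coancestry {e_min.parental_coancestry:.4f}")

plan = optimize_matings(cand, config)
print("\nOptimized plan at target 45 degrees:")
for key, val in plan.summary().items():
    print(f"  {key}: {val if not isinstance(val, float) else round(val, 4)}")
print("\n45 degrees trades roughly half the attainable index gain for a")
print("substantially lower parental coancestry than the max-gain plan.")
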