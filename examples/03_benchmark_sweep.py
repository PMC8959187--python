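"""Sweep caller parameters and trace the precision-recall frontier.

Runs the caller over a small grid of HMM transition probabilities with and
without SVD denoising, tries every quality cutoff, and keeps the best
precision at each attainable recall — the standard protocol for comparing
CNV callers against a truth set.
"""

import depthcnv as dc

config = dc.SimulationConfig(
    n_samples=60,
    chromosomes=(("1", 200_000_000),),
    bias_sd=0.1,  # strong shared batch bias
    seed=11,
)
config = dc.plant_random_cnvs(config, n_del=6, n_dup=6, min_bins=6, max_bins=15)
cov, truth = dc.simulate_cohort(config)

grid = {"transition_prob": [1e-8, 1e-5, 1e-2], "n_discard": [0, 5]}
frontier, all_points = dc.sweep(cov, truth, grid)

print("PR frontier (recall, precision, f | parameters):")
for p in frontier:
    print(f"  {p.recall:.2f}  {p.precision:.2f}  {p.f:.2f}  | "
          f"t={p.params['transition_prob']:g} n_discard={p.params['n_discard']} "
          f"q>={p.params['min_quality']:.0f}")

best = dc.max_recall_at_precision(all_points, 0.5)
print(f"\nmax recall at precision >= 50%: {best.recall:.2f} "
      f"(precision {best.precision:.2f})")
best_on = max(p.f for p in all_points if p.params["n_discard"] == 5)
best_off = max(p.f for p in all_points if p.params["n_discard"] == 0)
print(f"best f with SVD denoising: {best_on:.2f}; without: {best_off:.2f}")
print("(discarding the top singular vectors removes the shared batch bias)")
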