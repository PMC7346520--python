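"""Parameter recovery on a synthetic expert panel.

Simulates a study-sized panel (14 experts, lognormal judgment noise,
unit TFN spread) whose judgments are generated from a known ground-truth
priority vector, then scores how well each derivation method recovers it.
"""

from fanp.simulate import PanelSpec, recovery_experiment

spec = PanelSpec(
    ground_truth=(0.459, 0.370, 0.171),  # paradigm-level priorities
    n_experts=14,
    noise_sigma=0.2,
    fuzz_delta=1.0,
    seed=1,
)
res = recovery_experiment(spec, methods=("buckley", "eigenvector", "extent"))

print(f"ground truth: {spec.ground_truth}")
for method, est in res.methods.items():
    print(
        f"  {method:12s} estimate={[round(float(x), 3) for x in est]}"
        f"  MAE={res.mae[method]:.4f}  ranks match: {res.rank_exact[method]}"
    )
print(f"experts passing the CR < 0.1 gate: {res.cr_acceptance_rate:.0%}")
print(
    "MAE is the mean absolute error of the recovered weights; extent\n"
    "analysis can underweight (even zero out) the smallest element when the\n"
    "fuzzy extents separate, which is why it is not the default method."
)
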