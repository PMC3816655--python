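"""Rank candidate docking poses by predicted dG and score success rates.

Candidate poses of one complex are represented by their feature sets; the
model scores each and the pose with the lowest predicted dG is selected.
Success rates count how often the selected pose lies within an RMSD
threshold of the reference geometry (2 A is the usual "correct" cut).
"""

from diabind import (
    ModelParams, make_feature_dataset, predict_dg, rank_poses, success_rates,
)

poses = make_feature_dataset(seed=5, n=5, noise_sd=0.0)
params = ModelParams(alpha=0.05, beta=0.01, model_kind="simple")
order = rank_poses(poses, params)
print("rank  pose   predicted dG (kcal/mol)")
for rank, i in enumerate(order, start=1):
    print(f"{rank:>4}  {poses[i].complex_id}  {predict_dg(poses[i], params):8.3f}")

best_pose_rmsd = [0.8, 1.6, 2.3, 0.4, 3.1, 1.1]  # A, one per complex
thresholds = [1.0, 2.0, 3.0]
rates = success_rates(best_pose_rmsd, thresholds)
for t, f in zip(thresholds, rates):
    print(f"RMSD < {t:.0f} A: {100 * f:.1f}% of complexes")
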