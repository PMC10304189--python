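"""Run the full four-model comparison pipeline on a toy crystal.

On the hydrogen-fluoride chain fixture: extract and optimize the single
molecule, build and optimize the H-bonded repeating unit, cut the central
molecule back out, intercept the fragment, compute harmonic frequencies for
each, and score all four against pseudo-experimental peaks taken from the
full repeating-unit calculation (central-localized modes).
"""

import numpy as np

from vibrafrag import PipelineConfig, ToyCrystalSpec, make_toy_crystal, run_pipeline

cell, truth = make_toy_crystal(ToyCrystalSpec("hf_chain", reps=(5, 1, 1)))
cfg = PipelineConfig(hbond_criteria=truth.hbond_criteria)
report = run_pipeline(cfg, cell, truth=truth)

print(f"central molecule index: {report.central_index}")
print(f"pseudo-experimental peaks (cm⁻¹): {np.round(report.exp_peaks, 1)}\n")
print(f"{'model':14s} {'MAE':>8s} {'RMSE':>8s} {'n':>3s}")
for name, summary in report.summaries.items():
    d = summary.to_dict()
    print(f"{name:14s} {d['mae']:8.2f} {d['rmse']:8.2f} {d['n']:3d}")

print("\nThe fragment model keeps the central molecule's hydrogen-bond")
print("environment and reproduces the reference frequencies; the isolated")
print("single molecule misses the H-bond stiffening of the stretch, and the")
print("uniform 0.99 scaling over-corrects it.")
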