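"""Generate the synthetic study data: archetype trajectories and a rendered stack.

Writes under results/:
  - trajectories_truth.csv : 5 archetypes x 100 cells, noise_sd 0.02
  - stack.tif + stack_truth.csv : a 50-cell noiseless transient render
    for the image-based stages.
"""

from pathlib import Path

from ktrquant import synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

cfg = synth.SynthConfig(n_cells=100, noise_sd=0.02, seed=SEED)
table = synth.generate_trajectories(cfg)
table.to_csv(OUT / "trajectories_truth.csv", index=False)
print(f"trajectory table: {table.cell_id.nunique()} cells x "
      f"{table.timepoint.nunique()} time points "
      f"({sorted(table.truth_label.unique())})")

render_cfg = synth.SynthConfig(n_cells=50, noise_sd=0.0, amplitude_cv=0.2,
                               seed=SEED)
truth = synth.generate_trajectories(
    render_cfg, [synth.default_archetypes()["transient"]])
render = synth.render_timelapse(truth, seed=SEED)
synth.write_render(render, OUT / "stack.tif", OUT / "stack_truth.yaml")
truth.to_csv(OUT / "stack_truth.csv", index=False)
print(f"rendered stack: {render.stack.shape} (T, C, Y, X), "
      f"{render.centroids.shape[1]} cells, 12-bit max {render.stack.max()}")
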