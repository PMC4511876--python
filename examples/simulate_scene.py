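"""Render a synthetic two-color RCP scene and inspect its ground truth.

A "compact" scene models rolling-circle products condensed by a compaction
oligonucleotide (one tight spot each); a "dispersed" scene models regular
RCPs that may disintegrate into several nearby same-color sub-foci.
"""

import rcpquant as rq

config = rq.SceneConfig(mode="dispersed", n_spots_per_color=(50, 50),
                        image_shape=(384, 384), seed=1)
stacks, truth = rq.generate_scene(config)
paths = rq.write_scene("scratch/example_scene", stacks, truth, config)

subfoci_per_rcp = truth.table.groupby("rcp_id").size()
print(f"scene: {truth.n_rcps()} RCPs over {config.n_z} z-levels, "
      f"{stacks[0].shape[1]}x{stacks[0].shape[2]} px")
print(f"sub-foci per RCP: mean {subfoci_per_rcp.mean():.2f}, "
      f"max {subfoci_per_rcp.max()}")
print(f"written to {paths['truth'].parent}")
# Each dispersed RCP splits its fluorophore content across its sub-foci, so
# the per-spot brightness drops even though the total signal is conserved.
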