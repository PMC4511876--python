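"""Compare per-signal SNR between compact and dispersed renderings of the
same ground truth (same parent positions and amplitudes, same seed)."""

import numpy as np

import rcpquant as rq

geom = rq.DiskGeometry(3, 7)
results = {}
for mode in ("compact", "dispersed"):
    cfg = rq.SceneConfig(mode=mode, seed=4)
    stacks, _ = rq.generate_scene(cfg)
    pair = rq.project(stacks[0])
    thr = rq.mode_threshold(pair.corrected)
    objs = [o for o in rq.segment_signals(pair.corrected, thr.threshold)
            if o.area_px >= 4]
    kept = rq.filter_clusters(objs)  # drop clusters: area > 40 or circ < 0.5
    centers = [o.peak_location for o in kept]
    retained = rq.exclude_overlapping(centers, geom, kept,
                                      pair.corrected.shape)
    ms = [rq.measure_snr(pair.corrected, centers[j], geom)
          for j in retained]
    results[mode] = ms
    s = rq.summarize_intensity(ms)
    print(f"{mode:10s} n={s['n']:3d}  peak {s['peak_intensity']['mean']:6.1f} "
          f"(SD {s['peak_intensity']['sd']:5.1f})  "
          f"SNR {s['snr_db']['mean']:5.2f} dB (SD {s['snr_db']['sd']:4.2f})")

cmp = rq.compare_groups([m.snr_db for m in results["compact"]],
                        [m.snr_db for m in results["dispersed"]])
print(f"{cmp['test']}: p = {cmp['p_value']:.3g}")
# Compacted spots concentrate the same fluorophores in one blob, so both the
# peak intensity and the dB SNR exceed the dispersed rendering.
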