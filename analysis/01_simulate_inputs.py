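#!/usr/bin/env python
"""Generate every synthetic input consumed by the downstream analyses.

Writes tables under results/inputs/ (the MpIAA turnover fixture trace plus
flat controls, replicate ARF fold-change time courses, planted expression
tables, image ground truth) and the bulky image stacks themselves under
scratch/scenes/ (three replicate gemmae at four germination time points).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from napdyn import synthetic
from napdyn.params import load_mpiaa_decay

OUT = Path("results/inputs")
SCENES = Path("scratch/scenes")
SEED = 20260926

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    SCENES.mkdir(parents=True, exist_ok=True)

    # decay fixture and controls
    fx = load_mpiaa_decay()
    traces = {
        "mpiaa_1naa": synthetic.make_decay_trace(fx["half_life_min"], 30.0, 60,
                                                 0.02, seed=42, label="1-NAA"),
        "mpiaa_mg132": synthetic.make_decay_trace(np.inf, 30.0, 60, 0.02,
                                                  seed=SEED + 1, label="MG132"),
        "arf1_photostability": synthetic.make_decay_trace(np.inf, 30.0, 60, 0.02,
                                                          seed=SEED + 2,
                                                          label="ARF1 control"),
    }
    for name, tr in traces.items():
        pd.DataFrame({"time_min": tr.times, "value": tr.values,
                      "label": tr.label}).to_csv(OUT / f"trace_{name}.csv", index=False)
    print(f"wrote {len(traces)} decay traces (fixture half-life "
          f"{fx['half_life_min']} min + 2 flat controls)")

    # ARF fold-change time courses, 3 replicates
    fc, fc_truth = synthetic.make_arf_timecourse(n_replicates=3, rep_cv=0.1,
                                                 seed=SEED)
    fc.to_csv(OUT / "arf_foldchange.csv", index=False)
    fc_truth.to_csv(OUT / "arf_foldchange_truth.csv", index=False)
    print(f"wrote ARF fold-change table: {fc.arf.nunique()} ARFs x 3 replicates "
          f"x {fc.time_h.nunique()} time points")

    # double-knockin-style two-channel scenes: ARF1 (ch1) and ARF2 (ch2)
    # intensities follow the noise-free fold-change truth per time point
    shapes = {a: g.set_index("time_h").fc
              for a, g in fc_truth[fc_truth.replicate == 1].groupby("arf")}
    rng = np.random.default_rng(SEED)
    scene_rows = []
    for gemma in range(1, 4):
        for t in sorted(fc.time_h.unique()):
            scene = synthetic.random_scene(
                n_nuclei=10, seed=SEED + 97 * gemma + int(t),
                intensity_range=(1.0, 1.0))  # placeholder, overwritten below
            base = rng.uniform(15000, 30000, size=(scene.n_nuclei, 1))
            intensity = np.hstack([base * shapes["ARF1"].loc[t],
                                   base * rng.uniform(0.8, 1.2) * shapes["ARF2"].loc[t]])
            scene = synthetic.SyntheticScene(
                width=scene.width, height=scene.height, centroids=scene.centroids,
                radii=scene.radii, true_intensity=intensity,
                background_level=scene.background_level,
                channel_names=("ARF1-mScarlet-I", "ARF2-mNeonGreen"))
            stacks, truth = synthetic.make_image_stack(
                scene, synthetic.NoiseModel(read_noise_sd=1.0, shot_noise=True,
                                            multiplicative_cv=0.05),
                n_z=5, seed=SEED + 13 * gemma + int(t))
            np.savez_compressed(SCENES / f"scene_g{gemma}_t{t:04.1f}.npz", **stacks)
            scene_rows.append(truth.assign(gemma_id=f"g{gemma}", time_h=t))
    pd.concat(scene_rows).to_csv(OUT / "scene_ground_truth.csv", index=False)
    print(f"wrote {len(scene_rows)} image scenes (3 gemmae x 4 time points)")

    # independent planted expression tables for two contrasts (overlap between
    # their regulated sets arises only by chance)
    a, truth_a = synthetic.make_expression_table(4000, n_de_up=90, n_de_down=62,
                                                 n_low_count=300, seed=SEED)
    b, truth_b = synthetic.make_expression_table(4000, n_de_up=80, n_de_down=57,
                                                 n_low_count=300, seed=SEED + 1)
    a.assign(truth=truth_a.to_numpy()).to_csv(OUT / "expression_1h.csv", index=False)
    b.assign(truth=truth_b.to_numpy()).to_csv(OUT / "expression_3p5h.csv", index=False)
    print("wrote two planted expression tables (4000 genes each)")
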