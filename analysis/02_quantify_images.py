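#!/usr/bin/env python
"""Quantify nuclei in the simulated gemma scenes and check recovery.

Runs the full measurement chain (projection, log-scale Otsu segmentation,
label expansion, background-corrected integration) on every scene written by
01_simulate_inputs.py, reports recovery against ground truth, and writes the
per-nucleus table consumed by the stoichiometry analysis.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from napdyn import image_quant

IN_TRUTH = Path("results/inputs/scene_ground_truth.csv")
SCENES = Path("scratch/scenes")
OUT = Path("results")

if __name__ == "__main__":
    truth = pd.read_csv(IN_TRUTH)
    tables = []
    count_exact = True
    for npz in sorted(SCENES.glob("scene_*.npz")):
        _, gemma, t_tag = npz.stem.split("_")
        time_h = float(t_tag[1:])
        stacks = dict(np.load(npz))
        table, labels = image_quant.quantify_image(stacks, gemma_id=gemma,
                                                   time_h=time_h)
        n_true = truth[(truth.gemma_id == gemma)
                       & (truth.time_h == time_h)].nucleus_id.nunique()
        count_exact &= labels.max() == n_true
        tables.append(table)
    quant = pd.concat(tables, ignore_index=True)
    quant.to_csv(OUT / "nucleus_quantification.csv", index=False)

    # recovery of detectable (uncensored) signals vs rendered ground truth,
    # matched by nearest centroid
    errs = []
    for (gemma, t, ch), sub in quant.groupby(["gemma_id", "time_h", "channel"]):
        tt = truth[(truth.gemma_id == gemma) & (truth.time_h == t)
                   & (truth.channel == ch)].reset_index(drop=True)
        d = np.hypot(sub.centroid_row.to_numpy()[:, None] - tt.centroid_row.to_numpy(),
                     sub.centroid_col.to_numpy()[:, None] - tt.centroid_col.to_numpy())
        ref = tt.rendered_intensity.to_numpy()[d.argmin(axis=1)]
        keep = ~sub.censored.to_numpy()
        errs.extend((np.abs(sub.intensity.to_numpy() - ref)[keep] / ref[keep]).tolist())
    errs = np.array(errs)

    print(f"quantified {len(quant)} nucleus-channel measurements "
          f"across {quant.groupby(['gemma_id', 'time_h']).ngroups} images")
    print(f"nucleus counts exact in every image: {count_exact}")
    print(f"intensity recovery vs rendered truth (uncensored): median "
          f"{np.median(errs):.2%}; {np.mean(errs < 0.10):.0%} of measurements "
          f"within 10% (the tail is dim near-floor ARF2 signal at late times, "
          f"where background noise dominates the integral)")
    print(f"censored measurements (below detection floor): "
          f"{int(quant.censored.sum())} "
          f"(ARF2 channel at late times: "
          f"{int(quant[(quant.channel.str.contains('ARF2')) & (quant.time_h >= 12)].censored.sum())})")
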