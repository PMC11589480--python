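#!/usr/bin/env python
"""Predicted transcription of an auxin-regulated gene during germination.

Fits shape-preserving piecewise-cubic profiles to each replicate ARF
fold-change time course, drives the NAP competition model with them, and
contrasts normal ARF degradation against in-silico loss of ARF2 degradation
(ARF2 frozen at its dormant level).  Writes results/nap_scenarios.csv.
"""

from pathlib import Path

import pandas as pd

from napdyn import nap_model

OUT = Path("results")

if __name__ == "__main__":
    fc = pd.read_csv(OUT / "inputs" / "arf_foldchange.csv")
    params = nap_model.NAPParameters.defaults()
    profiles = nap_model.fit_arf_profiles(fc)
    reps = sorted({rep for (arf, rep) in profiles if arf == "ARF1"})

    results = []
    for rep in reps:
        for scenario in ("degradation_on", "arf2_degradation_off"):
            results.append(nap_model.simulate(params, profiles[("ARF1", rep)],
                                              profiles[("ARF2", rep)],
                                              scenario=scenario, replicate=rep))
    report = nap_model.scenario_report(results)
    report.to_csv(OUT / "nap_scenarios.csv", index=False)

    print(f"simulated {len(reps)} replicate ARF profiles x 2 scenarios "
          f"(auxin saturating; IAA half-life "
          f"{nap_model.iaa_effective_halflife(params, 1e9):.2f} min)")
    for rep, grp in report.groupby("replicate"):
        on, off = grp.degradation_on, grp.arf2_degradation_off
        print(f"replicate {rep}: output rises {on.iloc[-1] / on.iloc[0]:.2f}x "
              f"with degradation on; frozen-ARF2 trajectory stays within "
              f"{(off.max() - off.min()) / off.iloc[0]:.1%} of its initial "
              f"(near-basal) value; on >= off everywhere: "
              f"{bool((on >= off - 1e-12).all())}")
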