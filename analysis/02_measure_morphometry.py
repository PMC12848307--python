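"""Vessel and cell morphometry + strain decomposition.

Reads the synthetic imaging tables from results/synth/, measures vessel
diameters from the wall-peak profiles (averaging the replicates as in
the >=3-measurements-per-vessel protocol), then decomposes the vessel
strain between consecutive stages into cell-deformation and cell-number
strain on both axes, and labels the mechanism per axis.

Writes results/diameters.csv, results/strains.csv.
Usage: python analysis/02_measure_morphometry.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from vesselmech.morphometrics import (
    IntensityProfile,
    diameter_from_profile,
    mean_diameter,
)
from vesselmech.strain import (
    decompose_interval,
    label_mechanism,
    strains_to_frame,
    summarize_group,
)


def main(indir="results/synth", out="results"):
    indir, out = Path(indir), Path(out)
    out.mkdir(parents=True, exist_ok=True)

    profiles = pd.read_csv(indir / "profiles.csv")
    ests = []
    for k, df in profiles.groupby("replicate"):
        pos = df.position_um.to_numpy()
        prof = IntensityProfile(pos, df.intensity.to_numpy(),
                                float(np.median(np.diff(pos))))
        ests.append(diameter_from_profile(prof))
    avg = mean_diameter(ests)
    pd.DataFrame([dict(replicate=i, diameter_um=e.diameter)
                  for i, e in enumerate(ests)] +
                 [dict(replicate="mean", diameter_um=avg.diameter)]).to_csv(
        out / "diameters.csv", index=False)
    print(f"diameter: {avg.diameter:.3f} um "
          f"(mean of {avg.n_profiles_averaged} profiles)")

    vessels = pd.read_csv(indir / "vessels.csv")
    cells = pd.read_csv(indir / "cells.csv")
    tps = list(dict.fromkeys(vessels.timepoint))
    intervals = []
    for t1, t2 in zip(tps, tps[1:]):
        s = decompose_interval(summarize_group(vessels, cells, t1),
                               summarize_group(vessels, cells, t2))
        intervals.append(s)
        lab = label_mechanism(s)
        print(f"{t1}->{t2}: radial vessel strain {s.eps_vessel_radial:+.3f} "
              f"({lab['radial']['vessel']}; cell {lab['radial']['cell']}, "
              f"number {lab['radial']['number']}), axial "
              f"{s.eps_vessel_axial:+.3f} ({lab['axial']['vessel']})")
    table = strains_to_frame(intervals)
    table.to_csv(out / "strains.csv", index=False)

    truth = json.loads((indir / "true_strains.json").read_text())
    err = max(abs(g.eps_vessel_radial - t["eps_vessel_radial"])
              for g, t in zip(intervals, truth))
    print(f"max |radial vessel-strain error| vs ground truth: {err:.4f}")
    return table


if __name__ == "__main__":
    main()
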