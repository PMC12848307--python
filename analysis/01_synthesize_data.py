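"""Generate the synthetic study inputs.

Emulates the imaging-derived datasets the measurement pipeline consumes:
per-cell shape tables and per-vessel geometry across 2/3/4 dpf with
prescribed constriction/elongation trajectories, wall-peak intensity
profiles, post-ablation kymographs, width/alignment-style lagged series,
and oriented actin textures.  Ground truth is saved next to each dataset
so downstream scripts can score recovery.

Writes results/synth/.  Usage: python analysis/01_synthesize_data.py [--seed N]
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from vesselmech.synthetic import (
    CellTrajectorySpec,
    KymographSpec,
    LaggedSeriesSpec,
    TextureSpec,
    WallProfileSpec,
    gen_cell_shape_table,
    gen_kymograph,
    gen_lagged_series,
    gen_oriented_texture,
    gen_wall_profile,
)


def main(seed: int = 0, out: str = "results/synth") -> Path:
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    def sub(n=2**31 - 1):
        return int(rng.integers(n))

    # cell shape + vessel geometry trajectories (constriction + elongation)
    cells, vessels, truth = gen_cell_shape_table(CellTrajectorySpec(seed=sub()))
    cells.to_csv(outdir / "cells.csv", index=False)
    vessels.to_csv(outdir / "vessels.csv", index=False)
    (outdir / "true_strains.json").write_text(json.dumps(
        [dataclasses.asdict(t) for t in truth], indent=2))

    # wall-peak diameter profiles: 5 noisy replicates of one vessel
    profiles = []
    for k in range(5):
        spec = WallProfileSpec(wall_centers=(3.0, 9.0), wall_halfwidth=0.3,
                               noise_sd=0.02, seed=sub())
        profile, true_d = gen_wall_profile(spec)
        df = pd.DataFrame(dict(position_um=profile.positions,
                               intensity=profile.intensities))
        df["replicate"] = k
        profiles.append(df)
    pd.concat(profiles).to_csv(outdir / "profiles.csv", index=False)

    # ablation kymographs at three tension levels (recoil velocities,
    # emulating circumferential > mesh ~ longitudinal)
    kymo_truth = {}
    for name, v in [("circumferential", 0.5), ("mesh", 0.2),
                    ("longitudinal", 0.18)]:
        kym, gaps = gen_kymograph(KymographSpec(true_velocity=v,
                                                noise_sd=0.05, seed=sub()))
        tifffile.imwrite(outdir / f"kymograph_{name}.tif",
                         kym.matrix.astype(np.float32))
        kymo_truth[name] = dict(true_velocity=v, pixel_size=kym.pixel_size,
                                frame_interval=kym.frame_interval,
                                ablation_frame=kym.ablation_frame)

    # lagged width/alignment-style series (negative correlation, 2.5 min lag)
    lag_spec = LaggedSeriesSpec(n_frames=240, frame_interval=0.25,
                                true_lag=2.5, correlation_sign="negative",
                                noise_sd=0.1, seed=sub())
    t, a, b = gen_lagged_series(lag_spec)
    pd.DataFrame(dict(t_min=t, alignment=a, width=b)).to_csv(
        outdir / "lagged_series.csv", index=False)

    # oriented textures, one per class
    tex_truth = {}
    for label in ("C", "M", "L"):
        img = gen_oriented_texture(TextureSpec(label=label, noise_sd=0.05,
                                               angle_jitter_sd=4.0, seed=sub()))
        tifffile.imwrite(outdir / f"texture_{label}.tif",
                         img.astype(np.float32))
        tex_truth[label] = label

    (outdir / "ground_truth.json").write_text(json.dumps(dict(
        seed=seed, kymographs=kymo_truth,
        lagged_series=dict(true_lag_min=lag_spec.true_lag, sign="negative"),
        textures=tex_truth), indent=2))
    print(f"synthetic study inputs written to {outdir}/")
    return outdir


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/synth")
    a = ap.parse_args()
    main(a.seed, a.out)
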