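"""Post-processing of the deformable-membrane runs.

For each trajectory written by 04_simulate_cortex.py: detects bundle
episodes (sustained elevation of normalised circumferential alignment in
the central band), compares stress anisotropy inside vs outside
episodes, and estimates the lag between central alignment and vessel
width by cross-correlation of the detrended series — the constriction
mechanism predicts a negative correlation with alignment leading.

Writes results/sim/run_summaries.csv.
Usage: python analysis/05_analyze_simulation.py
"""

from pathlib import Path

import pandas as pd

from vesselmech.cortex import load_params
from vesselmech.cortex.run import TrajectoryRecord
from vesselmech.sim_analysis import summarize_run


def main(indir="results/sim", out="results/sim"):
    indir, out = Path(indir), Path(out)
    rows = []
    for traj in sorted(indir.glob("deformable_seed*.csv")):
        if "_params" in traj.name:
            continue
        params = load_params(traj.with_name(traj.stem + "_params.json"))
        rec = TrajectoryRecord.from_frame(pd.read_csv(traj), params)
        s = summarize_run(rec, max_lag=600.0)
        s["run"] = traj.stem
        rows.append(s)
        print(f"{traj.stem}: {s['n_episodes']} episodes, min width "
              f"{s['min_width']:.3f} um, lag {s['lag'] / 60.0:+.2f} min "
              f"(corr {s['lag_correlation']:+.2f})")
    if not rows:
        print("no deformable runs found; run 04_simulate_cortex.py first")
        return None
    summaries = pd.DataFrame(rows)
    summaries.to_csv(out / "run_summaries.csv", index=False)
    neg = (summaries.lag_correlation < 0) & (summaries.lag > 0)
    print(f"{int(neg.sum())}/{len(summaries)} runs show negative correlation "
          f"with alignment leading width")
    return summaries


if __name__ == "__main__":
    main()
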