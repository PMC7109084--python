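#!/usr/bin/env python
"""Groove-pocket collapse along a synthetic breathing trajectory.

Emulates the apo-form behaviour: the portal aperture relaxes from its
crystal-like open value (14.3 Å) toward a collapsed value (11.9 Å), and the
inter-helix groove pocket shrinks with it. Tracks per-frame pocket volume
(raw and Savitzky-Golay smoothed) and the persistence of pocket voxels as
occupancy shells. Writes CSV tables and an occupancy OpenDX map.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from groovescope.electrostatics import ScalarGrid, write_dx
from groovescope.pocket_dynamics import (PocketConfig, occupancy_grid,
                                         occupancy_shell, savitzky_golay,
                                         volume_trace)
from groovescope.structure_io import align_frames
from groovescope.synthetic_data import make_breathing_trajectory, make_portal_scaffold

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_FRAMES = 120  # desk-scale stand-in for the 2,500-frame production runs


def main() -> None:
    OUT.mkdir(exist_ok=True)
    scaffold = make_portal_scaffold(14.3)
    traj = make_breathing_trajectory(scaffold, d0=14.3, d_inf=11.9, tau=30.0,
                                     noise_sd=0.2, n_frames=N_FRAMES, seed=SEED)
    traj = align_frames(traj, scaffold.select_indices(chain="S", names=("CA",)))
    cfg = PocketConfig(spacing=1.0)
    ts = volume_trace(traj, cfg, site=np.array([0.0, 0.0, 4.0]))
    smooth = savitzky_golay(ts, window=31, order=3)
    pd.DataFrame({"frame": np.arange(N_FRAMES), "time_ns": ts.time,
                  "volume_A3": ts.values, "volume_smoothed_A3": smooth.values}
                 ).to_csv(OUT / "pocket_volume_trace.csv", index=False)
    print(f"groove pocket volume: first 10-frame mean {ts.values[:10].mean():.0f} Å³, "
          f"last 10-frame mean {ts.values[-10:].mean():.0f} Å³ "
          f"(collapse tracks the 14.3 -> 11.9 Å aperture relaxation)")

    og = occupancy_grid(traj, cfg)
    shells = [(0.0, 0.6), (0.6, 0.8), (0.8, 1.0)]
    rows = [{"shell": f"{lo}-{hi}", "volume_A3": occupancy_shell(og, lo, hi)[1]}
            for lo, hi in shells]
    pd.DataFrame(rows).to_csv(OUT / "occupancy_shells.csv", index=False)
    grid = ScalarGrid(og.lattice.origin, np.full(3, og.lattice.spacing),
                      og.occupancy.astype(float), units="occupancy")
    (OUT / "occupancy.dx").write_text(write_dx(grid, comment="pocket occupancy"))
    for r in rows:
        print(f"occupancy {r['shell']}: {r['volume_A3']:.0f} Å³")
    print("High-occupancy (0.8-1.0) voxels mark the persistently enclosed core "
          "of the groove; transient voxels populate the lower shells.")


if __name__ == "__main__":
    main()
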