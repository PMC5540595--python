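"""Do players walk geodesics between gallery saves?

Compares shortest-to-actual path-length ratios between exploration and
exploitation phases (the optimal-foraging prediction is direct travel while
harvesting a patch and meandering travel between patches).  Writes
results/path_ratios.json.
"""

import argparse
import json
from pathlib import Path

from creative_foraging.game_log import read_logs
from creative_foraging.phase_metrics import path_ratio_summary
from creative_foraging.segmentation import segment
from creative_foraging.shape_space import MoveGraph


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--n", type=int, default=10)
    args = parser.parse_args()

    logs = read_logs(args.cohort / "logs.csv")
    segmentations = [segment(log) for log in logs]
    graph = MoveGraph.lazy(args.n)
    summary = path_ratio_summary(logs, segmentations, graph)

    for kind in ("exploration", "exploitation"):
        s = summary[kind]
        print(f"{kind}: median over players of the per-player median ratio = "
              f"{s['player_median']:.2f}  (pooled {s['pooled_median']:.2f}, "
              f"{s['n_pairs']} save pairs)")
    mw = summary["mann_whitney"]
    print(f"Mann-Whitney on per-player medians: U={mw['U']:.0f}, "
          f"p={mw['p']:.2g}, rank-biserial effect={mw['effect']:.2f}")

    with open(args.out / "path_ratios.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"wrote {args.out / 'path_ratios.json'}")


if __name__ == "__main__":
    main()
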