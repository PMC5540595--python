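"""Simulate the study-scale synthetic cohort.

100 players, 15-minute games on the full ten-square move graph, 14 planted
shape categories, shared per-player tempo — the conditions every later
analysis script consumes.  Writes logs.csv, truth.json and categories.json
under results/cohort/.
"""

import argparse
import json
import time
from pathlib import Path

from creative_foraging.game_log import validate_log, write_logs
from creative_foraging.shape_space import MoveGraph
from creative_foraging.synthetic_data import SimParams, simulate_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    params = SimParams()
    graph = MoveGraph.lazy(params.n)
    print(f"shape space ready ({graph.number_of_nodes()} shapes, "
          f"{time.perf_counter() - t0:.0f}s)")

    logs, truths, categories = simulate_cohort(graph, params, seed=args.seed)
    n_saves = sum(len(l.gallery_shapes()) for l in logs) / len(logs)
    n_moves = sum(len(l.move_times()) for l in logs) / len(logs)
    print(f"simulated {len(logs)} games: {n_moves:.0f} moves and "
          f"{n_saves:.0f} gallery saves per game on average "
          f"({time.perf_counter() - t0:.0f}s)")

    bad = sum(1 for log in logs
              if any(v.severity == "error" for v in validate_log(log, graph)))
    print(f"validation: {len(logs) - bad}/{len(logs)} logs clean")

    write_logs(logs, args.out / "logs.csv")
    with open(args.out / "truth.json", "w") as fh:
        json.dump([
            {"player_id": t.player_id,
             "tempo_exploration": t.tempo_exploration,
             "tempo_exploitation": t.tempo_exploitation,
             "phases": [{"kind": p.kind,
                         "gallery_indices": [p.gallery_start, p.gallery_end],
                         "t_start": p.t_start, "t_end": p.t_end,
                         "transition_index": p.transition_index,
                         "category_id": p.category_id} for p in t.phases]}
            for t in truths], fh, indent=1, sort_keys=True)
    with open(args.out / "categories.json", "w") as fh:
        json.dump({str(i): sorted(sh.to_string() for sh in cat)
                   for i, cat in enumerate(categories)}, fh, indent=1)
    print(f"wrote cohort to {args.out}")


if __name__ == "__main__":
    main()
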