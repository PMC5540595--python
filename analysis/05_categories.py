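"""Shape categories from the patch-overlap network, and what they imply.

Builds the network of exploitation patches (edge = two shared shapes),
detects categories with Girvan–Newman at maximum modularity, then measures
patch depletion (per-visit coverage, departure distance), the interleaved
geometry of categories (within/between distances, k-step same-category
ratio), transition-shape ambiguity, and the road-not-taken share.
Writes results/categories.json and results/categories_summary.json.
"""

import argparse
import json
from pathlib import Path

from creative_foraging import category_analysis as ca
from creative_foraging.game_log import read_logs
from creative_foraging.segmentation import segment
from creative_foraging.shape_space import MoveGraph


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--n", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-boot", type=int, default=10_000)
    parser.add_argument("--max-pairs", type=int, default=20_000)
    parser.add_argument("--gn-patience", type=int, default=200)
    args = parser.parse_args()

    logs = read_logs(args.cohort / "logs.csv")
    segmentations = [segment(log) for log in logs]
    graph = MoveGraph.lazy(args.n)

    patches = ca.extract_patches(segmentations, logs)
    network = ca.build_patch_network(patches)
    partition = ca.detect_categories(network, patience=args.gn_patience)
    n_shapes = len({sh for cat in partition.categories for sh in cat})
    print(f"{len(patches)} patches; giant component "
          f"{len(partition.giant_component)} patches, "
          f"{partition.n_components - 1} smaller components")
    print(f"{len(partition.categories)} categories aggregating {n_shapes} shapes "
          f"(modularity {partition.modularity:.2f})")

    summary = {"n_patches": len(patches),
               "giant_component_patches": len(partition.giant_component),
               "n_components": partition.n_components,
               "n_categories": len(partition.categories),
               "n_category_shapes": n_shapes,
               "modularity": partition.modularity}

    summary["depletion"] = ca.depletion_summary(patches, partition, graph)
    print(f"per-visit coverage of a category: "
          f"{100 * summary['depletion']['mean_coverage']:.1f}% on average; "
          f"nearest unharvested category shape at departure: "
          f"{summary['depletion']['mean_departure_distance']:.2f} moves")

    inter = ca.interleaving_stats(partition.categories, graph,
                                  max_pairs=args.max_pairs, seed=args.seed)
    summary["interleaving"] = {k: v for k, v in inter.items()
                               if not k.endswith("distances") and k != "k_step_ratios"}
    print(f"geodesics within categories: median {inter['within_median']}; "
          f"between categories: median {inter['between_median']}; "
          f"k-step same:other category ratio: median "
          f"{inter['k_step_ratio_median']:.2f}")

    summary["transition_ambiguity"] = ca.transition_ambiguity(
        segmentations, partition, logs, n_boot=args.n_boot, seed=args.seed)
    ta = summary["transition_ambiguity"]
    print(f"ambiguous-shape share: {100 * ta['transition_share']:.0f}% of "
          f"transition saves vs {100 * ta['nontransition_share']:.0f}% of other "
          "exploitation saves")

    rnt = ca.road_not_taken(logs, segmentations)
    summary["road_not_taken"] = {k: v for k, v in rnt.items() if k != "per_shape"}
    print(f"share of visits to a transition shape that start an exploitation "
          f"phase: {100 * rnt['mean_fraction']:.0f}% (the rest are roads not "
          f"taken; {rnt['n_transition_shapes']} transition shapes)")

    with open(args.out / "categories.json", "w") as fh:
        json.dump({str(i): sorted(sh.to_string() for sh in cat)
                   for i, cat in enumerate(partition.categories)}, fh, indent=1)
    with open(args.out / "categories_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"wrote {args.out / 'categories_summary.json'}")


if __name__ == "__main__":
    main()
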