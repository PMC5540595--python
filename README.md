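# creative-foraging

Analysis toolkit for **creative foraging**: how people explore a large but
fully enumerable space of visual shapes, discover categories of
"interesting and beautiful" solutions, exploit them, and move on.  In the
underlying game paradigm players rearrange ten squares one legal move at a
time (slide one square to any empty cell edge-adjacent to the rest, keeping
all squares edge-connected) and save shapes they like to a gallery.  The
space of ten-square shapes — fixed decominoes, identified up to translation
— has exactly **36,446** members, so every intermediate step of a creative
search lives in a well-defined metric space where shortest paths can be
computed.

The package is aimed at researchers in cognitive/behavioural science who
want to analyze such game telemetry or to study the analysis pipeline
itself on ground-truthed synthetic cohorts.  It provides:

* `shape_space` — census enumeration, the legal-move graph, BFS geodesics
  (lazy, memoized adjacency for the 36,446-node decomino graph);
* `game_log` — CSV/JSONL log I/O and rule validation;
* `segmentation` — the two-pass gap-run algorithm labelling gallery saves
  into *exploration* (slowing saves) and *exploitation* (accelerating
  bursts) phases: maximal strictly-decreasing stretches of inter-save gaps
  Δₖ, merged when an earlier stretch's peak gap exceeds the later one's;
* `phase_metrics` — phase-characteristic medians with player-bootstrap
  CIs, geodesic-to-actual path ratios (1 = optimal travel), Mann-Whitney U
  with rank-biserial effect, Spearman strategy correlations, and the
  fluency/originality/composite creativity scores;
* `category_analysis` — the patch-overlap network (patches = shapes saved
  in one exploitation phase; edge = ≥ 2 shared shapes), Girvan-Newman
  communities cut at maximum modularity, patch-depletion statistics,
  category interleaving, transition-shape ambiguity, and the
  road-not-taken share;
* `synthetic_data` — a cohort simulator with planted phases, categories,
  and individual-difference correlations, providing exact ground truth for
  every downstream stage;
* `pipeline` / a `creative-foraging` CLI — orchestration with caching,
  YAML configs and deterministic, machine-readable reports.

## Worked example

Simulate a small cohort on the 6-square toy space (216 shapes), segment it,
and print the exploration/exploitation path-ratio contrast:

```python
from creative_foraging import MoveGraph, SimParams, simulate_cohort, segment
from creative_foraging.phase_metrics import path_ratio_summary

graph = MoveGraph.build(6)
params = SimParams(n_players=12, n=6, n_categories=3, category_size=12,
                   category_radius=3)
logs, truths, categories = simulate_cohort(graph, params, seed=202)
segs = [segment(log) for log in logs]
summary = path_ratio_summary(logs, segs, graph)
for kind in ("exploration", "exploitation"):
    print(kind, round(summary[kind]["player_median"], 2))
```

```
exploration 0.4
exploitation 1.0
```

Exploration meanders (actual paths ~2.5× the geodesic), exploitation
harvests along exact shortest paths — the simulator's geodesic policy by
construction, and the qualitative contrast the analysis measures on real
logs.

## The full analysis

Numbered drivers under `analysis/` run the study-scale pipeline (100
players, 15-minute games, the full decomino space) and write their tables
under `results/`:

```bash
python analysis/01_enumerate_space.py            # census 1..10 squares
python analysis/02_simulate_cohort.py --seed 42  # the synthetic cohort
python analysis/03_segmentation.py               # phases + Table-1-style medians
python analysis/04_path_optimality.py            # geodesic ratios + MW test
python analysis/05_categories.py                 # patch network, categories, ...
python analysis/06_individual_differences.py     # strategy correlation, scores
```

Headline output of a run with `--seed 42` (all regenerable; later scripts
read `results/cohort/` written by script 02):

```
n=10:  36446 shapes
reachability closure from the 10-line: 36446 shapes (matches the census)
median phase pairs per game: 7 (range 2-26)
planted-boundary recovery F1: 0.995
exploration: median over players of the per-player median ratio = 0.50
exploitation: median over players of the per-player median ratio = 1.00
Mann-Whitney on per-player medians: U=100, p=1.7e-37, rank-biserial effect=0.98
exploration vs exploitation duration: rho=0.92 95% CI [0.86,0.95] p=0.0001
planted duration correlation (ground truth): 0.92
per-visit coverage of a category: 20.0% on average; nearest unharvested
  category shape at departure: 1.04 moves
```

The cohort shows the study's qualitative fingerprint: ~7 alternating phase
pairs per game, near-optimal travel only while exploiting, a strong
fast-vs-thorough strategy continuum recovered exactly from the planted
tempo, and patch departure long before categories are depleted.  Values on
the original human dataset require that dataset; an ingestion dialect for
per-player CSV/JSONL logs is documented in `creative_foraging.game_log`.

See `docs/methods.md` for the model, conventions, parameter defaults and
their rationale, and known limitations.

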