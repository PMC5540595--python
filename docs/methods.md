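# Methods

## The shape space

A shape is a set of *n* unit squares on the integer grid, connected
edge-to-edge; diagonal contact does not connect.  Shapes are identified up
to translation only — rotated or mirrored shapes are distinct — which makes
the space the census of *fixed polyominoes*.  Canonical form translates the
cell set so `min(row) = min(col) = 0` and sorts cells by `(row, col)`; the
sorted tuple is the hash key, the tie-break order, and the file encoding
(`"r,c;r,c;..."`).  For the game's *n* = 10 the census has 36,446 shapes.

Enumeration grows (k+1)-square shapes from k-square shapes by attaching one
square to any boundary cell and deduplicating canonical forms; every
polyomino has at least one non-cut square, so the growth closure is the full
census (~1 s at *n* = 10 in pure Python).

A *legal move* picks up one square whose removal leaves the remaining
squares edge-connected and drops it on any empty cell edge-adjacent to that
remainder (pick-up-and-place semantics: the intermediate 9-square state must
be connected).  Placements that reproduce a translate of the input are not
moves.  The relation is symmetric, and the resulting move graph is a single
connected component for every *n* up to 10 — verified by closing the move
relation from the starting line, which reproduces the census exactly.

Distances are unweighted BFS geodesics.  The graph object supports a fully
materialized mode (used for small-*n* exhaustive tests, with a gzip text
cache keyed by an n-dependent checksum) and a lazy mode that memoizes
neighbour lists on demand — on the decomino graph most analyses touch a
small working set, so lazy mode avoids the ~40-neighbour × 36,446-node
build.  Distance queries use bidirectional level-synchronous BFS; path
queries break ties by the canonical shape order, so results are
reproducible run to run.

## Game logs

A log is the ordered event list of one game: at each event the time (s), the
current shape, and whether the player saved it to the gallery.  A *move* is
defined operationally as an event whose shape differs from the previous
event's shape; a save re-records the current shape with the gallery flag, so
sources that log saves as separate rows and sources that flag a move-event
both parse identically.  Validation enforces: the first event is the
horizontal n-line at t = 0, times are non-decreasing and within the game
duration, shapes are connected n-square sets, and consecutive distinct
shapes differ by exactly one legal move.  Two saves at the same instant are
flagged as a warning, not an error.

## Segmentation

The input is the series of gaps Δₖ between consecutive gallery saves.  Two
passes:

1. **Decreasing runs.**  Maximal stretches of at least two strictly
   decreasing gaps become candidate exploitation phases.  Equal gaps
   terminate a stretch (strict monotonicity avoids unbounded flat runs).
2. **De-fragmentation merge.**  Two candidates are adjacent when the second
   starts at the gap immediately after the first ends; they merge when the
   earlier candidate's largest gap exceeds the later one's largest gap.
   Merging cascades left-to-right to a fixed point.  This repairs phases
   split by a single long pause.

A run over gaps Δₖ..Δⱼ labels gallery events k−1..j as one exploitation
phase.  Its first event — the *transition shape* — is the event before the
phase's largest gap; the gap *into* that event belongs to the preceding
exploration.  All remaining gallery events are exploration.  Conventions:
an exploitation phase spans its transition save to its last save; an
exploration phase starts where the previous phase ended (game start for the
first) and ends at the next transition save, so it owns the inter-phase
move stream.  Phase move counts tally shape-changing events in
`(t_start, t_end]`.

Corner case: two unmerged runs can abut, and the run-to-events mapping then
assigns one gallery event to both.  The contested event stays with the
earlier phase and the later phase starts at its next event; this is the one
place an exploitation phase can hold only two saves.

## Phase statistics

* Phase-characteristic tables pool phases across players and report medians
  with 95% percentile confidence intervals from bootstrap over *players*
  (10,000 replicates by default) — resampling players, not phases, respects
  the within-player dependence.
* Path optimality: for each pair of consecutive saves inside one phase,
  `ratio = geodesic distance / number of moves between the saves`; 1 means
  the player walked a shortest path.  Pairs that straddle a phase boundary,
  repeat a shape (distance 0), or contain no move are excluded.  The
  headline statistic is the median over players of each player's median
  ratio, compared between phase kinds with a two-sided Mann-Whitney U and
  the rank-biserial effect size |1 − 2U/(n₁n₂)|.
* Strategy continuum: Spearman correlation across players of mean
  exploration vs mean exploitation phase duration (and move count), with a
  player-bootstrap CI and a permutation p-value.  Degenerate inputs
  (constant columns, fewer than three players) raise instead of returning
  an undefined coefficient.
* Creativity scores: fluency is the number of exploitation-phase saves;
  originality is the mean rarity 1 − f of those shapes, where f is the
  fraction of reference players who ever saved the shape; the composite
  averages the within-cohort z-scores of the two (population SD; a
  zero-variance measure z-scores to 0).

## Categories

Every exploitation phase contributes a *patch* (its saved shapes,
deduplicated).  Patches are nodes of an undirected network with an edge
whenever two patches share at least two shapes (built via an inverted
shape→patch index, so construction is linear in total patch content).
Categories are the communities of the giant component under Girvan-Newman
edge-betweenness removal, cutting the dendrogram at maximum Newman-Girvan
modularity.  The one-community partition (modularity 0) is the baseline, so
structureless networks stay whole.  Determinism: betweenness ties resolve
by edge serialization order, and only strictly higher modularity replaces
the incumbent partition.

Maximum modularity along the GN dendrogram equals exhaustive-partition
modularity maximization on small block-structured graphs (verified by
enumerating all partitions up to 8 nodes), but not for arbitrary graphs —
the 8-cycle's optimal 3-arc partition never appears in its dendrogram.  For
large networks an optional *patience* parameter stops the descent after a
fixed number of levels without improvement (200 in the analysis scripts);
modularity along the dendrogram is near-unimodal in practice, and the full
descent is quadratic in edges.

A shape may belong to several categories through patches in different
communities; such shapes are *ambiguous*.  Downstream statistics:

* per-visit coverage |patch ∩ category| / |category| and the geodesic
  distance from a patch's last save to the nearest unharvested category
  member (patch-depletion tests);
* within- vs between-category geodesic distributions over categorized
  shape pairs (subsampled to a pair budget on large cohorts) and, per shape
  and step budget K = 1..5, the ratio of same-category to other-category
  shapes within K moves (one BFS ball at K_max per shape serves all K);
* the ambiguous share among transition saves vs other exploitation saves
  (occurrence-level, restricted to categorized shapes, player-bootstrap
  CIs);
* the road-not-taken share: per transition shape, the fraction of players
  who visited it anywhere in their trajectory and started an exploitation
  phase there.

## The synthetic cohort generator

The generator is a test harness that reproduces the statistical signatures
of real games — it is not a cognitive model.  Defaults emulate the original
study's conditions: 100 players, 900-second games on the ten-square space,
~3 s per move, and alternating phases whose save gaps slow down during
exploration and accelerate during exploitation.

**Timing grammar.**  Per phase pair, gaps follow geometric ladders planned
directly in tempo-scaled seconds: exploration gaps grow by `gap_growth`
(default 1.5) from a base pace (`gap_base`, 12 s × the player's tempo); the
gap into the transition save continues the growth; the exploitation burst
opens one growth factor above the deepest possible exploration peak and
shrinks geometrically to `gap_decay` (default 0.07) of its opening gap.
These inequalities make the planted transition save the anchor of a strictly
decreasing gap run — precisely the segmentation's signature — for every
tempo combination, so planted boundaries are recoverable exactly without
timing noise and with F1 ≈ 1 under the default 10% multiplicative
log-normal gap jitter.  A phase pair is only started if its whole ladder
fits in the remaining game time.

**Movement.**  Exploration walks are uniform non-backtracking random walks
with one move per `move_seconds` of the gap, saving wherever the walk
stands.  The transition save targets a nearest unharvested member of any
planted category (ties broken by the player's RNG, so different players
enter a category through different doors).  Exploitation visits
nearest-unvisited members of the entered category, along exact geodesics
(`exploit_policy="geodesic"`, giving path ratios of exactly 1) or an
ε-greedy meander.  Moves are spread evenly inside each gap.

**Planted categories** are BFS balls around random seed shapes, thinned
nearest-first to a fixed size with cores disjoint; a configurable fraction
of each category is copied into the next one, creating the planted
ambiguous shapes (defaults: 14 categories of 40 shapes, radius 4, 10%
overlap).

**Individual differences.**  Each player draws a log-normal tempo
(σ = 0.4) that multiplies all their gaps; the exploitation save count also
scales with the exploitation tempo, so slow-to-discover players are also
thorough harvesters.  With a shared tempo this plants a strong positive
across-player correlation between exploration and exploitation effort
(duration and move count), recovered by the estimator to within ~0.02.
With independent per-kind tempos most of the correlation vanishes; a small
residual (|ρ| ≲ 0.25) remains because a very slow explorer's peak gap still
forces a higher burst opening — a structural property of the decreasing-run
grammar, reported faithfully by the ground-truth oracle
`planted_strategy_rho`.  The generator's true zero-correlation condition is
`tempo_sigma = 0`, under which measured |ρ| stays within sampling noise of
zero (median ≈ 0.05 over replicate 100-player cohorts).

**What the defaults reproduce and what they do not.**  Simulated games show
a median of ~7 phase pairs and ~40 gallery saves per 900 s (the study's
orders), and ~3 s per move during exploration.  Per-game move counts
(~120-130) undershoot real games (~300) because burst travel is geodesic —
a deliberate trade for the exact path-ratio contract; consequently
exploitation seconds-per-move is inflated.  Passing tests on synthetic
cohorts therefore demonstrate the correctness of the pipeline's mechanics
and its parameter recovery, not the reproduction of human behavioural
values; the statistics printed for the deposited human dataset require that
dataset.

## Problem sizes and numerical choices

Exhaustive structural tests run on the 4-6-square spaces (19/63/216
shapes), which share every invariant with the decomino space; cohort-level
tests use 10-100 simulated players on the 5-6-square spaces, where a cohort
simulates in under a second.  The census and move-graph checks run on the
full ten-square space.  Bootstrap and permutation replicates default to
10,000 in the analysis scripts and are reduced (100-400) in tests, where
only the machinery is under test.  All randomness flows from explicit
seeds through `numpy` `SeedSequence` spawning — per-player streams derive
from (cohort seed, player index) — and every tie-break in graph search,
community detection and serialization is deterministic, so identical
configurations reproduce byte-identical outputs.

## Known limitations

* The deposited human data's file schema is undocumented here; `read_logs`
  defines a canonical CSV/JSONL dialect and an adapter for the original
  export remains an extension point.
* Girvan-Newman is quadratic-ish in network edges; very large cohorts need
  the patience cap (or a different community algorithm, out of scope).
* The simulator's meander policy bounds its detours, so extreme path
  tortuosity (ratios ≪ 0.1) is not generated.
* With abutting exploitation bursts the contested save's assignment is a
  convention; no downstream statistic depends on it beyond one save.
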