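# Methods

## Model

A problem domain is an undirected, connected, simple graph: vertices are
discrete states, edges are atomic actions (transitions are deterministic
and fully reversible, so one undirected edge stands for both directed
moves).  The task ensemble is the set of all ordered start–goal
shortest-path problems in the graph, faced in an unpredictable order; the
target data are the concatenated state–action pairs of the solution
trajectories, delimited by task-boundary markers that carry no probability
content.

A candidate hierarchy is a partition of the vertices into connected
regions.  Region interfaces follow the entrance/exit convention:
*entrances* are vertices inside the region with at least one neighbor
outside; *exits* are vertices outside that receive at least one edge from
inside.  Each region induces one option per exit: initiation set = the
region's entrances plus the current task's start state, policy domain = the
region's vertices, action set = atomic actions only (hierarchies are two
levels deep), termination set = the region's exits, with one designated
exit as the option's subgoal.  The main-text convention that an option
terminates only at its single subgoal and the region-interface convention
that it terminates at any exit coincide for the deterministic
shortest-path-to-subgoal policies used throughout; the implementation
stores termination = exits with a designated subgoal, and execution
semantics treat arrival at a different exit as a failed (incompatible)
parameterization.

### Evidence by constraint counting

The agent carries one deterministic root policy per task (choosing, at a
vertex of degree `n`, among the `m = n + #initiable options` alternatives)
and one shared deterministic policy per option (among the `n` atomic
actions).  Under a uniform prior over parameterizations, the evidence is
the fraction of parameterizations compatible with the data.  Walking each
trajectory under root control:

* the set of initiable options at vertex `v` is the options of `region(v)`
  when `v` is an entrance of its region or the task start, else empty;
* if the remaining subsequence leaves `region(v)`, the option whose
  subgoal is the first vertex reached outside is invoked — option use is
  mandatory, which is required for the optimality properties of the score;
  the first element constrains the root parameter (`m` alternatives) and,
  if not already fixed, the option parameter at `v`; subsequent in-option
  elements constrain only unfixed option parameters (`n` alternatives
  each);
* otherwise the element constrains the root parameter (`m` alternatives).

Root parameters are per-task (a recurring task reuses its table; data
contradicting an already-fixed root or option parameter is an
evidence-zero condition reported as a distinct error, not a silent
fallback).  The product of the per-element counts `k_i` is accumulated in
exact integer arithmetic, with the log taken last; the normalizing total
parameter count cancels and is never materialized.

`codelength = -log2 evidence` exactly, and the geometric-mean search time
over the `T` tasks and `O` options equals `2^(codelength/(T+O))`; both are
derived quantities of the same result object, and the per-task /
per-option attempt counts are reported alongside.

### Brute-force oracle

`brute_force_evidence` recomputes the evidence without constraint
counting: it enumerates every joint setting of the option policy tables,
simulates every task under the mandatory-use execution rule (options
execute their table step by step and must terminate at their own subgoal),
and counts compatible parameterizations exactly (root parameters never
visited contribute their full value counts as free factors).  It is
guarded to small parameter spaces and agrees with the fast path to 1e-9
bits on every connected graph of up to four vertices, every partition, and
multiple frozen-noise seeds.

## Target-behavior construction

Edge costs are one i.i.d. uniform draw per edge on (−1.05, −0.95), frozen
across tasks.  The bounds keep costs near unit so a path with fewer edges
is always cheaper than one with more (for path lengths up to ~10); the
noise only breaks ties among equal-length paths.  Draws are redrawn (from
a derived seed) until the all-pairs unique-shortest-path check passes:
from every source, every vertex must have exactly one predecessor
attaining the shortest distance (tolerance 1e-9 relative).  Unique
shortest paths are automatically reversal-symmetric and
subpath-consistent, which is what lets deterministic option policies
transfer across tasks; both properties are asserted.

Because a particular path choice can channel behavior across a few edges
and create spurious "behavioral bottlenecks", the path set actually used
is betweenness-matched: `select_path_set` draws `n_samples` candidate
frozen-noise path sets and keeps the one whose per-edge usage vector is
closest (Euclidean distance after L1 normalization; both vectors use
unordered pairs) to the graph's unweighted edge-betweenness vector.
Normalization before the comparison is a package choice; raw-count mode is
available via the `normalize` flag.  Desk-scale sample counts (20–200
depending on graph size) already reach near-zero distances on the fixture
graphs; the knob scales to very large samples for bigger domains.

## Fixtures

All domains are generated programmatically.  The classic illustrations of
these tasks fix only structural constraints (degrees, bottleneck placement,
community sizes), so the fixtures are documented reconstructions of those
constraints, and tests assert properties of the generated graphs rather
than identity with any particular drawing.

* **Rooms**: 2×2 arrangement of `w×h` four-neighbor grid rooms joined by
  four doorway vertices at mid-walls (degree 2 each).  Named partitions:
  `flat`; `doorways` (each doorway grouped with the room clockwise of it —
  the assignment tie is symmetric); `corners` (the four inner-corner
  cells as singletons; only for rooms ≥ 3×3, since in 2-wide rooms the
  corner coincides with a doorway attachment cell).  The default test
  scale is 3×3 rooms (40 vertices), keeping all-pairs ensembles
  desk-sized; 5×5 is available.
* **Tower of Hanoi** (n disks, default 3): vertices are the `3^n` legal
  configurations, edges the single legal moves (a disk moves if no smaller
  disk sits on its source or destination peg).  `largest_disk` partitions
  states by the largest disk's peg (three 9-state regions for n = 3).
* **Three-cluster graph**: three 5-vertex clusters, complete except the
  connector–connector edge, joined connector-to-connector in a ring; all
  15 vertices have degree 4.
* **Towns**: size 10 — two 5-vertex communities with internal degrees
  (2,3,3,3,3) joined by a single bridge between the two bottleneck
  vertices, making the graph 3-regular with a unique central bottleneck
  edge.  Size 19 — two complete 9-vertex communities attached through a
  single central vertex of degree 2.  Complete communities make every
  intra-community shortest path unique, which (with the mirror symmetry)
  makes the two `two_sides` parses — bottleneck assimilated to either
  side — *exactly* tied in evidence for any frozen-noise path set; the
  tie is a structural property, not a numerical coincidence.

## Partition search

The search space is encoded as one binary variable per edge; connected
components of the 'on' subgraph are the regions, so many masks map to one
partition and fitness is cached by canonical partition (labels renumbered
by smallest contained vertex).  Small graphs (≤ 18 edges by default) are
searched exhaustively, returning every argmax partition.  Larger graphs
use a seeded genetic algorithm: tournament selection (k = 3), uniform
crossover (rate 0.9), per-bit mutation (rate 1/|E|), elitism 2, halting
when a restart's best fitness is unchanged for 20 generations, with
independent restarts from fresh random populations.  The GA operator suite
is a package choice (the search method is standard binary-mask GA; no
specific operators are prescribed by the problem).  Desk-scale defaults
are population 200 with 10 restarts; `SearchConfig.full_scale()` gives
heavy-duty settings (population 2000, hundreds of restarts).  The
winner's fitness is always re-verified against the full ledger-based
scorer, and tied optima (within 1e-9 bits) are all returned.

The fitness path uses a streamlined scorer that exploits two properties of
all-pairs ensembles built from consistent path sets — tasks are distinct
and option segments can never conflict — and is tested to agree with the
full scorer exactly on every fixture.

## Learning simulation

Tabular, epsilon-greedy agents on a fixed start–goal task: flat Q-learning
over atomic actions versus SMDP Q-learning whose root menu adds the
options initiable at the current state (the option's region entrances plus
the task start).  Option policies are pretrained as the in-region shortest
path to the subgoal and frozen; no intra-option learning.  The SMDP update
discounts the reward accumulated over the option's duration by
`gamma^tau`.

Defaults: learning rate 0.1, epsilon 0.1, discount 0.9, 300 episodes,
1000-step episode cap, sparse rewards (`goal_reward = 1`, `step_reward =
0`).  The sparse scheme is the package's deliberate choice for this
demonstration: with per-step costs and zero-initialized Q-tables, the
initially attractive (zero-valued) options act as pure exploration
distractors — every agent pays to rule them out, and convergence ordering
reflects menu size rather than hierarchy quality.  Under sparse rewards
the value signal propagates backwards from the goal, jumping an entire
option segment per backup, so a hierarchy whose subgoals lie on target
routes (doorways) accelerates convergence while one whose subgoals lie off
them (corners) leaves the greedy policy detouring through its subgoals
far longer.  Per-step costs remain available via `step_reward`.

`episodes_to_criterion` reports the first episode that itself meets the
threshold (optimal steps + slack) and whose following `window`-episode
median meets it too; agents that never meet it report `None`.  The
simulation demonstrates ordinal claims only (doorway < flat < corner in
median episodes-to-criterion over ≥ 20 seeds); exact learning curves
depend on hyperparameters that have no principled setting here and are out
of scope.

## Predictions

* **Bus stops**: vertices are ranked by how often the tie-optimal
  partitions name them as option subgoals (then, for the rest, by the best
  evidence among evaluated partitions naming them).  On the 10-location
  town the two bridge endpoints rank first.
* **Path preference**: among all tied unweighted shortest paths between a
  start and goal, the predicted choice minimizes the number of region
  boundary crossings.  On the 3-disk Tower of Hanoi with the largest-disk
  partition there exist start–goal pairs with exactly two tied solutions
  crossing one vs. two boundaries; the enumeration utility locates all of
  them rather than hard-coding one instance.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use desk-scale sizes chosen as
reasonable demonstration sizes: rooms 3×3 per room (1560 tasks, ~8200
data elements), Tower of Hanoi with 3 disks (702 tasks), towns of 10 and
19 locations, betweenness-matching over 20–200 candidate path sets, GA
population 200 with 5–10 restarts, and 20 seeds for learning-curve
medians.  Evidence is exact (integer products, log last); score ties use
an absolute tolerance of 1e-9 bits; shortest-path tie detection uses 1e-9
relative tolerance.  Degenerate inputs are rejected with descriptive
errors (disconnected graphs or regions, self-loops, duplicate edges,
cost intervals that are not strictly negative, trajectories that leave the
edge set).

## Limitations

* Transitions must be deterministic and reversible; directed or stochastic
  domains, rewards beyond uniform negative step costs, and hierarchies
  deeper than two levels are out of scope.
* The synthetic domains reproduce structural constraints (degrees,
  bottlenecks, community sizes), not any specific drawing of these tasks;
  quantities that depend on an exact topology are not comparable across
  reconstructions, so tests assert orderings and structural recoveries
  instead.
* The genetic search is heuristic: it provably lower-bounds the optimum
  only; on every graph small enough to enumerate it matches the exhaustive
  optimum, and on larger fixtures results are asserted as "finds the known
  optimum".
* Human behavioral data are not modeled; the predictions module derives
  only the stimulus-side predictions (subgoal locations, path preferences)
  that behavioral experiments can test.
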