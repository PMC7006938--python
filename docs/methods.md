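# Methods

This note documents the models implemented by `animats`, the parameters
that matter, the numerical conventions, and what the bundled synthetic
conditions can and cannot show.

## The task and the agents

Groups of clonal agents ("animats") inhabit a 32×32 grid world divided
into two rooms connected by a single rewarding gate. An animat occupies
one cell, faces one of four directions, and each timestep may stand
still, turn 90° left or right, or step forward. Fitness rewards
travelling back and forth between the rooms (+1.0 per rewarded gate
crossing) and penalizes crowding (−0.075 per timestep spent on a cell
shared with another animat, when the penalty rule is active). A trial
lasts T = 500 timesteps; after a crossing, the same animat earns no
further reward for a 100-step refractory window, so a trial is worth at
most 4 points.

Each animat is controlled by a Markov brain: a set of binary units
(sensors, memory, motors) updated by deterministic lookup-table gates.
The baseline architecture has a front wall sensor, a front agent sensor,
four memory units and two motors (8 units); variants change the sensor
complement (`3sides`, `no-agent`, `w=a`), the memory size (`smallbrain`,
`bigbrain`) or remove motor feedback (`no-feedback`, which removes the
motors from the legal gate-input set and thereby shrinks effective
memory). Both motors on = forward, one motor on = turn, none = idle. The
left/right assignment of the two single-motor patterns is a labeling
convention; the task is symmetric under swapping it.

### Genome encoding

A genome is a string of 2,000–20,000 integers in [0, 255]. Every
occurrence of the start-codon pair (42, 213) opens a gate description:
one byte each for the input and output arity (mapped to 1–4), four input
id bytes, four output id bytes (reduced modulo the architecture's legal
input/output unit lists), then 2^n_in table bytes reduced modulo
2^n_out. Reading wraps cyclically past the genome end so every codon
yields a complete gate. Multiple gates writing one unit combine by OR;
unwritten units fall to 0. The byte-level layout is not specified by the
original study (it defers to its simulation framework's conventions); the
layout above follows the canonical Markov-brain literature and is fixed
here for reproducibility.

### Initialization

`random_genome` draws loci uniformly and, by default, plants 8 start
codons at spaced positions (`seed_gates=True`). With `seed_gates=False`
no codons are planted (accidental pairs are scrubbed), which reproduces
the alternative convention of starting evolution from unconnected
brains. The seeded default exists because a uniform 5,000-locus genome
contains a codon pair only with probability ≈ 0.07; at desk scale (a few
hundred generations) evolution would otherwise spend most of its budget
waiting for gates to arise by chance, whereas at the original campaign's
scale (10,000 generations) the distinction washes out.

## Evolution

A population of genomes (default 100) evolves by fitness-proportional
selection and asexual mutation; there is no crossover. A genome's
fitness F is the mean over independently seeded trials (default 30) of
the score of one randomly picked clone per trial. Mutation applies, in
order: per-locus substitution (default rate 0.005), at most one segment
deletion (probability 0.02), and at most one segment duplication
(probability 0.05; an existing segment is copied and re-inserted, the
standard gene-duplication move), with segment lengths uniform on
[128, 512]. Deletions that would undershoot 2,000 loci and insertions
that would overshoot 20,000 are skipped. Because collision penalties
make scores negative, roulette selection acts on f − min(f) + ε with
ε = 10⁻⁶ (uniform in the all-equal limit); tournament selection and
elitism are available but off by default. The original study defers its
exact genetic-algorithm parameters to a supplementary table that is not
part of the main text; the defaults above are reconstructions in the
customary range, and every one is configurable.

All randomness flows from a master seed through named
`SeedSequence` spawn keys — `(0, i)` genome init, `(1, g, i)` evaluation,
`(2, g)` selection, `(3, g, i)` mutation — with MT19937 generators, so a
lineage, or any single genome evaluation inside it, replays exactly.

## Trial semantics

Placement samples distinct start slots (72 are defined on a 6×6 lattice
per room) without replacement; initial orientations are uniform; brains
start all-zero. One serial-order permutation is drawn per trial and
reused every timestep. Each timestep an animat senses the live occupancy
(animats earlier in the order are already at their new positions),
updates its brain, and acts. Sensors have range one: wall sensors fire
on walls (the boundary is solid), agent sensors on occupied cells, the
universal sensor on either. Forward into a wall realizes no movement;
forward into an occupied cell is blocked only under the blocking rule
(otherwise cells may be shared, and every animat on a cell with
occupancy > 1 pays the penalty each such timestep). A crossing is
registered when an animat enters a cell whose room differs from the room
of its last non-gate cell — i.e. it came through a gate — and carries
that gate's reward tag. A repeat crossing spaced exactly 100 steps after
the previous crossing is still unrewarded (the window is closed on the
left); any crossing, rewarded or not, restarts the window. Rewarded
crossings are capped at 4 per trial: the literal reward rule would admit
a fifth for a very early first crossing, but the stated per-trial
maximum is 4 points, and the cap enforces it.

The dynamics are implemented once in a numba kernel (~20 ns per
animat-step); the library keeps pure-Python reference primitives
(`sense`, `step`, `resolve_action`) and the test suite checks that the
kernel reproduces a step-by-step pure-Python replay and that its online
scorer equals the log-based scorer.

## Post-evolutionary evaluation

Evolved champions are re-tested across 21 group sizes
(1, 4, 7, …, 68, 72) in eight conditions: the original world under four
interaction-rule variants (Original, No Penalty, Blocked, Blocked and no
Penalty) and four modified wall arrangements under original rules (Noisy
Corners, Small Gates, 4 Rooms — all four gates rewarding, 4 Messy
Rooms — only the gates on the vertical mid-line rewarding). Task fitness
TF per cell averages the genome fitness across evolution replicates;
reliability R is the unweighted mean of the 21 Original-condition TF
values. The modified-world geometries are published only as figures;
the bundled ASCII maps are reconstructions that preserve the stated
structure (room counts, gate counts and reward assignment, 72 start
slots, reachability), and the map format lets users substitute exact
geometries if they have them.

Behavior statistics pool animat-timesteps across trials: the profile is
the fraction of realized actions (a blocked forward attempt counts as no
movement); the 4×4 transition table conditions on the composite SM state
(S = any sensor fired, M = moved or turned), with zero-support rows
reported as missing rather than renormalized so that table differences
are unbiased.

## Brain complexity

Integrated information is computed in the IIT 3.0 cause-effect framework
on candidate sets of computational (non-sensor) units, with sensors
clamped to their observed state and non-member units frozen as
background. For a mechanism in a state, cause repertoires multiply
per-mechanism-node likelihoods under a uniform perturbation prior and
normalize; effect repertoires factorize over purview nodes. Small phi is
the minimum over the past and future directions of the maximally
irreducible purview's distance to its best bipartition; distances are
earth mover's distances with Hamming ground metric over purview states,
solved exactly as transportation LPs. Mechanisms with positive small phi
are concepts. Big Phi is the minimum over unidirectional system cuts
(connections from one part into the other are noised) of a minimum-cost
transport of small-phi mass between the intact and cut concept
structures; the ground distance between concepts sums the EMDs of their
cause and effect repertoires expanded to the full candidate set (uniform
over non-purview units on both sides — a deliberate, documented
simplification of the reference convention, which uses the unconstrained
effect repertoire on the effect side), and surplus mass is routed to the
null concept (uniform cause, unconstrained effect). A single-unit
candidate set admits no bipartition and is assigned Phi = 0 (a lone
unit has no parts to integrate across). Phi^Max maximizes
big Phi over candidate subsets and over every deduplicated brain state
visited during one trial; ties resolve to the first subset in
ascending-size, lexicographic order.

Two exact consequences of these definitions serve as fixed points: a
system admitting a bipartition with no effective connections across it
(feed-forward or disconnected systems always do) has Phi = 0, and the
two-unit mutual-copy system has two first-order concepts (phi = 0.5
each) and positive Phi. Searches are exhaustive and guarded: candidate
sets up to 8 units, whole brains up to 10 units; larger brains return an
explicit "not computed" result rather than an approximation. The test
suite re-derives small phi and big Phi with an independent brute-force
oracle (separate code path, no pruning) and requires agreement to 1e-9
on systems of up to three units; the implementation's prunings
(purviews restricted to connected units, mechanisms containing a node
with no connections in the tested direction, zero-crossing cuts) are
exact, not approximations, and the oracle verifies this.

## Problem sizes and what the tests show

The published campaign (30 replicates × 15 setups × 10,000 generations,
population 100, 30 trials) is far beyond a desk run, and its aggregate
figures are not reproduced here. The package's tests instead pin the
exact printed constants (world size, slot count, point values, window
lengths, group-size vector, setup table), verify the scoring rule on
worked examples, and check the evolutionary machinery directionally: at
the bundled scaled-down size (population 50, 300 generations, group 18,
10 trials per genome) mean fitness at the final generation exceeds the
first generation's in at least 9 of 10 master seeds. At this scale the
dominant selection pressure is collision avoidance (random movers start
near −5 points and the mean climbs toward 0); reliably evolving
high-scoring gate-crossers requires generation counts closer to the
original campaign. Passing these tests therefore demonstrates that the
machinery is correct and improvement-directed, not that desk-scale runs
reach the published fitness levels.

## Known limitations

* Gate decoding byte layout, mutation rates, and selection scheme are
  reconstructions of under-specified originals (all configurable).
* Modified-world maps are structural reconstructions of pictorial
  originals.
* Phi values depend on the pinned IIT conventions above; they are
  self-consistent (implementation vs oracle) but not guaranteed to equal
  the reference implementation's output digit-for-digit on systems where
  the expansion convention matters.
* Exact Phi is limited to small subsystems; big architectures report
  "not computed", mirroring the original study's treatment of its
  largest brains.
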