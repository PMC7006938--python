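# animats

Evolution and analysis of grid-world agents ("animats") controlled by
genome-encoded Markov brains. The package is aimed at researchers in
artificial life and evolutionary multi-agent systems who want a
reproducible platform for studying how group size, interaction rules,
sensorimotor/memory capacity, and environment design shape evolved
behavior, its **reliability** under modified conditions, and the causal
complexity of the evolved controllers.

## The model

Groups of clones of a single genome navigate a 32×32 two-room grid world
and are rewarded for travelling through the gate between the rooms while
avoiding each other. The per-animat fitness over a T = 500-step trial is

```
f(a) = Σ_t [ +1.0  if a crosses a rewarding gate at t and has not
             crossed any gate in the previous 100 steps ]
     − Σ_t [ 0.075 if a shares its cell with another animat at t ]
```

with rewarded crossings capped at 4 points per trial. A genome's fitness
`F(A)` is the mean of `f(rand(A))` over 30 independently seeded trials.
Genomes — integer strings in [0, 255], length 2,000–20,000 — encode
deterministic lookup-table gates (hidden Markov gates) wiring binary
sensor, memory and motor units; populations of 100 evolve by
fitness-proportional selection and mutation (point substitution, segment
duplication and deletion; no crossover).

After evolution, champions are re-tested across 21 group sizes
(1, 4, …, 72) in eight conditions (modified interaction rules and
modified wall arrangements). Task fitness `TF` is the fitness measured
in a test cell; **reliability** `R = ⟨TF⟩` averages the Original-condition
task fitness across the 21 group sizes. Brain complexity is measured in
the integrated-information framework: `Φ^Max` is the largest integrated
information of any subsystem over all brain states visited in a trial,
and `#Concepts(Φ^Max)` counts that subsystem's irreducible internal
mechanisms. See `docs/methods.md` for the full model description and
every pinned convention.

## Worked example

Fitness-rule fixtures (exact values):

```python
>>> from animats.fixtures import gate_oscillator_log
>>> from animats.engine import InteractionRules, score_animat
>>> score_animat(gate_oscillator_log(), 0, InteractionRules())
4.0
```

An animat crossing the gate at the minimum rewarded spacing for the whole
trial earns the per-trial maximum of 4 points; one co-occupancy timestep
with penalties active scores exactly −0.075.

A scaled-down evolution (population 50, 300 generations, groups of 18,
10 trials per genome — about 30 s):

```python
>>> from animats import build_evolution_config, evolve
>>> cfg = build_evolution_config("0.25", master_seed=1, population_size=50,
...                              generations=300, trials_per_genome=10)
>>> lin = evolve(cfg)
>>> round(lin.mean_fitness[0], 4), round(lin.mean_fitness[-1], 4)
(-5.1737, 0.0)
```

Random first-generation brains blunder into each other (mean fitness
≈ −5.2 from collision penalties); selection drives the population mean
up to 0 within 300 generations — at this scale animats mostly learn to
avoid collisions, while reliably evolving high-scoring gate-crossers
needs generation counts near the original campaign scale (10,000).

Integrated information of a hand-wired brain whose two memory units copy
each other (a minimal integrated core):

```python
>>> from animats.fixtures import copy_loop_brain
>>> from animats.engine import TrialConfig, run_trial
>>> from animats.world import builtin_world
>>> from animats.complexity import phi_max_over_lifetime
>>> import numpy as np
>>> brain = copy_loop_brain()
>>> log = run_trial(builtin_world("original"), brain,
...                 TrialConfig(T=20, group_size=1), InteractionRules(),
...                 np.random.Generator(np.random.MT19937(0)))
>>> res = phi_max_over_lifetime(brain, log, max_subset_size=2)
>>> res.phi_max, res.subset, res.n_concepts
(1.0, (2, 3), 2)
```

The two-unit copy loop is irreducible: each unit is a concept (φ = 0.5)
and cutting either direction of the loop destroys cause-effect
information (Φ = 1). A strictly feed-forward brain
(`animats.fixtures.chain_brain`) yields Φ^Max = 0.

The same workflows are available from the shell:

```bash
animats worlds                       # list the five bundled maps
animats evolve --setup 0.50 --seed 1 --out runs/baseline
animats simulate --brain runs/baseline/best_brain.txt --group-size 36 --seed 2
animats evaluate --brain runs/baseline/best_brain.txt --out runs/baseline/eval
animats complexity --brain runs/baseline/best_brain.txt
animats run experiment.yaml          # full pipeline from a flat config file
```

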