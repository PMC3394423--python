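# Methods

## Model

A bicluster of an n×m expression matrix D is a gene subset g and condition
subset c. Coherence is measured by the Cheng–Church mean squared residue

    r(d_ij)  = d_ij − d_ic − d_gj + d_gc
    MSR(g,c) = (1/|g||c|) Σ r(d_ij)²

with d_ic the gene mean within c, d_gj the condition mean within g and
d_gc the overall mean of the block; MSR = 0 exactly when the block is
additive (d_ij = a_i + b_j), and also for any single-gene or
single-condition block, where the residue cancels identically. Row
variance RVAR(g,c) = (1/|g||c|) Σ (d_ij − d_ic)² separates genuinely
co-varying blocks from flat ones. All statistics use population
(divide-by-count) normalization.

Search minimizes the objective vector

    f1 = n·m / (|g||c|)      size (f1 ≥ 1, =1 for the full matrix)
    f2 = MSR / δ             coherence relative to the residue budget δ
    f3 = 1 / RVAR            non-flatness

under Pareto semantics. δ is a per-dataset calibration: it both defines
which biclusters count as homogeneous (MSR < δ) and sets the exchange rate
between coherence and the other objectives inside f2. Flat blocks
(RVAR = 0) would make f3 infinite; they instead receive a large finite
penalty (default 1e12, configurable) so dominance comparisons remain
total.

A candidate is encoded as a binary vector of length n+m — the first n bits
select genes, the last m select conditions — and decoded by taking the set
bits. Degenerate vectors (no gene or no condition bit) are repaired by
setting one uniformly random bit in the empty section before evaluation.

## Optimizer

The engine is a discrete shuffled frog-leaping swarm with an ε-dominance
archive:

1. **Initialization.** A small non-dominated-sorting GA (binary tournament
   on rank/crowding, uniform crossover, bit-flip mutation, elitist
   truncation) with 50 individuals and 20 generations seeds the swarm.
2. **Generation loop** (default 100 generations): grow the population to
   `pop_max` with archive-derived spawns; deal the swarm into 6 memeplexes
   by (non-domination rank, crowding distance) round-robin; run 10
   improvement cycles per memeplex; recombine; offer every frog to the
   archive; shrink the population.
3. **Worst-frog improvement** (per cycle): the memeplex's worst frog is
   improved through a sequential fallback — (1) velocity/position move
   toward its personal best, the memeplex best and a sigma-selected
   archive guide; (2) bit-flip mutation; (3) crossover with the guide;
   (4) unconditional replacement by a random frog. The velocity rule is

       v' = ξ(ω·v + c1·r1·(Pb−x) + k·μ1·c2·r2·(gb−x) + μ2·c3·r3·(XB−x))

   with fresh uniform r per bit, direction k ∈ {±1} drawn once per update,
   clamping to ±v_max, and the threshold position rule x' = 1 iff
   x + v ≥ 0 (boundary inclusive, as the method family defines it).
4. **Archive.** Additive ε-boxes floor(f_i/ε_i); a candidate is rejected
   if its box or vector is dominated, competes by distance-to-box-corner
   when it lands in an occupied box (incumbent wins ties), and otherwise
   enters and evicts everything its box or vector dominates. This keeps
   members mutually non-dominated, one per box, and guarantees every
   candidate ever seen stays within an additive ε margin of some surviving
   member. Guides come from the sigma method: a frog follows the archive
   member whose direction signature σ (for three objectives,
   (f1²−f2², f2²−f3², f3²−f1²)/Σf²) is nearest in Euclidean distance, ties
   broken uniformly at random.
5. **Dynamic population.** Growth spawns mutants of least-crowded archive
   members (largest crowding distance, top quarter) and refines each spawn
   with a short greedy climb (below); shrinkage ranks frogs by
   sigma-distance to their local guide and removes the most redundant
   `selection_ratio` fraction, each with probability 0.5, never dropping
   below `pop_min`.

### Acceptance rule and local refinement

Two design points were genuinely open and we settled them empirically.

*Move acceptance.* Reading "a better solution" in the improvement steps as
strict three-objective Pareto dominance makes steps 1–3 inert: almost
every guided move trades one objective against another, so every cycle
falls through to random replacement and the search degrades to a random
walk (planted-recovery overlap stalls near the random baseline). The
default acceptance is therefore *dominates or is admitted by the
ε-archive* — admission being the standard ε-MOEA notion of a useful
solution: non-dominated at the front and claiming (or winning) an ε-box.
The strict rule remains available (`step_acceptance="dominates"`), and the
single-objective reduction test uses it.

*Spawn refinement.* The population-adding strategy's goal is to place new
individuals where they contribute. Each spawn is a mutant (bit-flip at
twice the mutation rate) of a least-crowded archive member, refined by a
greedy climb of `spawn_climb_trials` structured edits — gene/condition
swaps and additions, half of them residue-guided in the Cheng–Church
node-substitution sense (drop the worst-fitting member, admit one of the
best-fitting outsiders) — accepted only when the edited bicluster Pareto-
dominates its predecessor. The dominance guard means refinement can never
trade coherence away for size or vice versa; the archive's parent pool is
refreshed after every spawn so an improved offspring can immediately seed
the next. This memetic component supplies the exploitation pressure the
bare operator set lacks: without it the archive provably performs neutral
drift on planted benchmarks.

*Random frogs.* Wherever a "random solution over the feasible space" is
required (initialization fallback, step 4, empty-archive spawns), gene and
condition bit densities are drawn per frog from U(2/n, 0.5) rather than
using Bernoulli(0.5) bits, so small seed biclusters are sampled as well as
half-matrix ones.

## Parameters

| parameter | default | meaning |
|---|---|---|
| δ (`delta`) | preset: 300 (yeast-style), 1200 (human-style), 1.0 (unit-variance synthetic) | residue budget; scales f2 |
| `n_frogs`, `n_memeplexes`, `cycles_per_memeplex` | 60, 6, 10 | swarm shape per the published configuration |
| `n_generations` | 100 | shuffling iterations |
| `epsilon` | (0.02, 0.02, 0.02) | archive box widths per objective |
| `c1,c2,c3`; `mu1,mu2` | 2,2,2; 0.5,0.5 | acceleration and influence factors |
| `xi`, `v_max` | 0.729, 4.0 | constriction factor; velocity clamp |
| ω schedule | 0.9 → 0.4 linear | inertia weight over generations (the source's definition is circular; this is the standard schedule) |
| `mutation_rate` | 0.02 | per-bit flip probability (spawn kicks use 2×) |
| `crossover_type` | uniform | single-point also available |
| `pop_min`, `pop_max`, `selection_ratio` | 40, 120, 0.2 | population dynamics bounds |
| `ga_individuals`, `ga_generations` | 50, 20 | initializer budget |
| `spawn_climb_trials` | 300 | greedy refinement budget per spawn |
| `rvar_penalty` | 1e12 | f3 for flat biclusters |
| imputation ranges | [0, 800] / [−800, 800] | uniform fill for missing cells, yeast/human presets |

Seeding: one `numpy` generator initialized from `SFLConfig.seed` is
threaded through every stochastic step; identical config ⇒ bit-identical
archive and log.

## Synthetic data

The generator emulates two microarray scales — yeast-style (values
0–600, 17 conditions) and human B-cell-style (values −750 to 650, 96
conditions) — via presets, and a unit-variance benchmark used throughout
the tests: a 200×30 standard-normal background with one planted additive
40×10 bicluster, per-gene and per-condition offsets drawn from U(−2, 2)
and cell noise at half the background standard deviation; δ = 1.0 (about
four times the plant's expected residue, comfortably above it and at the
background-variance scale). Plant patterns: `constant` (flat),
`shifted` (shared condition profile), `additive` (profile + per-gene
offset). Overlapping plants resolve last-writer-wins.

What the generator does *not* emulate: heavy-tailed and count-valued
intensities, correlated background structure, batch effects, overlapping
or scaling (multiplicative) biclusters, and missingness mechanisms beyond
missing-completely-at-random. Passing the planted-recovery tests
therefore shows the optimizer can find a clean additive needle under
Gaussian noise; it does not certify performance on real arrays, where δ
must be calibrated to the data scale and coherent structure is rarely
exactly additive.

Missing-value imputation follows the microarray convention of uniform
random fill over a stated range. The yeast-style preset range [0, 800]
intentionally exceeds the 0–600 data range, mirroring the established
preprocessing for that dataset; the range is a visible parameter precisely
because such draws influence which biclusters are found.

## Numerical and degenerate-case choices

- Population normalization everywhere; no n−1 corrections.
- Hypergeometric enrichment p = P(X ≥ k) is computed with the scipy
  survival function (log-space internally); the test oracle is an exact
  rational enumeration. No multiple-testing correction is applied to the
  reported p; a Bonferroni column is emitted alongside, labelled as an
  extension.
- Archive same-box ties: smaller Euclidean distance to the box's lower
  corner wins; exact ties keep the incumbent (insertion order).
- Crowding distance: boundary members infinite; zero-range objectives
  contribute nothing; fronts of ≤2 members are all-infinite.
- Personal bests update on dominance; mutually non-dominated outcomes
  replace with probability 0.5.
- The all-zero objective vector has no sigma signature and is rejected;
  f1 ≥ 1 makes it unreachable for real frogs.
- "Worst" frog in a multi-objective memeplex = last under
  (non-domination rank, then crowding distance descending).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
unit tests on matrices up to 60×12, the planted-recovery experiment on
200×30 with the full default configuration (about 50 s per run; five
seeds in the suite, three instances in the acceptance script). The
yeast- and human-scale presets (300×17, 400×40) are generation presets for
the CLI; full-scale runs (2,884×17, 4,026×96) use the same code paths and
scale linearly in cells × generations.

## Known limitations

- On instances whose planted profile happens to be flat (drawn row
  variance at or below the background's), f3 opposes the plant direction
  and the dominance-guarded refinement cannot follow it; recovery then
  depends on chance archive placement. This is a property of the
  three-objective formulation, not of the implementation.
- The ε-archive uses additive boxes, so its coverage guarantee is
  additive (within ε_i of a member per objective); the multiplicative
  form holds on objective values ≥ 1 (always true for f1).
- Maximality of biclusters is not enforced; size pressure comes only
  through f1.
- The position threshold x' = 1 iff x+v ≥ 0 turns zero-velocity bits on;
  step-1 moves therefore explore mostly by expansion, and the burden of
  contraction falls on swaps inside the refinement climbs.
- Single-threaded; memeplexes evolve sequentially.
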