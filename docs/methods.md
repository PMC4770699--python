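# Methods

## Model structure

One *epoch* is `G` non-overlapping generations.  A generation comprises
(1) resetting the landscape to a uniform ("structureless") state and
peppering the population uniformly at random over it, (2) 100 ecological
time steps of foraging, and (3) one reproduction event.  All randomness in
an epoch derives from a single seed: a numpy `SeedSequence` spawns one child
stream per generation, so partial reruns are reproducible and batch runs
with seeds `base + i` are independent.

### Ecology

Resource cells hold above-ground biomass `R ∈ [0, K]` and regrow as
`R' = R + r(R + refuge)(1 − R/K)`.  The constant below-ground `refuge`
(0.05 K) keeps the growth rate positive at `R = 0`, so grazed-out cells
recover; this is the minimal logistic-with-reservoir form.  The grid is
toroidal so the initial landscape has no edge gradients.

Agents perceive a 5×5 neighborhood.  A cell's worth to an agent with
competition-tradeoff `δ` is `max(0, R − δC)`, where `C` counts the agents
currently within one move of that cell (its 3×3 block), excluding the focal
agent itself when it is within that block.  A movement direction's value is
the neighbor cell's worth plus `α` times the mean worth of the outer-ring
cells reachable by a second move that way — 3 cells for a cardinal
direction, 5 for a diagonal (adjacent directions share corner cells; the
sets jointly cover all 16 outer-ring cells).  The value of *staying* is
defined symmetrically: own-cell worth plus `α` times the mean worth of the
8 neighbors.  This symmetric definition is deliberate: on a featureless
landscape staying and moving are then valued identically, so a lone agent
does not walk for free.  An agent moves to the best direction iff
`current < ρ · best` (ties broken uniformly; equality stays), paying
`move_cost` and — by default — forfeiting intake that step, the stricter
reading of the stay-and-eat/move alternative (`movers_feed` flips this).

Agents that feed demand
`i_max R^q / (R^q + [H(1 + wC)]^q)` with `C` the number of same-cell
co-occupants; per-cell demand is capped at the available `R` by
proportional scaling, so extraction never exceeds stock.  Biomass updates
as `conversion · intake − metabolic_cost`, floored at `b_floor = 1e-3`;
there is no within-generation death — failed foragers persist as
near-zero-biomass individuals with correspondingly negligible fecundity.

Updates are randomized-sequential: agents act in a freshly shuffled order
each step, against the current occupancy.  This avoids having to invent a
simultaneous-move conflict rule.

### Genetics and mate choice

Each individual is diploid at four unlinked loci (`α, δ, ρ, m`), expressed
codominantly (trait = allele mean).  Offspring draw one allele per locus
from each parent independently (free recombination).  Every allele of every
offspring is then perturbed multiplicatively by `1 + u`,
`u ~ Uniform(−s, s)`, with `s` annealed geometrically from 10% at the first
generation to 0.1% at the last; the multiplicative kernel matches the
relative ("%") character of the perturbation, and geometric interpolation
is the standard annealing schedule that hits both endpoints exactly.
Foraging alleles are clipped below at 0; `m` alleles to `[0, 1]`, which
keeps the mating deviation `D = 2|m − 0.5| ∈ [0, 1]` a valid probability
base.  Founders draw foraging alleles uniformly (`α ∈ [0, 1.5]`,
`δ ∈ [0, 2]`, `ρ ∈ [0, 1]`) and all start with `m` alleles exactly 0.5.

Reproduction is hermaphroditic soft selection.  Individuals are ranked by
end-of-generation biomass (ties by id); starting with the largest, each
not-yet-paired individual chooses a mate from all remaining unpaired
individuals — mate search is population-wide, not spatial.  With
probability `D^γ` on the focal's own `m` the choice is non-random:
`m < 0.5` takes the nearest candidate by Euclidean distance over
`(α, δ, ρ)` (the magic-trait linkage; `m` itself is excluded from the
distance), `m > 0.5` the farthest, distance ties uniform.  Otherwise the
mate is uniform-random.  The same coin is drawn in `random` mode and
ignored, so paired runs of the two modes share one RNG stream until a
non-random choice actually fires.  Chosen mates leave the pool (monogamous
matching); an odd leftover goes unmated.  Each pair draws
`n_pair ~ Binomial(n_max = 4, B_pair/B_max)` progeny, all starting at
biomass 1.0 at fresh uniform-random positions.  Zero total progeny is an
extinction signal and ends the epoch.

## Parameter defaults and calibration

| parameter | default | meaning |
|---|---|---|
| r | 0.05 | regrowth rate per step |
| K | 5.0 | per-cell carrying capacity (biomass units) |
| refuge | 0.25 | below-ground reserve (0.05 K) |
| i_max | 1.0 | max intake per agent-step |
| H | 2.0 | half-saturation biomass |
| w | 0.5 | interference weight per same-cell competitor |
| q | 2.0 | abruptness (intermediate contest/scramble) |
| conversion | 0.5 | intake → biomass efficiency |
| metabolic_cost | 0.2 | biomass per step |
| move_cost | 0.2 | biomass per move |
| γ | 0.2 | mate-choice exponent (non-random 72% at m = 0.6/0.4) |
| n_max | 4 | max progeny per pair |
| founders | 100 | first-generation population |
| grid | 50×50 | default landscape |

The ecological defaults were calibrated to one target: 100 founders on the
default 50×50 grid grow to a stochastic plateau of a few hundred agents by
generation ~100.  With the values above the plateau sits at ≈330–370 with
coefficient of variation well under 0.3, and populations recover from early
dips rather than exploding or crashing.  Under soft selection the
equilibrium is set by biomass inequality (mean pair biomass ≈ half the
maximum), so per-capita scarcity — not any explicit cap — regulates N.
More productive parameterizations (higher r or K, lower metabolic cost)
push the plateau into the thousands.

Desk-scale experiments use a 25×25 grid and 150 generations, where the same
ecology supports ≈30–120 agents per run; the test suite's cross-run
comparisons use 8–32 replicate epochs per mating arm, sizes chosen so the
whole suite and the acceptance script each complete in minutes on one CPU.

## Numerical and implementation choices

* The 100-step ecological inner loop runs in a numba kernel; a pure-Python
  reference implementation built from the documented per-operation
  functions is kept alongside, and the test suite asserts bit-identical
  trajectories between the two over multi-step runs.  Both paths consume
  identical pre-drawn random arrays (one permutation and one tie-break
  uniform per agent per step).
* Movement tie-breaks and mate-choice distance ties are uniform via a
  single uniform draw; the stay/move comparison uses strict inequality, so
  exact value ties mean "stay".
* Allele-class calling for the continuous alleles is single-linkage 1-D
  clustering: sort the 2N values and cut where adjacent gaps exceed ε
  (default 5% of the locus's founder range).  Hardy–Weinberg expected
  heterozygosity is the multi-allelic `1 − Σ p_i²`; the deviance
  `(H_obs − H_exp)/H_exp` is reported as undefined for monomorphic loci and
  when ≥5 classes are called (insufficient structure to treat values as
  discrete alleles).
* PCA and Ward clustering standardize phenotype columns (z-score) and drop
  zero-variance columns; rank-≤2 data report exactly 100% first-two-PC
  variance.  The Mann–Whitney test uses the exact null distribution for
  combined n ≤ 20 (full permutation enumeration under ties) and the
  tie-corrected normal approximation otherwise.

## What the generator emulates — and what it does not

The simulator reproduces the study conditions it models: a structureless,
locally depletable and renewable resource; ecologically identical
consumers differing only in heritable strategy; population-wide mate
search; soft selection.  It deliberately omits perception error, memory,
learning, sexes, parental care, kin recognition, spatial mate limitation,
linkage, and any imposed resource spectrum — so emergent structure cannot
be an artifact of built-in environmental or genetic templates.  Passing
tests therefore demonstrate internal consistency of the mechanism, not
predictions for any real species.

## Known limitations

* At the desk scale (25×25, ≈30–120 agents) drift is strong relative to
  selection.  The m-trait arm reliably evolves below the random arm
  (typically ≈0.40 vs ≈0.50 mean m at generation 150; arm separation is
  highly significant with ≥16 replicates per arm), but individual runs
  reaching mean m < 0.3 within 150 generations are rare, and by the time m
  falls that far the α locus has usually fixed — small populations purge
  polymorphism quickly under assortment, which makes the heterozygote
  deficit transient: strongly negative while two α classes coexist
  (deviances of −0.4 to −0.8 are typical), undefined after fixation.
* The rate of m evolution is slower than in large-population regimes;
  500-generation 50×50 runs reach mean m ≈ 0.27–0.33 while random-mating
  controls stay at ≈0.53–0.55.
* Absolute population sizes depend on the ecological parameterization and
  should not be read as predictions; only the qualitative plateau and the
  contrast between mating modes are calibrated behavior.
* Extinction is possible (and signaled) for harsh parameterizations, but
  the defaults were chosen so that it is not observed in practice.
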