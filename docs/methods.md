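# Methods

`handedkin` models the evolution of human handedness as a kin-selected,
negatively frequency-dependent trait. This note records the model, its
assumptions, the numerical choices, and the design decisions that were
genuinely open, in enough detail to re-derive every number the package
produces.

## The trait and the games

The evolving trait is an individual's propensity `x ∈ [0, 1]` to develop
left-handedness (a continuous predisposition; realised handedness is
Bernoulli(x)). Left-handers pay a proportional fecundity cost `k` (the
"basic disadvantage") and enjoy a surprise advantage in combat while rare:
a left-hander beats a right-hander with probability

    p = 1/2 + a (1 − q),        clamped to [0, 1],

where `q` is the frequency of left-handers among the opponent's accustomed
adversaries, so the advantage is maximal (`1/2 + a`) when left-handers are
vanishingly rare and vanishes as they become ubiquitous. Same-handed
pairings are even, and the mirror pairing is the complement, so win
probability is conserved exactly. The linear decay in `q` is the simplest
form with those two limits.

Two illustrative fitness scenarios embed the duel in a social context:

* **within-group combat** — each adult fights one uniformly random
  patch-mate, with `q` equal to the local (others-only) left-handedness
  level; winning multiplies own fecundity by `1 + B(2p − 1)`. The
  surprise advantage is harvested from relatives, so at an interior
  equilibrium the trait is marginally *selfish* (c < 0, b < 0).
* **between-group combat** — each patch member fights one member of a
  random other patch, with `q` equal to the global level; the patch's mean
  success `s` multiplies every member's fecundity by `1 + G(2s − 1)`.
  Gains are shared with relatives, so at an interior equilibrium the
  trait is marginally *altruistic* (c > 0, b > 0).

Expected fecundities are computed by exact marginalisation over both
combatants' realised handedness (the cost and the contest outcome are
correlated through own handedness), verified against brute-force
enumeration of all `2^(2N)` handedness realisations in the tests.

Parameter defaults: `a = 0.1`, `k = 0.02`, `B = 0.5`, `G = 2.5`. `a`, `k`
and `B` are illustrative weak-selection values; `G` was set by analysing
the gradient so that *both* scenarios exhibit interior, negatively
frequency-dependent equilibria across the dispersal range `m ∈ [0.05, 1]`
— the regime in which the theory's comparative predictions are
non-degenerate. (With `G` of order `B`, the between-group indirect
benefit `r·b` never overcomes the cost at any dispersal rate and the
altruistic branch collapses to `x* = 0` everywhere.) Validity constraints
`B·min(2a, 1) < 1` and `G·min(2a, 1) < 1` keep all fecundities positive;
they are checked at evaluation time.

## Demography and relatedness

The population is an infinite-island model: patches of `N` breeding
females and `N` breeding males, discrete non-overlapping generations,
monogamous pairing by default (random-within-patch mating optional),
sex-specific offspring dispersal `m_f`, `m_m` into a global pool, and
regulation back to `N` breeders per sex. Immigrants carry no identity
with natives.

Stationary probabilities of identity by descent satisfy a 4-unknown
linear system in `Q_ff, Q_fm, Q_mm` (identity between random genes of two
distinct same-patch adults of the indicated sexes) and `F` (adult
inbreeding). With `u = 1 − m_f`, `v = 1 − m_m`:

    Q_xy = phil_x · phil_y · Q0,        F = Q_fm,

where `Q0` is the identity of two random offspring born on one patch:
under monogamy two random local offspring are full siblings with
probability `1/N` (identity `(1+F)/4 + Q_fm/2`) and otherwise children of
distinct pairs (identity `(Q_ff + 2Q_fm + Q_mm)/4`); under random mating
the mother and father are shared independently with probability `1/N`
each. The system is solved directly (`numpy.linalg.solve`) and the
residual of the fixed point is checked against 1e−9. Three independent
oracles corroborate it: the textbook haploid closed form
`(1−m)²/(N − (N−1)(1−m)²)` (agreement ≤ 1e−10), a hand-derived scalar
closed form for the diploid monogamous `Q0`, and neutral gene-dropping
simulation (below).

Relatedness is reported as others-only regression relatedness against the
global population, `r = Q_pair / ((1+F)/2)`. Derived coefficients:

* `r_group_others[x][y]` — an adult's relatedness to a random same-patch
  adult, by sex;
* `r_group_origin[maternal|paternal]` — the same partner valued through
  one parental-origin half of the genome. A focal's maternal-origin gene
  is a random gene of its mother, so this equals the mother's relatedness
  to the focal's patch-mates; sex-biased dispersal therefore splits the
  two origins (the more-dispersing parent's origin is less locally
  related), and the two origins average exactly to the diploid value;
* `r_parent_to_offspring` — `(1+F)/4 + Q_fm/2` normalised, which exceeds
  1/2 under local inbreeding (an `outbred_approximation` switch restores
  the textbook 1/2);
* `r_parent_to_group` — a parent's relatedness to its offspring's random
  adult patch-mate, marginalised over the offspring's own dispersal.

## Selection analysis

Selection gradients follow the Taylor–Frank neighbour-modulated form: a
rare mutant deviates from a monomorphic resident, and

    S(x) = −c(x) + r_party · b(x),

with `c = −∂w/∂x_focal` and `b = ∂w/∂x_group` by central finite
differences (step 1e−6; the trait space is well-conditioned at that
scale). `r_party` is the controlling party's relatedness ratio: the
individual's own (possibly sex-specific) group relatedness; for a parent,
`r_parent_to_group / r_parent_to_offspring` (the parent trades the
offspring's direct fitness against groupmates' fitness in units of its
own relatedness to each); for a single parental-origin gene, that
origin's group relatedness. Equilibria are located by a sign-change scan
(257 points) plus Brent's method to 1e−10; multiple interior roots raise
an error; boundary outcomes are flagged. Convergence stability is the
sign of the gradient's slope across the root. Sex-specific optima are
solved independently per sex (no cross-sex genetic correlation; sexual
antagonism is out of scope), optionally with sex-specific payoff
parameters.

### Competition structure: the one genuinely open design choice

How fecundity differences translate into breeding slots matters more than
any parameter. The package exposes two compositions:

* `competition="global"` (default): relative fitness is own expected
  fecundity over the global mean. Density regulation is decoupled from
  the social interaction, so relatedness acts at full strength and the
  comparative statics follow: higher dispersal → lower relatedness →
  more left-handedness at a selfish equilibrium, less at an altruistic
  one, with sex, parental and parent-of-origin differences inheriting
  the corresponding relatedness asymmetries.
* `competition="local"`: the full island composition — philopatric
  offspring compete against the patch mean fecundity, dispersed offspring
  against the global mean, weighted by the sex-specific dispersal rates.
  In this composition the kin-competition cost of helping (or relief
  from harming) patch-mates offsets the relatedness benefit essentially
  exactly — the classic cancellation result for fecundity effects in
  Wright's island model with non-overlapping generations — and the
  equilibrium becomes nearly independent of dispersal for both scenarios.

The default is "global" because the framework's comparative predictions
are statements about how relatedness modulates the equilibrium; under the
fully coupled island life cycle those predictions are structurally
suppressed, which is itself a known and documented property of that life
cycle, not of the handedness game. The "local" composition is retained
because it is the exact analytical counterpart of the individual-based
simulator's life cycle and is used for the quantitative
simulation-vs-analytics validation. Readers should interpret the default
analysis as applying to populations where the socially affected fitness
component is regulated at a larger scale than the patch.

## Imprinting predictions

Per-origin optima from the selection analysis feed the loudest-voice-
prevails resolution: at a left-handedness *promoter* locus the origin
favouring the higher incidence stays expressed and the other falls
silent; at an *inhibitor* locus the origin favouring the lower incidence
stays expressed; equal optima (symmetric dispersal) leave both copies
expressed. Expression is binary at the resolution endpoint — graded
intermediate states belong to an arms-race resolution model, which is out
of scope. Perturbation outcomes follow two-copy dosage bookkeeping
(expressed copy = 1 unit of product, silenced = 0): deletion or
epimutational silencing zeroes the affected copy, duplication doubles it,
and uniparental disomy of an origin replaces the other origin's copy with
a second copy of the affected origin's state. Total product unchanged →
no effect; reduced to zero where there was expression → major loss of
function (with the direction of the accompanying shift set by the locus
type); otherwise a directional shift. Directions are reported
qualitatively only.

## Individual-based simulator

A finite island world (default 200 patches) realises the life cycle
explicitly: phenotype determination per the configured controlling party
(own genotype mean, a parent's recorded genotype, or a single
parental-origin allele — alleles are re-tagged by origin at every
meiosis), Bernoulli handedness, combat, reproduction with per-allele
Gaussian mutation clamped to [0, 1], sex-specific dispersal, and
regulation back to `N + N` breeders per patch: each slot is won by a
philopatric native with probability `(1−m)F_p / ((1−m)F_p + mF̄)` and by
an immigrant from a fecundity-weighted source patch otherwise. All
randomness flows from one seeded generator in a fixed draw order, so runs
are bit-reproducible.

Three composition details keep the simulator the exact counterpart of the
`competition="local"` analytics, and were fixed by matching the two
structures term-by-term in a linearised expansion:

* a patch's juvenile supply `F_p` counts each adult's fecundity once
  (sum / 2, times the patch contest multiplier once) — a pair-product
  supply would let patch-level fecundity deviations act twice (once per
  parent) and double kin competition;
* the between-group multiplier scales a mated pair's joint output once;
* within-group exposure `q` is propensity-based and excludes both
  combatants, because realised-hand exposure lets a fighter's own
  handedness dull its opponents' naivety — an O(1/N) self-shadowing
  absent from the analytic marginalisation. Contest stakes enter as
  expected success (win probabilities, standing for many small
  contests), which also keeps all multipliers inside their analytic
  bounds.

Monogamy couples the fecundities of mates (a couple's output reflects
both parents), which the individual-fitness analytics do not model; the
quantitative validation therefore uses `mating="random"`, where maternity
and paternity are drawn independently in proportion to each parent's own
fecundity. Monogamy remains the default for relatedness and for
gene-dropping, where neutrality makes the coupling irrelevant.

**Gene-dropping mode** runs the life cycle neutrally from unique founder
alleles and measures within-patch identity. In a finite world all
lineages slowly coalesce, so the infinite-island prediction corresponds
to the *excess* identity `(Q_within − Q_between)/(1 − Q_between)`; the
affine structure of the identity recursions makes this correction exact
up to the slow drift of the background. Validation sizes: `N = 5`,
`m = 0.2`, 200 patches, 600 generations (200 burn-in, sampling every 20),
10 replicates; agreement with the fixed point is well within the
replicate standard error.

**Evolutionary mode** is validated against `solve_ess(...,
competition="local")` at `N = 10`, `m = 0.3`, random mating, 200 patches,
8000 generations from `init_x = 0.5`, 5 replicates, mutation rate 0.02
and mutational standard deviation 0.05 per allele. The validation
configurations use stronger stakes than the analysis defaults
(within-group: `a = 0.2, k = 0.1, B = 0.6`; between-group: `a = 0.25,
k = 0.02, G = 1.6`) so that equilibria sit near 0.5 — far from the
allele-clamping boundaries, whose truncation otherwise drags the
stationary mean toward the interior — and selection is strong enough to
converge well inside the run length. Final-epoch summaries average the
last 20% of generations, with a batch-means Monte-Carlo standard error.

What the simulator does and does not show: it confirms the identity fixed
point, the analytic island-composition equilibria (including the
cancellation: under the island life cycle the long-run propensity is
nearly flat in dispersal, so dispersal contrasts are *not* resolvable by
simulation there), determinism, and census conservation. It does not
emulate real human demography — patch sizes, dispersal and contest
payoffs are stylised — so passing tests certify internal consistency of
theory and implementation, not empirical adequacy.

## Degenerate inputs and numerical edges

`m = 1` gives zero relatedness and the panmictic equilibrium exactly;
`m = 0` drives identity to 1 (the linear solver handles the limit; the
closed patch is a consistency check, not a biologically interesting
case). `N = 1` is supported (sibship probability 1). Root bracketing
stays 1e−9 off the boundaries to avoid clamped-probability kinks.
Equality of per-origin optima is declared below 1e−7 (solver tolerance is
1e−10). `haploid-check-mode` requires a single dispersal rate and exists
only to check the solver against the closed form.

## Known limitations

* The "global" default and "local" island composition bracket, rather
  than resolve, the real scale-of-competition question; intermediate
  scales are not implemented.
* Battleground only: no arms-race resolution dynamics for
  parent-offspring or intragenomic conflict, and no coevolution of
  offspring and parental control loci in one simulation run.
* No sexual antagonism constraint between the sex-specific optima; no
  X-linkage; no overlapping generations; no stochastic-expression
  ("chaotic voice") variant for developmental-instability loci.
* The empirical incidence figures for human handedness are not
  calibration targets; the package's outputs are comparative predictions.
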