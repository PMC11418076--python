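# handedkin

Kin-selection modelling of the evolution of human handedness.

About 10% of humans are left-handed, a low but persistent minority that
game-theoretic accounts explain by negative frequency-dependent selection:
left-handers suffer a basic disadvantage but enjoy a "surprise" advantage
in combat against opponents used to fighting right-handers. Those combat
games are social interactions — and social partners in small-scale human
groups are relatives. `handedkin` works out what kin selection does to
this balance: how relatedness between groupmates (set by group size and
sex-specific dispersal) shifts the evolutionarily favoured incidence of
left-handedness, how it generates sex differences, parent–offspring and
mother–father conflicts over an offspring's handedness, and conflicts
between the maternal-origin and paternal-origin copies of handedness
genes — culminating in testable genomic-imprinting predictions.

The package is aimed at evolutionary biologists and geneticists who want
the framework as runnable, checkable code: a library first, with worked
examples in `examples/` and a thin `handedkin` command-line interface.

## The model in brief

Hamilton's rule says a trait is favoured when `−c + r·b > 0`, with `c` the
actor's direct fitness cost, `b` the partners' benefit and `r` their
relatedness. Left-handedness propensity `x` is the evolving trait; a
left-hander beats a right-hander with probability `½ + a(1 − q)` (`q` the
opponent's accustomed exposure to left-handers) and pays fecundity cost
`k`. Two scenarios fix who receives `b`:

* **within-group combat** (stakes `B`): the loser is a groupmate, so at
  equilibrium the trait is *marginally selfish* (c < 0, b < 0) and higher
  relatedness favours **less** left-handedness;
* **between-group combat** (group stakes `G`): success boosts the whole
  group, so the trait is *marginally altruistic* (c > 0, b > 0) and
  higher relatedness favours **more** left-handedness.

Relatedness comes from an infinite-island model with `N` breeding pairs
per patch and sex-specific dispersal rates `m_f`, `m_m`, solved as a small
linear identity-by-descent system — including relatedness through each
parent and through each parental-origin half of the genome. The
evolutionarily stable incidence is the root of the selection gradient
`S(x) = −c(x) + r_party·b(x)`, where `r_party` depends on who controls
the phenotype (the individual, a parent, or a single parental-origin
gene). An individual-based island simulator validates the analytics. See
`docs/methods.md` for the full model and the design decisions.

## Worked example

```python
from handedkin import ControlParty, Demography, GameParams, solve_ess

demog = Demography(n_breeders_per_sex=10, dispersal_female=0.3, dispersal_male=0.3)
for scenario in ("within_group", "between_group"):
    res = solve_ess(ControlParty.INDIVIDUAL_POOLED, GameParams(scenario), demog)
    print(scenario, round(res.x_star, 4), res.classification)
```

prints

```
within_group 0.7898 selfish
between_group 0.5681 altruistic
```

With groupmate relatedness r ≈ 0.046 (N = 10, m = 0.3), the favoured
incidence of left-handedness settles at 0.79 in the within-group game —
*below* its panmictic value of 0.80, because harming relatives is
discounted — and at 0.57 in the between-group game, *above* its panmictic
value of 0.19, because helping relatives is rewarded. Sweeping dispersal
(`examples/03_ess_and_dispersal_sweep.py`) traces the two opposite
comparative-statics curves; `examples/04_battleground_and_imprinting.py`
prints each party's optimum under female-biased dispersal and the
resulting eight-cell imprinting table (e.g. a left-handedness promoter is
predicted maternally expressed and paternally silenced when combat is
within-group and dispersal female-biased).

The same machinery is scriptable from the shell:

```bash
handedkin ess --scenario within --N 10 --mf 0.3 --mm 0.3 --out runs/
handedkin sweep --grid 0.05:1.0:0.05 --out runs/
handedkin reproduce-fig3 --out runs/
handedkin relatedness --fam pedigree.tsv --i child1 --j child2 --out runs/
```

Each invocation writes its table (TSV/JSON) plus a run manifest recording
the full parameter set, seed and package version; pedigree input is a
PLINK-style `id sex mother father` table with `0`/empty marking founders.

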