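"""ESS analysis: selection gradients, equilibria, and conflict battlegrounds.

The selection gradient follows Hamilton's rule in its marginal
(Taylor-Frank neighbour-modulated) form,

    S(x) = -c(x) + r_party * b(x),

where c and b are the marginal direct cost and partner benefit of the trait
evaluated in a monomorphic resident population at x, and ``r_party`` is the
relatedness ratio appropriate to whichever party controls the phenotype:

* the individual itself (possibly sex-specific) -- its others-only
  relatedness to a random patch-mate;
* a parent -- the ratio r_parent_to_group / r_parent_to_offspring, because
  a parent trades its offspring's direct fitness against the groupmates'
  fitness in units of its own relatedness to each;
* a single parental-origin gene -- the per-origin relatedness of that
  genome half to a random patch-mate.

Negative frequency dependence of the surprise advantage makes S decreasing
in x, giving a unique interior threshold where selection favours neither
more nor less left-handedness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .demography import Demography, RelatednessSet, island_relatedness
from .errors import MultipleRootsError
from .games import (
    DEFAULT_COMPETITION,
    Competition,
    GameParams,
    StrategyProfile,
    marginal_effects,
)

ROOT_TOL = 1e-10
_EDGE = 1e-9  # root bracketing kept off the exact boundary
_SCAN_POINTS = 257


class ControlParty(str, enum.Enum):
    """Which party's genes control the handedness phenotype."""

    INDIVIDUAL_FEMALE = "individual_female"
    INDIVIDUAL_MALE = "individual_male"
    INDIVIDUAL_POOLED = "individual_pooled"
    MOTHER = "mother"
    FATHER = "father"
    MATERNAL_ORIGIN_GENE = "maternal_origin_gene"
    PATERNAL_ORIGIN_GENE = "paternal_origin_gene"


def party_relatedness(party: ControlParty | str, rset: RelatednessSet) -> float:
    """The relatedness ratio weighting b against c for the controlling party."""
    party = ControlParty(party)
    if party is ControlParty.INDIVIDUAL_FEMALE:
        return rset.r_individual("female")
    if party is ControlParty.INDIVIDUAL_MALE:
        return rset.r_individual("male")
    if party is ControlParty.INDIVIDUAL_POOLED:
        return rset.r_individual()
    if party is ControlParty.MOTHER:
        return rset.parent_valuation_ratio("female")
    if party is ControlParty.FATHER:
        return rset.parent_valuation_ratio("male")
    if party is ControlParty.MATERNAL_ORIGIN_GENE:
        return rset.r_group_origin["maternal"]
    return rset.r_group_origin["paternal"]


@dataclass(frozen=True)
class ESSResult:
    """Candidate evolutionary equilibrium for one controlling party."""

    party: ControlParty
    x_star: float
    boundary: bool
    classification: str  # "selfish" | "altruistic" | "neutral" | "boundary"
    convergence_stable: bool
    gradient_residual: float
    marginal_c: float
    marginal_b: float
    r_party: float


def selection_gradient(
    x: float,
    party: ControlParty | str,
    params: GameParams,
    demog: Demography,
    rset: RelatednessSet | None = None,
    competition: Competition = DEFAULT_COMPETITION,
) -> float:
    """S(x) = -c + r_party b at a monomorphic resident trait value x."""
    if rset is None:
        rset = island_relatedness(demog)
    r = party_relatedness(party, rset)
    c, b = marginal_effects(StrategyProfile.monomorphic(x), params, demog, competition=competition)
    return -c + r * b


def _interior_roots(f, lo: float, hi: float, n: int = _SCAN_POINTS) -> list[float]:
    """All sign-change roots of f on [lo, hi], located by scan + Brent."""
    xs = np.linspace(lo, hi, n)
    vals = np.array([f(x) for x in xs])
    roots: list[float] = []
    for i in range(len(xs) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(xs[i]))
        elif a * b < 0.0:
            roots.append(float(brentq(f, xs[i], xs[i + 1], xtol=ROOT_TOL)))
    if vals[-1] == 0.0:
        roots.append(float(xs[-1]))
    # collapse near-duplicates from grid-point hits
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-7:
            dedup.append(r)
    return dedup


def solve_ess(
    party: ControlParty | str,
    params: GameParams,
    demog: Demography,
    rset: RelatednessSet | None = None,
    competition: Competition = DEFAULT_COMPETITION,
) -> ESSResult:
    """Locate the evolutionarily favoured trait value for a controlling party.

    Returns the interior root of the selection gradient when one exists, and
    otherwise the boundary (0 if selection pushes down everywhere, 1 if up).
    Convergence stability is read from the sign change of the gradient
    across the equilibrium.
    """
    party = ControlParty(party)
    if rset is None:
        rset = island_relatedness(demog)
    r = party_relatedness(party, rset)

    def grad(x: float) -> float:
        c, b = marginal_effects(StrategyProfile.monomorphic(x), params, demog, competition=competition)
        return -c + r * b

    roots = _interior_roots(grad, _EDGE, 1.0 - _EDGE)
    if len(roots) > 1:
        raise MultipleRootsError(roots)

    if roots:
        x_star = roots[0]
        boundary = False
        residual = abs(grad(x_star))
        slope = (grad(min(1.0 - _EDGE, x_star + 1e-4)) - grad(max(_EDGE, x_star - 1e-4))) / 2e-4
        stable = slope < 0.0
    else:
        g0 = grad(_EDGE)
        x_star = 1.0 if g0 > 0.0 else 0.0
        boundary = True
        residual = abs(g0 if x_star == 0.0 else grad(1.0 - _EDGE))
        stable = True  # selection pushes toward the boundary throughout

    c, b = marginal_effects(StrategyProfile.monomorphic(x_star), params, demog, competition=competition)
    if boundary:
        classification = "boundary"
    elif abs(c) < 1e-12 and abs(b) < 1e-12:
        classification = "neutral"
    elif c < 0.0 and b < 0.0:
        classification = "selfish"
    elif c > 0.0 and b > 0.0:
        classification = "altruistic"
    else:
        classification = "mixed"  # not expected at an interior ESS with r > 0
    return ESSResult(
        party=party,
        x_star=x_star,
        boundary=boundary,
        classification=classification,
        convergence_stable=stable,
        gradient_residual=residual,
        marginal_c=c,
        marginal_b=b,
        r_party=r,
    )


def sex_difference(
    params: GameParams,
    demog: Demography,
    sex_specific_params: dict[str, GameParams] | None = None,
    competition: Competition = DEFAULT_COMPETITION,
) -> tuple[ESSResult, ESSResult]:
    """Female and male optima under sex-specific relatedness (and, optionally,
    sex-specific payoff parameters encoding e.g. more frequent male combat).

    Each sex's optimum is solved against a resident population of its own
    trait value; cross-sex genetic correlation is out of scope.
    """
    sex_specific_params = sex_specific_params or {}
    rset = island_relatedness(demog)
    res_f = solve_ess(
        ControlParty.INDIVIDUAL_FEMALE, sex_specific_params.get("female", params), demog, rset,
        competition=competition,
    )
    res_m = solve_ess(
        ControlParty.INDIVIDUAL_MALE, sex_specific_params.get("male", params), demog, rset,
        competition=competition,
    )
    return res_f, res_m


BATTLEGROUND_PARTIES = [
    ControlParty.INDIVIDUAL_POOLED,
    ControlParty.INDIVIDUAL_FEMALE,
    ControlParty.INDIVIDUAL_MALE,
    ControlParty.MOTHER,
    ControlParty.FATHER,
    ControlParty.MATERNAL_ORIGIN_GENE,
    ControlParty.PATERNAL_ORIGIN_GENE,
]

#: optima closer than this are reported as coinciding (no conflict)
CONFLICT_TOL = 1e-7


@dataclass(frozen=True)
class Battleground:
    """Every party's optimum plus pairwise conflict indicators.

    ``conflicts[(p1, p2)]`` is the sign (+1/0/-1) of x_star(p1) - x_star(p2);
    a non-zero sign marks an evolutionary conflict of interests (battleground
    only -- no arms-race resolution dynamics are modelled).
    """

    results: dict[ControlParty, ESSResult]
    conflicts: dict[tuple[ControlParty, ControlParty], int]

    def optimum(self, party: ControlParty | str) -> float:
        return self.results[ControlParty(party)].x_star


def battleground(
    params: GameParams,
    demog: Demography,
    parties: list[ControlParty] | None = None,
    competition: Competition = DEFAULT_COMPETITION,
) -> Battleground:
    """Solve every party's ESS and tabulate the pairwise optimum orderings."""
    parties = parties or BATTLEGROUND_PARTIES
    rset = island_relatedness(demog)
    results = {p: solve_ess(p, params, demog, rset, competition=competition) for p in parties}
    conflicts = {}
    for p1 in parties:
        for p2 in parties:
            if p1 is p2:
                continue
            d = results[p1].x_star - results[p2].x_star
            conflicts[(p1, p2)] = 0 if abs(d) <= CONFLICT_TOL else (1 if d > 0 else -1)
    return Battleground(results=results, conflicts=conflicts)
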