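"""Frequency-dependent combat fitness scenarios.

Two illustrative scenarios give left-handedness its negative
frequency-dependent payoff:

* **within-group combat** -- each adult fights one uniformly random
  patch-mate; winning raises own fecundity by a factor (1 + B(2p - 1)).
  The surprise advantage is harvested from relatives, so at equilibrium the
  trait is marginally selfish.
* **between-group combat** -- each patch member fights one member of a
  random other patch; the patch's mean success s multiplies every member's
  fecundity by (1 + G(2s - 1)).  The advantage is shared with relatives, so
  at equilibrium the trait is marginally altruistic.

A left-hander fighting a right-hander wins with probability
1/2 + a (1 - q), where q is the frequency of left-handers among the
opponent's accustomed adversaries (the local pool for within-group combat,
the global pool for between-group combat): the surprise advantage is
maximal when left-handers are vanishingly rare and vanishes when they are
ubiquitous.  Left-handers pay a proportional fecundity cost k (the basic
disadvantage) regardless of combat.

Fitness is neighbour-modulated (Taylor-Frank): the focal adult's expected
fecundity competes against the patch mean among philopatric offspring and
against the global mean among dispersed offspring, per the island-model
life cycle of :mod:`handedkin.demography`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from .demography import Demography
from .errors import ParameterError, ValidationError

Hand = Literal["left", "right"]

#: Baseline parameters.  Chosen so that both scenarios exhibit an interior,
#: negatively frequency-dependent equilibrium across the dispersal range of
#: interest (see docs/methods.md); a and B/G are weak enough that fecundity
#: multipliers stay positive and the weak-selection analysis applies.
DEFAULT_A = 0.1
DEFAULT_K = 0.02
DEFAULT_B = 0.5
DEFAULT_G = 2.5

#: How offspring compete for breeding slots when fitness is assembled.
#: "global": fecundity is normalised by the global mean only -- density
#: regulation is decoupled from the social interaction, so relatedness
#: effects act at full strength (the regime in which dispersal modulates
#: the equilibrium; the package default).
#: "local": the full island composition -- philopatric offspring compete
#: against the patch mean fecundity, dispersed offspring against the global
#: mean.  Kin competition then exactly offsets relatedness benefits
#: (Taylor's cancellation) and dispersal drops out of the equilibrium; kept
#: for cross-validation against the individual-based simulator's island
#: life cycle.  See docs/methods.md.
Competition = Literal["global", "local"]
DEFAULT_COMPETITION: Competition = "global"


@dataclass(frozen=True)
class GameParams:
    """Combat scenario and its payoff parameters.

    surprise_advantage (a): maximum increment to the win probability of a
    left-hander facing a right-hander when left-handers are vanishingly rare.
    handedness_cost (k): proportional fecundity cost paid by left-handers.
    stakes (B): fecundity consequence of winning vs losing a within-group duel.
    group_stakes (G): scaling of group fecundity by between-group success.
    """

    scenario: Literal["within_group", "between_group"]
    surprise_advantage: float = DEFAULT_A
    handedness_cost: float = DEFAULT_K
    stakes: float = DEFAULT_B
    group_stakes: float = DEFAULT_G

    def __post_init__(self):
        if self.scenario not in ("within_group", "between_group"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        for name in ("surprise_advantage", "handedness_cost", "stakes", "group_stakes"):
            val = getattr(self, name)
            if not (val >= 0.0 and val == val and val != float("inf")):
                raise ValidationError(f"{name} must be finite and non-negative")
        if self.handedness_cost > 1.0:
            raise ValidationError("handedness_cost > 1 gives negative fecundity")

    def with_scenario(self, scenario: str) -> "GameParams":
        return replace(self, scenario=scenario)


@dataclass(frozen=True)
class StrategyProfile:
    """Trait values: focal individual, patch-mates (others-only mean), population."""

    x_focal: float
    x_group: float
    x_pop: float

    def __post_init__(self):
        for name in ("x_focal", "x_group", "x_pop"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {x}")

    @classmethod
    def monomorphic(cls, x: float) -> "StrategyProfile":
        return cls(x, x, x)


def win_probability(
    hand_focal: Hand, hand_opponent: Hand, q_exposure: float, params: GameParams
) -> float:
    """Probability the focal wins a duel.

    Same-handedness pairings are even; a left-hander beats a right-hander
    with probability 1/2 + a (1 - q), clamped to [0, 1], where q is the
    left-hander frequency the opponent is accustomed to.  The mirror pairing
    is the complement, so probability is conserved exactly.
    """
    if not 0.0 <= q_exposure <= 1.0:
        raise ValidationError(f"q_exposure must lie in [0, 1], got {q_exposure}")
    for h in (hand_focal, hand_opponent):
        if h not in ("left", "right"):
            raise ValidationError(f"unknown handedness {h!r}")
    if hand_focal == hand_opponent:
        return 0.5
    edge = min(params.surprise_advantage * (1.0 - q_exposure), 0.5)
    return 0.5 + edge if hand_focal == "left" else 0.5 - edge


def _duel_win_given_hand(hand: Hand, p_opponent_left: float, q: float, params: GameParams) -> float:
    """Win probability given own hand, marginal over the opponent's hand."""
    return p_opponent_left * win_probability(hand, "left", q, params) + (
        1.0 - p_opponent_left
    ) * win_probability(hand, "right", q, params)


def expected_fecundities(
    profile: StrategyProfile, params: GameParams, demog: Demography
) -> dict[str, float]:
    """Exact expected fecundities: focal, a patch-mate, the patch mean, and the
    (monomorphic) global mean.

    Expectations marginalise jointly over the focal's and opponents'
    realised handedness (the cost and the contest outcome are correlated
    through own handedness), so they agree with exhaustive enumeration of
    all handedness realisations.
    """
    k, B, G = params.handedness_cost, params.stakes, params.group_stakes
    xf, xg, xp = profile.x_focal, profile.x_group, profile.x_pop
    n_adults = 2 * demog.n_breeders_per_sex

    def cost(hand_is_left: bool) -> float:
        return 1.0 - k if hand_is_left else 1.0

    if params.scenario == "within_group":
        q = xg  # opponents are accustomed to their local adversaries
        # focal's opponent is a uniformly random patch-mate (trait x_group);
        # a patch-mate's opponent includes the focal with weight 1/(2N-1)
        x_mix = (xf + (n_adults - 2) * xg) / (n_adults - 1) if n_adults > 1 else xf
        f_focal = sum(
            p_h * cost(left) * (1.0 + B * (2.0 * _duel_win_given_hand(h, xg, q, params) - 1.0))
            for h, left, p_h in (("left", True, xf), ("right", False, 1.0 - xf))
        )
        f_other = sum(
            p_h * cost(left) * (1.0 + B * (2.0 * _duel_win_given_hand(h, x_mix, q, params) - 1.0))
            for h, left, p_h in (("left", True, xg), ("right", False, 1.0 - xg))
        )
        f_pop = sum(
            p_h * cost(left) * (1.0 + B * (2.0 * _duel_win_given_hand(h, xp, xp, params) - 1.0))
            for h, left, p_h in (("left", True, xp), ("right", False, 1.0 - xp))
        )
        if min(f_focal, f_other, f_pop) <= 0.0:
            raise ParameterError("within-group stakes B yield non-positive fecundity")
    else:
        q = xp  # opponents come from, and are accustomed to, the global pool
        pw_focal_mean = xf * _duel_win_given_hand("left", xp, q, params) + (
            1.0 - xf
        ) * _duel_win_given_hand("right", xp, q, params)
        pw_other_mean = xg * _duel_win_given_hand("left", xp, q, params) + (
            1.0 - xg
        ) * _duel_win_given_hand("right", xp, q, params)

        def member_fec(x_self: float, others_mean_win: float) -> float:
            # patch success s averages the member's own win (weight 1/2N)
            # with its 2N-1 patch-mates'; conditioning on own hand keeps the
            # cost-success correlation exact
            total = 0.0
            for h, left, p_h in (("left", True, x_self), ("right", False, 1.0 - x_self)):
                s = (_duel_win_given_hand(h, xp, q, params) + (n_adults - 1) * others_mean_win) / n_adults
                total += p_h * cost(left) * (1.0 + G * (2.0 * s - 1.0))
            return total

        others_for_focal = pw_other_mean
        others_for_other = (
            (pw_focal_mean + (n_adults - 2) * pw_other_mean) / (n_adults - 1)
            if n_adults > 1
            else pw_focal_mean
        )
        f_focal = member_fec(xf, others_for_focal)
        f_other = member_fec(xg, others_for_other)
        f_pop = member_fec(xp, 0.5)
        if min(f_focal, f_other, f_pop) <= 0.0:
            raise ParameterError("between-group stakes G yield non-positive fecundity")

    f_patch_mean = (f_focal + (n_adults - 1) * f_other) / n_adults
    return {
        "focal": f_focal,
        "other": f_other,
        "patch_mean": f_patch_mean,
        "global_mean": f_pop,
    }


def _relative_fitness(
    profile: StrategyProfile,
    params: GameParams,
    demog: Demography,
    competition: Competition = DEFAULT_COMPETITION,
) -> float:
    fec = expected_fecundities(profile, params, demog)
    if competition == "global":
        return fec["focal"] / fec["global_mean"]
    if competition != "local":
        raise ValidationError(f"unknown competition structure {competition!r}")
    w = 0.0
    for m in (demog.dispersal_female, demog.dispersal_male):
        local = (1.0 - m) * fec["focal"] / ((1.0 - m) * fec["patch_mean"] + m * fec["global_mean"])
        away = m * fec["focal"] / fec["global_mean"]
        w += 0.5 * (local + away)
    return w


def fitness_within_group(
    profile: StrategyProfile,
    params: GameParams,
    demog: Demography,
    competition: Competition = DEFAULT_COMPETITION,
) -> float:
    """Expected relative fitness of a focal adult under within-group combat."""
    if params.scenario != "within_group":
        params = params.with_scenario("within_group")
    return _relative_fitness(profile, params, demog, competition)


def fitness_between_group(
    profile: StrategyProfile,
    params: GameParams,
    demog: Demography,
    competition: Competition = DEFAULT_COMPETITION,
) -> float:
    """Expected relative fitness of a focal adult under between-group combat."""
    if params.scenario != "between_group":
        params = params.with_scenario("between_group")
    return _relative_fitness(profile, params, demog, competition)


def fitness(
    profile: StrategyProfile,
    params: GameParams,
    demog: Demography,
    competition: Competition = DEFAULT_COMPETITION,
) -> float:
    """Scenario-dispatching relative fitness."""
    return _relative_fitness(profile, params, demog, competition)


#: central-difference step for the marginal fitness effects; the trait space
#: [0, 1] is well-conditioned at this scale
DERIVATIVE_STEP = 1e-6


def marginal_effects(
    profile: StrategyProfile,
    params: GameParams,
    demog: Demography,
    step: float = DERIVATIVE_STEP,
    competition: Competition = DEFAULT_COMPETITION,
) -> tuple[float, float]:
    """Marginal direct cost c = -dw/dx_focal and partner benefit b = dw/dx_group.

    Signs follow Hamilton's convention: an altruistic trait has c > 0 and
    b > 0.  Central finite differences with the stencil clipped into [0, 1].
    """

    def deriv(attr: str) -> float:
        x0 = getattr(profile, attr)
        lo, hi = max(0.0, x0 - step), min(1.0, x0 + step)
        w_hi = _relative_fitness(replace(profile, **{attr: hi}), params, demog, competition)
        w_lo = _relative_fitness(replace(profile, **{attr: lo}), params, demog, competition)
        return (w_hi - w_lo) / (hi - lo)

    return -deriv("x_focal"), deriv("x_group")
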