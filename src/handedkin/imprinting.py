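"""Parent-of-origin expression predictions via "loudest voice prevails".

When maternal-origin and paternal-origin genes favour different levels of
left-handedness, the two copies of a gene at an affected locus are favoured
to push expression in opposite directions until the copy favouring less
expression falls silent.  The direction of the imprint then depends on the
gene product's function:

* at a *promoter* locus (more expression -> more left-handedness) the
  origin with the **higher** left-handedness optimum remains expressed;
* at an *inhibitor* locus (more expression -> less left-handedness) the
  origin with the **lower** optimum remains expressed.

Equal optima mean no conflict and no imprint (both copies expressed).
Phenotypic consequences of perturbations (deletion, duplication,
epimutational silencing, uniparental disomy) follow from a two-copy dosage
bookkeeping: silenced copies contribute no product, so e.g. deleting an
already-silenced copy changes nothing, while deleting the expressed copy
abolishes the locus's product entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .demography import Demography
from .errors import ValidationError
from .games import Competition, DEFAULT_COMPETITION, GameParams
from .selection import ControlParty, solve_ess
from .demography import island_relatedness

#: per-origin optima closer than this count as coinciding (no imprint)
OPTIMA_TOL = 1e-7


class LocusType(str, enum.Enum):
    PROMOTER = "promoter"  # increased expression increases left-handedness
    INHIBITOR = "inhibitor"  # increased expression decreases left-handedness


class Perturbation(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"
    EPIMUTATION = "epimutation"  # aberrant silencing of the affected copy
    UNIPARENTAL_DISOMY = "uniparental_disomy"  # two copies from the affected origin


class Effect(str, enum.Enum):
    NONE = "none"
    SHIFT_HIGHER_LEFT = "shift_toward_higher_left"
    SHIFT_LOWER_LEFT = "shift_toward_lower_left"
    LOSS_OF_FUNCTION_MAJOR = "loss_of_function_major"


@dataclass(frozen=True)
class LocusSpec:
    """A handedness locus: its functional direction and the per-origin optima."""

    locus_type: LocusType
    optimum_maternal_origin: float
    optimum_paternal_origin: float

    def __post_init__(self):
        for name in ("optimum_maternal_origin", "optimum_paternal_origin"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValidationError(f"{name} must be finite")


@dataclass(frozen=True)
class ImprintPrediction:
    """Which parental copy is expressed/silenced, and why."""

    expressed_origin: str  # "maternal" | "paternal" | "both"
    silenced_origin: str  # complement, or "none"
    rationale_tag: str  # e.g. "selfish/maternal-favours-higher"


@dataclass(frozen=True)
class PerturbationOutcome:
    perturbation: Perturbation
    affected_origin: str
    predicted_effect: Effect
    #: direction of the phenotypic shift accompanying a major loss of
    #: function (Effect.NONE direction otherwise redundant)
    shift_direction: Effect


def predict_imprint(locus: LocusSpec) -> ImprintPrediction:
    """Resolution endpoint of the intragenomic tug-of-war at one locus."""
    om, op = locus.optimum_maternal_origin, locus.optimum_paternal_origin
    if abs(om - op) <= OPTIMA_TOL:
        return ImprintPrediction("both", "none", "no-conflict")
    maternal_higher = om > op
    if locus.locus_type is LocusType.PROMOTER:
        expressed = "maternal" if maternal_higher else "paternal"
    else:
        expressed = "paternal" if maternal_higher else "maternal"
    silenced = "paternal" if expressed == "maternal" else "maternal"
    tag = "maternal-favours-higher" if maternal_higher else "paternal-favours-higher"
    return ImprintPrediction(expressed, silenced, tag)


def per_origin_optima(
    params: GameParams,
    demog: Demography,
    competition: Competition = DEFAULT_COMPETITION,
) -> tuple[float, float]:
    """(maternal-origin, paternal-origin) favoured trait values."""
    rset = island_relatedness(demog)
    om = solve_ess(ControlParty.MATERNAL_ORIGIN_GENE, params, demog, rset, competition=competition)
    op = solve_ess(ControlParty.PATERNAL_ORIGIN_GENE, params, demog, rset, competition=competition)
    return om.x_star, op.x_star


def imprint_table(
    params: GameParams,
    demog: Demography,
    competition: Competition = DEFAULT_COMPETITION,
) -> dict[tuple[str, str, str], ImprintPrediction]:
    """The 2 x 2 x 2 prediction table over scenario x dispersal bias x locus type.

    ``demog`` supplies the patch size and the magnitudes of the two
    dispersal rates; the female-biased cell assigns the larger rate to
    females, the male-biased cell the larger rate to males.  Requires
    unequal rates (otherwise no cell carries a conflict).
    """
    hi = max(demog.dispersal_female, demog.dispersal_male)
    lo = min(demog.dispersal_female, demog.dispersal_male)
    if hi == lo:
        raise ValidationError(
            "imprint_table needs a dispersal-biased demography (m_f != m_m)"
        )
    biased = {
        "female_biased": Demography(
            demog.n_breeders_per_sex, hi, lo, demog.mating, demog.genetic_system
        ),
        "male_biased": Demography(
            demog.n_breeders_per_sex, lo, hi, demog.mating, demog.genetic_system
        ),
    }
    table: dict[tuple[str, str, str], ImprintPrediction] = {}
    for scenario in ("within_group", "between_group"):
        scen_params = params.with_scenario(scenario)
        for bias, d in biased.items():
            om, op = per_origin_optima(scen_params, d, competition=competition)
            for locus_type in LocusType:
                locus = LocusSpec(locus_type, om, op)
                table[(scenario, bias, locus_type.value)] = predict_imprint(locus)
    return table


def predict_perturbation(
    prediction: ImprintPrediction,
    locus: LocusSpec,
    perturbation: Perturbation | str,
    affected_origin: str,
) -> PerturbationOutcome:
    """Phenotypic consequence of perturbing one parental copy.

    Dosage bookkeeping: each origin's copy contributes 1 unit of product if
    expressed, 0 if silenced.  A deletion or epimutational silencing zeroes
    the affected copy; a duplication doubles it; a uniparental disomy
    replaces the *other* origin's copy with a second copy of the affected
    origin's state.  The phenotype shifts with total product in the
    direction set by the locus type; total product of zero where there was
    expression is a major loss of function.
    """
    perturbation = Perturbation(perturbation)
    if affected_origin not in ("maternal", "paternal"):
        raise ValidationError(f"unknown origin {affected_origin!r}")
    if prediction.expressed_origin not in ("maternal", "paternal", "both"):
        raise ValidationError(f"inconsistent prediction {prediction!r}")

    dose = {
        "maternal": 1 if prediction.expressed_origin in ("maternal", "both") else 0,
        "paternal": 1 if prediction.expressed_origin in ("paternal", "both") else 0,
    }
    baseline = dose["maternal"] + dose["paternal"]
    other = "paternal" if affected_origin == "maternal" else "maternal"

    new = dict(dose)
    if perturbation in (Perturbation.DELETION, Perturbation.EPIMUTATION):
        new[affected_origin] = 0
    elif perturbation is Perturbation.DUPLICATION:
        new[affected_origin] = 2 * dose[affected_origin]
    else:  # uniparental disomy of the affected origin
        new[other] = dose[affected_origin]
    total = new["maternal"] + new["paternal"]

    up = (
        Effect.SHIFT_HIGHER_LEFT
        if locus.locus_type is LocusType.PROMOTER
        else Effect.SHIFT_LOWER_LEFT
    )
    down = Effect.SHIFT_LOWER_LEFT if up is Effect.SHIFT_HIGHER_LEFT else Effect.SHIFT_HIGHER_LEFT

    if total == baseline:
        effect = shift = Effect.NONE
    elif total == 0 and baseline > 0:
        effect, shift = Effect.LOSS_OF_FUNCTION_MAJOR, down
    elif total > baseline:
        effect = shift = up
    else:
        effect = shift = down
    return PerturbationOutcome(perturbation, affected_origin, effect, shift)
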