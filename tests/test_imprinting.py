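"""Loudest-voice-prevails imprinting predictions and perturbation outcomes."""

import itertools

import pytest

from handedkin import (
    Demography,
    Effect,
    GameParams,
    ImprintPrediction,
    LocusSpec,
    LocusType,
    Perturbation,
    ValidationError,
    imprint_table,
    predict_imprint,
    predict_perturbation,
)


def test_promoter_expresses_the_origin_favouring_more_left():
    # selfish scenario under female-biased dispersal: maternal-origin genes
    # favour the higher incidence
    locus = LocusSpec(LocusType.PROMOTER, 0.75, 0.70)
    pred = predict_imprint(locus)
    assert pred.expressed_origin == "maternal"
    assert pred.silenced_origin == "paternal"


def test_inhibitor_expresses_the_origin_favouring_less_left():
    locus = LocusSpec(LocusType.INHIBITOR, 0.75, 0.70)
    pred = predict_imprint(locus)
    assert pred.expressed_origin == "paternal"
    assert pred.silenced_origin == "maternal"


def test_equal_optima_mean_no_imprint():
    pred = predict_imprint(LocusSpec(LocusType.PROMOTER, 0.5, 0.5))
    assert pred.expressed_origin == "both"
    assert pred.silenced_origin == "none"


@pytest.fixture(scope="module")
def table():
    return imprint_table(GameParams("within_group"), Demography(10, 0.3, 0.1))


def test_eight_cell_table_matches_predictions(table):
    """Expression patterns across scenario x bias x locus type."""
    expected = {
        # selfish (within-group): promoters maternally expressed under
        # female-biased dispersal, maternally silenced under male-biased
        ("within_group", "female_biased", "promoter"): "maternal",
        ("within_group", "female_biased", "inhibitor"): "paternal",
        ("within_group", "male_biased", "promoter"): "paternal",
        ("within_group", "male_biased", "inhibitor"): "maternal",
        # altruistic (between-group): the reverse
        ("between_group", "female_biased", "promoter"): "paternal",
        ("between_group", "female_biased", "inhibitor"): "maternal",
        ("between_group", "male_biased", "promoter"): "maternal",
        ("between_group", "male_biased", "inhibitor"): "paternal",
    }
    assert len(table) == 8
    for cell, origin in expected.items():
        assert table[cell].expressed_origin == origin, cell


def test_antisymmetry_under_bias_flip(table):
    for (scenario, bias, locus), pred in table.items():
        other = "male_biased" if bias == "female_biased" else "female_biased"
        flipped = table[(scenario, other, locus)]
        assert pred.expressed_origin == flipped.silenced_origin
        assert pred.silenced_origin == flipped.expressed_origin


def test_duality_under_locus_type_flip(table):
    for (scenario, bias, locus), pred in table.items():
        other = "inhibitor" if locus == "promoter" else "promoter"
        dual = table[(scenario, bias, other)]
        assert pred.expressed_origin == dual.silenced_origin


def test_unbiased_dispersal_gives_no_imprint():
    with pytest.raises(ValidationError):
        imprint_table(GameParams("within_group"), Demography(10, 0.2, 0.2))
    # directly: per-origin optima coincide, so no conflict at either locus
    locus = LocusSpec(LocusType.PROMOTER, 0.61803, 0.61803)
    assert predict_imprint(locus).expressed_origin == "both"


# --- perturbations ---------------------------------------------------------


def test_deleting_the_silenced_copy_changes_nothing():
    locus = LocusSpec(LocusType.PROMOTER, 0.8, 0.7)
    pred = predict_imprint(locus)  # maternally expressed
    out = predict_perturbation(pred, locus, Perturbation.DELETION, "paternal")
    assert out.predicted_effect is Effect.NONE


def test_deleting_the_expressed_copy_is_major():
    locus = LocusSpec(LocusType.PROMOTER, 0.8, 0.7)
    pred = predict_imprint(locus)
    out = predict_perturbation(pred, locus, Perturbation.DELETION, "maternal")
    assert out.predicted_effect is Effect.LOSS_OF_FUNCTION_MAJOR
    assert out.shift_direction is Effect.SHIFT_LOWER_LEFT  # promoter product lost
    # losing an expressed inhibitor shifts the other way
    loc2 = LocusSpec(LocusType.INHIBITOR, 0.8, 0.7)
    pred2 = predict_imprint(loc2)  # paternally expressed
    out2 = predict_perturbation(pred2, loc2, Perturbation.DELETION, "paternal")
    assert out2.shift_direction is Effect.SHIFT_HIGHER_LEFT


def test_duplication_dosage_logic():
    locus = LocusSpec(LocusType.PROMOTER, 0.8, 0.7)
    pred = predict_imprint(locus)
    dup_expressed = predict_perturbation(pred, locus, Perturbation.DUPLICATION, "maternal")
    assert dup_expressed.predicted_effect is Effect.SHIFT_HIGHER_LEFT
    dup_silenced = predict_perturbation(pred, locus, Perturbation.DUPLICATION, "paternal")
    assert dup_silenced.predicted_effect is Effect.NONE


def test_uniparental_disomy_composes_deletion_and_duplication():
    locus = LocusSpec(LocusType.PROMOTER, 0.8, 0.7)
    pred = predict_imprint(locus)  # maternally expressed, paternally silenced
    # maternal disomy: two expressed maternal copies, no silent paternal copy
    upd_m = predict_perturbation(pred, locus, Perturbation.UNIPARENTAL_DISOMY, "maternal")
    assert upd_m.predicted_effect is Effect.SHIFT_HIGHER_LEFT
    # paternal disomy: two silenced copies -> no product at all
    upd_p = predict_perturbation(pred, locus, Perturbation.UNIPARENTAL_DISOMY, "paternal")
    assert upd_p.predicted_effect is Effect.LOSS_OF_FUNCTION_MAJOR


def test_perturbation_enumeration_is_total_and_consistent():
    """Every origin x perturbation x table cell maps to exactly one outcome,
    and outcomes obey the dosage bookkeeping re-derived independently."""
    table = imprint_table(GameParams("within_group"), Demography(10, 0.3, 0.1))
    n = 0
    for (scenario, bias, locus_type), pred in table.items():
        locus = LocusSpec(LocusType(locus_type), 0.0, 0.0)  # optima unused here
        for perturbation, origin in itertools.product(Perturbation, ("maternal", "paternal")):
            out = predict_perturbation(pred, locus, perturbation, origin)
            n += 1
            # independent re-derivation from the two-copy state space
            state = {
                "maternal": int(pred.expressed_origin in ("maternal", "both")),
                "paternal": int(pred.expressed_origin in ("paternal", "both")),
            }
            base = sum(state.values())
            if perturbation in (Perturbation.DELETION, Perturbation.EPIMUTATION):
                state[origin] = 0
            elif perturbation is Perturbation.DUPLICATION:
                state[origin] *= 2
            else:
                other = "paternal" if origin == "maternal" else "maternal"
                state[other] = state[origin]
            tot = sum(state.values())
            if tot == base:
                assert out.predicted_effect is Effect.NONE
            elif tot == 0:
                assert out.predicted_effect is Effect.LOSS_OF_FUNCTION_MAJOR
            else:
                assert out.predicted_effect in (
                    Effect.SHIFT_HIGHER_LEFT,
                    Effect.SHIFT_LOWER_LEFT,
                )
    assert n == 8 * 4 * 2


def test_inconsistent_inputs_rejected():
    locus = LocusSpec(LocusType.PROMOTER, 0.8, 0.7)
    pred = predict_imprint(locus)
    with pytest.raises(ValidationError):
        predict_perturbation(pred, locus, Perturbation.DELETION, "grandmaternal")
    with pytest.raises(ValidationError):
        predict_perturbation(
            ImprintPrediction("neither", "none", "bad"), locus, Perturbation.DELETION, "maternal"
        )
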