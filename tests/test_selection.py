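"""ESS analysis: gradients, equilibria, comparative statics, sex
differences and the conflict battleground."""

import numpy as np
import pytest

from handedkin import (
    ControlParty,
    Demography,
    GameParams,
    MultipleRootsError,
    battleground,
    island_relatedness,
    party_relatedness,
    selection_gradient,
    sex_difference,
    solve_ess,
)
from handedkin.games import marginal_effects, StrategyProfile
from handedkin.selection import _interior_roots


@pytest.fixture(scope="module")
def demog():
    return Demography(10, 0.3, 0.3)


def test_zero_relatedness_reduces_to_direct_gradient(demog):
    """With full dispersal the gradient is the panmictic -c."""
    full = Demography(10, 1.0, 1.0)
    gp = GameParams("within_group")
    for x in (0.2, 0.5, 0.8):
        c, _ = marginal_effects(StrategyProfile.monomorphic(x), gp, full)
        g = selection_gradient(x, "individual_pooled", gp, full)
        assert g == pytest.approx(-c, abs=1e-12)


def test_relatedness_shifts_gradient_by_scenario(demog):
    """More relatedness pushes the gradient down for the selfish scenario
    and up for the altruistic one."""
    low_r = Demography(10, 0.8, 0.8)
    high_r = Demography(10, 0.1, 0.1)
    x = 0.6
    gw_low = selection_gradient(x, "individual_pooled", GameParams("within_group"), low_r)
    gw_high = selection_gradient(x, "individual_pooled", GameParams("within_group"), high_r)
    assert gw_high < gw_low
    gb_low = selection_gradient(x, "individual_pooled", GameParams("between_group"), low_r)
    gb_high = selection_gradient(x, "individual_pooled", GameParams("between_group"), high_r)
    assert gb_high > gb_low


def test_interior_root_properties(demog):
    for scenario in ("within_group", "between_group"):
        res = solve_ess("individual_pooled", GameParams(scenario), demog)
        assert not res.boundary
        assert 0.0 < res.x_star < 1.0
        assert res.gradient_residual <= 1e-9
        assert res.convergence_stable
        g = selection_gradient(res.x_star, "individual_pooled", GameParams(scenario), demog)
        assert g == pytest.approx(0.0, abs=1e-9)


def test_pure_cost_is_purged(demog):
    gp = GameParams("within_group", surprise_advantage=0.0, handedness_cost=0.05)
    for party in ControlParty:
        res = solve_ess(party, gp, demog)
        assert res.boundary and res.x_star == 0.0


def test_comparative_statics_direction():
    """Favoured incidence rises with dispersal when the trait is selfish and
    falls when it is altruistic; full dispersal recovers the panmictic
    equilibrium in both scenarios."""
    ms = np.arange(0.05, 1.0001, 0.05)
    panmictic = {
        s: solve_ess("individual_pooled", GameParams(s), Demography(10, 1.0, 1.0)).x_star
        for s in ("within_group", "between_group")
    }
    for scenario, sign in (("within_group", 1), ("between_group", -1)):
        xs = [
            solve_ess("individual_pooled", GameParams(scenario), Demography(10, m, m)).x_star
            for m in ms
        ]
        assert all(sign * d >= -1e-9 for d in np.diff(xs)), scenario
        assert xs[-1] == pytest.approx(panmictic[scenario], abs=1e-9)


@pytest.mark.parametrize(
    "mf, mm, cmp_within", [(0.4, 0.1, "gt"), (0.1, 0.4, "lt"), (0.25, 0.25, "eq")]
)
def test_sex_difference_orderings(mf, mm, cmp_within):
    """The more-dispersing (less related) sex is favoured to be more
    left-handed when the trait is selfish, less when altruistic."""
    demog = Demography(10, mf, mm)
    f_w, m_w = sex_difference(GameParams("within_group"), demog)
    f_b, m_b = sex_difference(GameParams("between_group"), demog)
    if cmp_within == "gt":
        assert f_w.x_star > m_w.x_star
        assert f_b.x_star < m_b.x_star
    elif cmp_within == "lt":
        assert f_w.x_star < m_w.x_star
        assert f_b.x_star > m_b.x_star
    else:
        assert f_w.x_star == pytest.approx(m_w.x_star, abs=1e-9)
        assert f_b.x_star == pytest.approx(m_b.x_star, abs=1e-9)


def test_sex_specific_stakes_shift_the_optimum():
    """A stronger surprise advantage for males raises the male optimum even
    under symmetric dispersal."""
    demog = Demography(10, 0.25, 0.25)
    base = GameParams("within_group")
    male_heavy = GameParams("within_group", surprise_advantage=0.15)
    f, m = sex_difference(base, demog, sex_specific_params={"male": male_heavy})
    assert m.x_star > f.x_star


def test_battleground_orderings_female_biased():
    demog = Demography(10, 0.3, 0.1)
    within = battleground(GameParams("within_group"), demog)
    between = battleground(GameParams("between_group"), demog)
    I, MO, FA = (
        ControlParty.INDIVIDUAL_POOLED,
        ControlParty.MOTHER,
        ControlParty.FATHER,
    )
    MAT, PAT = ControlParty.MATERNAL_ORIGIN_GENE, ControlParty.PATERNAL_ORIGIN_GENE
    # selfish: parents favour less left-handedness than the offspring itself
    assert within.optimum(MO) < within.optimum(I)
    assert within.optimum(FA) < within.optimum(I)
    # altruistic: parents favour more
    assert between.optimum(MO) > between.optimum(I)
    assert between.optimum(FA) > between.optimum(I)
    # female-biased dispersal: the less-locally-related party (mother,
    # maternal-origin gene) leans further toward the selfish direction
    assert within.optimum(MO) > within.optimum(FA)
    assert within.optimum(MAT) > within.optimum(PAT)
    assert between.optimum(MO) < between.optimum(FA)
    assert between.optimum(MAT) < between.optimum(PAT)
    # conflict indicator signs are consistent with the optima
    assert within.conflicts[(MO, I)] == -1
    assert between.conflicts[(MO, I)] == 1


def test_battleground_consistency_of_asymmetries():
    """Mother-vs-father and maternal-origin-vs-paternal-origin differences
    carry the same sign under a shared dispersal bias."""
    for mf, mm in ((0.35, 0.1), (0.1, 0.35)):
        demog = Demography(8, mf, mm)
        for scenario in ("within_group", "between_group"):
            bg = battleground(GameParams(scenario), demog)
            d_parent = bg.optimum(ControlParty.MOTHER) - bg.optimum(ControlParty.FATHER)
            d_origin = bg.optimum(ControlParty.MATERNAL_ORIGIN_GENE) - bg.optimum(
                ControlParty.PATERNAL_ORIGIN_GENE
            )
            assert d_parent * d_origin > 0


def test_all_conflicts_vanish_without_relatedness():
    demog = Demography(10, 1.0, 1.0)
    for scenario in ("within_group", "between_group"):
        bg = battleground(GameParams(scenario), demog)
        xs = [res.x_star for res in bg.results.values()]
        assert max(xs) - min(xs) <= 1e-9
        assert all(v == 0 for v in bg.conflicts.values())


def test_party_relatedness_values(demog):
    rset = island_relatedness(demog)
    r_ind = party_relatedness("individual_pooled", rset)
    assert 0.0 < r_ind < 1.0
    # parents weight groupmates more heavily than the offspring itself does
    assert party_relatedness("mother", rset) > r_ind


def test_multiple_roots_detected():
    roots = _interior_roots(lambda x: np.sin(3 * np.pi * x), 1e-6, 1.0 - 1e-6)
    assert len(roots) == 2
    assert roots[0] == pytest.approx(1 / 3, abs=1e-8)
    assert roots[1] == pytest.approx(2 / 3, abs=1e-8)
    with pytest.raises(MultipleRootsError):
        raise MultipleRootsError(roots)
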