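"""Machine-readable comparative-statics tables.

These reproduce, as numbers, the package's two headline prediction
surfaces: how dispersal moves the favoured incidence of left-handedness in
each combat scenario and for each sex, and the eight-cell imprinting
prediction table over scenario x dispersal bias x locus function.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .demography import Demography, island_relatedness
from .errors import ValidationError
from .games import Competition, DEFAULT_COMPETITION, GameParams
from .imprinting import imprint_table
from .selection import sex_difference


def fig1_table(
    dispersal_grid: Sequence[tuple[float, float]],
    n_breeders_per_sex: int = 10,
    params: GameParams | None = None,
    competition: Competition = DEFAULT_COMPETITION,
) -> pd.DataFrame:
    """Favoured incidence of left-handedness over a dispersal grid.

    One row per scenario x (m_f, m_m) pair x sex, with the sex's
    relatedness to a random patch-mate and its ESS.
    """
    rows = []
    for m_f, m_m in dispersal_grid:
        demog = Demography(n_breeders_per_sex, m_f, m_m)
        rset = island_relatedness(demog)
        for scenario in ("within_group", "between_group"):
            scen_params = (params or GameParams(scenario)).with_scenario(scenario)
            res_f, res_m = sex_difference(scen_params, demog, competition=competition)
            for sex, res in (("female", res_f), ("male", res_m)):
                rows.append(
                    {
                        "scenario": scenario,
                        "m_f": m_f,
                        "m_m": m_m,
                        "sex": sex,
                        "r": rset.r_individual(sex),
                        "x_star": res.x_star,
                    }
                )
    return pd.DataFrame(rows)


def reproduce_fig1(
    ms: Iterable[float] | None = None,
    n_breeders_per_sex: int = 10,
    params: GameParams | None = None,
    bias: float = 0.0,
    competition: Competition = DEFAULT_COMPETITION,
) -> pd.DataFrame:
    """Symmetric-dispersal sweep (optionally with a fixed sex bias).

    ``ms`` gives the mean dispersal grid (default 0.05..1.0 by 0.05);
    ``bias`` > 0 adds +bias/2 to female and -bias/2 to male dispersal.
    """
    if ms is None:
        ms = [round(0.05 * i, 10) for i in range(1, 21)]
    grid = []
    for m in ms:
        m_f = min(1.0, max(0.0, m + bias / 2))
        m_m = min(1.0, max(0.0, m - bias / 2))
        grid.append((m_f, m_m))
    if not grid:
        raise ValidationError("empty dispersal grid")
    return fig1_table(grid, n_breeders_per_sex, params, competition)


def reproduce_fig3(
    n_breeders_per_sex: int = 10,
    m_high: float = 0.3,
    m_low: float = 0.1,
    params: GameParams | None = None,
    competition: Competition = DEFAULT_COMPETITION,
) -> pd.DataFrame:
    """Eight-cell imprinting prediction table (scenario x bias x locus type)."""
    demog = Demography(n_breeders_per_sex, m_high, m_low)
    table = imprint_table(
        params or GameParams("within_group"), demog, competition=competition
    )
    rows = [
        {
            "scenario": scenario,
            "dispersal_bias": biaskey,
            "locus_type": locus,
            "expressed_origin": pred.expressed_origin,
            "silenced_origin": pred.silenced_origin,
        }
        for (scenario, biaskey, locus), pred in sorted(table.items())
    ]
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path: str | Path, manifest_id: str = "-") -> Path:
    """TSV with a commented header naming the package version and manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# handedkin {__version__} manifest={manifest_id}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path
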