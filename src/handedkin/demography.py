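"""Island-model demography and stationary relatedness coefficients.

The population is subdivided into infinitely many patches, each carrying
``N`` breeding females and ``N`` breeding males.  Generations are discrete
and non-overlapping.  Each generation: adults mate (monogamous pairs by
default), offspring disperse with sex-specific probabilities ``m_f`` and
``m_m`` into a global migrant pool, and density-dependent regulation returns
each patch to N breeders per sex.  Immigrants carry no identity-by-descent
with natives (infinite-island idealisation), so all identity is generated by
common ancestry within a patch and eroded by dispersal.

Stationary probabilities of identity by descent between classes of
patch-mates satisfy a small linear fixed-point system, assembled and solved
here directly.  The unknowns are

* ``Q_ff, Q_fm, Q_mm`` -- identity between random genes of two distinct
  same-patch adults of the indicated sexes, and
* ``F`` -- the inbreeding coefficient of an adult (identity between its two
  homologous genes).

With ``u = 1 - m_f`` and ``v = 1 - m_m``, two distinct adults are both
native to the patch with probability given by the product of their
philopatry probabilities, and conditional on both being native their
identity is that of two random offspring born on one patch (``Q0``).  Under
monogamy two random local offspring are full siblings with probability 1/N;
under random-within-patch mating they share each parent independently with
probability 1/N.  Offspring inbreeding equals the identity of a random
mated pair, ``Q_fm``.

Relatedness is reported on the others-only regression scale appropriate to
the infinite-island model: r = Q_pair / Q_self with Q_self = (1 + F)/2, the
identity of two genes drawn (with replacement) from the focal individual.
Parent-of-origin coefficients condition the focal's gene on having been
inherited from the mother (a female, philopatric with probability u) or the
father (philopatric with probability v); their average recovers the diploid
coefficient exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import NumericalError, ValidationError

Sex = Literal["female", "male"]
Origin = Literal["maternal", "paternal"]

_SOLVE_TOL = 1e-12


@dataclass(frozen=True)
class Demography:
    """Patch demography: breeder numbers, sex-specific dispersal, mating system.

    Parameters
    ----------
    n_breeders_per_sex:
        N, the number of breeding females (= breeding males) per patch.
    dispersal_female, dispersal_male:
        Probabilities m_f, m_m that a female / male offspring disperses
        before competing for a breeding slot.
    mating:
        ``"monogamy"`` (N exclusive pairs per patch, the default) or
        ``"random"`` (each offspring's father is an independent random
        male of the patch).
    genetic_system:
        ``"diploid"`` for the full model; ``"haploid-check-mode"`` restricts
        to one clonal haploid sex (requires m_f == m_m) and exists to check
        the solver against the textbook island-model closed form.
    """

    n_breeders_per_sex: int
    dispersal_female: float
    dispersal_male: float
    mating: Literal["monogamy", "random"] = "monogamy"
    genetic_system: Literal["diploid", "haploid-check-mode"] = "diploid"

    def __post_init__(self):
        if self.n_breeders_per_sex < 1:
            raise ValidationError("n_breeders_per_sex must be >= 1")
        for name in ("dispersal_female", "dispersal_male"):
            m = getattr(self, name)
            if not 0.0 <= m <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {m}")
        if self.mating not in ("monogamy", "random"):
            raise ValidationError(f"unknown mating system {self.mating!r}")
        if self.genetic_system not in ("diploid", "haploid-check-mode"):
            raise ValidationError(f"unknown genetic system {self.genetic_system!r}")
        if (
            self.genetic_system == "haploid-check-mode"
            and self.dispersal_female != self.dispersal_male
        ):
            raise ValidationError(
                "haploid-check-mode requires a single dispersal rate (m_f == m_m)"
            )

    @property
    def philopatry(self) -> dict[Sex, float]:
        return {
            "female": 1.0 - self.dispersal_female,
            "male": 1.0 - self.dispersal_male,
        }


@dataclass(frozen=True)
class RelatednessSet:
    """The full complement of stationary relatedness coefficients.

    All social-partner coefficients are on the others-only scale (the focal
    individual is excluded from its own partner pool, as combat opponents
    are distinct individuals).
    """

    r_self: float
    r_group_others: dict[Sex, dict[Sex, float]]
    r_group_origin: dict[Origin, float]
    r_parent_to_offspring: dict[Sex, float]
    r_parent_to_group: dict[Sex, float]
    inbreeding: float
    identities: dict[str, float] = field(default_factory=dict)

    def r_individual(self, sex: Sex | None = None) -> float:
        """Others-only relatedness of an adult to a uniformly random patch-mate."""
        if sex is None:
            return 0.5 * (self.r_individual("female") + self.r_individual("male"))
        row = self.r_group_others[sex]
        return 0.5 * (row["female"] + row["male"])

    def parent_valuation_ratio(self, parent_sex: Sex) -> float:
        """r_parent_to_group / r_parent_to_offspring: the weight a parent puts on
        its offspring's social partners relative to the offspring itself."""
        return self.r_parent_to_group[parent_sex] / self.r_parent_to_offspring[parent_sex]

    def to_flat_dict(self) -> dict[str, float]:
        out = {"r_self": self.r_self, "inbreeding": self.inbreeding}
        for sx in ("female", "male"):
            for sy in ("female", "male"):
                out[f"r_group_others.{sx}.{sy}"] = self.r_group_others[sx][sy]
        for origin in ("maternal", "paternal"):
            out[f"r_group_origin.{origin}"] = self.r_group_origin[origin]
        for sx in ("female", "male"):
            out[f"r_parent_to_offspring.{sx}"] = self.r_parent_to_offspring[sx]
            out[f"r_parent_to_group.{sx}"] = self.r_parent_to_group[sx]
        return out

    def to_json(self) -> str:
        import json

        return json.dumps(self.to_flat_dict(), indent=2)

    def to_tsv(self) -> str:
        lines = ["coefficient\tvalue"]
        lines += [f"{k}\t{v:.12g}" for k, v in self.to_flat_dict().items()]
        return "\n".join(lines) + "\n"


def _solve_linear_identity_system(A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve q = A q + rhs directly, verifying the fixed-point residual."""
    n = A.shape[0]
    try:
        q = np.linalg.solve(np.eye(n) - A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate demography
        raise NumericalError(f"identity system singular: {exc}") from exc
    residual = float(np.max(np.abs(q - (A @ q + rhs))))
    if residual > 1e-9:
        raise NumericalError(
            f"identity fixed point residual {residual:.3e} exceeds tolerance",
            residual=residual,
        )
    return q


def stationary_identities(demog: Demography) -> dict[str, float]:
    """Stationary identity-by-descent probabilities for the island model.

    Returns a dict with keys ``Q_ff, Q_fm, Q_mm, F, Q0`` (diploid) or
    ``Q`` (haploid check mode).
    """
    N = demog.n_breeders_per_sex
    u = 1.0 - demog.dispersal_female
    v = 1.0 - demog.dispersal_male

    if demog.genetic_system == "haploid-check-mode":
        # Q = (1-m)^2 [ 1/N + (1 - 1/N) Q ]
        m = demog.dispersal_female
        w = (1.0 - m) ** 2
        A = np.array([[w * (1.0 - 1.0 / N)]])
        rhs = np.array([w / N])
        (Q,) = _solve_linear_identity_system(A, rhs)
        return {"Q": float(Q)}

    # Unknowns q = [Q_ff, Q_fm, Q_mm, F].  Q0 is linear in q: Q0 = g . q + g0.
    if demog.mating == "monogamy":
        # Q0 = (1/N) [ (1+F)/4 + Q_fm/2 ] + (1 - 1/N) (Q_ff + 2 Q_fm + Q_mm)/4
        s = 1.0 - 1.0 / N
        g = np.array([s / 4.0, 1.0 / (2.0 * N) + s / 2.0, s / 4.0, 1.0 / (4.0 * N)])
        g0 = 1.0 / (4.0 * N)
    else:
        # Random mating: share mother w.p. 1/N and father independently w.p. 1/N.
        #   full sibs:       (1+F)/4 + Q_fm/2
        #   maternal half:   (1+F)/8 + Q_mm/4 + Q_fm/2
        #   paternal half:   (1+F)/8 + Q_ff/4 + Q_fm/2
        #   non-sibs:        (Q_ff + 2 Q_fm + Q_mm)/4
        p = 1.0 / N
        pf, ph, pn = p * p, p * (1.0 - p), (1.0 - p) ** 2
        g = np.array(
            [
                ph / 4.0 + pn / 4.0,
                pf / 2.0 + 2 * ph / 2.0 + pn / 2.0,
                ph / 4.0 + pn / 4.0,
                pf / 4.0 + 2 * ph / 8.0,
            ]
        )
        g0 = pf / 4.0 + 2 * ph / 8.0
    # Q_ff = u^2 Q0 ; Q_fm = u v Q0 ; Q_mm = v^2 Q0 ; F = Q_fm.
    A = np.vstack(
        [
            u * u * g,
            u * v * g,
            v * v * g,
            np.array([0.0, 1.0, 0.0, 0.0]),
        ]
    )
    rhs = np.array([u * u * g0, u * v * g0, v * v * g0, 0.0])
    Qff, Qfm, Qmm, F = _solve_linear_identity_system(A, rhs)
    Q0 = float(g @ np.array([Qff, Qfm, Qmm, F]) + g0)
    return {
        "Q_ff": float(Qff),
        "Q_fm": float(Qfm),
        "Q_mm": float(Qmm),
        "F": float(F),
        "Q0": Q0,
    }


def island_relatedness(demog: Demography) -> RelatednessSet:
    """Stationary relatedness coefficients for the infinite-island model.

    See the module docstring for the identity system; coefficients are
    regression relatedness relative to the global population (in which
    identity is zero), i.e. r = Q / ((1+F)/2).
    """
    ids = stationary_identities(demog)
    if demog.genetic_system == "haploid-check-mode":
        Q = ids["Q"]
        r = {"female": {"female": Q, "male": Q}, "male": {"female": Q, "male": Q}}
        return RelatednessSet(
            r_self=1.0,
            r_group_others=r,
            r_group_origin={"maternal": Q, "paternal": Q},
            r_parent_to_offspring={"female": 1.0, "male": 1.0},
            r_parent_to_group={"female": Q, "male": Q},
            inbreeding=0.0,
            identities=ids,
        )

    N = demog.n_breeders_per_sex
    u = 1.0 - demog.dispersal_female
    v = 1.0 - demog.dispersal_male
    ubar = 0.5 * (u + v)
    Qff, Qfm, Qmm, F, Q0 = (ids[k] for k in ("Q_ff", "Q_fm", "Q_mm", "F", "Q0"))
    q_self = 0.5 * (1.0 + F)
    phil = {"female": u, "male": v}

    r_group = {
        sx: {sy: phil[sx] * phil[sy] * Q0 / q_self for sy in ("female", "male")}
        for sx in ("female", "male")
    }

    # Per-origin identity to a random patch-mate.  The focal's maternal-origin
    # gene is a random gene of its mother.  The patch-mate's random gene comes
    # from the patch-mate's mother or father (1/2 each); the patch-mate's
    # mother is the focal's mother with probability 1/N (same for fathers),
    # under either mating system.
    parent_child = 0.25 * (1.0 + F) + 0.5 * Qfm  # identity, random genes of parent & child
    K_mat = 0.5 * ((1.0 + F) / (2.0 * N) + (1.0 - 1.0 / N) * Qff) + 0.5 * Qfm
    K_pat = 0.5 * ((1.0 + F) / (2.0 * N) + (1.0 - 1.0 / N) * Qmm) + 0.5 * Qfm
    r_origin = {
        "maternal": ubar * ubar * K_mat / q_self,
        "paternal": ubar * ubar * K_pat / q_self,
    }

    # Parent-centric coefficients: a parent (sex s) values its offspring via
    # parent_child identity, and the offspring's random adult patch-mate via
    # the offspring's philopatry (averaged over offspring sex), the partner's
    # philopatry, and the chance 1/N that the partner is another own child.
    K_parent = {
        s: parent_child / N
        + (1.0 - 1.0 / N) * 0.5 * ({"female": Qff, "male": Qfm}[s] + {"female": Qfm, "male": Qmm}[s])
        for s in ("female", "male")
    }
    r_p2o = {s: parent_child / q_self for s in ("female", "male")}
    r_p2g = {s: ubar * ubar * K_parent[s] / q_self for s in ("female", "male")}

    return RelatednessSet(
        r_self=1.0,
        r_group_others=r_group,
        r_group_origin=r_origin,
        r_parent_to_offspring=r_p2o,
        r_parent_to_group=r_p2g,
        inbreeding=F,
        identities=ids,
    )


def parent_centric_relatedness(
    demog: Demography, outbred_approximation: bool = False
) -> tuple[dict[Sex, float], dict[Sex, float]]:
    """Relatedness of each parent to (its own offspring, the offspring's patch-mates).

    By default parent-to-offspring relatedness uses the island-model
    stationary identities and therefore exceeds 1/2 when dispersal is low
    (local inbreeding); with ``outbred_approximation`` it is fixed at the
    textbook 1/2.
    """
    rset = island_relatedness(demog)
    r_p2o = dict(rset.r_parent_to_offspring)
    if outbred_approximation:
        r_p2o = {s: 0.5 for s in r_p2o}
    return r_p2o, dict(rset.r_parent_to_group)
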