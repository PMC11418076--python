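"""Individual-based island-model simulator.

A finite number of patches (default 200) stands in for the infinite island
model.  Each patch holds exactly N breeding females and N breeding males,
each diploid at a single handedness-propensity locus whose two alleles are
tagged by parental origin every generation.  The life cycle per generation:

1. **phenotype** -- each adult's left-handedness propensity is read from
   the configured controlling party (own genotype mean, a parent's recorded
   genotype, or a single parental-origin allele), clamped to [0, 1], and
   handedness is drawn Bernoulli(propensity);
2. **combat** -- within-group: each adult duels one uniformly random
   patch-mate; between-group: each adult duels a random member of a random
   other patch and the patch's mean success scales every member's
   fecundity.  Contest stakes are realised as expected success (win
   *probabilities* enter fecundity, standing for many small contests), so
   fecundity multipliers stay within their analytic bounds;
3. **reproduction** -- monogamous random pairing (or random-within-patch
   mating), offspring weights proportional to pair fecundity, Mendelian
   transmission with per-allele Gaussian mutation clamped to [0, 1];
4. **dispersal + regulation** -- each breeding slot is won by a philopatric
   native with probability (1-m) F_p / ((1-m) F_p + m F̄) and by an
   immigrant (source patch proportional to its total fecundity) otherwise,
   so philopatric and immigrant offspring compete exactly as in the island
   life cycle.

Because the life cycle regulates every patch back to N + N breeders, the
simulator realises the *local*-competition fitness structure of
:mod:`handedkin.games`; its evolutionary equilibria are the
``competition="local"`` analytical predictions (see docs/methods.md for why
kin competition cancels relatedness effects in this life cycle).

Gene-dropping mode runs the same life cycle neutrally with unique founder
alleles and measures within-patch identity (relative to the between-patch
baseline, which absorbs the slow global coalescence of a finite world),
providing an independent oracle for the stationary identity fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .demography import Demography
from .errors import ValidationError
from .games import GameParams

ControlRule = Literal[
    "own_genotype_additive",
    "maternal_genotype",
    "paternal_genotype",
    "maternal_origin_allele_only",
    "paternal_origin_allele_only",
]


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run."""

    n_patches: int
    demog: Demography
    game: GameParams | None
    control: ControlRule = "own_genotype_additive"
    mutation_sd: float = 0.05
    mutation_rate: float = 0.02
    generations: int = 2000
    seed: int = 0
    init_x: float = 0.5
    mode: Literal["evolution", "gene_dropping"] = "evolution"
    #: gene-dropping: generations discarded before identity is sampled
    burn_in: int = 100
    #: gene-dropping: sampling stride after burn-in
    sample_every: int = 10

    def __post_init__(self):
        if self.n_patches < 2:
            raise ValidationError("n_patches must be >= 2")
        if self.mode == "evolution" and self.game is None:
            raise ValidationError("evolution mode requires game parameters")
        for name in ("mutation_sd", "mutation_rate", "init_x"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        if self.demog.genetic_system != "diploid":
            raise ValidationError("the simulator is diploid-only")


@dataclass
class SimState:
    """Adults of one generation: (n_patches, 2N) arrays; columns 0..N-1 are
    female, N..2N-1 male.  Alleles are tagged by parental origin."""

    mat: np.ndarray  # maternal-origin allele value
    pat: np.ndarray  # paternal-origin allele value
    mother_g: np.ndarray  # mother's genotypic mean, recorded at birth
    father_g: np.ndarray


@dataclass
class SimResult:
    config: SimConfig
    mean_propensity: np.ndarray  # per generation
    incidence_left: np.ndarray  # realised handedness frequency per generation
    identity: list[dict] = field(default_factory=list)  # gene-dropping samples
    final_mean: float = float("nan")
    final_se: float = float("nan")

    def summarise_final_epoch(self, fraction: float = 0.2, n_blocks: int = 10):
        """Mean propensity over the last ``fraction`` of generations, with a
        batch-means Monte-Carlo standard error."""
        tail = self.mean_propensity[int(len(self.mean_propensity) * (1 - fraction)) :]
        self.final_mean = float(np.mean(tail))
        n_blocks = max(2, min(n_blocks, len(tail)))
        blocks = np.array_split(tail, n_blocks)
        means = np.array([b.mean() for b in blocks])
        self.final_se = float(means.std(ddof=1) / np.sqrt(n_blocks))
        return self.final_mean, self.final_se


def _init_state(config: SimConfig, rng: np.random.Generator) -> SimState:
    P, N = config.n_patches, config.demog.n_breeders_per_sex
    shape = (P, 2 * N)
    if config.mode == "gene_dropping":
        ids = np.arange(2 * P * 2 * N, dtype=np.float64)
        rng.shuffle(ids)
        mat = ids[: P * 2 * N].reshape(shape).copy()
        pat = ids[P * 2 * N :].reshape(shape).copy()
    else:
        mat = np.full(shape, config.init_x)
        pat = np.full(shape, config.init_x)
    g = 0.5 * (mat + pat) if config.mode == "evolution" else np.full(shape, config.init_x)
    return SimState(mat=mat, pat=pat, mother_g=g.copy(), father_g=g.copy())


def _propensity(state: SimState, control: ControlRule) -> np.ndarray:
    if control == "own_genotype_additive":
        z = 0.5 * (state.mat + state.pat)
    elif control == "maternal_genotype":
        z = state.mother_g
    elif control == "paternal_genotype":
        z = state.father_g
    elif control == "maternal_origin_allele_only":
        z = state.mat
    elif control == "paternal_origin_allele_only":
        z = state.pat
    else:  # pragma: no cover
        raise ValidationError(f"unknown control rule {control!r}")
    return np.clip(z, 0.0, 1.0)


def _combat_fecundity(
    hand: np.ndarray, z: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Combat stage: per-adult fecundity plus a per-patch multiplier.

    Returns ``(fec, patch_mult)``.  Between-group contest success scales the
    whole patch's reproductive output, so it is returned as a patch-level
    multiplier applied once per mated pair (a couple's joint production is
    scaled by the group's success once, not once per parent); within-group
    duel outcomes are individual and enter each adult's own fecundity.
    """
    game = config.game
    P, two_n = hand.shape
    a, k = game.surprise_advantage, game.handedness_cost
    h = hand.astype(np.float64)
    if game.scenario == "within_group":
        # opponent: uniformly random *other* patch-mate
        shift = rng.integers(1, two_n, size=(P, two_n))
        cols = (np.arange(two_n)[None, :] + shift) % two_n
        h_opp = np.take_along_axis(h, cols, axis=1)
        # exposure: long-run left-handedness (propensity) of the local
        # adversaries each fighter trains against, excluding the two
        # combatants themselves
        z_opp = np.take_along_axis(z, cols, axis=1)
        q = (z.sum(axis=1, keepdims=True) - z - z_opp) / max(two_n - 2, 1)
        edge = np.minimum(a * (1.0 - q), 0.5)
        p_win = 0.5 + edge * (h - h_opp)
        fec = (1.0 - k * h) * (1.0 + game.stakes * (2.0 * p_win - 1.0))
        patch_mult = np.ones((P, 1))
    else:
        # opponent: random member of a uniformly random other patch
        opp_patch = (np.arange(P)[:, None] + rng.integers(1, P, size=(P, two_n))) % P
        opp_col = rng.integers(0, two_n, size=(P, two_n))
        h_opp = h[opp_patch, opp_col]
        q = z.mean()  # global exposure
        edge = min(a * (1.0 - q), 0.5)
        p_win = 0.5 + edge * (h - h_opp)
        s = p_win.mean(axis=1, keepdims=True)  # patch contest success
        fec = 1.0 - k * h
        patch_mult = 1.0 + game.group_stakes * (2.0 * s - 1.0)
    if np.any(fec <= 0.0) or np.any(patch_mult <= 0.0):
        raise ValidationError("stakes produce non-positive fecundity; reduce B or G")
    return fec, patch_mult


def _sample_pairs_for_slots(
    source_patch: np.ndarray,
    weights: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """For each slot, a weighted draw of a column index within its source patch.

    ``weights`` is (P, n) with strictly positive entries; returns flat pair
    indices (source_patch * n + column).
    """
    P, n = weights.shape
    flat = np.cumsum(weights.ravel())
    totals = flat[n - 1 :: n].copy()
    offsets = np.concatenate([[0.0], totals])[:-1]
    patch_tot = np.diff(np.concatenate([[0.0], totals]))
    target = offsets[source_patch] + u * patch_tot[source_patch]
    idx = np.searchsorted(flat, target, side="right")
    return np.clip(idx, source_patch * n, source_patch * n + n - 1)


def run_generation(
    state: SimState, config: SimConfig, rng: np.random.Generator
) -> tuple[SimState, dict]:
    """Advance one generation; returns the new state and per-generation stats.

    Random draws occur in a fixed order (phenotype, combat, pairing,
    slot origin, source patches, parent picks, meiosis, mutation) so runs
    are bit-reproducible given the seed.
    """
    P = config.n_patches
    N = config.demog.n_breeders_per_sex
    two_n = 2 * N
    z = _propensity(state, config.control)
    hand = rng.random((P, two_n)) < z

    if config.mode == "evolution":
        fec, patch_mult = _combat_fecundity(hand, z, config, rng)
    else:
        fec, patch_mult = np.ones((P, two_n)), np.ones((P, 1))

    # monogamous pairing: female column f mates male column N + perm[f]
    perm = np.argsort(rng.random((P, N)), axis=1)
    fec_f = fec[:, :N]
    fec_m = np.take_along_axis(fec[:, N:], perm, axis=1)
    monogamy = config.demog.mating == "monogamy"
    if monogamy:
        pair_fec = fec_f * fec_m
    # a patch's juvenile supply counts each parent's fecundity once (plus the
    # patch-level contest multiplier once), matching the patch-mean-fecundity
    # competition of the analytical island composition
    F_patch = patch_mult[:, 0] * fec.sum(axis=1) / 2.0

    F_bar = F_patch.mean()
    new = {key: np.empty((P, two_n)) for key in ("mat", "pat", "mother_g", "father_g")}

    for sex, m_disp in (("female", config.demog.dispersal_female),
                        ("male", config.demog.dispersal_male)):
        sl = slice(0, N) if sex == "female" else slice(N, two_n)
        p_native = (1.0 - m_disp) * F_patch / ((1.0 - m_disp) * F_patch + m_disp * F_bar)
        native = rng.random((P, N)) < p_native[:, None]
        # immigrant source patches, proportional to patch total fecundity
        cum_F = np.cumsum(F_patch)
        src = np.repeat(np.arange(P)[:, None], N, axis=1)
        n_imm = int((~native).sum())
        if n_imm:
            src[~native] = np.searchsorted(cum_F, rng.random(n_imm) * cum_F[-1], side="right")
        src = np.clip(src, 0, P - 1)
        if monogamy:
            pair_idx = _sample_pairs_for_slots(src, pair_fec, rng.random((P, N)))
            src_p, pair_col = pair_idx // N, pair_idx % N
            mother_col = pair_col
            father_col = N + perm[src_p, pair_col]
        else:
            mi = _sample_pairs_for_slots(src, fec_f, rng.random((P, N)))
            fi = _sample_pairs_for_slots(src, fec[:, N:], rng.random((P, N)))
            src_p, mother_col = mi // N, mi % N
            father_col = N + fi % N
        mother_mat = state.mat[src_p, mother_col]
        mother_pat = state.pat[src_p, mother_col]
        father_mat = state.mat[src_p, father_col]
        father_pat = state.pat[src_p, father_col]
        pick_m = rng.random((P, N)) < 0.5
        pick_f = rng.random((P, N)) < 0.5
        child_mat = np.where(pick_m, mother_mat, mother_pat)
        child_pat = np.where(pick_f, father_mat, father_pat)
        if config.mode == "evolution" and config.mutation_rate > 0.0:
            for arr in (child_mat, child_pat):
                hit = rng.random((P, N)) < config.mutation_rate
                n_hit = int(hit.sum())
                if n_hit:
                    arr[hit] = np.clip(
                        arr[hit] + rng.normal(0.0, config.mutation_sd, n_hit), 0.0, 1.0
                    )
        new["mat"][:, sl] = child_mat
        new["pat"][:, sl] = child_pat
        new["mother_g"][:, sl] = 0.5 * (mother_mat + mother_pat)
        new["father_g"][:, sl] = 0.5 * (father_mat + father_pat)

    stats = {
        "mean_propensity": float(np.mean(0.5 * (state.mat + state.pat))),
        "incidence_left": float(hand.mean()),
    }
    return SimState(**new), stats


def _identity_sample(state: SimState, N: int) -> dict:
    """Within-patch (cross-individual), between-patch and within-individual
    identity frequencies from the current allele configuration."""
    P, two_n = state.mat.shape
    alleles = np.stack([state.mat, state.pat]).astype(np.int64)  # (2, P, 2N)
    n_ids = int(alleles.max()) + 1
    # per-patch pair counts via combined patch*allele keys
    keys = (np.arange(P)[None, :, None] * n_ids + alleles).ravel()
    counts = np.bincount(keys, minlength=P * n_ids)
    # sum over ordered identical copy-pairs per patch = sum of c_a^2
    per_patch_sq = np.zeros(P)
    patch_of_key = np.arange(P * n_ids) // n_ids
    nz = counts > 0
    np.add.at(per_patch_sq, patch_of_key[nz], counts[nz].astype(np.float64) ** 2)
    eq_self = (state.mat == state.pat).sum(axis=1)  # per patch
    within_identical = per_patch_sq - (2.0 * two_n + 2.0 * eq_self)
    Q_w = float(np.mean(within_identical / (4.0 * two_n * (two_n - 1))))
    # between-patch: global pairs minus within-patch pairs
    g_counts = np.bincount(alleles.ravel(), minlength=n_ids).astype(np.float64)
    T = 2.0 * P * two_n
    global_sq = float(np.sum(g_counts**2))
    between_identical = global_sq - float(per_patch_sq.sum())
    between_pairs = T * T - float(P * (2.0 * two_n) ** 2)
    Q_b = between_identical / between_pairs
    F_hat = float(eq_self.sum() / (P * two_n))
    return {"Q_within": Q_w, "Q_between": Q_b, "F": F_hat}


def corrected_within_identity(sample: dict) -> float:
    """Within-patch identity relative to the between-patch baseline.

    In a finite world all lineages slowly coalesce, inflating every raw
    identity; (Q_w - Q_b) / (1 - Q_b) removes that common background and is
    the finite-population estimate of the infinite-island Q.
    """
    return (sample["Q_within"] - sample["Q_between"]) / (1.0 - sample["Q_between"])


def simulate(config: SimConfig) -> SimResult:
    """Run the configured simulation; reproducible bit-for-bit given the seed."""
    rng = np.random.default_rng(config.seed)
    state = _init_state(config, rng)
    N = config.demog.n_breeders_per_sex
    mean_prop = np.empty(config.generations)
    incidence = np.empty(config.generations)
    identity: list[dict] = []
    for gen in range(config.generations):
        state, stats = run_generation(state, config, rng)
        mean_prop[gen] = stats["mean_propensity"]
        incidence[gen] = stats["incidence_left"]
        if (
            config.mode == "gene_dropping"
            and gen >= config.burn_in
            and (gen - config.burn_in) % config.sample_every == 0
        ):
            sample = _identity_sample(state, N)
            sample["generation"] = gen
            identity.append(sample)
    result = SimResult(
        config=config,
        mean_propensity=mean_prop,
        incidence_left=incidence,
        identity=identity,
    )
    result.summarise_final_epoch()
    return result


def pooled_theory_identity(demog: Demography) -> float:
    """Fixed-point prediction for the sex-pooled within-patch identity
    measured by gene dropping (ordered pairs of distinct adults)."""
    from .demography import stationary_identities

    ids = stationary_identities(demog)
    N = demog.n_breeders_per_sex
    n_ff = N * (N - 1)
    n_mm = N * (N - 1)
    n_fm = 2 * N * N
    tot = n_ff + n_mm + n_fm
    return (n_ff * ids["Q_ff"] + n_mm * ids["Q_mm"] + n_fm * ids["Q_fm"]) / tot
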