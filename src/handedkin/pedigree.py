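"""Pedigree-based relatedness via exact recursive kinship coefficients.

The coefficient of kinship phi(i, j) is the probability that a random
autosomal gene from i and a random homologous gene from j are identical by
descent, with pedigree founders taken as unrelated and non-inbred.  It obeys

    phi(i, i) = (1 + phi(mother_i, father_i)) / 2
    phi(i, j) = (phi(mother_i, j) + phi(father_i, j)) / 2    (i not an
                ancestor of j; expand the later-generation individual)

The reported coefficient of relatedness is r = 2 phi, which gives the
familiar 1/2 (full siblings), 1/4 (half-siblings), 1/8 (first cousins) in
an outbred pedigree, and 1 for self.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ValidationError

FOUNDER = ("0", "", None)


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "female" | "male"
    mother: str | None  # None = founder
    father: str | None


@dataclass
class Pedigree:
    """A validated pedigree: acyclic parent links, both parents or neither."""

    individuals: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self):
        self._depth: dict[str, int] = {}
        self._validate()

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "Pedigree":
        """Build from (id, sex, mother, father) tuples; '0'/''/None mark founders."""
        inds = {}
        for rec in records:
            pid, sex, mo, fa = (str(x) if x is not None else None for x in rec)
            mo = None if mo in FOUNDER else mo
            fa = None if fa in FOUNDER else fa
            if (mo is None) != (fa is None):
                raise ValidationError(
                    f"individual {pid!r} has exactly one recorded parent; "
                    "every non-founder needs both a mother and a father"
                )
            sex = {"f": "female", "1": "male", "2": "female", "m": "male"}.get(
                sex.lower(), sex.lower()
            )
            if sex not in ("female", "male"):
                raise ValidationError(f"individual {pid!r}: unknown sex {rec[1]!r}")
            if pid in inds:
                raise ValidationError(f"duplicate individual id {pid!r}")
            inds[pid] = Individual(pid, sex, mo, fa)
        return cls(inds)

    @classmethod
    def from_fam(cls, path: str | Path) -> "Pedigree":
        """Read a PLINK-style tab/whitespace-separated table: id sex mother father.

        A header line starting with '#' or with the literal column names is
        skipped.  '0' or empty parent fields mark founders.
        """
        records = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0].lower() == "id":
                continue
            if len(parts) < 4:
                parts = parts + [""] * (4 - len(parts))
            records.append(tuple(parts[:4]))
        return cls.from_records(records)

    def _validate(self):
        for ind in self.individuals.values():
            for parent, want in ((ind.mother, "female"), (ind.father, "male")):
                if parent is None:
                    continue
                if parent not in self.individuals:
                    raise ValidationError(
                        f"individual {ind.id!r} references unknown parent {parent!r}"
                    )
                if self.individuals[parent].sex != want:
                    raise ValidationError(
                        f"parent {parent!r} of {ind.id!r} has inconsistent sex"
                    )
        # depth assignment doubles as cycle detection
        WORKING, DONE = 1, 2
        state: dict[str, int] = {}

        def depth(pid: str) -> int:
            if pid in self._depth:
                return self._depth[pid]
            if state.get(pid) == WORKING:
                raise ValidationError(f"pedigree contains a cycle through {pid!r}")
            state[pid] = WORKING
            ind = self.individuals[pid]
            d = 0 if ind.mother is None else 1 + max(depth(ind.mother), depth(ind.father))
            state[pid] = DONE
            self._depth[pid] = d
            return d

        for pid in self.individuals:
            depth(pid)

    def kinship(self, i: str, j: str) -> float:
        """Coefficient of kinship phi(i, j)."""
        for pid in (i, j):
            if pid not in self.individuals:
                raise ValidationError(f"unknown individual id {pid!r}")
        cache: dict[frozenset, float] = {}

        def phi(a: str, b: str) -> float:
            key = frozenset((a, b))
            if key in cache:
                return cache[key]
            ia, ib = self.individuals[a], self.individuals[b]
            if a == b:
                val = 0.5 if ia.mother is None else 0.5 * (1.0 + phi(ia.mother, ia.father))
            else:
                # expand the individual in the later generation; a founder
                # pair is unrelated by definition
                if self._depth[a] < self._depth[b]:
                    ia, ib = ib, ia
                if ia.mother is None:
                    val = 0.0
                else:
                    val = 0.5 * (phi(ia.mother, ib.id) + phi(ia.father, ib.id))
            cache[key] = val
            return val

        return phi(i, j)


def pedigree_relatedness(ped: Pedigree, i: str, j: str) -> float:
    """Outbred-population coefficient of relatedness: twice the kinship."""
    return 2.0 * ped.kinship(i, j)
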