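"""Pedigree containers and PED-format I/O.

A pedigree here is a small directed acyclic parent graph with a binary
trait status per individual. The analysis modules only ever need two
things from it: the parent links (for gene-dropping simulation) and the
affected/unaffected partition (for the dominant co-segregation filter),
so the container stays deliberately minimal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree or PED file."""


@dataclass
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for a founder side; otherwise
    they must resolve to another individual in the same pedigree.
    ``affected`` is the binary trait status; individuals whose phenotype
    was coded unknown in the source file are stored as unaffected with
    ``phenotype_known=False``.
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: bool = False
    phenotype_known: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be non-empty")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """An ordered collection of individuals forming a valid parent DAG."""

    individuals: list[Individual]
    name: str = "FAM"
    _by_id: dict[str, Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.individuals:
            raise PedigreeError("pedigree must contain at least one individual")
        self._by_id = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        for ind in self.individuals:
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{role} id {pid!r} of {ind.id!r} does not resolve to any individual"
                    )
                expected = Sex.MALE if role == "father" else Sex.FEMALE
                if parent.sex is not Sex.UNKNOWN and parent.sex is not expected:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} has inconsistent sex {parent.sex.value}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Iterative DFS over parent links; a back edge means someone is
        # their own ancestor.
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {i.id: WHITE for i in self.individuals}
        for start in colour:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(self._parent_ids(start)))]
            colour[start] = GREY
            while stack:
                node, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    colour[node] = BLACK
                    stack.pop()
                elif colour[nxt] == GREY:
                    raise PedigreeError(f"parent cycle involving {nxt!r}")
                elif colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(self._parent_ids(nxt))))

    def _parent_ids(self, iid: str) -> list[str]:
        ind = self._by_id[iid]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [i.id for i in self.individuals]

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.is_founder]

    def topological_order(self) -> list[Individual]:
        """Individuals ordered so every parent precedes its children."""
        done: set[str] = set()
        out: list[Individual] = []
        pending = list(self.individuals)
        while pending:
            rest = []
            for ind in pending:
                if all(p in done for p in self._parent_ids(ind.id)):
                    out.append(ind)
                    done.add(ind.id)
                else:
                    rest.append(ind)
            if len(rest) == len(pending):  # unreachable on a validated DAG
                raise PedigreeError("pedigree parent graph is not orderable")
            pending = rest
        return out

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "individuals": [
                {
                    "id": i.id,
                    "father_id": i.father_id,
                    "mother_id": i.mother_id,
                    "sex": i.sex.value,
                    "affected": i.affected,
                    "phenotype_known": i.phenotype_known,
                }
                for i in self.individuals
            ],
        }
        return json.dumps(payload, indent=2)


def affected_partition(ped: Pedigree) -> tuple[set[str], set[str]]:
    """Split pedigree ids into (affected, unaffected) sets.

    The sets are disjoint and their union is every id in the pedigree;
    individuals with unknown phenotype fall on the unaffected side.
    """
    affected = {i.id for i in ped if i.affected}
    return affected, set(ped.ids) - affected


def load_pedigree(path: str | Path) -> Pedigree:
    """Read a PLINK-style 6-column PED file.

    Columns: family, id, father, mother, sex, phenotype — whitespace
    delimited, extra columns ignored. Parent code "0" means no recorded
    parent; phenotype 2 = affected, 1 = unaffected, 0/-9 = unknown
    (stored as unaffected with a warning).
    """
    path = Path(path)
    individuals: list[Individual] = []
    fam_name = "FAM"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path.name}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            fam, iid, fid, mid, sex_code, pheno = fields[:6]
            fam_name = fam
            if pheno in ("0", "-9"):
                warnings.warn(
                    f"{path.name}:{lineno}: unknown phenotype for {iid!r}; treated as unaffected",
                    stacklevel=2,
                )
                affected, known = False, False
            elif pheno == "2":
                affected, known = True, True
            elif pheno == "1":
                affected, known = False, True
            else:
                raise PedigreeError(
                    f"{path.name}:{lineno}: unrecognised phenotype code {pheno!r}"
                )
            individuals.append(
                Individual(
                    id=iid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_PED_SEX.get(sex_code, Sex.UNKNOWN),
                    affected=affected,
                    phenotype_known=known,
                )
            )
    try:
        return Pedigree(individuals, name=fam_name)
    except PedigreeError as exc:
        raise PedigreeError(f"{path.name}: {exc}") from exc


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree back out as 6-column PED."""
    with open(path, "w") as fh:
        for ind in ped:
            pheno = ("2" if ind.affected else "1") if ind.phenotype_known else "0"
            fh.write(
                "\t".join(
                    [
                        ped.name,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_PED[ind.sex],
                        pheno,
                    ]
                )
                + "\n"
            )
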