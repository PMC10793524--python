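"""Pedigree structures and PED/phenotype-table parsing.

A family is a small directed graph of :class:`Individual` records plus the
phenotype metadata driving the search: the disease group (which selects the
cell types whose peaks define the non-coding search space), whether the
presentation is isolated or syndromic, and whether the pedigree is already
solved (solved pedigrees are excluded from all searches feeding
aggregation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

DISEASE_GROUPS = (
    "CFEOM", "CP", "FNP", "DRS", "CFP", "MBS", "MGJW", "PTOSIS_MGJWS",
)

_SEX = {"1": "male", "2": "female"}
_STATUS = {"1": "unaffected", "2": "affected"}


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"          # male / female / unknown
    status: str = "unknown"       # affected / unaffected / unknown

    @property
    def affected(self) -> bool:
        return self.status == "affected"

    @property
    def unaffected(self) -> bool:
        return self.status == "unaffected"


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual]
    disease_group: str = "DRS"
    presentation: str = "isolated"   # isolated / syndromic
    structure: str = "other"         # trio / multiplex / other
    solved: bool = False
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {m.id: m for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._index:
                    raise ValueError(
                        f"{m.id}: parent {pid!r} not in family {self.family_id}"
                    )
        self._check_acyclic()
        if self.disease_group not in DISEASE_GROUPS:
            raise ValueError(f"unknown disease group {self.disease_group!r}")
        if not any(m.affected for m in self.members):
            warnings.warn(f"family {self.family_id} has no affected member")
        if self.structure == "auto":
            self.structure = self._infer_structure()

    def _check_acyclic(self) -> None:
        for m in self.members:
            seen = set()
            stack = [m.id]
            while stack:
                cur = stack.pop()
                ind = self._index[cur]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is None:
                        continue
                    if pid == m.id:
                        raise ValueError(
                            f"cyclic parentage: {m.id} is its own ancestor"
                        )
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def _infer_structure(self) -> str:
        affected = [m for m in self.members if m.affected]
        if (
            len(self.members) == 3
            and len(affected) == 1
            and affected[0].father_id is not None
            and affected[0].mother_id is not None
        ):
            return "trio"
        if len(affected) >= 2:
            return "multiplex"
        return "other"

    # -- convenience accessors -------------------------------------------
    def get(self, sample_id: str) -> Individual:
        return self._index[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def affected_members(self) -> list[Individual]:
        return [m for m in self.members if m.affected]

    def unaffected_members(self) -> list[Individual]:
        return [m for m in self.members if m.unaffected]

    def children_with_parents(self) -> list[Individual]:
        """Members whose father and mother are both present in the family."""
        return [
            m for m in self.members
            if m.father_id is not None and m.mother_id is not None
        ]


def read_pedigree(ped_path, phenotype_path) -> list[Pedigree]:
    """Read a 6-column PED file plus a phenotype table into pedigrees.

    PED columns: family, id, father, mother, sex (1/2), status (1/2);
    ``0`` encodes an absent parent / unknown sex or status. The phenotype
    TSV is keyed by ``family_id`` with columns ``disease_group``,
    ``presentation`` and ``solved`` (``solved``/``unsolved`` or a boolean
    literal). Families missing from the phenotype table raise.
    """
    import pandas as pd

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    pheno = pheno.set_index("family_id")

    by_family: dict[str, list[Individual]] = {}
    with open(ped_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fam, iid, fid, mid, sex, status = line.split()[:6]
            by_family.setdefault(fam, []).append(
                Individual(
                    id=iid,
                    family_id=fam,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX.get(sex, "unknown"),
                    status=_STATUS.get(status, "unknown"),
                )
            )
    out = []
    for fam, members in by_family.items():
        if fam not in pheno.index:
            raise ValueError(f"family {fam!r} absent from phenotype table")
        row = pheno.loc[fam]
        solved = str(row["solved"]).strip().lower() in {"solved", "true", "1", "yes"}
        out.append(
            Pedigree(
                family_id=fam,
                members=members,
                disease_group=str(row["disease_group"]),
                presentation=str(row["presentation"]),
                structure="auto",
                solved=solved,
            )
        )
    return out


def write_pedigree(pedigrees: list[Pedigree], ped_path, phenotype_path) -> None:
    """Emit PED + phenotype TSV in deterministic order."""
    with open(ped_path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                sex = {"male": "1", "female": "2"}.get(m.sex, "0")
                status = {"unaffected": "1", "affected": "2"}.get(m.status, "0")
                fh.write(
                    f"{ped.family_id}\t{m.id}\t{m.father_id or 0}\t"
                    f"{m.mother_id or 0}\t{sex}\t{status}\n"
                )
    with open(phenotype_path, "w") as fh:
        fh.write("family_id\tdisease_group\tpresentation\tsolved\n")
        for ped in pedigrees:
            fh.write(
                f"{ped.family_id}\t{ped.disease_group}\t{ped.presentation}\t"
                f"{'solved' if ped.solved else 'unsolved'}\n"
            )
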