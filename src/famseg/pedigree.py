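"""Pedigree structures for family-based variant filtering.

A pedigree here is the minimal object segregation filtering needs: who is
related to whom, who is affected with what (and at which age), and whose DNA
was actually sequenced.  Phenotypes are free-form labels (``breast_cancer``,
``lung_cancer``, ``rcc``, ``gist`` ...) with optional onset ages, matching how
clinical cancer-family studies record diagnoses; no ontology coding is
attempted.  An individual is *unaffected* for a given analysis simply when
none of their labels is in the disease label set under consideration, so a
relative with an unrelated diagnosis still counts as unaffected for
breast-cancer filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_PED_SEX = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
_PED_SEX_INV = {"1": MALE, "2": FEMALE, "0": UNKNOWN}


@dataclass(frozen=True)
class Phenotype:
    """A diagnosis label with an optional onset age in years."""

    label: str
    onset_age: int | None = None

    def __str__(self) -> str:
        if self.onset_age is None:
            return self.label
        return f"{self.label}@{self.onset_age}"

    @classmethod
    def parse(cls, text: str) -> "Phenotype":
        text = text.strip()
        if "@" in text:
            label, age = text.rsplit("@", 1)
            return cls(label, int(age))
        return cls(text)


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    phenotypes: frozenset[Phenotype] = frozenset()
    sequenced: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(p.label for p in self.phenotypes)

    def has_label(self, label: str) -> bool:
        return label in self.labels


@dataclass
class Pedigree:
    """A single family: an ordered mapping of individual id -> Individual."""

    family_id: str
    individuals: dict[str, Individual] = field(default_factory=dict)

    @classmethod
    def from_members(cls, family_id: str, members: Iterable[Individual]) -> "Pedigree":
        ped = cls(family_id)
        for ind in members:
            if ind.id in ped.individuals:
                raise ValueError(f"duplicate individual id {ind.id!r} in family {family_id}")
            ped.individuals[ind.id] = ind
        return ped

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals.values())

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.individuals

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[individual_id]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self if ind.is_founder]

    @property
    def sequenced_ids(self) -> list[str]:
        return [ind.id for ind in self if ind.sequenced]

    def label_vocabulary(self) -> frozenset[str]:
        """All phenotype labels observed anywhere in the family."""
        labels: set[str] = set()
        for ind in self:
            labels |= ind.labels
        return frozenset(labels)

    def topological_order(self) -> list[Individual]:
        """Members ordered parents-before-children (founders first).

        Raises ValueError if the parent graph is cyclic; run
        :func:`validate_pedigree` first for diagnostics instead of exceptions.
        """
        order: list[Individual] = []
        placed: set[str] = set()
        pending = list(self.individuals.values())
        while pending:
            progressed = False
            remaining = []
            for ind in pending:
                parents_ok = all(
                    pid is None or pid not in self.individuals or pid in placed
                    for pid in (ind.father_id, ind.mother_id)
                )
                if parents_ok:
                    order.append(ind)
                    placed.add(ind.id)
                    progressed = True
                else:
                    remaining.append(ind)
            if not progressed:
                raise ValueError(
                    f"pedigree {self.family_id}: cycle in parent graph involving "
                    + ", ".join(sorted(i.id for i in remaining))
                )
            pending = remaining
        return order


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    code: str
    message: str


def validate_pedigree(pedigree: Pedigree) -> list[Diagnostic]:
    """Check structural invariants; returns one diagnostic per violation.

    Never raises and never mutates its input: an empty list means the
    pedigree is internally consistent.  Checked: parent references resolve,
    parent sexes are compatible (father male, mother female; unknown-sex
    parents draw a warning), the parent graph is acyclic, onset ages are
    non-negative.
    """
    diags: list[Diagnostic] = []
    for ind in pedigree:
        for role, pid, wanted_sex in (
            ("father", ind.father_id, MALE),
            ("mother", ind.mother_id, FEMALE),
        ):
            if pid is None:
                continue
            if pid == ind.id:
                diags.append(
                    Diagnostic("error", "cycle", f"{ind.id} lists itself as its own {role}")
                )
                continue
            parent = pedigree.individuals.get(pid)
            if parent is None:
                diags.append(
                    Diagnostic(
                        "error", "missing-parent", f"{role} {pid!r} of {ind.id} is not in the pedigree"
                    )
                )
            elif parent.sex == UNKNOWN:
                diags.append(
                    Diagnostic(
                        "warning",
                        "unknown-parent-sex",
                        f"{role} {pid} of {ind.id} has unknown sex",
                    )
                )
            elif parent.sex != wanted_sex:
                diags.append(
                    Diagnostic(
                        "error",
                        "sex-inconsistency",
                        f"{role} {pid} of {ind.id} is recorded as {parent.sex}",
                    )
                )
        for ph in ind.phenotypes:
            if ph.onset_age is not None and ph.onset_age < 0:
                diags.append(
                    Diagnostic(
                        "error",
                        "negative-onset",
                        f"{ind.id}: negative onset age for {ph.label}",
                    )
                )
    # acyclicity (self-parenting already reported above; deeper cycles here)
    if not any(d.code == "cycle" for d in diags):
        try:
            pedigree.topological_order()
        except ValueError as exc:
            diags.append(Diagnostic("error", "cycle", str(exc)))
    return diags


@dataclass(frozen=True)
class PhenotypeQuery:
    """Select individuals by phenotype labels.

    ``all_of``: every required label must be present (e.g. the breast+lung
    double-primary patients); ``any_of``: at least one must be.
    """

    required_labels: frozenset[str]
    mode: str = "all_of"  # "all_of" | "any_of"

    def __post_init__(self) -> None:
        if not self.required_labels:
            raise ValueError("PhenotypeQuery requires at least one label")
        if self.mode not in ("all_of", "any_of"):
            raise ValueError(f"unknown query mode {self.mode!r}")

    def matches(self, individual: Individual) -> bool:
        labels = individual.labels
        if self.mode == "all_of":
            return self.required_labels <= labels
        return bool(self.required_labels & labels)


def select_individuals(
    pedigree: Pedigree,
    query: PhenotypeQuery,
    sequenced_only: bool = False,
    allow_unknown_labels: bool = False,
) -> set[str]:
    """Ids of family members whose phenotype labels satisfy ``query``.

    A query label that occurs nowhere in the pedigree is treated as a likely
    typo and raises, unless ``allow_unknown_labels`` is set.
    """
    if not allow_unknown_labels:
        vocab = pedigree.label_vocabulary()
        unknown = query.required_labels - vocab
        if unknown:
            raise ValueError(
                f"unknown phenotype label(s) {sorted(unknown)} in family {pedigree.family_id}; "
                f"known labels: {sorted(vocab)}"
            )
    hits = {ind.id for ind in pedigree if query.matches(ind)}
    if sequenced_only:
        hits &= set(pedigree.sequenced_ids)
    return hits


# ---------------------------------------------------------------------------
# PED I/O (6-column pre-makeped format) + phenotype sidecar
# ---------------------------------------------------------------------------

def write_ped(pedigree: Pedigree, ped_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write a 6-column PED file plus an optional phenotype sidecar.

    PED columns: family, individual, father, mother, sex (1/2/0), phenotype
    (2 = any phenotype label recorded, 1 = none).  The sidecar is a TSV with
    columns individual / phenotypes / sequenced, where phenotypes is a
    comma-separated list of ``label@age`` (age optional).
    """
    lines = []
    for ind in pedigree:
        status = "2" if ind.phenotypes else "1"
        lines.append(
            "\t".join(
                [
                    pedigree.family_id,
                    ind.id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    _PED_SEX[ind.sex],
                    status,
                ]
            )
        )
    Path(ped_path).write_text("\n".join(lines) + "\n")
    if sidecar_path is not None:
        rows = ["individual\tphenotypes\tsequenced"]
        for ind in pedigree:
            phen = ",".join(str(p) for p in sorted(ind.phenotypes, key=str)) or "."
            rows.append(f"{ind.id}\t{phen}\t{int(ind.sequenced)}")
        Path(sidecar_path).write_text("\n".join(rows) + "\n")


def read_ped(ped_path: str | Path, sidecar_path: str | Path | None = None) -> Pedigree:
    """Read a 6-column PED file (single family) and optional sidecar."""
    sidecar: dict[str, tuple[frozenset[Phenotype], bool]] = {}
    if sidecar_path is not None:
        text = Path(sidecar_path).read_text().strip().splitlines()
        for line in text[1:]:
            iid, phen, seq = line.rstrip("\n").split("\t")
            phenos = frozenset() if phen in (".", "") else frozenset(
                Phenotype.parse(p) for p in phen.split(",")
            )
            sidecar[iid] = (phenos, bool(int(seq)))

    family_id = None
    members: list[Individual] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"{ped_path}: line {lineno}: expected 6 PED columns")
        fam, iid, fid, mid, sex, status = fields[:6]
        if family_id is None:
            family_id = fam
        elif fam != family_id:
            raise ValueError(f"{ped_path}: line {lineno}: multiple families in one file")
        phenos, seq = sidecar.get(iid, (frozenset(), False))
        if not phenos and status == "2":
            phenos = frozenset({Phenotype("affected")})
        members.append(
            Individual(
                id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_PED_SEX_INV.get(sex, UNKNOWN),
                phenotypes=phenos,
                sequenced=seq,
            )
        )
    if family_id is None:
        raise ValueError(f"{ped_path}: empty PED file")
    return Pedigree.from_members(family_id, members)
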