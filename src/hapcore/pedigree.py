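"""Nuclear-family genotype containers.

The analysis unit is the nuclear family: father, mother, and an ordered list
of children.  When a family is analyzed for association, its children are
reordered so that the first child is the first affected one (the proband);
the proband's parental haplotypes define the transmitted group, the parents'
other haplotypes the non-transmitted group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "AFFECTED",
    "UNAFFECTED",
    "UNKNOWN",
    "SnpPanel",
    "Genotype",
    "Individual",
    "Family",
    "FamilySet",
    "validate_family",
]

UNKNOWN = 0
UNAFFECTED = 1
AFFECTED = 2


@dataclass(frozen=True)
class SnpPanel:
    """The ordered marker panel spanning the haplotype block."""

    marker_ids: tuple
    liability_index: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        if self.n_markers < 1:
            raise ValueError("panel needs at least one marker")
        if self.liability_index is not None and not (
            0 <= self.liability_index < self.n_markers
        ):
            raise ValueError("liability_index out of range")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def from_length(cls, n_markers: int, liability_index: Optional[int] = None) -> "SnpPanel":
        return cls(tuple(f"M{i + 1}" for i in range(n_markers)), liability_index)


class Genotype:
    """Unphased multilocus genotype: one unordered allele pair per marker.

    Alleles are coded 1/2; 0 means missing, and both alleles of a marker are
    missing together.  Three bitmasks summarize the genotype for fast
    compatibility checks against haplotype bitmasks:

    * ``care_mask`` — markers with observed alleles,
    * ``het_mask``  — observed heterozygous markers,
    * ``hom2_mask`` — observed markers homozygous for allele 2.

    A haplotype pair ``(x, y)`` (bitmask encoded) reproduces the genotype iff
    ``(x ^ y) & care == het`` and ``(x & y) & care == hom2``.
    """

    __slots__ = ("a1", "a2", "care_mask", "het_mask", "hom2_mask")

    def __init__(self, a1, a2) -> None:
        a1 = tuple(int(a) for a in a1)
        a2 = tuple(int(a) for a in a2)
        if len(a1) != len(a2):
            raise ValueError("allele vectors differ in length")
        care = het = hom2 = 0
        for i, (x, y) in enumerate(zip(a1, a2)):
            if x not in (0, 1, 2) or y not in (0, 1, 2):
                raise ValueError(f"invalid allele code at marker {i}: {x}/{y}")
            if (x == 0) != (y == 0):
                raise ValueError(
                    f"marker {i} half-missing; both alleles must be missing together"
                )
            if x == 0:
                continue
            care |= 1 << i
            if x != y:
                het |= 1 << i
            elif x == 2:
                hom2 |= 1 << i
        self.a1 = a1
        self.a2 = a2
        self.care_mask = care
        self.het_mask = het
        self.hom2_mask = hom2

    @classmethod
    def from_haplotypes(cls, h1: int, h2: int, n_markers: int) -> "Genotype":
        """Collapse an ordered haplotype pair (bitmasks) to an unphased genotype."""
        a1 = tuple(2 if (h1 >> i) & 1 else 1 for i in range(n_markers))
        a2 = tuple(2 if (h2 >> i) & 1 else 1 for i in range(n_markers))
        return cls(a1, a2)

    @property
    def n_markers(self) -> int:
        return len(self.a1)

    def is_missing(self, i: int) -> bool:
        return self.a1[i] == 0

    def alleles_at(self, i: int) -> tuple:
        return (self.a1[i], self.a2[i])

    def __eq__(self, other) -> bool:
        return isinstance(other, Genotype) and self.a1 == other.a1 and self.a2 == other.a2

    def __hash__(self) -> int:
        return hash((self.a1, self.a2))

    def __repr__(self) -> str:
        pairs = " ".join(f"{x}/{y}" for x, y in zip(self.a1, self.a2))
        return f"Genotype({pairs})"


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str
    mother_id: str
    sex: int
    affection: int
    genotype: Genotype

    @property
    def is_founder(self) -> bool:
        return self.father_id == "0" and self.mother_id == "0"


@dataclass
class Family:
    """A father-mother-children unit; children keep their input order."""

    father: Individual
    mother: Individual
    children: list

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("family must have at least one child")

    @property
    def family_id(self) -> str:
        return self.father.family_id

    @property
    def n_children(self) -> int:
        return len(self.children)

    def members(self) -> Iterator[Individual]:
        yield self.father
        yield self.mother
        yield from self.children

    def first_affected_index(self) -> Optional[int]:
        for i, child in enumerate(self.children):
            if child.affection == AFFECTED:
                return i
        return None

    @property
    def has_affected_child(self) -> bool:
        return self.first_affected_index() is not None


@dataclass
class FamilySet:
    panel: SnpPanel
    families: list = field(default_factory=list)

    def __post_init__(self) -> None:
        L = self.panel.n_markers
        for fam in self.families:
            for ind in fam.members():
                if ind.genotype.n_markers != L:
                    raise ValueError(
                        f"genotype length {ind.genotype.n_markers} of "
                        f"{ind.family_id}/{ind.individual_id} does not match panel ({L})"
                    )

    @property
    def n(self) -> int:
        return len(self.families)

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[Family]:
        return iter(self.families)


def _pair_options(g: Genotype, i: int):
    """Possible single-allele contributions of a parent at marker i."""
    if g.is_missing(i):
        return (1, 2)
    x, y = g.alleles_at(i)
    return (x,) if x == y else (x, y)


def validate_family(fam: Family) -> list:
    """Report per-marker Mendelian impossibilities at the genotype level.

    A child's allele pair at a marker must be producible from one paternal
    and one maternal allele; missing markers act as wildcards.  Returns a
    list of human-readable issue strings (empty means clean).  This is a
    marker-wise check and deliberately ignores haplotype-level phase
    constraints, which the explanation machinery enforces separately.
    """
    issues = []
    L = fam.father.genotype.n_markers
    for child in fam.children:
        g = child.genotype
        for i in range(L):
            if g.is_missing(i):
                continue
            c1, c2 = g.alleles_at(i)
            pf = _pair_options(fam.father.genotype, i)
            pm = _pair_options(fam.mother.genotype, i)
            ok = any(
                (a == c1 and b == c2) or (a == c2 and b == c1)
                for a in pf
                for b in pm
            )
            if not ok:
                issues.append(
                    f"family {fam.family_id}, child {child.individual_id}, marker {i}: "
                    f"genotype {c1}/{c2} not producible from parents"
                )
    return issues
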