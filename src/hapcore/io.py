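"""Reading and writing linkage PED files and haplotype pool tables.

The PED dialect is the classic pre-makeped layout: six leading columns
(family, individual, father, mother, sex, affection) followed by two allele
columns per marker.  Affection is coded 2 = affected, 1 = unaffected,
0 = unknown.  Pool tables are two-column TSVs (haplotype, frequency).
"""

from __future__ import annotations

import logging

import pandas as pd

from .haplotypes import HaplotypeTable
from .pedigree import Family, FamilySet, Genotype, Individual, SnpPanel

__all__ = [
    "PedFormatError",
    "PedStructureError",
    "read_ped",
    "write_ped",
    "read_haplotype_pool",
    "write_haplotype_pool",
]

logger = logging.getLogger("hapcore")


class PedFormatError(ValueError):
    """Malformed PED line (wrong column count, bad allele code, ...)."""


class PedStructureError(ValueError):
    """Structurally inconsistent pedigree (e.g. child references absent parent)."""


def _parse_line(line: str, lineno: int, n_markers: int | None):
    fields = line.split()
    if len(fields) < 6:
        raise PedFormatError(f"line {lineno}: fewer than 6 columns")
    allele_cols = fields[6:]
    if len(allele_cols) % 2 != 0:
        raise PedFormatError(f"line {lineno}: odd number of allele columns")
    L = len(allele_cols) // 2
    if n_markers is not None and L != n_markers:
        raise PedFormatError(
            f"line {lineno}: {L} markers, expected {n_markers}"
        )
    fam_id, ind_id, fa_id, mo_id, sex_s, aff_s = fields[:6]
    try:
        sex = int(sex_s)
    except ValueError:
        raise PedFormatError(f"line {lineno}: bad sex code {sex_s!r}") from None
    if sex not in (0, 1, 2):
        sex = 0
    if aff_s in ("-9", "-"):
        aff = 0
    else:
        try:
            aff = int(aff_s)
        except ValueError:
            raise PedFormatError(f"line {lineno}: bad affection code {aff_s!r}") from None
        if aff not in (0, 1, 2):
            raise PedFormatError(f"line {lineno}: bad affection code {aff_s!r}")
    try:
        alleles = [int(a) for a in allele_cols]
    except ValueError:
        raise PedFormatError(f"line {lineno}: non-integer allele code") from None
    a1 = alleles[0::2]
    a2 = alleles[1::2]
    try:
        genotype = Genotype(a1, a2)
    except ValueError as exc:
        raise PedFormatError(f"line {lineno}: {exc}") from None
    return Individual(fam_id, ind_id, fa_id, mo_id, sex, aff, genotype), L


def read_ped(path, panel_hint: int | None = None) -> FamilySet:
    """Read a whitespace-delimited linkage PED file into a :class:`FamilySet`.

    Pedigrees are split into independent father-mother-children nuclear
    units.  The marker count is inferred from the column count unless
    ``panel_hint`` pins it.  Individuals that are neither parents nor
    children of anyone (childless founders) are dropped with a log message.
    """
    individuals: list[Individual] = []
    n_markers = panel_hint
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ind, L = _parse_line(line, lineno, n_markers)
            n_markers = L
            individuals.append(ind)
    if not individuals:
        return FamilySet(SnpPanel.from_length(panel_hint or 1), [])

    by_key = {(ind.family_id, ind.individual_id): ind for ind in individuals}
    if len(by_key) != len(individuals):
        raise PedStructureError("duplicate (family, individual) identifier")

    # group children by their (father, mother) couple, preserving file order
    units: dict[tuple, list[Individual]] = {}
    used = set()
    for ind in individuals:
        if ind.is_founder:
            continue
        if ind.father_id == "0" or ind.mother_id == "0":
            raise PedStructureError(
                f"{ind.family_id}/{ind.individual_id}: child must reference both parents"
            )
        fa = by_key.get((ind.family_id, ind.father_id))
        mo = by_key.get((ind.family_id, ind.mother_id))
        if fa is None or mo is None:
            raise PedStructureError(
                f"{ind.family_id}/{ind.individual_id}: parent not present in file"
            )
        key = (ind.family_id, ind.father_id, ind.mother_id)
        units.setdefault(key, []).append(ind)
        used.add((ind.family_id, ind.individual_id))
        used.add((ind.family_id, ind.father_id))
        used.add((ind.family_id, ind.mother_id))

    families = []
    for (fam_id, fa_id, mo_id), children in units.items():
        father = by_key[(fam_id, fa_id)]
        mother = by_key[(fam_id, mo_id)]
        families.append(Family(father, mother, list(children)))

    n_dropped = sum(1 for ind in individuals
                    if (ind.family_id, ind.individual_id) not in used)
    if n_dropped:
        logger.info("read_ped: dropped %d childless unattached individuals", n_dropped)
    return FamilySet(SnpPanel.from_length(n_markers), families)


def _format_individual(ind: Individual) -> str:
    geno = " ".join(f"{x} {y}" for x, y in zip(ind.genotype.a1, ind.genotype.a2))
    return (
        f"{ind.family_id} {ind.individual_id} {ind.father_id} {ind.mother_id} "
        f"{ind.sex} {ind.affection} {geno}"
    )


def write_ped(fams: FamilySet, path) -> None:
    """Write a FamilySet back to linkage PED; re-readable by :func:`read_ped`."""
    with open(path, "w") as fh:
        for fam in fams:
            for ind in fam.members():
                fh.write(_format_individual(ind) + "\n")


def read_haplotype_pool(path) -> HaplotypeTable:
    """Read a haplotype pool TSV with columns ``haplotype`` and ``frequency``.

    Frequencies are renormalized if their sum is within 0.01 of 1 and
    rejected otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"haplotype": str})
    for col in ("haplotype", "frequency"):
        if col not in df.columns:
            raise ValueError(f"pool file missing column {col!r}")
    haps = df["haplotype"].tolist()
    freqs = df["frequency"].to_numpy(dtype=float)
    if len(set(haps)) != len(haps):
        raise ValueError("duplicate haplotype in pool file")
    if (freqs < 0).any():
        raise ValueError("negative frequency in pool file")
    return HaplotypeTable.normalized(haps, freqs, tol=0.01)


def write_haplotype_pool(table: HaplotypeTable, path) -> None:
    pd.DataFrame(
        {"haplotype": table.haplotypes, "frequency": table.frequencies}
    ).to_csv(path, sep="\t", index=False)
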