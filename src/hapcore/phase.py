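"""Haplotype explanation sets for nuclear families.

For a family with unphased genotypes, an *explanation* is an ordered
quadruple ``(j, k, u, v)`` of haplotype indices: ``j`` is the father's
haplotype transmitted to the proband, ``k`` his non-transmitted one, and
``u``/``v`` the mother's transmitted/non-transmitted haplotypes.  Each
explanation carries the product over the remaining children of the
transmission count ``s`` — the number of the four gamete combinations
``(j,u), (j,v), (k,u), (k,v)`` compatible with that child's genotype.
Explanations whose ``s`` product vanishes are discarded.

The proband-conditional set requires ``(j, u)`` to reproduce the proband's
genotype exactly; the unconditional set drops that constraint and folds the
proband into the ``s`` product, which makes it invariant to the choice of
proband — the property that lets a single pooled frequency estimate serve
every family regardless of ascertainment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .haplotypes import HaplotypeTable, int_to_hap
from .pedigree import AFFECTED, Family, FamilySet, Genotype

__all__ = [
    "Explanation",
    "ExplanationSet",
    "ExplosionError",
    "NoAffectedChildError",
    "reorder_children",
    "compatible_pairs",
    "transmission_count_s",
    "build_explanations",
    "infer_candidate_haplotypes",
]

DEFAULT_EXPLANATION_CAP = 100_000


class NoAffectedChildError(ValueError):
    """Family has no affected child and cannot define a proband."""


class ExplosionError(RuntimeError):
    """Explanation or candidate enumeration exceeded its configured cap."""


@dataclass
class Explanation:
    j: int
    k: int
    u: int
    v: int
    s_product: int
    weight: Optional[float] = None


@dataclass
class ExplanationSet:
    family: Family
    mode: str  # "proband" or "unconditional"
    explanations: list

    def __len__(self) -> int:
        return len(self.explanations)

    def set_weights(self, freqs: np.ndarray) -> None:
        """Populate posterior weights proportional to pi_j pi_k pi_u pi_v s."""
        w = np.array(
            [
                freqs[e.j] * freqs[e.k] * freqs[e.u] * freqs[e.v] * e.s_product
                for e in self.explanations
            ],
            dtype=float,
        )
        total = w.sum()
        if total <= 0:
            raise ValueError("explanation weights sum to zero")
        for e, wi in zip(self.explanations, w / total):
            e.weight = float(wi)


def dump_explanations(expl_sets, path) -> None:
    """Write explanation sets as a debugging TSV
    (family_id, j, k, u, v, s_product, weight)."""
    with open(path, "w") as fh:
        fh.write("family_id\tj\tk\tu\tv\ts_product\tweight\n")
        for es in expl_sets:
            for e in es.explanations:
                w = "" if e.weight is None else f"{e.weight:.6g}"
                fh.write(
                    f"{es.family.family_id}\t{e.j}\t{e.k}\t{e.u}\t{e.v}\t"
                    f"{e.s_product}\t{w}\n"
                )


def reorder_children(fam: Family) -> Family:
    """Return the family with the first affected child moved to position 0.

    The relative order of the remaining children is preserved.  Raises
    :class:`NoAffectedChildError` when no child is affected, since such a
    family cannot contribute a proband-conditional explanation set.
    """
    idx = fam.first_affected_index()
    if idx is None:
        raise NoAffectedChildError(
            f"family {fam.family_id} has no affected child"
        )
    children = [fam.children[idx]] + fam.children[:idx] + fam.children[idx + 1:]
    return Family(fam.father, fam.mother, children)


def _merged_matches(x, y, g: Genotype):
    """Whether haplotype bitmasks x, y merge to genotype g at observed markers.

    Works elementwise on numpy arrays as well as on scalars.
    """
    care, het, hom2 = g.care_mask, g.het_mask, g.hom2_mask
    return (((x ^ y) & care) == het) & (((x & y) & care) == hom2)


def compatible_pairs(g: Genotype, candidates: HaplotypeTable) -> set:
    """Unordered candidate index pairs whose merge reproduces ``g``.

    Missing markers match anything; ``(a, a)`` pairs are allowed.  The
    result may be empty if no candidate pair explains the genotype.
    """
    ints = candidates.as_ints()
    H = len(ints)
    X = ints[:, None]
    Y = ints[None, :]
    ok = _merged_matches(X, Y, g)
    pairs = set()
    for a in range(H):
        for b in range(a, H):
            if ok[a, b]:
                pairs.add((a, b))
    return pairs


def transmission_count_s(
    j: int, k: int, u: int, v: int, g_child: Genotype, candidates: HaplotypeTable
) -> int:
    """The s-function: how many of the four gamete combinations from the
    ordered parental quadruple ``(j, k, u, v)`` are compatible with the
    child's genotype (an integer in 0..4)."""
    ints = candidates.as_ints()
    hj, hk, hu, hv = (int(ints[i]) for i in (j, k, u, v))
    return int(
        bool(_merged_matches(hj, hu, g_child))
        + bool(_merged_matches(hj, hv, g_child))
        + bool(_merged_matches(hk, hu, g_child))
        + bool(_merged_matches(hk, hv, g_child))
    )


def _ordered_parent_pairs(g: Genotype, ints: np.ndarray) -> np.ndarray:
    """All ordered index pairs (a, b) compatible with a parent's genotype."""
    ok = _merged_matches(ints[:, None], ints[None, :], g)
    a, b = np.nonzero(ok)
    return np.stack([a, b], axis=1)


def _explanation_arrays(
    fam: Family,
    candidates: HaplotypeTable,
    mode: str = "proband",
    cap: int = DEFAULT_EXPLANATION_CAP,
):
    """Vectorized enumeration of the explanation quadruples of one family.

    Returns arrays (j, k, u, v, s_product); in proband mode the family must
    already have the proband first.
    """
    ints = candidates.as_ints()
    pf = _ordered_parent_pairs(fam.father.genotype, ints)
    pm = _ordered_parent_pairs(fam.mother.genotype, ints)
    if len(pf) == 0 or len(pm) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z, z, np.zeros(0, dtype=float)

    if mode == "proband":
        proband = fam.children[0]
        if proband.affection != AFFECTED:
            raise NoAffectedChildError(
                f"family {fam.family_id}: first child is not affected; "
                "call reorder_children first"
            )
        # prune parent pairs that cannot transmit to the proband before
        # forming the cross product
        Mp = _merged_matches(ints[:, None], ints[None, :], proband.genotype)
        pf = pf[Mp[pf[:, 0]].any(axis=1)]
        pm = pm[Mp[:, pm[:, 0]].any(axis=0)]
        if len(pf) == 0 or len(pm) == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z, z, z, np.zeros(0, dtype=float)
        others = fam.children[1:]
    elif mode == "unconditional":
        others = fam.children
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if len(pf) * len(pm) > max(100 * cap, 1_000_000):
        raise ExplosionError(
            f"family {fam.family_id}: {len(pf) * len(pm)} candidate quadruples; "
            "consider windowing the markers"
        )
    nf, nm = len(pf), len(pm)
    j = np.repeat(pf[:, 0], nm)
    k = np.repeat(pf[:, 1], nm)
    u = np.tile(pm[:, 0], nf)
    v = np.tile(pm[:, 1], nf)
    if mode == "proband":
        keep = Mp[j, u]
        j, k, u, v = j[keep], k[keep], u[keep], v[keep]

    s = np.ones(len(j), dtype=float)
    hj, hk, hu, hv = ints[j], ints[k], ints[u], ints[v]
    for child in others:
        g = child.genotype
        sc = (
            _merged_matches(hj, hu, g).astype(np.int64)
            + _merged_matches(hj, hv, g)
            + _merged_matches(hk, hu, g)
            + _merged_matches(hk, hv, g)
        )
        s *= sc
    keep = s > 0
    j, k, u, v, s = j[keep], k[keep], u[keep], v[keep], s[keep]
    if len(j) > cap:
        raise ExplosionError(
            f"family {fam.family_id}: {len(j)} retained explanations exceed "
            f"the cap of {cap}"
        )
    return j, k, u, v, s


def build_explanations(
    fam: Family,
    candidates: HaplotypeTable,
    mode: str = "proband",
    cap: int = DEFAULT_EXPLANATION_CAP,
) -> ExplanationSet:
    """Enumerate the explanation set of a family over a candidate table."""
    if mode == "proband":
        fam = reorder_children(fam)
    j, k, u, v, s = _explanation_arrays(fam, candidates, mode=mode, cap=cap)
    expls = [
        Explanation(int(a), int(b), int(c), int(d), int(si))
        for a, b, c, d, si in zip(j, k, u, v, s)
    ]
    return ExplanationSet(fam, mode, expls)


# -- candidate inference -------------------------------------------------


def _compatible_diplotypes(g: Genotype, cap: int) -> list:
    """All unordered haplotype bitmask pairs compatible with one genotype.

    Enumerates assignments of the heterozygous markers (one side fixed by
    symmetry) and, for missing markers, all four allele combinations.
    """
    het_bits = [i for i in range(g.n_markers) if (g.het_mask >> i) & 1]
    miss_bits = [i for i in range(g.n_markers) if not (g.care_mask >> i) & 1]
    n = max(0, len(het_bits) - 1) + 2 * len(miss_bits)
    if 2 ** n > cap:
        raise ExplosionError(
            f"genotype with {len(het_bits)} heterozygous and {len(miss_bits)} "
            f"missing markers yields too many diplotypes (> {cap}); "
            "consider windowing the markers"
        )
    base = g.hom2_mask
    pairs = set()
    het_free = het_bits[1:]
    first_het = het_bits[0] if het_bits else None
    for hsel in range(1 << len(het_free)):
        x = base
        y = base
        if first_het is not None:
            x |= 1 << first_het  # fix orientation at the first het site
        for t, bit in enumerate(het_free):
            if (hsel >> t) & 1:
                x |= 1 << bit
            else:
                y |= 1 << bit
        for msel in range(1 << (2 * len(miss_bits))):
            xx, yy = x, y
            for t, bit in enumerate(miss_bits):
                if (msel >> (2 * t)) & 1:
                    xx |= 1 << bit
                if (msel >> (2 * t + 1)) & 1:
                    yy |= 1 << bit
            pairs.add((min(xx, yy), max(xx, yy)))
    return sorted(pairs)


def _filter_pairs_by_children(pairs, children):
    """Drop parental diplotypes that cannot supply a gamete to some child.

    A haplotype h can be a parent's gamete for a child only if, at every
    observed marker, h's allele occurs in the child's pair; a diplotype
    (a, b) is viable only if a or b passes this for every child.  This is a
    necessary condition, used as a cheap pre-filter before the joint
    parental enumeration.
    """
    if not pairs:
        return pairs
    a = np.array([p[0] for p in pairs], dtype=np.int64)
    b = np.array([p[1] for p in pairs], dtype=np.int64)
    keep = np.ones(len(pairs), dtype=bool)
    for child in children:
        g = child.genotype
        hom1 = g.care_mask & ~g.het_mask & ~g.hom2_mask
        hom2 = g.hom2_mask

        def half_ok(h):
            return ((h & hom1) == 0) & ((h & hom2) == hom2)

        keep &= half_ok(a) | half_ok(b)
    return [p for p, k in zip(pairs, keep) if k]


def infer_candidate_haplotypes(
    fams: FamilySet,
    pair_cap: int = 4096,
    cap: int = DEFAULT_EXPLANATION_CAP,
) -> HaplotypeTable:
    """Reconstruct the candidate haplotype universe from a family set.

    For each family, parental diplotypes are enumerated from the genotypes
    alone and jointly filtered: a parental configuration survives only if
    every child's genotype is compatible with at least one of its gamete
    combinations.  The union of haplotypes appearing in surviving
    configurations, with uniform initial frequencies, is the candidate
    table handed to the EM.
    """
    if fams.n == 0:
        raise ValueError("empty FamilySet")
    L = fams.panel.n_markers
    found: set[int] = set()
    for fam in fams:
        pf = _filter_pairs_by_children(
            _compatible_diplotypes(fam.father.genotype, pair_cap), fam.children
        )
        pm = _filter_pairs_by_children(
            _compatible_diplotypes(fam.mother.genotype, pair_cap), fam.children
        )
        if len(pf) * len(pm) > 100 * cap:
            raise ExplosionError(
                f"family {fam.family_id}: joint parental enumeration too large; "
                "consider windowing the markers"
            )
        fa = np.array([p[0] for p in pf], dtype=np.int64)
        fb = np.array([p[1] for p in pf], dtype=np.int64)
        ma = np.array([p[0] for p in pm], dtype=np.int64)
        mb = np.array([p[1] for p in pm], dtype=np.int64)
        # chunk the father side so transient grids stay small
        chunk = max(1, min(len(fa), 2_000_000 // max(len(ma), 1)))
        for lo in range(0, len(fa), chunk):
            FA = np.repeat(fa[lo:lo + chunk], len(ma))
            FB = np.repeat(fb[lo:lo + chunk], len(ma))
            MA = np.tile(ma, len(fa[lo:lo + chunk]))
            MB = np.tile(mb, len(fa[lo:lo + chunk]))
            ok = np.ones(len(FA), dtype=bool)
            for child in fam.children:
                g = child.genotype
                sc = (
                    _merged_matches(FA, MA, g)
                    | _merged_matches(FA, MB, g)
                    | _merged_matches(FB, MA, g)
                    | _merged_matches(FB, MB, g)
                )
                ok &= sc
                if not ok.any():
                    break
            for arr in (FA[ok], FB[ok], MA[ok], MB[ok]):
                found.update(int(x) for x in np.unique(arr))
    if not found:
        raise ValueError("no candidate haplotype is compatible with the data")
    haps = sorted(int_to_hap(x, L) for x in found)
    freqs = np.full(len(haps), 1.0 / len(haps))
    return HaplotypeTable(haps, freqs)
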