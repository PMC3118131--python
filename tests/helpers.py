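"""Independent brute-force oracles and small construction helpers.

Everything here deliberately avoids the package's bitmask machinery:
compatibility is checked positionwise on allele strings, explanation sets
are enumerated with plain quadruple loops, and maximum-likelihood estimates
come from exhaustive simplex grids, so these routines can serve as
independent references for the vectorized implementations.
"""

from itertools import product

import numpy as np

from hapcore.haplotypes import HaplotypeTable
from hapcore.pedigree import (
    AFFECTED,
    Family,
    FamilySet,
    Genotype,
    Individual,
    SnpPanel,
    UNAFFECTED,
)
from hapcore.phase import reorder_children


def geno_from_strings(h1: str, h2: str) -> Genotype:
    return Genotype([int(c) for c in h1], [int(c) for c in h2])


def make_family(father, mother, children, family_id="F1"):
    """Handcraft a nuclear family from haplotype-string pairs.

    ``father``/``mother`` are (hap1, hap2) string pairs; ``children`` is a
    list of (hap1, hap2, affection) triples.  Genotypes are the unphased
    collapse of the pairs.
    """

    def person(ind_id, fa, mo, sex, aff, pair):
        return Individual(family_id, ind_id, fa, mo, sex, aff,
                          geno_from_strings(pair[0], pair[1]))

    fa = person("1", "0", "0", 1, 0, father)
    mo = person("2", "0", "0", 2, 0, mother)
    kids = [
        person(str(3 + i), "1", "2", 1, aff, (h1, h2))
        for i, (h1, h2, aff) in enumerate(children)
    ]
    return Family(fa, mo, kids)


def family_set(families, liability_index=None):
    L = families[0].father.genotype.n_markers
    return FamilySet(SnpPanel.from_length(L, liability_index), list(families))


# -- positionwise compatibility oracle ----------------------------------


def merge_matches_oracle(h1: str, h2: str, g: Genotype) -> bool:
    """Whether two haplotype strings collapse to genotype g (missing = wildcard)."""
    for i in range(g.n_markers):
        if g.is_missing(i):
            continue
        if sorted((int(h1[i]), int(h2[i]))) != sorted(g.alleles_at(i)):
            return False
    return True


def s_oracle(hj, hk, hu, hv, g: Genotype) -> int:
    return sum(
        merge_matches_oracle(a, b, g)
        for a, b in ((hj, hu), (hj, hv), (hk, hu), (hk, hv))
    )


def brute_force_explanations(fam: Family, table: HaplotypeTable, mode="proband"):
    """Quadruple-loop enumeration of explanation quadruples (j, k, u, v, s)."""
    H = len(table)
    haps = table.haplotypes
    if mode == "proband":
        fam = reorder_children(fam)
        proband = fam.children[0]
        others = fam.children[1:]
    else:
        proband = None
        others = fam.children
    out = []
    for j, k, u, v in product(range(H), repeat=4):
        if not merge_matches_oracle(haps[j], haps[k], fam.father.genotype):
            continue
        if not merge_matches_oracle(haps[u], haps[v], fam.mother.genotype):
            continue
        if proband is not None and not merge_matches_oracle(
            haps[j], haps[u], proband.genotype
        ):
            continue
        s = 1
        for child in others:
            s *= s_oracle(haps[j], haps[k], haps[u], haps[v], child.genotype)
            if s == 0:
                break
        if s > 0:
            out.append((j, k, u, v, s))
    return out


# -- likelihood oracle and exhaustive-grid MLEs -------------------------


def loglik_oracle(fams, table, freqs_tr, freqs_ntr=None, scores=None, mode="proband"):
    """Log-likelihood from brute-force explanations and direct products.

    ``scores`` optionally maps a parameter vector to per-haplotype scores
    (for recoded likelihoods); identity by default.  ``freqs_ntr`` defaults
    to ``freqs_tr`` (the null restriction).
    """
    if scores is None:
        scores = lambda g: np.asarray(g, float)  # noqa: E731
    ft = np.maximum(scores(freqs_tr), 1e-12)
    fn = ft if freqs_ntr is None else np.maximum(scores(freqs_ntr), 1e-12)
    total = 0.0
    for fam in fams:
        contrib = sum(
            ft[j] * ft[u] * fn[k] * fn[v] * s
            for j, k, u, v, s in brute_force_explanations(fam, table, mode)
        )
        total += np.log(max(contrib, 1e-300))
    return float(total)


def simplex_grid(n_dim: int, step: float):
    """All frequency vectors on the n-simplex lattice with spacing ``step``."""
    m = round(1.0 / step)
    if n_dim == 1:
        yield np.array([1.0])
        return
    for combo in _compositions(m, n_dim):
        yield np.array(combo, dtype=float) / m


def _compositions(total, parts):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def grid_mle(fams, table, n_dim, step=1e-3, scores=None, mode="proband",
             tr_ntr=False):
    """Exhaustive-grid maximum likelihood over the simplex (or a tr/ntr pair).

    Vectorizes the evaluation over brute-force explanation rows; with
    ``tr_ntr`` the search is over the product of two simplex lattices.
    Returns (argmax, max loglik).
    """
    rows = []
    fam_of_row = []
    for fi, fam in enumerate(fams):
        for row in brute_force_explanations(fam, table, mode):
            rows.append(row)
            fam_of_row.append(fi)
    rows = np.array(rows)
    fam_of_row = np.array(fam_of_row)
    n_fam = fam_of_row.max() + 1
    j, k, u, v, s = rows.T
    if scores is None:
        scores = lambda g: np.asarray(g, float)  # noqa: E731

    grid = np.array(list(simplex_grid(n_dim, step)))

    def fam_terms(gt_scores, gn_scores):
        # gt_scores: (G, H) -> per-grid-point per-family likelihood (G, n_fam)
        w = gt_scores[:, j] * gt_scores[:, u] * gn_scores[:, k] * gn_scores[:, v] * s
        out = np.zeros((w.shape[0], n_fam))
        for fi in range(n_fam):
            out[:, fi] = w[:, fam_of_row == fi].sum(axis=1)
        return out

    S = np.maximum(np.array([scores(g) for g in grid]), 1e-12)
    if not tr_ntr:
        best_ll = -np.inf
        best = None
        chunk = 20000
        for lo in range(0, len(grid), chunk):
            T = fam_terms(S[lo:lo + chunk], S[lo:lo + chunk])
            ll = np.log(np.maximum(T, 1e-300)).sum(axis=1)
            i = int(np.argmax(ll))
            if ll[i] > best_ll:
                best_ll = float(ll[i])
                best = grid[lo + i]
        return best, best_ll

    # tr/ntr: families factor as sums of products of a tr-part and ntr-part
    G = len(grid)
    ll = np.zeros((G, G))
    for fi in range(n_fam):
        mask = fam_of_row == fi
        st = S[:, j[mask]] * S[:, u[mask]]
        sn = S[:, k[mask]] * S[:, v[mask]] * s[mask]
        ll += np.log(np.maximum(st @ sn.T, 1e-300))
    a, b = np.unravel_index(np.argmax(ll), ll.shape)
    return (grid[a], grid[b]), float(ll[a, b])
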