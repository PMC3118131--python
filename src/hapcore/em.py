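"""Maximum-likelihood haplotype frequency estimation by EM.

A family's likelihood contribution is a sum over its explanation quadruples
``(j, k, u, v)`` of the product of the four haplotype frequencies and the
transmission-count product ``s``.  Under the null the same frequency vector
scores every slot; under the alternative the transmitted slots ``(j, u)``
are scored by one vector and the non-transmitted slots ``(k, v)`` by
another.  The E-step weights each explanation by its posterior probability;
the M-step sets each frequency to its expected slot count divided by the
number of slots (4n pooled, 2n per transmission group).

The same engine also maximizes *recoded* likelihoods in which every
haplotype's score is a fixed linear function ``(A @ gamma)[h]`` of a reduced
parameter vector: the identity matrix recovers the plain EM, a rare-group
indicator column gives the grouped test, and rows taken from the
evolutionary allocation products give the core-coded test.  Linearity makes
the recoded model a latent-ancestry mixture, so the EM update (expected
core counts) still increases the likelihood monotonically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .haplotypes import HaplotypeTable
from .pedigree import FamilySet
from .phase import ExplanationSet, _explanation_arrays, reorder_children

__all__ = [
    "EmResult",
    "TrNtrFrequencies",
    "ExplanationData",
    "family_loglik_null",
    "family_loglik_alt",
    "em_frequencies",
    "em_tr_ntr",
    "em_core_coded",
    "pooled_estimate",
]

logger = logging.getLogger("hapcore")

FREQ_FLOOR = 1e-12
PRUNE_THRESHOLD = 1e-6
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


@dataclass
class TrNtrFrequencies:
    """Transmitted / non-transmitted frequency vectors over one space."""

    tr: np.ndarray
    ntr: np.ndarray

    def __post_init__(self) -> None:
        self.tr = np.asarray(self.tr, float)
        self.ntr = np.asarray(self.ntr, float)
        for name, v in (("tr", self.tr), ("ntr", self.ntr)):
            if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} is not a probability vector")


@dataclass
class EmResult:
    frequencies: object  # np.ndarray or TrNtrFrequencies
    loglik: float
    n_iter: int
    converged: bool
    trace: list = field(default_factory=list)


@dataclass
class ExplanationData:
    """Flat arrays of explanation quadruples for a whole family set.

    ``fam_index`` maps each row to a family slot in 0..n_families-1; rows of
    one family are contiguous.  ``proband`` flags, per family slot, whether
    the rows were built proband-conditionally (families without an affected
    child fall back to the unconditional set and still inform the pooled
    frequencies, but are excluded from transmitted/non-transmitted fits).
    """

    fam_index: np.ndarray
    j: np.ndarray
    k: np.ndarray
    u: np.ndarray
    v: np.ndarray
    s: np.ndarray
    n_families: int
    n_haplotypes: int
    proband: np.ndarray  # bool per family slot
    family_ids: list = field(default_factory=list)

    @classmethod
    def from_family_set(
        cls,
        fams: FamilySet,
        table: HaplotypeTable,
        cap: int = 100_000,
    ) -> "ExplanationData":
        rows_f, rows_j, rows_k, rows_u, rows_v, rows_s = [], [], [], [], [], []
        proband_flags = []
        ids = []
        slot = 0
        for fam in fams:
            if fam.has_affected_child:
                ordered = reorder_children(fam)
                j, k, u, v, s = _explanation_arrays(ordered, table, "proband", cap)
                proband_flags.append(True)
            else:
                logger.warning(
                    "family %s has no affected child; excluded from association "
                    "testing, retained for pooled frequency estimation",
                    fam.family_id,
                )
                j, k, u, v, s = _explanation_arrays(fam, table, "unconditional", cap)
                proband_flags.append(False)
            if len(j) == 0:
                raise ValueError(
                    f"family {fam.family_id}: no haplotype explanation is "
                    "compatible with the genotypes (data inconsistency)"
                )
            rows_f.append(np.full(len(j), slot, dtype=np.int64))
            rows_j.append(j)
            rows_k.append(k)
            rows_u.append(u)
            rows_v.append(v)
            rows_s.append(s)
            ids.append(fam.family_id)
            slot += 1
        return cls(
            fam_index=np.concatenate(rows_f),
            j=np.concatenate(rows_j),
            k=np.concatenate(rows_k),
            u=np.concatenate(rows_u),
            v=np.concatenate(rows_v),
            s=np.concatenate(rows_s).astype(float),
            n_families=slot,
            n_haplotypes=len(table),
            proband=np.array(proband_flags, dtype=bool),
            family_ids=ids,
        )

    def restrict_to_probands(self) -> "ExplanationData":
        """Keep only families with a proband-conditional explanation set."""
        if self.proband.all():
            return self
        keep_slot = np.nonzero(self.proband)[0]
        remap = -np.ones(self.n_families, dtype=np.int64)
        remap[keep_slot] = np.arange(len(keep_slot))
        row_keep = self.proband[self.fam_index]
        return ExplanationData(
            fam_index=remap[self.fam_index[row_keep]],
            j=self.j[row_keep],
            k=self.k[row_keep],
            u=self.u[row_keep],
            v=self.v[row_keep],
            s=self.s[row_keep],
            n_families=len(keep_slot),
            n_haplotypes=self.n_haplotypes,
            proband=np.ones(len(keep_slot), dtype=bool),
            family_ids=[self.family_ids[i] for i in keep_slot],
        )

    def restrict_haplotypes(self, survivors) -> tuple["ExplanationData", list]:
        """Drop rows referencing haplotypes outside ``survivors``.

        If a family would lose all of its rows, the haplotypes its rows use
        are added back to the survivor set (logged); the final survivor
        index list is returned alongside the reindexed data.
        """
        survivors = set(int(i) for i in survivors)
        while True:
            keep_hap = np.zeros(self.n_haplotypes, dtype=bool)
            keep_hap[list(survivors)] = True
            row_keep = (
                keep_hap[self.j] & keep_hap[self.k] & keep_hap[self.u] & keep_hap[self.v]
            )
            fam_rows = np.bincount(
                self.fam_index[row_keep], minlength=self.n_families
            )
            lost = np.nonzero(fam_rows == 0)[0]
            if len(lost) == 0:
                break
            lost_rows = np.isin(self.fam_index, lost)
            extra = set(
                int(x)
                for arr in (self.j, self.k, self.u, self.v)
                for x in np.unique(arr[lost_rows])
            )
            logger.warning(
                "haplotype pruning would empty %d families; restoring %d haplotypes",
                len(lost),
                len(extra - survivors),
            )
            survivors |= extra
        order = sorted(survivors)
        remap = -np.ones(self.n_haplotypes, dtype=np.int64)
        remap[order] = np.arange(len(order))
        data = ExplanationData(
            fam_index=self.fam_index[row_keep],
            j=remap[self.j[row_keep]],
            k=remap[self.k[row_keep]],
            u=remap[self.u[row_keep]],
            v=remap[self.v[row_keep]],
            s=self.s[row_keep],
            n_families=self.n_families,
            n_haplotypes=len(order),
            proband=self.proband,
            family_ids=self.family_ids,
        )
        return data, order


# -- likelihood evaluation ----------------------------------------------


def _data_loglik(data: ExplanationData, rho_t: np.ndarray, rho_n: np.ndarray) -> float:
    rt = np.maximum(rho_t, FREQ_FLOOR)
    rn = np.maximum(rho_n, FREQ_FLOOR)
    w = rt[data.j] * rt[data.u] * rn[data.k] * rn[data.v] * data.s
    den = np.bincount(data.fam_index, weights=w, minlength=data.n_families)
    return float(np.log(np.maximum(den, 1e-300)).sum())


def family_loglik_null(expls: ExplanationSet, freqs: np.ndarray) -> float:
    """log sum over explanations of pi_j pi_k pi_u pi_v * s (floored at 1e-12)."""
    f = np.maximum(np.asarray(freqs, float), FREQ_FLOOR)
    total = sum(
        f[e.j] * f[e.k] * f[e.u] * f[e.v] * e.s_product for e in expls.explanations
    )
    if total <= 0:
        return float("-inf")
    return float(np.log(total))


def family_loglik_alt(expls: ExplanationSet, tn: TrNtrFrequencies) -> float:
    """Same sum with transmitted slots scored under tr, non-transmitted under ntr."""
    ft = np.maximum(tn.tr, FREQ_FLOOR)
    fn = np.maximum(tn.ntr, FREQ_FLOOR)
    total = sum(
        ft[e.j] * ft[e.u] * fn[e.k] * fn[e.v] * e.s_product
        for e in expls.explanations
    )
    if total <= 0:
        return float("-inf")
    return float(np.log(total))


# -- EM engine -----------------------------------------------------------


def _em_engine(
    data: ExplanationData,
    A: Optional[np.ndarray],
    mode: str,
    init,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """Run EM on (possibly recoded) explanation data.

    ``A`` is the (n_haplotypes x n_params) recode matrix (None = identity).
    ``mode`` is "pooled" (one vector) or "trntr" (a tr/ntr pair);
    ``init`` is the matching start value.  Returns (params, loglik, n_iter,
    converged, trace) with the log-likelihood recomputed at the final
    parameters.
    """
    identity = A is None
    if not identity:
        A = np.asarray(A, float)
    n = data.n_families
    if n == 0:
        raise ValueError("no families to fit")

    def scores(g):
        return g if identity else A @ g

    if mode == "pooled":
        g = np.asarray(init, float).copy()
        gt = gn = g
    else:
        gt = np.asarray(init[0], float).copy()
        gn = np.asarray(init[1], float).copy()

    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rho_t = np.maximum(scores(gt), FREQ_FLOOR)
        rho_n = np.maximum(scores(gn), FREQ_FLOOR)
        w = rho_t[data.j] * rho_t[data.u] * rho_n[data.k] * rho_n[data.v] * data.s
        den = np.bincount(data.fam_index, weights=w, minlength=n)
        ll = float(np.log(np.maximum(den, 1e-300)).sum())
        trace.append(ll)
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
        wn = w / np.maximum(den[data.fam_index], 1e-300)
        Wt = np.bincount(data.j, weights=wn, minlength=data.n_haplotypes) + np.bincount(
            data.u, weights=wn, minlength=data.n_haplotypes
        )
        Wn = np.bincount(data.k, weights=wn, minlength=data.n_haplotypes) + np.bincount(
            data.v, weights=wn, minlength=data.n_haplotypes
        )
        if mode == "pooled":
            W = Wt + Wn
            back = W / rho_t if identity else A.T @ (W / rho_t)
            g = gt * back / (4.0 * n)
            g = np.maximum(g, 0.0)
            g /= g.sum()
            gt = gn = g
        else:
            back_t = Wt / rho_t if identity else A.T @ (Wt / rho_t)
            back_n = Wn / rho_n if identity else A.T @ (Wn / rho_n)
            gt = np.maximum(gt * back_t / (2.0 * n), 0.0)
            gn = np.maximum(gn * back_n / (2.0 * n), 0.0)
            gt /= gt.sum()
            gn /= gn.sum()

    final_ll = _data_loglik(data, scores(gt), scores(gn))
    params = gt if mode == "pooled" else (gt, gn)
    return params, final_ll, it, converged, trace


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _softmax_polish(data, A, mode, params, tol):
    """Quasi-Newton refinement on softmax-parameterized simplex coordinates.

    Used as a fallback when the core-coded EM hits its iteration cap without
    converging; accepts the refined point only if it improves the
    likelihood.
    """
    identity = A is None

    def scores(g):
        return g if identity else A @ g

    if mode == "pooled":
        z0 = np.log(np.maximum(np.asarray(params, float), 1e-10))

        def negll(z):
            g = _softmax(z)
            return -_data_loglik(data, scores(g), scores(g))

    else:
        gt, gn = params
        z0 = np.concatenate(
            [np.log(np.maximum(gt, 1e-10)), np.log(np.maximum(gn, 1e-10))]
        )
        c = len(gt)

        def negll(z):
            g_t = _softmax(z[:c])
            g_n = _softmax(z[c:])
            return -_data_loglik(data, scores(g_t), scores(g_n))

    res = minimize(negll, z0, method="L-BFGS-B", options={"maxiter": 200})
    if mode == "pooled":
        refined = _softmax(res.x)
    else:
        c = len(params[0])
        refined = (_softmax(res.x[:c]), _softmax(res.x[c:]))
    ll_ref = -float(res.fun)
    return refined, ll_ref


# -- public estimation routines -----------------------------------------


def _uniform(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def em_frequencies(
    fams: FamilySet,
    candidates: Optional[HaplotypeTable] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    prune: bool = False,
) -> EmResult:
    """Pooled (null) haplotype frequency estimate over a candidate table.

    Starts from uniform frequencies.  With ``prune=True``, haplotypes ending
    below 1e-6 are dropped and the vector renormalized (the returned vector
    then refers to the surviving candidate order; use :func:`pooled_estimate`
    when the pruned table itself is needed).
    """
    from .phase import infer_candidate_haplotypes

    if candidates is None:
        candidates = infer_candidate_haplotypes(fams)
    data = ExplanationData.from_family_set(fams, candidates)
    g, ll, it, conv, trace = _em_engine(
        data, None, "pooled", _uniform(len(candidates)), tol, max_iter
    )
    if prune:
        keep = g >= PRUNE_THRESHOLD
        g = np.where(keep, g, 0.0)
        g /= g.sum()
    return EmResult(g, ll, it, conv, trace)


def em_tr_ntr(
    fams: FamilySet,
    candidates: HaplotypeTable,
    init: Optional[TrNtrFrequencies] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EmResult:
    """Separate transmitted / non-transmitted frequency vectors (alternative).

    Only families with an affected proband contribute.  By default the
    start point is the pooled null estimate, which makes the alternative
    log-likelihood provably at least the null one (monotone EM from the
    null point) and hence the LRT statistic nonnegative.
    """
    data = ExplanationData.from_family_set(fams, candidates).restrict_to_probands()
    if init is None:
        null = _em_engine(
            data, None, "pooled", _uniform(len(candidates)), tol, max_iter
        )[0]
        start = (null, null.copy())
    else:
        start = (init.tr, init.ntr)
    (gt, gn), ll, it, conv, trace = _em_engine(
        data, None, "trntr", start, tol, max_iter
    )
    return EmResult(TrNtrFrequencies(gt, gn), ll, it, conv, trace)


def em_core_coded(
    fams: FamilySet,
    core_system,
    candidates: HaplotypeTable,
    mode: str = "null",
    init=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EmResult:
    """Core-coded likelihood maximization over the c-dimensional simplex.

    Every haplotype's score is its core representation: a core haplotype
    scores its own parameter, a layered haplotype the dot product of its
    allocation-product row with the parameter vector.  ``mode`` is "null"
    (one vector) or "alternative" (tr/ntr pair).
    """
    A = core_system.recode_matrix(candidates)
    data = ExplanationData.from_family_set(fams, candidates).restrict_to_probands()
    c = A.shape[1]
    em_mode = "pooled" if mode == "null" else "trntr"
    if init is None:
        init = _uniform(c) if mode == "null" else (_uniform(c), _uniform(c))
    params, ll, it, conv, trace = _em_engine(data, A, em_mode, init, tol, max_iter)
    if not conv:
        refined, ll_ref = _softmax_polish(data, A, em_mode, params, tol)
        if ll_ref > ll + 1e-12:
            params, ll = refined, ll_ref
            conv = True
    if em_mode == "pooled":
        return EmResult(params, ll, it, conv, trace)
    return EmResult(TrNtrFrequencies(*params), ll, it, conv, trace)


def pooled_estimate(
    fams: FamilySet,
    candidates: Optional[HaplotypeTable] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """Infer candidates, run the pooled EM, prune, and re-converge.

    Returns ``(table, data, result)`` where ``table`` is the pruned
    candidate table carrying the estimated frequencies, ``data`` the
    explanation arrays reindexed to it, and ``result`` the final pooled
    :class:`EmResult` on the pruned space.  This is the shared front end of
    the association tests and of the core-identification studies.
    """
    from .phase import infer_candidate_haplotypes

    if candidates is None:
        candidates = infer_candidate_haplotypes(fams)
    data0 = ExplanationData.from_family_set(fams, candidates)
    g0, _, _, _, _ = _em_engine(
        data0, None, "pooled", _uniform(len(candidates)), tol, max_iter
    )
    survivors = np.nonzero(g0 >= PRUNE_THRESHOLD)[0]
    data, order = data0.restrict_haplotypes(survivors)
    freqs = g0[order]
    freqs = freqs / freqs.sum()
    g, ll, it, conv, trace = _em_engine(data, None, "pooled", freqs, tol, max_iter)
    table = candidates.subset(order).with_frequencies(g)
    return table, data, EmResult(g, ll, it, conv, trace)
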