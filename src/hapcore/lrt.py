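"""Likelihood-ratio association tests on nuclear-family haplotype data.

Three nested comparisons of transmitted versus non-transmitted haplotype
frequencies, all referred to a chi-square distribution:

* ``lrt_full``      — every haplotype its own parameter (df = h - 1);
* ``lrt_grouped``   — rare haplotypes merged into one synthetic group
  (df = kept + 1 - 1);
* ``lrt_clustered`` — frequencies rewritten in terms of the evolutionary
  core system, so the alternative has only c - 1 extra parameters
  (df = c - 1).  With a core mass of 1.0 the clustering is the identity and
  the clustered test coincides with the full one.

All three share one explanation enumeration and one pooled EM per dataset;
the alternative fits are warm-started at the corresponding null optimum,
which together with the monotone EM updates guarantees a nonnegative
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import chi2

from .clustering import CoreSystem
from .em import (
    ExplanationData,
    PRUNE_THRESHOLD,
    _em_engine,
    _uniform,
    pooled_estimate,
)
from .haplotypes import HaplotypeTable
from .pedigree import FamilySet

__all__ = [
    "TestResult",
    "chisq_pvalue",
    "lrt_full",
    "lrt_grouped",
    "lrt_clustered",
    "run_tests",
]

logger = logging.getLogger("hapcore")

METHOD_NAMES = {"full": "LRT-full", "lrtg": "LRT-G", "lrtc": "LRT-C"}


@dataclass
class TestResult:
    method: str
    statistic: float
    df: int
    p_value: float
    n_families: int
    space_size: int
    loglik_null: float
    loglik_alt: float


def chisq_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability for a nested LRT statistic."""
    if df < 1 or int(df) != df:
        raise ValueError(f"invalid degrees of freedom: {df}")
    if stat < 0:
        raise ValueError(f"negative statistic: {stat}")
    return float(chi2.sf(stat, df))


def _finish(method, ll_null, ll_alt, df, n_families, space_size) -> TestResult:
    stat = 2.0 * (ll_alt - ll_null)
    if stat < -1e-6:
        raise RuntimeError(
            f"{method}: alternative log-likelihood below null by {-stat / 2:.3g}; "
            "optimization failure"
        )
    stat = max(stat, 0.0)
    df = max(int(df), 1)
    return TestResult(
        method=method,
        statistic=stat,
        df=df,
        p_value=chisq_pvalue(stat, df),
        n_families=n_families,
        space_size=space_size,
        loglik_null=ll_null,
        loglik_alt=ll_alt,
    )


def _grouped_recode(freqs: np.ndarray, rare_cutoff: float):
    """Recode matrix merging rare haplotypes into a single trailing group.

    Returns (A, kept_indices) or (None, None) when nothing is rare, in
    which case the grouped test reduces to the full one.
    """
    kept = np.nonzero(freqs >= rare_cutoff)[0]
    rare = np.nonzero(freqs < rare_cutoff)[0]
    if len(rare) == 0:
        return None, None
    if len(kept) == 0:
        return np.ones((len(freqs), 1)), kept
    c = len(kept) + 1
    A = np.zeros((len(freqs), c))
    for pos, h in enumerate(kept):
        A[h, pos] = 1.0
    A[rare, c - 1] = 1.0
    return A, kept


def run_tests(
    fams: FamilySet,
    methods=("lrtc", "lrtg", "full"),
    core_mass: float = 0.9,
    rare_cutoff: float = 0.05,
    candidates: Optional[HaplotypeTable] = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> dict:
    """Run the requested tests on one dataset, sharing the phase enumeration
    and the pooled EM.  Returns ``{method: TestResult}`` plus the pruned
    haplotype table under the key ``"table"``."""
    table, data, pooled = pooled_estimate(
        fams, candidates=candidates, tol=tol, max_iter=max_iter
    )
    pro = data.restrict_to_probands()
    if pro.n_families == 0:
        raise ValueError("no family with an affected child; tests undefined")
    freqs = np.asarray(pooled.frequencies, float)
    h = int((freqs >= PRUNE_THRESHOLD).sum())

    if pro.n_families == data.n_families:
        ll_null_full = pooled.loglik
        null_full = freqs
    else:
        null_full, ll_null_full, _, _, _ = _em_engine(
            pro, None, "pooled", freqs, tol, max_iter
        )

    out: dict = {"table": table}
    full_cache: list = []

    def full_result() -> TestResult:
        if not full_cache:
            (_, _), ll_alt, _, _, _ = _em_engine(
                pro, None, "trntr", (null_full, null_full.copy()), tol, max_iter
            )
            full_cache.append(
                _finish("LRT-full", ll_null_full, ll_alt, h - 1, pro.n_families, h)
            )
        return full_cache[0]

    if "full" in methods:
        out["full"] = full_result()

    if "lrtg" in methods:
        A, kept = _grouped_recode(freqs, rare_cutoff)
        if A is None:
            f = full_result()
            out["lrtg"] = TestResult(
                "LRT-G",
                f.statistic,
                f.df,
                f.p_value,
                f.n_families,
                f.space_size,
                f.loglik_null,
                f.loglik_alt,
            )
        else:
            c = A.shape[1]
            if c == 1:
                logger.warning("LRT-G: all haplotypes rare; single group, statistic 0")
                ll0 = _em_engine(pro, A, "pooled", _uniform(1), tol, max_iter)[1]
                out["lrtg"] = _finish("LRT-G", ll0, ll0, 1, pro.n_families, 1)
            else:
                init = np.append(freqs[kept], freqs.sum() - freqs[kept].sum())
                init = np.maximum(init, 1e-12)
                init /= init.sum()
                g0, ll0, _, _, _ = _em_engine(pro, A, "pooled", init, tol, max_iter)
                (gt, gn), ll1, _, _, _ = _em_engine(
                    pro, A, "trntr", (g0, g0.copy()), tol, max_iter
                )
                out["lrtg"] = _finish("LRT-G", ll0, ll1, c - 1, pro.n_families, c)

    if "lrtc" in methods:
        cs = CoreSystem.build(table, mass=core_mass)
        c = cs.n_cores
        if c == 1:
            logger.warning("LRT-C: single core haplotype; statistic 0")
            A = cs.recode_matrix(table)
            ll0 = _em_engine(pro, A, "pooled", _uniform(1), tol, max_iter)[1]
            out["lrtc"] = _finish("LRT-C", ll0, ll0, 1, pro.n_families, 1)
        else:
            A = cs.recode_matrix(table)
            init = np.maximum(cs.revised_core_freqs, 1e-12)
            init /= init.sum()
            g0, ll0, _, conv0, _ = _em_engine(pro, A, "pooled", init, tol, max_iter)
            (gt, gn), ll1, _, conv1, _ = _em_engine(
                pro, A, "trntr", (g0, g0.copy()), tol, max_iter
            )
            out["lrtc"] = _finish("LRT-C", ll0, ll1, c - 1, pro.n_families, c)
        out["core_system"] = cs

    return out


def lrt_full(fams: FamilySet, candidates=None, **kw) -> TestResult:
    """Transmitted vs non-transmitted LRT over the full haplotype space."""
    return run_tests(fams, methods=("full",), candidates=candidates, **kw)["full"]


def lrt_grouped(
    fams: FamilySet, rare_cutoff: float = 0.05, candidates=None, **kw
) -> TestResult:
    """LRT with all rare haplotypes (pooled frequency < cutoff) in one group."""
    return run_tests(
        fams, methods=("lrtg",), rare_cutoff=rare_cutoff, candidates=candidates, **kw
    )["lrtg"]


def lrt_clustered(
    fams: FamilySet, core_mass: float = 0.9, candidates=None, **kw
) -> TestResult:
    """The clustered LRT: null and alternative in core-coded parameters."""
    return run_tests(
        fams, methods=("lrtc",), core_mass=core_mass, candidates=candidates, **kw
    )["lrtc"]
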