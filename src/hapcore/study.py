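"""Monte-Carlo studies: type-I error, power, and core identification.

Each study simulates replicate family datasets, runs the association tests
or the clustering front end on every replicate, and aggregates rejection
rates (with binomial standard errors) or core-recovery fractions.
Replicate r uses seed ``seed + r`` while sibship sizes are drawn once from
``seed`` and reused, so a family keeps its sibship size across replicates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .clustering import select_core
from .em import pooled_estimate
from .lrt import run_tests
from .simulate import DiseaseModel, FixturePool, SimConfig, simulate_dataset

__all__ = [
    "StudyResult",
    "run_type1_study",
    "run_power_study",
    "run_core_identification_study",
    "report",
    "read_report",
]

logger = logging.getLogger("hapcore")


@dataclass
class StudyResult:
    """Aggregated outcome of one (setting, method) Monte-Carlo cell."""

    study: str
    method: str
    mode: str
    r: float
    p: float
    n_families: int
    n_reps: int
    n_failed: int = 0
    alpha: Optional[float] = None
    rejection_rate: Optional[float] = None
    se: Optional[float] = None
    mean_core_count: Optional[float] = None
    mean_haplotype_count: Optional[float] = None
    mean_true_core_fraction: Optional[float] = None
    runtime_s: Optional[float] = None
    seed: Optional[int] = None

    @staticmethod
    def binomial_se(rate: float, n: int) -> float:
        return float(np.sqrt(rate * (1.0 - rate) / n)) if n > 0 else float("nan")


def _simulate_replicate(pools, model, n_families, mean_extra, seed, rep):
    cfg = SimConfig(
        n_families=n_families,
        pools=pools,
        model=model,
        mean_extra_children=mean_extra,
        seed=seed + rep,
        sibship_seed=seed,
    )
    return simulate_dataset(cfg)


def _test_study(
    study_name,
    pools,
    model,
    n_families,
    n_reps,
    alpha,
    methods,
    seed,
    mean_extra_children,
    core_mass,
    rare_cutoff,
) -> dict:
    t0 = time.time()
    rejections = {m: 0 for m in methods}
    n_ok = 0
    n_failed = 0
    for rep in range(n_reps):
        fams, _ = _simulate_replicate(
            pools, model, n_families, mean_extra_children, seed, rep
        )
        try:
            results = run_tests(
                fams, methods=methods, core_mass=core_mass, rare_cutoff=rare_cutoff
            )
        except Exception as exc:  # noqa: BLE001 - failures are counted, not fatal
            logger.warning("replicate %d failed: %s", rep, exc)
            n_failed += 1
            continue
        n_ok += 1
        for m in methods:
            if results[m].p_value < alpha:
                rejections[m] += 1
    dt = time.time() - t0
    out = {}
    for m in methods:
        rate = rejections[m] / n_ok if n_ok else float("nan")
        out[m] = StudyResult(
            study=study_name,
            method=m,
            mode=model.mode,
            r=model.r,
            p=model.p,
            n_families=n_families,
            n_reps=n_ok,
            n_failed=n_failed,
            alpha=alpha,
            rejection_rate=rate,
            se=StudyResult.binomial_se(rate, n_ok),
            runtime_s=dt,
            seed=seed,
        )
    return out


def run_type1_study(
    pool: FixturePool,
    n_families: int = 200,
    n_reps: int = 400,
    alpha: float = 0.05,
    methods=("lrtc", "lrtg", "full"),
    seed: int = 0,
    K: float = 0.01,
    mean_extra_children: float = 2.0,
    core_mass: float = 0.9,
    rare_cutoff: float = 0.05,
) -> dict:
    """Empirical rejection rates under the null (all penetrances = K)."""
    model = DiseaseModel.null(p=max(pool.carrier_frequency, 1e-6), K=K)
    return _test_study(
        "type1",
        pool,
        model,
        n_families,
        n_reps,
        alpha,
        methods,
        seed,
        mean_extra_children,
        core_mass,
        rare_cutoff,
    )


def run_power_study(
    settings,
    n_families: int = 200,
    n_reps: int = 200,
    alpha: float = 0.05,
    methods=("lrtc", "lrtg", "full"),
    seed: int = 0,
    K: float = 0.01,
    mean_extra_children: float = 2.0,
    core_mass: float = 0.9,
    rare_cutoff: float = 0.05,
    pool_factory=None,
    pools=None,
) -> list:
    """Rejection rates over a grid of (mode, r, p) disease settings.

    ``pool_factory(p)`` builds the haplotype pool for a liability-allele
    frequency (defaults to the standard fixture pool with a fixed seed);
    pass ``pools`` explicitly — a single pool or admixture spec — to reuse
    one pool across settings.
    """
    from .simulate import make_fixture_pool

    if pool_factory is None:
        def pool_factory(p):  # noqa: ANN001
            return make_fixture_pool(target_p=p, seed=seed)

    results = []
    for idx, (mode, r, p) in enumerate(settings):
        model = DiseaseModel.from_mode(mode, r, p, K)
        setting_pools = pools if pools is not None else pool_factory(p)
        out = _test_study(
            "power",
            setting_pools,
            model,
            n_families,
            n_reps,
            alpha,
            methods,
            seed + 10_000 * idx,
            mean_extra_children,
            core_mass,
            rare_cutoff,
        )
        results.extend(out[m] for m in methods)
    return results


def run_core_identification_study(
    pool: FixturePool,
    model: DiseaseModel,
    n_families: int = 100,
    n_reps: int = 200,
    seed: int = 0,
    mean_extra_children: float = 2.0,
    core_mass: float = 0.9,
) -> StudyResult:
    """How well the pooled EM plus core selection recovers the true cores.

    Per replicate: simulate, estimate haplotype frequencies, select the
    core at ``core_mass``; record the fraction of the pool's true core
    haplotypes present in the estimated core set, the estimated core count,
    and the number of haplotypes with positive estimated frequency.
    """
    t0 = time.time()
    true_cores = set(pool.true_cores)
    fractions = []
    core_counts = []
    hap_counts = []
    n_failed = 0
    for rep in range(n_reps):
        fams, _ = _simulate_replicate(
            pool, model, n_families, mean_extra_children, seed, rep
        )
        try:
            table, _, _ = pooled_estimate(fams)
        except Exception as exc:  # noqa: BLE001
            logger.warning("replicate %d failed: %s", rep, exc)
            n_failed += 1
            continue
        core_idx = select_core(table, core_mass)
        core_haps = {table.haplotypes[i] for i in core_idx}
        fractions.append(len(true_cores & core_haps) / len(true_cores))
        core_counts.append(len(core_idx))
        hap_counts.append(len(table))
    n_ok = len(fractions)
    return StudyResult(
        study="core_identification",
        method="pooled-em",
        mode=model.mode,
        r=model.r,
        p=model.p,
        n_families=n_families,
        n_reps=n_ok,
        n_failed=n_failed,
        mean_true_core_fraction=float(np.mean(fractions)) if n_ok else float("nan"),
        mean_core_count=float(np.mean(core_counts)) if n_ok else float("nan"),
        mean_haplotype_count=float(np.mean(hap_counts)) if n_ok else float("nan"),
        runtime_s=time.time() - t0,
        seed=seed,
    )


_COLUMNS = [f.name for f in dataclasses.fields(StudyResult)]


def report(results, path, format: str = "tsv") -> None:
    """Serialize study results deterministically as TSV or JSON."""
    rows = [dataclasses.asdict(r) for r in results]
    if format == "tsv":
        df = pd.DataFrame(rows, columns=_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path, format: str = "json") -> list:
    """Load study results written by :func:`report` (JSON round-trips)."""
    if format == "json":
        with open(path) as fh:
            rows = json.load(fh)
    else:
        rows = pd.read_csv(path, sep="\t").to_dict("records")
        rows = [
            {k: (None if pd.isna(v) else v) for k, v in row.items()} for row in rows
        ]
    return [StudyResult(**row) for row in rows]
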