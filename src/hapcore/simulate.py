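"""Disease-model simulation of nuclear-family genotype data.

The generative scheme mirrors classic family-based association study
designs: a biallelic liability SNP sits inside a haplotype block; genotype
relative risks follow an additive, dominant, or recessive pattern with
relative ratio r; penetrances are anchored to a population prevalence K.
Each family is ascertained through an affected proband: the proband's
haplotype pair is drawn from the case distribution, the parents'
non-transmitted haplotypes from the population pool, and the remaining
siblings receive parental haplotypes at random with affection drawn from
their own penetrance.  All haplotypes are collapsed to unphased genotypes.

The fixture pool emulates a tag-SNP block of 13 SNPs carrying 15
haplotypes, the 10 most frequent of which hold 90% of the mass — the shape
of the simulated region used to benchmark the clustered tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .haplotypes import HaplotypeTable
from .pedigree import (
    AFFECTED,
    Family,
    FamilySet,
    Genotype,
    Individual,
    SnpPanel,
    UNAFFECTED,
    UNKNOWN,
)

__all__ = [
    "DiseaseModel",
    "FixturePool",
    "SimConfig",
    "SimTruth",
    "penetrances",
    "allele_freq_in_cases",
    "make_fixture_pool",
    "simulate_family",
    "simulate_dataset",
]

logger = logging.getLogger("hapcore")

_MODES = ("additive", "dominant", "recessive")


def penetrances(mode: str, r: float, p: float, K: float):
    """Penetrances (f0, f1, f2) from inheritance mode, relative ratio r,
    liability-allele frequency p, and prevalence K.

    Genotype relative risks are (1, r, 2r-1) additive, (1, r, r) dominant,
    (1, 1, r) recessive; f0 solves the prevalence identity
    K = (1-p)^2 f0 + 2p(1-p) f1 + p^2 f2.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown inheritance mode {mode!r}")
    if r < 1:
        raise ValueError("relative ratio r must be >= 1")
    if not (0 < p < 1) or not (0 < K < 1):
        raise ValueError("p and K must lie strictly between 0 and 1")
    if mode == "additive":
        w = (1.0, r, 2.0 * r - 1.0)
    elif mode == "dominant":
        w = (1.0, r, r)
    else:
        w = (1.0, 1.0, r)
    denom = (1 - p) ** 2 * w[0] + 2 * p * (1 - p) * w[1] + p**2 * w[2]
    f0 = K / denom
    f = (f0 * w[0], f0 * w[1], f0 * w[2])
    if f[2] > 1.0:
        raise ValueError(
            f"infeasible model: f2 = {f[2]:.4f} > 1 for {mode}, r={r}, p={p}, K={K}"
        )
    return f


@dataclass
class DiseaseModel:
    """A penetrance model for a single liability allele."""

    mode: str
    r: float
    p: float
    K: float
    f0: float
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not (self.f0 <= self.f1 + 1e-15 and self.f1 <= self.f2 + 1e-15):
            raise ValueError("penetrances must satisfy f0 <= f1 <= f2")
        prev = (
            (1 - self.p) ** 2 * self.f0
            + 2 * self.p * (1 - self.p) * self.f1
            + self.p**2 * self.f2
        )
        if abs(prev - self.K) > 1e-10:
            raise ValueError(
                f"penetrances violate the prevalence identity: {prev} != {self.K}"
            )

    @classmethod
    def from_mode(cls, mode: str, r: float, p: float, K: float = 0.01) -> "DiseaseModel":
        f0, f1, f2 = penetrances(mode, r, p, K)
        return cls(mode, r, p, K, f0, f1, f2)

    @classmethod
    def null(cls, p: float = 0.1, K: float = 0.01) -> "DiseaseModel":
        """No genetic effect: every penetrance equals the prevalence."""
        return cls.from_mode("additive", 1.0, p, K)

    @property
    def is_null(self) -> bool:
        return abs(self.f2 - self.f0) < 1e-15

    @property
    def penetrance_vector(self) -> np.ndarray:
        return np.array([self.f0, self.f1, self.f2])


def allele_freq_in_cases(model: DiseaseModel) -> float:
    """P(A|D) = [f2 p^2 + f1 p (1-p)] / K, the liability-allele frequency
    among affected individuals.  Its distance from p governs how detectable
    the locus is."""
    return (model.f2 * model.p**2 + model.f1 * model.p * (1 - model.p)) / model.K


@dataclass
class FixturePool:
    """A haplotype pool plus its ground truth for simulation studies."""

    table: HaplotypeTable
    true_cores: list
    liability_index: int
    carrier_allele: str = "2"

    def carrier_indicator(self) -> np.ndarray:
        return np.array(
            [1 if h[self.liability_index] == self.carrier_allele else 0
             for h in self.table.haplotypes],
            dtype=np.int64,
        )

    @property
    def carrier_frequency(self) -> float:
        return float((self.table.frequencies * self.carrier_indicator()).sum())


def make_fixture_pool(
    n_haplotypes: int = 15,
    n_cores: int = 10,
    core_mass: float = 0.9,
    n_markers: int = 13,
    target_p: Optional[float] = None,
    liability_index: int = 6,
    decay: float = 0.86,
    seed: Optional[int] = None,
) -> FixturePool:
    """Build a synthetic tag-SNP haplotype pool with known core structure.

    Cores arise by sequential single-site mutations from a random root,
    with geometric-decay frequencies rescaled to ``core_mass``; the
    remaining haplotypes are single-site mutants of random cores sharing
    the leftover mass equally, so every non-core haplotype sits at Hamming
    distance 1 from a core.  Structural mutations avoid the liability
    marker; when ``target_p`` is given, the liability allele is assigned
    clade-wise (a core and its descendants carry it together) so that the
    carrier frequency equals ``target_p`` exactly, splitting off one extra
    distance-1 haplotype when no clade subset sums to ``target_p`` (the
    pool then holds at most ``n_haplotypes + 1`` haplotypes; logged).
    """
    if not (1 <= n_cores <= n_haplotypes):
        raise ValueError("need 1 <= n_cores <= n_haplotypes")
    if not (0 < core_mass <= 1):
        raise ValueError("core_mass must lie in (0, 1]")
    if n_haplotypes == n_cores and core_mass < 1:
        raise ValueError("no rare haplotypes to carry the non-core mass")
    if not (0 <= liability_index < n_markers):
        raise ValueError("liability_index out of range")
    if target_p is not None and not (0 < target_p < 1):
        raise ValueError("target_p must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    sites = [i for i in range(n_markers) if i != liability_index]
    if n_cores - 1 > len(sites):
        raise ValueError("not enough markers for distinct sequential core mutations")

    core_freqs = decay ** np.arange(n_cores)
    core_freqs = core_freqs / core_freqs.sum() * core_mass
    n_rare = n_haplotypes - n_cores
    rare_unit = (1.0 - core_mass) / n_rare if n_rare else 0.0

    last_err = None
    for _attempt in range(40):
        root = rng.integers(0, 2, size=n_markers)
        root[liability_index] = 0  # carrier allele assigned separately
        mut_sites = rng.choice(len(sites), size=n_cores - 1, replace=False)
        cores = [root.copy()]
        for ms in mut_sites:
            nxt = cores[-1].copy()
            nxt[sites[ms]] ^= 1
            cores.append(nxt)

        seen = {tuple(c) for c in cores}
        rares = []
        rare_parent = []
        for _ in range(n_rare):
            for _try in range(1000):
                parent = int(rng.integers(n_cores))
                site = sites[int(rng.integers(len(sites)))]
                cand = cores[parent].copy()
                cand[site] ^= 1
                if tuple(cand) not in seen:
                    seen.add(tuple(cand))
                    rares.append(cand)
                    rare_parent.append(parent)
                    break
            else:
                raise RuntimeError("could not place a distinct rare haplotype")

        try:
            return _assign_liability_and_build(
                cores,
                core_freqs,
                rares,
                rare_parent,
                list([rare_unit] * n_rare),
                rare_unit,
                target_p,
                liability_index,
                n_cores,
            )
        except ValueError as exc:
            last_err = exc  # retry with a fresh random arrangement
    raise ValueError(
        f"target_p = {target_p} unattainable with this pool structure: {last_err}"
    )


def _assign_liability_and_build(
    cores,
    core_freqs,
    rares,
    rare_parent,
    rare_freqs,
    rare_unit,
    target_p,
    liability_index,
    n_cores,
) -> FixturePool:
    """Assign the liability allele clade-wise and assemble the pool.

    Carrier status is chosen per clade (a core and its one-step mutants
    together), which preserves every rare haplotype's distance-1 link to a
    core.  A residual up to one rare-haplotype mass, of either sign, is
    absorbed by splitting one rare haplotype's mass into an extra
    liability-site mutant of a core.
    """
    n_rare = len(rares)
    carrier_core = np.zeros(n_cores, dtype=bool)
    extra = None  # (structural array, frequency, carrier flag)

    if target_p is not None:
        clade_mass = np.asarray(core_freqs, float).copy()
        for parent, f in zip(rare_parent, rare_freqs):
            clade_mass[parent] += f
        best = None  # (|delta|, delta, subset_bits)
        for bits in range(1 << n_cores):
            members = [i for i in range(n_cores) if (bits >> i) & 1]
            delta = target_p - float(clade_mass[members].sum())
            if abs(delta) > rare_unit + 1e-12:
                continue
            if delta > 1e-9:
                # extra carrier haplotype split off a non-carrier clade
                outside = [i for i in range(n_cores) if not (bits >> i) & 1]
                if not outside or not any(rp in outside for rp in rare_parent):
                    continue
            elif delta < -1e-9:
                # extra non-carrier haplotype split off a carrier clade
                if not members or not any(rp in members for rp in rare_parent):
                    continue
            if best is None or abs(delta) < best[0] - 1e-15:
                best = (abs(delta), delta, bits)
        if best is None:
            raise ValueError("no clade subset within one rare mass of target_p")
        _, delta, bits = best
        for i in range(n_cores):
            carrier_core[i] = bool((bits >> i) & 1)
        if abs(delta) > 1e-9:
            want_carrier_extra = delta > 0
            donor = next(
                t
                for t in range(n_rare)
                if carrier_core[rare_parent[t]] != want_carrier_extra
            )
            base = next(
                i for i in range(n_cores) if carrier_core[i] != want_carrier_extra
            )
            rare_freqs[donor] -= abs(delta)
            extra = (cores[base].copy(), abs(delta), want_carrier_extra)
            logger.info(
                "fixture pool: split %.4g mass into an extra liability-site "
                "mutant of core %d to hit target_p exactly",
                abs(delta),
                base,
            )

    def to_string(arr, carrier: bool) -> str:
        s = ["2" if b else "1" for b in arr]
        s[liability_index] = "2" if carrier else "1"
        return "".join(s)

    haps, freqs, labels = [], [], []
    for i, (c, f) in enumerate(zip(cores, core_freqs)):
        haps.append(to_string(c, carrier_core[i]))
        freqs.append(f)
        labels.append(f"core{i + 1:02d}")
    for t, (arr, f) in enumerate(zip(rares, rare_freqs)):
        if f <= 1e-12:
            continue
        haps.append(to_string(arr, carrier_core[rare_parent[t]]))
        freqs.append(f)
        labels.append(f"rare{t + 1:02d}")
    if extra is not None:
        arr, f, carrier = extra
        haps.append(to_string(arr, carrier))
        freqs.append(f)
        labels.append("split01")

    freqs = np.asarray(freqs)
    freqs = freqs / freqs.sum()
    table = HaplotypeTable(haps, freqs, labels=labels)
    pool = FixturePool(
        table=table,
        true_cores=haps[:n_cores],
        liability_index=liability_index,
    )
    if target_p is not None and abs(pool.carrier_frequency - target_p) > 1e-9:
        raise AssertionError("carrier frequency does not match target_p")
    return pool


class _FamilySampler:
    """Precomputed proband-conditional sampling machinery for one pool."""

    def __init__(self, pool: FixturePool, model: DiseaseModel) -> None:
        self.pool = pool
        self.model = model
        self.ints = pool.table.as_ints()
        self.L = pool.table.n_markers
        pi = pool.table.frequencies
        a = pool.carrier_indicator()
        self.carrier = a
        f = model.penetrance_vector
        joint = pi[:, None] * pi[None, :] * f[a[:, None] + a[None, :]]
        joint = joint / joint.sum()
        self._joint_cum = np.cumsum(joint.ravel())
        self._pi_cum = np.cumsum(pi)
        self._n = len(pi)

    def _draw_proband_pair(self, rng) -> tuple:
        idx = int(np.searchsorted(self._joint_cum, rng.random(), side="right"))
        idx = min(idx, self._n * self._n - 1)
        return idx // self._n, idx % self._n

    def _draw_pop(self, rng) -> int:
        idx = int(np.searchsorted(self._pi_cum, rng.random(), side="right"))
        return min(idx, self._n - 1)

    def sample(self, rng, n_extra_children: int, family_id: str) -> Family:
        j, u = self._draw_proband_pair(rng)
        k = self._draw_pop(rng)
        v = self._draw_pop(rng)
        hj, hk, hu, hv = (int(self.ints[i]) for i in (j, k, u, v))
        f = self.model.penetrance_vector

        def person(ind_id, father, mother, sex, affection, h1, h2):
            return Individual(
                family_id,
                ind_id,
                father,
                mother,
                sex,
                affection,
                Genotype.from_haplotypes(h1, h2, self.L),
            )

        father = person("1", "0", "0", 1, UNKNOWN, hj, hk)
        mother = person("2", "0", "0", 2, UNKNOWN, hu, hv)
        children = [person("3", "1", "2", 1, AFFECTED, hj, hu)]
        for t in range(n_extra_children):
            pat_idx = j if rng.random() < 0.5 else k
            mat_idx = u if rng.random() < 0.5 else v
            g = int(self.carrier[pat_idx] + self.carrier[mat_idx])
            affected = rng.random() < f[g]
            children.append(
                person(
                    str(4 + t),
                    "1",
                    "2",
                    1 if rng.random() < 0.5 else 2,
                    AFFECTED if affected else UNAFFECTED,
                    int(self.ints[pat_idx]),
                    int(self.ints[mat_idx]),
                )
            )
        return Family(father, mother, children)


def simulate_family(
    pool: FixturePool,
    model: DiseaseModel,
    n_extra_children: int,
    rng,
    family_id: str = "F1",
) -> Family:
    """Generate one ascertained nuclear family.

    The proband's ordered haplotype pair (j, u) is drawn from
    P(j, u | affected) proportional to pi_j pi_u f_{a(j)+a(u)}; the
    non-transmitted parental haplotypes k, v come independently from the
    pool; each additional sibling receives one paternal and one maternal
    haplotype uniformly at random and an affection status drawn from the
    penetrance of its own liability genotype.
    """
    return _FamilySampler(pool, model).sample(rng, n_extra_children, family_id)


@dataclass
class SimConfig:
    """Configuration of one simulated dataset.

    ``pools`` is either a single :class:`FixturePool` or a list of
    ``(pool, n_families)`` pairs for admixture designs.  Sibship sizes are
    1 + Poisson(``mean_extra_children``); when ``sibship_seed`` is set the
    sizes are drawn from their own generator, so repeated replicates with
    different ``seed`` but the same ``sibship_seed`` reuse identical
    per-family sibship sizes (the fixed-sibship replication design).
    """

    n_families: int
    pools: object
    model: DiseaseModel
    mean_extra_children: float = 2.0
    seed: Optional[int] = None
    sibship_seed: Optional[int] = None

    def pool_spec(self) -> list:
        if isinstance(self.pools, FixturePool):
            return [(self.pools, self.n_families)]
        spec = list(self.pools)
        if sum(n for _, n in spec) != self.n_families:
            raise ValueError("admixture family counts must sum to n_families")
        return spec


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    model: DiseaseModel
    pools: list
    populations: list
    sibship_sizes: np.ndarray
    true_cores: list = field(default_factory=list)


def simulate_dataset(cfg: SimConfig) -> tuple:
    """Generate a :class:`FamilySet` of ascertained families plus its truth.

    Deterministic for a fixed (seed, sibship_seed) pair.
    """
    if cfg.n_families < 1:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.pool_spec()
    L = spec[0][0].table.n_markers
    liab = spec[0][0].liability_index
    for pool, _ in spec:
        if pool.table.n_markers != L or pool.liability_index != liab:
            raise ValueError("admixture pools must share panel and liability site")

    if cfg.sibship_seed is not None:
        size_rng = np.random.default_rng(cfg.sibship_seed)
    else:
        size_rng = rng
    sizes = size_rng.poisson(cfg.mean_extra_children, size=cfg.n_families)

    families = []
    populations = []
    truth_cores: list = []
    fam_no = 0
    for pop_label, (pool, count) in enumerate(spec):
        sampler = _FamilySampler(pool, cfg.model)
        truth_cores.append(list(pool.true_cores))
        for _ in range(count):
            fam_no += 1
            fid = f"F{fam_no:04d}"
            families.append(sampler.sample(rng, int(sizes[fam_no - 1]), fid))
            populations.append(pop_label)

    panel = SnpPanel.from_length(L, liability_index=liab)
    truth = SimTruth(
        model=cfg.model,
        pools=[p for p, _ in spec],
        populations=populations,
        sibship_sizes=sizes,
        true_cores=truth_cores[0] if len(spec) == 1 else truth_cores,
    )
    return FamilySet(panel, families), truth
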