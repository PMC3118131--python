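"""Evolution-guided clustering of haplotypes onto a core set.

Frequency approximates age: the most frequent haplotypes are treated as
ancestral.  The *core* is the shortest descending-frequency prefix whose
cumulative mass reaches the threshold (0.9 by default).  Every remaining
haplotype is layered by its minimum Hamming distance m to the core; layer m
is linked to layer m-1 by a row-stochastic allocation matrix B^(m) whose
entries are the probabilities that a haplotype descends from each
one-mutation ancestor, taken proportional to the ancestor's frequency.
The matrix products Gamma^m = B^(m) ... B^(1) map every layered haplotype
to a probability row over the cores; those rows both revise the core
frequencies (each rare haplotype's mass flows back to its likely ancestors)
and recode rare frequencies as linear combinations of core parameters for
the clustered likelihood-ratio test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .haplotypes import HaplotypeTable, hamming

__all__ = [
    "CoreSystem",
    "select_core",
    "layer_haplotypes",
    "allocation_matrix",
    "gamma_products",
    "revise_core_frequencies",
    "recode_frequency",
]

logger = logging.getLogger("hapcore")


def select_core(table: HaplotypeTable, mass: float = 0.9) -> list:
    """Indices of the core haplotypes, ordered by descending frequency.

    The core is the smallest descending-frequency prefix whose cumulative
    frequency reaches ``mass``; boundary ties are broken lexicographically
    on the haplotype string so the result is deterministic.
    """
    order = table.frequency_order()
    cum = 0.0
    core = []
    for i in order:
        core.append(i)
        cum += float(table.frequencies[i])
        if cum >= mass - 1e-12:
            break
    return core


def layer_haplotypes(table: HaplotypeTable, core_indices) -> list:
    """Partition non-core haplotypes into layers by distance to the core.

    Layer m holds the haplotypes whose minimum Hamming distance to any core
    haplotype is exactly m; the list runs m = 1..M.  Within a layer,
    haplotypes are ordered by descending frequency (lexicographic
    tie-break).
    """
    core_set = set(core_indices)
    dist = {}
    for i in range(len(table)):
        if i in core_set:
            continue
        dist[i] = min(hamming(table.haplotypes[i], table.haplotypes[c]) for c in core_indices)
    if not dist:
        return []
    M = max(dist.values())
    layers = []
    for m in range(1, M + 1):
        members = [i for i, d in dist.items() if d == m]
        members.sort(key=lambda i: (-table.frequencies[i], table.haplotypes[i]))
        layers.append(members)
    return layers


def allocation_matrix(layer_m, prev_level, table: HaplotypeTable) -> np.ndarray:
    """Row-stochastic descent probabilities from layer m to layer m-1.

    Row i covers the previous-level haplotypes at Hamming distance exactly 1
    from haplotype i, weighted by the ancestor's frequency.  When no
    distance-1 ancestor exists in the sample (an unobserved intermediate),
    the row falls back to the minimal-distance previous-level haplotypes,
    again frequency-proportional; each fallback is logged.
    """
    if len(prev_level) == 0:
        raise ValueError("previous level is empty")
    B = np.zeros((len(layer_m), len(prev_level)))
    for r, i in enumerate(layer_m):
        d = np.array(
            [hamming(table.haplotypes[i], table.haplotypes[p]) for p in prev_level]
        )
        dmin = d.min()
        if dmin != 1:
            logger.info(
                "haplotype %s has no one-step ancestor in the previous level; "
                "falling back to distance-%d allocation",
                table.haplotypes[i],
                int(dmin),
            )
        anc = d == dmin
        w = np.where(anc, np.maximum(table.frequencies[prev_level], 1e-12), 0.0)
        B[r] = w / w.sum()
    return B


def gamma_products(B_list) -> list:
    """Gamma^m = B^(m) B^(m-1) ... B^(1), for m = 1..M."""
    gammas = []
    acc = None
    for m, B in enumerate(B_list, start=1):
        if acc is None:
            acc = np.asarray(B, float)
        else:
            B = np.asarray(B, float)
            if B.shape[1] != acc.shape[0]:
                raise ValueError(
                    f"allocation matrix chain broken at layer {m}: "
                    f"{B.shape} cannot multiply {acc.shape}"
                )
            acc = B @ acc
        gammas.append(acc)
    return gammas


def revise_core_frequencies(table: HaplotypeTable, core_system: "CoreSystem") -> np.ndarray:
    """Fold every layered haplotype's mass back onto the cores.

    pi~^(0) = pi^(0) + sum_m (Gamma^m)^T pi^(m); row-stochastic Gamma
    matrices conserve the total mass exactly.
    """
    revised = table.frequencies[core_system.core_indices].astype(float).copy()
    for layer, gamma in zip(core_system.layers, core_system.Gamma):
        pi_m = table.frequencies[layer]
        revised += gamma.T @ pi_m
    return revised


def recode_frequency(h_index: int, core_system: "CoreSystem", core_freqs) -> float:
    """Score one haplotype under a core-parameter vector.

    A core haplotype scores its own entry; a layered haplotype scores the
    dot product of its Gamma row with the parameter vector.
    """
    gamma = np.asarray(core_freqs, float)
    core_pos = {h: p for p, h in enumerate(core_system.core_indices)}
    if h_index in core_pos:
        return float(gamma[core_pos[h_index]])
    for layer, G in zip(core_system.layers, core_system.Gamma):
        if h_index in layer:
            return float(G[layer.index(h_index)] @ gamma)
    raise KeyError(f"haplotype index {h_index} not in the core system")


@dataclass
class CoreSystem:
    """The clustered representation of a haplotype table.

    Holds the ordered core (H^(0)), the distance layers H^(1)..H^(M), the
    allocation matrices B^(m), their products Gamma^m, and the revised core
    frequencies.  All indices refer to positions in the source table.
    """

    core_indices: list
    layers: list
    B: list
    Gamma: list
    revised_core_freqs: np.ndarray
    mass_threshold: float
    _table: HaplotypeTable = field(repr=False, default=None)

    @classmethod
    def build(cls, table: HaplotypeTable, mass: float = 0.9) -> "CoreSystem":
        core = select_core(table, mass)
        # empty intermediate layers (unobserved intermediates) are dropped so
        # the allocation chain always links consecutive non-empty levels; the
        # minimal-distance fallback inside allocation_matrix absorbs the gap
        layers = [layer for layer in layer_haplotypes(table, core) if layer]
        B_list = []
        prev = core
        for layer in layers:
            B_list.append(allocation_matrix(layer, prev, table))
            prev = layer
        gammas = gamma_products(B_list)
        cs = cls(
            core_indices=core,
            layers=layers,
            B=B_list,
            Gamma=gammas,
            revised_core_freqs=np.zeros(len(core)),
            mass_threshold=mass,
            _table=table,
        )
        cs.revised_core_freqs = revise_core_frequencies(table, cs)
        return cs

    @property
    def n_cores(self) -> int:
        return len(self.core_indices)

    def recode_matrix(self, table: HaplotypeTable | None = None) -> np.ndarray:
        """(n_haplotypes x c) matrix A with A @ gamma scoring every haplotype."""
        table = table or self._table
        A = np.zeros((len(table), self.n_cores))
        for p, h in enumerate(self.core_indices):
            A[h, p] = 1.0
        for layer, G in zip(self.layers, self.Gamma):
            for r, h in enumerate(layer):
                A[h] = G[r]
        return A

    def to_json(self, path=None) -> str:
        payload = {
            "mass_threshold": self.mass_threshold,
            "core": [self._table.haplotypes[i] for i in self.core_indices]
            if self._table
            else list(self.core_indices),
            "core_indices": list(map(int, self.core_indices)),
            "layers": [list(map(int, layer)) for layer in self.layers],
            "B": [b.tolist() for b in self.B],
            "Gamma": [g.tolist() for g in self.Gamma],
            "revised_core_frequencies": self.revised_core_freqs.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
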