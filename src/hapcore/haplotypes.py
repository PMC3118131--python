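"""Haplotype universes and their frequency vectors.

A haplotype is an allele string over the biallelic PED alphabet ``{"1", "2"}``,
one character per tag SNP.  Internally haplotypes are also carried as integer
bitmasks (bit *i* set iff marker *i* carries allele ``2``), which makes
genotype-compatibility checks cheap bitwise operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeTable", "hamming", "hap_to_int", "int_to_hap"]

_FREQ_SUM_TOL = 1e-9


def hap_to_int(h: str) -> int:
    """Encode an allele string over {1,2} as a bitmask (allele 2 -> bit set)."""
    x = 0
    for i, ch in enumerate(h):
        if ch == "2":
            x |= 1 << i
        elif ch != "1":
            raise ValueError(f"invalid allele {ch!r} in haplotype {h!r}")
    return x


def int_to_hap(x: int, length: int) -> str:
    """Inverse of :func:`hap_to_int`."""
    return "".join("2" if (x >> i) & 1 else "1" for i in range(length))


def hamming(h1: str, h2: str) -> int:
    """Number of markers at which two haplotype strings differ.

    One-step mutations correspond to Hamming distance 1, which is the
    distance underlying the evolutionary layering of rare haplotypes.
    """
    if len(h1) != len(h2):
        raise ValueError(f"haplotype length mismatch: {len(h1)} vs {len(h2)}")
    return sum(a != b for a, b in zip(h1, h2))


@dataclass
class HaplotypeTable:
    """An ordered haplotype universe with a frequency vector.

    Frequencies must be nonnegative and sum to 1 within 1e-9; use
    :meth:`normalized` to build a table from unnormalized weights (for
    example a pool file whose rows sum to 0.999).
    """

    haplotypes: list[str]
    frequencies: np.ndarray
    labels: list[str] | None = None
    _ints: np.ndarray = field(init=False, repr=False)
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = list(self.haplotypes)
        if not self.haplotypes:
            raise ValueError("haplotype table may not be empty")
        L = len(self.haplotypes[0])
        if any(len(h) != L for h in self.haplotypes):
            raise ValueError("all haplotypes must have equal length")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotype strings")
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.shape != (len(self.haplotypes),):
            raise ValueError("frequency vector length mismatch")
        if np.any(freqs < 0):
            raise ValueError("negative haplotype frequency")
        if abs(freqs.sum() - 1.0) > _FREQ_SUM_TOL:
            raise ValueError(f"frequencies sum to {freqs.sum():.12f}, not 1")
        self.frequencies = freqs
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(self.haplotypes):
                raise ValueError("label list length mismatch")
        self._ints = np.array([hap_to_int(h) for h in self.haplotypes], dtype=np.int64)
        self._index = {h: i for i, h in enumerate(self.haplotypes)}

    @classmethod
    def normalized(
        cls,
        haplotypes,
        weights,
        labels=None,
        tol: float = 0.01,
    ) -> "HaplotypeTable":
        """Build a table, renormalizing weights whose sum is within ``tol`` of 1."""
        w = np.asarray(weights, dtype=float)
        total = w.sum()
        if abs(total - 1.0) > tol:
            raise ValueError(f"frequencies sum to {total:.6f}, outside 1 +/- {tol}")
        if total <= 0:
            raise ValueError("nonpositive total frequency")
        return cls(list(haplotypes), w / total, labels=labels)

    # -- basic accessors -------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_markers(self) -> int:
        return len(self.haplotypes[0])

    def __len__(self) -> int:
        return len(self.haplotypes)

    def as_ints(self) -> np.ndarray:
        """Bitmask encoding of every haplotype (do not mutate the result)."""
        return self._ints

    def index_of(self, h: str) -> int:
        try:
            return self._index[h]
        except KeyError:
            raise KeyError(f"haplotype {h!r} not in table") from None

    def subset(self, indices, renormalize: bool = True) -> "HaplotypeTable":
        """Restrict the table to ``indices`` (renormalizing by default)."""
        indices = list(indices)
        haps = [self.haplotypes[i] for i in indices]
        freqs = self.frequencies[indices]
        labels = [self.labels[i] for i in indices] if self.labels else None
        if renormalize:
            total = freqs.sum()
            if total <= 0:
                raise ValueError("subset has zero total frequency")
            freqs = freqs / total
        return HaplotypeTable(haps, freqs, labels=labels)

    def frequency_order(self) -> list[int]:
        """Indices sorted by descending frequency, lexicographic tie-break."""
        return sorted(
            range(len(self.haplotypes)),
            key=lambda i: (-self.frequencies[i], self.haplotypes[i]),
        )

    def with_frequencies(self, freqs) -> "HaplotypeTable":
        """Same haplotypes with a replacement frequency vector."""
        return HaplotypeTable(self.haplotypes, np.asarray(freqs, float), labels=self.labels)
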