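"""Cell/clone genotypes: homolog-level bin copy numbers and mutation addresses.

A genotype stores, per chromosome ``i``, a ``(J_i, M_i)`` integer array of
per-bin copy numbers, one row per homolog.  Every mutation (driver or
passenger) carries an address ``(chrom, homolog, bin, unit)`` identifying the
copy-number unit it resides on; copy-number events duplicate or remove
mutations together with the units they sit on.  Addresses are 0-based
internally (``unit`` indexes ``0..K-1`` within a bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import ArmId, GenomeSpec

__all__ = [
    "Mutation",
    "CloneGenotype",
    "diploid_genotype",
    "ploidy",
    "arm_cn",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (2.5 -> 3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class Mutation:
    """A single mutant copy with its genomic address.

    ``tag`` names the driver gene for driver mutations, or an opaque
    identifier for passenger SNVs.
    """

    tag: str
    chrom: int
    homolog: int
    bin: int
    unit: int


class CloneGenotype:
    """Bin-level, homolog-resolved copy-number profile plus mutations."""

    __slots__ = ("cn", "mutations", "wgd_count")

    def __init__(self, cn, mutations=None, wgd_count: int = 0):
        self.cn = cn  # list of (J_i, M_i) int arrays
        self.mutations: list = list(mutations) if mutations else []
        self.wgd_count = int(wgd_count)

    # -- basic structure -------------------------------------------------
    def homolog_count(self, chrom: int) -> int:
        return self.cn[chrom].shape[0]

    @property
    def total_homologs(self) -> int:
        return sum(a.shape[0] for a in self.cn)

    def copy(self) -> "CloneGenotype":
        return CloneGenotype(
            [a.copy() for a in self.cn], list(self.mutations), self.wgd_count
        )

    def total_cn_profile(self) -> np.ndarray:
        """Genome-wide per-bin total CN (summed over homologs)."""
        return np.concatenate(
            [a.sum(axis=0) if a.shape[0] else np.zeros(a.shape[1], dtype=a.dtype)
             for a in self.cn]
        )

    def total_cn(self) -> int:
        return int(sum(int(a.sum()) for a in self.cn))

    def __eq__(self, other):
        if not isinstance(other, CloneGenotype):
            return NotImplemented
        return (
            self.wgd_count == other.wgd_count
            and len(self.cn) == len(other.cn)
            and all(
                a.shape == b.shape and np.array_equal(a, b)
                for a, b in zip(self.cn, other.cn)
            )
            and sorted(map(_mut_key, self.mutations))
            == sorted(map(_mut_key, other.mutations))
        )

    def __hash__(self):  # pragma: no cover - only identity uses in dicts
        return id(self)

    # -- bookkeeping helpers ---------------------------------------------
    def mutant_copies(self, tag: str) -> int:
        return sum(1 for m in self.mutations if m.tag == tag)

    def validate(self, genome: GenomeSpec) -> None:
        """Raise if the genotype violates its structural invariants."""
        if len(self.cn) != genome.n_chroms:
            raise ValueError("chromosome count mismatch")
        for i, a in enumerate(self.cn):
            if a.shape[1] != genome.bins_per_chrom[i]:
                raise ValueError(f"bin count mismatch on chromosome {i}")
            if (a < 0).any():
                raise ValueError("negative copy number")
        for m in self.mutations:
            a = self.cn[m.chrom]
            if not (0 <= m.homolog < a.shape[0]):
                raise ValueError(f"mutation homolog out of range: {m}")
            if not (0 <= m.bin < a.shape[1]):
                raise ValueError(f"mutation bin out of range: {m}")
            if not (0 <= m.unit < a[m.homolog, m.bin]):
                raise ValueError(f"mutation unit exceeds bin CN: {m}")


def _mut_key(m: Mutation):
    return (m.tag, m.chrom, m.homolog, m.bin, m.unit)


def diploid_genotype(genome: GenomeSpec) -> CloneGenotype:
    """Unmutated diploid genotype: two homologs per chromosome, CN 1 per bin."""
    cn = [
        np.ones((2, int(m)), dtype=np.int32) for m in genome.bins_per_chrom
    ]
    return CloneGenotype(cn)


def ploidy(genotype: CloneGenotype, genome: GenomeSpec) -> int:
    """Genome-wide mean bin CN, rounded to nearest integer (ties up)."""
    return round_half_up(genotype.total_cn() / genome.total_bins)


def arm_cn(genotype: CloneGenotype, arm: ArmId, genome: GenomeSpec) -> int:
    """Arm copy number: mean homolog-summed CN over the arm's bins, rounded."""
    a = genotype.cn[arm.chrom]
    if a.shape[0] == 0:
        return 0
    seg = a[:, arm.bin_start : arm.bin_stop]
    return round_half_up(float(seg.sum()) / arm.n_bins)
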