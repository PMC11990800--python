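"""Genome geometry: chromosomes, equal-length bins, centromeres and arms.

The genome is discretised into bins of a fixed size ``L`` (in bp).  Chromosome
``i`` of length ``length_i`` contributes ``M_i = ceil(length_i / L)`` bins; the
bin containing the centromere terminates the p-arm, and the q-arm runs from the
next bin to the end of the chromosome.  All bin indices are 0-based half-open
internally; exported tables use BED-style bp intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArmId", "GenomeSpec", "build_genome", "toy_genome", "human_genome"]


@dataclass(frozen=True)
class ArmId:
    """One chromosome arm: a contiguous, non-empty bin range on a chromosome."""

    label: str
    chrom: int  # 0-based chromosome index
    bin_start: int  # 0-based inclusive
    bin_stop: int  # 0-based exclusive

    @property
    def n_bins(self) -> int:
        return self.bin_stop - self.bin_start


@dataclass(frozen=True)
class GenomeSpec:
    """Static genome geometry shared by every cell of a simulation."""

    chrom_names: tuple
    chrom_lengths: tuple  # bp
    bin_size: int  # bp
    bins_per_chrom: np.ndarray = field(compare=False)  # M_i
    centromere_bin: np.ndarray = field(compare=False)  # p-arm bin count per chromosome
    arms: tuple = ()  # ArmId, ordered 1p, 1q, 2p, ...

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def total_bins(self) -> int:
        return int(self.bins_per_chrom.sum())

    @property
    def arm_labels(self) -> list:
        return [a.label for a in self.arms]

    def arm(self, label: str) -> ArmId:
        for a in self.arms:
            if a.label == label:
                return a
        raise KeyError(f"unknown arm {label!r}")

    def bin_offsets(self) -> np.ndarray:
        """Genome-wide start offset of each chromosome's first bin."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)[:-1]])


def build_genome(
    chrom_lengths,
    centromere_positions,
    bin_size: int,
    chrom_names=None,
) -> GenomeSpec:
    """Construct a :class:`GenomeSpec` from bp lengths and centromere positions.

    Parameters
    ----------
    chrom_lengths
        Chromosome lengths in bp, one per chromosome.
    centromere_positions
        Centromere position in bp per chromosome; must lie strictly inside
        the chromosome.
    bin_size
        Bin length ``L`` in bp.
    """
    chrom_lengths = [int(x) for x in chrom_lengths]
    centromere_positions = [int(x) for x in centromere_positions]
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(chrom_lengths) != len(centromere_positions):
        raise ValueError("chrom_lengths and centromere_positions length mismatch")
    if any(x <= 0 for x in chrom_lengths):
        raise ValueError("chromosome lengths must be positive")
    for ln, cen in zip(chrom_lengths, centromere_positions):
        if not (0 < cen < ln):
            raise ValueError("centromere must lie strictly inside the chromosome")
    if chrom_names is None:
        chrom_names = tuple(str(i + 1) for i in range(len(chrom_lengths)))
    else:
        chrom_names = tuple(str(c) for c in chrom_names)

    bins = np.array([math.ceil(ln / bin_size) for ln in chrom_lengths], dtype=np.int64)
    cen_bin = np.array(
        [math.ceil(c / bin_size) for c in centromere_positions], dtype=np.int64
    )
    # the centromere-containing bin terminates the p-arm
    cen_bin = np.minimum(cen_bin, bins)

    arms = []
    for i, name in enumerate(chrom_names):
        p_stop = int(cen_bin[i])
        if p_stop > 0:
            arms.append(ArmId(f"{name}p", i, 0, p_stop))
        if p_stop < int(bins[i]):
            arms.append(ArmId(f"{name}q", i, p_stop, int(bins[i])))
    return GenomeSpec(
        chrom_names=chrom_names,
        chrom_lengths=tuple(chrom_lengths),
        bin_size=int(bin_size),
        bins_per_chrom=bins,
        centromere_bin=cen_bin,
        arms=tuple(arms),
    )


def toy_genome(n_chroms: int = 4) -> GenomeSpec:
    """Small test genome: chromosomes of 50, 40, 30, 20, ... Mb, 1-Mb bins.

    Centromeres sit at 40% of each chromosome, giving 8 arms for the default
    4-chromosome genome (140 bins total).
    """
    mb = 1_000_000
    lengths = [(50 - 10 * i) * mb for i in range(n_chroms)]
    if any(ln <= 0 for ln in lengths):
        raise ValueError("too many chromosomes for the toy layout")
    cens = [int(0.4 * ln) for ln in lengths]
    return build_genome(lengths, cens, mb)


# hg19 chromosome lengths and (approximate) centromere midpoints, bp.
_HG19 = {
    "1": (249250621, 125000000), "2": (243199373, 93300000),
    "3": (198022430, 91000000), "4": (191154276, 50400000),
    "5": (180915260, 48400000), "6": (171115067, 61000000),
    "7": (159138663, 59900000), "8": (146364022, 45600000),
    "9": (141213431, 49000000), "10": (135534747, 40200000),
    "11": (135006516, 53700000), "12": (133851895, 35800000),
    "13": (115169878, 17900000), "14": (107349540, 17600000),
    "15": (102531392, 19000000), "16": (90354753, 36600000),
    "17": (81195210, 24000000), "18": (78077248, 17200000),
    "19": (59128983, 26500000), "20": (63025520, 27500000),
    "21": (48129895, 13200000), "22": (51304566, 14700000),
    "X": (155270560, 60600000), "Y": (59373566, 12500000),
}


def human_genome(bin_size: int = 500_000) -> GenomeSpec:
    """24-chromosome human genome preset (hg19 lengths), default 500-kb bins."""
    names = list(_HG19)
    lengths = [_HG19[n][0] for n in names]
    cens = [_HG19[n][1] for n in names]
    return build_genome(lengths, cens, bin_size, chrom_names=names)
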