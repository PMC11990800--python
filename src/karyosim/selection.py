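"""Fitness models: chromosome-arm selection, driver-gene selection, hybrid.

Arm model: each arm ``r`` has a selection rate ``lambda_r > 0``; a cell with
arm copy numbers ``c_r`` and ploidy ``c`` has fitness
``s = prod_r lambda_r ** (c_r / c)``.  Because the exponents are ratios of
copy number to ploidy, a whole-genome duplication leaves arm fitness exactly
unchanged.

Driver model: each driver gene has wild-type/mutant allele rates derived from
a base rate ``lambda_d >= 1`` -- oncogenes: ``(lambda_d, lambda_d**2)``;
tumor suppressors: ``(1/lambda_d, 1)`` -- and the cell's fitness is
``prod_d lam_WT ** (2 n_WT / c) * lam_MUT ** (2 n_MUT / c)``, so that mutating
or losing a TSG allele and mutating or gaining an OG allele both raise
fitness.

Hybrid model: the product of the two.  Viability checkpoints set fitness to
zero for karyotypes beyond configured ploidy / CN / nullisomy / WGD limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeSpec
from .genotype import CloneGenotype, arm_cn, ploidy

__all__ = [
    "ArmSelectionRates",
    "DriverGene",
    "ViabilityConfig",
    "SelectionModel",
    "arm_fitness",
    "driver_fitness",
    "hybrid_fitness",
    "check_viability",
    "clone_fitness",
]


class ArmSelectionRates(dict):
    """Map arm label -> selection rate; arms absent from the map default to 1."""

    def __init__(self, rates=None):
        super().__init__()
        if rates:
            for k, v in dict(rates).items():
                v = float(v)
                if v <= 0:
                    raise ValueError(f"selection rate for {k} must be > 0")
                self[k] = v

    def rate(self, label: str) -> float:
        return self.get(label, 1.0)


@dataclass(frozen=True)
class DriverGene:
    """A driver gene with its role, locus and base selection rate."""

    name: str
    role: str  # "TSG" or "OG"
    rate: float  # lambda_d >= 1
    chrom: int  # 0-based chromosome index
    bin: int  # 0-based bin index

    def __post_init__(self):
        if self.role not in ("TSG", "OG"):
            raise ValueError(f"driver role must be TSG or OG, got {self.role!r}")
        if self.rate < 1:
            raise ValueError("driver base rate must be >= 1")

    @property
    def lam_wt(self) -> float:
        return self.rate if self.role == "OG" else 1.0 / self.rate

    @property
    def lam_mut(self) -> float:
        return self.rate**2 if self.role == "OG" else 1.0


@dataclass(frozen=True)
class ViabilityConfig:
    """Karyotype viability thresholds; violating any one is lethal.

    ``nullisomy_max=None`` means a budget of 5% of the genome's bins with
    zero total copy number.
    """

    ploidy_max: float = 8
    cn_max: float = 20
    cn_max_normalized: float = 5
    nullisomy_max: int | None = None
    driver_max: float = math.inf
    wgd_max: float = 2

    def nullisomy_budget(self, genome: GenomeSpec) -> float:
        if self.nullisomy_max is None:
            return math.floor(0.05 * genome.total_bins)
        return self.nullisomy_max


def check_viability(
    genotype: CloneGenotype, cfg: ViabilityConfig, genome: GenomeSpec
):
    """Return ``(viable, reason)``; ``reason`` is None when viable."""
    c = ploidy(genotype, genome)
    if c < 1:
        return False, "zero ploidy"
    if c > cfg.ploidy_max:
        return False, "ploidy"
    max_bin = max((int(a.max()) if a.size else 0) for a in genotype.cn)
    if max_bin > cfg.cn_max:
        return False, "cn_max"
    if max_bin / c > cfg.cn_max_normalized:
        return False, "cn_max_normalized"
    null_bins = int((genotype.total_cn_profile() == 0).sum())
    if null_bins > cfg.nullisomy_budget(genome):
        return False, "nullisomy"
    if cfg.driver_max != math.inf:
        n_drivers = len({m.tag for m in genotype.mutations})
        if n_drivers > cfg.driver_max:
            return False, "driver_count"
    if genotype.wgd_count > cfg.wgd_max:
        return False, "wgd_count"
    return True, None


def arm_fitness(
    genotype: CloneGenotype, rates: ArmSelectionRates, genome: GenomeSpec
) -> float:
    """Arm-selection fitness ``prod_r lambda_r ** (c_r / c)``; 0 if ploidy 0.

    The numerator is the exact (unrounded) mean arm copy number; the
    normalising ploidy ``c`` is the lineage's reference ploidy
    ``2 * 2**wgd_count``.  Both double under a whole-genome duplication, so
    fitness is exactly invariant under WGD, and changes in one arm's dosage
    do not leak into the exponents of the others.  For near-diploid and
    near-tetraploid karyotypes -- the regime the model operates in -- the
    reference ploidy coincides with the rounded mean ploidy returned by
    :func:`~karyosim.genotype.ploidy`, which remains the reported statistic.
    A genotype with no genomic material at all has fitness 0.
    """
    if genotype.total_cn() == 0:
        return 0.0
    c = 2.0 * 2**genotype.wgd_count
    log_s = 0.0
    for arm in genome.arms:
        lam = rates.rate(arm.label) if isinstance(rates, ArmSelectionRates) else rates.get(arm.label, 1.0)
        if lam == 1.0:
            continue
        seg = genotype.cn[arm.chrom][:, arm.bin_start : arm.bin_stop]
        cr = float(seg.sum()) / arm.n_bins
        log_s += (cr / c) * math.log(lam)
    return math.exp(log_s)


def driver_fitness(
    genotype: CloneGenotype, drivers, genome: GenomeSpec
) -> float:
    """Driver-gene fitness from WT/mutant allele counts at each gene's locus.

    As in :func:`arm_fitness`, the normalising ploidy in the exponent is
    the lineage reference ploidy ``2 * 2**wgd_count``.
    """
    if genotype.total_cn() == 0:
        return 0.0
    c = 2.0 * 2**genotype.wgd_count
    log_s = 0.0
    for gene in drivers:
        n_tot = int(genotype.cn[gene.chrom][:, gene.bin].sum())
        n_mut = genotype.mutant_copies(gene.name)
        n_wt = max(n_tot - n_mut, 0)
        if n_wt:
            log_s += (2.0 * n_wt / c) * math.log(gene.lam_wt)
        if n_mut:
            log_s += (2.0 * n_mut / c) * math.log(gene.lam_mut)
    return math.exp(log_s)


def hybrid_fitness(genotype, rates, drivers, genome) -> float:
    return arm_fitness(genotype, rates, genome) * driver_fitness(
        genotype, drivers, genome
    )


@dataclass
class SelectionModel:
    """Bundle of the selection configuration used by the simulator.

    ``model`` is one of ``"arm"``, ``"driver"``, ``"hybrid"``.
    """

    model: str = "arm"
    rates: ArmSelectionRates = field(default_factory=ArmSelectionRates)
    drivers: tuple = ()
    viability: ViabilityConfig = field(default_factory=ViabilityConfig)

    def __post_init__(self):
        if self.model not in ("arm", "driver", "hybrid"):
            raise ValueError(f"unknown selection model {self.model!r}")
        if not isinstance(self.rates, ArmSelectionRates):
            self.rates = ArmSelectionRates(self.rates)
        self.drivers = tuple(self.drivers)


import functools


def _arm_geometry(genome: GenomeSpec):
    """(arm labels, start offsets in the concatenated profile, arm lengths)."""
    cached = genome.__dict__.get("_geom")
    if cached is not None:
        return cached
    offsets = genome.bin_offsets()
    starts = np.array([offsets[a.chrom] + a.bin_start for a in genome.arms], dtype=np.intp)
    lengths = np.array([a.n_bins for a in genome.arms], dtype=float)
    labels = tuple(a.label for a in genome.arms)
    geom = (labels, starts, lengths)
    object.__setattr__(genome, "_geom", geom)
    return geom


def _log_rates(sel: SelectionModel, genome: GenomeSpec) -> np.ndarray:
    cached = getattr(sel, "_loglam", None)
    if cached is not None:
        return cached
    labels, _, _ = _arm_geometry(genome)
    loglam = np.array([math.log(sel.rates.rate(lab)) for lab in labels])
    sel._loglam = loglam
    return loglam


def clone_fitness(
    genotype: CloneGenotype, sel: SelectionModel, genome: GenomeSpec
) -> float:
    """Fitness rate of a clone under the configured model, gated by viability.

    Equivalent to gating :func:`arm_fitness` / :func:`driver_fitness` /
    :func:`hybrid_fitness` with :func:`check_viability`; the arm term is
    evaluated through a vectorised path (this is the per-clone hot spot of
    the simulator).
    """
    cfg = sel.viability
    profile = genotype.total_cn_profile()
    total = int(profile.sum())
    m_bins = genome.total_bins
    c_int = int(math.floor(total / m_bins + 0.5))
    if c_int < 1 or c_int > cfg.ploidy_max:
        return 0.0
    max_bin = max((int(a.max()) if a.size else 0) for a in genotype.cn)
    if max_bin > cfg.cn_max or max_bin / c_int > cfg.cn_max_normalized:
        return 0.0
    if int((profile == 0).sum()) > cfg.nullisomy_budget(genome):
        return 0.0
    if genotype.wgd_count > cfg.wgd_max:
        return 0.0
    if cfg.driver_max != math.inf:
        if len({m.tag for m in genotype.mutations}) > cfg.driver_max:
            return 0.0
    if sel.model == "driver":
        return driver_fitness(genotype, sel.drivers, genome)
    # arm term (vectorised; lineage reference ploidy in the exponent)
    c = 2.0 * 2**genotype.wgd_count
    loglam = _log_rates(sel, genome)
    if loglam.any():
        _, starts, lengths = _arm_geometry(genome)
        sums = np.add.reduceat(profile, starts)
        s_arm = math.exp(float(((sums / lengths) / c) @ loglam))
    else:
        s_arm = 1.0
    if sel.model == "arm":
        return s_arm
    return s_arm * driver_fitness(genotype, sel.drivers, genome)
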