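"""Copy-number aberration mechanisms and driver mutation acquisition.

Five CNA mechanisms act at cell division: whole-genome duplication (one
daughter receives two copies of every homolog), whole-chromosome
missegregation (one homolog is misplaced between the daughters), arm
missegregation (one arm of a homolog is misplaced), focal amplification
(doubles the CN across a bin range on one homolog) and focal deletion (zeroes
it).  Driver mutations convert one wild-type copy-number unit of a gene's
locus to mutant.  Mutations ride on their copy-number units: duplication of a
unit duplicates the mutations on it, deletion removes them.

Focal event lengths are modelled as a Beta-distributed fraction of the arm
length.  Missegregation probabilities are per homolog per division and are
multiplied by the WGD-aneuploidy rate ``alpha`` in lineages that have
undergone whole-genome duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ArmId, GenomeSpec
from .genotype import CloneGenotype, Mutation, round_half_up

__all__ = [
    "EventProbabilities",
    "FocalLengthModel",
    "apply_wgd",
    "apply_chrom_missegregation",
    "apply_arm_missegregation",
    "apply_focal_amplification",
    "apply_focal_deletion",
    "apply_driver_mutation",
    "sample_focal_range",
    "sample_division_events",
    "divide",
    "apply_op",
    "replay_ops",
    "event_probability",
]


@dataclass(frozen=True)
class FocalLengthModel:
    """Beta parameters for focal event length as a fraction of arm length."""

    a_amp: float = 2.0
    b_amp: float = 5.0
    a_del: float = 2.0
    b_del: float = 5.0

    def __post_init__(self):
        if min(self.a_amp, self.b_amp, self.a_del, self.b_del) <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass(frozen=True)
class EventProbabilities:
    """Per-division event probabilities.

    ``p_misseg`` and ``p_arm_misseg`` are per homolog per division; the
    remaining probabilities are per division.  ``alpha`` multiplies both
    missegregation probabilities in WGD lineages (clamped to [0, 1]).
    """

    p_wgd: float = 0.0
    p_misseg: float = 0.0
    p_arm_misseg: float = 0.0
    p_focal_amp: float = 0.0
    p_focal_del: float = 0.0
    p_driver_mut: float = 0.0
    alpha: float = 1.0
    focal_lengths: FocalLengthModel = field(default_factory=FocalLengthModel)

    def __post_init__(self):
        for name in (
            "p_wgd", "p_misseg", "p_arm_misseg",
            "p_focal_amp", "p_focal_del", "p_driver_mut",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def misseg_rates(self, wgd_count: int):
        """Effective per-homolog (whole-chromosome, arm) rates for a lineage."""
        mult = self.alpha if wgd_count > 0 else 1.0
        return (
            min(self.p_misseg * mult, 1.0),
            min(self.p_arm_misseg * mult, 1.0),
        )


# ---------------------------------------------------------------------------
# primitive operations (single-genotype, replayable)
# ---------------------------------------------------------------------------

def _dup_homolog(g: CloneGenotype, i: int, j: int) -> None:
    """Append a copy of homolog j of chromosome i (new index J_i)."""
    a = g.cn[i]
    jn = a.shape[0]
    g.cn[i] = np.vstack([a, a[j : j + 1]])
    g.mutations.extend(
        Mutation(m.tag, i, jn, m.bin, m.unit)
        for m in list(g.mutations)
        if m.chrom == i and m.homolog == j
    )


def _del_homolog(g: CloneGenotype, i: int, j: int) -> None:
    """Remove homolog j of chromosome i; re-index higher homologs."""
    g.cn[i] = np.delete(g.cn[i], j, axis=0)
    out = []
    for m in g.mutations:
        if m.chrom == i:
            if m.homolog == j:
                continue
            if m.homolog > j:
                m = Mutation(m.tag, i, m.homolog - 1, m.bin, m.unit)
        out.append(m)
    g.mutations = out


def _amp_region(g: CloneGenotype, i: int, j: int, start: int, stop: int) -> None:
    """Double CN across bins [start, stop) of homolog j; duplicate mutations."""
    a = g.cn[i]
    old = a[j, start:stop].copy()
    a[j, start:stop] = 2 * old
    g.mutations.extend(
        Mutation(m.tag, i, j, m.bin, m.unit + int(old[m.bin - start]))
        for m in list(g.mutations)
        if m.chrom == i and m.homolog == j and start <= m.bin < stop
    )


def _del_region(g: CloneGenotype, i: int, j: int, start: int, stop: int) -> None:
    """Zero CN across bins [start, stop) of homolog j; drop mutations there."""
    g.cn[i][j, start:stop] = 0
    g.mutations = [
        m
        for m in g.mutations
        if not (m.chrom == i and m.homolog == j and start <= m.bin < stop)
    ]


def _apply_wgd_inplace(g: CloneGenotype) -> None:
    new_muts = []
    for i, a in enumerate(g.cn):
        jn = a.shape[0]
        g.cn[i] = np.vstack([a, a])
        new_muts.extend(
            Mutation(m.tag, i, m.homolog + jn, m.bin, m.unit)
            for m in g.mutations
            if m.chrom == i
        )
    g.mutations.extend(new_muts)
    g.wgd_count += 1


def apply_op(g: CloneGenotype, op: tuple) -> None:
    """Apply one replayable division op to a genotype in place.

    Ops referencing homologs that no longer exist are silently skipped; this
    can only arise when several events co-occur in one division.
    """
    kind = op[0]
    if kind == "wgd":
        _apply_wgd_inplace(g)
        return
    if kind in ("driver_mut", "passenger_mut"):
        _, tag, i, j, b, u = op
        if j < g.cn[i].shape[0] and u < g.cn[i][j, b]:
            g.mutations.append(Mutation(tag, i, j, b, u))
        return
    _, i, j, *rest = op
    if j >= g.cn[i].shape[0]:
        return
    if kind == "dup_homolog":
        _dup_homolog(g, i, j)
    elif kind == "del_homolog":
        _del_homolog(g, i, j)
    elif kind == "amp_region":
        _amp_region(g, i, j, *rest)
    elif kind == "del_region":
        _del_region(g, i, j, *rest)
    else:
        raise ValueError(f"unknown op {kind!r}")


def replay_ops(genotype: CloneGenotype, ops) -> CloneGenotype:
    """Return a copy of ``genotype`` with ``ops`` applied in order."""
    g = genotype.copy()
    for op in ops:
        apply_op(g, op)
    return g


# ---------------------------------------------------------------------------
# spec-level event operations (mother -> daughters)
# ---------------------------------------------------------------------------

def apply_wgd(mother: CloneGenotype):
    """WGD at division: one daughter with every homolog doubled, one plain."""
    d_wgd = mother.copy()
    _apply_wgd_inplace(d_wgd)
    return d_wgd, mother.copy()


def apply_chrom_missegregation(mother: CloneGenotype, chrom: int, homolog: int):
    """Misplace one homolog: returns (gainer, loser).

    The gainer receives an extra copy of the homolog; the loser lacks it.
    Per-bin CN summed over the daughters equals twice the mother's.
    """
    if homolog >= mother.cn[chrom].shape[0]:
        return mother.copy(), mother.copy()
    gainer, loser = mother.copy(), mother.copy()
    _dup_homolog(gainer, chrom, homolog)
    _del_homolog(loser, chrom, homolog)
    return gainer, loser


def apply_arm_missegregation(mother: CloneGenotype, chrom: int, homolog: int, arm: ArmId):
    """Misplace one arm of a homolog: the detached segment moves entirely."""
    if homolog >= mother.cn[chrom].shape[0]:
        return mother.copy(), mother.copy()
    gainer, loser = mother.copy(), mother.copy()
    _amp_region(gainer, chrom, homolog, arm.bin_start, arm.bin_stop)
    _del_region(loser, chrom, homolog, arm.bin_start, arm.bin_stop)
    return gainer, loser


def apply_focal_amplification(genotype: CloneGenotype, chrom: int, homolog: int, bin_range):
    """Double CN across the bin range [start, stop) on one homolog."""
    start, stop = bin_range
    if stop <= start:
        raise ValueError("empty focal range")
    g = genotype.copy()
    if homolog < g.cn[chrom].shape[0]:
        _amp_region(g, chrom, homolog, start, stop)
    return g


def apply_focal_deletion(genotype: CloneGenotype, chrom: int, homolog: int, bin_range):
    """Zero CN across the bin range [start, stop) on one homolog."""
    start, stop = bin_range
    if stop <= start:
        raise ValueError("empty focal range")
    g = genotype.copy()
    if homolog < g.cn[chrom].shape[0]:
        _del_region(g, chrom, homolog, start, stop)
    return g


def _wt_units(genotype: CloneGenotype, gene) -> list:
    """All wild-type (homolog, unit) slots at a gene's locus."""
    taken = {
        (m.homolog, m.unit)
        for m in genotype.mutations
        if m.tag == gene.name and m.chrom == gene.chrom and m.bin == gene.bin
    }
    a = genotype.cn[gene.chrom]
    return [
        (j, u)
        for j in range(a.shape[0])
        for u in range(int(a[j, gene.bin]))
        if (j, u) not in taken
    ]


def apply_driver_mutation(genotype: CloneGenotype, drivers, rng) -> CloneGenotype:
    """Mutate one wild-type allele of a uniformly chosen driver gene.

    Genes with no wild-type copy cannot be selected; if none qualifies the
    genotype is returned unchanged.
    """
    g = genotype.copy()
    op = _sample_driver_op(g, drivers, rng)
    if op is not None:
        apply_op(g, op)
    return g


def _sample_driver_op(genotype, drivers, rng):
    eligible = [(gene, _wt_units(genotype, gene)) for gene in drivers]
    eligible = [(gene, units) for gene, units in eligible if units]
    if not eligible:
        return None
    gene, units = eligible[rng.integers(len(eligible))]
    j, u = units[rng.integers(len(units))]
    return ("driver_mut", gene.name, gene.chrom, j, gene.bin, u)


def sample_focal_range(arm: ArmId, model: FocalLengthModel, rng, kind: str = "del"):
    """Draw a focal event's bin range within an arm.

    Length is ``max(1, round(Beta(a, b) * arm_bins))``; start is uniform among
    positions where the range fits.
    """
    a, b = (model.a_amp, model.b_amp) if kind == "amp" else (model.a_del, model.b_del)
    ratio = rng.beta(a, b)
    length = min(max(1, round_half_up(ratio * arm.n_bins)), arm.n_bins)
    start = arm.bin_start + int(rng.integers(arm.n_bins - length + 1))
    return start, start + length


# ---------------------------------------------------------------------------
# division-level sampling
# ---------------------------------------------------------------------------

def _category_zero_probs(genotype: CloneGenotype, probs: EventProbabilities):
    j = genotype.total_homologs
    key = (j, genotype.wgd_count > 0)
    cache = probs.__dict__.get("_qz_cache")
    if cache is None:
        cache = {}
        object.__setattr__(probs, "_qz_cache", cache)
    qz = cache.get(key)
    if qz is None:
        pm, pa = probs.misseg_rates(genotype.wgd_count)
        qz = np.array(
            [
                1.0 - probs.p_wgd,
                (1.0 - pm) ** j,
                (1.0 - pa) ** j,
                1.0 - probs.p_focal_amp,
                1.0 - probs.p_focal_del,
                1.0 - probs.p_driver_mut,
            ]
        )
        cache[key] = qz
    return qz


def event_probability(genotype: CloneGenotype, probs: EventProbabilities) -> float:
    """Probability that at least one event occurs in one division."""
    return float(1.0 - _category_zero_probs(genotype, probs).prod())


def _binom_ge1(n: int, p: float, rng) -> int:
    """Sample Binomial(n, p) conditioned on being >= 1 by pmf inversion."""
    if n == 0 or p <= 0:
        return 1  # degenerate; caller guarantees positive mass
    if p >= 1:
        return n
    q = 1.0 - p
    norm = 1.0 - q**n
    u = rng.random() * norm
    pmf = n * p * q ** (n - 1)
    k = 1
    acc = pmf
    while acc < u and k < n:
        pmf *= (n - k) / (k + 1) * (p / q)
        k += 1
        acc += pmf
    return k


def _sample_event_counts(genotype, probs, rng, condition: bool):
    """Counts per category (wgd, misseg, arm misseg, amp, del, driver)."""
    pm, pa = probs.misseg_rates(genotype.wgd_count)
    j = genotype.total_homologs
    pvec = [probs.p_wgd, pm, pa, probs.p_focal_amp, probs.p_focal_del, probs.p_driver_mut]
    nvec = [1, j, j, 1, 1, 1]
    if not condition:
        return [rng.binomial(n, p) if n > 0 and p > 0 else 0 for n, p in zip(nvec, pvec)]
    qz = _category_zero_probs(genotype, probs)
    p_any = 1.0 - qz.prod()
    if p_any <= 0:
        return [0] * 6
    # pick the first category with a non-zero count, then sample later
    # categories unconditionally
    u = rng.random() * p_any
    prefix = 1.0
    first = 5
    for idx in range(6):
        mass = prefix * (1.0 - qz[idx])
        if u < mass:
            first = idx
            break
        u -= mass
        prefix *= qz[idx]
    counts = [0] * 6
    if nvec[first] == 1:
        counts[first] = 1
    else:
        counts[first] = _binom_ge1(nvec[first], pvec[first], rng)
    for idx in range(first + 1, 6):
        n, p = nvec[idx], pvec[idx]
        counts[idx] = rng.binomial(n, p) if n > 0 and p > 0 else 0
    return counts


def _pick_homolog(genotype: CloneGenotype, rng):
    """Uniform homolog across the genome; returns (chrom, homolog) or None."""
    total = genotype.total_homologs
    if total == 0:
        return None
    k = int(rng.integers(total))
    for i, a in enumerate(genotype.cn):
        if k < a.shape[0]:
            return i, k
        k -= a.shape[0]
    return None  # pragma: no cover


def _chrom_arms(genome: GenomeSpec, chrom: int):
    return [a for a in genome.arms if a.chrom == chrom]


def divide(
    mother: CloneGenotype,
    probs: EventProbabilities,
    genome: GenomeSpec,
    rng,
    drivers=(),
    condition_on_event: bool = False,
):
    """Simulate one division: sample events and produce the two daughters.

    Events are applied in a fixed order (WGD, whole-chromosome missegregation,
    arm missegregation, focal amplification, focal deletion, driver mutation),
    each acting on the already-updated daughter pair.  Which daughter receives
    the WGD / gained homolog / amplified region is a fair coin flip.

    Returns ``(daughter_a, daughter_b, ops_a, ops_b)`` where the op lists
    deterministically transform the mother genotype into each daughter via
    :func:`replay_ops`.
    """
    counts = _sample_event_counts(mother, probs, rng, condition_on_event)
    d = (mother.copy(), mother.copy())
    ops: tuple = ([], [])

    def do(side: int, op: tuple):
        apply_op(d[side], op)
        ops[side].append(op)

    n_wgd, n_mis, n_arm, n_amp, n_del, n_drv = counts
    if n_wgd:
        do(int(rng.integers(2)), ("wgd",))
    for _ in range(n_mis):
        loser = int(rng.integers(2))
        pick = _pick_homolog(d[loser], rng)
        if pick is None:
            continue
        i, j = pick
        if j < d[1 - loser].cn[i].shape[0]:
            do(1 - loser, ("dup_homolog", i, j))
        do(loser, ("del_homolog", i, j))
    for _ in range(n_arm):
        loser = int(rng.integers(2))
        pick = _pick_homolog(d[loser], rng)
        if pick is None:
            continue
        i, j = pick
        arms = _chrom_arms(genome, i)
        if not arms:
            continue
        arm = arms[int(rng.integers(len(arms)))]
        if d[loser].cn[i][j, arm.bin_start : arm.bin_stop].sum() == 0:
            continue  # nothing to detach
        if j < d[1 - loser].cn[i].shape[0]:
            do(1 - loser, ("amp_region", i, j, arm.bin_start, arm.bin_stop))
        do(loser, ("del_region", i, j, arm.bin_start, arm.bin_stop))
    for kind, n_ev in (("amp", n_amp), ("del", n_del)):
        for _ in range(n_ev):
            side = int(rng.integers(2))
            g = d[side]
            i = int(rng.integers(genome.n_chroms))
            if g.cn[i].shape[0] == 0:
                continue
            j = int(rng.integers(g.cn[i].shape[0]))
            arms = _chrom_arms(genome, i)
            arm = arms[int(rng.integers(len(arms)))]
            start, stop = sample_focal_range(arm, probs.focal_lengths, rng, kind)
            opname = "amp_region" if kind == "amp" else "del_region"
            do(side, (opname, i, j, start, stop))
    for _ in range(n_drv):
        side = int(rng.integers(2))
        op = _sample_driver_op(d[side], drivers, rng)
        if op is not None:
            do(side, op)
    return d[0], d[1], ops[0], ops[1]


def sample_division_events(
    genotype: CloneGenotype,
    probs: EventProbabilities,
    rng,
    genome: GenomeSpec,
    drivers=(),
):
    """Sample the event list of one division (flat list of replayable ops).

    Convenience wrapper around :func:`divide`; returns the concatenated op
    lists of both daughters.
    """
    _, _, ops_a, ops_b = divide(genotype, probs, genome, rng, drivers)
    return ops_a + ops_b
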