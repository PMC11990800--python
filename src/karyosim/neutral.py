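"""Neutral variation overlay on the sampled-cell phylogeny.

After the tree is fixed, passenger SNVs and neutral CNAs (the same five
mechanisms, selection-blind) are superimposed along its branches without
altering clonal fitness.  Event counts per branch are Poisson with mean
``rate * expected divisions on the branch``; the default clock approximates
expected divisions as ``branch duration * turnover / 2`` (at homeostasis
about half of lifespan ends are divisions), with an exact mode replaying the
recorded per-clone division counts.  Descendant cells inherit events from
their ancestral branches; passenger SNVs receive copy-number-unit addresses
and are multiplied or lost by downstream CNAs exactly as driver SNVs are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import CloneHistory
from .events import FocalLengthModel, apply_op, sample_focal_range
from .genome import GenomeSpec
from .genotype import CloneGenotype
from .phylogeny import SampleTree

__all__ = ["NeutralRates", "overlay_neutral"]


@dataclass(frozen=True)
class NeutralRates:
    """Per-division rates of neutral (fitness-blind) variation.

    ``snv_rate`` is the expected passenger SNV count per division; the CNA
    rates are probabilities that the tracked daughter acquires the event in
    one division.
    """

    snv_rate: float = 0.0
    p_wgd: float = 0.0
    p_misseg: float = 0.0
    p_arm_misseg: float = 0.0
    p_focal_amp: float = 0.0
    p_focal_del: float = 0.0
    focal_lengths: FocalLengthModel = field(default_factory=FocalLengthModel)

    def __post_init__(self):
        for name in ("snv_rate", "p_wgd", "p_misseg", "p_arm_misseg",
                     "p_focal_amp", "p_focal_del"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _branch_divisions_exact(history, node, t_lo, t_hi) -> float:
    """Expected divisions on a branch from the recorded division counts."""
    rec = history.clones[node.clone]
    tau = float(history.times[1] - history.times[0])
    total = 0.0
    s_lo = max(0, int((t_lo - history.t0) / tau))
    s_hi = min(history.n_steps - 1, int((t_hi - history.t0) / tau))
    for s in range(s_lo, s_hi + 1):
        step_lo = history.times[s]
        step_hi = history.times[s + 1]
        overlap = max(0.0, min(t_hi, step_hi) - max(t_lo, step_lo))
        if overlap <= 0:
            continue
        n = rec.count_at(s + 1)
        if n > 0:
            total += (overlap / tau) * rec.divisions_in(s) / n
    return total


def _sample_neutral_ops(genotype, rates, genome, rng, b, counter):
    """Sample the neutral ops for one branch with ``b`` expected divisions."""
    ops = []
    g = genotype  # current state, used only to pick valid targets
    def poi(rate):
        return int(rng.poisson(rate * b)) if rate > 0 and b > 0 else 0

    for _ in range(poi(rates.p_wgd)):
        ops.append(("wgd",))
    for _ in range(poi(rates.p_misseg)):
        pick = _pick_homolog(g, rng)
        if pick is None:
            continue
        i, j = pick
        kind = "dup_homolog" if rng.random() < 0.5 else "del_homolog"
        ops.append((kind, i, j))
    for _ in range(poi(rates.p_arm_misseg)):
        pick = _pick_homolog(g, rng)
        if pick is None:
            continue
        i, j = pick
        arms = [a for a in genome.arms if a.chrom == i]
        if not arms:
            continue
        arm = arms[int(rng.integers(len(arms)))]
        kind = "amp_region" if rng.random() < 0.5 else "del_region"
        ops.append((kind, i, j, arm.bin_start, arm.bin_stop))
    for kind, rate in (("amp", rates.p_focal_amp), ("del", rates.p_focal_del)):
        for _ in range(poi(rate)):
            i = int(rng.integers(genome.n_chroms))
            if g.cn[i].shape[0] == 0:
                continue
            j = int(rng.integers(g.cn[i].shape[0]))
            arms = [a for a in genome.arms if a.chrom == i]
            arm = arms[int(rng.integers(len(arms)))]
            start, stop = sample_focal_range(arm, rates.focal_lengths, rng, kind)
            ops.append(("amp_region" if kind == "amp" else "del_region",
                        i, j, start, stop))
    n_snv = poi(rates.snv_rate)
    for _ in range(n_snv):
        addr = _pick_cn_unit(g, rng)
        if addr is None:
            continue
        i, j, b_, u = addr
        counter[0] += 1
        ops.append(("passenger_mut", f"p{counter[0]}", i, j, b_, u))
    return ops


def _pick_homolog(genotype, rng):
    total = genotype.total_homologs
    if total == 0:
        return None
    k = int(rng.integers(total))
    for i, a in enumerate(genotype.cn):
        if k < a.shape[0]:
            return i, k
        k -= a.shape[0]
    return None  # pragma: no cover


def _pick_cn_unit(genotype, rng):
    """Uniform copy-number unit across the genome (CN-weighted address)."""
    totals = [int(a.sum()) for a in genotype.cn]
    grand = sum(totals)
    if grand == 0:
        return None
    k = int(rng.integers(grand))
    for i, tot in enumerate(totals):
        if k >= tot:
            k -= tot
            continue
        a = genotype.cn[i]
        flat = a.ravel()
        cs = np.cumsum(flat)
        pos = int(np.searchsorted(cs, k, side="right"))
        j, b = divmod(pos, a.shape[1])
        u = int(k - (cs[pos - 1] if pos else 0))
        return i, j, b, u
    return None  # pragma: no cover


def overlay_neutral(
    tree: SampleTree,
    rates: NeutralRates,
    genome: GenomeSpec,
    rng,
    history: CloneHistory,
    turnover: float = 1.0,
    clock: str = "approx",
) -> dict:
    """Superimpose neutral variation on a sampled-cell tree.

    Returns ``{tip label: CloneGenotype}`` with the final per-cell profiles
    (clonal events plus inherited neutral events).  Branch neutral ops are
    stored on each node's ``neutral_ops``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if clock not in ("approx", "exact"):
        raise ValueError("clock must be 'approx' or 'exact'")
    counter = [0]
    root_g = history.clones[tree.root.clone].genotype.copy()
    profiles: dict = {}

    if tree.root.is_leaf:
        profiles[tree.root.label] = root_g
        return profiles
    stack = [(tree.root, root_g)]
    while stack:
        node, genotype = stack.pop()
        for child in node.children:
            g = genotype.copy()
            for op in child.edge_ops:
                apply_op(g, op)
            t_hi = tree.t_end if child.is_leaf else child.time
            if clock == "approx":
                b = max(0.0, (t_hi - node.time)) * turnover * 0.5
            else:
                b = _branch_divisions_exact(history, child, node.time, t_hi)
            child.neutral_ops = _sample_neutral_ops(g, rates, genome, rng, b, counter)
            for op in child.neutral_ops:
                apply_op(g, op)
            if child.is_leaf:
                profiles[child.label] = g
            else:
                stack.append((child, g))
    return profiles
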