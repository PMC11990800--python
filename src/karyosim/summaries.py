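"""Sample- and cohort-level summary statistics.

Per sample: pseudobulk copy-number profile of the sampled cells, per-arm
gain/loss calls against a baseline ploidy, fraction of genome altered (FGA),
WGD status, clone diversity (Shannon index), MRCA age, and clonal/subclonal
event counts.  Per cohort: per-arm gain/loss frequencies -- the summary the
arm-selection inference consumes -- plus WGD proportion and the WGD FGA
difference ``mean(FGA | WGD) - mean(FGA | non-WGD)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import CloneHistory
from .genome import GenomeSpec
from .genotype import round_half_up
from .phylogeny import SampleTree, clonal_ops, mrca_age

__all__ = [
    "SampleSummary",
    "pseudobulk_profile",
    "sample_pseudobulk",
    "call_gain_loss",
    "cohort_frequencies",
    "fga",
    "wgd_statistics",
    "shannon_index",
    "clonal_subclonal_events",
    "monosomy_fraction",
    "classify_arms",
    "summarize_sample",
]

_GAIN_OPS = {"dup_homolog", "amp_region"}
_LOSS_OPS = {"del_homolog", "del_region"}


def pseudobulk_profile(profiles, weights=None) -> np.ndarray:
    """Rounded per-bin mean of total CN over cells.

    ``profiles`` is a sequence of per-bin total-CN vectors (or objects with a
    ``total_cn_profile`` method); optional ``weights`` give cell multiplicity
    per profile.
    """
    rows = [
        p.total_cn_profile() if hasattr(p, "total_cn_profile") else np.asarray(p)
        for p in profiles
    ]
    if not rows:
        raise ValueError("no cell profiles")
    mat = np.vstack(rows).astype(float)
    mean = np.average(mat, axis=0, weights=weights)
    return np.floor(mean + 0.5).astype(np.int64)


def sample_pseudobulk(history: CloneHistory, sampled: dict):
    """Pseudobulk of a clone-count sample: ``(rounded profile, raw mean)``."""
    ids = sorted(sampled)
    weights = np.array([sampled[i] for i in ids], dtype=float)
    mat = np.vstack([history.clones[i].genotype.total_cn_profile() for i in ids])
    mean = np.average(mat.astype(float), axis=0, weights=weights)
    return np.floor(mean + 0.5).astype(np.int64), mean


def call_gain_loss(pseudobulk: np.ndarray, genome: GenomeSpec, baseline: int = 2) -> dict:
    """Per-arm gain/loss/neutral call from a pseudobulk profile."""
    offsets = genome.bin_offsets()
    calls = {}
    for arm in genome.arms:
        lo = offsets[arm.chrom] + arm.bin_start
        hi = offsets[arm.chrom] + arm.bin_stop
        cn = round_half_up(float(pseudobulk[lo:hi].mean()))
        calls[arm.label] = "gain" if cn > baseline else ("loss" if cn < baseline else "neutral")
    return calls


def cohort_frequencies(calls_per_sample) -> pd.DataFrame:
    """Per-arm gain/loss frequencies across samples.

    Returns a DataFrame with columns ``arm``, ``fr_gain``, ``fr_loss``.
    """
    calls_per_sample = list(calls_per_sample)
    if not calls_per_sample:
        raise ValueError("empty cohort")
    arms = list(calls_per_sample[0])
    n = len(calls_per_sample)
    rows = []
    for arm in arms:
        g = sum(1 for c in calls_per_sample if c[arm] == "gain")
        l = sum(1 for c in calls_per_sample if c[arm] == "loss")
        rows.append((arm, g / n, l / n))
    return pd.DataFrame(rows, columns=["arm", "fr_gain", "fr_loss"])


def fga(pseudobulk: np.ndarray, baseline: int) -> float:
    """Fraction of bins whose total CN differs from the baseline ploidy."""
    pseudobulk = np.asarray(pseudobulk)
    return float((pseudobulk != baseline).mean())


def wgd_statistics(wgd_flags, fga_values):
    """Cohort WGD proportion and FGA difference between WGD and non-WGD.

    Returns ``(wgd_proportion, fga_difference)``; the difference is NaN when
    either group is empty.
    """
    wgd_flags = np.asarray(list(wgd_flags), dtype=bool)
    fga_values = np.asarray(list(fga_values), dtype=float)
    if wgd_flags.size == 0:
        raise ValueError("empty cohort")
    prop = float(wgd_flags.mean())
    if wgd_flags.all() or not wgd_flags.any():
        return prop, float("nan")
    diff = float(fga_values[wgd_flags].mean() - fga_values[~wgd_flags].mean())
    return prop, diff


def shannon_index(frequencies) -> float:
    """Shannon diversity ``H = -sum p_i ln p_i`` over clone frequencies."""
    p = np.asarray(list(frequencies), dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def _classify_op(op):
    if op[0] in _GAIN_OPS:
        return "gain"
    if op[0] in _LOSS_OPS:
        return "loss"
    return None


def clonal_subclonal_events(tree: SampleTree, history: CloneHistory) -> dict:
    """Count gain/loss events by clonality.

    Clonal events lie on the lineage from the simulation start to the MRCA
    (the ancestry of the root's clone); subclonal events lie on branches
    below the MRCA.
    """
    counts = {(c, t): 0 for c in ("clonal", "subclonal") for t in ("gain", "loss")}
    for op in clonal_ops(history, tree.root.clone):
        t = _classify_op(op)
        if t:
            counts[("clonal", t)] += 1
    for op in tree.subclonal_ops():
        t = _classify_op(op)
        if t:
            counts[("subclonal", t)] += 1
    return counts


def monosomy_fraction(pseudobulk: np.ndarray) -> float:
    """Fraction of bins with total CN exactly 1."""
    pseudobulk = np.asarray(pseudobulk)
    return float((pseudobulk == 1).mean())


def classify_arms(
    posterior_means: dict,
    frequencies: pd.DataFrame,
    freq_threshold: float = 0.1,
    use_abs: bool = True,
) -> dict:
    """GAIN/LOSS arm classification from posterior mean selection rates.

    Arms are considered only if their cohort gain/loss frequency difference
    passes the filter (``|fr_gain - fr_loss| >= freq_threshold`` by default;
    ``use_abs=False`` applies the raw signed difference).  GAIN arms have
    mean posterior rate > 1, LOSS arms < 1.
    """
    freq = frequencies.set_index("arm")
    gain_arms, loss_arms = [], []
    for arm, mean_rate in posterior_means.items():
        if arm not in freq.index:
            continue
        d = float(freq.loc[arm, "fr_gain"] - freq.loc[arm, "fr_loss"])
        passed = abs(d) >= freq_threshold if use_abs else d >= freq_threshold
        if not passed:
            continue
        if mean_rate > 1:
            gain_arms.append(arm)
        elif mean_rate < 1:
            loss_arms.append(arm)
    report = {
        "gain_arms": sorted(gain_arms),
        "loss_arms": sorted(loss_arms),
        "n_gain": len(gain_arms),
        "n_loss": len(loss_arms),
        "mean_gain_rate": (
            float(np.mean([posterior_means[a] for a in gain_arms])) if gain_arms else float("nan")
        ),
        "mean_inverse_loss_rate": (
            float(np.mean([1.0 / posterior_means[a] for a in loss_arms])) if loss_arms else float("nan")
        ),
    }
    return report


@dataclass
class SampleSummary:
    """Summary statistics of one simulated sample."""

    n_cells: int
    pseudobulk: np.ndarray
    mean_ploidy: float
    ploidy: int
    wgd_fraction: float
    is_wgd: bool
    fga: float
    arm_calls: dict
    clone_count: int
    shannon: float
    monosomy_fraction: float
    mrca_age: float | None = None
    event_counts: dict = field(default_factory=dict)


def summarize_sample(
    history: CloneHistory,
    sampled: dict,
    genome: GenomeSpec,
    tree: SampleTree | None = None,
    gain_loss_baseline: int = 2,
) -> SampleSummary:
    """Compute the per-sample summary from a clone-count sample.

    FGA is measured against the rounded sample mean ploidy, so a freshly
    genome-doubled sample has FGA 0 and accumulates FGA through post-WGD
    instability.  A sample is WGD if the majority of its sampled cells carry
    at least one whole-genome duplication.
    """
    n = sum(sampled.values())
    pb, raw = sample_pseudobulk(history, sampled)
    mean_ploidy = float(raw.mean())
    ploidy = round_half_up(mean_ploidy)
    wgd_cells = sum(
        k for cid, k in sampled.items() if history.clones[cid].genotype.wgd_count >= 1
    )
    wgd_fraction = wgd_cells / n
    summary = SampleSummary(
        n_cells=n,
        pseudobulk=pb,
        mean_ploidy=mean_ploidy,
        ploidy=ploidy,
        wgd_fraction=wgd_fraction,
        is_wgd=wgd_fraction > 0.5,
        fga=fga(pb, ploidy),
        arm_calls=call_gain_loss(pb, genome, baseline=gain_loss_baseline),
        clone_count=len(sampled),
        shannon=shannon_index(sampled.values()),
        monosomy_fraction=monosomy_fraction(pb),
    )
    if tree is not None:
        summary.mrca_age = mrca_age(tree)
        summary.event_counts = clonal_subclonal_events(tree, history)
    return summary
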