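"""Parameter-study grids over the arm-selection model.

Four knobs, each with three settings, mirroring the model's qualitative
behaviour: stronger selection for GAIN arms sweeps gains to fixation
(raising sample ploidy, lowering diversity); higher missegregation
probability adds subclonal variation (raising the Shannon index and event
counts while the clonal:subclonal ratio stays roughly constant); larger
carrying capacity and faster growth both relax competition and retain more
subclones.

The study design is fixed: 4-chromosome toy genome, tumors grown from a
single diploid cell, 50 cells sampled per tumor.  Sizes were chosen so a
full sweep (3 settings x 100 replicates) runs in tens of seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import DynamicsConfig, PopulationSchedule, simulate_clonal_evolution
from .events import EventProbabilities
from .genome import toy_genome
from .phylogeny import build_sample_phylogeny, clonal_ops, sample_cells
from .selection import SelectionModel
from .summaries import summarize_sample

__all__ = ["run_sweep", "SWEEP_SETTINGS"]

_GAIN_LOSS_OPS = {"dup_homolog", "del_homolog", "amp_region", "del_region"}

SWEEP_SETTINGS = {
    "selection": [1.0, 1.3, 1.6],  # lambda of GAIN (p) arms
    "misseg": [0.002, 0.005, 0.01],  # whole-chromosome missegregation prob
    "capacity": [100, 200, 400],  # carrying capacity
    "growth": [1, 5, 10],  # growth mode index
}


def _design(knob: str, setting, genome):
    p_arms = [a.label for a in genome.arms if a.label.endswith("p")]
    q_arms = [a.label for a in genome.arms if a.label.endswith("q")]
    rates: dict = {}
    p_mis, p_arm = 0.002, 0.01
    t_end, tau, capacity = 25.0, 0.25, 150
    schedule = None
    if knob == "selection":
        rates = {a: float(setting) for a in p_arms}
    elif knob == "misseg":
        # selection on both arm classes so sweeps carry events to fixation
        rates = {a: 1.3 for a in p_arms} | {a: 0.77 for a in q_arms}
        p_mis, p_arm = float(setting), 0.012
        t_end, tau = 50.0, 0.3
    elif knob == "capacity":
        capacity = int(setting)
    elif knob == "growth":
        schedule = PopulationSchedule.growth_mode(int(setting), 150, t_end)
    else:
        raise ValueError(f"unknown sweep knob {knob!r}")
    if schedule is None:
        schedule = PopulationSchedule.constant(capacity)
    cfg = DynamicsConfig(t_end=t_end, tau=tau, initial_count=1)
    sel = SelectionModel(rates=rates)
    probs = EventProbabilities(p_misseg=p_mis, p_arm_misseg=p_arm)
    return cfg, sel, probs, schedule


def _one_replicate(cfg, sel, probs, schedule, genome, rng, n_sample=50, max_tries=5):
    for _ in range(max_tries):
        history = simulate_clonal_evolution(cfg, probs, sel, schedule, rng, genome)
        if history.status == "ok" and history.pop_size[-1] >= n_sample:
            break
    else:
        return None
    sampled = sample_cells(history, n_sample, rng)
    tree = build_sample_phylogeny(history, sampled, rng)
    summary = summarize_sample(history, sampled, genome, tree)
    clonal = sum(
        1 for op in clonal_ops(history, tree.root.clone) if op[0] in _GAIN_LOSS_OPS
    )
    subclonal = sum(1 for op in tree.subclonal_ops() if op[0] in _GAIN_LOSS_OPS)
    return {
        "shannon": summary.shannon,
        "mean_ploidy": summary.mean_ploidy,
        "clone_count": summary.clone_count,
        "mrca_age": summary.mrca_age,
        "clonal_events": clonal,
        "subclonal_events": subclonal,
        "total_events": clonal + subclonal,
    }


def run_sweep(knob: str, replicates: int, seed: int, genome=None) -> pd.DataFrame:
    """Run one knob's 3-setting sweep; returns one row per replicate."""
    genome = genome or toy_genome()
    rows = []
    for setting in SWEEP_SETTINGS[knob]:
        knob_id = sorted(SWEEP_SETTINGS).index(knob)
        rng = np.random.default_rng([seed, knob_id, int(setting * 1000)])
        for rep in range(replicates):
            stats = _one_replicate(*_design(knob, setting, genome), genome, rng)
            if stats is None:
                continue
            rows.append({"knob": knob, "setting": setting, "replicate": rep, **stats})
    return pd.DataFrame(rows)
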