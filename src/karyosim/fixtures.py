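"""Synthetic study designs: cohort simulators and observed-data stand-ins.

Everything here is simulation-generated; no external data is required.  The
default cohort models run at a desk scale chosen so that selection leaves a
clear footprint in cohort frequencies within seconds of compute: a small
4-chromosome genome, a tumor founded by a single diploid cell growing into a
carrying capacity of a few hundred cells over ~25 cell generations, with
per-homolog missegregation probabilities scaled up in proportion to the
reduction in cell count and time (so the expected number of events per
tumor is comparable to a full-scale run).  All values are overridable.

``make_synthetic_cohort`` simulates a cohort under known ("true") parameters
and writes exactly the observed-summary tables the inference consumes,
together with a truth manifest for recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DynamicsConfig, PopulationSchedule, simulate_clonal_evolution
from .events import EventProbabilities, FocalLengthModel
from .genome import GenomeSpec, toy_genome
from .genotype import round_half_up
from .phylogeny import sample_cells
from .selection import DriverGene, SelectionModel, ViabilityConfig
from .summaries import (
    call_gain_loss,
    cohort_frequencies,
    fga,
    sample_pseudobulk,
    wgd_statistics,
)

__all__ = [
    "CohortModel",
    "default_arm_model",
    "default_wgd_model",
    "default_driver_model",
    "make_synthetic_cohort",
]


@dataclass
class CohortModel:
    """A cohort-level simulation design: one call = one simulated sample.

    The model owns everything the inference must hold fixed (genome,
    population dynamics, fixed event probabilities, sample and cohort
    sizes); the inferred parameters are supplied per call.
    """

    genome: GenomeSpec
    dynamics: DynamicsConfig
    schedule: PopulationSchedule
    n_sample: int = 50
    cohort_size: int = 10
    p_misseg: float = 0.002
    p_driver_mut: float = 0.0
    p_focal_amp: float = 0.0
    focal_lengths: FocalLengthModel = field(default_factory=FocalLengthModel)
    viability: ViabilityConfig = field(default_factory=ViabilityConfig)
    drivers: tuple = ()
    selection_kind: str = "arm"
    max_tries: int = 5

    # -- single samples ---------------------------------------------------
    def _events(self, p_arm_misseg=0.0, p_wgd=0.0, alpha=1.0, p_focal_del=0.0):
        return EventProbabilities(
            p_wgd=p_wgd,
            p_misseg=self.p_misseg,
            p_arm_misseg=p_arm_misseg,
            p_focal_amp=self.p_focal_amp,
            p_focal_del=p_focal_del,
            p_driver_mut=self.p_driver_mut,
            alpha=alpha,
            focal_lengths=self.focal_lengths,
        )

    def _selection(self, rates=None, lam_overrides=None):
        drivers = self.drivers
        if lam_overrides:
            drivers = tuple(replace(d, rate=lam_overrides.get(d.name, d.rate))
                            for d in drivers)
        return SelectionModel(
            model=self.selection_kind,
            rates=dict(rates or {}),
            drivers=drivers,
            viability=self.viability,
        )

    def simulate_sample(self, probs, sel, rng, record_history=False):
        """One simulated tumor with at least ``n_sample`` surviving cells.

        Extinct or undersized runs are redrawn (fresh randomness) up to
        ``max_tries`` times; persistent failure raises.
        """
        for _ in range(self.max_tries):
            history = simulate_clonal_evolution(
                self.dynamics, probs, sel, self.schedule, rng, self.genome,
                record_history=record_history,
            )
            if history.status == "ok" and history.pop_size[-1] >= self.n_sample:
                sampled = sample_cells(history, self.n_sample, rng)
                return history, sampled
        raise RuntimeError("simulated population repeatedly went extinct")

    # -- cohort summaries -------------------------------------------------
    def cohort_arm_frequencies(self, rates, p_arm_misseg, rng) -> pd.DataFrame:
        """Per-arm gain/loss frequencies of one simulated cohort."""
        sel = self._selection(rates=rates)
        probs = self._events(p_arm_misseg=p_arm_misseg)
        calls = []
        for _ in range(self.cohort_size):
            history, sampled = self.simulate_sample(probs, sel, rng)
            pb, _ = sample_pseudobulk(history, sampled)
            calls.append(call_gain_loss(pb, self.genome))
        return cohort_frequencies(calls)

    def cohort_wgd_stats(self, rates, p_wgd, alpha, rng, p_arm_misseg=0.004):
        """``[wgd_proportion, wgd_fga_difference]`` of one simulated cohort.

        A sample is WGD when the majority of its sampled cells carry at
        least one genome doubling.  FGA is computed on the pseudobulk of the
        majority WGD-status component (mirroring bulk pipelines, which call
        copy number on the dominant clone) against that component's rounded
        mean ploidy.  The FGA difference is 0 when either group is empty.
        """
        sel = self._selection(rates=rates)
        probs = self._events(p_arm_misseg=p_arm_misseg, p_wgd=p_wgd, alpha=alpha)
        flags, fgas = [], []
        for _ in range(self.cohort_size):
            history, sampled = self.simulate_sample(probs, sel, rng)
            n = sum(sampled.values())
            wgd_cells = sum(
                k for cid, k in sampled.items()
                if history.clones[cid].genotype.wgd_count >= 1
            )
            is_wgd = wgd_cells / n > 0.5
            majority = {
                cid: k for cid, k in sampled.items()
                if (history.clones[cid].genotype.wgd_count >= 1) == is_wgd
            }
            pb, raw = sample_pseudobulk(history, majority)
            ploidy = round_half_up(float(raw.mean()))
            flags.append(is_wgd)
            fgas.append(fga(pb, max(ploidy, 1)))
        prop, diff = wgd_statistics(flags, fgas)
        if not np.isfinite(diff):
            diff = 0.0
        return np.array([prop, diff])

    def cohort_gene_frequencies(self, lam, p_focal_del, rng) -> pd.DataFrame:
        """Per-gene mutation/gain/loss frequencies of one simulated cohort.

        A sample carries a gene mutation if more than half of its sampled
        cells hold at least one mutant copy; gains/losses are pseudobulk CN
        calls at the gene's bin against the diploid baseline.
        """
        sel = self._selection(lam_overrides=lam)
        probs = self._events(p_focal_del=p_focal_del)
        offsets = self.genome.bin_offsets()
        rows = {d.name: [0, 0, 0] for d in self.drivers}  # mut, gain, loss
        for _ in range(self.cohort_size):
            history, sampled = self.simulate_sample(probs, sel, rng)
            pb, _ = sample_pseudobulk(history, sampled)
            n = sum(sampled.values())
            for d in self.drivers:
                mut_cells = sum(
                    k for cid, k in sampled.items()
                    if history.clones[cid].genotype.mutant_copies(d.name) >= 1
                )
                if mut_cells / n > 0.5:
                    rows[d.name][0] += 1
                cn = int(pb[offsets[d.chrom] + d.bin])
                if cn > 2:
                    rows[d.name][1] += 1
                elif cn < 2:
                    rows[d.name][2] += 1
        data = [
            (g, m / self.cohort_size, ga / self.cohort_size, lo / self.cohort_size)
            for g, (m, ga, lo) in rows.items()
        ]
        return pd.DataFrame(data, columns=["gene", "fr_mut", "fr_gain", "fr_loss"])


def default_arm_model(**overrides) -> CohortModel:
    """Desk-scale cohort design for arm-selection inference.

    The 20-sample cohort reflects a typical per-cancer-type cohort (the
    guard refuses cohorts below 10); per-arm frequency noise at 20 samples
    is what lets clustered selection rates remain rank-identifiable.
    """
    kw = dict(
        genome=toy_genome(),
        dynamics=DynamicsConfig(t_end=25.0, tau=0.25, initial_count=1),
        schedule=PopulationSchedule.constant(150),
        n_sample=50,
        cohort_size=20,
        p_misseg=0.002,
    )
    kw.update(overrides)
    return CohortModel(**kw)


def default_wgd_model(**overrides) -> CohortModel:
    """Desk-scale cohort design for WGD-parameter inference."""
    kw = dict(
        genome=toy_genome(),
        dynamics=DynamicsConfig(t_end=25.0, tau=0.25, initial_count=1),
        schedule=PopulationSchedule.constant(150),
        n_sample=50,
        cohort_size=10,
        p_misseg=0.002,
    )
    kw.update(overrides)
    return CohortModel(**kw)


def default_driver_genes(genome: GenomeSpec | None = None):
    """Five-gene driver library on the toy genome (mixed TSGs and OGs)."""
    return (
        DriverGene("TSG1", "TSG", 1.35, 0, 5),
        DriverGene("OG1", "OG", 1.10, 1, 10),
        DriverGene("TSG2", "TSG", 1.25, 2, 18),
        DriverGene("OG2", "OG", 1.05, 0, 35),
        DriverGene("TSG3", "TSG", 1.18, 3, 12),
    )


def default_driver_model(**overrides) -> CohortModel:
    """Desk-scale cohort design for driver-gene inference.

    Emulates a chromosomally quiet cohort: no missegregation, small focal
    rates, driver mutations at a fixed per-division probability.
    """
    kw = dict(
        genome=toy_genome(),
        dynamics=DynamicsConfig(t_end=25.0, tau=0.25, initial_count=1),
        schedule=PopulationSchedule.constant(150),
        n_sample=50,
        cohort_size=10,
        p_misseg=0.0,
        p_driver_mut=0.02,
        p_focal_amp=0.002,
        drivers=default_driver_genes(),
        selection_kind="driver",
    )
    kw.update(overrides)
    return CohortModel(**kw)


def make_synthetic_cohort(
    kind: str,
    truth: dict,
    rng,
    out_dir=None,
    model: CohortModel | None = None,
):
    """Simulate an "observed" cohort under known parameters.

    ``kind`` is one of ``"arms"``, ``"wgd"``, ``"drivers"``.  Returns
    ``(observed, truth)`` where ``observed`` is the summary table (or stats
    array) the corresponding inference consumes; when ``out_dir`` is given
    the summaries and a truth manifest are also written as TSV/JSON.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if kind == "arms":
        model = model or default_arm_model()
        observed = model.cohort_arm_frequencies(
            truth.get("rates", {}), truth["p_arm_misseg"], rng
        )
    elif kind == "wgd":
        model = model or default_wgd_model()
        observed = model.cohort_wgd_stats(
            truth.get("rates", {}), truth["p_wgd"], truth["alpha"], rng
        )
    elif kind == "drivers":
        model = model or default_driver_model()
        observed = model.cohort_gene_frequencies(
            truth.get("lam", {}), truth["p_focal_del"], rng
        )
    else:
        raise ValueError(f"unknown cohort kind {kind!r}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_arm_frequencies

        if kind == "arms":
            write_arm_frequencies(observed, out_dir / "arm_frequencies.tsv")
        elif kind == "wgd":
            pd.DataFrame(
                {"statistic": ["wgd_proportion", "wgd_fga_difference"],
                 "value": list(observed)}
            ).to_csv(out_dir / "wgd_stats.tsv", sep="\t", index=False)
        else:
            observed.to_csv(out_dir / "gene_frequencies.tsv", sep="\t", index=False)
        manifest = {k: v for k, v in truth.items()}
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    return observed, truth
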