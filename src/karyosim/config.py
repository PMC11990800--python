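"""Run configuration: YAML schema, named profiles, seeding.

A run configuration bundles the genome, selection model, event
probabilities, population dynamics, sampling and neutral-overlay settings.
Two named profiles ship with the package:

* ``paper`` -- published-scale settings: 24-chromosome human genome with
  500-kb bins, whole-chromosome missegregation probability 5e-5 per homolog
  per division, arm-missegregation prior U(1e-5, 1e-4), WGD priors
  alpha ~ U(0, 300) and log10 p_wgd ~ U(-6.5, -3.5), 1,000 sampled cells and
  10,000 reference simulations;
* ``test`` -- the desk-scale study design used throughout the test suite:
  4-chromosome toy genome, a tumor grown from one cell to a carrying
  capacity of 150 over 25 generations, event probabilities scaled up in
  proportion, 50 sampled cells, 2,000 reference simulations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import DynamicsConfig, PopulationSchedule
from .events import EventProbabilities, FocalLengthModel
from .genome import GenomeSpec, build_genome, human_genome, toy_genome
from .neutral import NeutralRates
from .selection import SelectionModel, ViabilityConfig

__all__ = ["RunConfig", "load_config", "profile"]


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    genome: GenomeSpec
    selection: SelectionModel
    events: EventProbabilities
    dynamics: DynamicsConfig
    schedule: PopulationSchedule
    neutral: NeutralRates = field(default_factory=NeutralRates)
    n_sample: int = 50
    n_reference_sims: int = 2000
    seed: int = 0

    def describe(self) -> dict:
        """JSON-serialisable echo of the resolved configuration."""
        return {
            "genome": {
                "chroms": list(self.genome.chrom_names),
                "bin_size": self.genome.bin_size,
                "total_bins": self.genome.total_bins,
            },
            "selection": {
                "model": self.selection.model,
                "rates": dict(self.selection.rates),
                "drivers": [d.name for d in self.selection.drivers],
            },
            "events": {
                f.name: getattr(self.events, f.name)
                for f in dataclasses.fields(EventProbabilities)
                if f.name != "focal_lengths"
            },
            "dynamics": {
                "t0": self.dynamics.t0, "t_end": self.dynamics.t_end,
                "tau": self.dynamics.step, "turnover": self.dynamics.turnover,
                "initial_count": self.dynamics.initial_count,
            },
            "schedule": {
                "kind": self.schedule.kind, "final_size": self.schedule.final_size,
                "rate": self.schedule.rate,
            },
            "n_sample": self.n_sample,
            "seed": self.seed,
        }


def _genome_from_dict(d: dict) -> GenomeSpec:
    preset = d.get("preset")
    if preset == "toy":
        return toy_genome(d.get("n_chroms", 4))
    if preset == "human":
        return human_genome(d.get("bin_size", 500_000))
    return build_genome(
        d["chrom_lengths"], d["centromere_positions"], d["bin_size"],
        chrom_names=d.get("chrom_names"),
    )


def _schedule_from_dict(d: dict, t_end: float) -> PopulationSchedule:
    kind = d.get("kind", "constant")
    if kind == "constant":
        return PopulationSchedule.constant(d["size"])
    if kind == "exponential":
        return PopulationSchedule.exponential(d["final_size"], d["rate"], t_end)
    if kind == "growth_mode":
        return PopulationSchedule.growth_mode(
            d["mode"], d["size"], t_end, d.get("max_rate", 0.12)
        )
    raise ValueError(f"unknown schedule kind {kind!r}")


def config_from_dict(d: dict) -> RunConfig:
    try:
        genome = _genome_from_dict(d.get("genome", {"preset": "toy"}))
        dyn = d.get("dynamics", {})
        dynamics = DynamicsConfig(
            t_end=float(dyn.get("t_end", 25.0)),
            t0=float(dyn.get("t0", 0.0)),
            turnover=float(dyn.get("turnover", 1.0)),
            tau=dyn.get("tau", 0.25),
            initial_count=dyn.get("initial_count", 1),
        )
        schedule = _schedule_from_dict(
            d.get("schedule", {"kind": "constant", "size": 150}), dynamics.t_end
        )
        ev = d.get("events", {})
        fl = ev.get("focal_lengths", {})
        events = EventProbabilities(
            p_wgd=float(ev.get("p_wgd", 0.0)),
            p_misseg=float(ev.get("p_misseg", 0.0)),
            p_arm_misseg=float(ev.get("p_arm_misseg", 0.0)),
            p_focal_amp=float(ev.get("p_focal_amp", 0.0)),
            p_focal_del=float(ev.get("p_focal_del", 0.0)),
            p_driver_mut=float(ev.get("p_driver_mut", 0.0)),
            alpha=float(ev.get("alpha", 1.0)),
            focal_lengths=FocalLengthModel(
                a_amp=float(fl.get("a_amp", 2.0)), b_amp=float(fl.get("b_amp", 5.0)),
                a_del=float(fl.get("a_del", 2.0)), b_del=float(fl.get("b_del", 5.0)),
            ),
        )
        sel = d.get("selection", {})
        via = sel.get("viability", {})
        drivers = ()
        if sel.get("drivers"):
            from .selection import DriverGene

            name_to_idx = {n: i for i, n in enumerate(genome.chrom_names)}
            drivers = tuple(
                DriverGene(g["gene"], g["role"], float(g["lambda"]),
                           name_to_idx[str(g["chrom"])], int(g["bin"]))
                for g in sel["drivers"]
            )
        selection = SelectionModel(
            model=sel.get("model", "arm"),
            rates=sel.get("rates", {}),
            drivers=drivers,
            viability=ViabilityConfig(**via),
        )
        neu = d.get("neutral", {})
        neutral = NeutralRates(
            snv_rate=float(neu.get("snv_rate", 0.0)),
            p_wgd=float(neu.get("p_wgd", 0.0)),
            p_misseg=float(neu.get("p_misseg", 0.0)),
            p_arm_misseg=float(neu.get("p_arm_misseg", 0.0)),
            p_focal_amp=float(neu.get("p_focal_amp", 0.0)),
            p_focal_del=float(neu.get("p_focal_del", 0.0)),
        )
        return RunConfig(
            genome=genome, selection=selection, events=events,
            dynamics=dynamics, schedule=schedule, neutral=neutral,
            n_sample=int(d.get("n_sample", 50)),
            n_reference_sims=int(d.get("n_reference_sims", 2000)),
            seed=int(d.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def profile(name: str, **overrides) -> RunConfig:
    """Named configuration profiles: ``paper`` or ``test``."""
    if name == "paper":
        d = {
            "genome": {"preset": "human", "bin_size": 500_000},
            "dynamics": {"t_end": 80.0, "tau": 0.01, "initial_count": 1},
            "schedule": {"kind": "constant", "size": 10_000},
            "events": {"p_misseg": 5e-5, "p_arm_misseg": 5e-5},
            "n_sample": 1000,
            "n_reference_sims": 10_000,
        }
    elif name == "test":
        d = {
            "genome": {"preset": "toy"},
            "dynamics": {"t_end": 25.0, "tau": 0.25, "initial_count": 1},
            "schedule": {"kind": "constant", "size": 150},
            "events": {"p_misseg": 0.002, "p_arm_misseg": 0.01},
            "n_sample": 50,
            "n_reference_sims": 2000,
        }
    else:
        raise ValueError(f"unknown profile {name!r}")
    d.update(overrides)
    return config_from_dict(d)
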