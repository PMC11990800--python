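"""Clone-level birth-death dynamics with carrying-capacity feedback.

The population is a collection of clones (cells sharing one genotype).  Each
cell's lifespan is exponential with turnover rate ``lam``; at the end of its
lifespan it divides with probability ``p_div = g(t) * f(s_k)`` and dies
otherwise, where ``g(t) = Pbar(t) / (Pbar(t) + P(t))`` is a negative feedback
keeping the population near the expected size ``Pbar(t)`` and
``f(s_k) = s_k * P(t) / sum_cells s`` rewards fitter cells.

Evolution is advanced with tau-leaping: per step and clone, binomial draws
give the number of cells ending their lifespan, the number dividing and the
number of divisions that carry CNA / driver-mutation events; event-carrying
divisions found new clones.  The recorded per-step, per-clone cell counts and
division counts are the sufficient statistics for the backward-time sampled
phylogeny.  An exact event-by-event (Gillespie) counterpart is provided as a
validation oracle for small populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import EventProbabilities, divide, event_probability
from .genome import GenomeSpec
from .genotype import CloneGenotype, diploid_genotype
from .selection import SelectionModel, clone_fitness

__all__ = [
    "PopulationSchedule",
    "DynamicsConfig",
    "CloneRecord",
    "CloneHistory",
    "division_probability",
    "simulate_clonal_evolution",
    "exact_reference_simulation",
]


@dataclass(frozen=True)
class PopulationSchedule:
    """Expected population size ``Pbar(t)`` as a function of time."""

    kind: str
    final_size: float
    rate: float = 0.0
    t_end: float = 0.0
    floor: float = 10.0

    def __call__(self, t: float) -> float:
        if self.kind == "constant":
            return self.final_size
        if self.kind == "exponential":
            # grows toward final_size reached at t_end
            return max(self.floor, self.final_size * math.exp(-self.rate * (self.t_end - t)))
        if self.kind == "logistic":
            p0 = max(self.floor, self.final_size * math.exp(-self.rate * self.t_end))
            k = self.final_size
            return k * p0 / (p0 + (k - p0) * math.exp(-self.rate * t))
        raise ValueError(f"unknown schedule kind {self.kind!r}")

    @staticmethod
    def constant(size: float) -> "PopulationSchedule":
        return PopulationSchedule("constant", float(size))

    @staticmethod
    def exponential(final_size: float, rate: float, t_end: float, floor: float = 10.0):
        return PopulationSchedule("exponential", float(final_size), rate, t_end, floor)

    @staticmethod
    def growth_mode(
        mode: int, base_size: float, t_end: float, max_rate: float = 0.12
    ) -> "PopulationSchedule":
        """Growth patterns indexed 1..10: constant (1) to fast exponential (10).

        All modes start from the same expected size ``base_size``; mode
        ``m > 1`` grows exponentially at rate ``max_rate * (m-1)/9``, so
        faster modes reach larger final sizes.  In growing tumors the
        carrying-capacity feedback is weaker and low-fitness subclones
        survive, raising clone counts and diversity.
        """
        if not 1 <= mode <= 10:
            raise ValueError("growth mode must be in 1..10")
        if mode == 1:
            return PopulationSchedule.constant(base_size)
        rate = max_rate * (mode - 1) / 9.0
        final = base_size * math.exp(rate * t_end)
        return PopulationSchedule.exponential(final, rate, t_end)


@dataclass(frozen=True)
class DynamicsConfig:
    """Timing and turnover of the birth-death process.

    Time is measured in expected cell lifespans (``turnover = 1`` by default);
    ``tau`` defaults to ``0.01 / turnover``.
    """

    t_end: float
    t0: float = 0.0
    turnover: float = 1.0
    tau: float | None = None
    initial_count: int | None = None  # default: Pbar(t0), at least 1

    def __post_init__(self):
        if self.turnover <= 0:
            raise ValueError("turnover must be > 0")
        if self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be > 0")

    @property
    def step(self) -> float:
        return self.tau if self.tau is not None else 0.01 / self.turnover


class CloneRecord:
    """Trajectory of one clone: genotype, ancestry and per-step counts."""

    __slots__ = (
        "id", "parent", "birth_step", "birth_time", "genotype", "fitness",
        "ops", "n_founded", "sibling", "first_index", "counts",
        "divisions", "deaths", "stats",
    )

    def __init__(self, id, parent, birth_step, birth_time, genotype, fitness,
                 ops=(), n_founded=1, sibling=None):
        self.id = id
        self.parent = parent  # parent clone id, None for initial clones
        self.birth_step = birth_step  # step during which founded (-1 initial)
        self.birth_time = birth_time
        self.genotype = genotype
        self.fitness = fitness
        self.ops = list(ops)  # replayable ops transforming parent genotype
        self.n_founded = n_founded
        self.sibling = sibling  # other-daughter clone id if both spawned
        self.first_index = birth_step + 1  # first grid index with a count
        # lists aligned to grid points first_index, first_index+1, ...;
        # divisions[k]/deaths[k] happened in the interval ending at that point
        self.counts: list = []
        self.divisions: list = []
        self.deaths: list = []
        self.stats = None  # lazy fitness bookkeeping (arm model fast path)

    def count_at(self, grid_index: int) -> int:
        k = grid_index - self.first_index
        if k < 0 or k >= len(self.counts):
            return 0
        return self.counts[k]

    def divisions_in(self, step: int) -> int:
        """Within-clone divisions during step interval (grid step, step+1)."""
        k = step + 1 - self.first_index
        if k < 0 or k >= len(self.divisions):
            return 0
        return self.divisions[k]

    def deaths_in(self, step: int) -> int:
        k = step + 1 - self.first_index
        if k < 0 or k >= len(self.deaths):
            return 0
        return self.deaths[k]


@dataclass
class CloneHistory:
    """Full record of a clonal-evolution run on a fixed time grid."""

    genome: GenomeSpec
    times: np.ndarray  # grid points t0 .. t_end, length n_steps + 1
    clones: list  # CloneRecord, id == index
    pop_size: np.ndarray  # population at each grid point
    status: str = "ok"  # "ok" or "extinct"
    config: DynamicsConfig | None = None

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def final_counts(self) -> dict:
        """clone id -> cell count at the final grid point (> 0 only)."""
        last = self.n_steps
        out = {}
        for c in self.clones:
            n = c.count_at(last)
            if n > 0:
                out[c.id] = n
        return out

    def children_by_step(self) -> dict:
        """step index -> list of clone ids founded during that step."""
        out: dict = {}
        for c in self.clones:
            if c.parent is not None:
                out.setdefault(c.birth_step, []).append(c.id)
        return out


def division_probability(s_k: float, total_fitness: float, P: float, Pbar: float) -> float:
    """``p_div = min(1, g * f)`` with ``g = Pbar/(Pbar+P)``, ``f = s_k*P/sum s``."""
    if P <= 0:
        raise ValueError("population is extinct")
    if total_fitness <= 0:
        return 0.0
    g = Pbar / (Pbar + P)
    f = s_k * P / total_fitness
    return min(1.0, g * f)


class _FitnessContext:
    """Incremental fitness evaluation for spawned clones (arm model).

    Per clone it caches the genome-wide total-CN profile, per-chromosome
    maximum bin CN, per-arm CN sums, total CN and nullisomic-bin count.  A
    daughter differing from its mother by one replayable op updates these in
    O(affected bins) instead of recomputing over the genome.  All updates
    are integer-exact, so the resulting fitness is bit-identical to
    :func:`~karyosim.selection.clone_fitness`; anything the delta path does
    not cover (multi-op daughters, WGD, driver/hybrid selection, finite
    driver limits) falls back to the full computation.
    """

    def __init__(self, sel, genome):
        from .selection import _arm_geometry, _log_rates

        self.sel = sel
        self.genome = genome
        self.enabled = sel.model == "arm" and sel.viability.driver_max == math.inf
        if not self.enabled:
            return
        _, self.arm_starts, self.arm_lengths = _arm_geometry(genome)
        self.loglam = _log_rates(sel, genome)
        self.offsets = genome.bin_offsets()
        self.null_budget = sel.viability.nullisomy_budget(genome)
        self.m_bins = genome.total_bins
        # arm index lookup by (chrom, containing bin)
        self.arms_by_chrom = {}
        for k, arm in enumerate(genome.arms):
            self.arms_by_chrom.setdefault(arm.chrom, []).append((k, arm))

    def stats_for(self, rec):
        if rec.stats is None:
            g = rec.genotype
            profile = g.total_cn_profile().astype(np.int64)
            chrom_max = np.array(
                [int(a.max()) if a.size else 0 for a in g.cn], dtype=np.int64
            )
            arm_sums = np.add.reduceat(profile, self.arm_starts).astype(float)
            rec.stats = [profile, chrom_max, arm_sums, int(profile.sum()),
                         int((profile == 0).sum())]
        return rec.stats

    def _arm_of(self, chrom, start):
        for k, arm in self.arms_by_chrom.get(chrom, ()):
            if arm.bin_start <= start < arm.bin_stop:
                return k
        return None

    def fitness(self, mother_rec, daughter, ops):
        """Fitness of a daughter; returns (fitness, stats-or-None)."""
        if not self.enabled or len(ops) != 1 or daughter.wgd_count != mother_rec.genotype.wgd_count:
            return clone_fitness(daughter, self.sel, self.genome), None
        op = ops[0]
        kind = op[0]
        if kind in ("driver_mut", "passenger_mut", "wgd"):
            return clone_fitness(daughter, self.sel, self.genome), None
        profile, chrom_max, arm_sums, total, nulls = self.stats_for(mother_rec)
        mg = mother_rec.genotype
        i, j = op[1], op[2]
        if j >= mg.cn[i].shape[0]:  # no-op replay guard
            return mother_rec.fitness, None
        lo = int(self.offsets[i])
        new_profile = profile.copy()
        new_cmax = chrom_max.copy()
        new_arms = arm_sums.copy()
        if kind == "dup_homolog":
            row = mg.cn[i][j]
            new_profile[lo : lo + row.shape[0]] += row
            for k, arm in self.arms_by_chrom.get(i, ()):
                new_arms[k] += int(row[arm.bin_start : arm.bin_stop].sum())
            new_total = total + int(row.sum())
            new_nulls = nulls
        elif kind == "del_homolog":
            row = mg.cn[i][j]
            seg_prof = profile[lo : lo + row.shape[0]]
            new_profile[lo : lo + row.shape[0]] -= row
            new_nulls = nulls + int(((seg_prof == row) & (row > 0)).sum())
            for k, arm in self.arms_by_chrom.get(i, ()):
                new_arms[k] -= int(row[arm.bin_start : arm.bin_stop].sum())
            new_total = total - int(row.sum())
            new_cmax[i] = int(daughter.cn[i].max()) if daughter.cn[i].size else 0
        elif kind in ("amp_region", "del_region"):
            start, stop = op[3], op[4]
            k = self._arm_of(i, start)
            if k is None:
                return clone_fitness(daughter, self.sel, self.genome), None
            seg = mg.cn[i][j, start:stop]
            seg_sum = int(seg.sum())
            if kind == "amp_region":
                new_profile[lo + start : lo + stop] += seg
                new_arms[k] += seg_sum
                new_total = total + seg_sum
                new_nulls = nulls
                new_cmax[i] = max(int(chrom_max[i]), 2 * int(seg.max()) if seg.size else 0)
            else:
                seg_prof = profile[lo + start : lo + stop]
                new_profile[lo + start : lo + stop] -= seg
                new_nulls = nulls + int(((seg_prof == seg) & (seg > 0)).sum())
                new_arms[k] -= seg_sum
                new_total = total - seg_sum
                new_cmax[i] = int(daughter.cn[i].max()) if daughter.cn[i].size else 0
        else:
            return clone_fitness(daughter, self.sel, self.genome), None

        stats = [new_profile, new_cmax, new_arms, new_total, new_nulls]
        cfg = self.sel.viability
        c_int = int(math.floor(new_total / self.m_bins + 0.5))
        if c_int < 1 or c_int > cfg.ploidy_max:
            return 0.0, stats
        max_bin = int(new_cmax.max())
        if max_bin > cfg.cn_max or max_bin / c_int > cfg.cn_max_normalized:
            return 0.0, stats
        if new_nulls > self.null_budget:
            return 0.0, stats
        if daughter.wgd_count > cfg.wgd_max:
            return 0.0, stats
        if self.loglam.any():
            c = 2.0 * 2**daughter.wgd_count
            s = math.exp(float(((new_arms / self.arm_lengths) / c) @ self.loglam))
        else:
            s = 1.0
        return s, stats


def _spawn_children(
    clones, active, mother_record, step, t_now, genome, sel, probs, rng, drivers,
    fitctx=None,
):
    """One event-carrying division of a cell in ``mother_record``.

    Returns the net count increment for the mother clone (0, 1 or 2).
    """
    da, db, ops_a, ops_b = divide(
        mother_record.genotype, probs, genome, rng, drivers, condition_on_event=True
    )
    stayed = 0
    spawned = []
    for g, ops in ((da, ops_a), (db, ops_b)):
        if not ops:
            stayed += 1
        else:
            spawned.append((g, ops))

    def evaluate(g, ops):
        if fitctx is not None:
            return fitctx.fitness(mother_record, g, ops)
        return clone_fitness(g, sel, genome), None

    if len(spawned) == 2 and spawned[0][1] == spawned[1][1]:
        # both daughters carry identical ops -> identical genotype, one clone
        g, ops = spawned[0]
        fit, stats = evaluate(g, ops)
        cid = len(clones)
        rec = CloneRecord(cid, mother_record.id, step, t_now, g, fit, ops,
                          n_founded=2)
        rec.stats = stats
        clones.append(rec)
        active.append(rec)
        return stayed
    prev_id = None
    for g, ops in spawned:
        fit, stats = evaluate(g, ops)
        cid = len(clones)
        rec = CloneRecord(cid, mother_record.id, step, t_now, g, fit, ops,
                          n_founded=1, sibling=prev_id)
        rec.stats = stats
        if prev_id is not None:
            clones[prev_id].sibling = cid
        prev_id = cid
        clones.append(rec)
        active.append(rec)
    return stayed


def simulate_clonal_evolution(
    cfg: DynamicsConfig,
    probs: EventProbabilities,
    sel: SelectionModel,
    schedule: PopulationSchedule,
    rng,
    genome: GenomeSpec,
    initial: list | None = None,
    record_history: bool = True,
) -> CloneHistory:
    """Tau-leap simulation of clone-level evolution over ``[t0, t_end]``.

    ``initial`` is a list of ``(genotype, count)`` founding clones; by default
    a single diploid clone of size ``Pbar(t0)`` (rounded, at least 1).
    Deterministic given the ``numpy.random.Generator`` passed as ``rng``.

    With ``record_history=False`` only final clone counts are kept (enough
    for final-time sampling and cohort summaries, not for phylogeny
    reconstruction); this is the fast path used when building large ABC
    reference tables.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    tau = cfg.step
    n_steps = max(1, int(round((cfg.t_end - cfg.t0) / tau)))
    times = cfg.t0 + tau * np.arange(n_steps + 1)
    p_end = 1.0 - math.exp(-cfg.turnover * tau)
    drivers = sel.drivers

    if initial is None:
        n0 = cfg.initial_count
        if n0 is None:
            n0 = max(1, int(round(schedule(cfg.t0))))
        initial = [(diploid_genotype(genome), n0)]

    clones: list = []
    active: list = []
    for g, n in initial:
        rec = CloneRecord(len(clones), None, -1, cfg.t0, g, clone_fitness(g, sel, genome))
        if record_history:
            rec.counts.append(int(n))
            rec.divisions.append(0)
            rec.deaths.append(0)
        clones.append(rec)
        active.append(rec)

    counts = np.array([int(n) for _, n in initial], dtype=np.int64)
    fit = np.array([c.fitness for c in active])
    p_any = np.array([event_probability(c.genotype, probs) for c in active])
    fitctx = _FitnessContext(sel, genome)

    pop = np.zeros(n_steps + 1, dtype=np.int64)
    pop[0] = int(counts.sum())
    status = "ok"

    for step in range(1, n_steps + 1):
        t = times[step - 1]
        P = int(counts.sum())
        if P == 0:
            status = "extinct"
            break
        total_fitness = float(counts @ fit)
        pbar = schedule(t)
        if total_fitness > 0:
            g_fb = pbar / (pbar + P)
            p_div = np.minimum(1.0, g_fb * fit * P / total_fitness)
        else:
            p_div = np.zeros_like(fit)

        m = rng.binomial(counts, p_end)
        d = rng.binomial(m, p_div)
        e = rng.binomial(d, p_any)

        new_counts = counts - m + 2 * (d - e)
        n_active = len(active)
        if e.any():
            for k in np.nonzero(e)[0]:
                rec = active[k]
                extra_within = 0
                for _ in range(int(e[k])):
                    inc = _spawn_children(
                        clones, active, rec, step - 1, float(t), genome,
                        sel, probs, rng, drivers, fitctx,
                    )
                    new_counts[k] += inc
                    if inc == 2:
                        extra_within += 1
                # events whose daughters both stayed count as within-clone
                e[k] -= extra_within
        if record_history:
            for k in range(n_active):
                rec = active[k]
                rec.counts.append(int(new_counts[k]))
                rec.divisions.append(int(d[k] - e[k]))
                rec.deaths.append(int(m[k] - d[k]))
        n_new = len(active) - n_active
        if n_new:
            newcl = active[n_active:]
            if record_history:
                for rec in newcl:
                    rec.counts.append(rec.n_founded)
                    rec.divisions.append(0)
                    rec.deaths.append(0)
            new_counts = np.concatenate(
                [new_counts, [rec.n_founded for rec in newcl]]
            )
            fit = np.concatenate([fit, [rec.fitness for rec in newcl]])
            p_any = np.concatenate(
                [p_any, [event_probability(rec.genotype, probs) for rec in newcl]]
            )
        counts = new_counts
        pop[step] = int(counts.sum())
        if (counts == 0).any():
            keep = counts > 0
            counts = counts[keep]
            fit = fit[keep]
            p_any = p_any[keep]
            active = [c for c, k in zip(active, keep) if k]

    if not record_history:
        # retain only final counts, aligned to the last grid point
        for rec, n in zip(active, counts):
            rec.first_index = n_steps
            rec.counts = [int(n)]

    if status == "extinct":
        times = times[:step]
        pop = pop[:step]

    return CloneHistory(
        genome=genome, times=times, clones=clones, pop_size=pop,
        status=status, config=cfg,
    )


def exact_reference_simulation(
    cfg: DynamicsConfig,
    probs: EventProbabilities,
    sel: SelectionModel,
    schedule: PopulationSchedule,
    rng,
    genome: GenomeSpec,
    initial: list | None = None,
) -> CloneHistory:
    """Event-by-event (Gillespie) counterpart of the tau-leap simulator.

    Every lifespan end is simulated individually; feedback and fitness terms
    are re-evaluated at each event.  Only practical for small populations;
    used as a validation oracle.  Counts are recorded on the same time grid
    as the tau-leap for comparability.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    tau = cfg.step
    n_steps = max(1, int(round((cfg.t_end - cfg.t0) / tau)))
    times = cfg.t0 + tau * np.arange(n_steps + 1)
    drivers = sel.drivers

    if initial is None:
        n0 = cfg.initial_count
        if n0 is None:
            n0 = max(1, int(round(schedule(cfg.t0))))
        initial = [(diploid_genotype(genome), n0)]

    clones: list = []
    active: list = []
    for g, n in initial:
        rec = CloneRecord(len(clones), None, -1, cfg.t0, g, clone_fitness(g, sel, genome))
        rec.counts.append(int(n))
        rec.divisions.append(0)
        rec.deaths.append(0)
        clones.append(rec)
        active.append(rec)

    live = {c.id: c.counts[-1] for c in active}
    pend_div = {c.id: 0 for c in active}
    pend_death = {c.id: 0 for c in active}
    pop = np.zeros(n_steps + 1, dtype=np.int64)
    pop[0] = sum(live.values())
    grid = 1
    t = cfg.t0
    status = "ok"

    def flush(upto: int):
        nonlocal grid
        while grid <= upto:
            for c in clones:
                if c.first_index <= grid and grid - c.first_index == len(c.counts):
                    n = live.get(c.id, 0)
                    # stop recording once a clone is extinct and fully flushed
                    if n == 0 and not c.counts:
                        continue
                    c.counts.append(n)
                    c.divisions.append(pend_div.get(c.id, 0))
                    c.deaths.append(pend_death.get(c.id, 0))
                    pend_div[c.id] = 0
                    pend_death[c.id] = 0
            pop[grid] = sum(live.values())
            grid += 1

    while t < cfg.t_end:
        P = sum(live.values())
        if P == 0:
            status = "extinct"
            break
        t += rng.exponential(1.0 / (cfg.turnover * P))
        if t >= cfg.t_end:
            break
        step_now = min(int((t - cfg.t0) / tau), n_steps - 1)
        flush(step_now)  # grid points strictly before the event
        # pick the cell ending its lifespan
        ids = list(live)
        w = np.array([live[i] for i in ids], dtype=float)
        cid = ids[int(rng.choice(len(ids), p=w / w.sum()))]
        rec = clones[cid]
        total_fitness = sum(live[i] * clones[i].fitness for i in ids)
        p_div = division_probability(rec.fitness, total_fitness, P, schedule(t))
        if rng.random() < p_div:
            if rng.random() < event_probability(rec.genotype, probs):
                before = len(clones)
                inc = _spawn_children(
                    clones, active, rec, step_now, float(t), genome,
                    sel, probs, rng, drivers,
                )
                live[cid] += inc - 1
                if inc == 2:
                    pend_div[cid] = pend_div.get(cid, 0) + 1
                for child in clones[before:]:
                    child.birth_step = step_now
                    child.first_index = step_now + 1
                    live[child.id] = child.n_founded
                    pend_div[child.id] = 0
                    pend_death[child.id] = 0
            else:
                live[cid] += 1
                pend_div[cid] = pend_div.get(cid, 0) + 1
        else:
            live[cid] -= 1
            pend_death[cid] = pend_death.get(cid, 0) + 1
        live = {k: v for k, v in live.items() if v > 0}

    if status == "extinct":
        flush(min(int((t - cfg.t0) / tau), n_steps))
        times = times[:grid]
        pop = pop[:grid]
    else:
        flush(n_steps)

    return CloneHistory(
        genome=genome, times=times, clones=clones, pop_size=pop,
        status=status, config=cfg,
    )
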