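"""Sampling and backward-time phylogeny reconstruction."""

import numpy as np
import pytest

from karyosim.dynamics import (
    DynamicsConfig,
    PopulationSchedule,
    simulate_clonal_evolution,
)
from karyosim.events import EventProbabilities, replay_ops
from karyosim.phylogeny import (
    build_sample_phylogeny,
    clonal_ops,
    mrca_age,
    sample_cells,
)
from karyosim.selection import SelectionModel


def run_history(genome, seed, t_end=15.0, tau=0.1, capacity=120,
                p_misseg=0.01, p_arm=0.01, initial_count=None):
    cfg = DynamicsConfig(t_end=t_end, tau=tau, initial_count=initial_count)
    probs = EventProbabilities(p_misseg=p_misseg, p_arm_misseg=p_arm)
    return simulate_clonal_evolution(
        cfg, probs, SelectionModel(), PopulationSchedule.constant(capacity),
        seed, genome,
    )


class TestSampling:
    def test_full_census_returns_exact_counts(self, genome):
        h = run_history(genome, 1)
        final = h.final_counts()
        total = sum(final.values())
        s = sample_cells(h, total, np.random.default_rng(0))
        assert s == final

    def test_oversampling_rejected(self, genome):
        h = run_history(genome, 2)
        total = sum(h.final_counts().values())
        with pytest.raises(ValueError):
            sample_cells(h, total + 1, np.random.default_rng(0))

    def test_hypergeometric_allocation_mean(self, genome):
        h = run_history(genome, 3)
        final = h.final_counts()
        total = sum(final.values())
        biggest = max(final, key=final.get)
        frac = final[biggest] / total
        n = total // 2
        rng = np.random.default_rng(5)
        draws = [sample_cells(h, n, rng).get(biggest, 0) / n for _ in range(300)]
        se = np.sqrt(frac * (1 - frac) / n)  # conservative (ignores fpc)
        assert abs(np.mean(draws) - frac) < 3 * se / np.sqrt(300) + 0.01


class TestTreeContracts:
    def test_tip_count_and_clone_labels(self, genome):
        h = run_history(genome, 4)
        s = sample_cells(h, 40, np.random.default_rng(1))
        tree = build_sample_phylogeny(h, s, np.random.default_rng(2))
        assert tree.n_tips == 40
        from collections import Counter

        tip_clones = Counter(t.clone for t in tree.tips)
        assert dict(tip_clones) == s

    def test_binary_ultrametric_times_in_range(self, genome):
        h = run_history(genome, 5)
        s = sample_cells(h, 30, np.random.default_rng(1))
        tree = build_sample_phylogeny(h, s, np.random.default_rng(2))
        for node in tree.nodes():
            if not node.is_leaf:
                assert len(node.children) == 2
                assert h.t0 <= node.time <= h.t_end
                for ch in node.children:
                    child_time = h.t_end if ch.is_leaf else ch.time
                    assert child_time >= node.time

    def test_single_tip_tree(self, genome):
        h = run_history(genome, 6)
        s = sample_cells(h, 1, np.random.default_rng(1))
        tree = build_sample_phylogeny(h, s, np.random.default_rng(2))
        assert tree.root.is_leaf
        assert mrca_age(tree) == 0.0

    def test_replay_reconstructs_tip_genotypes(self, genome):
        """Replaying the ops on root-to-tip paths yields each tip's clone
        genotype exactly."""
        h = run_history(genome, 7, p_misseg=0.02, p_arm=0.02)
        s = sample_cells(h, 50, np.random.default_rng(1))
        tree = build_sample_phylogeny(h, s, np.random.default_rng(2))
        root_g = h.clones[tree.root.clone].genotype

        def walk(node, genotype):
            for ch in node.children:
                g = replay_ops(genotype, ch.edge_ops)
                if ch.is_leaf:
                    assert g == h.clones[ch.clone].genotype
                else:
                    walk(ch, g)

        walk(tree.root, root_g)

    def test_clonal_ops_prefix_root_genotype(self, genome):
        h = run_history(genome, 8, p_misseg=0.02, p_arm=0.02)
        s = sample_cells(h, 20, np.random.default_rng(1))
        tree = build_sample_phylogeny(h, s, np.random.default_rng(2))
        initial = [c for c in h.clones if c.parent is None][0]
        g = replay_ops(initial.genotype, clonal_ops(h, tree.root.clone))
        assert g == h.clones[tree.root.clone].genotype


class TestMrcaAge:
    def test_forced_recent_mrca(self, genome):
        """Two cells sampled from a clone whose only division is recorded in
        the final step must coalesce in that step."""
        from karyosim.dynamics import CloneHistory, CloneRecord
        from karyosim.genotype import diploid_genotype

        times = np.linspace(0.0, 10.0, 101)
        rec = CloneRecord(0, None, -1, 0.0, diploid_genotype(genome), 1.0)
        rec.counts = [1] * 100 + [2]
        rec.divisions = [0] * 100 + [1]
        rec.deaths = [0] * 101
        h = CloneHistory(genome=genome, times=times, clones=[rec],
                         pop_size=np.array(rec.counts))
        tree = build_sample_phylogeny(h, {0: 2}, np.random.default_rng(0))
        assert -0.011 <= mrca_age(tree) <= 0.0

    def test_forced_root_at_start(self, genome):
        """Two initial clones cannot coalesce: the root sits at t0 (age -1)."""
        from karyosim.genotype import diploid_genotype
        from karyosim.dynamics import DynamicsConfig

        cfg = DynamicsConfig(t_end=5.0, tau=0.1)
        init = [(diploid_genotype(genome), 50), (diploid_genotype(genome), 50)]
        h = simulate_clonal_evolution(
            cfg, EventProbabilities(), SelectionModel(),
            PopulationSchedule.constant(100), 11, genome, initial=init,
        )
        final = h.final_counts()
        assert len(final) == 2  # both clones alive
        s = {cid: 2 for cid in final}
        tree = build_sample_phylogeny(h, s, np.random.default_rng(1))
        assert mrca_age(tree) == pytest.approx(-1.0)

    def test_linear_age_formula(self, genome):
        h = run_history(genome, 12)
        s = sample_cells(h, 10, np.random.default_rng(1))
        tree = build_sample_phylogeny(h, s, np.random.default_rng(2))
        t_mrca = tree.root.time
        assert mrca_age(tree) == pytest.approx(
            (t_mrca - h.t_end) / (h.t_end - h.t0)
        )
        assert -1.0 <= mrca_age(tree) <= 0.0


class TestCoalescentLimit:
    def test_neutral_pairwise_coalescence_time(self, genome):
        """In a constant neutral population of N cells, two random lineages
        coalesce on average ~N generations back (division rate ~ N/2 per
        generation, pairing probability 2/(N(N-1)))."""
        N = 25
        ages = []
        rng = np.random.default_rng(99)
        for i in range(80):
            h = run_history(
                genome, 2000 + i, t_end=150.0, tau=0.25, capacity=N,
                p_misseg=0.0, p_arm=0.0,
            )
            s = sample_cells(h, 2, rng)
            tree = build_sample_phylogeny(h, s, rng)
            ages.append(h.t_end - tree.root.time)
        mean_age = np.mean(ages)
        # exponential-ish with mean N; allow broad Monte-Carlo band (censored
        # at t_end=150 => slight downward bias)
        assert 0.6 * N < mean_age < 1.45 * N
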