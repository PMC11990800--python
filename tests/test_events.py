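"""CNA mechanisms: daughter conservation, mutation bookkeeping, sampling."""

import numpy as np
import pytest
from scipy import stats

from karyosim.events import (
    EventProbabilities,
    FocalLengthModel,
    _binom_ge1,
    apply_arm_missegregation,
    apply_chrom_missegregation,
    apply_driver_mutation,
    apply_focal_amplification,
    apply_focal_deletion,
    apply_wgd,
    divide,
    event_probability,
    replay_ops,
    sample_focal_range,
)
from karyosim.genome import build_genome
from karyosim.genotype import Mutation, diploid_genotype, ploidy
from karyosim.selection import DriverGene


def total_profile(g):
    return g.total_cn_profile()


class TestWgd:
    def test_doubles_everything(self, genome):
        d = diploid_genotype(genome)
        w, plain = apply_wgd(d)
        assert w.total_homologs == 2 * d.total_homologs
        assert w.total_cn() == 2 * d.total_cn()
        assert w.wgd_count == 1
        assert plain == d

    def test_mutations_copied_to_both_homolog_sets(self, genome):
        d = diploid_genotype(genome)
        d.mutations.append(Mutation("m", 0, 0, 3, 0))
        w, _ = apply_wgd(d)
        homs = sorted(m.homolog for m in w.mutations)
        assert homs == [0, 2]


class TestMissegregation:
    def test_chromosome_conservation(self, genome):
        d = diploid_genotype(genome)
        gainer, loser = apply_chrom_missegregation(d, 1, 0)
        assert gainer.homolog_count(1) == 3
        assert loser.homolog_count(1) == 1
        np.testing.assert_array_equal(
            total_profile(gainer) + total_profile(loser), 2 * total_profile(d)
        )

    def test_losing_last_homolog_gives_nullisomy(self, genome):
        d = diploid_genotype(genome)
        _, loser = apply_chrom_missegregation(d, 0, 0)
        _, loser2 = apply_chrom_missegregation(loser, 0, 0)
        assert loser2.homolog_count(0) == 0

    def test_mutations_follow_homolog(self, genome):
        d = diploid_genotype(genome)
        d.mutations.append(Mutation("m", 0, 0, 2, 0))
        gainer, loser = apply_chrom_missegregation(d, 0, 0)
        assert gainer.mutant_copies("m") == 2
        assert loser.mutant_copies("m") == 0

    def test_arm_conservation_and_other_arm_untouched(self, genome):
        d = diploid_genotype(genome)
        arm_p = genome.arm("2p")
        gainer, loser = apply_arm_missegregation(d, 1, 0, arm_p)
        np.testing.assert_array_equal(
            total_profile(gainer) + total_profile(loser), 2 * total_profile(d)
        )
        arm_q = genome.arm("2q")
        for daughter in (gainer, loser):
            np.testing.assert_array_equal(
                daughter.cn[1][:2, arm_q.bin_start : arm_q.bin_stop],
                d.cn[1][:, arm_q.bin_start : arm_q.bin_stop],
            )

    def test_arm_mutations_move_with_segment(self, genome):
        d = diploid_genotype(genome)
        arm = genome.arm("1p")
        d.mutations.append(Mutation("m", 0, 0, arm.bin_start, 0))
        gainer, loser = apply_arm_missegregation(d, 0, 0, arm)
        assert gainer.mutant_copies("m") == 2
        assert loser.mutant_copies("m") == 0


class TestFocalEvents:
    def test_amplification_doubles_range(self):
        g = build_genome([6], [2], 2)  # 3 bins
        d = diploid_genotype(g)
        out = apply_focal_amplification(d, 0, 0, (1, 3))
        assert out.cn[0][0].tolist() == [1, 2, 2]
        assert out.cn[0][1].tolist() == [1, 1, 1]

    def test_amplification_of_zero_stays_zero(self, genome):
        d = diploid_genotype(genome)
        d.cn[0][0, 1:3] = 0
        out = apply_focal_amplification(d, 0, 0, (1, 3))
        assert out.cn[0][0, 1:3].tolist() == [0, 0]

    def test_amplification_multiplies_mutations(self, genome):
        d = diploid_genotype(genome)
        d.cn[0][0, 2] = 3
        d.mutations.append(Mutation("m", 0, 0, 2, 1))
        out = apply_focal_amplification(d, 0, 0, (2, 3))
        assert out.cn[0][0, 2] == 6
        assert out.mutant_copies("m") == 2

    def test_deletion_resets_range(self):
        g = build_genome([6], [2], 2)
        d = diploid_genotype(g)
        out = apply_focal_deletion(d, 0, 0, (0, 2))
        assert out.cn[0][0].tolist() == [0, 0, 1]

    def test_deletion_removes_exactly_addressed_mutations(self, genome):
        d = diploid_genotype(genome)
        d.mutations += [Mutation("a", 0, 0, 1, 0), Mutation("b", 0, 0, 5, 0),
                        Mutation("c", 0, 1, 1, 0)]
        out = apply_focal_deletion(d, 0, 0, (0, 3))
        assert sorted(m.tag for m in out.mutations) == ["b", "c"]

    def test_empty_range_rejected(self, genome):
        with pytest.raises(ValueError):
            apply_focal_deletion(diploid_genotype(genome), 0, 0, (2, 2))


class TestDriverMutation:
    def test_mutation_flips_one_wt_allele(self, genome, rng):
        gene = DriverGene("g", "TSG", 1.2, 0, 4)
        d = diploid_genotype(genome)
        out = apply_driver_mutation(d, [gene], rng)
        assert out.mutant_copies("g") == 1
        out2 = apply_driver_mutation(out, [gene], rng)
        assert out2.mutant_copies("g") == 2
        out3 = apply_driver_mutation(out2, [gene], rng)  # no WT copies left
        assert out3.mutant_copies("g") == 2

    def test_zero_cn_locus_cannot_be_mutated(self, genome, rng):
        gene = DriverGene("g", "TSG", 1.2, 0, 4)
        d = diploid_genotype(genome)
        d.cn[0][:, 4] = 0
        out = apply_driver_mutation(d, [gene], rng)
        assert out.mutant_copies("g") == 0


class TestFocalRangeSampling:
    def test_range_fits_in_arm(self, genome, rng):
        arm = genome.arm("3q")
        for _ in range(200):
            start, stop = sample_focal_range(arm, FocalLengthModel(), rng)
            assert arm.bin_start <= start < stop <= arm.bin_stop

    def test_beta_mean_ratio(self, genome, rng):
        arm = genome.arm("1q")  # 30 bins
        model = FocalLengthModel(a_del=2.0, b_del=5.0)
        lengths = [
            (lambda r: r[1] - r[0])(sample_focal_range(arm, model, rng, "del"))
            for _ in range(10_000)
        ]
        # Beta(2,5) mean is 2/7; discretisation inflates short events slightly
        assert np.mean(lengths) / arm.n_bins == pytest.approx(2 / 7, abs=0.03)


class TestDivisionSampling:
    def test_all_zero_probabilities_changes_nothing(self, genome, rng):
        d = diploid_genotype(genome)
        a, b, ops_a, ops_b = divide(d, EventProbabilities(), genome, rng)
        assert ops_a == [] and ops_b == []
        assert a == d and b == d

    def test_alpha_scales_missegregation_rate(self):
        probs = EventProbabilities(p_misseg=5e-5, alpha=10.0)
        assert probs.misseg_rates(0) == (5e-5, 0.0)
        assert probs.misseg_rates(1)[0] == pytest.approx(5e-4)

    def test_binomial_mean_event_count(self, genome):
        from karyosim.events import _sample_event_counts

        rng = np.random.default_rng(7)
        probs = EventProbabilities(p_misseg=0.5)
        d = diploid_genotype(genome)  # 8 homologs
        counts = [
            _sample_event_counts(d, probs, rng, condition=False)[1]
            for _ in range(4000)
        ]
        assert np.mean(counts) == pytest.approx(4.0, abs=0.12)

    def test_conditioned_division_always_has_events(self, genome):
        rng = np.random.default_rng(3)
        probs = EventProbabilities(p_misseg=1e-4, p_wgd=1e-5, p_focal_del=1e-4)
        d = diploid_genotype(genome)
        for _ in range(200):
            _, _, ops_a, ops_b = divide(
                d, probs, genome, rng, condition_on_event=True
            )
            assert ops_a or ops_b

    def test_truncated_binomial_matches_conditional_law(self):
        rng = np.random.default_rng(5)
        n, p = 8, 0.3
        draws = np.array([_binom_ge1(n, p, rng) for _ in range(20_000)])
        pmf = stats.binom.pmf(np.arange(1, n + 1), n, p)
        pmf /= pmf.sum()
        observed = np.bincount(draws, minlength=n + 1)[1:] / len(draws)
        assert np.abs(observed - pmf).max() < 0.01

    def test_replay_reconstructs_daughters(self, genome):
        rng = np.random.default_rng(11)
        probs = EventProbabilities(
            p_misseg=0.3, p_arm_misseg=0.3, p_wgd=0.05, p_focal_amp=0.2,
            p_focal_del=0.2, p_driver_mut=0.2,
        )
        gene = DriverGene("g", "OG", 1.1, 1, 3)
        d = diploid_genotype(genome)
        for _ in range(100):
            a, b, ops_a, ops_b = divide(d, probs, genome, rng, drivers=[gene])
            assert replay_ops(d, ops_a) == a
            assert replay_ops(d, ops_b) == b


class TestConservationProperty:
    def test_symmetric_events_conserve_cn(self, genome, random_genotype, rng):
        """WGD and missegregations conserve summed daughter CN exactly."""
        for _ in range(300):
            g = random_genotype(steps=3)
            w, plain = apply_wgd(g)
            np.testing.assert_array_equal(
                total_profile(w) - total_profile(g), total_profile(g)
            )
            i = int(rng.integers(genome.n_chroms))
            if g.homolog_count(i) > 0:
                j = int(rng.integers(g.homolog_count(i)))
                ga, lo = apply_chrom_missegregation(g, i, j)
                np.testing.assert_array_equal(
                    total_profile(ga) + total_profile(lo), 2 * total_profile(g)
                )
                arms = [a for a in genome.arms if a.chrom == i]
                arm = arms[int(rng.integers(len(arms)))]
                ga, lo = apply_arm_missegregation(g, i, j, arm)
                np.testing.assert_array_equal(
                    total_profile(ga) + total_profile(lo), 2 * total_profile(g)
                )

    def test_focal_events_touch_only_target_range(self, genome, random_genotype, rng):
        offsets = genome.bin_offsets()
        for _ in range(100):
            g = random_genotype(steps=3)
            i = int(rng.integers(genome.n_chroms))
            if g.homolog_count(i) == 0:
                continue
            j = int(rng.integers(g.homolog_count(i)))
            arms = [a for a in genome.arms if a.chrom == i]
            arm = arms[int(rng.integers(len(arms)))]
            start, stop = sample_focal_range(arm, FocalLengthModel(), rng)
            for fn in (apply_focal_amplification, apply_focal_deletion):
                out = fn(g, i, j, (start, stop))
                mask = np.ones(genome.total_bins, dtype=bool)
                mask[offsets[i] + start : offsets[i] + stop] = False
                np.testing.assert_array_equal(
                    total_profile(out)[mask], total_profile(g)[mask]
                )
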