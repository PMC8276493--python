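import numpy as np
import pytest

from selsig import funcvar
from selsig.simdata import (SelectedLocus, SimConfig, divergent_locus, evolve_line,
                            simulate_annotated_variants, simulate_base,
                            simulate_experiment)

SMALL = dict(n_chrom=1, chrom_len_bp=3_000_000, snps_per_chrom=120,
             pop_size_per_line=50, base_pop_size=50, base_sample_size=40,
             line_sample_sizes={})


def small_config(seed, gens=(0, 6), loci=()):
    return SimConfig(seed=seed, generations_sampled=gens,
                     selected_loci=tuple(loci), **SMALL)


class TestSimulateBase:
    def test_deterministic_given_seed(self):
        p1 = simulate_base(small_config(3))
        p2 = simulate_base(small_config(3))
        assert np.array_equal(p1.haps, p2.haps)
        assert p1.markers == p2.markers

    def test_two_founders_without_recombination_give_two_haplotypes(self):
        cfg = SimConfig(seed=1, n_founder_haplotypes=2, recomb_rate_cM_per_Mb=0.0,
                        generations_sampled=(0, 2), **SMALL)
        pool = simulate_base(cfg)
        flat = pool.haps.reshape(-1, pool.haps.shape[2])
        assert len(np.unique(flat, axis=0)) <= 2

    def test_ld_decays_with_distance(self):
        """Mean r^2 in distance bins is non-increasing from the nearest to
        the farthest bin, averaged over 20 replicates."""
        edges = np.array([0, 50_000, 200_000, 800_000, 3_000_000])
        sums = np.zeros(len(edges) - 1)
        counts = np.zeros(len(edges) - 1)
        for seed in range(20):
            pool = simulate_base(small_config(seed))
            dose = pool.haps.sum(axis=1).astype(float)
            keep = dose.std(axis=0) > 0
            dose, pos = dose[:, keep], pool.markers.pos_bp[keep]
            r = np.corrcoef(dose, rowvar=False) ** 2
            d = np.abs(pos[:, None] - pos[None, :])
            iu = np.triu_indices(len(pos), k=1)
            which = np.digitize(d[iu], edges) - 1
            for b in range(len(edges) - 1):
                m = which == b
                sums[b] += r[iu][m].sum()
                counts[b] += m.sum()
        means = sums / counts
        assert means[0] > means[-1]
        assert all(means[i] >= means[i + 1] - 0.01 for i in range(len(means) - 1))

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="more SNPs"):
            SimConfig(chrom_len_bp=10, snps_per_chrom=20)


class TestEvolveLine:
    def test_deterministic_trajectories(self):
        cfg = small_config(5, loci=[SelectedLocus("1", 1_500_000, 0.3, "HIGH")])
        pool = simulate_base(cfg)
        _, t1 = evolve_line(pool, cfg, "HIGH")
        _, t2 = evolve_line(pool, cfg, "HIGH")
        np.testing.assert_array_equal(t1.trajectories[(0, "HIGH")],
                                      t2.trajectories[(0, "HIGH")])

    def test_neutral_drift_variance_matches_wright_fisher(self):
        """With s = 0, E[(p_t - p_0)^2] across replicates tracks the
        closed form p0 (1 - p0) (1 - (1 - 1/2N)^t)."""
        t, N = 6, 50
        sq, expect = [], []
        for seed in range(100):
            cfg = SimConfig(seed=seed, generations_sampled=(0, t),
                            selected_loci=(SelectedLocus("1", 1_500_000, 0.0,
                                                         "HIGH", 1, 0.5),),
                            n_chrom=1, chrom_len_bp=3_000_000, snps_per_chrom=40,
                            pop_size_per_line=N, base_pop_size=N,
                            base_sample_size=N, line_sample_sizes={})
            pool = simulate_base(cfg)
            _, truth = evolve_line(pool, cfg, "HIGH", n_generations=t)
            traj = truth.trajectories[(0, "HIGH")]
            p0 = traj[0]
            sq.append((traj[-1] - p0) ** 2)
            expect.append(p0 * (1 - p0) * (1 - (1 - 1 / (2 * N)) ** t))
        observed, predicted = np.mean(sq), np.mean(expect)
        assert observed == pytest.approx(predicted, rel=0.35)

    def test_strong_selection_fixes_favored_allele(self):
        """s = 0.5 from p0 = 0.5 reaches > 0.9 in >= 90% of replicates
        after 11 generations (deterministic recursion predicts ~0.99)."""
        # haploid-equivalent deterministic recursion as sanity oracle:
        # p' = p (1 + s (1 + p)) / (1 + 2 s p)
        p, s = 0.5, 0.5
        for _ in range(11):
            p = p * (1 + s * (1 + p)) / (1 + 2 * s * p)
        assert p > 0.95
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = SimConfig(seed=seed, generations_sampled=(0, 11),
                            selected_loci=(SelectedLocus("1", 1_500_000, 0.5,
                                                         "HIGH", 1, 0.5),),
                            n_chrom=1, chrom_len_bp=3_000_000, snps_per_chrom=40,
                            pop_size_per_line=100, base_pop_size=100,
                            base_sample_size=50, line_sample_sizes={})
            pool = simulate_base(cfg)
            _, truth = evolve_line(pool, cfg, "HIGH", n_generations=11)
            wins += truth.trajectories[(0, "HIGH")][-1] > 0.9
        assert wins >= int(0.9 * n_rep)

    def test_mean_final_frequency_increases_with_s(self):
        means = []
        for s in (0.0, 0.1, 0.3, 0.5):
            finals = []
            for seed in range(50):
                cfg = SimConfig(seed=seed, generations_sampled=(0, 8),
                                selected_loci=(SelectedLocus("1", 1_500_000, s,
                                                             "HIGH", 1, 0.5),),
                                n_chrom=1, chrom_len_bp=3_000_000, snps_per_chrom=30,
                                pop_size_per_line=50, base_pop_size=50,
                                base_sample_size=30, line_sample_sizes={})
                pool = simulate_base(cfg)
                _, truth = evolve_line(pool, cfg, "HIGH", n_generations=8)
                finals.append(truth.trajectories[(0, "HIGH")][-1])
            means.append(np.mean(finals))
        assert all(means[i] < means[i + 1] for i in range(3))


class TestSimulateExperiment:
    def test_cohort_structure_and_dosage_domain(self):
        cfg = small_config(7, gens=(0, 3, 4))
        res = simulate_experiment(cfg)
        sizes = res.cohorts.table.groupby(["line", "generation"]).size()
        assert sizes[("BASE", 0)] == 40
        assert sizes[("HIGH", 3)] == sizes[("HIGH", 4)] == 50
        assert set(np.unique(res.genotypes.values)) <= {0, 1, 2}
        # both generations of a line come from one continuous simulation
        assert res.cohorts.covers(res.genotypes)

    def test_divergent_locus_moves_lines_apart(self):
        cfg = small_config(11, gens=(0, 6),
                           loci=divergent_locus("1", 1_500_000, 0.8))
        res = simulate_experiment(cfg)
        assert (res.truth.trajectories[(0, "HIGH")][-1]
                > res.truth.trajectories[(0, "HIGH")][0])
        # locus index 1 favors the ref allele in LOW
        assert (res.truth.trajectories[(1, "LOW")][-1]
                > res.truth.trajectories[(1, "LOW")][0])


class TestAnnotatedVariantFixture:
    def test_planted_truth_is_recovered_exactly(self):
        variants, _, truth = simulate_annotated_variants(
            n_variants=200, n_planted_fixed_divergent=7, seed=4)
        hits = funcvar.fixed_divergent_functional_indels(variants)
        assert sorted((v.chrom, v.pos_bp) for v in hits) == truth
        assert len(truth) == 7

    def test_zero_planted_gives_empty_filter(self):
        variants, _, truth = simulate_annotated_variants(
            n_variants=150, n_planted_fixed_divergent=0, seed=9)
        assert truth == []
        assert funcvar.fixed_divergent_functional_indels(variants) == []

    def test_byte_identical_given_seed(self, tmp_path):
        for i in (1, 2):
            variants, _, _ = simulate_annotated_variants(seed=123)
            funcvar.write_variant_table(variants, tmp_path / f"v{i}.tsv")
        assert (tmp_path / "v1.tsv").read_bytes() == (tmp_path / "v2.tsv").read_bytes()
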