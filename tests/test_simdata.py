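"""Coalescent simulator calibration and synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from cushaw import _kernels, simdata
from cushaw.core import StructuralModelError, ValidationError

from conftest import two_deme_genotypes


def _single_deme(n_e=1000.0):
    return simdata.DemographicModel(pop_labels=["a"],
                                    deme_sizes={"a": n_e})


class TestCoalescentCalibration:
    def test_no_mutation_gives_no_sites(self):
        params = simdata.SimParams(samples_per_deme={"a": 1},
                                   mutation_mode="rate", n_loci=20,
                                   mu=0.0, seed=1)
        haps = simdata.simulate_coalescent(_single_deme(), params)
        assert haps.n_sites == 0

    def test_pairwise_tmrca_matches_closed_form(self):
        # E[T2] = 2 N_e for two lineages in a diploid deme
        model = _single_deme(1000.0)
        N, M, me, et, es, ed, ef = model.kernel_arrays()
        t = _kernels.tmrca_batch(4000, np.zeros(2, np.int64), N, M, me,
                                 et, es, ed, ef, 99)
        se = t.std() / np.sqrt(t.size)
        assert abs(t.mean() - 2000.0) < 3 * se

    def test_watterson_segregating_sites(self):
        # theta = 4 N mu L = 10 with n = 10 haploids:
        # E[S] = theta * sum_{i=1}^{9} 1/i = 28.29
        n_loci = 300
        params = simdata.SimParams(samples_per_deme={"a": 5},
                                   mutation_mode="rate", n_loci=n_loci,
                                   mu=0.0025 / 500, locus_len=500, seed=3)
        haps = simdata.simulate_coalescent(_single_deme(1000.0), params)
        expected = 10 * sum(1 / i for i in range(1, 10))
        # SE of the mean via the across-locus spread of S
        counts = np.bincount(
            np.searchsorted(np.arange(n_loci) * params.locus_spacing + 1,
                            haps.pos, side="right") - 1,
            minlength=n_loci)
        se = counts.std(ddof=1) / np.sqrt(n_loci)
        assert abs(haps.n_sites / n_loci - expected) < 3 * se

    @pytest.mark.parametrize("model_kw,samples", [
        (dict(), {"wild": 5, "dom": 5}),
        (dict(t_split=4000), {"wild": 5, "dom": 5}),
        (dict(gene_flow_mode="continuous", m=1e-4), {"wild": 5, "dom": 5}),
    ])
    def test_agreement_with_msprime(self, model_kw, samples):
        """Mean segregating sites and pairwise diversity match an
        independent coalescent implementation within 3 SE."""
        import msprime

        n_loci, mu, L = 150, 2e-7, 500
        model = simdata.two_deme_model(**model_kw)
        params = simdata.SimParams(samples_per_deme=samples,
                                   mutation_mode="rate", n_loci=n_loci,
                                   mu=mu, locus_len=L, seed=11)
        haps = simdata.simulate_coalescent(model, params)
        p = haps.haplotypes.mean(axis=0)
        pi_own = float((2 * p * (1 - p)
                        * haps.haplotypes.shape[0]
                        / (haps.haplotypes.shape[0] - 1)).sum()) / n_loci
        s_own = haps.n_sites / n_loci

        dem = msprime.Demography()
        dem.add_population(name="wild", initial_size=model.deme_sizes["wild"])
        dem.add_population(name="dom", initial_size=model.deme_sizes["dom"])
        dem.add_population(name="anc", initial_size=model.deme_sizes["anc"])
        t_split = model.split_events[0][0]
        if model.gene_flow_mode == "continuous":
            m = model.migration[("wild", "dom")]
            dem.set_migration_rate("wild", "dom", m)
            dem.set_migration_rate("dom", "wild", m)
        dem.add_population_split(time=t_split, derived=["wild", "dom"],
                                 ancestral="anc")
        s_ms, pi_ms = [], []
        reps = msprime.sim_ancestry(
            samples={k: v for k, v in samples.items()}, demography=dem,
            sequence_length=L, num_replicates=n_loci, random_seed=5)
        for rep_i, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=7 + rep_i,
                                        discrete_genome=False)
            s_ms.append(mts.num_sites)
            pi_ms.append(mts.diversity(span_normalise=False))
        se = np.std(s_ms, ddof=1) / np.sqrt(n_loci)
        assert abs(s_own - np.mean(s_ms)) < 3 * np.hypot(se, se)
        se_pi = np.std(pi_ms, ddof=1) / np.sqrt(n_loci)
        assert abs(pi_own - np.mean(pi_ms)) < 3 * np.hypot(se_pi, se_pi)

    def test_divergence_grows_with_split_time(self):
        # no gene flow, equal sizes: mean absolute between-deme divergence
        # (per-locus d_xy, mutation-rate mode) is monotone over a grid of
        # three split times
        means = []
        for t_split in (500, 4000, 16000):
            dxy = []
            for rep in range(50):
                model = simdata.two_deme_model(t_split=t_split)
                params = simdata.SimParams(
                    samples_per_deme={"wild": 4, "dom": 4},
                    mutation_mode="rate", n_loci=40, mu=2e-7,
                    locus_len=500, seed=9000 + rep + int(t_split))
                haps = simdata.simulate_coalescent(model, params)
                if haps.n_sites == 0:
                    dxy.append(0.0)
                    continue
                pw = haps.haplotypes[haps.demes == "wild"].mean(axis=0)
                pdom = haps.haplotypes[haps.demes == "dom"].mean(axis=0)
                dxy.append(float((pw * (1 - pdom)
                                  + pdom * (1 - pw)).sum()) / 40)
            means.append(np.mean(dxy))
        assert means[0] < means[1] < means[2]

    def test_isolated_demes_raise(self):
        model = simdata.DemographicModel(
            pop_labels=["a", "b"], deme_sizes={"a": 100, "b": 100})
        params = simdata.SimParams(samples_per_deme={"a": 2, "b": 2},
                                   n_snps=5, seed=1)
        with pytest.raises(StructuralModelError):
            simdata.simulate_coalescent(model, params)

    def test_invalid_rates_raise(self):
        with pytest.raises(ValidationError):
            simdata.DemographicModel(
                pop_labels=["a", "b"],
                deme_sizes={"a": 100, "b": 100},
                migration={("a", "b"): 1.5},
                gene_flow_mode="continuous").validate()

    def test_determinism(self):
        params = simdata.SimParams(samples_per_deme={"wild": 3, "dom": 3},
                                   n_snps=50, seed=77)
        model = simdata.two_deme_model()
        h1 = simdata.simulate_coalescent(model, params)
        h2 = simdata.simulate_coalescent(model, params)
        assert np.array_equal(h1.haplotypes, h2.haplotypes)
        assert np.array_equal(h1.pos, h2.pos)

    def test_deme_relabeling_is_neutral(self):
        # consistently swapping deme names leaves statistics unchanged
        base = dict(n_wild=8000, n_dom=8000, n_anc=8000, t_split=1500)
        m1 = simdata.two_deme_model(**base)
        m2 = simdata.DemographicModel(
            pop_labels=["dom", "wild", "anc"],
            deme_sizes={"dom": 8000, "wild": 8000, "anc": 8000},
            split_events=[(1500, "wild", "anc"), (1500, "dom", "anc")],
            domesticated_deme="dom")
        p1 = simdata.SimParams(samples_per_deme={"wild": 4, "dom": 4},
                               n_snps=400, seed=5)
        p2 = simdata.SimParams(samples_per_deme={"dom": 4, "wild": 4},
                               n_snps=400, seed=5)
        d1 = simdata.simulate_joint_counts(m1, {"wild": 4, "dom": 4},
                                           400, 5)
        d2 = simdata.simulate_joint_counts(m2, {"dom": 4, "wild": 4},
                                           400, 5)
        # same marginal SFS distribution; compare pooled frequencies
        f1 = np.sort(np.concatenate([d1["wild"], d1["dom"]]))
        f2 = np.sort(np.concatenate([d2["dom"], d2["wild"]]))
        assert stats.ks_2samp(f1, f2).pvalue > 0.01


class TestGenotypeEmission:
    def test_single_pair_dosage(self):
        haps = simdata.HaplotypeSet(
            np.array([[0], [1]], dtype=np.int8), np.array(["a", "a"]),
            np.array(["chr1"]), np.array([100]))
        G = simdata.emit_genotypes(haps)
        assert G.dosages.tolist() == [[1]]

    def test_zero_missing_rate(self):
        G = two_deme_genotypes(3, n_snps=100, n_dip=5)
        assert (G.dosages >= 0).all()

    def test_missing_fraction_binomial(self):
        model = _single_deme(5000)
        params = simdata.SimParams(samples_per_deme={"a": 25}, n_snps=1000,
                                   seed=9)
        haps = simdata.simulate_coalescent(model, params)
        G = simdata.emit_genotypes(haps, pairing_seed=2, missing_rate=0.2)
        n = G.dosages.size
        frac = (G.dosages < 0).mean()
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * se

    def test_odd_haplotype_count_raises(self):
        haps = simdata.HaplotypeSet(
            np.zeros((3, 2), dtype=np.int8), np.array(["a", "a", "a"]),
            np.array(["chr1", "chr1"]), np.array([1, 2]))
        with pytest.raises(ValidationError):
            simdata.emit_genotypes(haps)


class TestEnvVector:
    def test_wild_zero_domesticated_one(self):
        env = simdata.make_env_vector({"P1": None, "P2": None}, ["P2"])
        assert env.tolist() == [0.0, 1.0]

    def test_all_wild(self):
        env = simdata.make_env_vector({"a": 1, "b": 2, "c": 3}, [])
        assert env.tolist() == [0.0, 0.0, 0.0]

    def test_permutation_equivariance(self):
        pops = {"a": 1, "b": 2, "c": 3}
        env = simdata.make_env_vector(pops, ["b"])
        perm = {"c": 3, "b": 2, "a": 1}
        env_p = simdata.make_env_vector(perm, ["b"])
        assert env.tolist() == [0.0, 1.0, 0.0]
        assert env_p.tolist() == [0.0, 1.0, 0.0]

    def test_unknown_deme_raises(self):
        with pytest.raises(ValidationError):
            simdata.make_env_vector({"a": 1}, ["zz"])


class TestSpikeSelection:
    def test_shift_one_fixes_target(self):
        G = two_deme_genotypes(21, n_snps=300, n_dip=10)
        Gs, truth = simdata.spike_selection(G, 5, "dom", 1.0, seed=4)
        rows = Gs.pops == "dom"
        for sid in truth.selected_site_ids:
            s = list(Gs.site_ids).index(sid)
            col = Gs.dosages[rows, s]
            assert (col[col >= 0] == 2).all()

    def test_zero_loci_is_identity(self):
        G = two_deme_genotypes(22, n_snps=100, n_dip=5)
        Gs, truth = simdata.spike_selection(G, 0, "dom", 0.5, seed=4)
        assert np.array_equal(Gs.dosages, G.dosages)
        assert truth.selected_site_ids == []

    def test_excess_loci_raise(self):
        G = two_deme_genotypes(23, n_snps=50, n_dip=5)
        with pytest.raises(ValidationError):
            simdata.spike_selection(G, 10_000, "dom", 1.0)

    def test_spiked_fst_exceeds_genome_median(self):
        from cushaw.diversity import wc_fst

        wins = 0
        for seed in range(20):
            G = two_deme_genotypes(100 + seed, n_snps=200, n_dip=10)
            Gs, truth = simdata.spike_selection(G, 5, "dom", 1.0,
                                                seed=seed)
            res = wc_fst(Gs)
            spiked = np.isin(Gs.site_ids, truth.selected_site_ids)
            med = np.nanmedian(res.per_locus[~spiked])
            if np.nanmean(res.per_locus[spiked]) > med:
                wins += 1
        assert wins >= 18


class TestSvCallsets:
    def test_zero_jitter_identical(self):
        A, B, truth = simdata.make_sv_callsets(10, 0, 0, 0.0, seed=1)
        cols = ["chrom", "start", "end", "type"]
        assert A[cols].equals(B[cols])

    def test_no_shared_gives_empty_consensus(self):
        from cushaw.svconsensus import consensus_svs

        A, B, _ = simdata.make_sv_callsets(0, 10, 10, 5.0, seed=2)
        res = consensus_svs(A, B)
        assert len(res.consensus) == 0

    def test_jitter_recovery_matches_normal_tail(self):
        # both endpoints within +-100 of a N(0, 20) rounded jitter
        A, B, truth = simdata.make_sv_callsets(400, 0, 0, 20.0, seed=3)
        p1 = stats.norm.cdf(100.5 / 20) - stats.norm.cdf(-100.5 / 20)
        shared = truth.true_params["shared_ids"]
        merged = A.merge(B, on="id", suffixes=("_a", "_b"))
        both_types = ~merged["type_a"].eq("translocation")
        d_ok = ((merged["start_a"] - merged["start_b"]).abs() <= 100) & \
               ((merged["end_a"] - merged["end_b"]).abs() <= 100)
        n_loci = 2
        expect = p1 ** n_loci
        frac = d_ok[both_types].mean()
        n = both_types.sum()
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 3 * se + 1e-9
        assert len(shared) == 400

    def test_negative_counts_raise(self):
        with pytest.raises(ValidationError):
            simdata.make_sv_callsets(-1, 0, 0, 1.0)
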