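"""Multidimensional SFS construction, composite likelihood, and the
scenario bank / fitting machinery."""

import math

import numpy as np
import pytest

from cushaw import demography, simdata
from cushaw.core import ValidationError

from conftest import make_matrix


def _toy_msfs(counts, n_hap=(2, 2)):
    return demography.MultiSFS(["a", "b"], n_hap, counts)


class TestMultiSfs:
    def test_polarize_hand_tally(self):
        # three demes of 1 diploid each (2 haploids) + 1 outgroup diploid;
        # hand-set dosages at 3 sites
        d = np.array([
            # s0 s1 s2
            [1, 0, 2],   # deme a
            [0, 1, 2],   # deme b
            [2, 0, 2],   # deme c
            [0, 2, 0],   # outgroup: ancestral REF at s0; ALT at s1;
                         # REF at s2
        ], dtype=np.int8)
        G = make_matrix(d, pops=["a", "b", "c", "out"])
        sfs = demography.polarize_and_build_msfs(G, ["a", "b", "c"],
                                                 "out")
        # s0: derived counts (1, 0, 2); s1: outgroup fixed ALT -> flip:
        # (2-0, 2-1, 2-0) = (2, 1, 2); s2: (2, 2, 2) = corner -> masked
        assert sfs.counts[1, 0, 2] == 1
        assert sfs.counts[2, 1, 2] == 1
        assert sfs.total == 2

    def test_fixed_ancestral_excluded(self):
        d = np.array([[0], [0], [0], [0]], dtype=np.int8)
        G = make_matrix(d, pops=["a", "a", "b", "out"])
        with pytest.raises(ValidationError):
            demography.polarize_and_build_msfs(G, ["a", "b"], "out")

    def test_total_is_conserved(self):
        model = simdata.domestication_model(outgroup=True)
        params = simdata.SimParams(
            samples_per_deme={"jalisco": 4, "southern": 4, "dom": 4,
                              "moschata": 3},
            n_snps=300, seed=6)
        G = simdata.emit_genotypes(
            simdata.simulate_coalescent(model, params), 1)
        sfs = demography.polarize_and_build_msfs(
            G, ["jalisco", "southern", "dom"], "moschata")
        kept = G.n_sites - sfs.n_dropped_outgroup - sfs.n_dropped_missing
        # corner (in-group monomorphic) sites are also excluded
        assert sfs.total <= kept
        assert sfs.total > 0

    def test_roundtrip(self, tmp_path):
        counts = np.arange(9.0).reshape(3, 3)
        counts[0, 0] = counts[2, 2] = 0
        sfs = _toy_msfs(counts)
        path = tmp_path / "obs.fs"
        sfs.save(path)
        back = demography.MultiSFS.load(path)
        assert back.pop_names == ["a", "b"]
        assert np.allclose(back.counts, sfs.counts)


class TestExpectedSfs:
    def test_single_deme_follows_one_over_i(self):
        model = simdata.DemographicModel(pop_labels=["a"],
                                         deme_sizes={"a": 5000})
        e, _ = demography.expected_sfs(model, {"a": 2}, 40_000, seed=3,
                                       snps_per_tree=10)
        # n = 4 haploids: e(1):e(2):e(3) proportional to 1, 1/2, 1/3
        expect = np.array([1, 0.5, 1 / 3])
        expect /= expect.sum()
        got = e[1:4]
        assert np.allclose(got, expect, atol=0.01)

    def test_proportions_sum_to_one(self):
        model = simdata.two_deme_model()
        e, _ = demography.expected_sfs(model, {"wild": 3, "dom": 3},
                                       5000, seed=1)
        assert e.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fixed_difference_mass_grows_with_split_time(self):
        masses = []
        for t in (1000, 10_000, 100_000):
            model = simdata.two_deme_model(t_split=t)
            e, _ = demography.expected_sfs(model, {"wild": 3, "dom": 3},
                                           20_000, seed=2)
            masses.append(e[6, 0] + e[0, 6])
        assert masses[0] < masses[1] < masses[2]


class TestCompositeLoglik:
    def test_proportional_obs_attains_multinomial_max(self):
        e = np.array([[0.0, 0.5], [0.3, 0.2]])
        obs = _toy_msfs(np.array([[0.0, 5.0], [3.0, 2.0]]), n_hap=(1, 1))
        lnl = demography.composite_loglik(obs, e)
        m = obs.counts[~obs.mask]
        manual = sum(x * math.log(x / 10) for x in m if x > 0)
        assert lnl == pytest.approx(manual, abs=1e-12)

    def test_single_cell_identity(self):
        obs = _toy_msfs(np.array([[0.0, 10.0], [0.0, 0.0]]), n_hap=(1, 1))
        e = np.array([[0.0, 1.0], [0.0, 0.0]])
        assert demography.composite_loglik(obs, e) == 0.0

    def test_hand_three_cell_value(self):
        obs = demography.MultiSFS(["a", "b"], (1, 2),
                                  np.array([[0.0, 5.0, 3.0],
                                            [2.0, 0.0, 0.0]]))
        e = np.array([[0.0, 0.5, 0.3], [0.2, 0.0, 0.0]])
        hand = 5 * math.log(0.5) + 3 * math.log(0.3) + 2 * math.log(0.2)
        assert demography.composite_loglik(obs, e) == pytest.approx(
            hand, abs=1e-10)
        assert hand == pytest.approx(-10.2965, abs=1e-3)

    def test_min_count_filters_cells(self):
        obs = demography.MultiSFS(["a", "b"], (1, 2),
                                  np.array([[0.0, 5.0, 0.5],
                                            [2.0, 0.0, 0.0]]))
        e = np.array([[0.0, 0.5, 0.3], [0.2, 0.05, 0.0]])
        lnl = demography.composite_loglik(obs, e, min_count=1)
        # the 0.5-count cell falls below the minimum SFS count of 1
        hand = 5 * math.log(0.5) + 2 * math.log(0.2)
        assert lnl == pytest.approx(hand, abs=1e-12)

    def test_all_below_min_count_raises(self):
        obs = _toy_msfs(np.zeros((2, 2)), n_hap=(1, 1))
        with pytest.raises(ValidationError):
            demography.composite_loglik(obs, np.full((2, 2), 0.25))

    def test_maximized_at_observed_proportions(self, rng):
        # numeric check of the multinomial maximum property
        for _ in range(5):
            m = rng.integers(1, 20, size=4).astype(float)
            counts = np.zeros((2, 3))
            counts.flat[[1, 2, 3, 4]] = m
            obs = demography.MultiSFS(["a", "b"], (1, 2), counts)
            best = counts / m.sum()
            lnl_best = demography.composite_loglik(obs, best)
            for _ in range(20):
                alt = rng.dirichlet(np.ones(4))
                e = np.zeros((2, 3))
                e.flat[[1, 2, 3, 4]] = alt
                assert demography.composite_loglik(obs, e) <= lnl_best \
                    + 1e-9


class TestModelBank:
    def test_six_scenarios_with_directional_migration(self):
        assert len(demography.SCENARIOS) == 6
        origins = {demography.SCENARIOS[s][0] for s in demography.SCENARIOS}
        flows = {demography.SCENARIOS[s][1] for s in demography.SCENARIOS}
        assert origins == {"jalisco", "southern"}
        assert flows == {"none", "continuous", "secondary_contact"}
        names = demography.scenario_param_names("jalisco_continuous")
        # independent migration rates per direction
        assert {"m_dom_wild", "m_wild_dom", "m_dom_far",
                "m_far_dom"} <= set(names)
        assert "t_contact" in demography.scenario_param_names(
            "southern_secondary")

    def test_constraint_forces_recent_domestication(self):
        with pytest.raises(ValidationError):
            simdata.domestication_model(t_wild=5000, t_dom=9000).validate()

    def test_aic_arithmetic(self):
        assert demography.aic(3, -100.0) == 206.0
        f1 = demography.FitResult("a", {}, -50.0, 4, demography.aic(4, -50),
                                  0, True, ("x",))
        f2 = demography.FitResult("b", {}, -50.0, 6, demography.aic(6, -50),
                                  0, True, ("x",))
        tab = demography.compare_models([f1, f2])
        assert tab["model"].iloc[0] == "a"
        assert tab["delta_aic"].iloc[1] == pytest.approx(4.0)

    def test_mixed_observations_raise(self):
        f1 = demography.FitResult("a", {}, -50.0, 4, 108, 0, True, ("x",))
        f2 = demography.FitResult("b", {}, -50.0, 4, 108, 0, True, ("y",))
        with pytest.raises(ValidationError):
            demography.compare_models([f1, f2])


def _anchored_obs(seed, n_loci=400):
    model = simdata.domestication_model(outgroup=True)
    params = simdata.SimParams(
        samples_per_deme={"jalisco": 6, "southern": 6, "dom": 6,
                          "moschata": 3},
        mutation_mode="rate", n_loci=n_loci, mu=1e-8, locus_len=500,
        seed=seed)
    G = simdata.emit_genotypes(simdata.simulate_coalescent(model, params),
                               1)
    obs = demography.polarize_and_build_msfs(
        G, ["jalisco", "southern", "dom"], "moschata")
    obs.n_loci_surveyed = n_loci
    obs.u_per_locus = 1e-8 * 500
    return obs


class TestFitting:
    def test_zero_cycles_returns_best_initial_draw(self):
        obs = _anchored_obs(5)
        fit = demography.fit_model(obs, "jalisco_none", n_cycles=0,
                                   sims_per_eval=2000, seed=1, n_init=6,
                                   outgroup_deme="moschata",
                                   outgroup_samples=3)
        # initial draws only (random draws plus moment-based candidates)
        assert 6 <= fit.n_evals <= 6 + 12
        for name in demography.scenario_param_names("jalisco_none"):
            lo, hi = demography.DEFAULT_PRIORS[name]
            assert lo <= fit.params[name] <= hi
        assert fit.params["t_dom"] <= fit.params["t_wild"]

    def test_truth_beats_distant_parameters(self):
        # composite likelihood prefers the generating parameters over a
        # parameter vector 10x off, in >= 9 of 10 seeds
        truth = dict(n_jalisco=15000, n_south=15000, n_dom=8000,
                     n_anc=20000, t_wild=15000, t_dom=8700,
                     m_dom_wild=2e-4, m_wild_dom=2e-4, m_dom_far=5e-5,
                     m_far_dom=5e-5, t_contact=2000)
        off = {k: (v / 10 if k.startswith(("n_", "t_")) else v)
               for k, v in truth.items()}
        off["t_contact"] = min(off["t_contact"], 0.9 * off["t_dom"])
        samples = {"jalisco": 6, "southern": 6, "dom": 6}
        wins = 0
        for seed in range(10):
            obs = _anchored_obs(700 + seed)

            def lnl(par):
                model = demography.scenario_model("jalisco_secondary",
                                                  par, outgroup=True)
                e, ml = demography.expected_sfs_polarized(
                    model, samples, "moschata", 3, 20_000, seed, 10)
                out = demography.composite_loglik(obs, e)
                lam = obs.n_loci_surveyed * obs.u_per_locus * ml
                return out + obs.total * math.log(lam) - lam

            wins += lnl(truth) > lnl(off)
        assert wins >= 9

    def test_single_population_size_recovery(self):
        """Grid search over N for a single-deme model (mutation-rate
        anchored) recovers the generating size within +-50% (median over
        10 seeds)."""
        truth_n = 8000.0
        grid = np.exp(np.linspace(np.log(500), np.log(60_000), 25))
        estimates = []
        for seed in range(10):
            n_loci = 300
            model = simdata.DemographicModel(pop_labels=["a"],
                                             deme_sizes={"a": truth_n})
            params = simdata.SimParams(samples_per_deme={"a": 10},
                                       mutation_mode="rate",
                                       n_loci=n_loci, mu=1e-8,
                                       locus_len=500, seed=400 + seed)
            G = simdata.emit_genotypes(
                simdata.simulate_coalescent(model, params), 1)
            counts = np.zeros(21)
            for s in range(G.n_sites):
                k = int(G.dosages[:, s].sum())
                if 0 < k < 20:
                    counts[k] += 1
            obs = demography.MultiSFS(["a"], (20,), counts)
            S = obs.total
            best, best_lnl = None, -np.inf
            for n_e in grid:
                m = simdata.DemographicModel(pop_labels=["a"],
                                             deme_sizes={"a": n_e})
                e, ml = demography.expected_sfs(m, {"a": 10}, 10_000,
                                                seed=77)
                lam = n_loci * 5e-6 * ml
                lnl = demography.composite_loglik(obs, e) \
                    + S * math.log(lam) - lam
                if lnl > best_lnl:
                    best, best_lnl = n_e, lnl
            estimates.append(best)
        med = float(np.median(estimates))
        assert 0.5 * truth_n <= med <= 1.5 * truth_n
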