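"""Outlier scans: multiple-testing helpers, convergence diagnostics,
PCA-Mahalanobis and latent-factor scans, the F-model MCMC, and the
multi-test consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cushaw import scans, simdata
from cushaw.core import ValidationError

from conftest import make_matrix, spike_all, star_genotypes, \
    two_deme_genotypes


class TestMultipleTesting:
    def test_bh_hand_stepup(self):
        q = scans.bh_qvalues([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert scans.bh_qvalues([0.2])[0] == pytest.approx(0.2)
        assert scans.bonferroni([0.2])[0] == pytest.approx(0.2)

    def test_bonferroni_cap(self):
        assert scans.bonferroni([0.04] + [1.0] * 99)[0] == 1.0

    def test_empty_input(self):
        assert scans.bh_qvalues([]).size == 0
        assert scans.bonferroni([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_bh_monotone_and_order_invariant(self, ps):
        p = np.array(ps)
        q = scans.bh_qvalues(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(p.size)
        q2 = scans.bh_qvalues(p[perm])
        assert np.allclose(np.sort(q), np.sort(q2))


class TestGelmanRubin:
    def test_identical_chains_degenerate(self):
        c = np.tile(np.full(50, 1.5), (2, 1))
        assert np.isnan(scans.gelman_rubin(c))

    def test_same_distribution_below_threshold(self):
        rng = np.random.default_rng(4)
        chains = rng.normal(0, 1, size=(2, 1000))
        assert scans.gelman_rubin(chains) < 1.1

    def test_offset_chains_and_hand_formula(self):
        rng = np.random.default_rng(5)
        chains = rng.normal(0, 1, size=(2, 10))
        chains[1] += 5.0
        got = scans.gelman_rubin(chains)
        n = 10
        w = chains.var(axis=1, ddof=1).mean()
        b_over_n = chains.mean(axis=1).var(ddof=1)
        hand = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert got == pytest.approx(hand, abs=1e-12)
        assert got > 1.5

    def test_too_few_chains_raise(self):
        with pytest.raises(ValidationError):
            scans.gelman_rubin(np.zeros((1, 100)))


class TestPcadapt:
    def test_unstructured_snp_not_flagged(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.4, size=(40, 300)).astype(np.int8)
        G = make_matrix(d)
        res = scans.pcadapt_scan(G, K=2)
        assert res.table["significant"].sum() <= 3
        # typical SNP uncorrelated with the PCs: modest statistic
        assert np.nanmedian(res.table["p"]) > 0.2

    def test_null_gif_and_uniformity(self):
        # panmictic bank of 5 seeds: lambda in [0.5, 2] and p-values
        # approximately uniform
        pvals = []
        for seed in range(5):
            model = simdata.DemographicModel(pop_labels=["a"],
                                             deme_sizes={"a": 10_000})
            params = simdata.SimParams(samples_per_deme={"a": 40},
                                       n_snps=600, seed=500 + seed)
            G = simdata.emit_genotypes(
                simdata.simulate_coalescent(model, params), 1)
            res = scans.pcadapt_scan(G, K=2)
            assert 0.5 <= res.extras["gif"] <= 2.0
            pvals.append(res.table["p"].dropna().to_numpy())
        ks = stats.kstest(np.concatenate(pvals), "uniform")
        assert ks.pvalue > 0.01

    def test_matches_classical_mahalanobis_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 50),
                         size=(25, 50)).astype(np.int8)
        G = make_matrix(d)
        res = scans.pcadapt_scan(G, K=2, robust=False, maf_min=0.0)
        # recompute z-scores and D^2 independently
        p_hat = d.mean(axis=0) / 2
        X = (d - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        proj = U[:, :2].T @ X
        resid = X - U[:, :2] @ proj
        sigma = np.sqrt((resid ** 2).sum(axis=0) / (25 - 2 - 1))
        T = (proj / sigma).T
        Z = stats.norm.ppf(np.clip(stats.t.cdf(T, 25 - 2 - 1),
                                   1e-300, 1 - 1e-16))
        mu = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False)
        delta = Z - mu
        d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)
        assert np.allclose(res.table["statistic"].to_numpy(), d2,
                           atol=1e-8)

    def test_constant_column_excluded(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.5, size=(30, 20)).astype(np.int8)
        d[:, 0] = 1
        G = make_matrix(d)
        res = scans.pcadapt_scan(G, K=2)
        assert np.isnan(res.table["p"].iloc[0])
        assert not res.table["significant"].iloc[0]
        assert res.extras["n_excluded"] >= 1

    def test_sample_order_invariance(self):
        G = two_deme_genotypes(61, n_snps=300, n_dip=10)
        r1 = scans.pcadapt_scan(G, K=2)
        perm = np.random.default_rng(1).permutation(G.n_samples)
        r2 = scans.pcadapt_scan(G.take_samples(perm), K=2)
        assert np.allclose(r1.table["statistic"].dropna(),
                           r2.table["statistic"].dropna(), atol=1e-6)


class TestLfmm:
    def test_reduces_to_ols(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.5, size=(30, 40)).astype(np.int8)
        G = make_matrix(d)
        env = rng.normal(size=30)
        res = scans.lfmm_scan(G, env, K=0, ridge_lambda=0.0)
        xc = env - env.mean()
        Y = d - d.mean(axis=0)
        B = (xc @ Y) / (xc @ xc)
        resid = Y - np.outer(xc, B)
        sigma = np.sqrt((resid ** 2).sum(axis=0) / (30 - 2))
        z = B / (sigma / np.sqrt(xc @ xc))
        assert np.allclose(res.table["statistic"].to_numpy(), z,
                           atol=1e-8)

    def test_constant_env_raises(self):
        G = make_matrix([[0, 1], [1, 0]])
        with pytest.raises(ValidationError):
            scans.lfmm_scan(G, [1.0, 1.0], K=0)

    def test_null_fdr_control(self):
        fracs = []
        for seed in range(5):
            G = two_deme_genotypes(70 + seed, n_snps=800, n_dip=20)
            env = np.random.default_rng(seed).permutation(
                [1.0 if p == "dom" else 0.0 for p in G.pops])
            res = scans.lfmm_scan(G, env, K=2)
            fracs.append(res.table["significant"].mean())
        assert np.median(fracs) <= 0.02

    def test_power_on_spiked_loci(self):
        # crossed design: two geographic clades (the latent structure,
        # K_true = 2) each holding a wild and a domesticated deme, so the
        # domestication contrast is not collinear with geography
        rates = []
        for seed in range(5):
            demes = ["g1w", "g1d", "g2w", "g2d"]
            model = simdata.DemographicModel(
                pop_labels=demes + ["a1", "a2", "anc"],
                deme_sizes={d: 10_000 for d in demes
                            + ["a1", "a2", "anc"]},
                split_events=[(600, "g1w", "a1"), (600, "g1d", "a1"),
                              (600, "g2w", "a2"), (600, "g2d", "a2"),
                              (3000, "a1", "anc"), (3000, "a2", "anc")])
            params = simdata.SimParams(
                samples_per_deme={d: 10 for d in demes}, n_snps=800,
                seed=80 + seed)
            G = simdata.emit_genotypes(
                simdata.simulate_coalescent(model, params), seed)
            rng = np.random.default_rng(seed)
            wf = G.allele_freq(np.isin(G.pops, ["g1w", "g2w"]))
            maf = np.minimum(G.allele_freq(), 1 - G.allele_freq())
            cand = np.flatnonzero((maf >= 0.1) & (wf <= 0.6))
            chosen = np.sort(rng.choice(cand, 10, replace=False))
            dos = G.dosages.copy()
            for deme in ("g1d", "g2d"):
                rows = np.flatnonzero(G.pops == deme)
                for s in chosen:
                    p = dos[rows, s].mean() / 2
                    p_new = p + 0.8 * (1 - p)
                    dos[rows, s] = rng.binomial(2, p_new, rows.size)
            Gs = make_matrix(dos, pops=G.pops, chrom=G.chrom, pos=G.pos)
            env = np.array([1.0 if p.endswith("d") else 0.0
                            for p in Gs.pops])
            res = scans.lfmm_scan(Gs, env, K=2)
            sig = set(res.table.loc[res.table["significant"], "snp_id"])
            spiked = set(Gs.site_ids[chosen])
            rates.append(len(sig & spiked) / 10)
        assert np.median(rates) >= 0.7


class TestBayescenv:
    small = dict(pilot_runs=4, pilot_len=200, burn_in=800,
                 sample_iters=1600, thin=8)

    def test_no_signal_low_env_posterior(self):
        rng = np.random.default_rng(11)
        n = np.full((100, 4), 40.0)
        p = rng.uniform(0.1, 0.9, 100)
        a = rng.binomial(40, p[:, None], size=(100, 4)).astype(float)
        env = np.array([0, 0, 1, 1.0])
        st1 = scans.bayescenv_scan(a, n, env, seeds=(1, 2), **self.small)
        assert (st1.post_env < 0.5).all()
        assert st1.result.table["significant"].sum() == 0

    def test_power_and_fpr_on_spiked_star_data(self):
        hits, fps = [], []
        for seed in (1, 2, 3):
            G, wdem, ddem = star_genotypes(900 + seed, n_snps=300)
            rng = np.random.default_rng(seed)
            wildfreq = G.allele_freq(np.isin(G.pops, wdem))
            cand = np.flatnonzero((wildfreq >= 0.2) & (wildfreq <= 0.6))
            chosen = np.sort(rng.choice(cand, 10, replace=False))
            Gs = spike_all(G, ddem, chosen)
            state = scans.bayescenv_scan_genotypes(
                Gs, ddem, pilot_runs=6, pilot_len=250, burn_in=1500,
                sample_iters=4000, thin=10)
            sig = state.result.table["significant"].to_numpy()
            hits.append(sig[chosen].sum())
            fps.append(sig.sum() - sig[chosen].sum())
        assert np.median(hits) >= 8
        assert np.median(fps) <= 0.02 * 290

    def test_sampling_length_stability(self):
        G, wdem, ddem = star_genotypes(77, n_snps=200)
        rng = np.random.default_rng(3)
        wildfreq = G.allele_freq(np.isin(G.pops, wdem))
        cand = np.flatnonzero((wildfreq >= 0.2) & (wildfreq <= 0.6))
        chosen = np.sort(rng.choice(cand, 8, replace=False))
        Gs = spike_all(G, ddem, chosen)
        kw = dict(pilot_runs=5, pilot_len=250, burn_in=1200, thin=8)
        s1 = scans.bayescenv_scan_genotypes(Gs, ddem, sample_iters=2400,
                                            **kw)
        s2 = scans.bayescenv_scan_genotypes(Gs, ddem, sample_iters=4800,
                                            **kw)
        f1 = set(s1.result.table.loc[s1.result.table["significant"],
                                     "snp_id"])
        f2 = set(s2.result.table.loc[s2.result.table["significant"],
                                     "snp_id"])
        union = f1 | f2
        jacc = len(f1 & f2) / len(union) if union else 1.0
        assert jacc >= 0.75

    def test_convergence_diagnostics_reported(self):
        G = two_deme_genotypes(88, n_snps=120, n_dip=8)
        state = scans.bayescenv_scan_genotypes(G, ["dom"], **self.small)
        assert set(state.rhat) >= {"beta_0", "beta_1", "loglik"}
        assert isinstance(state.converged, bool)


class TestConsensus:
    @staticmethod
    def _result(name, flags):
        tab = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(len(flags))],
            "statistic": 0.0, "p": 0.5, "adjusted": 0.5,
            "significant": flags})
        return scans.ScanResult(name, tab)

    def test_all_three_is_candidate(self):
        rs = [self._result(n, [True]) for n in ("a", "b", "c")]
        out = scans.consensus_candidates(rs)
        assert out["candidate"].iloc[0]

    def test_single_test_is_not(self):
        rs = [self._result("a", [True]), self._result("b", [False]),
              self._result("c", [False])]
        out = scans.consensus_candidates(rs)
        assert not out["candidate"].iloc[0]

    def test_matches_set_logic_oracle(self, rng):
        flags = rng.random((3, 50)) < 0.3
        rs = [self._result(n, flags[i])
              for i, n in enumerate(("a", "b", "c"))]
        out = scans.consensus_candidates(rs, min_tests=2)
        oracle = flags.sum(axis=0) >= 2
        assert np.array_equal(out["candidate"].to_numpy(), oracle)

    def test_mismatched_indices_raise(self):
        r1 = self._result("a", [True, False])
        r2 = self._result("b", [True])
        with pytest.raises(ValidationError):
            scans.consensus_candidates([r1, r2])
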