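"""Wild-vs-domesticated outlier scans and the multi-test consensus.

Three complementary tests: a hierarchical F-model MCMC with a 0/1
domestication covariate per population (q < 0.05), a PCA-based Mahalanobis
outlier scan controlling for the leading principal components
(genomic-inflation-corrected, Bonferroni p < 0.05), and a latent-factor
ridge association scan with the covariate per sample (FDR q < 0.05).
Candidates are SNPs flagged by at least two tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _fmodel
from .core import GenotypeMatrix, ValidationError
from .diversity import genotype_pca


@dataclass
class ScanResult:
    test: str
    table: pd.DataFrame           # snp_id, statistic, p, adjusted, significant
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# multiple-testing helpers


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def bonferroni(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.minimum(1.0, p * p.size)


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` is (n_chains, n_draws).  Zero within-chain variance in all
    chains gives NaN.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 10:
        raise ValidationError("need >= 2 chains of equal length >= 10")
    n = c.shape[1]
    w = c.var(axis=1, ddof=1).mean()
    b_over_n = c.mean(axis=1).var(ddof=1)
    if w == 0:
        return float("nan")
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# the F-model MCMC scan


@dataclass
class BayesScanState:
    result: ScanResult
    post_env: np.ndarray          # posterior P(env model) per locus
    post_locus: np.ndarray
    beta: np.ndarray              # posterior-mean population effects
    rhat: dict                    # Gelman-Rubin per monitored parameter
    converged: bool
    proposal_sds: dict


def pop_allele_counts(G: GenotypeMatrix, pops: list):
    """Derived counts and non-missing allele totals per locus x pop."""
    a = np.zeros((G.n_sites, len(pops)))
    n = np.zeros_like(a)
    for j, pop in enumerate(pops):
        d = G.dosages[G.pops == pop]
        ok = d >= 0
        a[:, j] = np.where(ok, d, 0).sum(axis=0)
        n[:, j] = 2 * ok.sum(axis=0)
    return a, n


def _pep_qvalues(pep: np.ndarray) -> np.ndarray:
    """q-values as running means of sorted posterior error probabilities."""
    order = np.argsort(pep, kind="mergesort")
    q_sorted = np.cumsum(pep[order]) / np.arange(1, pep.size + 1)
    out = np.empty_like(pep)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


def bayescenv_scan(allele_counts, allele_totals, env, snp_ids=None,
                   pilot_runs: int = 20, pilot_len: int = 10_000,
                   burn_in: int = 100_000, sample_iters: int = 100_000,
                   thin: int = 20, seeds=(1, 2), alpha: float = 0.05,
                   prior_alpha_sd: float = 3.0, prior_g_sd: float = 3.0,
                   prior_beta_mean: float = -1.0,
                   prior_beta_sd: float = 1.8,
                   prior_odds_neutral: float = 10.0,
                   beta_every: int = 1, rhat_max: float = 1.1
                   ) -> BayesScanState:
    """F-model MCMC with an environmental (wild=0 / domesticated=1) model.

    Two independent chains are run; pilot runs tune the proposal widths
    towards 25-45% acceptance; q-values come from the sorted posterior
    error probabilities of the environmental model and loci with q < alpha
    are flagged.  Convergence between the chains is checked with the
    Gelman-Rubin statistic on the population effects and the
    log-likelihood; a non-convergent run is flagged, not silently passed.
    """
    a = np.asarray(allele_counts, dtype=np.float64)
    n = np.asarray(allele_totals, dtype=np.float64)
    E = np.asarray(env, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValidationError("need allele counts for >= 2 populations")
    if E.shape[0] != a.shape[1]:
        raise ValidationError("env length must equal the population count")
    L, P = a.shape
    if snp_ids is None:
        snp_ids = np.array([f"snp{i}" for i in range(L)])
    p_alt = 1.0 / (2.0 + prior_odds_neutral)
    logp_m = np.log(np.array([prior_odds_neutral * p_alt, p_alt, p_alt]))
    n_samples = sample_iters // thin
    chain_env = np.empty((len(seeds), L))
    chain_locus = np.empty((len(seeds), L))
    beta_traces = []
    lnl_traces = []
    beta_means = []
    sds_used = {}
    for ci, seed in enumerate(seeds):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed),
                                                            0xB5]))
        # initial state: moment-matched pi, neutral indicators
        with np.errstate(invalid="ignore", divide="ignore"):
            pobs = np.where(n.sum(1) > 0, a.sum(1) / np.maximum(n.sum(1), 1),
                            0.5)
        pi = np.clip(pobs + rng.normal(0, 0.01, L), 1e-3, 1 - 1e-3)
        alpha_v = rng.normal(0, 0.1, L)
        g_v = rng.normal(0, 0.1, L)
        beta = np.full(P, prior_beta_mean) + rng.normal(0, 0.1, P)
        mcur = np.zeros(L, dtype=np.int64)
        ll = np.empty((L, P))
        sd = {"pi": 0.3, "alpha": 0.5, "g": 0.5, "beta": 0.1}
        kseed = int(np.random.SeedSequence([int(seed), 0xC4]).generate_state(
            1, dtype=np.uint32)[0] >> 1)
        dummy_pc = np.zeros((L, 3), dtype=np.int64)
        dummy_bt = np.empty((1, P))
        dummy_lt = np.empty(1)
        for pr in range(pilot_runs):
            acc = np.zeros((4, 2), dtype=np.int64)
            _fmodel.run_chain(a, n, E, pi, alpha_v, g_v, beta, mcur, ll,
                              pilot_len, False, thin,
                              sd["pi"], sd["alpha"], sd["g"], sd["beta"],
                              prior_alpha_sd, prior_g_sd, prior_beta_mean,
                              prior_beta_sd, logp_m, beta_every,
                              (kseed + pr) % (2 ** 31),
                              dummy_pc, dummy_bt, dummy_lt, acc)
            for bi, name in enumerate(("pi", "alpha", "g", "beta")):
                if acc[bi, 1] == 0:
                    continue
                rate = acc[bi, 0] / acc[bi, 1]
                if rate < 0.25:
                    sd[name] *= 0.7
                elif rate > 0.45:
                    sd[name] *= 1.4
        sds_used[f"chain{ci}"] = dict(sd)
        acc = np.zeros((4, 2), dtype=np.int64)
        _fmodel.run_chain(a, n, E, pi, alpha_v, g_v, beta, mcur, ll,
                          burn_in, False, thin,
                          sd["pi"], sd["alpha"], sd["g"], sd["beta"],
                          prior_alpha_sd, prior_g_sd, prior_beta_mean,
                          prior_beta_sd, logp_m, beta_every,
                          (kseed + 7777) % (2 ** 31),
                          dummy_pc, dummy_bt, dummy_lt, acc)
        post_counts = np.zeros((L, 3), dtype=np.int64)
        beta_trace = np.empty((n_samples, P))
        lnl_trace = np.empty(n_samples)
        acc = np.zeros((4, 2), dtype=np.int64)
        n_rec = _fmodel.run_chain(a, n, E, pi, alpha_v, g_v, beta, mcur, ll,
                                  sample_iters, True, thin,
                                  sd["pi"], sd["alpha"], sd["g"], sd["beta"],
                                  prior_alpha_sd, prior_g_sd,
                                  prior_beta_mean, prior_beta_sd, logp_m,
                                  beta_every, (kseed + 31337) % (2 ** 31),
                                  post_counts, beta_trace, lnl_trace, acc)
        tot = post_counts.sum(axis=1)
        chain_env[ci] = post_counts[:, _fmodel.M_ENV] / np.maximum(tot, 1)
        chain_locus[ci] = post_counts[:, _fmodel.M_LOCUS] / np.maximum(tot, 1)
        beta_traces.append(beta_trace[:n_rec])
        lnl_traces.append(lnl_trace[:n_rec])
        beta_means.append(beta_trace[:n_rec].mean(axis=0))
    post_env = chain_env.mean(axis=0)
    post_locus = chain_locus.mean(axis=0)
    rhat = {}
    n_common = min(t.shape[0] for t in beta_traces)
    for j in range(P):
        rhat[f"beta_{j}"] = gelman_rubin(
            np.stack([t[:n_common, j] for t in beta_traces]))
    rhat["loglik"] = gelman_rubin(
        np.stack([t[:n_common] for t in lnl_traces]))
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = all(v < rhat_max for v in finite) if finite else True
    pep = 1.0 - post_env
    q = _pep_qvalues(pep)
    table = pd.DataFrame({
        "snp_id": snp_ids, "statistic": post_env, "p": pep, "adjusted": q,
        "significant": q < alpha})
    result = ScanResult("bayescenv", table,
                        {"converged": converged, "rhat": rhat})
    return BayesScanState(result, post_env, post_locus,
                          np.mean(beta_means, axis=0), rhat, converged,
                          sds_used)


def bayescenv_scan_genotypes(G: GenotypeMatrix, domesticated_pops,
                             **kwargs) -> BayesScanState:
    pops = G.pop_names()
    a, n = pop_allele_counts(G, pops)
    env = np.array([1.0 if p in set(domesticated_pops) else 0.0
                    for p in pops])
    return bayescenv_scan(a, n, env, snp_ids=G.site_ids, **kwargs)


# ---------------------------------------------------------------------------
# PCA Mahalanobis scan


def pcadapt_scan(G: GenotypeMatrix, K: int = 2, alpha: float = 0.05,
                 robust: bool = True, maf_min: float = 0.05) -> ScanResult:
    """Mahalanobis outlier scan on per-SNP z-scores against K PCs.

    Each SNP's scaled dosages are regressed on the first K principal-
    component scores; the K z-scores are combined into a robust
    Mahalanobis distance, rescaled by the genomic inflation factor
    (median D^2 over the chi-squared_K median), and converted to
    Bonferroni-adjusted chi-squared_K p-values.  Sites below ``maf_min``
    are excluded from the test (their z-scores are too heavy-tailed for
    the chi-squared calibration) and reported with NaN p-values.
    """
    if G.n_samples <= K:
        raise ValidationError("need more samples than components")
    p_hat = G.allele_freq()
    mean = 2 * p_hat
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.sqrt(2 * p_hat * (1 - p_hat))
    with np.errstate(invalid="ignore"):
        obs_var = np.nanvar(np.where(G.dosages >= 0,
                                     G.dosages.astype(float), np.nan),
                            axis=0)
    valid = (np.isfinite(scale) & (scale > 0) & (obs_var > 0)
             & (np.minimum(p_hat, 1 - p_hat) >= maf_min))
    d = np.where(G.dosages >= 0, G.dosages.astype(float), mean[None, :])
    X = (d[:, valid] - mean[valid]) / scale[valid]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    Uk = U[:, :K]
    proj = Uk.T @ X                       # K x p
    ss_tot = (X ** 2).sum(axis=0)
    resid_ss = np.maximum(ss_tot - (proj ** 2).sum(axis=0), 1e-12)
    dof = max(G.n_samples - K - 1, 1)
    sigma = np.sqrt(resid_ss / dof)
    T = (proj / sigma).T                  # p x K, t-distributed under null
    # map through the t CDF to normal quantiles so the Mahalanobis
    # distance is chi-squared calibrated at small sample sizes
    Z = stats.norm.ppf(np.clip(stats.t.cdf(T, dof), 1e-300, 1 - 1e-16))
    if robust:
        center, cov = _robust_location_cov(Z)
    else:
        center = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False)
    delta = Z - center
    d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)
    gif = float(np.median(d2) / stats.chi2.ppf(0.5, K))
    pvals = stats.chi2.sf(d2 / gif, K)
    stat = np.full(G.n_sites, np.nan)
    p_full = np.full(G.n_sites, np.nan)
    stat[valid] = d2
    p_full[valid] = pvals
    adj = np.full(G.n_sites, np.nan)
    adj[valid] = bonferroni(pvals)
    table = pd.DataFrame({
        "snp_id": G.site_ids, "statistic": stat, "p": p_full,
        "adjusted": adj,
        "significant": np.where(np.isfinite(adj), adj < alpha, False)})
    return ScanResult("pcadapt", table,
                      {"gif": gif, "n_excluded": int((~valid).sum())})


def _robust_location_cov(Z: np.ndarray):
    """Robust location/scatter of the z-score cloud: minimum covariance
    determinant when enough SNPs are available, else median/MAD."""
    if Z.shape[0] >= 25 * Z.shape[1]:
        from sklearn.covariance import MinCovDet
        mcd = MinCovDet(random_state=0).fit(Z)
        cov = mcd.covariance_
        if np.linalg.det(cov) > 1e-300:
            return mcd.location_, cov
    med = np.median(Z, axis=0)
    mad = np.median(np.abs(Z - med), axis=0) * 1.4826
    mad = np.maximum(mad, 1e-12)
    return med, np.diag(mad ** 2)


# ---------------------------------------------------------------------------
# latent-factor ridge scan


def lfmm_scan(G: GenotypeMatrix, env_per_sample, K: int = 6,
              ridge_lambda: float = 1e-5, alpha: float = 0.05
              ) -> ScanResult:
    """Latent-factor ridge association between dosages and the covariate.

    Latent factors are the top-K SVD factors of the genotype matrix after
    projecting out the covariate; effect sizes come from a ridge
    regression of the residualized genotypes on the covariate; z-scores
    are recalibrated with the genomic inflation factor and converted to
    Benjamini-Hochberg q-values.
    """
    x = np.asarray(env_per_sample, dtype=float)
    if x.std() == 0:
        raise ValidationError("environmental covariate has no contrast")
    if G.n_samples <= K + 1:
        raise ValidationError("need n_samples > K + 1")
    d = G.dosages.astype(float)
    col_mean = np.where(G.dosages >= 0, d, np.nan)
    mean = np.nanmean(col_mean, axis=0)
    d = np.where(G.dosages >= 0, d, mean[None, :])
    Y = d - d.mean(axis=0)
    xc = x - x.mean()
    xtx = float(xc @ xc)
    if K > 0:
        P = np.eye(G.n_samples) - np.outer(xc, xc) / xtx
        U, s, Vt = np.linalg.svd(P @ Y, full_matrices=False)
        W = (U[:, :K] * s[:K]) @ Vt[:K]
    else:
        W = np.zeros_like(Y)
    R = Y - W
    B = (xc @ R) / (xtx + ridge_lambda)
    resid = R - np.outer(xc, B)
    dof = max(G.n_samples - K - 2, 1)
    sigma = np.sqrt((resid ** 2).sum(axis=0) / dof)
    se = sigma / np.sqrt(xtx)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = B / se
    z[~np.isfinite(z)] = 0.0
    gif = float(np.median(z ** 2) / stats.chi2.ppf(0.5, 1))
    gif = max(gif, 1e-12)
    pvals = stats.chi2.sf(z ** 2 / gif, 1)
    q = bh_qvalues(pvals)
    table = pd.DataFrame({
        "snp_id": G.site_ids, "statistic": z, "p": pvals, "adjusted": q,
        "significant": q < alpha})
    return ScanResult("lfmm", table, {"gif": gif})


# ---------------------------------------------------------------------------
# consensus


def consensus_candidates(results: list, min_tests: int = 2) -> pd.DataFrame:
    """SNPs significant in at least ``min_tests`` of the scans.

    All results must share the SNP index.  Returns the per-test flags and
    the consensus flag per SNP.
    """
    if not results:
        raise ValidationError("no scan results supplied")
    ids = results[0].table["snp_id"].to_numpy()
    out = pd.DataFrame({"snp_id": ids})
    for r in results:
        rid = r.table["snp_id"].to_numpy()
        if rid.shape != ids.shape or not np.array_equal(rid, ids):
            raise ValidationError("scan results have mismatched SNP indices")
        out[r.test] = r.table["significant"].to_numpy().astype(bool)
    tests = [r.test for r in results]
    out["n_tests"] = out[tests].sum(axis=1)
    out["candidate"] = out["n_tests"] >= min_tests
    return out
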