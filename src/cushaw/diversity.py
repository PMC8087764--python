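"""Diversity and structure statistics.

Per-SNP nucleotide diversity (unbiased expected heterozygosity), the
Weir & Cockerham (1984) F_ST estimator with a loci-bootstrap confidence
interval, and genotype PCA with Patterson scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, ValidationError


@dataclass
class DiversityResult:
    pop: str
    per_site_pi: np.ndarray      # NaN where < 2 non-missing alleles
    mean_pi: float
    n_sites_used: int


@dataclass
class FstResult:
    pops: list
    a: np.ndarray                # among-population variance component
    b: np.ndarray                # among individuals within populations
    c: np.ndarray                # within individuals
    per_locus: np.ndarray        # a / (a+b+c), NaN where undefined
    theta: float                 # multilocus ratio of sums
    ci: tuple | None = None


def nucleotide_diversity(G: GenotypeMatrix, pop: str) -> DiversityResult:
    """Unbiased per-SNP pi for one population; mean over usable sites.

    pi_site = n/(n-1) * 2 p (1-p) with n the non-missing allele count.
    The population mean averages over every site with n >= 2 (per-SNP
    convention: magnitudes ~0.1 on SNP panels, not per-bp diversity).
    """
    if pop not in G.pops:
        raise ValidationError(f"population {pop} absent")
    mask = G.pops == pop
    d = G.dosages[mask]
    ok = d >= 0
    n = 2 * ok.sum(axis=0)
    derived = np.where(ok, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = derived / n
        pi = n / (n - 1) * 2 * p * (1 - p)
    pi = np.where(n >= 2, pi, np.nan)
    usable = np.isfinite(pi)
    mean = float(np.nanmean(pi)) if usable.any() else float("nan")
    return DiversityResult(pop, pi, mean, int(usable.sum()))


def _wc_components(G: GenotypeMatrix, pops: list):
    """Weir & Cockerham (1984) per-locus variance components a, b, c."""
    r = len(pops)
    S = G.n_sites
    n_i = np.zeros((r, S))
    p_i = np.zeros((r, S))
    h_i = np.zeros((r, S))
    for k, pop in enumerate(pops):
        d = G.dosages[G.pops == pop]
        ok = d >= 0
        n_i[k] = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[k] = np.where(ok, d, 0).sum(axis=0) / (2 * n_i[k])
            h_i[k] = np.where(ok, d == 1, False).sum(axis=0) / n_i[k]
    usable = (n_i >= 1).all(axis=0) & (n_i.sum(axis=0) > r)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        nc = (r * nbar - (n_i ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    for arr in (a, b, c):
        arr[~usable] = np.nan
    return a, b, c


def wc_fst(G: GenotypeMatrix, pops: list | None = None) -> FstResult:
    """Multilocus Weir-Cockerham theta as a ratio of summed components.

    Loci with zero total variance (or without data in every population)
    are skipped in the sums.
    """
    pops = list(pops) if pops is not None else G.pop_names()
    if len(pops) < 2:
        raise ValidationError("need at least 2 populations")
    a, b, c = _wc_components(G, pops)
    tot = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / tot
    use = np.isfinite(tot) & (tot != 0)
    if not use.any():
        raise ValidationError("no usable loci for F_ST")
    theta = float(a[use].sum() / tot[use].sum())
    return FstResult(pops, a, b, c, per_locus, theta)


def bootstrap_fst_ci(G: GenotypeMatrix, pops: list | None = None,
                     n_boot: int = 100, level: float = 0.95,
                     seed: int = 0) -> tuple:
    """Percentile bootstrap CI over loci for the multilocus theta."""
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if G.n_sites < 2:
        raise ValidationError("need >= 2 loci to bootstrap")
    pops = list(pops) if pops is not None else G.pop_names()
    a, b, c = _wc_components(G, pops)
    tot = a + b + c
    use = np.isfinite(tot) & (tot != 0)
    a, tot = a[use], tot[use]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF57]))
    n = a.size
    thetas = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        thetas[i] = a[idx].sum() / tot[idx].sum()
    alpha = (1 - level) / 2
    lo, hi = np.quantile(thetas, [alpha, 1 - alpha])
    return float(lo), float(hi)


def pairwise_fst_table(G: GenotypeMatrix, pops: list | None = None,
                       n_boot: int = 100, level: float = 0.95,
                       seed: int = 0) -> pd.DataFrame:
    pops = list(pops) if pops is not None else G.pop_names()
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pair = [pops[i], pops[j]]
            res = wc_fst(G, pair)
            lo, hi = bootstrap_fst_ci(G, pair, n_boot=n_boot, level=level,
                                      seed=seed)
            rows.append({"pop1": pops[i], "pop2": pops[j],
                         "fst": res.theta, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def genotype_pca(G: GenotypeMatrix, n_components: int = 10):
    """PCA of the genotype matrix with Patterson scaling.

    Sites are centred by 2 p-hat and scaled by sqrt(2 p-hat (1 - p-hat));
    missing dosages are mean-imputed per site before scaling.  Returns
    (scores, loadings, explained_variance_ratio).
    """
    if G.n_samples < 2:
        raise ValidationError("need at least 2 samples for PCA")
    d = G.dosages.astype(float)
    p = G.allele_freq()
    mean = 2 * p
    d = np.where(G.dosages >= 0, d, mean[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.sqrt(2 * p * (1 - p))
    keep = np.isfinite(scale) & (scale > 0)
    X = (d[:, keep] - mean[keep]) / scale[keep]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, s.size)
    evr = s ** 2 / (s ** 2).sum()
    return U[:, :k] * s[:k], Vt[:k].T, evr[:k]
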