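"""ABBA-BABA introgression statistics and candidate-SNP polarization.

Frequency-weighted Patterson's D over the fixed (((P1, P2), P3), O)
arrangement, block-jackknife significance, the f_G admixture fraction
(donor proxy from random halves of the P3 sample), sliding SNP-window
local D, and the classification of candidate SNPs into selection-direction
and ABBA/BABA categories using outgroup-based polarization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

LABELS = ("sel_domesticated", "sel_wild", "ABBA", "BABA", "unknown")


@dataclass
class DStatResult:
    d: float
    abba: np.ndarray
    baba: np.ndarray
    n_sites: int
    n_dropped: int
    se: float | None = None
    z: float | None = None
    p: float | None = None
    f_g: float | None = None
    windows: pd.DataFrame | None = None


def site_weights(p1, p2, p3, p4):
    """Per-site ABBA and BABA weights from derived-allele frequencies."""
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def d_statistic(freqs: pd.DataFrame, cols=("p1", "p2", "p3", "p4")
                ) -> DStatResult:
    """Genome-wide frequency-weighted D.

    ``freqs`` holds derived-allele frequencies per site for the four taxa;
    rows with a missing frequency are dropped and counted.
    """
    sub = freqs.loc[:, list(cols)].astype(float)
    ok = sub.notna().all(axis=1).to_numpy()
    dropped = int((~ok).sum())
    p1, p2, p3, p4 = (sub.loc[ok, c].to_numpy() for c in cols)
    for arr in (p1, p2, p3, p4):
        if np.any((arr < 0) | (arr > 1)):
            raise ValidationError("frequencies must lie in [0, 1]")
    abba, baba = site_weights(p1, p2, p3, p4)
    den = abba.sum() + baba.sum()
    if den == 0:
        warnings.warn("zero ABBA+BABA denominator; D undefined")
        d = float("nan")
    else:
        d = float((abba.sum() - baba.sum()) / den)
    return DStatResult(d, abba, baba, int(ok.sum()), dropped)


def block_jackknife(abba: np.ndarray, baba: np.ndarray,
                    block_assignment: np.ndarray):
    """Delete-one-block weighted jackknife for D; returns (se, z, p).

    Blocks are weighted by their share of the ABBA+BABA denominator
    (Busing et al. delete-m_j jackknife).  With degenerate (zero) variance
    the p-value is reported as 0 with a warning.
    """
    abba = np.asarray(abba, float)
    baba = np.asarray(baba, float)
    blocks = pd.unique(np.asarray(block_assignment))
    if len(blocks) < 5:
        raise ValidationError("need >= 5 non-empty blocks for the jackknife")
    num_tot = abba.sum() - baba.sum()
    den_tot = abba.sum() + baba.sum()
    d_hat = num_tot / den_tot
    B = len(blocks)
    d_del = np.empty(B)
    m = np.empty(B)
    for i, b in enumerate(blocks):
        sel = np.asarray(block_assignment) == b
        num_b = abba[sel].sum() - baba[sel].sum()
        den_b = abba[sel].sum() + baba[sel].sum()
        m[i] = den_b
        d_del[i] = (num_tot - num_b) / (den_tot - den_b)
    M = den_tot
    h = M / np.maximum(m, 1e-300)
    d_jack = B * d_hat - np.sum((1 - m / M) * d_del)
    tau = h * d_hat - (h - 1) * d_del
    var = np.sum((tau - d_jack) ** 2 / (h - 1)) / B
    se = float(np.sqrt(var))
    if se == 0:
        warnings.warn("degenerate jackknife variance (all blocks identical)")
        return 0.0, float("inf"), 0.0
    z = float(d_hat / se)
    p = float(2 * stats.norm.sf(abs(z)))
    return se, z, p


def equal_snp_blocks(n_sites: int, n_blocks: int) -> np.ndarray:
    """Contiguous equal-SNP-count block assignment."""
    return np.minimum(np.arange(n_sites) * n_blocks // max(n_sites, 1),
                      n_blocks - 1)


def f_admixture(counts: pd.DataFrame, seed: int = 0,
                cols=("p1", "p2", "p3", "p4"),
                p3_counts=("p3_der", "p3_n")) -> float:
    """f_G admixture fraction with P3 split into random halves.

    ``counts`` needs derived-allele frequencies for the four taxa plus the
    derived count and haploid sample size of P3 (``p3_der``, ``p3_n``) so
    its alleles can be halved per site (seeded hypergeometric split).
    f_G = S(p1, p2, p3a, p4) / S(p1, p3b, p3a, p4) with S the ABBA-BABA
    numerator sum.
    """
    need = list(cols) + list(p3_counts)
    counts = counts.loc[counts[need].notna().all(axis=1)]
    der = counts[p3_counts[0]].to_numpy(dtype=float)
    n3 = counts[p3_counts[1]].to_numpy(dtype=float)
    if np.any(n3 < 2):
        raise ValidationError("P3 needs >= 2 sampled alleles at every site")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF6]))
    n_a = (n3 // 2).astype(int)
    k_a = rng.hypergeometric(der.astype(int), (n3 - der).astype(int), n_a)
    p3a = k_a / n_a
    p3b = (der - k_a) / (n3 - n_a)
    p1 = counts[cols[0]].to_numpy(dtype=float)
    p2 = counts[cols[1]].to_numpy(dtype=float)
    p4 = counts[cols[3]].to_numpy(dtype=float)
    a_num, b_num = site_weights(p1, p2, p3a, p4)
    a_den, b_den = site_weights(p1, p3b, p3a, p4)
    den = a_den.sum() - b_den.sum()
    if den == 0:
        warnings.warn("zero f_G denominator")
        return float("nan")
    return float((a_num.sum() - b_num.sum()) / den)


def windowed_d(abba: np.ndarray, baba: np.ndarray, window: int = 500,
               step: int = 250) -> pd.DataFrame:
    """Local D in sliding SNP-count windows (trailing partial reported)."""
    abba = np.asarray(abba, float)
    baba = np.asarray(baba, float)
    n = abba.size
    rows = []
    start = 0
    while start < n:
        end = min(start + window, n)
        a = abba[start:end].sum()
        b = baba[start:end].sum()
        d = (a - b) / (a + b) if (a + b) > 0 else float("nan")
        rows.append({"start": start, "end": end, "n_snps": end - start,
                     "partial": end - start < window, "d": d})
        if end == n:
            break
        start += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidate classification


@dataclass
class CandidateClassification:
    snp_id: str
    label: str
    ancestral: str | None
    derived_freqs: dict = field(default_factory=dict)


def _ancestral_from_outgroups(out_freqs) -> str | None:
    """Ancestral allele ('ref'/'alt') from outgroup ALT frequencies.

    Each available outgroup must be monomorphic; all available outgroups
    must agree; otherwise None.
    """
    calls = []
    for f in out_freqs:
        if f is None or (isinstance(f, float) and np.isnan(f)):
            continue
        if f == 0:
            calls.append("ref")
        elif f == 1:
            calls.append("alt")
        else:
            return None
    if not calls or len(set(calls)) > 1:
        return None
    return calls[0]


def classify_candidates(freq_table: pd.DataFrame, hi: float = 0.8,
                        lo: float = 0.2) -> list:
    """Classify candidate SNPs by selection direction or ABBA/BABA state.

    ``freq_table`` columns: snp_id, alt frequency in the wild subspecies
    (``wild_alt``), the domesticate (``dom_alt``), the sister species
    (``sister_alt``), and one or two outgroup ALT frequencies
    (``out1_alt``, optional ``out2_alt``).  The outgroup fixes the
    ancestral allele; derived frequencies d_wild, d_dom, d_sister then
    drive the labels: ABBA (d_dom, d_sister high, d_wild low) and BABA
    (d_wild, d_sister high, d_dom low) take precedence over
    sel_domesticated (d_dom high, d_wild low) and sel_wild (d_wild high,
    d_dom low); anything else, or an undetermined ancestral state, is
    unknown.
    """
    if not (0 <= lo < hi <= 1):
        raise ValidationError("need 0 <= lo < hi <= 1")
    out = []
    has_out2 = "out2_alt" in freq_table.columns
    for _, row in freq_table.iterrows():
        outs = [row.get("out1_alt")]
        if has_out2:
            outs.append(row.get("out2_alt"))
        anc = _ancestral_from_outgroups(outs)
        if anc is None or any(
                pd.isna(row[c]) for c in ("wild_alt", "dom_alt",
                                          "sister_alt")):
            out.append(CandidateClassification(str(row["snp_id"]),
                                               "unknown", anc))
            continue
        flip = anc == "alt"
        d_w = 1 - row["wild_alt"] if flip else row["wild_alt"]
        d_d = 1 - row["dom_alt"] if flip else row["dom_alt"]
        d_m = 1 - row["sister_alt"] if flip else row["sister_alt"]
        if d_d >= hi and d_m >= hi and d_w <= lo:
            label = "ABBA"
        elif d_w >= hi and d_m >= hi and d_d <= lo:
            label = "BABA"
        elif d_d >= hi and d_w <= lo:
            label = "sel_domesticated"
        elif d_w >= hi and d_d <= lo:
            label = "sel_wild"
        else:
            label = "unknown"
        out.append(CandidateClassification(
            str(row["snp_id"]), label, anc,
            {"wild": d_w, "dom": d_d, "sister": d_m}))
    return out


def classification_counts(classifications: list) -> dict:
    counts = {lab: 0 for lab in LABELS}
    for c in classifications:
        counts[c.label] += 1
    return counts
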