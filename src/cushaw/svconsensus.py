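"""Dual-caller structural-variant consensus and downstream gene analysis.

Two call sets (e.g. a whole-genome-alignment caller and a long-read
caller) are intersected with a +/-100 bp endpoint rule; consensus SVs are
assigned genes by overlap (inversions, translocations) or containment
(CNVs, unaligned regions); gene sets are tested for term enrichment with
one-sided Fisher exact tests.  Coordinates are 1-based inclusive
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import ValidationError

MATCHABLE_TYPES = ("CNV_gain", "CNV_loss", "inversion", "translocation")
CONTAINMENT_TYPES = ("CNV_gain", "CNV_loss", "unaligned")
SV_COLUMNS = ["caller", "chrom", "start", "end", "type", "id", "chrom2",
              "start2", "end2", "support"]


def _dedup(callset: pd.DataFrame, name: str) -> pd.DataFrame:
    key = ["chrom", "start", "end", "type"]
    dup = callset.duplicated(subset=key)
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate records removed from "
                      f"call set {name}")
        callset = callset[~dup]
    return callset.reset_index(drop=True)


def _validate(callset: pd.DataFrame) -> None:
    if np.any(callset["start"] > callset["end"]):
        raise ValidationError("SV records need start <= end")
    bad = ~callset["type"].isin(MATCHABLE_TYPES + ("unaligned",))
    if bad.any():
        raise ValidationError(
            f"unknown SV types: {sorted(callset.loc[bad, 'type'].unique())}")


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame       # matched A-records with B links
    matches: pd.DataFrame         # pair table with endpoint offsets
    unaligned: pd.DataFrame       # A-side unaligned regions (bypass channel)


def consensus_svs(callsetA: pd.DataFrame, callsetB: pd.DataFrame,
                  tol: int = 100) -> ConsensusResult:
    """High-confidence SVs: A records matched by a B record of the same
    chromosome and type with both endpoint offsets <= ``tol``.

    Matching is one-to-one and greedy by smallest total offset (ties by
    leftmost A record).  Translocations must satisfy the rule at both
    loci.  Unaligned-region records bypass matching and are returned on a
    separate channel.
    """
    A = _dedup(callsetA.copy(), "A")
    B = _dedup(callsetB.copy(), "B")
    _validate(A)
    _validate(B)
    unaligned = A[A["type"] == "unaligned"].reset_index(drop=True)
    A = A[A["type"] != "unaligned"].reset_index(drop=True)
    B = B[B["type"] != "unaligned"].reset_index(drop=True)
    pairs = []
    for (chrom, typ), a_grp in A.groupby(["chrom", "type"], sort=False):
        b_grp = B[(B["chrom"] == chrom) & (B["type"] == typ)]
        if b_grp.empty:
            continue
        for ia, ra in a_grp.iterrows():
            ds = (b_grp["start"] - ra["start"]).abs()
            de = (b_grp["end"] - ra["end"]).abs()
            ok = (ds <= tol) & (de <= tol)
            if typ == "translocation":
                ok &= (b_grp["chrom2"] == ra["chrom2"])
                ok &= (b_grp["start2"] - ra["start2"]).abs() <= tol
                ok &= (b_grp["end2"] - ra["end2"]).abs() <= tol
            for ib in b_grp.index[ok]:
                pairs.append((int(ds[ib] + de[ib]), ia, ib,
                              int(ds[ib]), int(de[ib])))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    usedA, usedB, kept = set(), set(), []
    for total, ia, ib, ds, de in pairs:
        if ia in usedA or ib in usedB:
            continue
        usedA.add(ia)
        usedB.add(ib)
        kept.append({"idA": A.loc[ia, "id"], "idB": B.loc[ib, "id"],
                     "d_start": ds, "d_end": de, "total_offset": total})
    matches = pd.DataFrame(kept, columns=["idA", "idB", "d_start", "d_end",
                                          "total_offset"])
    consensus = A[A["id"].isin(matches["idA"])].merge(
        matches.rename(columns={"idA": "id", "idB": "match_id"}), on="id")
    return ConsensusResult(consensus.reset_index(drop=True), matches,
                           unaligned)


def assign_genes(svs: pd.DataFrame, gene_intervals: pd.DataFrame
                 ) -> pd.DataFrame:
    """Genes per SV: any overlap for inversions/translocations, full
    containment for CNVs and unaligned regions.

    ``gene_intervals`` columns: chrom, start, end, gene_id (1-based
    inclusive).  Returns one row per (sv id, gene).
    """
    bad = ~svs["type"].isin(MATCHABLE_TYPES + ("unaligned",))
    if bad.any():
        raise ValidationError(
            f"unknown SV types: {sorted(svs.loc[bad, 'type'].unique())}")
    trees: dict = {}
    for _, g in gene_intervals.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(
            g["start"], g["end"] + 1, (g["gene_id"], g["start"], g["end"]))
    rows = []
    for _, sv in svs.iterrows():
        loci = [(sv["chrom"], sv["start"], sv["end"])]
        if sv["type"] == "translocation" and sv.get("chrom2"):
            loci.append((sv["chrom2"], sv["start2"], sv["end2"]))
        hits = set()
        for chrom, start, end in loci:
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(start, end + 1):
                gid, gs, ge = iv.data
                if sv["type"] in CONTAINMENT_TYPES:
                    if gs >= start and ge <= end:
                        hits.add(gid)
                else:
                    hits.add(gid)
        for gid in sorted(hits):
            rows.append({"sv_id": sv["id"], "type": sv["type"],
                         "gene_id": gid})
    return pd.DataFrame(rows, columns=["sv_id", "type", "gene_id"])


def fisher_enrichment(foreground_genes, universe_genes,
                      term_map: pd.DataFrame, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Per-term one-sided Fisher exact enrichment of a gene foreground.

    The 2x2 table is (in/out foreground) x (has/lacks term) over the
    universe.  Returns all terms with counts and p; ``enriched`` flags
    p < alpha.
    """
    fg = set(foreground_genes)
    uni = set(universe_genes)
    if not fg <= uni:
        raise ValidationError("foreground must be a subset of the universe")
    rows = []
    by_term = term_map[term_map["gene_id"].isin(uni)].groupby("term")
    for term, grp in by_term:
        with_term = set(grp["gene_id"])
        a = len(fg & with_term)
        b = len(fg - with_term)
        c = len(with_term - fg)
        d = len(uni) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term": term, "fg_with": a, "fg_without": b,
                     "bg_with": c, "bg_without": d, "p": float(p),
                     "enriched": p < alpha})
    return pd.DataFrame(rows, columns=["term", "fg_with", "fg_without",
                                       "bg_with", "bg_without", "p",
                                       "enriched"])
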