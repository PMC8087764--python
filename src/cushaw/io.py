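"""File formats: VCFv4.2, population maps, SV call sets, gene intervals,
term maps, truth tables.

VCF reading goes through cyvcf2; writing emits minimal VCFv4.2 text with
the ancestral allele as REF and an ``AA`` INFO tag.  All tabular formats
are TSV with explicit headers; SV coordinates are 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, ValidationError
from .svconsensus import SV_COLUMNS

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path, ref: str = "A",
              alt: str = "T") -> None:
    """VCFv4.2 with REF as the ancestral allele and an AA INFO tag."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for c in pd.unique(G.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in G.samples) + "\n")
        for s in range(G.n_sites):
            gts = "\t".join(_GT[int(d)] for d in G.dosages[:, s])
            fh.write(f"{G.chrom[s]}\t{G.pos[s]}\t{G.site_ids[s]}\t{ref}\t"
                     f"{alt}\t.\tPASS\tAA={ref}\tGT\t{gts}\n")


def read_vcf(path, popmap: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Biallelic-SNP VCF into a GenotypeMatrix (cyvcf2 reader).

    ``popmap`` (from :func:`read_popmap`) attaches population labels and
    statuses; samples missing from the map raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        # gts012: 0/1/2 dosage, 3 = missing
        d = var.gt_types.astype(np.int8)
        d[d == 3] = MISSING
        rows.append(d)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not rows:
        raise ValidationError(f"no biallelic SNPs in {path}")
    dos = np.stack(rows, axis=1)
    if popmap is not None:
        pm = popmap.set_index("sample")
        missing = [s for s in samples if s not in pm.index]
        if missing:
            raise ValidationError(f"samples not in popmap: {missing[:5]}")
        pops = np.array([pm.loc[s, "population"] for s in samples])
        status = dict(zip(pm["population"], pm["status"]))
    else:
        pops = np.array(["pop0"] * len(samples))
        status = {}
    return GenotypeMatrix(dos, np.array(chroms), np.array(poss, np.int64),
                          samples, pops, status)


def write_popmap(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame({
        "sample": G.samples, "population": G.pops,
        "status": [G.status.get(p, "wild") for p in G.pops]})
    df.to_csv(path, sep="\t", index=False)


def read_popmap(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample", "population", "status"}
    if not need <= set(df.columns):
        raise ValidationError(f"popmap needs columns {sorted(need)}")
    return df


def write_sv_callset(callset: pd.DataFrame, path) -> None:
    callset.to_csv(path, sep="\t", index=False)


def read_sv_callset(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "start", "end", "type", "id")
               if c not in df.columns]
    if missing:
        raise ValidationError(f"SV call set lacks columns {missing}")
    for c in SV_COLUMNS:
        if c not in df.columns:
            df[c] = "" if c in ("caller", "chrom2") else -1
    return df[SV_COLUMNS]


def write_gene_gff3(genes: pd.DataFrame, path) -> None:
    """Gene intervals as GFF3 (gene features only, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(f"{g['chrom']}\tcushaw\tgene\t{g['start']}\t{g['end']}"
                     f"\t.\t+\t.\tID={g['gene_id']}\n")


def read_gene_gff3(path) -> pd.DataFrame:
    names = ["chrom", "source", "feature", "start", "end", "score",
             "strand", "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", names=names,
                     dtype={"chrom": str})
    df = df[df["feature"] == "gene"].copy()
    df["gene_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    return df[["chrom", "start", "end", "gene_id"]].reset_index(drop=True)


def read_term_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", names=["gene_id", "term"],
                         dtype=str)
    return df[["gene_id", "term"]]


def read_outgroup_table(path, G: GenotypeMatrix) -> np.ndarray:
    """Per-site outgroup ALT frequency aligned to ``G`` (NaN = absent)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "pos", "alt_freq"}
    if not need <= set(df.columns):
        raise ValidationError(f"outgroup table needs columns {sorted(need)}")
    key = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]])
    series = pd.Series(df["alt_freq"].to_numpy(), index=key)
    out = np.full(G.n_sites, np.nan)
    for i, (c, p) in enumerate(zip(G.chrom, G.pos)):
        if (c, p) in series.index:
            out[i] = series[(c, p)]
    return out
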