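import numpy as np
import pytest

from cushaw import simdata
from cushaw.core import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(dosages, pops=None, status=None, chrom=None, pos=None):
    """Small GenotypeMatrix from a plain dosage list."""
    d = np.asarray(dosages, dtype=np.int8)
    n_samp, n_site = d.shape
    pops = np.asarray(pops if pops is not None
                      else ["p1"] * n_samp)
    chrom = np.asarray(chrom if chrom is not None else ["chr1"] * n_site)
    pos = np.asarray(pos if pos is not None
                     else np.arange(1, n_site + 1) * 100)
    return GenotypeMatrix(d, chrom, pos,
                          [f"s{i}" for i in range(n_samp)], pops,
                          status or {})


def two_deme_genotypes(seed, n_snps=1000, n_dip=20, **model_kw):
    """Neutral two-deme (wild/domesticated) dataset."""
    model = simdata.two_deme_model(**model_kw)
    params = simdata.SimParams(
        samples_per_deme={"wild": n_dip, "dom": n_dip},
        n_snps=n_snps, seed=seed)
    haps = simdata.simulate_coalescent(model, params)
    return simdata.emit_genotypes(
        haps, pairing_seed=seed,
        status={"wild": "wild", "dom": "domesticated"})


def star_genotypes(seed, n_snps=400, n_demes_per_status=4, n_dip=10,
                   t_split=800, n_e=10_000):
    """Star phylogeny with several wild and domesticated demes."""
    wdem = [f"w{i}" for i in range(n_demes_per_status)]
    ddem = [f"d{i}" for i in range(n_demes_per_status)]
    demes = wdem + ddem
    model = simdata.DemographicModel(
        pop_labels=demes + ["anc"],
        deme_sizes={d: n_e for d in demes + ["anc"]},
        split_events=[(t_split, d, "anc") for d in demes])
    params = simdata.SimParams(samples_per_deme={d: n_dip for d in demes},
                               n_snps=n_snps, seed=seed)
    haps = simdata.simulate_coalescent(model, params)
    status = {**{w: "wild" for w in wdem},
              **{d: "domesticated" for d in ddem}}
    return simdata.emit_genotypes(haps, pairing_seed=seed,
                                  status=status), wdem, ddem


def spike_all(G, demes, site_idx):
    """Fix the derived allele in every listed deme at the given sites."""
    dos = G.dosages.copy()
    for deme in demes:
        rows = np.flatnonzero(G.pops == deme)
        dos[np.ix_(rows, site_idx)] = 2
    return GenotypeMatrix(dos, G.chrom, G.pos, list(G.samples),
                          G.pops.copy(), dict(G.status),
                          G.site_ids.copy())
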