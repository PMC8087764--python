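"""Synthetic-data generation for the domestication pipeline.

A structured-coalescent simulator (own implementation; see
``cushaw._kernels``) generates haplotypes, genotype matrices, and joint
derived-allele count tables under user-defined demographies: population
splits, admixture pulses, and backward migration that can be switched off
(no gene flow), always on (continuous), or restricted to a recent epoch
(secondary contact).  Companion generators produce spiked selected loci,
toy structural-variant call sets, and toy gene/term annotations, so every
downstream stage of the pipeline can be exercised without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .core import (MISSING, GenotypeMatrix, StructuralModelError,
                   ValidationError)

GENE_FLOW_MODES = ("none", "continuous", "secondary_contact")
SV_TYPES = ("CNV_gain", "CNV_loss", "inversion", "translocation")


# ---------------------------------------------------------------------------
# model containers


@dataclass
class DemographicModel:
    """Backward-in-time demography over named demes.

    ``split_events`` are (time_generations, derived, ancestral): looking
    back, every lineage of the derived deme joins the ancestral deme and
    the derived deme is retired.  ``pulse_events`` are
    (time, source, dest, fraction): each source lineage jumps with the
    given probability (a forward-time admixture pulse of that fraction).
    ``migration[i][j]`` is the backward per-generation, per-lineage rate at
    which a lineage in deme i moves to deme j; under secondary contact it
    applies only at times more recent than ``secondary_contact_end``.
    """

    pop_labels: list
    deme_sizes: dict
    split_events: list = field(default_factory=list)
    pulse_events: list = field(default_factory=list)
    migration: dict = field(default_factory=dict)
    gene_flow_mode: str = "none"
    secondary_contact_end: float | None = None
    domesticated_deme: str | None = None

    def validate(self) -> None:
        if self.gene_flow_mode not in GENE_FLOW_MODES:
            raise ValidationError(
                f"gene_flow_mode must be one of {GENE_FLOW_MODES}")
        for d in self.pop_labels:
            if d not in self.deme_sizes:
                raise ValidationError(f"no deme size for {d}")
        for d, n in self.deme_sizes.items():
            if not n >= 1:
                raise ValidationError(f"deme size of {d} must be >= 1")
        for (src, dst), m in self.migration.items():
            if not (0 <= m < 1):
                raise ValidationError(f"migration rate {src}->{dst} "
                                      "must be in [0, 1)")
            if src not in self.pop_labels or dst not in self.pop_labels:
                raise ValidationError(f"migration between unknown demes "
                                      f"{src}->{dst}")
        split_times = []
        for t, der, anc in self.split_events:
            if not t > 0:
                raise ValidationError("split times must be strictly positive")
            if der not in self.pop_labels or anc not in self.pop_labels:
                raise ValidationError(f"split event names unknown deme "
                                      f"({der}, {anc})")
            split_times.append(t)
        for t, src, dst, f in self.pulse_events:
            if not (t > 0 and 0 < f <= 1):
                raise ValidationError("pulse events need t > 0, 0 < f <= 1")
            if src not in self.pop_labels or dst not in self.pop_labels:
                raise ValidationError("pulse event names unknown deme")
        if self.domesticated_deme is not None:
            t_dom = [t for t, der, _ in self.split_events
                     if der == self.domesticated_deme]
            others = [t for t, der, _ in self.split_events
                      if der != self.domesticated_deme]
            if t_dom and others and min(t_dom) > min(others) + 1e-9:
                raise ValidationError(
                    "domesticated deme must diverge after the wild demes")
        if self.gene_flow_mode == "secondary_contact":
            if self.secondary_contact_end is None:
                raise ValidationError("secondary_contact_end required")
            if split_times and not (
                    self.secondary_contact_end < min(split_times)):
                raise ValidationError(
                    "secondary_contact_end must precede the earliest split")

    def _check_coalescible(self, sampled: list) -> None:
        """Sampled demes must be joinable through splits/pulses/migration."""
        parent = {d: d for d in self.pop_labels}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            parent[find(a)] = find(b)

        for _, der, anc in self.split_events:
            union(der, anc)
        for _, src, dst, _ in self.pulse_events:
            union(src, dst)
        if self.gene_flow_mode != "none":
            for (src, dst), m in self.migration.items():
                if m > 0:
                    union(src, dst)
        roots = {find(d) for d in sampled}
        if len(roots) > 1:
            raise StructuralModelError(
                "sampled demes are never joined by any split, pulse or "
                "migration route")

    def kernel_arrays(self):
        """Encode the model for the numba kernels."""
        self.validate()
        idx = {d: i for i, d in enumerate(self.pop_labels)}
        D = len(self.pop_labels)
        N = np.array([float(self.deme_sizes[d]) for d in self.pop_labels])
        M = np.zeros((D, D))
        if self.gene_flow_mode != "none":
            for (src, dst), m in self.migration.items():
                M[idx[src], idx[dst]] = m
        if self.gene_flow_mode == "secondary_contact":
            mig_end = float(self.secondary_contact_end)
        elif self.gene_flow_mode == "continuous":
            mig_end = np.inf
        else:
            mig_end = 0.0
        ev = ([(t, idx[der], idx[anc], 1.0)
               for t, der, anc in self.split_events]
              + [(t, idx[s], idx[d], f)
                 for t, s, d, f in self.pulse_events])
        ev.sort(key=lambda e: e[0])
        ev_time = np.array([e[0] for e in ev], dtype=np.float64)
        ev_src = np.array([e[1] for e in ev], dtype=np.int64)
        ev_dst = np.array([e[2] for e in ev], dtype=np.int64)
        ev_frac = np.array([e[3] for e in ev], dtype=np.float64)
        return N, M, mig_end, ev_time, ev_src, ev_dst, ev_frac


@dataclass
class SimParams:
    """Simulator-side knobs for one synthetic dataset.

    Mutation model: ``fixed_s`` drops exactly one mutation per genealogy
    (unlinked SNPs, one independent tree each); ``rate`` drops
    Poisson(mu * locus_len * total branch length) infinite-sites mutations
    per genealogy, giving linked SNPs within a reduced-representation
    'tag'.  One generation is one calendar year for this annual species.
    """

    samples_per_deme: dict = field(default_factory=dict)
    mutation_mode: str = "fixed_s"   # "fixed_s" | "rate"
    n_snps: int = 2000               # fixed_s: segregating sites requested
    n_loci: int = 2000               # rate mode: independent genealogies
    mu: float = 1e-8                 # rate mode: per-bp per-generation
    locus_len: int = 500             # bp of sequence per genealogy
    locus_spacing: int = 25_000      # bp between locus starts
    chrom_count: int = 1
    seed: int = 0
    missing_rate: float = 0.0

    def validate(self) -> None:
        if not self.samples_per_deme:
            raise ValidationError("samples_per_deme is empty")
        for d, n in self.samples_per_deme.items():
            if n < 1:
                raise ValidationError(f"need >= 1 diploid in {d}")
        if self.mutation_mode not in ("fixed_s", "rate"):
            raise ValidationError("mutation_mode must be fixed_s or rate")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.mutation_mode == "rate" and not math.isfinite(
                self.mu * self.locus_len):
            raise ValidationError("mu * locus_len must be finite")


@dataclass
class TruthTable:
    """Ground truth carried alongside a synthetic dataset."""

    selected_site_ids: list = field(default_factory=list)
    selected_deme: str | None = None
    introgressed_site_ids: list = field(default_factory=list)
    introgression_direction: str | None = None
    true_model_id: str | None = None
    true_params: dict = field(default_factory=dict)

    def validate_against(self, site_ids) -> None:
        known = set(site_ids)
        for sid in list(self.selected_site_ids) + list(
                self.introgressed_site_ids):
            if sid not in known:
                raise ValidationError(f"truth refers to unknown site {sid}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"site_id": s, "kind": "selected",
                 "detail": self.selected_deme or ""}
                for s in self.selected_site_ids]
        rows += [{"site_id": s, "kind": "introgressed",
                  "detail": self.introgression_direction or ""}
                 for s in self.introgressed_site_ids]
        return pd.DataFrame(rows, columns=["site_id", "kind", "detail"])


@dataclass
class HaplotypeSet:
    """Haploid 0/1 matrix with site positions and per-haplotype demes."""

    haplotypes: np.ndarray       # (n_hap, n_sites) int8, 1 = derived
    demes: np.ndarray            # per-haplotype deme label
    chrom: np.ndarray
    pos: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


# ---------------------------------------------------------------------------
# simulation


def _deme0_vector(model: DemographicModel, samples_per_deme: dict):
    idx = {d: i for i, d in enumerate(model.pop_labels)}
    demes = []
    for d, n in samples_per_deme.items():
        if d not in idx:
            raise ValidationError(f"sampled deme {d} not in model")
        demes += [idx[d]] * (2 * int(n))
    return np.array(demes, dtype=np.int64)


def _seed_stream(seed: int, n: int) -> np.ndarray:
    s = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return (s >> 1).astype(np.int64)  # keep below 2**31 for the kernels


def simulate_coalescent(model: DemographicModel,
                        params: SimParams) -> HaplotypeSet:
    """Simulate haplotypes under the structured coalescent.

    Each locus is an independent genealogy; mutations follow the infinite-
    sites model mapped to integer positions inside the locus window
    (collisions resolved by rejection).
    """
    params.validate()
    model.validate()
    model._check_coalescible(list(params.samples_per_deme))
    deme0 = _deme0_vector(model, params.samples_per_deme)
    if deme0.shape[0] < 2:
        raise ValidationError("need at least 2 haploid lineages")
    N, M, mig_end, et, es, ed, ef = model.kernel_arrays()
    n_loci = (params.n_snps if params.mutation_mode == "fixed_s"
              else params.n_loci)
    seeds = _seed_stream(params.seed, n_loci + 1)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(params.seed), 0xC0A1]))
    n_hap = deme0.shape[0]
    cols, chroms, poss = [], [], []
    loci_per_chrom = int(np.ceil(n_loci / max(params.chrom_count, 1)))
    for j in range(n_loci):
        parent, node_time, root, err = _kernels.sim_tree_once(
            deme0, N, M, mig_end, et, es, ed, ef, seeds[j])
        if err != _kernels.ERR_OK:
            raise StructuralModelError(
                "genealogy failed to coalesce; check splits and migration")
        bl = np.empty(2 * n_hap - 1)
        for v in range(2 * n_hap - 1):
            bl[v] = 0.0 if v == root else node_time[parent[v]] - node_time[v]
        tot = bl.sum()
        if params.mutation_mode == "fixed_s":
            n_mut = 1 if tot > 0 else 0
        else:
            n_mut = rng.poisson(params.mu * params.locus_len * tot)
        if n_mut == 0:
            continue
        n_mut = min(n_mut, params.locus_len)
        branches = rng.choice(2 * n_hap - 1, size=n_mut, p=bl / tot)
        # descendant leaves per chosen branch
        children = [[] for _ in range(2 * n_hap - 1)]
        for v in range(2 * n_hap - 1):
            if v != root:
                children[parent[v]].append(v)
        offs = rng.choice(params.locus_len, size=n_mut, replace=False)
        offs.sort()
        c = j // loci_per_chrom
        base = (j - c * loci_per_chrom) * params.locus_spacing + 1
        for b, off in zip(branches, offs):
            col = np.zeros(n_hap, dtype=np.int8)
            stack = [int(b)]
            while stack:
                v = stack.pop()
                if v < n_hap:
                    col[v] = 1
                else:
                    stack.extend(children[v])
            cols.append(col)
            chroms.append(f"chr{c + 1}")
            poss.append(base + int(off))
    if not cols:
        haps = np.zeros((n_hap, 0), dtype=np.int8)
        chrom = np.array([], dtype=object)
        pos = np.array([], dtype=np.int64)
    else:
        haps = np.stack(cols, axis=1)
        chrom = np.array(chroms)
        pos = np.array(poss, dtype=np.int64)
    labels = np.array([model.pop_labels[d] for d in deme0])
    return HaplotypeSet(haps, labels, chrom, pos)


def simulate_joint_counts(model: DemographicModel, samples_per_deme: dict,
                          n_snps: int, seed: int,
                          snps_per_tree: int = 1) -> pd.DataFrame:
    """Per-SNP joint derived-allele counts for the sampled demes.

    Faster than full haplotype simulation when only per-deme frequencies
    are needed (D statistics, SFS checks).  Column ``<deme>`` holds the
    derived count; ``<deme>_n`` the haploid sample size.
    """
    model.validate()
    model._check_coalescible(list(samples_per_deme))
    deme0 = _deme0_vector(model, samples_per_deme)
    N, M, mig_end, et, es, ed, ef = model.kernel_arrays()
    axis_names = list(samples_per_deme)
    idx = {d: i for i, d in enumerate(model.pop_labels)}
    axis_of_deme = np.full(len(model.pop_labels), -1, dtype=np.int64)
    for a, d in enumerate(axis_names):
        axis_of_deme[idx[d]] = a
    axis_n = np.array([2 * samples_per_deme[d] for d in axis_names],
                      dtype=np.int64)
    n_trees = int(np.ceil(n_snps / snps_per_tree))
    counts, tree_id, m = _kernels.joint_count_sample(
        n_trees, snps_per_tree, deme0, N, M, mig_end, et, es, ed, ef,
        axis_of_deme, axis_n, int(seed) % (2 ** 31))
    if m == 0:
        raise StructuralModelError("simulation produced no polymorphic sites")
    counts = counts[:min(m, n_snps)]
    out = pd.DataFrame({d: counts[:, a] for a, d in enumerate(axis_names)})
    for a, d in enumerate(axis_names):
        out[f"{d}_n"] = axis_n[a]
    return out


# ---------------------------------------------------------------------------
# genotype emission and ground-truth manipulation


def emit_genotypes(haps: HaplotypeSet, pairing_seed: int = 0,
                   missing_rate: float = 0.0,
                   status: dict | None = None) -> GenotypeMatrix:
    """Pair haplotypes into diploids and emit a dosage matrix.

    Haplotypes are paired at random (seeded) within their deme; dosage is
    the derived-allele count; missing entries are injected uniformly at
    ``missing_rate``.
    """
    if not (0 <= missing_rate < 1):
        raise ValidationError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(pairing_seed), 0xD1]))
    demes = pd.unique(haps.demes)
    rows, samples, pops = [], [], []
    for d in demes:
        hap_idx = np.flatnonzero(haps.demes == d)
        if len(hap_idx) % 2:
            raise ValidationError(f"odd haplotype count in deme {d}")
        perm = rng.permutation(hap_idx)
        for i in range(0, len(perm), 2):
            rows.append(haps.haplotypes[perm[i]]
                        + haps.haplotypes[perm[i + 1]])
            samples.append(f"{d}_{i // 2:03d}")
            pops.append(d)
    dos = np.array(rows, dtype=np.int8)
    if missing_rate > 0:
        miss = rng.random(dos.shape) < missing_rate
        dos[miss] = MISSING
    status = dict(status or {})
    for d in demes:
        status.setdefault(d, "wild")
    return GenotypeMatrix(dos, haps.chrom, haps.pos, samples,
                          np.array(pops), status)


def make_env_vector(pop_map: dict, domesticated_demes) -> np.ndarray:
    """0/1 covariate per population: wild = 0, domesticated = 1."""
    dom = set(domesticated_demes)
    unknown = dom - set(pop_map)
    if unknown:
        raise ValidationError(f"unknown demes: {sorted(unknown)}")
    return np.array([1.0 if p in dom else 0.0 for p in pop_map])


def spike_selection(G: GenotypeMatrix, n_loci: int, target_deme: str,
                    shift: float, seed: int = 0,
                    min_maf: float = 0.05) -> tuple:
    """Spike differentiated loci by shifting derived frequency in one deme.

    At each chosen locus the derived-allele frequency p in the target deme
    is moved to p + shift * (1 - p) and the deme's genotypes are resampled
    binomially at the new frequency (missing entries stay missing).
    Returns (new GenotypeMatrix, TruthTable).
    """
    if not (0 < shift <= 1):
        raise ValidationError("shift must be in (0, 1]")
    if target_deme not in G.pops:
        raise ValidationError(f"unknown deme {target_deme}")
    maf = np.minimum(G.allele_freq(), 1 - G.allele_freq())
    candidates = np.flatnonzero(maf >= min_maf)
    if n_loci > candidates.size:
        raise ValidationError(
            f"requested {n_loci} loci but only {candidates.size} "
            f"polymorphic sites with MAF >= {min_maf}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E1]))
    chosen = np.sort(rng.choice(candidates, size=n_loci, replace=False))
    dos = G.dosages.copy()
    tgt = np.flatnonzero(G.pops == target_deme)
    for s in chosen:
        col = dos[tgt, s]
        ok = col >= 0
        if ok.sum() == 0:
            continue
        p = col[ok].sum() / (2 * ok.sum())
        p_new = p + shift * (1 - p)
        col[ok] = rng.binomial(2, p_new, size=int(ok.sum())).astype(np.int8)
        dos[tgt, s] = col
    out = GenotypeMatrix(dos, G.chrom, G.pos, list(G.samples), G.pops.copy(),
                         dict(G.status), G.site_ids.copy())
    truth = TruthTable(selected_site_ids=[G.site_ids[s] for s in chosen],
                       selected_deme=target_deme)
    return out, truth


# ---------------------------------------------------------------------------
# preset demographies


def two_deme_model(n_wild: float = 10_000, n_dom: float = 10_000,
                   n_anc: float = 10_000, t_split: float = 1_500,
                   gene_flow_mode: str = "none", m: float = 0.0,
                   secondary_contact_end: float | None = None
                   ) -> DemographicModel:
    """Wild + domesticated demes splitting from a common ancestor."""
    mig = {}
    if m > 0:
        mig = {("wild", "dom"): m, ("dom", "wild"): m}
    return DemographicModel(
        pop_labels=["wild", "dom", "anc"],
        deme_sizes={"wild": n_wild, "dom": n_dom, "anc": n_anc},
        split_events=[(t_split, "dom", "anc"), (t_split, "wild", "anc")],
        migration=mig, gene_flow_mode=gene_flow_mode,
        secondary_contact_end=secondary_contact_end,
        domesticated_deme="dom")


def domestication_model(origin: str = "jalisco",
                        gene_flow: str = "secondary_contact",
                        n_jalisco: float = 15_000, n_south: float = 15_000,
                        n_dom: float = 8_000, n_anc: float = 20_000,
                        t_wild: float = 15_000, t_dom: float = 8_700,
                        m_dom_wild: float = 2e-4, m_wild_dom: float = 2e-4,
                        m_dom_far: float = 5e-5, m_far_dom: float = 5e-5,
                        t_contact: float = 2_000,
                        outgroup: bool = False, n_out: float = 20_000,
                        t_out: float = 1_000_000,
                        second_outgroup: bool = False,
                        n_out2: float = 20_000, t_out2: float = 3_000_000,
                        introgression_fraction: float = 0.0,
                        t_introgression: float = 500) -> DemographicModel:
    """Three-deme domestication scenario with optional outgroup demes.

    The domesticated deme buds off the chosen wild source (Jalisco or
    Southern) at ``t_dom``; the two wild demes split from the ancestor at
    ``t_wild`` >= ``t_dom``.  Migration runs between the domesticate and
    each wild deme with independent rates per direction (the near rate pair
    applies to the source deme, the far pair to the other wild deme).
    ``outgroup`` adds a sister-species deme (moschata) used for SFS
    polarization and ABBA-BABA; ``second_outgroup`` adds a deeper outgroup
    (martinezii) for ancestral-state calls.  A positive
    ``introgression_fraction`` adds a recent admixture pulse from the
    sister species into the domesticate.
    """
    if origin not in ("jalisco", "southern"):
        raise ValidationError("origin must be jalisco or southern")
    labels = ["jalisco", "southern", "dom", "anc"]
    sizes = {"jalisco": n_jalisco, "southern": n_south, "dom": n_dom,
             "anc": n_anc}
    src = "jalisco" if origin == "jalisco" else "southern"
    far = "southern" if origin == "jalisco" else "jalisco"
    splits = [(t_dom, "dom", src), (t_wild, "southern", "anc"),
              (t_wild, "jalisco", "anc")]
    mig = {("dom", src): m_dom_wild, (src, "dom"): m_wild_dom,
           ("dom", far): m_dom_far, (far, "dom"): m_far_dom}
    pulses = []
    if outgroup:
        labels.append("moschata")
        sizes["moschata"] = n_out
        splits.append((t_out, "moschata", "anc"))
        if introgression_fraction > 0:
            pulses.append((t_introgression, "dom", "moschata",
                           introgression_fraction))
    if second_outgroup:
        labels.append("martinezii")
        sizes["martinezii"] = n_out2
        splits.append((t_out2, "martinezii", "anc"))
    return DemographicModel(
        pop_labels=labels, deme_sizes=sizes, split_events=splits,
        pulse_events=pulses,
        migration=mig if gene_flow != "none" else {},
        gene_flow_mode=gene_flow,
        secondary_contact_end=(t_contact if gene_flow == "secondary_contact"
                               else None),
        domesticated_deme="dom")


def abba_baba_model(admixture_fraction: float = 0.0,
                    t_pulse: float = 1_000, n_e: float = 20_000,
                    t12: float = 15_000, t123: float = 60_000,
                    t1234: float = 200_000) -> DemographicModel:
    """(((P1, P2), P3), P4) species topology with an optional P3->P2 pulse.

    P1 = wild subspecies, P2 = domesticate, P3 = sister crop species,
    P4 = outgroup.  ``admixture_fraction`` f > 0 moves each P2 lineage into
    P3 with probability f at ``t_pulse`` (backward), i.e. a forward-time
    introgression pulse of fraction f from P3 into P2.
    """
    labels = ["P1", "P2", "P3", "P4", "A12", "A123", "A1234"]
    sizes = {d: n_e for d in labels}
    splits = [(t12, "P1", "A12"), (t12, "P2", "A12"),
              (t123, "P3", "A123"), (t123, "A12", "A123"),
              (t1234, "P4", "A1234"), (t1234, "A123", "A1234")]
    pulses = []
    if admixture_fraction > 0:
        pulses = [(t_pulse, "P2", "P3", admixture_fraction)]
    return DemographicModel(pop_labels=labels, deme_sizes=sizes,
                            split_events=splits, pulse_events=pulses)


# ---------------------------------------------------------------------------
# toy SV call sets and annotations


def make_sv_callsets(n_shared: int, n_onlyA: int, n_onlyB: int,
                     jitter_sd: float, seed: int = 0,
                     n_chrom: int = 5, chrom_len: int = 10_000_000,
                     n_unaligned: int = 0,
                     callers: tuple = ("syri", "sniffles")) -> tuple:
    """Two SV call sets with known overlap for consensus testing.

    Shared records appear in both sets, with the second caller's endpoints
    perturbed by rounded Gaussian jitter of SD ``jitter_sd``; private
    records appear in one set only.  Returns (callsetA, callsetB, truth)
    where truth maps shared ids.
    """
    if min(n_shared, n_onlyA, n_onlyB) < 0:
        raise ValidationError("record counts must be non-negative")
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F]))

    def _records(n, caller, tag):
        rows = []
        for i in range(n):
            typ = SV_TYPES[rng.integers(len(SV_TYPES))]
            c = f"chr{rng.integers(n_chrom) + 1}"
            length = int(rng.integers(500, 50_000))
            start = int(rng.integers(1, chrom_len - length))
            row = {"caller": caller, "chrom": c, "start": start,
                   "end": start + length, "type": typ,
                   "id": f"{tag}{i:04d}", "chrom2": "", "start2": -1,
                   "end2": -1, "support": int(rng.integers(6, 40))}
            if typ == "translocation":
                c2 = f"chr{rng.integers(n_chrom) + 1}"
                l2 = int(rng.integers(500, 50_000))
                s2 = int(rng.integers(1, chrom_len - l2))
                row.update(chrom2=c2, start2=s2, end2=s2 + l2)
            rows.append(row)
        cols = ["caller", "chrom", "start", "end", "type", "id", "chrom2",
                "start2", "end2", "support"]
        return pd.DataFrame(rows, columns=cols)

    shared = _records(n_shared, callers[0], "shared")
    onlyA = _records(n_onlyA, callers[0], "onlyA")
    onlyB = _records(n_onlyB, callers[1], "onlyB")
    jitter = shared.copy()
    jitter["caller"] = callers[1]
    for col in ("start", "end", "start2", "end2"):
        active = (jitter[col] >= 0).to_numpy() if col.endswith("2") \
            else np.ones(len(jitter), bool)
        if jitter_sd > 0 and active.any():
            noise = np.rint(rng.normal(0, jitter_sd, size=len(jitter))
                            ).astype(int)
            vals = jitter[col].to_numpy(copy=True)
            vals[active] = np.maximum(1, vals[active] + noise[active])
            jitter[col] = vals
    parts_a = [shared, onlyA]
    if n_unaligned > 0:
        una = _records(n_unaligned, callers[0], "unaln")
        una["type"] = "unaligned"
        una[["chrom2", "start2", "end2"]] = ["", -1, -1]
        parts_a.append(una)
    callsetA = pd.concat(parts_a, ignore_index=True)
    callsetB = pd.concat([jitter, onlyB], ignore_index=True)
    truth = TruthTable(true_params={"shared_ids": list(shared["id"]),
                                    "jitter_sd": jitter_sd})
    return callsetA, callsetB, truth


def make_gene_annotation(n_genes: int = 100, n_terms: int = 10,
                         seed: int = 0, n_chrom: int = 5,
                         chrom_len: int = 10_000_000) -> tuple:
    """Toy gene intervals and a gene -> term annotation map."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA2]))
    rows = []
    for i in range(n_genes):
        c = f"chr{rng.integers(n_chrom) + 1}"
        length = int(rng.integers(1_000, 20_000))
        start = int(rng.integers(1, chrom_len - length))
        rows.append({"chrom": c, "start": start, "end": start + length,
                     "gene_id": f"gene{i:04d}"})
    genes = pd.DataFrame(rows).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    terms = []
    for i in range(n_genes):
        for t in range(n_terms):
            if rng.random() < 0.15:
                terms.append({"gene_id": f"gene{i:04d}",
                              "term": f"TERM:{t:04d}"})
    return genes, pd.DataFrame(terms, columns=["gene_id", "term"])
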