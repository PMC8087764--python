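"""End-to-end pipeline: one config drives generation (or loading) of the
inputs and the full analysis chain in the order of the study design:
filters -> diversity/structure -> demography -> selection scans ->
introgression -> structural variants.

Every stage writes a TSV table plus a JSON metrics sidecar into the run
directory, and ``summary.md`` aggregates the headline numbers.  A single
global seed fans out to per-stage seeds through ``numpy.random
.SeedSequence`` so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (demography, diversity, filters, introgression, io, scans,
               simdata, svconsensus)
from .core import CushawError, ValidationError

# paper-stated defaults; every threshold lives here, never hard-coded in
# the stages, so sensitivity re-runs only touch the config
DEFAULTS = {
    "filters": {"maf_min": 0.01, "max_site_missing": 0.5,
                "max_sample_missing": 0.5, "hwe_p": 0.01,
                "ld_r2": 0.25, "ld_window_bp": 100_000, "ld_step_bp": 100},
    "diversity": {"n_boot": 100, "ci_level": 0.95, "n_components": 10,
                  "ld_decay_r2_min": 0.001},
    "demography": {"n_cycles": 40, "sims_per_eval": 200_000,
                   "min_count": 1, "n_init": 8, "snps_per_tree": 10,
                   "scenarios": list(demography.SCENARIOS)},
    "scans": {"k_pcadapt": 2, "k_lfmm": 6, "alpha": 0.05, "min_tests": 2,
              "ridge_lambda": 1e-5,
              "bayescenv": {"pilot_runs": 20, "pilot_len": 10_000,
                            "burn_in": 100_000, "sample_iters": 100_000,
                            "thin": 20}},
    "introgression": {"window": 500, "step": 250, "n_blocks": 20,
                      "hi": 0.8, "lo": 0.2},
    "sv": {"tol": 100, "alpha": 0.05},
}

_STAGES = ("simdata", "filters", "diversity", "demography", "scans",
           "introgression", "sv")


class StageError(CushawError):
    def __init__(self, stage, exc):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg


def merged_config(cfg: dict) -> dict:
    out = json.loads(json.dumps(cfg))  # deep copy, json-safe
    for stage, defaults in DEFAULTS.items():
        blk = dict(defaults)
        user = out.get(stage, {}) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(blk.get(k), dict):
                blk[k] = {**blk[k], **v}
            else:
                blk[k] = v
        out[stage] = blk
    out.setdefault("seed", 0)
    return out


def validate_config(cfg: dict) -> list:
    """Exhaustive checks; returns a list of violation strings (empty = ok)."""
    v = []
    cfg = merged_config(cfg)
    if "simdata" not in cfg and "inputs" not in cfg:
        v.append("config: needs a 'simdata' or an 'inputs' block")
    if "inputs" in cfg:
        for key in ("vcf", "popmap"):
            p = cfg["inputs"].get(key)
            if p is None:
                v.append(f"inputs.{key}: missing path")
            elif not Path(p).exists():
                v.append(f"inputs.{key}: file not found ({p})")
    f = cfg["filters"]
    for key in ("maf_min", "max_site_missing", "max_sample_missing",
                "hwe_p", "ld_r2"):
        if not (0 <= f[key] <= 1):
            v.append(f"filters.{key}: must be in [0, 1], got {f[key]}")
    if f["ld_window_bp"] <= 0:
        v.append("filters.ld_window_bp: must be positive")
    d = cfg["diversity"]
    if d["n_boot"] < 2:
        v.append("diversity.n_boot: must be >= 2")
    if not (0 < d["ci_level"] < 1):
        v.append("diversity.ci_level: must be in (0, 1)")
    dem = cfg["demography"]
    for sc in dem["scenarios"]:
        if sc not in demography.SCENARIOS:
            v.append(f"demography.scenarios: unknown scenario {sc}")
    if dem["n_cycles"] < 0:
        v.append("demography.n_cycles: must be >= 0")
    s = cfg["scans"]
    if not (0 < s["alpha"] < 1):
        v.append("scans.alpha: must be in (0, 1)")
    if s["min_tests"] < 1:
        v.append("scans.min_tests: must be >= 1")
    i = cfg["introgression"]
    if not (0 <= i["lo"] < i["hi"] <= 1):
        v.append("introgression: need 0 <= lo < hi <= 1")
    if i["n_blocks"] < 5:
        v.append("introgression.n_blocks: must be >= 5")
    if cfg["sv"]["tol"] < 0:
        v.append("sv.tol: must be >= 0")
    return v


def _stage_seed(global_seed: int, stage: str) -> int:
    h = sum(ord(c) * 131 ** i for i, c in enumerate(stage)) % 9973
    return int(np.random.SeedSequence([int(global_seed), h]).generate_state(
        1, dtype=np.uint32)[0] >> 1)


def _write_metrics(outdir: Path, stage: str, metrics: dict) -> None:
    with open(outdir / f"{stage}.metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Run every configured stage; returns the aggregated summary dict.

    A stage failure raises :class:`StageError` naming the stage; outputs
    written before the failure are retained.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValidationError("invalid config: " + "; ".join(violations))
    cfg = merged_config(cfg)
    outdir = Path(outdir if outdir is not None
                  else cfg.get("outdir", "cushaw_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {"seed": seed}
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"seed": seed, "config": cfg,
                   "stage_seeds": {s: _stage_seed(seed, s)
                                   for s in _STAGES}}, fh, indent=2)

    # ---- stage: inputs -------------------------------------------------
    stage = "simdata"
    try:
        data = _stage_inputs(cfg, outdir, _stage_seed(seed, stage))
    except Exception as exc:
        raise StageError(stage, exc) from exc
    G = data["G"]
    summary["n_samples"] = G.n_samples
    summary["n_sites_input"] = G.n_sites

    # ---- stage: filters ------------------------------------------------
    stage = "filters"
    try:
        fcfg = cfg["filters"]
        G13, rep = filters.filter_sites(
            G, maf_min=fcfg["maf_min"],
            max_site_missing=fcfg["max_site_missing"],
            max_sample_missing=fcfg["max_sample_missing"])
        Ghwe, rep_hwe = filters.hwe_filter(G13, p_threshold=fcfg["hwe_p"])
        kept = filters.ld_prune(Ghwe, r2_max=fcfg["ld_r2"],
                                window_bp=fcfg["ld_window_bp"],
                                step_bp=fcfg["ld_step_bp"])
        Gdem = Ghwe.take_sites(kept)
        report = pd.concat([rep.to_frame(), rep_hwe.to_frame(),
                            pd.DataFrame([{"step": "ld_prune",
                                           "removed": Ghwe.n_sites
                                           - len(kept),
                                           "remaining": len(kept)}])],
                           ignore_index=True)
        report.to_csv(outdir / "filters.report.tsv", sep="\t", index=False)
        statuses = np.array([G13.status.get(p, "wild") for p in G13.pops])
        Gscan = G13.take_samples(np.isin(statuses,
                                         ["wild", "domesticated"]))
        Gscan, _ = filters.filter_sites(Gscan, maf_min=fcfg["maf_min"],
                                        max_site_missing=fcfg[
                                            "max_site_missing"],
                                        max_sample_missing=1.0)
        metrics = {"n_snps_core": G13.n_sites,
                   "n_snps_demography": Gdem.n_sites,
                   "n_snps_scans": Gscan.n_sites}
        _write_metrics(outdir, stage, metrics)
        summary.update(metrics)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: diversity ----------------------------------------------
    stage = "diversity"
    try:
        dcfg = cfg["diversity"]
        ingroup = [p for p in G13.pop_names()
                   if G13.status.get(p) in ("wild", "domesticated",
                                            "feral")]
        pi_rows = [{"population": p,
                    "pi": diversity.nucleotide_diversity(G13, p).mean_pi}
                   for p in ingroup]
        pi_tab = pd.DataFrame(pi_rows)
        pi_tab.to_csv(outdir / "diversity.pi.tsv", sep="\t", index=False)
        fst_tab = diversity.pairwise_fst_table(
            G13.take_samples(np.isin(G13.pops, ingroup)), ingroup,
            n_boot=dcfg["n_boot"], level=dcfg["ci_level"],
            seed=_stage_seed(seed, stage))
        fst_tab.to_csv(outdir / "diversity.fst.tsv", sep="\t", index=False)
        scores, _, evr = diversity.genotype_pca(
            G13, n_components=dcfg["n_components"])
        pca = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in
                                            range(scores.shape[1])])
        pca.insert(0, "sample", G13.samples)
        pca.to_csv(outdir / "diversity.pca.tsv", sep="\t", index=False)
        metrics = {"pi": {r["population"]: r["pi"] for r in pi_rows},
                   "fst": fst_tab.to_dict("records"),
                   "pca_evr": list(map(float, evr))}
        _write_metrics(outdir, stage, metrics)
        summary["pi"] = metrics["pi"]
        summary["fst"] = metrics["fst"]
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: demography ----------------------------------------------
    stage = "demography"
    try:
        dem = cfg["demography"]
        wild_pops = [p for p in Gdem.pop_names()
                     if Gdem.status.get(p) == "wild"]
        dom_pops = [p for p in Gdem.pop_names()
                    if Gdem.status.get(p) == "domesticated"]
        out_pops = [p for p in Gdem.pop_names()
                    if Gdem.status.get(p) == "outgroup"]
        if out_pops and wild_pops and dom_pops:
            ingroup_order = wild_pops + dom_pops
            obs = demography.polarize_and_build_msfs(Gdem, ingroup_order,
                                                     out_pops[0])
            if data.get("n_loci_surveyed"):
                obs.n_loci_surveyed = data["n_loci_surveyed"]
                obs.u_per_locus = data["u_per_locus"]
            obs.save(outdir / "demography.msfs.txt")
            if len(obs.pop_names) == 3:
                # map onto the scenario deme names (wilds first)
                obs.pop_names = ["jalisco", "southern", "dom"]
            n_out_dip = int((Gdem.pops == out_pops[0]).sum())
            fits = []
            for sc in dem["scenarios"]:
                fits.append(demography.fit_model(
                    obs, sc, n_cycles=dem["n_cycles"],
                    sims_per_eval=dem["sims_per_eval"],
                    seed=_stage_seed(seed, stage),
                    n_init=dem["n_init"],
                    snps_per_tree=dem["snps_per_tree"],
                    min_count=dem["min_count"],
                    outgroup_deme="moschata",
                    outgroup_samples=n_out_dip))
            if len(fits) >= 2:
                scored = demography.score_fits(
                    obs, fits, seed=_stage_seed(seed, stage) + 1,
                    sims_per_eval=dem["sims_per_eval"],
                    outgroup_deme="moschata",
                    outgroup_samples=int((Gdem.pops == out_pops[0]).sum()))
                tab = demography.compare_models(scored)
            else:
                tab = pd.DataFrame([{"model": fits[0].model_id,
                                     "k": fits[0].k,
                                     "loglik": fits[0].loglik,
                                     "aic": fits[0].aic, "delta_aic": 0.0}])
            tab.to_csv(outdir / "demography.aic.tsv", sep="\t", index=False)
            metrics = {"aic_table": tab.to_dict("records"),
                       "best_model": tab["model"].iloc[0],
                       "msfs_snps": obs.total}
            _write_metrics(outdir, stage, metrics)
            summary["best_model"] = metrics["best_model"]
            summary["aic_table"] = metrics["aic_table"]
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: scans ----------------------------------------------------
    stage = "scans"
    try:
        scfg = cfg["scans"]
        dom_set = [p for p in Gscan.pop_names()
                   if Gscan.status.get(p) == "domesticated"]
        bs = scfg["bayescenv"]
        sseed = _stage_seed(seed, stage)
        state = scans.bayescenv_scan_genotypes(
            Gscan, dom_set, pilot_runs=bs["pilot_runs"],
            pilot_len=bs["pilot_len"], burn_in=bs["burn_in"],
            sample_iters=bs["sample_iters"], thin=bs["thin"],
            seeds=(sseed, sseed + 1), alpha=scfg["alpha"])
        r_bayes = state.result
        r_pc = scans.pcadapt_scan(Gscan, K=scfg["k_pcadapt"],
                                  alpha=scfg["alpha"])
        env = np.array([1.0 if p in dom_set else 0.0 for p in Gscan.pops])
        r_lf = scans.lfmm_scan(Gscan, env, K=scfg["k_lfmm"],
                               ridge_lambda=scfg["ridge_lambda"],
                               alpha=scfg["alpha"])
        for r in (r_bayes, r_pc, r_lf):
            r.table.to_csv(outdir / f"scans.{r.test}.tsv", sep="\t",
                           index=False)
        cons = scans.consensus_candidates([r_bayes, r_pc, r_lf],
                                          min_tests=scfg["min_tests"])
        cons.to_csv(outdir / "scans.consensus.tsv", sep="\t", index=False)
        metrics = {"n_candidates": int(cons["candidate"].sum()),
                   "per_test": {r.test: int(r.table["significant"].sum())
                                for r in (r_bayes, r_pc, r_lf)},
                   "bayescenv_converged": state.converged}
        _write_metrics(outdir, stage, metrics)
        summary.update(metrics)
        candidate_ids = cons.loc[cons["candidate"], "snp_id"].tolist()
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: introgression --------------------------------------------
    stage = "introgression"
    try:
        icfg = cfg["introgression"]
        taxa = _introgression_taxa(G13)
        if taxa is not None:
            p1m, p2m, p3m, p4m = taxa
            freqs = pd.DataFrame({
                "p1": G13.allele_freq(p1m), "p2": G13.allele_freq(p2m),
                "p3": G13.allele_freq(p3m), "p4": G13.allele_freq(p4m)})
            freqs["p3_der"] = np.where(G13.dosages[p3m] >= 0,
                                       G13.dosages[p3m], 0).sum(axis=0)
            freqs["p3_n"] = 2 * (G13.dosages[p3m] >= 0).sum(axis=0)
            res = introgression.d_statistic(freqs)
            blocks = introgression.equal_snp_blocks(res.abba.size,
                                                   icfg["n_blocks"])
            se, z, p = introgression.block_jackknife(res.abba, res.baba,
                                                     blocks)
            ok3 = freqs["p3_n"].to_numpy() >= 2
            f_g = introgression.f_admixture(
                freqs[ok3], seed=_stage_seed(seed, stage))
            wtab = introgression.windowed_d(res.abba, res.baba,
                                            icfg["window"], icfg["step"])
            wtab.to_csv(outdir / "introgression.windows.tsv", sep="\t",
                        index=False)
            cls_tab = _classify_stage(G13, candidate_ids, p1m, p2m, p3m,
                                      p4m, icfg)
            cls_tab.to_csv(outdir / "introgression.candidates.tsv",
                           sep="\t", index=False)
            counts = cls_tab["label"].value_counts().to_dict()
            metrics = {"d": res.d, "se": se, "z": z, "p": p, "f_g": f_g,
                       "n_windows": len(wtab),
                       "candidate_labels": counts}
            _write_metrics(outdir, stage, metrics)
            summary["d_statistic"] = {"d": res.d, "z": z, "p": p,
                                      "f_g": f_g}
            summary["candidate_labels"] = counts
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: structural variants --------------------------------------
    stage = "sv"
    try:
        if data.get("sv_a") is not None:
            scfg = cfg["sv"]
            cons_sv = svconsensus.consensus_svs(data["sv_a"], data["sv_b"],
                                                tol=scfg["tol"])
            cons_sv.consensus.to_csv(outdir / "sv.consensus.tsv", sep="\t",
                                     index=False)
            assigned = svconsensus.assign_genes(
                pd.concat([cons_sv.consensus, cons_sv.unaligned],
                          ignore_index=True), data["genes"])
            assigned.to_csv(outdir / "sv.genes.tsv", sep="\t", index=False)
            enr = svconsensus.fisher_enrichment(
                assigned["gene_id"].unique(),
                data["genes"]["gene_id"], data["terms"],
                alpha=scfg["alpha"])
            enr.to_csv(outdir / "sv.enrichment.tsv", sep="\t", index=False)
            metrics = {"n_consensus": len(cons_sv.consensus),
                       "n_unaligned": len(cons_sv.unaligned),
                       "n_genes_assigned": int(
                           assigned["gene_id"].nunique()),
                       "n_terms_enriched": int(enr["enriched"].sum())}
            _write_metrics(outdir, stage, metrics)
            summary.update(metrics)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _write_summary(outdir, summary)
    return summary


def _stage_inputs(cfg: dict, outdir: Path, sseed: int) -> dict:
    """Generate (simdata block) or load (inputs block) the pipeline data."""
    if "simdata" in cfg and cfg["simdata"]:
        sd = cfg["simdata"]
        scenario = sd.get("scenario", "jalisco_secondary")
        origin, flow = demography.SCENARIOS[scenario]
        model = simdata.domestication_model(
            origin=origin, gene_flow=flow, outgroup=True,
            second_outgroup=True,
            introgression_fraction=sd.get("introgression_fraction", 0.0),
            **sd.get("model_params", {}))
        samples = sd.get("samples", {"jalisco": 10, "southern": 10,
                                     "dom": 10, "moschata": 5,
                                     "martinezii": 2})
        params = simdata.SimParams(
            samples_per_deme=samples,
            mutation_mode=sd.get("mutation_mode", "rate"),
            n_snps=sd.get("n_snps", 2000),
            n_loci=sd.get("n_loci", 800), mu=sd.get("mu", 1e-8),
            locus_len=sd.get("locus_len", 500),
            chrom_count=sd.get("chrom_count", 5),
            seed=sseed, missing_rate=sd.get("missing_rate", 0.0))
        haps = simdata.simulate_coalescent(model, params)
        status = {"jalisco": "wild", "southern": "wild",
                  "dom": "domesticated", "moschata": "outgroup",
                  "martinezii": "outgroup"}
        G = simdata.emit_genotypes(haps, pairing_seed=sseed + 1,
                                   missing_rate=params.missing_rate,
                                   status=status)
        truth = simdata.TruthTable(true_model_id=scenario)
        if sd.get("spike"):
            sp = sd["spike"]
            G, truth_sel = simdata.spike_selection(
                G, sp.get("n_loci", 10), sp.get("target_deme", "dom"),
                sp.get("shift", 1.0), seed=sseed + 2)
            truth.selected_site_ids = truth_sel.selected_site_ids
            truth.selected_deme = truth_sel.selected_deme
        io.write_vcf(G, outdir / "simdata.vcf")
        io.write_popmap(G, outdir / "simdata.popmap.tsv")
        truth.to_frame().to_csv(outdir / "simdata.truth.tsv", sep="\t",
                                index=False)
        svcfg = sd.get("sv", {})
        sv_a, sv_b, _ = simdata.make_sv_callsets(
            svcfg.get("n_shared", 50), svcfg.get("n_onlyA", 20),
            svcfg.get("n_onlyB", 20), svcfg.get("jitter_sd", 20.0),
            n_unaligned=svcfg.get("n_unaligned", 5), seed=sseed + 3)
        ann = sd.get("annotation", {})
        genes, terms = simdata.make_gene_annotation(
            ann.get("n_genes", 100), ann.get("n_terms", 10),
            seed=sseed + 4)
        io.write_sv_callset(sv_a, outdir / "simdata.sv_a.tsv")
        io.write_sv_callset(sv_b, outdir / "simdata.sv_b.tsv")
        io.write_gene_gff3(genes, outdir / "simdata.genes.gff3")
        terms.to_csv(outdir / "simdata.terms.tsv", sep="\t", index=False)
        return {"G": G, "sv_a": sv_a, "sv_b": sv_b, "genes": genes,
                "terms": terms,
                "n_loci_surveyed": (params.n_loci
                                    if params.mutation_mode == "rate"
                                    else None),
                "u_per_locus": (params.mu * params.locus_len
                                if params.mutation_mode == "rate"
                                else None)}
    inputs = cfg["inputs"]
    popmap = io.read_popmap(inputs["popmap"])
    G = io.read_vcf(inputs["vcf"], popmap)
    out = {"G": G, "sv_a": None, "sv_b": None, "genes": None,
           "terms": None}
    if inputs.get("sv_a") and inputs.get("sv_b"):
        out["sv_a"] = io.read_sv_callset(inputs["sv_a"])
        out["sv_b"] = io.read_sv_callset(inputs["sv_b"])
    if inputs.get("genes"):
        out["genes"] = io.read_gene_gff3(inputs["genes"])
    if inputs.get("terms"):
        out["terms"] = io.read_term_map(inputs["terms"])
    return out


def _introgression_taxa(G):
    """Sample masks for (P1 wild, P2 domesticated, P3 sister, P4 outgroup)."""
    status = np.array([G.status.get(p, "") for p in G.pops])
    wild = status == "wild"
    dom = status == "domesticated"
    outs = [p for p in G.pop_names() if G.status.get(p) == "outgroup"]
    if not (wild.any() and dom.any() and len(outs) >= 2):
        return None
    p3 = G.pops == outs[0]
    p4 = G.pops == outs[1]
    return wild, dom, p3, p4


def _classify_stage(G, candidate_ids, p1m, p2m, p3m, p4m, icfg):
    idx = {s: i for i, s in enumerate(G.site_ids)}
    rows = []
    f1, f2, f3, f4 = (G.allele_freq(m) for m in (p1m, p2m, p3m, p4m))
    for sid in candidate_ids:
        i = idx.get(sid)
        if i is None:
            continue
        rows.append({"snp_id": sid, "wild_alt": f1[i], "dom_alt": f2[i],
                     "sister_alt": f3[i], "out1_alt": f4[i]})
    tab = pd.DataFrame(rows, columns=["snp_id", "wild_alt", "dom_alt",
                                      "sister_alt", "out1_alt"])
    if tab.empty:
        return pd.DataFrame(columns=["snp_id", "label", "ancestral"])
    cls = introgression.classify_candidates(tab, hi=icfg["hi"],
                                            lo=icfg["lo"])
    return pd.DataFrame([{"snp_id": c.snp_id, "label": c.label,
                          "ancestral": c.ancestral} for c in cls])


def _write_summary(outdir: Path, summary: dict) -> None:
    lines = ["# Pipeline summary", ""]
    lines.append(f"- seed: {summary.get('seed')}")
    lines.append(f"- input sites: {summary.get('n_sites_input')}")
    for key in ("n_snps_core", "n_snps_demography", "n_snps_scans"):
        if key in summary:
            lines.append(f"- {key.replace('_', ' ')}: {summary[key]}")
    if "pi" in summary:
        lines.append("\n## Diversity\n")
        for pop, pi in summary["pi"].items():
            lines.append(f"- pi[{pop}] = {pi:.4f}")
        for row in summary.get("fst", []):
            lines.append(f"- F_ST {row['pop1']} vs {row['pop2']}: "
                         f"{row['fst']:.4f} "
                         f"[{row['ci_lo']:.4f}, {row['ci_hi']:.4f}]")
    if "best_model" in summary:
        lines.append("\n## Demography\n")
        lines.append(f"- AIC-best scenario: {summary['best_model']}")
        for row in summary.get("aic_table", []):
            lines.append(f"- {row['model']}: AIC {row['aic']:.1f} "
                         f"(delta {row['delta_aic']:.1f})")
    if "n_candidates" in summary:
        lines.append("\n## Selection scans\n")
        lines.append(f"- consensus candidates: {summary['n_candidates']}")
        for t, n in summary.get("per_test", {}).items():
            lines.append(f"- {t}: {n} significant")
    if "d_statistic" in summary:
        d = summary["d_statistic"]
        lines.append("\n## Introgression\n")
        lines.append(f"- D = {d['d']:.4f}, Z = {d['z']:.2f}, "
                     f"p = {d['p']:.3g}, f_G = {d['f_g']:.4f}")
        labels = summary.get("candidate_labels", {})
        if labels:
            lines.append("- candidate labels: "
                         + ", ".join(f"{k}={v}"
                                     for k, v in sorted(labels.items())))
    if "n_consensus" in summary:
        lines.append("\n## Structural variants\n")
        lines.append(f"- consensus SVs: {summary['n_consensus']}")
        lines.append(f"- unaligned-region records: "
                     f"{summary['n_unaligned']}")
        lines.append(f"- enriched terms: {summary['n_terms_enriched']}")
    with open(outdir / "summary.md", "w") as fh:
        fh.write("\n".join(lines) + "\n")
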