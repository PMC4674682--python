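"""Configuration-driven orchestration of the full synthetic-cohort analysis.

``run_pipeline`` executes simulate → preprocess → differential methylation →
cis-meQTL mapping → selection scans → enrichment in dependency order,
collecting stage tables and a manifest (config hash, seed, versions, timing)
sufficient to re-run bit-identically.  ``truth_evaluation`` scores the run
against the simulator's ground truth: empirical FDR and power for DMS
calling, meQTL detection and configuration recovery, interaction
classification, and sweep enrichment in the iHS top tail.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import selscan as sel_mod
from ._rng import stage_seed
from .dms import DifferentialMethylation, direction_concordance, overlap_resampling_test
from .meqtl import CisMeqtlScan
from .methio import (
    adjust_mvalues,
    annotate_sites_with_intervals,
    estimate_cell_proportions,
    filter_probes,
)
from .simulate import (
    CohortDesign,
    DmsSpec,
    MeqtlSpec,
    SyntheticCohort,
    effect_for_r2,
    simulate_cohort,
)

log = logging.getLogger("popepimeth")

__all__ = ["PipelineConfig", "ReportBundle", "demo_design", "run_pipeline", "truth_evaluation"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study's defaults."""

    design: CohortDesign
    q_threshold: float = 0.01
    delta_beta_classes: tuple[float, ...] = (0.0, 0.02, 0.05, 0.10)
    min_maf: float = 0.10
    window_bp: int = 200_000
    meqtl_fdr: float = 0.01
    best_posterior: float = 0.85
    tail_fraction: float = 0.05
    daf_bin_cmh: float = 0.1
    daf_bin_ihs: float = 0.025
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.8
    n_resamples: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name, v, lo, hi in [
            ("q_threshold", self.q_threshold, 0, 1),
            ("meqtl_fdr", self.meqtl_fdr, 0, 1),
            ("best_posterior", self.best_posterior, 0, 1),
            ("tail_fraction", self.tail_fraction, 0, 1),
            ("min_maf", self.min_maf, 0, 0.5),
            ("ld_r2", self.ld_r2, 0, 1),
        ]:
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.window_bp <= 0 or self.n_resamples < 100:
            raise ValueError("window_bp must be positive and n_resamples >= 100")

    def config_hash(self) -> str:
        d = asdict(self)
        d["design"]["cell_panel"] = None  # derived from the seed
        blob = yaml.safe_dump(d, sort_keys=True, default_flow_style=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    summaries: dict[str, str]
    manifest: dict
    cohort: SyntheticCohort = None
    dms_results: dict = field(default_factory=dict)
    meqtl_results: object = None

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=True)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        with open(os.path.join(outdir, "summaries.txt"), "w") as fh:
            for name, s in self.summaries.items():
                fh.write(f"== {name} ==\n{s}\n\n")


# ---------------------------------------------------------------------------
# demo design: three populations mirroring a forest hunter-gatherer /
# urban farmer / forest farmer comparison


def demo_design(
    seed: int = 0,
    n_probes: int = 5000,
    n_snps: int = 20_000,
    n_per_pop: int = 60,
    noise_sd: float = 0.3,
    n_meqtl: int = 400,
    n_dms: int = 150,
    meqtl_r2: float = 0.20,
) -> CohortDesign:
    """Three-population design: forest hunter-gatherers (wRHG), urban
    farmers (wAGR) and forest farmers (fAGR), with planted DMS, strong
    cis-meQTLs (default per-population variance explained 0.20, the range of
    a clearly visible genotype effect) of mixed activity configurations, and
    two selective sweeps.  Default prevalences — meQTLs at 8% of probes and
    DMS at 3% — mirror the order of magnitude blood-methylome studies report
    for cis-genetic and between-group methylation differences."""
    rng = np.random.default_rng(stage_seed(seed, "design"))
    pops = {"wRHG": n_per_pop, "wAGR": n_per_pop, "fAGR": n_per_pop}
    # keep planted effects sparse even on very small designs
    n_meqtl = min(n_meqtl, n_probes // 8, n_snps // 8)
    n_dms = min(n_dms, n_probes // 5)
    eff = effect_for_r2(meqtl_r2, 0.3, noise_sd)
    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    snp_ids = [f"rs{i:06d}" for i in range(n_snps)]
    chosen_probes = rng.choice(n_probes, size=n_meqtl + n_dms, replace=False)
    meqtl_probes = chosen_probes[:n_meqtl]
    dms_probes = chosen_probes[n_meqtl:]
    meqtl_snps = rng.choice(n_snps, size=n_meqtl, replace=False)
    configs = (
        [("wRHG", "wAGR", "fAGR")] * (n_meqtl // 2)
        + [("wRHG",)] * (n_meqtl // 4)
        + [("wAGR", "fAGR")] * (n_meqtl - n_meqtl // 2 - n_meqtl // 4)
    )
    meqtl_spec = [
        MeqtlSpec(probe_ids[p], snp_ids[s], eff * (1 if rng.random() < 0.5 else -1), c)
        for p, s, c in zip(meqtl_probes, meqtl_snps, configs)
    ]
    dms_spec = []
    for i, p in enumerate(dms_probes):
        if i % 2 == 0:  # population-driven ("historical"-like)
            dms_spec.append(DmsSpec(probe_ids[p], "population", {"wRHG": 0.5 * (1 if i % 4 == 0 else -1)}))
        else:  # habitat-driven ("recent"-like)
            dms_spec.append(DmsSpec(probe_ids[p], "habitat", {"forest": 0.4 * (1 if i % 4 == 1 else -1)}))
    sweep_snps = rng.choice(np.setdiff1d(np.arange(n_snps), meqtl_snps), size=2, replace=False)
    sweeps = [
        (snp_ids[sweep_snps[0]], "wRHG", 0.6, 300_000),
        (snp_ids[sweep_snps[1]], "fAGR", 0.6, 300_000),
    ]
    return CohortDesign(
        populations=pops,
        habitat={"wRHG": "forest", "wAGR": "urban", "fAGR": "forest"},
        lifestyle={"wRHG": "RHG", "wAGR": "AGR", "fAGR": "AGR"},
        f_div={"wRHG": 0.04, "wAGR": 0.02, "fAGR": 0.02},
        n_snps=n_snps,
        n_probes=n_probes,
        genome_layout={"chr1": 30_000_000, "chr2": 20_000_000},
        meqtl_spec=meqtl_spec,
        dms_spec=dms_spec,
        noise_sd=noise_sd,
        sweeps=sweeps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> ReportBundle:
    config.validate()
    t0 = time.time()
    timings: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, str] = {}

    def tic(stage):
        timings[stage] = time.time()

    def toc(stage):
        timings[stage] = round(time.time() - timings[stage], 2)
        log.info("stage %s done in %.1fs", stage, timings[stage])

    # -- simulate -----------------------------------------------------------
    tic("simulate")
    cohort = simulate_cohort(config.design)
    toc("simulate")

    # -- preprocess ---------------------------------------------------------
    tic("preprocess")
    filtered, filter_report = filter_probes(cohort.methyl, cohort.probe_annot)
    panel_probes = cohort.probe_annot.index[cohort.probe_annot["cell_predictor"]]
    panel_matrix = cohort.methyl.subset_probes(panel_probes)
    cellprops, _ = estimate_cell_proportions(panel_matrix, cohort.panel)
    covariates = cohort.metadata.join(cellprops)
    cell_terms = list(cohort.panel.cell_types)[:-1]  # proportions sum to 1: drop one
    adj_terms = ["sex", "age"] + cell_terms
    adjusted = adjust_mvalues(filtered, covariates, adj_terms)
    tables["filter_report"] = pd.DataFrame([filter_report])
    tables["cell_proportions"] = cellprops
    toc("preprocess")

    # -- differential methylation ------------------------------------------
    tic("dms")
    pops = config.design.pop_labels
    comparisons = [(pops[0], pops[1]), (pops[0], pops[2]), (pops[1], pops[2])]
    dms_results: dict[str, object] = {}
    dms_count_rows = []
    for a, b in comparisons:
        model = DifferentialMethylation(
            filtered, covariates, ("population", a, b), adj_terms
        )
        res = model.fit(q_threshold=config.q_threshold)
        dms_results[f"{a}-vs-{b}"] = res
        row = {"comparison": f"{a}-vs-{b}", "tested": len(res.table)}
        for thr in config.delta_beta_classes:
            row[f"dms_dbeta>{thr:g}"] = len(res.dms_at(thr))
        dms_count_rows.append(row)
    tables["dms_counts"] = pd.DataFrame(dms_count_rows).set_index("comparison")
    first, second = dms_results[f"{pops[0]}-vs-{pops[1]}"], dms_results[f"{pops[0]}-vs-{pops[2]}"]
    conc = direction_concordance(first.dms, second.dms)
    universe = cohort.probe_annot.loc[filtered.probes].sort_values(["chrom", "pos"]).index
    if len(first.dms) and len(second.dms):
        ovl = overlap_resampling_test(
            first.dms.probes, universe, second.dms.probes,
            n_resamples=config.n_resamples, seed=stage_seed(config.seed, "overlap"),
        )
        ovl.pop("null")
    else:
        ovl = {"observed": 0, "expected": np.nan, "p": np.nan}
    tables["dms_overlap"] = pd.DataFrame([{**conc, **{f"rot_{k}": v for k, v in ovl.items()}}])
    summaries["dms"] = "\n\n".join(r.summary() for r in dms_results.values())
    toc("dms")

    # -- meQTL --------------------------------------------------------------
    tic("meqtl")
    scan = CisMeqtlScan(
        adjusted,
        cohort.dosages,
        cohort.snp_annot,
        cohort.probe_annot.loc[adjusted.probes],
        covariates,
        covariate_terms=adj_terms,
        window_bp=config.window_bp,
        min_maf=config.min_maf,
    )
    meqtl_res = scan.fit(fdr=config.meqtl_fdr, best_posterior=config.best_posterior)
    tables["meqtl_calls"] = meqtl_res.calls.set_index("probe")
    if len(meqtl_res.r2):
        tables["meqtl_r2"] = meqtl_res.r2.set_index("probe")
    if len(meqtl_res.interactions):
        tables["meqtl_interactions"] = meqtl_res.interactions.set_index("probe")
    summaries["meqtl"] = meqtl_res.summary()
    toc("meqtl")

    # -- selection scans ----------------------------------------------------
    tic("selscan")
    dosages = cohort.dosages
    a_pop, b_pop, c_pop = pops[0], pops[1], pops[2]
    fst_ab = sel_mod.weir_cockerham_fst(dosages[a_pop], dosages[b_pop])
    fst_ac = sel_mod.weir_cockerham_fst(dosages[a_pop], dosages[c_pop])
    fst_bc = sel_mod.weir_cockerham_fst(dosages[b_pop], dosages[c_pop])
    lsbl_a, lsbl_b, lsbl_c = sel_mod.lsbl(fst_ab, fst_ac, fst_bc)
    sel_table = cohort.snp_annot[["chrom", "pos"]].copy()
    sel_table[f"fst_{a_pop}_{b_pop}"] = fst_ab
    sel_table[f"fst_{a_pop}_{c_pop}"] = fst_ac
    sel_table[f"fst_{b_pop}_{c_pop}"] = fst_bc
    sel_table[f"lsbl_{a_pop}"] = lsbl_a
    sel_table[f"lsbl_{b_pop}"] = lsbl_b
    sel_table[f"lsbl_{c_pop}"] = lsbl_c
    snp_chrom = cohort.snp_annot["chrom"].to_numpy()
    for pop in pops:
        unstd = np.full(len(sel_table), np.nan)
        for chrom in config.design.genome_layout:
            m = snp_chrom == chrom
            if not m.any():
                continue
            res = sel_mod.ihs(
                cohort.haplotypes[pop][:, m],
                cohort.snp_annot.loc[m, "pos"].to_numpy(float),
            )
            unstd[np.flatnonzero(m)[res["snp_idx"].to_numpy()]] = res["ihs_unstd"].to_numpy()
        daf = cohort.snp_annot[f"freq_{pop}"].to_numpy(float)
        sel_table[f"ihs_unstd_{pop}"] = unstd
        sel_table[f"ihs_{pop}"] = sel_mod.standardize_ihs(unstd, daf, config.daf_bin_ihs)
        sel_table[f"daf_{pop}"] = daf
    for col in [f"fst_{a_pop}_{b_pop}", f"lsbl_{a_pop}"] + [f"ihs_{p}" for p in pops]:
        absolute = col.startswith("ihs")
        sel_table[f"top5_{col}"] = sel_mod.top_tail_flags(
            sel_table[col].to_numpy(float), config.tail_fraction, absolute=absolute
        )
    tables["selscan"] = sel_table
    toc("selscan")

    # -- enrichment ---------------------------------------------------------
    tic("enrich")
    enrich_rows = []
    first_dms_probes = first.dms.probes
    analysis_annot = cohort.probe_annot.loc[adjusted.probes]
    target = analysis_annot.index.isin(first_dms_probes)
    for track_name, track in cohort.tracks.items():
        flags = annotate_sites_with_intervals(
            analysis_annot["chrom"].to_numpy(), analysis_annot["pos"].to_numpy(int), track
        )
        r = enrich_mod.region_enrichment_or(target, flags)
        enrich_rows.append(
            {"test": f"dms_x_{track_name}", "or": r.odds_ratio, "se": r.log_or_se, "p": r.pvalue, "method": r.method}
        )
    for cls in analysis_annot["region_class"].unique():
        r = enrich_mod.region_enrichment_or(
            target, (analysis_annot["region_class"] == cls).to_numpy()
        )
        enrich_rows.append(
            {"test": f"dms_x_{cls}", "or": r.odds_ratio, "se": r.log_or_se, "p": r.pvalue, "method": r.method}
        )

    # selection-score enrichment among meQTL SNPs, DAF-stratified
    meqtl_snps = pd.Index(
        sorted({s for row in meqtl_res.called["best_snps"] for s in row.split(",")})
    )
    background = enrich_mod.background_snps_near_probes(
        cohort.snp_annot,
        analysis_annot,
        window_bp=20_000,
        exclude=set(meqtl_snps),
        dosages_all=cohort.all_dosages,
        prune_r2=config.ld_r2,
    )
    snp_universe = meqtl_snps.append(background)
    if len(meqtl_snps) and len(background):
        uni = sel_table.loc[snp_universe]
        pooled_daf = np.vstack(
            [uni[f"daf_{p}"].to_numpy() for p in pops]
        ).mean(axis=0)
        strata = np.minimum((pooled_daf / config.daf_bin_cmh).astype(int), 9)
        is_meqtl = snp_universe.isin(meqtl_snps)
        for col in (f"top5_fst_{a_pop}_{b_pop}", f"top5_lsbl_{a_pop}"):
            r = enrich_mod.cmh_enrichment(uni[col].to_numpy(bool), is_meqtl, strata)
            enrich_rows.append(
                {"test": f"meqtl_x_{col}", "or": r.odds_ratio, "se": r.log_or_se, "p": r.pvalue, "method": r.method}
            )
        r = enrich_mod.region_enrichment_or(
            np.asarray(is_meqtl), uni[f"top5_ihs_{a_pop}"].to_numpy(bool)
        )
        enrich_rows.append(
            {"test": "meqtl_x_top5_abs_ihs", "or": r.odds_ratio, "se": r.log_or_se, "p": r.pvalue, "method": r.method}
        )

    # category over-representation of DMS genes, probe-count-bias-weighted
    gene_col = analysis_annot["gene"]
    probes_per_gene = gene_col[gene_col != "none"].value_counts()
    dms_genes = set(gene_col.loc[gene_col.index.isin(first_dms_probes)]) - {"none"}
    cat = enrich_mod.weighted_category_test(dms_genes, cohort.gene_sets, probes_per_gene)
    if len(cat):
        tables["category_enrichment"] = cat.set_index("category")

    # GWAS annotation
    overall, traits = enrich_mod.gwas_gene_enrichment(
        dms_genes,
        cohort.gwas_catalog,
        probes_per_gene,
        n_resamples=config.n_resamples,
        seed=stage_seed(config.seed, "gwas-gene"),
    )
    enrich_rows.append(
        {"test": "gwas_gene", "or": overall.odds_ratio, "se": overall.log_or_se, "p": overall.pvalue, "method": overall.method}
    )
    if len(traits):
        tables["gwas_traits"] = traits.set_index("trait")
    if len(meqtl_snps) and len(background) > len(meqtl_snps):
        catalog_hits = set(
            cohort.gwas_catalog.loc[cohort.gwas_catalog["pvalue"] < 5e-8, "snp"]
        )
        snp_r = enrich_mod.gwas_snp_enrichment(
            meqtl_snps,
            catalog_hits,
            cohort.snp_annot,
            cohort.all_dosages,
            background,
            r2=config.ld_r2,
            n_resamples=min(config.n_resamples, 2000),
            seed=stage_seed(config.seed, "gwas-snp"),
        )
        enrich_rows.append(
            {"test": "gwas_snp", "or": snp_r.odds_ratio, "se": snp_r.log_or_se, "p": snp_r.pvalue, "method": snp_r.method}
        )

    # PWM affinity of DMS probes (top-5% high-affinity rule per motif)
    seqs = analysis_annot["seq30"].tolist()
    scores, hi = enrich_mod.pwm_affinity(seqs, cohort.pwms, top_fraction=config.tail_fraction)
    for motif in list(cohort.pwms)[:3]:
        r = enrich_mod.region_enrichment_or(target, hi[motif].to_numpy(bool))
        enrich_rows.append(
            {"test": f"dms_x_tf_{motif}", "or": r.odds_ratio, "se": r.log_or_se, "p": r.pvalue, "method": r.method}
        )
    tables["enrichment"] = pd.DataFrame(enrich_rows).set_index("test")
    toc("enrich")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "timings_s": timings,
        "wall_clock_s": round(time.time() - t0, 2),
        "n_probes_analyzed": int(len(adjusted.probes)),
        "n_snps": int(config.design.n_snps),
    }
    bundle = ReportBundle(
        tables=tables,
        summaries=summaries,
        manifest=manifest,
        cohort=cohort,
        dms_results=dms_results,
        meqtl_results=meqtl_res,
    )
    if outdir:
        bundle.write(outdir)
    return bundle


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "popepimeth": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.version.full_version
        if hasattr(statsmodels, "version")
        else getattr(statsmodels, "__version__", "?"),
    }


# ---------------------------------------------------------------------------
# truth evaluation


def _true_dms_for_comparison(design: CohortDesign, pop_a: str, pop_b: str) -> dict[str, float]:
    """Probe -> true ΔM (A minus B) implied by the planted specs."""
    out: dict[str, float] = {}
    hab_a, hab_b = design.habitat[pop_a], design.habitat[pop_b]
    for spec in design.dms_spec:
        if spec.factor == "population":
            dm = spec.effects.get(pop_a, 0.0) - spec.effects.get(pop_b, 0.0)
        else:
            dm = spec.effects.get(hab_a, 0.0) - spec.effects.get(hab_b, 0.0)
        if dm != 0:
            out[spec.probe] = out.get(spec.probe, 0.0) + dm
    return {p: v for p, v in out.items() if v != 0}


def truth_evaluation(bundle: ReportBundle, config: PipelineConfig) -> pd.DataFrame:
    """Parameter-recovery metrics for a simulated run."""
    cohort = bundle.cohort
    if cohort is None:
        raise ValueError("truth evaluation needs an in-memory simulated run")
    design = config.design
    pops = design.pop_labels
    rows = []

    meqtl_probes = {spec.probe for spec in design.meqtl_spec}
    for name, res in bundle.dms_results.items():
        a, b = name.split("-vs-")
        true_dm = _true_dms_for_comparison(design, a, b)
        called = set(res.dms.probes)
        tested = set(res.table.index)
        true_pos = set(true_dm) & tested
        tp = len(called & true_pos)
        # probes carrying planted meQTLs can be genuinely differentially
        # methylated through allele-frequency differences; they are neither
        # false nor planted-true positives here
        fp = len(called - true_pos - meqtl_probes)
        rows.append(
            {
                "metric": f"dms_{name}",
                "n_true": len(true_pos),
                "n_called": len(called),
                "empirical_fdr": fp / max(len(called), 1),
                "power": tp / max(len(true_pos), 1),
            }
        )

    meqtl_res = bundle.meqtl_results
    if meqtl_res is not None:
        truth = cohort.truth.meqtl_effects
        kept_snps = set(meqtl_res.snps_kept)
        tested_probes = set(meqtl_res.calls["probe"])
        eligible = truth[truth["snp"].isin(kept_snps) & truth["probe"].isin(tested_probes)]
        called = meqtl_res.called
        called_probes = set(called["probe"])
        tp_probes = called_probes & set(eligible["probe"])
        fp = len(called_probes - set(truth["probe"]))
        cfg_ok = 0
        for _, t in eligible.iterrows():
            if t["probe"] in called_probes:
                row = called[called["probe"] == t["probe"]].iloc[0]
                if set(row["configuration"].split(",")) == set(t["configuration"].split(",")):
                    cfg_ok += 1
        det = len(tp_probes)
        rows.append(
            {
                "metric": "meqtl",
                "n_true": len(eligible),
                "n_called": len(called_probes),
                "empirical_fdr": fp / max(len(called_probes), 1),
                "power": det / max(len(eligible), 1),
                "config_recovery": cfg_ok / max(det, 1),
            }
        )
        # interaction classification vs planted configurations
        if len(meqtl_res.interactions):
            inter = meqtl_res.interactions.set_index("probe")
            truth_cfg = truth.set_index("probe")["configuration"]
            planted_gxe = {
                p for p, c in truth_cfg.items() if set(c.split(",")) != set(pops)
            }
            both = [p for p in inter.index if p in set(truth["probe"])]
            if both:
                pred_gxe = {p for p in both if inter.loc[p, "interaction_class"] == "GxGxE"}
                tp_i = len(pred_gxe & planted_gxe)
                n_gxe = len([p for p in both if p in planted_gxe])
                n_shared = len(both) - n_gxe
                fp_i = len(pred_gxe) - tp_i
                rows.append(
                    {
                        "metric": "interaction",
                        "n_true": n_gxe,
                        "n_called": len(pred_gxe),
                        "power": tp_i / max(n_gxe, 1),
                        "empirical_fdr": fp_i / max(n_shared, 1),
                    }
                )

    # sweep enrichment in the |iHS| top tail
    sel = bundle.tables.get("selscan")
    sweeps = cohort.truth.sweeps
    if sel is not None and len(sweeps):
        from scipy.stats import fisher_exact

        for _, sw in sweeps.iterrows():
            pop = sw["population"]
            col = f"top5_ihs_{pop}"
            if col not in sel.columns:
                continue
            srow = cohort.snp_annot.loc[sw["snp"]]
            in_region = (
                (sel["chrom"] == srow["chrom"])
                & (np.abs(sel["pos"] - srow["pos"]) <= sw["span_bp"] / 2)
            ).to_numpy()
            flags = sel[col].to_numpy(bool)
            scored = sel[f"ihs_{pop}"].notna().to_numpy()
            a = int((in_region & flags & scored).sum())
            b = int((in_region & ~flags & scored).sum())
            c = int((~in_region & flags & scored).sum())
            d = int((~in_region & ~flags & scored).sum())
            orr, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append(
                {
                    "metric": f"sweep_{sw['snp']}_{pop}",
                    "n_true": a + b,
                    "n_called": a,
                    "odds_ratio": orr,
                    "fisher_p": p,
                }
            )
    return pd.DataFrame(rows).set_index("metric")
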