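"""End-to-end orchestration: simulate -> meta -> signals -> coloc -> mr -> progem.

One YAML config drives the whole chain.  Every stage writes its outputs as
TSV plus a JSON manifest recording input hashes, threshold values, the seed
and record counts in/out, so a rerun with an identical config is
byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pqtlkit import coloc as coloc_mod
from pqtlkit import meta as meta_mod
from pqtlkit import mr as mr_mod
from pqtlkit import progem as progem_mod
from pqtlkit import signals as signals_mod
from pqtlkit import simulate as sim_mod
from pqtlkit.sumstats import VariantKey, write_sumstats


@dataclass
class PipelineConfig:
    """All knobs of the chain, defaulted to the study's analysis choices."""

    outdir: str = "pipeline_out"
    seed: int = 1

    # simulation design
    n_blocks: int = 4
    block_size: int = 50
    rho: float = 0.8
    cohort_ns: tuple = sim_mod.DEFAULT_COHORT_NS
    cis_beta: float = 0.12
    trans_beta: float = 0.12
    theta: float = 0.3
    tau: float = 0.0
    eqtl_n: int = 30000
    n_cases: int = 50000
    n_controls: int = 100000

    # meta filters
    p_sig: float = meta_mod.STUDY_WIDE_P
    i2_max: float = 30.0
    min_studies: int = 3
    min_n: float = 3500.0
    min_consistent: int = 3
    maf_min: float = 0.001
    hwe_min: float = 1e-6
    info_min: float = 0.3

    # signal definition
    region_flank: int = signals_mod.REGION_FLANK
    cis_window: int = signals_mod.CIS_WINDOW
    cojo_maf_floor: float = 0.01
    cojo_collinearity: float = 0.9
    prune_r2: float = 0.1

    # colocalization
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp4_robust: float = 0.8

    # MR
    mr_p_thresh: float = mr_mod.GWAS_P
    mr_clump_r2: float = mr_mod.CLUMP_R2
    mr_freq_diff: float = mr_mod.FREQ_DIFF_MAX
    mr_min_instruments: int = mr_mod.MIN_INSTRUMENTS
    heidi_p: float = mr_mod.HEIDI_P
    fdr_q: float = mr_mod.FDR_Q
    locus_p_max: float = mr_mod.LOCUS_P_MAX
    r2_sentinel_min: float = mr_mod.R2_SENTINEL_MIN

    # mediator prioritization
    progem_window: int = progem_mod.LOCAL_WINDOW

    stages: tuple = ("simulate", "meta", "signals", "coloc", "mr", "progem")

    def validate(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0,1)")
        for name in ("p_sig", "coloc_p1", "coloc_p2", "coloc_p12",
                     "mr_p_thresh", "heidi_p", "fdr_q", "locus_p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.min_studies < 1 or self.mr_min_instruments < 1:
            raise ValueError("count thresholds must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cohort_ns"] = list(self.cohort_ns)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["cohort_ns"] = tuple(d.get("cohort_ns", sim_mod.DEFAULT_COHORT_NS))
        d["stages"] = tuple(d.get("stages", cls.stages))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, stage: str, inputs: list[Path],
                    params: dict, counts: dict) -> None:
    manifest = {
        "stage": stage,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "params": params,
        "counts": counts,
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; returns a report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"stages": {}}

    sim = sim_mod.SimConfig(
        n_cohorts=len(config.cohort_ns), cohort_ns=tuple(config.cohort_ns),
        n_blocks=config.n_blocks, block_size=config.block_size,
        rho=config.rho, seed=config.seed)

    # --- simulate -----------------------------------------------------------
    rng = np.random.default_rng(config.seed)
    panel, ld = sim_mod.simulate_ld_panel(sim, rng)
    truth = default_truth(panel, sim, cis_beta=config.cis_beta,
                          trans_beta=config.trans_beta, tau=config.tau)
    cohorts = sim_mod.simulate_protein_gwas(panel, ld, truth, sim,
                                            trait="protein", rng=rng)
    eqtl_causal = {s.variant_index: s.beta_true
                   for s in truth.for_trait("transcript")}
    eqtl = sim_mod.simulate_single_gwas(panel, ld, eqtl_causal,
                                        config.eqtl_n, rng)
    disease = sim_mod.simulate_disease_gwas(
        panel, ld, truth, config.theta, "none", config.n_cases,
        config.n_controls, trait="protein", rng=rng)
    if "simulate" in config.stages:
        for name, df in cohorts.items():
            write_sumstats(df, out / f"protein_{name}.tsv")
        write_sumstats(eqtl, out / "eqtl.tsv")
        write_sumstats(disease, out / "disease.tsv")
        ld.write(out / "ld_matrix.tsv", out / "ld_index.tsv")
        truth.to_json(out / "truth.json")
        genes = default_gene_table(panel, truth)
        _write_gene_table(genes, out / "genes.tsv")
        _write_manifest(out, "simulate",
                        [out / f"protein_{n}.tsv" for n in cohorts]
                        + [out / "eqtl.tsv", out / "disease.tsv"],
                        {"seed": config.seed, "rho": config.rho,
                         "cohort_ns": list(config.cohort_ns)},
                        {"n_variants": len(panel), "n_cohorts": len(cohorts)})
        report["stages"]["simulate"] = {"n_variants": len(panel)}

    # --- meta ---------------------------------------------------------------
    meta = meta_mod.meta_analyze(
        cohorts, p_sig=config.p_sig, i2_max=config.i2_max,
        min_studies=config.min_studies, min_n=config.min_n,
        min_consistent=config.min_consistent, maf_min=config.maf_min,
        hwe_min=config.hwe_min, info_min=config.info_min)
    if "meta" in config.stages:
        meta.to_csv(out / "meta_protein.tsv", sep="\t", index=False,
                    float_format="%.10g")
        counts = meta["VERDICT"].value_counts().to_dict()
        counts["lambda_gc"] = meta_mod.genomic_lambda(meta["Z"].to_numpy())
        _write_manifest(out, "meta", [out / "meta_protein.tsv"],
                        {"p_sig": config.p_sig, "i2_max": config.i2_max,
                         "min_studies": config.min_studies, "min_n": config.min_n},
                        counts)
        report["stages"]["meta"] = counts

    # --- signals ------------------------------------------------------------
    sig = meta[meta["VERDICT"] == "significant"]
    regions = signals_mod.define_regions(sig, flank=config.region_flank,
                                         protein="protein")
    tss_chrom, tss_pos = truth.tss.get("protein", (None, None))
    n_conditional = 0
    for region in regions:
        signals_mod.classify_cis_trans(region, tss_chrom, tss_pos,
                                       window=config.cis_window)
        in_region = meta[(meta["CHR"] == region.chrom)
                         & (meta["POS"].between(region.start, region.end))]
        cond = signals_mod.conditional_stepwise(
            in_region, ld, p_enter=config.p_sig,
            maf_floor=config.cojo_maf_floor,
            collinearity=config.cojo_collinearity, sentinel=region.sentinel)
        pruned = signals_mod.prune_signals(cond, ld, r2_max=config.prune_r2,
                                           forced=[region.sentinel])
        region.conditional_signals = [
            VariantKey(str(r.CHR), int(r.POS), str(r.EA), str(r.OA))
            for r in pruned.itertuples()]
        n_conditional += len(region.conditional_signals)
    if regions:
        sent = [r.sentinel_row for r in regions]
        pve = signals_mod.compute_pve(
            [s["BETA"] for s in sent], [s["SE"] for s in sent],
            [s["N"] for s in sent], protein="protein")
        for region, term in zip(regions, pve.terms):
            region.pve_contribution = term
    if "signals" in config.stages:
        rframe = signals_mod.regions_to_frame(regions)
        rframe.to_csv(out / "regions.tsv", sep="\t", index=False)
        signals_mod.regions_to_bed(regions).to_csv(
            out / "regions.bed", sep="\t", index=False, header=False)
        _write_manifest(out, "signals", [out / "regions.tsv"],
                        {"flank": config.region_flank,
                         "cis_window": config.cis_window,
                         "prune_r2": config.prune_r2},
                        {"n_regions": len(regions),
                         "n_cis": sum(r.label == "cis" for r in regions),
                         "n_trans": sum(r.label == "trans" for r in regions),
                         "n_conditional": n_conditional})
        report["stages"]["signals"] = {"n_regions": len(regions),
                                       "n_conditional": n_conditional}

    # --- coloc --------------------------------------------------------------
    priors = (config.coloc_p1, config.coloc_p2, config.coloc_p12)
    coloc_rows = []
    best_pp4_by_region: dict[int, float] = {}
    for i, region in enumerate(regions):
        p_region = meta[(meta["CHR"] == region.chrom)
                        & (meta["POS"].between(region.start, region.end))]
        e_region = eqtl[(eqtl["CHR"] == region.chrom)
                        & (eqtl["POS"].between(region.start, region.end))]
        if len(e_region) == 0:
            continue
        # conditional-then-pairwise: multi-signal pQTL loci would otherwise
        # mask a shared signal behind the single-causal-variant assumption
        pw = coloc_mod.pwcoco(p_region, e_region, ld,
                              p_cutoff=config.mr_p_thresh,
                              collinearity=config.cojo_collinearity,
                              priors=priors)
        marg = pw.matrix[("marginal", "marginal")]
        best_pp4_by_region[i] = pw.max_pp4
        coloc_rows.append({"REGION": i, "LABEL": region.label,
                           "N_VARIANTS": marg.n_variants, **marg.as_dict(),
                           "MAX_PP4": pw.max_pp4,
                           "COLOCALIZED": pw.max_pp4 >= config.pp4_robust})
    if "coloc" in config.stages:
        cframe = pd.DataFrame(coloc_rows) if coloc_rows else pd.DataFrame(
            columns=["REGION", "LABEL", "N_VARIANTS", "PP0", "PP1", "PP2",
                     "PP3", "PP4", "MAX_PP4", "COLOCALIZED"])
        cframe.to_csv(out / "coloc_eqtl.tsv", sep="\t", index=False,
                      float_format="%.10g")
        _write_manifest(out, "coloc", [out / "coloc_eqtl.tsv"],
                        {"priors": list(priors), "pp4": config.pp4_robust},
                        {"n_tested": len(coloc_rows),
                         "n_colocalized": int(sum(r["COLOCALIZED"] for r in coloc_rows))})
        report["stages"]["coloc"] = {"n_tested": len(coloc_rows)}

    # --- mr -----------------------------------------------------------------
    mr_results = []
    locus_info = {}
    cis_regions = [r for r in regions if r.label == "cis"]
    for region in cis_regions:
        exp_df = meta[(meta["CHR"] == region.chrom)
                      & (meta["POS"].between(region.start, region.end))]
        out_df = disease[(disease["CHR"] == region.chrom)
                         & (disease["POS"].between(region.start, region.end))]
        res = mr_mod.mr_protein_disease(
            exp_df, out_df, ld, exposure="protein", outcome="disease",
            p_thresh=config.mr_p_thresh, clump_r2=config.mr_clump_r2,
            freq_diff_max=config.mr_freq_diff,
            min_instruments=config.mr_min_instruments, p_heidi=config.heidi_p)
        if res is None:
            continue
        dis_min_p = float(out_df["P"].min()) if len(out_df) else 1.0
        best_dis = out_df.loc[out_df["P"].idxmin()] if len(out_df) else None
        r2_sd = float("nan")
        if best_dis is not None:
            i = ld.index_of(region.sentinel)
            j = ld.index_of(VariantKey(str(best_dis["CHR"]), int(best_dis["POS"]),
                                       str(best_dis["EA"]), str(best_dis["OA"])))
            r2_sd = float(ld.r[i, j] ** 2)
        pw = coloc_mod.pwcoco(exp_df, out_df, ld, p_cutoff=config.mr_p_thresh,
                              collinearity=config.cojo_collinearity,
                              priors=priors,
                              prior_sd2=coloc_mod.PRIOR_SD_CC)
        locus_info[("protein", "disease")] = {
            "disease_min_p": dis_min_p, "r2_sentinel_disease": r2_sd,
            "pwcoco_pp4": pw.max_pp4}
        mr_results.append(res)
    mr_results = mr_mod.fdr_and_robustness(
        mr_results, locus_info, q_max=config.fdr_q,
        locus_p_max=config.locus_p_max, r2_min=config.r2_sentinel_min)
    if "mr" in config.stages:
        mframe = mr_mod.results_to_frame(mr_results)
        mframe.to_csv(out / "mr_results.tsv", sep="\t", index=False,
                      float_format="%.10g")
        _write_manifest(out, "mr", [out / "mr_results.tsv"],
                        {"p_thresh": config.mr_p_thresh,
                         "clump_r2": config.mr_clump_r2,
                         "heidi_p": config.heidi_p, "fdr_q": config.fdr_q},
                        {"n_tested": len(mr_results),
                         "n_robust": sum(r.verdict == "robust" for r in mr_results)})
        report["stages"]["mr"] = {"n_tested": len(mr_results)}

    # --- progem -------------------------------------------------------------
    progem_frames = []
    genes = default_gene_table(panel, truth)
    target = next((g for g in genes if g.gene == "TARGET"), None)
    eqtl_sent = _eqtl_sentinels(eqtl, genes, config)
    for region in regions:
        if region.label != "trans":
            continue
        rep = progem_mod.prioritize_mediators(
            region.sentinel, target, genes, eqtl_sentinels=eqtl_sent,
            ld=ld, window=config.progem_window)
        progem_frames.append(progem_mod.report_to_frame(rep))
    if "progem" in config.stages:
        pframe = (pd.concat(progem_frames, ignore_index=True)
                  if progem_frames else pd.DataFrame(
                      columns=["SENTINEL", "TARGET", "GENE", "RANK"]))
        pframe.to_csv(out / "mediators.tsv", sep="\t", index=False,
                      float_format="%.10g")
        _write_manifest(out, "progem", [out / "mediators.tsv"],
                        {"window": config.progem_window},
                        {"n_loci": len(progem_frames)})
        report["stages"]["progem"] = {"n_loci": len(progem_frames)}

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# default synthetic study layout
# ---------------------------------------------------------------------------


def default_truth(panel: pd.DataFrame, sim: sim_mod.SimConfig,
                  cis_beta: float = 0.12, trans_beta: float = 0.12,
                  tau: float = 0.0) -> sim_mod.TruthTable:
    """One protein with three cis causal variants (block 0) and one trans
    signal (block 2); a transcript sharing the first cis causal variant.

    Three quasi-independent cis variants give the MR stage its minimum
    instrument count; the trans signal exercises locus classification and
    mediator prioritization.  The protein's gene TSS sits at the centre of
    block 0.
    """
    bs = sim.block_size
    cis_idx = [bs // 8, bs // 2, (7 * bs) // 8]
    trans_idx = 2 * bs + bs // 2 if sim.n_blocks > 2 else None
    # the first cis variant is the strongest, so it is the sentinel and the
    # top disease variant with high probability (secondary signals at 3/4 size)
    cis_betas = [cis_beta, 0.75 * cis_beta, 0.75 * cis_beta]
    signals = [sim_mod.PlantedSignal("protein", i, b, tau=tau,
                                     shared_with=("transcript",) if i == cis_idx[0] else ())
               for i, b in zip(cis_idx, cis_betas)]
    signals.append(sim_mod.PlantedSignal("transcript", cis_idx[0], cis_beta))
    if trans_idx is not None:
        signals.append(sim_mod.PlantedSignal("protein", trans_idx, trans_beta))
        # the trans sentinel is also a cis-eQTL (for the mediating gene)
        signals.append(sim_mod.PlantedSignal("transcript", trans_idx, cis_beta))
    block0 = panel[panel["BLOCK"] == 0]
    tss = int(block0["POS"].iloc[len(block0) // 2])
    return sim_mod.TruthTable(signals=signals, tss={"protein": ("1", tss)})


def default_gene_table(panel: pd.DataFrame,
                       truth: sim_mod.TruthTable) -> list[progem_mod.GeneAnnotation]:
    """Gene annotation for the synthetic genome.

    The target protein's gene sits at its TSS; around each trans sentinel
    block a handful of local genes are laid out, one of which (the planted
    mediator, nearest the trans causal variant) interacts with the target
    and shares annotation terms with it.
    """
    genes: list[progem_mod.GeneAnnotation] = []
    chrom, tss = truth.tss.get("protein", ("1", int(panel["POS"].iloc[0])))
    target_terms = frozenset({f"GO:{i:04d}" for i in range(10)})
    genes.append(progem_mod.GeneAnnotation(
        "TARGET", chrom, tss, terms=target_terms,
        partners=frozenset({"MEDIATOR"})))
    trans_signals = [s for s in truth.signals
                     if s.trait == "protein"
                     and abs(int(panel["POS"].iloc[s.variant_index]) - tss) > 1_000_000]
    for t, s in enumerate(trans_signals):
        pos = int(panel["POS"].iloc[s.variant_index])
        genes.append(progem_mod.GeneAnnotation(
            "MEDIATOR", "1", max(pos - 5_000, 1),
            terms=frozenset(set(list(target_terms)[:6]) | {f"MED:{t}"}),
            partners=frozenset({"TARGET"})))
        for g in range(5):
            genes.append(progem_mod.GeneAnnotation(
                f"BYSTANDER{t}_{g}", "1", max(pos - 450_000 + 100_000 * g + 17_000, 1),
                terms=frozenset({f"BG:{t}:{g}:{i}" for i in range(8)})))
    return genes


def _write_gene_table(genes: list[progem_mod.GeneAnnotation], path: Path) -> None:
    pd.DataFrame({
        "GENE": [g.gene for g in genes],
        "CHR": [g.chrom for g in genes],
        "TSS": [g.tss for g in genes],
        "STRAND": [g.strand for g in genes],
        "TERMS": [";".join(sorted(g.terms)) for g in genes],
        "PARTNERS": [";".join(sorted(g.partners)) for g in genes],
    }).to_csv(path, sep="\t", index=False)


def _eqtl_sentinels(eqtl: pd.DataFrame, genes, config) -> dict[str, VariantKey]:
    """Per-gene cis-eQTL sentinel within the local window, if significant."""
    out = {}
    for g in genes:
        win = eqtl[(eqtl["CHR"] == g.chrom)
                   & (eqtl["POS"].between(g.tss - config.progem_window,
                                          g.tss + config.progem_window))]
        if len(win) == 0:
            continue
        best = win.loc[win["P"].idxmin()]
        if best["P"] <= mr_mod.GWAS_P:
            out[g.gene] = VariantKey(str(best["CHR"]), int(best["POS"]),
                                     str(best["EA"]), str(best["OA"]))
    return out
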