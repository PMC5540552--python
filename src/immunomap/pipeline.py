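"""End-to-end pipeline orchestration with fixed-seed reproducibility.

Stage order: simulate -> preprocess -> network -> preserve -> core ->
assoc -> qtl -> enrich. A single global seed fans out to per-stage seeds
by fixed offsets so that re-running one stage reproduces its results.
All thresholds default to the analysis constants: soft power 5 / 4 per
dataset, eigengene merge height 0.2, minimum module size 10,
preservation 20000 permutations at alpha 0.001, association FDR
threshold 6.25e-3, core-gene FDR 0.05, genome-wide 5e-8, cis
permutations 10000, cis/trans distances 1 Mb / 5 Mb, 10 genetic PCs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, core_genes, enrichment, network, preprocess, preservation, qtl
from .simulate import BACKGROUND, SimulationConfig, generate_cohorts, write_cohort

logger = logging.getLogger("immunomap.pipeline")

STAGES = ("simulate", "preprocess", "network", "preserve", "core",
          "assoc", "qtl", "enrich")

_STAGE_SEED_OFFSETS = {s: 1000 * (i + 1) for i, s in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    output_dir: str = "immunomap_results"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    power_discovery: int | None = 5
    power_test: int | None = 4
    r2_threshold: float = 0.85
    min_module_size: int = 10
    cut_quantile: float | None = None
    merge_height: float = 0.2
    preservation_n_perm: int = 20000
    preservation_alpha: float = 0.001
    association_threshold: float = 6.25e-3
    core_fdr: float = 0.05
    gw_threshold: float = 5e-8
    cis_n_perm: int = 10000
    n_pcs: int = 10
    seed: int = 0
    annotations: str | None = None
    last_stage: str = "enrich"

    def validate(self) -> None:
        for name in ("preservation_alpha", "association_threshold", "core_fdr",
                     "gw_threshold", "cut_quantile", "merge_height"):
            v = getattr(self, name)
            if v is not None and not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.last_stage not in STAGES:
            raise ValueError(f"unknown stage {self.last_stage!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return int(config.seed) + _STAGE_SEED_OFFSETS[stage]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the pipeline through ``config.last_stage``; returns the result dir.

    Each stage writes its tables under the result directory and records a
    row count in ``manifest.json``. Same seed, same config => identical
    result directories (timestamps excluded: none are written).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {},
                "config": {k: v for k, v in dataclasses.asdict(config).items()
                           if k != "simulation"},
                "simulation": dataclasses.asdict(config.simulation)}
    manifest["simulation"]["module_sizes"] = config.simulation.module_sizes
    last = STAGES.index(config.last_stage)

    def done(stage, n_rows):
        manifest["stages"][stage] = {"rows": int(n_rows)}
        logger.info("[%s] completed (%d rows)", stage, n_rows)

    # -- simulate ----------------------------------------------------------
    sim = dataclasses.replace(config.simulation, seed=_stage_seed(config, "simulate"))
    cohort1, cohort2, followup, truth = generate_cohorts(sim)
    for name, data in (("cohort1", cohort1), ("cohort2", cohort2),
                       ("followup", followup)):
        write_cohort(data, out / "data" / name)
    truth.module_membership.to_csv(out / "data" / "truth_modules.tsv", sep="\t")
    done("simulate", sum(len(d.samples) for d in (cohort1, cohort2, followup)))
    if last == 0:
        _write_manifest(out, manifest)
        return out

    # -- preprocess --------------------------------------------------------
    adjusted = {}
    for name, data in (("cohort1", cohort1), ("cohort2", cohort2),
                       ("followup", followup)):
        cov = data.covariates[["age", "sex"]]
        adjusted[name] = preprocess.residualize(data.expression.T, cov).T
    done("preprocess", sum(a.size for a in adjusted.values()))
    if last == 1:
        _write_manifest(out, manifest)
        return out

    # -- network -----------------------------------------------------------
    net1, modules1 = network.detect_modules(
        adjusted["cohort1"], beta=config.power_discovery,
        r2_threshold=config.r2_threshold, min_module_size=config.min_module_size,
        cut_quantile=config.cut_quantile, merge_height=config.merge_height)
    modules1.assignment.to_csv(out / "module_assignment.tsv", sep="\t")
    modules1.eigengenes.to_csv(out / "eigengenes_cohort1.tsv", sep="\t")
    modules1.kme.to_csv(out / "kme_cohort1.tsv", sep="\t")
    with open(out / "network_summary.json", "w") as fh:
        json.dump({"beta": net1.beta, "scale_free_r2": net1.scale_free_r2,
                   "n_modules": len(modules1.modules),
                   "module_sizes": {m: int((modules1.assignment == m).sum())
                                    for m in modules1.modules}}, fh, indent=1)
    done("network", len(modules1.assignment))
    if last == 2:
        _write_manifest(out, manifest)
        return out

    # -- preserve ----------------------------------------------------------
    cor_test = {name: network.spearman_correlation(adjusted[name])
                for name in ("cohort2", "followup")}
    beta_test = {"cohort2": config.power_test or net1.beta,
                 "followup": net1.beta}
    pres = {}
    for name in ("cohort2", "followup"):
        pres[name] = preservation.permutation_preservation(
            net1.cor, cor_test[name], modules1.assignment, net1.beta,
            beta_test[name], n_perm=config.preservation_n_perm,
            alpha=config.preservation_alpha,
            seed=_stage_seed(config, "preserve"))
        tidy = pres[name].p_values.stack().rename("p").reset_index()
        tidy.columns = ["module", "statistic", "p"]
        tidy["observed"] = pres[name].observed.stack().to_numpy()
        tidy.to_csv(out / f"preservation_{name}.tsv", sep="\t", index=False)
    preserved = list(pres["cohort2"].preserved.index[pres["cohort2"].preserved])
    with open(out / "preservation_summary.json", "w") as fh:
        json.dump({name: {m: bool(v) for m, v in pres[name].preserved.items()}
                   for name in pres}, fh, indent=1)
    done("preserve", sum(p.p_values.size for p in pres.values()))
    if last == 3:
        _write_manifest(out, manifest)
        return out

    # -- core --------------------------------------------------------------
    keep = modules1.assignment.where(modules1.assignment.isin(preserved), BACKGROUND)
    ms1 = network._module_set(adjusted["cohort1"], keep) if preserved else None
    ms2 = network._module_set(adjusted["cohort2"], keep) if preserved else None
    if preserved:
        core_scan = core_genes.core_gene_scan(
            {"cohort1": ms1, "cohort2": ms2},
            {"cohort1": adjusted["cohort1"], "cohort2": adjusted["cohort2"]},
            fdr_alpha=config.core_fdr)
        core = core_genes.core_sets(core_scan)
    else:
        core_scan = pd.DataFrame()
        core = {}
    core_scan.to_csv(out / "core_genes.tsv", sep="\t", index=False)
    done("core", len(core_scan))
    if last == 4:
        _write_manifest(out, manifest)
        return out

    # -- assoc -------------------------------------------------------------
    def _cohort_assoc(name, data, ms):
        cov_cols = [c for c in ("age", "sex", "oc_use") if c in data.covariates]
        return {"eigengenes": ms.eigengenes, "metabolites": data.metabolites,
                "covariates": data.covariates[cov_cols]}

    if preserved:
        ms_fu = network._module_set(adjusted["followup"], keep)
        scan = associations.module_metabolite_scan(
            [_cohort_assoc("cohort1", cohort1, ms1),
             _cohort_assoc("cohort2", cohort2, ms2)],
            threshold=config.association_threshold)
        scan_c1 = associations.module_metabolite_scan(
            [_cohort_assoc("cohort1", cohort1, ms1)],
            threshold=config.association_threshold)
        scan_fu = associations.module_metabolite_scan(
            [_cohort_assoc("followup", followup, ms_fu)],
            threshold=config.association_threshold)
        stability = associations.longitudinal_stability(
            scan_c1, scan_fu, threshold=config.association_threshold)
    else:
        scan = pd.DataFrame()
        stability = pd.DataFrame()
    scan.to_csv(out / "module_metabolite_meta.tsv", sep="\t", index=False)
    stability.to_csv(out / "longitudinal_stability.tsv", sep="\t", index=False)
    done("assoc", len(scan))
    if last == 5:
        _write_manifest(out, manifest)
        return out

    # -- qtl ---------------------------------------------------------------
    qtl_rows = []
    if preserved:
        pcs = {}
        for name, data in (("cohort1", cohort1), ("cohort2", cohort2)):
            kept = qtl.ld_prune(data.genotypes, data.snp_positions)
            pcs[name] = qtl.genetic_pcs(data.genotypes[kept], config.n_pcs)
        for module in ms1.eigengenes.columns:
            per = []
            for name, data, ms in (("cohort1", cohort1, ms1), ("cohort2", cohort2, ms2)):
                per.append(qtl.mqtl_scan(ms.eigengenes[module], data.genotypes,
                                         data.covariates[["age", "sex"]], pcs[name]))
            meta = qtl.meta_scan(per)
            meta["module"] = module
            meta["significant"] = meta["meta_p"] < config.gw_threshold
            qtl_rows.append(meta.reset_index())
    qtl_table = pd.concat(qtl_rows, ignore_index=True) if qtl_rows else pd.DataFrame()
    qtl_table.to_csv(out / "mqtl_meta.tsv", sep="\t", index=False)
    # eQTL follow-up of significant mQTLs against their module's probes
    eqtl_rows = []
    if len(qtl_table) and qtl_table["significant"].any():
        cdicts = [{"expression": adjusted[name], "dosages": data.genotypes,
                   "covariates": data.covariates[["age", "sex"]], "pcs": pcs[name],
                   "probe_positions": data.probe_positions,
                   "snp_positions": data.snp_positions}
                  for name, data in (("cohort1", cohort1), ("cohort2", cohort2))]
        pp, sp = cohort1.probe_positions, cohort1.snp_positions
        for _, hit in qtl_table[qtl_table["significant"]].iterrows():
            snp, module = hit["snp_id"], hit["module"]
            probes = keep.index[keep == module]
            tr = qtl.trans_eqtl(snp, probes, cdicts,
                                gw_threshold=config.gw_threshold)
            tr = tr.assign(snp=snp, module=module, kind="trans").reset_index(
                names="probe")
            eqtl_rows.append(tr)
            for probe in probes:
                kind = qtl.classify_locus(sp.loc[snp, "chrom"],
                                          int(sp.loc[snp, "pos"]),
                                          pp.loc[probe, "chrom"],
                                          int(pp.loc[probe, "start"]),
                                          int(pp.loc[probe, "end"]))
                if kind == "cis":
                    p_perm = qtl.cis_eqtl_permutation(
                        snp, probe, cdicts, n_perm=config.cis_n_perm,
                        seed=_stage_seed(config, "qtl"))
                    eqtl_rows.append(pd.DataFrame(
                        [{"probe": probe, "meta_z": np.nan, "meta_p": p_perm,
                          "significant": p_perm < 0.05, "snp": snp,
                          "module": module, "kind": "cis_permutation"}]))
    eqtl_table = pd.concat(eqtl_rows, ignore_index=True) if eqtl_rows else pd.DataFrame()
    eqtl_table.to_csv(out / "eqtl_meta.tsv", sep="\t", index=False)
    done("qtl", len(qtl_table) + len(eqtl_table))
    if last == 6:
        _write_manifest(out, manifest)
        return out

    # -- enrich ------------------------------------------------------------
    if config.annotations is not None:
        anns = enrichment.read_annotations(config.annotations)
    else:
        # default synthetic annotation: one term per planted module
        anns = {f"planted_{m}": set(truth.module_membership.index[
            truth.module_membership == m])
            for m in sorted(set(truth.module_membership) - {BACKGROUND})}
    universe = set(cohort1.expression.index)
    if core:
        enr = enrichment.enrich_modules(core, anns, universe, fdr_alpha=0.05)
    else:
        enr = pd.DataFrame()
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    done("enrich", len(enr))
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    manifest["versions"] = {"python": sys.version.split()[0],
                            "numpy": np.__version__, "pandas": pd.__version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
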