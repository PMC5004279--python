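"""End-to-end pipeline driver.

Executes the stage order of the study design: simulate -> qc -> covariates
-> ewas -> permutations -> sliding-window DMRs -> GWAS-region scan ->
enrichment -> mQTL -> co-localization -> meta-analysis.  Every stage writes
its outputs plus a manifest entry (stage, parameters, seed, input/output
checksums) into the run directory; a rerun with an identical configuration
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov_mod
from . import enrichment as enr_mod
from . import metastats, preprocess, qtl
from .coloc import ColocPriors, coloc_abf, coloc_table
from .ewas import DISCOVERY_P, EXPERIMENT_WIDE_P, EWAS, ModelSpec
from .permutation import run_permutations
from .regions import (
    DEFAULT_WINDOW_SIZES,
    SlidingWindowScanner,
    gwas_region_scan,
    reduce_nonoverlapping,
)
from .simulate import (
    GwasRegionSim,
    PlantedEffect,
    SimulationConfig,
    generate_cohort,
    generate_genotypes,
    generate_gwas_summary,
    probe_name,
)

log = logging.getLogger("ewaskit")

ALL_STAGES = (
    "simulate", "qc", "covars", "ewas", "permute", "dmr",
    "regions", "enrich", "mqtl", "coloc", "meta",
)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "ewaskit_run"
    seed: int = 0
    # simulation
    n_cases: int = 100
    n_controls: int = 100
    n_probes: int = 2000
    n_chromosomes: int = 4
    probe_spacing_bp: int = 1000
    batch_levels: int = 2
    noise_sd: float = 0.2
    n_x_probes: int = 40
    n_dmps: int = 3
    dmp_effect_pp: float = 5.0
    dmr_block_size: int = 5
    dmr_effect_pp: float = 3.0
    dmr_correlation: float = 0.5
    n_smoking_probes: int = 10
    smoking_effect_pp: float = 6.0
    n_mqtls: int = 3
    mqtl_slope_pp: float = 4.0
    # analysis
    n_perm: int = 200
    alpha: float = 0.05
    window_sizes: tuple = DEFAULT_WINDOW_SIZES
    experiment_wide_p: float = EXPERIMENT_WIDE_P
    discovery_p: float = DISCOVERY_P
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    n_gwas_regions: int = 4
    stages: tuple = ALL_STAGES
    with_genotypes: bool = True

    def __post_init__(self) -> None:
        for thr in (self.experiment_wide_p, self.discovery_p, self.alpha):
            if not 0 < thr < 1:
                raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("window_sizes", "stages"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Stateful driver over one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []
        self.state: dict = {}

    # ------------------------------------------------------------------ util
    def _record(self, stage: str, t0: float, outputs: list[Path], **params) -> None:
        self.manifest.append(
            {
                "stage": stage,
                "seed": self.config.seed,
                "config_hash": self.config.config_hash(),
                "seconds": round(time.time() - t0, 3),
                "params": params,
                "outputs": {str(p.name): _checksum(p) for p in outputs if p.exists()},
            }
        )
        (self.outdir / "run_manifest.json").write_text(
            json.dumps(self.manifest, indent=1)
        )
        log.info("stage %s done in %.2fs", stage, time.time() - t0)

    def _planted_effects(self) -> list[PlantedEffect]:
        c = self.config
        effects: list[PlantedEffect] = []
        step = max(c.n_probes // 20, c.dmr_block_size + 2)
        cursor = 5
        for _ in range(c.n_dmps):
            effects.append(PlantedEffect("dmp", (probe_name(cursor),), c.dmp_effect_pp))
            cursor += step
        block = tuple(probe_name(cursor + j) for j in range(c.dmr_block_size))
        effects.append(
            PlantedEffect("dmr_block", block, c.dmr_effect_pp, c.dmr_correlation)
        )
        cursor += step
        for j in range(c.n_smoking_probes):
            effects.append(
                PlantedEffect("smoking_probe", (probe_name(cursor + j),), c.smoking_effect_pp)
            )
        cursor += step
        for _ in range(c.n_mqtls):
            effects.append(PlantedEffect("mqtl", (probe_name(cursor),), c.mqtl_slope_pp))
            cursor += step
        return effects

    # ---------------------------------------------------------------- stages
    def stage_simulate(self) -> None:
        t0 = time.time()
        c = self.config
        sim_cfg = SimulationConfig(
            n_cases=c.n_cases,
            n_controls=c.n_controls,
            n_probes=c.n_probes,
            n_chromosomes=c.n_chromosomes,
            probe_spacing_bp=c.probe_spacing_bp,
            batch_levels=c.batch_levels,
            seed=c.seed,
            noise_sd=c.noise_sd,
            n_x_probes=c.n_x_probes,
        )
        effects = self._planted_effects()
        cohort = generate_cohort(sim_cfg, effects)
        genotypes = None
        if c.with_genotypes:
            mqtls = [e for e in effects if e.kind == "mqtl"]
            genotypes = generate_genotypes(
                sim_cfg, (0.1, 0.5), mqtls, cohort=cohort, n_background_snps=30
            )
            genotypes.write(self.outdir / "genotypes")
        cohort.write(self.outdir / "cohort")
        self.state.update(cohort=cohort, genotypes=genotypes, effects=effects)
        self._record(
            "simulate", t0,
            list((self.outdir / "cohort").iterdir()),
            n_samples=sim_cfg.n_samples, n_probes=c.n_probes,
        )

    def stage_qc(self) -> None:
        t0 = time.time()
        cohort = self.state["cohort"]
        rng = np.random.default_rng(self.config.seed + 17)
        det = pd.DataFrame(
            np.where(rng.random(cohort.beta.shape) < 0.002, 0.2, 0.001),
            index=cohort.beta.index, columns=cohort.beta.columns,
        )
        beta, det_report = preprocess.detection_filter(cohort.beta, det)
        outliers = preprocess.pc_outliers(beta.loc[beta.index.intersection(cohort.autosomal_probes())])
        beta = beta.drop(columns=outliers)
        sex_report = pd.DataFrame()
        if self.config.n_x_probes:
            sex_report = preprocess.sex_check(beta, cohort.manifest, cohort.sheet["sex"])
        analysis_probes = beta.index.intersection(cohort.autosomal_probes())
        beta_qc = beta.loc[analysis_probes]
        report = {
            "detection": det_report.to_dict(),
            "pc_outliers": outliers,
            "sex_discordant": sex_report.to_dict("records"),
            "order": "detection -> PC outliers -> sex check -> analysis probe subset",
        }
        (self.outdir / "qc_report.json").write_text(json.dumps(report, indent=1, default=str))
        self.state["beta_qc"] = beta_qc
        self.state["sheet_qc"] = cohort.sheet.loc[beta_qc.columns]
        self._record("qc", t0, [self.outdir / "qc_report.json"],
                     removed_samples=len(det_report.removed_samples) + len(outliers))

    def stage_covars(self) -> None:
        t0 = time.time()
        c = self.config
        beta = self.state["beta_qc"]
        sheet = self.state["sheet_qc"]
        smoking_probes = [
            p for e in self.state["effects"] if e.kind == "smoking_probe" for p in e.probe_ids
        ]
        if smoking_probes:
            wt = pd.DataFrame(
                {"probe": smoking_probes, "weight": 1.0, "direction": "hyper"}
            )
            wt.to_csv(self.outdir / "smoking_weights_used.tsv", sep="\t", index=False)
            score, n_used = cov_mod.smoking_score(beta, cov_mod.SmokingWeights(wt))
        else:
            score, n_used = pd.Series(0.0, index=beta.columns), 0
        k = min(10, beta.shape[1] - 1)
        pcs, pc_report = cov_mod.methylation_pcs(beta, k, phenotypes=sheet)
        covs = cov_mod.assemble_covariates(sheet, score, pcs)
        covs.to_csv(self.outdir / "covariates.csv")
        if pc_report is not None:
            pc_report.to_csv(self.outdir / "pc_phenotype_correlations.csv", index=False)
        self.state["covs"] = covs
        cells = [x for x in covs.columns if x.startswith("cell_")][:-1]
        self.state["base_covariates"] = ("age", "sex", "batch", *cells, "smoking_score")
        self._record("covars", t0, [self.outdir / "covariates.csv"], smoking_probes_used=n_used)

    def stage_ewas(self) -> None:
        t0 = time.time()
        beta = self.state["beta_qc"]
        covs = self.state["covs"]
        cohort = self.state["cohort"]
        spec = ModelSpec("status", self.state["base_covariates"])
        res = EWAS(beta, covs, spec, manifest=cohort.manifest).fit()
        res.to_tsv(self.outdir / "ewas_casecontrol.tsv")
        self.state["ewas_cc"] = res
        self.state["spec_cc"] = spec
        outputs = [self.outdir / "ewas_casecontrol.tsv"]
        if self.state.get("genotypes") is not None:
            gts = self.state["genotypes"]
            rng = np.random.default_rng(self.config.seed + 29)
            w = pd.DataFrame(
                {
                    "snp": gts.dosages.index,
                    "effect_allele": gts.manifest["alt"].to_numpy(),
                    "weight": rng.normal(0, 0.1, len(gts.dosages)),
                }
            )
            prs, _ = qtl.polygenic_score(gts, w)
            covs = covs.assign(prs=prs.reindex(covs.index).fillna(prs.mean()))
            self.state["covs"] = covs
            # smoking deliberately left out of the polygenic-score model
            prs_covs = tuple(x for x in self.state["base_covariates"] if x != "smoking_score")
            spec_prs = ModelSpec("prs", prs_covs)
            res_prs = EWAS(beta, covs, spec_prs, manifest=cohort.manifest).fit()
            res_prs.to_tsv(self.outdir / "ewas_prs.tsv")
            self.state["ewas_prs"] = res_prs
            outputs.append(self.outdir / "ewas_prs.tsv")
        self._record(
            "ewas", t0, outputs,
            experiment_wide_hits=res.count_below(self.config.experiment_wide_p),
            discovery_hits=res.count_below(self.config.discovery_p),
        )

    def stage_permute(self) -> None:
        t0 = time.time()
        perm = run_permutations(
            self.state["beta_qc"], self.state["covs"], self.state["spec_cc"],
            n_perm=self.config.n_perm, seed=self.config.seed + 101,
            store_full=True, alpha=self.config.alpha,
        )
        perm.save(self.outdir / "permutations")
        self.state["perm"] = perm
        self._record(
            "permute", t0,
            list((self.outdir / "permutations").iterdir()),
            n_perm=self.config.n_perm, fwer_threshold=perm.threshold,
        )

    def stage_dmr(self) -> None:
        t0 = time.time()
        beta = self.state["beta_qc"]
        cohort = self.state["cohort"]
        scanner = SlidingWindowScanner(
            beta, cohort.manifest, self.config.window_sizes
        )
        candidates = scanner.combined_p(self.state["ewas_cc"].pvalues())
        thresholds = scanner.thresholds(self.state["perm"], self.config.alpha)
        sig = candidates[
            candidates.apply(lambda r: r["p"] < thresholds[r["window"]], axis=1)
        ] if len(candidates) else candidates
        final = reduce_nonoverlapping(sig)
        out = final.assign(probes=final["probes"].apply(lambda t: ";".join(t)))
        out.to_csv(self.outdir / "dmrs.tsv", sep="\t", index=False)
        (self.outdir / "dmr_thresholds.json").write_text(
            json.dumps({str(k): v for k, v in thresholds.items()}, indent=1)
        )
        self.state["dmrs"] = final
        self._record(
            "dmr", t0, [self.outdir / "dmrs.tsv", self.outdir / "dmr_thresholds.json"],
            candidates=len(candidates), significant=len(sig), final=len(final),
        )

    def _gwas_region_bed(self) -> pd.DataFrame:
        cohort = self.state["cohort"]
        man = cohort.manifest.loc[self.state["beta_qc"].index]
        rng = np.random.default_rng(self.config.seed + 37)
        rows = []
        chroms = [c for c in man["chr"].unique() if c != "X"]
        for i in range(self.config.n_gwas_regions):
            chrom = chroms[i % len(chroms)]
            sub = man[man["chr"] == chrom]
            if len(sub) < 10:
                continue
            start_probe = rng.integers(0, len(sub) - 8)
            width = int(rng.integers(5, 30))
            lo = int(sub["pos"].iloc[start_probe])
            hi = int(sub["pos"].iloc[min(start_probe + width, len(sub) - 1)])
            rows.append({"chr": chrom, "start": lo, "end": hi, "name": f"gwas_region_{i}"})
        return pd.DataFrame(rows)

    def stage_regions(self) -> None:
        t0 = time.time()
        bed = self._gwas_region_bed()
        table = gwas_region_scan(
            self.state["ewas_cc"].pvalues(),
            self.state["ewas_prs"].pvalues() if "ewas_prs" in self.state else None,
            bed,
            self.state["beta_qc"],
            self.state["cohort"].manifest,
            perm_cc=self.state.get("perm"),
            alpha=self.config.alpha,
        )
        table.to_csv(self.outdir / "gwas_regions.tsv", sep="\t", index=False)
        self.state["gwas_regions"] = table
        self._record("regions", t0, [self.outdir / "gwas_regions.tsv"],
                     testable=int(table["testable"].sum()))

    def stage_enrich(self) -> None:
        t0 = time.time()
        cohort = self.state["cohort"]
        beta = self.state["beta_qc"]
        man = cohort.manifest.loc[beta.index]
        universe = set(beta.index)
        discovery = set(
            self.state["ewas_cc"].significant(self.config.discovery_p)["probe"]
        )
        features = {
            f"feature_{name}": set(man.index[man["feature"] == name])
            for name in ("TSS200", "Body")
        }
        results = [
            enr_mod.fisher_overlap(discovery, probes, universe, name, len(features))
            for name, probes in features.items()
            if probes
        ]
        pd.DataFrame([vars(r) for r in results]).to_csv(
            self.outdir / "feature_enrichment.tsv", sep="\t", index=False
        )
        # gene-set enrichment over the manifest's gene annotation
        genes = man[man["gene"] != ""]["gene"]
        probe_counts = genes.value_counts().to_dict()
        rng = np.random.default_rng(self.config.seed + 41)
        gene_pool = sorted(probe_counts)
        pathways = {
            f"pathway_{i:03d}": set(
                rng.choice(gene_pool, size=min(25, len(gene_pool)), replace=False)
            )
            for i in range(20)
        }
        collection = enr_mod.GeneSetCollection(pathways, probe_counts)
        test_genes = set(genes.loc[genes.index.isin(discovery)])
        if test_genes and collection.pathways:
            path_res = enr_mod.go_logistic_enrichment(test_genes, collection)
            grouped = enr_mod.group_pathways(path_res, test_genes, collection)
            path_res.to_csv(self.outdir / "pathway_enrichment.tsv", sep="\t", index=False)
            grouped.to_csv(self.outdir / "pathway_groups.tsv", sep="\t", index=False)
        self._record("enrich", t0, [self.outdir / "feature_enrichment.tsv"],
                     n_discovery=len(discovery))

    def stage_mqtl(self) -> None:
        if self.state.get("genotypes") is None:
            log.info("mqtl stage skipped: no genotypes")
            return
        t0 = time.time()
        gt_qc, report = qtl.genotype_qc(self.state["genotypes"])
        table = qtl.cis_mqtl_scan(
            self.state["beta_qc"], gt_qc, self.state["covs"],
            self.state["cohort"].manifest, window_bp=500_000,
        )
        table.to_csv(self.outdir / "mqtl.tsv", sep="\t", index=False)
        (self.outdir / "genotype_qc.json").write_text(json.dumps(report.to_dict(), indent=1))
        self.state["mqtl"] = table
        self.state["gt_qc"] = gt_qc
        self._record("mqtl", t0, [self.outdir / "mqtl.tsv"], pairs=len(table))

    def stage_coloc(self) -> None:
        if self.state.get("genotypes") is None:
            log.info("coloc stage skipped: no genotypes")
            return
        t0 = time.time()
        priors = ColocPriors(self.config.coloc_p1, self.config.coloc_p2, self.config.coloc_p12)
        results = {}
        rng = np.random.default_rng(self.config.seed + 53)
        for i in range(self.config.n_gwas_regions):
            shared = bool(i % 2 == 0)
            causal1 = int(rng.integers(10, 40))
            causal2 = causal1 if shared else (causal1 + 25) % 50
            sim = GwasRegionSim(
                n_snps=50, causal_index_trait1=causal1, causal_index_trait2=causal2,
                shared=shared, seed=int(rng.integers(0, 2**31 - 1)),
            )
            t1, t2 = generate_gwas_summary(sim)
            results[f"region_{i}"] = coloc_abf(t1, t2, priors)
        table = coloc_table(results)
        table.to_csv(self.outdir / "coloc.tsv", sep="\t", index=False)
        self.state["coloc"] = table
        self._record("coloc", t0, [self.outdir / "coloc.tsv"], n_regions=len(table))

    def stage_meta(self) -> None:
        t0 = time.time()
        c = self.config
        discovery = self.state["ewas_cc"].significant(c.discovery_p)
        if discovery.empty:
            log.info("meta stage: no discovery probes to meta-analyse")
            self._record("meta", t0, [], probes=0)
            return
        # an independent replication cohort with the same planted effects
        sim_cfg = SimulationConfig(
            n_cases=c.n_cases, n_controls=c.n_controls, n_probes=c.n_probes,
            n_chromosomes=c.n_chromosomes, probe_spacing_bp=c.probe_spacing_bp,
            batch_levels=c.batch_levels, seed=c.seed + 7919, noise_sd=c.noise_sd,
        )
        effects = [e for e in self.state["effects"] if e.kind != "mqtl"]
        rep = generate_cohort(sim_cfg, effects)
        cells = [x for x in rep.sheet.columns if x.startswith("cell_")][:-1]
        spec = ModelSpec("status", ("age", "sex", "batch", *cells))
        rep_res = EWAS(rep.beta, rep.sheet, spec).fit()
        probes = [p for p in discovery["probe"] if p in rep_res.table["probe"].values]
        d1 = self.state["ewas_cc"].table.set_index("probe")
        d2 = rep_res.table.set_index("probe")
        long = pd.concat(
            [
                pd.DataFrame({"probe": probes, "cohort": "phase1",
                              "beta": d1.loc[probes, "beta"].to_numpy(),
                              "se": d1.loc[probes, "se"].to_numpy()}),
                pd.DataFrame({"probe": probes, "cohort": "phase2",
                              "beta": d2.loc[probes, "beta"].to_numpy(),
                              "se": d2.loc[probes, "se"].to_numpy()}),
            ]
        )
        meta = metastats.meta_analyse_table(long)
        concordant = int(
            (np.sign(d1.loc[probes, "beta"].to_numpy()) == np.sign(d2.loc[probes, "beta"].to_numpy())).sum()
        )
        sign_p = metastats.sign_test(concordant, len(probes)) if probes else np.nan
        meta.to_csv(self.outdir / "meta_analysis.tsv", sep="\t", index=False)
        (self.outdir / "replication.json").write_text(
            json.dumps(
                {"n_probes": len(probes), "concordant": concordant, "sign_test_p": sign_p},
                indent=1,
            )
        )
        self._record("meta", t0, [self.outdir / "meta_analysis.tsv"],
                     probes=len(probes), concordant=concordant)

    # ------------------------------------------------------------------- run
    def run(self) -> Path:
        stage_fns = {
            "simulate": self.stage_simulate, "qc": self.stage_qc,
            "covars": self.stage_covars, "ewas": self.stage_ewas,
            "permute": self.stage_permute, "dmr": self.stage_dmr,
            "regions": self.stage_regions, "enrich": self.stage_enrich,
            "mqtl": self.stage_mqtl, "coloc": self.stage_coloc,
            "meta": self.stage_meta,
        }
        deps = {
            "qc": ["simulate"], "covars": ["qc"], "ewas": ["covars"],
            "permute": ["ewas"], "dmr": ["permute"], "regions": ["permute"],
            "enrich": ["ewas"], "mqtl": ["covars"], "coloc": ["simulate"],
            "meta": ["ewas"],
        }
        requested = [s for s in ALL_STAGES if s in self.config.stages]
        needed: list[str] = []

        def add(stage: str) -> None:
            for d in deps.get(stage, []):
                add(d)
            if stage not in needed:
                needed.append(stage)

        for s in requested:
            add(s)
        for stage in needed:
            try:
                stage_fns[stage]()
            except Exception as exc:
                raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc
        return self.outdir


def run_pipeline(config: RunConfig) -> Path:
    """Run all requested stages; returns the run directory."""
    return PipelineRun(config).run()


def validate_inputs(
    beta: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    genotypes=None,
    bed: pd.DataFrame | None = None,
) -> dict:
    """Cross-check identifier agreement and coordinate conventions."""
    errors: list[str] = []
    warnings_: list[str] = []
    if beta is not None and sheet is not None:
        missing = [s for s in beta.columns if s not in sheet.index]
        if missing:
            errors.append(f"samples in beta but not sample sheet: {missing[:10]}")
    if beta is not None and manifest is not None:
        missing = [p for p in beta.index if p not in manifest.index]
        if missing:
            errors.append(f"probes in beta but not manifest: {missing[:10]}")
    if genotypes is not None and beta is not None:
        shared = [s for s in beta.columns if s in genotypes.dosages.columns]
        if not shared:
            errors.append("no shared samples between methylation and genotype data")
    if bed is not None:
        if bed.attrs.get("sorted"):
            warnings_.append(bed.attrs["sorted"])
        if bed.attrs.get("coordinate_conversion"):
            warnings_.append(bed.attrs["coordinate_conversion"])
    report = {"errors": errors, "warnings": warnings_, "ok": not errors}
    if errors:
        raise ValueError("; ".join(errors))
    return report
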