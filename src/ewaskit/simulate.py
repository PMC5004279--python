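"""Synthetic 450K-style cohort, genotype and GWAS summary generation.

Emulates the statistical structure a blood-based methylation-array
case-control study assumes, so that every downstream stage of the pipeline
is testable without any external download:

* per-probe bimodal baseline methylation, mixed over cell types via
  sample-specific Dirichlet proportions times cell-type reference profiles
  (the confounding that cell-composition covariates remove);
* additive batch offsets and sample noise on the logit scale, transformed
  back and clipped to [0.001, 0.999];
* planted case-control DMPs (percentage-point shifts), correlated DMR
  blocks (shared latent factor per block), smoking-associated probes driven
  by a latent smoker indicator whose prevalence differs by case status;
* monozygotic twin pairs sharing age, sex, batch, genotypes and a tunable
  fraction of the baseline methylation variance;
* Hardy-Weinberg genotypes with planted cis-mQTLs (per-allele shifts), and
  X-chromosome / SNP-control probes for the sample QC checks;
* region-level GWAS summary statistics for two traits with exponential-decay
  LD and shared or distinct causal variants, feeding co-localization.

All randomness flows from a single ``numpy.random.default_rng(seed)``
stream; regenerating with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "GwasRegionSim",
    "Cohort",
    "Genotypes",
    "generate_cohort",
    "generate_genotypes",
    "generate_gwas_summary",
]

_BLOOD_CELLS = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran", "Eos")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic cohort."""

    n_cases: int = 100
    n_controls: int = 100
    n_probes: int = 1000
    n_chromosomes: int = 2
    probe_spacing_bp: int = 1000
    cell_types: int = 7
    batch_levels: int = 2
    seed: int = 0
    noise_sd: float = 0.2  # logit-scale residual sd (~5pp at mid-methylation)
    twin_pairs: int = 0
    twin_discordant_fraction: float = 0.8
    twin_correlation: float = 0.5  # within-pair share of residual variance
    smoking_prevalence_cases: float = 0.55
    smoking_prevalence_controls: float = 0.25
    n_x_probes: int = 0
    n_rs_probes: int = 0
    cell_mix_concentration: float = 60.0

    def __post_init__(self) -> None:
        counts = (
            self.n_cases, self.n_controls, self.n_probes, self.n_chromosomes,
            self.cell_types, self.batch_levels, self.twin_pairs,
            self.n_x_probes, self.n_rs_probes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be positive")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        for name in (
            "twin_discordant_fraction", "twin_correlation",
            "smoking_prevalence_cases", "smoking_prevalence_controls",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return 2 * self.twin_pairs if self.twin_pairs else self.n_cases + self.n_controls


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth signal injected into the synthetic data.

    ``effect_size`` is in percentage points of methylation (per allele for
    mQTLs); ``block_correlation`` applies only to ``dmr_block`` effects.
    """

    kind: str  # dmp | dmr_block | smoking_probe | mqtl
    probe_ids: tuple[str, ...]
    effect_size: float
    block_correlation: float = 0.0
    snp_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"dmp", "dmr_block", "smoking_probe", "mqtl"}:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.kind == "dmr_block" and len(self.probe_ids) < 2:
            raise ValueError("dmr_block requires >= 2 probes")
        if not -1.0 <= self.block_correlation <= 1.0:
            raise ValueError("block_correlation must be in [-1, 1]")
        if self.kind != "dmr_block" and self.block_correlation != 0.0:
            raise ValueError("block_correlation applies only to dmr_block effects")
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))


@dataclass(frozen=True)
class GwasRegionSim:
    """One simulated region of paired GWAS summary statistics."""

    n_snps: int
    causal_index_trait1: int
    causal_index_trait2: int
    shared: bool
    effect_sizes: tuple[float, float] = (0.3, 0.3)
    sample_sizes: tuple[int, int] = (10000, 10000)
    ld_decay: float = 0.9
    trait_types: tuple[str, str] = ("cc", "quant")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        for idx in (self.causal_index_trait1, self.causal_index_trait2):
            if not 0 <= idx < self.n_snps:
                raise ValueError("causal index out of range")
        if self.shared and self.causal_index_trait1 != self.causal_index_trait2:
            raise ValueError("shared=True requires equal causal indices")
        if any(n <= 0 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")


def probe_name(i: int) -> str:
    return f"cg{i:07d}"


@dataclass
class Cohort:
    """Container for one generated cohort: beta matrix, sheet, manifest, truth."""

    beta: pd.DataFrame  # probes x samples, in [0, 1]
    sheet: pd.DataFrame  # indexed by sample id
    manifest: pd.DataFrame  # indexed by probe id: chr, pos, gene, feature
    config: SimulationConfig
    effects: tuple[PlantedEffect, ...] = ()

    @property
    def cell_columns(self) -> list[str]:
        return [c for c in self.sheet.columns if c.startswith("cell_")]

    def autosomal_probes(self) -> pd.Index:
        m = self.manifest
        return m.index[~m["chr"].isin(["X"]) & (m["feature"] != "rs_control")]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.beta.to_csv(outdir / "beta.tsv", sep="\t", index_label="probe")
        self.sheet.to_csv(outdir / "samples.csv", index_label="sample_id")
        self.manifest.to_csv(outdir / "manifest.csv", index_label="probe")
        truth = {
            "seed": self.config.seed,
            "config": asdict(self.config),
            "effects": [asdict(e) for e in self.effects],
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


@dataclass
class Genotypes:
    """Allele-count genotypes (SNPs x samples, values 0/1/2 or NaN)."""

    dosages: pd.DataFrame
    manifest: pd.DataFrame  # indexed by snp id: chr, pos, ref, alt, maf

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dosages.to_csv(outdir / "dosages.tsv", sep="\t", index_label="snp")
        self.manifest.to_csv(outdir / "snps.csv", index_label="snp")
        self.write_vcf(outdir / "genotypes.vcf")

    def write_vcf(self, path) -> None:
        samples = list(self.dosages.columns)
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        ]
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for snp, row in self.dosages.iterrows():
            info = self.manifest.loc[snp]
            calls = [
                gt_map.get(int(v), "./.") if np.isfinite(v) else "./."
                for v in row.to_numpy()
            ]
            lines.append(
                f"{info['chr']}\t{int(info['pos'])}\t{snp}\t{info['ref']}\t{info['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls)
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _probe_manifest(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Autosomal probes on evenly spaced positions, then X and rs-control probes."""
    n = config.n_probes
    chroms = np.repeat(
        np.arange(1, config.n_chromosomes + 1),
        int(np.ceil(n / config.n_chromosomes)),
    )[:n]
    pos = np.empty(n, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        pos[idx] = (np.arange(len(idx)) + 1) * config.probe_spacing_bp
    genes = np.array([f"GENE{i // 10:05d}" for i in range(n)], dtype=object)
    intergenic = rng.random(n) < 0.2
    genes[intergenic] = ""
    features = np.where(
        rng.random(n) < 0.3, "TSS200", np.where(rng.random(n) < 0.5, "Body", "5'UTR")
    )
    features[intergenic] = ""
    rows = pd.DataFrame(
        {
            "chr": chroms.astype(str),
            "pos": pos,
            "gene": genes,
            "feature": features,
        },
        index=pd.Index([probe_name(i) for i in range(n)], name="probe"),
    )
    extra = []
    for i in range(config.n_x_probes):
        extra.append(("X", (i + 1) * config.probe_spacing_bp, "", "x_probe", f"cgX{i:05d}"))
    for i in range(config.n_rs_probes):
        extra.append(("1", 10_000_000 + i * 1000, "", "rs_control", f"rs{i:07d}"))
    if extra:
        ex = pd.DataFrame(
            [e[:4] for e in extra],
            columns=["chr", "pos", "gene", "feature"],
            index=pd.Index([e[4] for e in extra], name="probe"),
        )
        rows = pd.concat([rows, ex])
    return rows


def _sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    if config.twin_pairs:
        n_pairs = config.twin_pairs
        n = 2 * n_pairs
        n_disc = int(round(config.twin_discordant_fraction * n_pairs))
        status = np.zeros(n, dtype=int)
        status[0 : 2 * n_disc : 2] = 1  # first member of each discordant pair
        pair = np.repeat([f"pair{i:04d}" for i in range(n_pairs)], 2)
        age = np.repeat(np.clip(rng.normal(45, 12, n_pairs), 18, 90), 2)
        sex = np.repeat(rng.integers(0, 2, n_pairs), 2)
        batch = np.repeat(rng.integers(0, config.batch_levels, n_pairs), 2)
        cohort = "twins"
    else:
        n = config.n_cases + config.n_controls
        status = np.r_[np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
        pair = np.full(n, "", dtype=object)
        age = np.clip(rng.normal(45, 12, n), 18, 90)
        sex = rng.integers(0, 2, n)
        batch = rng.integers(0, config.batch_levels, n)
        cohort = "casecontrol"
    prev = np.where(
        status == 1, config.smoking_prevalence_cases, config.smoking_prevalence_controls
    )
    smoker = (rng.random(n) < prev).astype(int)
    sheet = pd.DataFrame(
        {
            "status": status,
            "age": np.round(age, 1),
            "sex": sex,
            "batch": np.array([f"b{b + 1}" for b in batch], dtype=object),
            "cohort": cohort,
            "twin_pair": pair,
            "smoker": smoker,
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id"),
    )
    k = config.cell_types
    names = list(_BLOOD_CELLS[:k]) if k <= len(_BLOOD_CELLS) else [f"ct{j}" for j in range(k)]
    base = np.array([0.55, 0.25, 0.08, 0.05, 0.04, 0.02, 0.01][:k] or [1.0])
    if len(base) < k:
        base = np.r_[base, np.full(k - len(base), 0.01)]
    base = base / base.sum()
    props = rng.dirichlet(base * config.cell_mix_concentration, size=n)
    if config.twin_pairs:
        props[1::2] = props[0::2]  # co-twins share composition structure loosely
        props[1::2] = 0.5 * props[1::2] + 0.5 * rng.dirichlet(
            base * config.cell_mix_concentration, size=config.twin_pairs
        )
        props = props / props.sum(axis=1, keepdims=True)
    for j, name in enumerate(names):
        sheet[f"cell_{name}"] = props[:, j]
    return sheet


def _baseline_logits(
    n_probes: int, planted: set[int], rng: np.random.Generator
) -> np.ndarray:
    """Bimodal per-probe baseline means, on the logit scale.

    Probes carrying planted effects are drawn mid-range so percentage-point
    shifts stay inside [0, 1].
    """
    u = rng.random(n_probes)
    mean_beta = np.where(
        u < 0.35, rng.beta(2, 12, n_probes), np.where(u < 0.7, rng.beta(12, 2, n_probes), rng.beta(6, 6, n_probes))
    )
    mean_beta = np.clip(mean_beta, 0.02, 0.98)
    if planted:
        idx = np.fromiter(planted, dtype=int)
        mean_beta[idx] = rng.uniform(0.35, 0.65, len(idx))
    return logit(mean_beta)


def generate_cohort(
    config: SimulationConfig, effects: Sequence[PlantedEffect] = ()
) -> Cohort:
    """Generate a full synthetic cohort with planted effects.

    Returns a :class:`Cohort` whose beta matrix is probes x samples in
    [0.001, 0.999], whose sample sheet carries status, age, sex, batch,
    cell proportions (summing to 1), latent smoker status and twin-pair ids,
    and whose manifest gives 1-based probe positions.
    """
    effects = tuple(effects)
    rng = np.random.default_rng(config.seed)
    manifest = _probe_manifest(config, rng)
    sheet = _sample_sheet(config, rng)
    probes = manifest.index
    probe_pos = {p: i for i, p in enumerate(probes)}
    for eff in effects:
        unknown = [p for p in eff.probe_ids if p not in probe_pos]
        if unknown:
            raise ValueError(f"planted effect names unknown probes: {unknown[:5]}")
    n_probes, n = len(probes), len(sheet)

    planted_rows = {
        probe_pos[p]
        for eff in effects
        if eff.kind in {"dmp", "dmr_block", "smoking_probe", "mqtl"}
        for p in eff.probe_ids
    }
    mu = _baseline_logits(n_probes, planted_rows, rng)

    # cell-type reference profiles: a fifth of probes are strongly
    # cell-variable, the rest nearly invariant
    k = config.cell_types
    cell_var = rng.random(n_probes) < 0.2
    delta = rng.normal(0.0, 0.08, size=(n_probes, k))
    delta[cell_var] = rng.normal(0.0, 0.8, size=(int(cell_var.sum()), k))
    ref = expit(mu[:, None] + delta)  # probes x cell types
    props = sheet[[c for c in sheet.columns if c.startswith("cell_")]].to_numpy()
    expected = ref @ props.T  # probes x samples, in (0, 1)

    # batch offsets + residual noise, on the logit scale
    batch_codes = pd.factorize(sheet["batch"])[0]
    batch_off = rng.normal(0.0, 0.08, size=(n_probes, config.batch_levels))
    z = logit(np.clip(expected, 1e-6, 1 - 1e-6)) + batch_off[:, batch_codes]
    if config.twin_pairs:
        rho = config.twin_correlation
        shared = rng.normal(0.0, config.noise_sd * np.sqrt(rho), size=(n_probes, config.twin_pairs))
        indiv = rng.normal(0.0, config.noise_sd * np.sqrt(1 - rho), size=(n_probes, n))
        z += np.repeat(shared, 2, axis=1) + indiv
    else:
        z += rng.normal(0.0, config.noise_sd, size=(n_probes, n))
    beta = expit(z)

    # X probes: bimodal by sex (the sex-check signal)
    if config.n_x_probes:
        is_x = (manifest["feature"] == "x_probe").to_numpy()
        sex = sheet["sex"].to_numpy()
        x_mean = np.where(sex == 0, 0.72, 0.30)  # female intermediate (inactivation)
        beta[is_x] = np.clip(
            x_mean[None, :] + rng.normal(0, 0.05, size=(int(is_x.sum()), n)), 0.01, 0.99
        )

    # rs control probes: genotype-like trimodal values, identical in co-twins
    if config.n_rs_probes:
        is_rs = (manifest["feature"] == "rs_control").to_numpy()
        g = rng.integers(0, 3, size=(int(is_rs.sum()), n)).astype(float)
        if config.twin_pairs:
            g[:, 1::2] = g[:, 0::2]
        beta[is_rs] = np.clip(
            g / 2 * 0.9 + 0.05 + rng.normal(0, 0.02, size=g.shape), 0.01, 0.99
        )

    status = sheet["status"].to_numpy()
    smoker = sheet["smoker"].to_numpy()
    resid_sd_beta = config.noise_sd * expit(mu) * (1 - expit(mu))  # delta method

    for eff in effects:
        rows = np.array([probe_pos[p] for p in eff.probe_ids])
        shift = eff.effect_size / 100.0
        exp_means = expit(mu[rows])
        if eff.kind in {"dmp", "dmr_block"}:
            pushed = exp_means + shift
            if ((pushed <= 0) | (pushed >= 1)).any():
                raise ValueError(
                    f"effect of {eff.effect_size} pp pushes expected methylation "
                    f"outside [0, 1] for probes {list(eff.probe_ids)[:3]}"
                )
            beta[np.ix_(rows, status == 1)] += shift
        if eff.kind == "dmr_block" and eff.block_correlation > 0:
            rho = eff.block_correlation
            f = rng.standard_normal(n)
            s = resid_sd_beta[rows] * np.sqrt(rho / (1 - rho)) if rho < 1 else resid_sd_beta[rows] * 100
            beta[rows] += s[:, None] * f[None, :]
        if eff.kind == "smoking_probe":
            beta[np.ix_(rows, smoker == 1)] += shift
        # mqtl effects are applied when genotypes are generated

    beta = np.clip(beta, 0.001, 0.999)
    beta_df = pd.DataFrame(beta, index=probes, columns=sheet.index)
    return Cohort(beta_df, sheet, manifest, config, effects)


def generate_genotypes(
    config: SimulationConfig,
    maf_range: tuple[float, float] = (0.1, 0.5),
    mqtl_effects: Sequence[PlantedEffect] = (),
    cohort: Cohort | None = None,
    n_background_snps: int = 20,
    missing_rate: float = 0.0,
) -> Genotypes:
    """Hardy-Weinberg genotypes, with planted cis-mQTLs applied to a cohort.

    One SNP is placed 137 bp from each mQTL target probe; background SNPs
    are spread over the autosomes.  When ``cohort`` is given, each planted
    mQTL shifts methylation at its target probe by ``effect_size``
    percentage points per alternate allele (in place, then re-clipped), and
    co-twins receive identical genotype columns.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    mqtl_effects = tuple(mqtl_effects)
    rng = np.random.default_rng(config.seed + 1_000_003)
    if cohort is not None:
        samples = list(cohort.sheet.index)
    else:
        samples = [f"S{i:04d}" for i in range(config.n_samples)]
    n = len(samples)

    snp_rows = []
    targets = []  # (snp_idx, probe_id, effect_size)
    for eff in mqtl_effects:
        if eff.kind != "mqtl":
            raise ValueError("mqtl_effects must all have kind='mqtl'")
        for p in eff.probe_ids:
            if cohort is not None and p not in cohort.manifest.index:
                raise ValueError(f"mQTL target probe {p} not in manifest")
            if cohort is not None:
                chrom = cohort.manifest.loc[p, "chr"]
                pos = int(cohort.manifest.loc[p, "pos"]) + 137
            else:
                chrom, pos = "1", 137
            sid = eff.snp_id or f"snp_{p}"
            snp_rows.append((sid, str(chrom), pos))
            targets.append((len(snp_rows) - 1, p, eff.effect_size))
    for i in range(n_background_snps):
        chrom = str(1 + i % max(config.n_chromosomes, 1))
        snp_rows.append((f"snpbg{i:05d}", chrom, 5_000_000 + i * 10_000))
    if not snp_rows:
        raise ValueError("no SNPs to generate (empty SNP set)")

    m = len(snp_rows)
    maf = rng.uniform(lo, hi, m)
    g = rng.binomial(2, maf[:, None], size=(m, n)).astype(float)
    if cohort is not None and (cohort.sheet["twin_pair"] != "").any():
        pair_codes = pd.factorize(cohort.sheet["twin_pair"])[0]
        for code in np.unique(pair_codes):
            members = np.flatnonzero(pair_codes == code)
            if cohort.sheet["twin_pair"].iloc[members[0]] == "":
                continue
            g[:, members[1:]] = g[:, [members[0]]]
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = np.nan

    if cohort is not None:
        for snp_idx, p, slope in targets:
            row = cohort.beta.index.get_loc(p)
            vals = cohort.beta.iloc[row].to_numpy() + slope / 100.0 * np.nan_to_num(g[snp_idx])
            clipped = (vals < 0.001) | (vals > 0.999)
            if clipped.mean() > 0.01:
                warnings.warn(
                    f"mQTL shift at {p} clipped {clipped.mean():.0%} of values; "
                    "the realized per-allele slope is attenuated. Declare the "
                    "effect to generate_cohort so the probe gets a mid-range "
                    "baseline.",
                    stacklevel=2,
                )
            cohort.beta.iloc[row] = np.clip(vals, 0.001, 0.999)

    ids = [r[0] for r in snp_rows]
    manifest = pd.DataFrame(
        {
            "chr": [r[1] for r in snp_rows],
            "pos": [r[2] for r in snp_rows],
            "ref": "A",
            "alt": "G",
            "maf": maf,
        },
        index=pd.Index(ids, name="snp"),
    )
    dosages = pd.DataFrame(g, index=manifest.index, columns=samples)
    return Genotypes(dosages, manifest)


def generate_gwas_summary(sim: GwasRegionSim) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP summary statistics for two traits over one LD region.

    Marginal effects follow the LD profile ``r^(|i - causal|)`` around each
    trait's causal SNP; sampling noise is drawn multivariate-normal with the
    LD correlation, and variances scale as ``1 / (N * 2 f (1 - f))``.
    Columns match what co-localization consumes: snp, beta, varbeta, maf,
    type, n.
    """
    rng = np.random.default_rng(sim.seed)
    m = sim.n_snps
    idx = np.arange(m)
    corr = sim.ld_decay ** np.abs(idx[:, None] - idx[None, :])
    maf = rng.uniform(0.1, 0.5, m)
    snps = [f"rs{i:06d}" for i in range(m)]

    def one_trait(causal: int, effect: float, n: int, trait_type: str) -> pd.DataFrame:
        se2 = 1.0 / (n * 2.0 * maf * (1.0 - maf))
        true_marginal = corr[:, causal] * effect
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
        noise = chol @ rng.standard_normal(m)
        beta_hat = true_marginal + np.sqrt(se2) * noise
        return pd.DataFrame(
            {
                "snp": snps,
                "beta": beta_hat,
                "varbeta": se2,
                "maf": maf,
                "type": trait_type,
                "n": n,
            }
        )

    t1 = one_trait(
        sim.causal_index_trait1, sim.effect_sizes[0], sim.sample_sizes[0], sim.trait_types[0]
    )
    t2 = one_trait(
        sim.causal_index_trait2, sim.effect_sizes[1], sim.sample_sizes[1], sim.trait_types[1]
    )
    return t1, t2
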