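"""Genotype quality control, cis-mQTL scanning and polygenic scoring.

Genotype QC removes samples and SNPs by missingness, then SNPs failing a
1-df chi-square Hardy-Weinberg test, a minor-allele-frequency floor, or a
minimum per-genotype-group count (collapsing to two groups when the rare
homozygote is absent).  The cis-mQTL scan fits, for every SNP-probe pair
within a physical window, an additive linear model of methylation (0-100
scale) on allele count with age, sex, and the first two genotype-derived
PCs as covariates.  Polygenic scores are generic weighted allele sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import _ols_many
from .simulate import Genotypes

__all__ = [
    "GenotypeQcParams",
    "GenotypeQcReport",
    "genotype_qc",
    "hwe_chisq_p",
    "genotype_pcs",
    "cis_mqtl_scan",
    "polygenic_score",
]


@dataclass(frozen=True)
class GenotypeQcParams:
    max_missing_sample: float = 0.05
    max_missing_snp: float = 0.05
    hwe_p_floor: float = 0.001
    maf_floor: float = 0.05
    min_group_count: int = 5


@dataclass
class GenotypeQcReport:
    removed_samples: list = field(default_factory=list)
    removed_missing: list = field(default_factory=list)
    removed_hwe: list = field(default_factory=list)
    removed_maf: list = field(default_factory=list)
    removed_group_count: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.__dict__.items()}


def hwe_chisq_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square Hardy-Weinberg test from genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    mask = exp > 0
    chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return float(stats.chi2.sf(chi2, 1))


def genotype_qc(
    gt: Genotypes, params: GenotypeQcParams = GenotypeQcParams()
) -> tuple[Genotypes, GenotypeQcReport]:
    """Missingness, HWE, MAF and genotype-group-count filters.

    Order: samples by missingness, then SNPs by missingness, HWE chi-square
    p < floor, MAF <= floor, and finally any genotype group smaller than
    ``min_group_count`` — checking only the two observed groups for SNPs
    whose rare homozygote is entirely absent.
    """
    report = GenotypeQcReport()
    d = gt.dosages
    sample_miss = d.isna().mean(axis=0)
    bad_samples = sample_miss[sample_miss > params.max_missing_sample].index
    report.removed_samples = sorted(bad_samples)
    d = d.drop(columns=bad_samples)

    snp_miss = d.isna().mean(axis=1)
    report.removed_missing = sorted(snp_miss[snp_miss > params.max_missing_snp].index)
    d = d.drop(index=report.removed_missing)

    keep = []
    for snp, row in d.iterrows():
        vals = row.dropna().to_numpy()
        counts = [(vals == g).sum() for g in (0, 1, 2)]
        n = sum(counts)
        if n == 0:
            report.removed_missing.append(snp)
            continue
        if hwe_chisq_p(*counts) < params.hwe_p_floor:
            report.removed_hwe.append(snp)
            continue
        af_alt = (counts[1] + 2 * counts[2]) / (2 * n)
        maf = min(af_alt, 1 - af_alt)
        if maf <= params.maf_floor:
            report.removed_maf.append(snp)
            continue
        rare_hom = counts[2] if af_alt <= 0.5 else counts[0]
        groups = [c for c in counts if c > 0] if rare_hom == 0 else counts
        if min(groups) < params.min_group_count:
            report.removed_group_count.append(snp)
            continue
        keep.append(snp)
    if not keep:
        raise ValueError(f"all SNPs removed by QC: {report.to_dict()}")
    out = Genotypes(d.loc[keep], gt.manifest.loc[keep])
    return out, report


def genotype_pcs(gt: Genotypes, k: int = 2) -> pd.DataFrame:
    """Top-k PCs of the centered dosage matrix (samples as observations)."""
    x = gt.dosages.to_numpy(dtype=float).T
    x = np.nan_to_num(x - np.nanmean(x, axis=0, keepdims=True))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(k, u.shape[1])
    return pd.DataFrame(
        u[:, :k] * s[:k], index=gt.dosages.columns, columns=[f"gPC{i + 1}" for i in range(k)]
    )


def cis_mqtl_scan(
    beta: pd.DataFrame,
    gt: Genotypes,
    covs: pd.DataFrame,
    manifest: pd.DataFrame,
    window_bp: int = 500_000,
    target_regions: pd.DataFrame | None = None,
    covariate_names: tuple[str, ...] = ("age", "sex"),
    n_genotype_pcs: int = 2,
) -> pd.DataFrame:
    """Additive cis-mQTL scan over SNP-probe pairs within ``window_bp``.

    Methylation is modeled on the 0-100 scale, so slopes read as
    percentage points per alternate allele.  Covariates: the named sample
    columns plus the first two genotype-derived PCs.  ``target_regions``
    (1-based inclusive chr/start/end) optionally restricts probes to those
    within ``window_bp`` of a region.
    """
    samples = [s for s in beta.columns if s in gt.dosages.columns]
    if not samples:
        raise ValueError("no shared samples between methylation and genotypes")
    man = manifest.loc[manifest.index.intersection(beta.index)]
    probe_ok = pd.Series(True, index=man.index)
    if target_regions is not None:
        probe_ok[:] = False
        for _, reg in target_regions.iterrows():
            hit = (man["chr"].astype(str) == str(reg["chr"])) & (
                man["pos"].between(reg["start"] - window_bp, reg["end"] + window_bp)
            )
            probe_ok |= hit
    man = man[probe_ok]

    gpcs = genotype_pcs(gt, n_genotype_pcs)
    cov_block = [covs.loc[samples, c].to_numpy(dtype=float) for c in covariate_names]
    cov_block += [gpcs.loc[samples, c].to_numpy() for c in gpcs.columns]

    rows = []
    y_all = beta.loc[man.index, samples].to_numpy(dtype=float) * 100.0
    for snp, srow in gt.manifest.iterrows():
        near = man[
            (man["chr"].astype(str) == str(srow["chr"]))
            & ((man["pos"] - int(srow["pos"])).abs() <= window_bp)
        ]
        if near.empty:
            continue
        g = gt.dosages.loc[snp, samples].to_numpy(dtype=float)
        ok = np.isfinite(g)
        X = np.column_stack(
            [np.ones(ok.sum()), g[ok]] + [c[ok] for c in cov_block]
        )
        if np.linalg.matrix_rank(X) < X.shape[1] or X.shape[0] <= X.shape[1] + 1:
            continue
        probe_rows = man.index.get_indexer(near.index)
        Y = y_all[probe_rows][:, ok].T
        B, _, XtX_inv, sigma2 = _ols_many(X, Y)
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = B[1] / se
        p = 2.0 * stats.t.sf(np.abs(t), X.shape[0] - X.shape[1])
        for j, probe in enumerate(near.index):
            rows.append(
                {
                    "snp": snp,
                    "probe": probe,
                    "slope": B[1, j],
                    "se": se[j],
                    "t": t[j],
                    "p": p[j],
                    "n": int(ok.sum()),
                }
            )
    if not rows:
        warnings.warn("no SNP-probe pairs within the cis window", stacklevel=2)
        return pd.DataFrame(columns=["snp", "probe", "slope", "se", "t", "p", "n"])
    return pd.DataFrame(rows)


def polygenic_score(
    gt: Genotypes, weights: pd.DataFrame
) -> tuple[pd.Series, dict]:
    """Weighted allele score per sample.

    ``weights`` columns: snp, effect_allele, weight.  When the effect
    allele is the reference allele the dosage is flipped to ``2 - g``;
    SNPs whose effect allele matches neither recorded allele are dropped
    with a warning.  Missing genotypes contribute ``2 * maf * weight``
    (mean imputation), and the report counts weight SNPs absent from the
    genotype data.
    """
    if weights["snp"].duplicated().any():
        raise ValueError("duplicate SNP ids in weight table")
    present = weights[weights["snp"].isin(gt.dosages.index)]
    report = {
        "n_weights": len(weights),
        "n_used": 0,
        "n_missing": int(len(weights) - len(present)),
        "n_unresolvable": 0,
    }
    if present.empty:
        raise ValueError("no weight SNPs present in the genotype data")
    scores = np.zeros(gt.dosages.shape[1])
    used = 0
    for _, wrow in present.iterrows():
        snp = wrow["snp"]
        info = gt.manifest.loc[snp]
        g = gt.dosages.loc[snp].to_numpy(dtype=float)
        maf = float(info.get("maf", np.nanmean(g) / 2))
        g = np.where(np.isfinite(g), g, 2 * maf)
        ea = wrow.get("effect_allele", info["alt"])
        if ea == info["alt"]:
            dose = g
        elif ea == info["ref"]:
            dose = 2.0 - g
        else:
            warnings.warn(f"effect allele mismatch for {snp}; SNP dropped", stacklevel=2)
            report["n_unresolvable"] += 1
            continue
        scores += wrow["weight"] * dose
        used += 1
    report["n_used"] = used
    return pd.Series(scores, index=gt.dosages.columns, name="prs"), report
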