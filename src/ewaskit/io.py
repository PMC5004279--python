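"""Readers and writers for the pipeline's file formats.

Text formats throughout: beta matrices as TSV (probes as rows), sample
sheets and probe manifests as CSV, genomic intervals as BED, gene sets as
GMT, genotypes as minimal VCF (via cyvcf2) or dosage TSV, GWAS summary
statistics and weight tables as TSV.

Coordinate conventions: probe manifests are 1-based (array-manifest style);
BED files are 0-based half-open and converted to 1-based inclusive on read
(start + 1, end unchanged), and back on write.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_beta",
    "write_beta",
    "read_sample_sheet",
    "read_manifest",
    "read_bed",
    "write_bed",
    "read_gmt",
    "read_vcf_genotypes",
    "read_dosage_tsv",
    "read_gwas_summary",
    "read_exclusion_list",
]


def read_beta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe"
    return df


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[])
    for col in df.columns:
        if col in ("twin_pair", "batch", "cohort", "sex"):
            continue
        df[col] = pd.to_numeric(df[col], errors="ignore")
    df.index.name = "sample_id"
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, dtype={"chr": str}, keep_default_na=False, na_values=[])
    df["pos"] = df["pos"].astype(int)
    df.index.name = "probe"
    return df


def read_bed(path, sorted_check: bool = True) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive chr/start/end table.

    Unsorted input is auto-sorted with a warning recorded in ``attrs``.
    """
    cols = ["chr", "start", "end", "name"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(4, df.shape[1])]
    df.columns = cols[: df.shape[1]]
    if "name" not in df:
        df["name"] = [f"region{i:04d}" for i in range(len(df))]
    df["chr"] = df["chr"].astype(str).str.removeprefix("chr")
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    df.attrs["coordinate_conversion"] = "BED 0-based half-open -> 1-based inclusive"
    if sorted_check:
        sorted_df = df.sort_values(["chr", "start"], kind="stable").reset_index(drop=True)
        if not df[["chr", "start"]].equals(sorted_df[["chr", "start"]]):
            import warnings

            warnings.warn("unsorted BED input auto-sorted", stacklevel=2)
            df = sorted_df
            df.attrs["sorted"] = "auto-sorted on read"
    return df


def write_bed(regions: pd.DataFrame, path) -> None:
    """1-based inclusive chr/start/end table -> BED (0-based half-open)."""
    out = regions.copy()
    out["start"] = out["start"].astype(int) - 1
    cols = [c for c in ("chr", "start", "end", "name") if c in out]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, set]:
    from gseapy.parser import read_gmt as _read_gmt

    return {name: set(genes) for name, genes in _read_gmt(str(path)).items()}


def read_vcf_genotypes(path):
    """Minimal VCF (GT field) -> :class:`~ewaskit.simulate.Genotypes`."""
    from cyvcf2 import VCF

    from .simulate import Genotypes

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        counts = var.gt_types.astype(float)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dose = np.where(
            counts == 0, 0.0, np.where(counts == 1, 1.0, np.where(counts == 3, 2.0, np.nan))
        )
        rows.append(dose)
        alt = var.ALT[0] if var.ALT else "."
        meta.append((var.ID, str(var.CHROM).removeprefix("chr"), var.POS, var.REF, alt))
    ids = [m[0] for m in meta]
    manifest = pd.DataFrame(
        {
            "chr": [m[1] for m in meta],
            "pos": [m[2] for m in meta],
            "ref": [m[3] for m in meta],
            "alt": [m[4] for m in meta],
        },
        index=pd.Index(ids, name="snp"),
    )
    dosages = pd.DataFrame(np.array(rows), index=manifest.index, columns=samples)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dosages.to_numpy(), axis=1) / 2
    manifest["maf"] = np.minimum(af, 1 - af)
    return Genotypes(dosages, manifest)


def read_dosage_tsv(path, snp_manifest_path=None):
    from .simulate import Genotypes

    dosages = pd.read_csv(path, sep="\t", index_col=0)
    dosages.index.name = "snp"
    if snp_manifest_path is not None:
        manifest = pd.read_csv(snp_manifest_path, index_col=0, dtype={"chr": str})
    else:
        af = np.nanmean(dosages.to_numpy(dtype=float), axis=1) / 2
        manifest = pd.DataFrame(
            {"chr": "1", "pos": np.arange(1, len(dosages) + 1), "ref": "A", "alt": "G",
             "maf": np.minimum(af, 1 - af)},
            index=dosages.index,
        )
    return Genotypes(dosages, manifest)


def read_gwas_summary(path) -> pd.DataFrame:
    """GWAS summary TSV with columns snp, beta, varbeta (or se), maf, type, n."""
    df = pd.read_csv(path, sep="\t")
    if "varbeta" not in df and "se" in df:
        df["varbeta"] = df["se"] ** 2
    required = {"snp", "beta", "varbeta"}
    if not required.issubset(df.columns):
        raise ValueError(f"GWAS summary needs columns {sorted(required)}")
    return df


def read_exclusion_list(path):
    """One probe id per line with a flag column (probe<TAB>flag)."""
    from .preprocess import ExclusionList

    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "flag"])
    return ExclusionList.from_frame(df)


def write_json(obj, path) -> None:
    import json

    Path(path).write_text(json.dumps(obj, indent=1, default=str))
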