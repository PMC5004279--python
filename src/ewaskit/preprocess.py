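"""Probe and sample quality filters computable from the data matrices.

Implements the matrix-level steps of a 450K QC pipeline: detection-p-value
filtering (samples first, then probes, both with strict ">" fraction rules),
manifest-based probe exclusion (SNP-proximal, cross-hybridizing, optionally
smoking-associated), principal-component outlier removal (flagged only when
beyond k SDs on *both* PC1 and PC2), an X-chromosome sex-concordance check,
and SNP-control-probe concordance within sample pairs (the MZ-twin identity
check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionList",
    "DetectionFilterReport",
    "detection_filter",
    "exclude_probes",
    "pc_outliers",
    "sex_check",
    "snp_probe_concordance",
]


@dataclass(frozen=True)
class ExclusionList:
    """Probe ids flagged for exclusion, by reason."""

    snp_proximal: frozenset = frozenset()
    cross_hybridizing: frozenset = frozenset()
    smoking_associated: frozenset = frozenset()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExclusionList":
        """Build from a two-column table (probe, flag)."""
        groups = {k: frozenset(v) for k, v in df.groupby("flag")["probe"]}
        return cls(
            snp_proximal=groups.get("snp_proximal", frozenset()),
            cross_hybridizing=groups.get("cross_hybridizing", frozenset()),
            smoking_associated=groups.get("smoking_associated", frozenset()),
        )


@dataclass
class DetectionFilterReport:
    removed_samples: list = field(default_factory=list)
    removed_probes: list = field(default_factory=list)
    order: str = "samples-then-probes"

    def to_dict(self) -> dict:
        return {
            "removed_samples": list(self.removed_samples),
            "removed_probes": list(self.removed_probes),
            "order": self.order,
        }


def detection_filter(
    beta: pd.DataFrame,
    det: pd.DataFrame,
    sample_frac: float = 0.01,
    probe_frac: float = 0.01,
    p_cut: float = 0.05,
) -> tuple[pd.DataFrame, DetectionFilterReport]:
    """Drop samples, then probes, with too many failed detections.

    A detection fails when its p-value exceeds ``p_cut``.  Samples whose
    failure fraction is strictly greater than ``sample_frac`` are removed
    first; probe failure fractions are then recomputed over the retained
    samples and probes strictly above ``probe_frac`` removed.
    """
    if not beta.index.equals(det.index) or not beta.columns.equals(det.columns):
        raise ValueError("beta and detection matrices must share identifiers and order")
    fails = det > p_cut
    sample_fail_frac = fails.mean(axis=0)
    bad_samples = sample_fail_frac[sample_fail_frac > sample_frac].index
    kept_samples = beta.columns.difference(bad_samples, sort=False)
    probe_fail_frac = fails[kept_samples].mean(axis=1)
    bad_probes = probe_fail_frac[probe_fail_frac > probe_frac].index
    out = beta.loc[beta.index.difference(bad_probes, sort=False), kept_samples]
    report = DetectionFilterReport(sorted(bad_samples), sorted(bad_probes))
    return out, report


def exclude_probes(
    manifest: pd.DataFrame, excl: ExclusionList, drop_smoking: bool = False
) -> pd.DataFrame:
    """Remove flagged probes from the manifest.

    SNP-proximal and cross-hybridizing probes are always dropped; the
    smoking-associated set only when ``drop_smoking`` is set (the pipeline
    re-runs its association stage with and without them).
    """
    drop = set(excl.snp_proximal) | set(excl.cross_hybridizing)
    if drop_smoking:
        drop |= set(excl.smoking_associated)
    return manifest.loc[~manifest.index.isin(drop)]


def _pc_scores(beta: pd.DataFrame, k: int) -> np.ndarray:
    """Sample scores on the top k PCs of the mean-centered beta matrix."""
    x = beta.to_numpy(dtype=float).T  # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k] * s[:k]


def pc_outliers(beta: pd.DataFrame, k_sd: float = 2.0) -> list[str]:
    """Samples beyond ``k_sd`` standard deviations on both PC1 and PC2.

    The conjunction is deliberate: a sample extreme on only one component is
    retained.  A zero-variance matrix yields no outliers.
    """
    if beta.shape[1] < 3:
        raise ValueError("PC outlier detection requires >= 3 samples")
    scores = _pc_scores(beta, 2)
    if scores.shape[1] < 2 or np.allclose(scores, 0):
        return []
    flags = np.ones(scores.shape[0], dtype=bool)
    for j in range(2):
        col = scores[:, j]
        sd = col.std()
        if sd == 0:
            return []
        flags &= np.abs(col - col.mean()) > k_sd * sd
    return [s for s, f in zip(beta.columns, flags) if f]


def sex_check(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    reported_sex: pd.Series,
    min_gap_sd: float = 0.5,
) -> pd.DataFrame:
    """Two-group partition of X-probe scores versus reported sex.

    Samples are scored on the first principal coordinate of the
    X-chromosome probes and split at the largest gap in the sorted scores;
    each cluster is assigned the majority reported sex, and discordant
    samples are returned.  When the split is degenerate (one cluster, or a
    gap smaller than ``min_gap_sd`` score SDs) a warning is issued and no
    calls are made.
    """
    x_probes = manifest.index[manifest["chr"].astype(str) == "X"]
    x_probes = x_probes.intersection(beta.index)
    if len(x_probes) == 0:
        raise ValueError("no X-chromosome probes available for the sex check")
    scores = _pc_scores(beta.loc[x_probes], 1)[:, 0]
    order = np.argsort(scores)
    sorted_scores = scores[order]
    gaps = np.diff(sorted_scores)
    empty = pd.DataFrame(columns=["sample", "reported", "inferred_cluster"])
    if len(gaps) == 0 or scores.std() == 0:
        warnings.warn("degenerate X-probe clustering; no sex calls made", stacklevel=2)
        return empty
    cut = int(np.argmax(gaps))
    if gaps[cut] < min_gap_sd * scores.std():
        warnings.warn(
            "no clear two-group separation on X probes; no sex calls made", stacklevel=2
        )
        return empty
    cluster = (scores > sorted_scores[cut]).astype(int)
    reported = reported_sex.loc[beta.columns]
    # majority-vote cluster -> sex assignment
    assign = {}
    for c in (0, 1):
        members = reported[cluster == c]
        if len(members) == 0:
            warnings.warn("degenerate X-probe clustering; no sex calls made", stacklevel=2)
            return empty
        assign[c] = members.mode().iloc[0]
    if assign[0] == assign[1]:
        warnings.warn("clusters map to a single sex; no sex calls made", stacklevel=2)
        return empty
    inferred = pd.Series([assign[c] for c in cluster], index=beta.columns)
    discordant = inferred != reported
    return pd.DataFrame(
        {
            "sample": beta.columns[discordant],
            "reported": reported[discordant].to_numpy(),
            "inferred_cluster": inferred[discordant].to_numpy(),
        }
    ).reset_index(drop=True)


def snp_probe_concordance(
    beta: pd.DataFrame,
    rs_probe_ids: list[str],
    pairs: list[tuple[str, str]],
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Within-pair Pearson correlation of SNP-control-probe values.

    Genetically identical pairs (MZ twins, duplicates) should correlate
    near 1 on the trimodal rs probes; pairs below ``threshold`` are flagged.
    """
    rs = [p for p in rs_probe_ids if p in beta.index]
    if len(rs) < 3:
        raise ValueError("need >= 3 SNP-control probes present in the matrix")
    sub = beta.loc[rs]
    rows = []
    for a, b in pairs:
        if a not in sub.columns or b not in sub.columns:
            raise ValueError(f"pair member missing from matrix: {(a, b)}")
        r = float(np.corrcoef(sub[a], sub[b])[0, 1])
        rows.append({"sample_a": a, "sample_b": b, "r": r, "flagged": r < threshold})
    return pd.DataFrame(rows)
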