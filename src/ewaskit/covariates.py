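"""Methylation-derived per-sample covariates.

The smoking score — a weighted sum of methylation values over a panel of
smoking-associated CpG sites — substitutes for unrecorded smoking status.
Methylation principal components capture residual structure (cell mixture,
batch, unmeasured exposures) for sensitivity analyses.  A small assembler
joins these with the sample sheet into one complete covariate table.

A 183-row synthetic weight panel (probe, weight, direction) ships with the
package for demonstrations and tests; real analyses supply their own panel
in the same TSV layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SmokingWeights",
    "load_synthetic_smoking_weights",
    "smoking_score",
    "methylation_pcs",
    "assemble_covariates",
]


@dataclass(frozen=True)
class SmokingWeights:
    """Weight panel for the smoking score.

    ``table`` columns: probe (unique), weight (finite), direction
    ('hyper' = methylation rises with smoking, 'hypo' = falls).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe", "weight", "direction"}
        if not required.issubset(t.columns):
            raise ValueError(f"weight table needs columns {sorted(required)}")
        if t["probe"].duplicated().any():
            raise ValueError("duplicate probe ids in weight table")
        if not np.isfinite(t["weight"]).all():
            raise ValueError("weights must be finite")
        if not t["direction"].isin(["hyper", "hypo"]).all():
            raise ValueError("direction must be 'hyper' or 'hypo'")

    @classmethod
    def from_tsv(cls, path) -> "SmokingWeights":
        return cls(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.table)


def load_synthetic_smoking_weights() -> SmokingWeights:
    """The packaged synthetic 183-probe weight panel (not published weights)."""
    with resources.as_file(
        resources.files("ewaskit.data").joinpath("smoking_weights_synthetic.tsv")
    ) as p:
        return SmokingWeights.from_tsv(p)


def smoking_score(
    beta: pd.DataFrame, weights: SmokingWeights, standardize: bool = False
) -> tuple[pd.Series, int]:
    """Weighted methylation score per sample, with the probe count used.

    ``s_i = sum_j w_j * m_ij`` over weight-panel probes present in the
    matrix, where ``m_ij`` is the beta value for 'hyper' sites and
    ``1 - beta`` for 'hypo' sites, so a positive contribution always points
    in the smoking-exposed direction.  ``standardize`` optionally z-scores
    each probe across samples before weighting.
    """
    t = weights.table
    present = t[t["probe"].isin(beta.index)]
    if present.empty:
        raise ValueError("no smoking-weight probes overlap the beta matrix")
    vals = beta.loc[present["probe"]].to_numpy(dtype=float)
    hypo = (present["direction"] == "hypo").to_numpy()
    vals[hypo] = 1.0 - vals[hypo]
    if standardize:
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        vals = (vals - vals.mean(axis=1, keepdims=True)) / sd
    w = present["weight"].to_numpy()
    scores = pd.Series(w @ vals, index=beta.columns, name="smoking_score")
    return scores, len(present)


def methylation_pcs(
    beta: pd.DataFrame, k: int, phenotypes: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Top-k principal-component scores of the methylation matrix.

    PCA of the mean-centered (unscaled) beta matrix with samples as
    observations.  Returns the score table (columns PC1..PCk, mutually
    uncorrelated) and, when ``phenotypes`` is given, the absolute Pearson
    correlation of every PC with every numeric-codable phenotype column.
    """
    n_samples, n_probes = beta.shape[1], beta.shape[0]
    max_k = min(n_samples - 1, n_probes)
    if k > max_k:
        raise ValueError(f"k={k} exceeds the matrix rank bound {max_k}")
    x = beta.to_numpy(dtype=float).T
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=beta.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    variance_share = (s[:k] ** 2) / (s**2).sum()
    scores.attrs["variance_share"] = variance_share
    report = None
    if phenotypes is not None:
        rows = []
        pheno = phenotypes.loc[beta.columns]
        for col in pheno.columns:
            series = pheno[col]
            if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
                series = pd.Series(pd.factorize(series)[0], index=series.index)
            v = series.to_numpy(dtype=float)
            if np.std(v) == 0:
                continue
            rows.append(
                {"phenotype": col}
                | {
                    f"PC{i + 1}": abs(float(np.corrcoef(scores.iloc[:, i], v)[0, 1]))
                    for i in range(k)
                }
            )
        report = pd.DataFrame(rows)
    return scores, report


def assemble_covariates(
    sheet: pd.DataFrame,
    smoking: pd.Series | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join sheet, smoking score and PCs into one complete covariate table."""
    covs = sheet.copy()
    if smoking is not None:
        covs["smoking_score"] = smoking
    if pcs is not None:
        covs = covs.join(pcs)
    model_cols = [
        c
        for c in covs.columns
        if c not in ("cohort", "twin_pair") and covs[c].dtype != object
    ]
    if covs[model_cols].isna().any().any():
        bad = covs[model_cols].isna().any()
        raise ValueError(f"missing covariate values in: {list(bad[bad].index)}")
    return covs
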