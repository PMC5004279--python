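"""Probe-wise epigenome-wide association models.

The central model: for every CpG probe, methylation (on the 0-100 percent
scale, so coefficients read as percentage-point differences) is regressed on
a phenotype — a case/control indicator or a continuous polygenic score —
with adjustment covariates (age, sex, batch, cell composition, derived
smoking score, optional methylation PCs).  Standard errors are classical OLS
by default; for twin designs they are replaced by CR1 cluster-robust
(sandwich) estimates clustered on twin-pair id, with the t reference
distribution on (clusters - parameters) degrees of freedom.

The probe loop is vectorised: one shared design matrix, all probe outcomes
solved in a single least-squares pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ModelSpec", "EwasRow", "EWAS", "EWASResults", "fit_probe", "pc_sensitivity"]

#: pipeline-wide significance thresholds (experiment-wide, discovery)
EXPERIMENT_WIDE_P = 1e-7
DISCOVERY_P = 5e-5


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``predictor`` is the sample-sheet column tested probe-by-probe;
    ``covariates`` are adjustment columns (categoricals are expanded to
    dummies); ``cluster`` optionally names a twin-pair id column, switching
    standard errors to the cluster-robust estimator.
    """

    predictor: str
    covariates: tuple[str, ...] = ()
    cluster: str | None = None
    scale_percent: bool = True  # model 0-100 rather than 0-1 methylation

    def __post_init__(self) -> None:
        if self.predictor in self.covariates:
            raise ValueError("predictor may not also appear among covariates")


@dataclass(frozen=True)
class EwasRow:
    """Per-probe association: effect in percentage points, SE, t, p, n."""

    probe: str
    beta: float
    se: float
    t: float
    p: float
    n: int


def _build_design(covs: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + predictor + covariates, categoricals dummy-coded."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(covs))}
    pred = covs[spec.predictor]
    if pred.dtype == object or isinstance(pred.dtype, pd.CategoricalDtype):
        raise TypeError("predictor must be numeric (code case/control as 0/1)")
    cols[spec.predictor] = pred.to_numpy(dtype=float)
    for name in spec.covariates:
        col = covs[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for dcol in dummies.columns:
                cols[dcol] = dummies[dcol].to_numpy()
        else:
            cols[name] = col.to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    if np.isnan(X).any():
        raise ValueError("missing values in design matrix; covariates must be complete")
    return X, list(cols)


def _ols_many(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every column of Y on the shared design X.

    Returns (B, resid, XtX_inv, sigma2) with B of shape (k, m).
    """
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} parameters")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / (n - k)
    return B, resid, XtX_inv, sigma2


def _cluster_robust_var(
    X: np.ndarray,
    resid: np.ndarray,
    XtX_inv: np.ndarray,
    coef_idx: int,
    cluster_codes: np.ndarray,
) -> tuple[np.ndarray, int]:
    """CR1 cluster-robust variance of one coefficient, for all probes at once.

    var_j = a' (sum_g X_g' e_g e_g' X_g) a with a = XtX_inv[:, j], scaled by
    the CR1 small-sample multiplier G/(G-1) * (N-1)/(N-K).
    """
    n, k = X.shape
    a = XtX_inv[:, coef_idx]
    w = X @ a  # (n,) projection weights
    we = resid * w[:, None]  # (n, m)
    order = np.argsort(cluster_codes, kind="stable")
    sorted_codes = cluster_codes[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
    g = len(boundaries)
    cluster_sums = np.add.reduceat(we[order], boundaries, axis=0)  # (G, m)
    meat = (cluster_sums**2).sum(axis=0)
    if g < 2:
        raise ValueError("cluster-robust SEs need >= 2 clusters")
    cr1 = (g / (g - 1)) * ((n - 1) / (n - k))
    return cr1 * meat, g


@dataclass
class EWASResults:
    """Fitted probe-wise association results.

    ``table`` columns: probe, beta (percentage points), se, t, p, n, plus
    chr/pos when a manifest was attached.  ``skipped`` records probes not
    fitted, with reasons.
    """

    table: pd.DataFrame
    spec: ModelSpec
    n_samples: int
    se_type: str  # "classical" | "CR1-cluster"
    skipped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["probe", "reason"]))
    metadata: dict = field(default_factory=dict)

    def pvalues(self) -> pd.Series:
        return self.table.set_index("probe")["p"]

    def effects(self) -> pd.Series:
        return self.table.set_index("probe")["beta"]

    def significant(self, threshold: float = EXPERIMENT_WIDE_P) -> pd.DataFrame:
        return self.table[self.table["p"] < threshold].sort_values("p")

    def count_below(self, threshold: float) -> int:
        return int((self.table["p"] < threshold).sum())

    def summary(self) -> str:
        lines = [
            f"EWAS of {self.spec.predictor!r} on {len(self.table)} probes, "
            f"{self.n_samples} samples ({self.se_type} SEs)",
            f"  covariates: {', '.join(self.spec.covariates) or 'none'}",
            f"  probes with p < {EXPERIMENT_WIDE_P:g} (experiment-wide): "
            f"{self.count_below(EXPERIMENT_WIDE_P)}",
            f"  probes with p < {DISCOVERY_P:g} (discovery): {self.count_below(DISCOVERY_P)}",
        ]
        top = self.table.nsmallest(min(5, len(self.table)), "p")
        lines.append("  top probes:")
        for _, r in top.iterrows():
            lines.append(
                f"    {r['probe']}: effect {r['beta']:+.3f} pp, se {r['se']:.3f}, p {r['p']:.3g}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = [c for c in ("probe", "chr", "pos", "beta", "se", "t", "p", "n") if c in self.table]
        self.table[cols].to_csv(path, sep="\t", index=False)


class EWAS:
    """Probe-wise linear-model EWAS over a methylation matrix.

    Parameters
    ----------
    beta:
        Probes x samples methylation proportions in [0, 1] (or 0-100 when
        ``spec.scale_percent`` is False and the data are already percent).
    covs:
        Sample sheet / covariate table indexed by sample id; must contain the
        predictor, every covariate, and the cluster column when requested.
    spec:
        The model specification.
    manifest:
        Optional probe manifest (index probe id, columns chr/pos) merged into
        the result table.
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        covs: pd.DataFrame,
        spec: ModelSpec,
        manifest: pd.DataFrame | None = None,
    ):
        missing = [s for s in beta.columns if s not in covs.index]
        if missing:
            raise ValueError(f"samples missing from covariate table: {missing[:10]}")
        self.beta = beta
        self.covs = covs.loc[beta.columns]
        self.spec = spec
        self.manifest = manifest
        self._X, self._colnames = _build_design(self.covs, spec)
        if np.linalg.matrix_rank(self._X) < self._X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def design_columns(self) -> list[str]:
        return list(self._colnames)

    def fit(self) -> EWASResults:
        X = self._X
        n, k = X.shape
        scale = 100.0 if self.spec.scale_percent else 1.0
        Y_full = self.beta.to_numpy(dtype=float).T * scale  # samples x probes
        probes = np.asarray(self.beta.index)

        variances = Y_full.var(axis=0)
        keep = variances > 0
        skipped = pd.DataFrame(
            {"probe": probes[~keep], "reason": "constant outcome"}
        )
        Y = Y_full[:, keep]
        B, resid, XtX_inv, sigma2 = _ols_many(X, Y)
        j = 1  # predictor column (after intercept)
        coef = B[j]
        if self.spec.cluster is not None:
            codes, g = self._cluster_codes()
            var_j, g = _cluster_robust_var(X, resid, XtX_inv, j, codes)
            se = np.sqrt(var_j)
            df = max(g - k, 1)
            se_type = "CR1-cluster"
        else:
            se = np.sqrt(sigma2 * XtX_inv[j, j])
            df = n - k
            se_type = "classical"
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coef / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        table = pd.DataFrame(
            {
                "probe": probes[keep],
                "beta": coef,
                "se": se,
                "t": t,
                "p": p,
                "n": n,
            }
        )
        if self.manifest is not None:
            ann = self.manifest.reindex(table["probe"])
            for col in ("chr", "pos"):
                if col in ann:
                    table[col] = ann[col].to_numpy()
        meta = {
            "design_columns": self._colnames,
            "df": int(df),
            "scale": "percent" if self.spec.scale_percent else "native",
        }
        return EWASResults(table, self.spec, n, se_type, skipped, meta)

    def _cluster_codes(self) -> tuple[np.ndarray, int]:
        col = self.covs[self.spec.cluster]
        codes, uniques = pd.factorize(col)
        sizes = np.bincount(codes)
        if (sizes == 1).any():
            warnings.warn(
                f"{int((sizes == 1).sum())} singleton cluster(s); each treated as its own cluster",
                stacklevel=3,
            )
        return codes, len(uniques)


def fit_probe(
    y: Sequence[float],
    predictor: Sequence[float],
    covariates: Mapping[str, Sequence[float]] | None = None,
    probe: str = "probe",
) -> EwasRow:
    """OLS fit of a single probe: effect of ``predictor`` on ``y``.

    ``y`` is expected on the percent (0-100) scale.  Classical SE, two-sided
    t-test p-value.
    """
    y = np.asarray(y, dtype=float)
    cols = [np.ones_like(y), np.asarray(predictor, dtype=float)]
    for v in (covariates or {}).values():
        cols.append(np.asarray(v, dtype=float))
    X = np.column_stack(cols)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("too few observations for the number of parameters")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design")
    B, resid, XtX_inv, sigma2 = _ols_many(X, y[:, None])
    se = float(np.sqrt(sigma2[0] * XtX_inv[1, 1]))
    coef = float(B[1, 0])
    if se == 0:
        t = np.inf if coef != 0 else 0.0
        p = 0.0 if coef != 0 else 1.0
    else:
        t = coef / se
        p = float(2.0 * stats.t.sf(abs(t), n - k))
    return EwasRow(probe, coef, se, float(t), p, n)


def pc_sensitivity(
    beta: pd.DataFrame,
    covs: pd.DataFrame,
    spec: ModelSpec,
    pc_columns: Sequence[str],
    max_pcs: int = 10,
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stability of probe effects as methylation PCs join the model.

    For k = 1..max_pcs, refits the EWAS adding the first k PC columns and
    reports the Spearman correlation between the base-model coefficient
    vector and the k-PC coefficient vector, over all probes and (optionally)
    restricted to ``subset`` probes.
    """
    from .metastats import spearman

    pc_columns = list(pc_columns)[:max_pcs]
    base = EWAS(beta, covs, spec).fit().effects()
    rows = []
    for k in range(1, len(pc_columns) + 1):
        spec_k = ModelSpec(
            spec.predictor,
            tuple(spec.covariates) + tuple(pc_columns[:k]),
            spec.cluster,
            spec.scale_percent,
        )
        eff_k = EWAS(beta, covs, spec_k).fit().effects()
        common = base.index.intersection(eff_k.index)
        row = {
            "n_pcs": k,
            "spearman_all": spearman(base.loc[common], eff_k.loc[common]),
        }
        if subset is not None:
            sub = common.intersection(pd.Index(subset))
            row["spearman_subset"] = (
                spearman(base.loc[sub], eff_k.loc[sub]) if len(sub) >= 3 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
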