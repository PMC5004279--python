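"""Regulatory-feature overlap tests and probe-bias-controlled GO enrichment.

Feature overlap uses the two-sided Fisher exact test on the 2x2
cross-tabulation of test-list membership against feature membership, with a
Bonferroni level over the features tested.

Pathway enrichment uses logistic regression of pathway membership on
test-list membership while adjusting for the number of array probes
annotated to each gene — the probe-count covariate is the method's reason
for existing, since genes with more probes are more likely to contain a
significant probe by chance alone.  Significant pathways are then grouped:
the most significant pathway is taken as a head, every remaining pathway is
retested with head-membership as an extra covariate, and any whose
test-list coefficient is no longer significant is marked explained by the
head; the procedure repeats until every pathway is a head or explained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "GeneSetCollection",
    "fisher_overlap",
    "go_logistic_enrichment",
    "group_pathways",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher 2x2 overlap of a probe list with an annotation feature."""

    feature: str
    in_list_in_feature: int
    in_list_out_feature: int
    out_list_in_feature: int
    out_list_out_feature: int
    odds_ratio: float
    p: float
    bonferroni_alpha: float = 0.05

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.in_list_in_feature, self.in_list_out_feature],
                [self.out_list_in_feature, self.out_list_out_feature],
            ]
        )


def fisher_overlap(
    test_probes: set,
    feature_probes: set,
    universe: set,
    feature: str = "feature",
    n_features_tested: int = 1,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Two-sided Fisher exact test of test-list x feature membership.

    The two-sided p sums all hypergeometric tables with point probability
    <= the observed one.  The odds ratio is the sample (cross-product)
    ratio; degenerate margins give inf/nan OR with p = 1.
    """
    if not universe:
        raise ValueError("empty probe universe")
    if not test_probes <= universe:
        raise ValueError("test set must be a subset of the universe")
    feature_probes = feature_probes & universe
    a = len(test_probes & feature_probes)
    b = len(test_probes) - a
    c = len(feature_probes) - a
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(feature, a, b, c, d, float(odds), float(p), alpha / n_features_tested)


@dataclass
class GeneSetCollection:
    """Pathway gene sets plus per-gene analyzed-probe counts.

    The gene universe is every gene with >= 1 probe and >= 1 pathway;
    pathways outside the size bounds (after restriction to the universe)
    are dropped.
    """

    pathways: dict[str, set] = field(repr=False)
    probe_counts: dict[str, int] = field(repr=False)
    min_size: int = 10
    max_size: int = 2000

    def __post_init__(self) -> None:
        counted = {g for g, c in self.probe_counts.items() if c >= 1}
        in_any = set().union(*self.pathways.values()) if self.pathways else set()
        self.universe = sorted(counted & in_any)
        uset = set(self.universe)
        self.pathways = {
            name: genes & uset
            for name, genes in self.pathways.items()
            if self.min_size <= len(genes & uset) <= self.max_size
        }

    @classmethod
    def from_gmt(cls, path, probe_counts: dict[str, int], **kw) -> "GeneSetCollection":
        from .io import read_gmt

        return cls(read_gmt(path), probe_counts, **kw)


def _firth_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Firth bias-reduced logistic fit: (coefficients, covariance).

    Jeffreys-prior penalized Newton iterations with step halving; finite
    estimates and usable Wald statistics even under complete separation.
    """
    n, k = X.shape
    b = np.zeros(k)
    for _ in range(100):
        eta = np.clip(X @ b, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        xw = X * w[:, None]
        info = X.T @ xw
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", xw, info_inv, X)  # hat diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # step halving for stability
        while np.max(np.abs(step)) > 5:
            step = step / 2
        b = b + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(X @ b, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-12)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return b, cov


def _logit_wald(
    y: np.ndarray, X: np.ndarray, coef_idx: int
) -> tuple[float, float, bool]:
    """(coefficient, two-sided Wald p, separation flag) for one column.

    Maximum likelihood via statsmodels; when the fit separates or fails to
    converge, a Firth bias-reduced fit supplies the estimate and Wald p and
    the result is flagged.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            converged = fit.mle_retvals.get("converged", False)
            if converged and np.all(np.isfinite(fit.bse)) and fit.bse[coef_idx] < 50:
                return float(fit.params[coef_idx]), float(fit.pvalues[coef_idx]), False
        except Exception:
            pass
    b, cov = _firth_logit(y, X)
    se = float(np.sqrt(max(cov[coef_idx, coef_idx], 1e-300)))
    z = b[coef_idx] / se
    return float(b[coef_idx]), float(2 * stats.norm.sf(abs(z))), True


def go_logistic_enrichment(
    test_genes: set, collection: GeneSetCollection, log_counts: bool = False
) -> pd.DataFrame:
    """Per-pathway logistic enrichment controlling for probe counts.

    For each pathway fits ``member(gene) ~ 1 + in_test_list(gene) +
    probe_count(gene)`` over the gene universe and reports the test-list
    coefficient with its two-sided Wald p.  Enrichment requires a positive
    coefficient; a negative one is depletion.  ``log_counts`` switches the
    probe-count covariate to log scale.
    """
    genes = np.array(collection.universe)
    if genes.size == 0:
        raise ValueError("empty gene universe")
    in_test = np.isin(genes, sorted(test_genes)).astype(float)
    counts = np.array([collection.probe_counts[g] for g in genes], dtype=float)
    if log_counts:
        counts = np.log(counts)
    X = np.column_stack([np.ones_like(counts), in_test, counts])
    rows = []
    for name, members in collection.pathways.items():
        y = np.isin(genes, sorted(members)).astype(float)
        coef, p, flagged = _logit_wald(y, X, 1)
        rows.append(
            {
                "pathway": name,
                "n_genes": len(members),
                "coef": coef,
                "p": p,
                "enriched": coef > 0,
                "separation": flagged,
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)


def group_pathways(
    results: pd.DataFrame,
    test_genes: set,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    log_counts: bool = False,
) -> pd.DataFrame:
    """Group significant pathways under the terms that explain them.

    Iteratively: the most significant unexplained pathway becomes a head;
    every remaining significant pathway is refitted with head-membership as
    an additional covariate, and assigned ``explained_by = head`` when its
    test-list coefficient p rises to >= alpha.  Every significant pathway
    ends up exactly once — as a head (explained_by empty) or explained.
    """
    cols = ["pathway", "p", "group", "explained_by"]
    if results.empty:
        return pd.DataFrame(columns=cols)
    sig = results[(results["p"] < alpha) & results["enriched"]].sort_values(
        "p", kind="stable"
    )
    if sig.empty:
        return pd.DataFrame(columns=cols)
    genes = np.array(collection.universe)
    in_test = np.isin(genes, sorted(test_genes)).astype(float)
    counts = np.array([collection.probe_counts[g] for g in genes], dtype=float)
    if log_counts:
        counts = np.log(counts)
    remaining = list(sig["pathway"])
    p_lookup = dict(zip(sig["pathway"], sig["p"]))
    assignments: dict[str, str] = {}
    heads: list[str] = []
    while remaining:
        head = remaining.pop(0)
        heads.append(head)
        head_member = np.isin(genes, sorted(collection.pathways[head])).astype(float)
        still = []
        for name in remaining:
            y = np.isin(genes, sorted(collection.pathways[name])).astype(float)
            X = np.column_stack([np.ones_like(counts), in_test, counts, head_member])
            _, p, _ = _logit_wald(y, X, 1)
            if p >= alpha:
                assignments[name] = head
            else:
                still.append(name)
        remaining = still
    rows = []
    for name in sig["pathway"]:
        rows.append(
            {
                "pathway": name,
                "p": p_lookup[name],
                "group": assignments.get(name, name),
                "explained_by": assignments.get(name, ""),
            }
        )
    return pd.DataFrame(rows)
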