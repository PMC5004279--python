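"""Cross-cohort meta-analysis and elementary comparison statistics.

Inverse-variance fixed-effect and DerSimonian-Laird random-effects pooling of
per-cohort probe effects, plus the exact one-sided sign test, Mann-Whitney
rank-sum comparison and Spearman rank correlation used to compare effect
estimates between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "MetaAnalysis",
    "sign_test",
    "mann_whitney",
    "spearman",
    "meta_analyse_table",
]


@dataclass(frozen=True)
class StudyEstimate:
    """One cohort's effect estimate for a probe (percentage points) and SE."""

    cohort: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError(f"non-finite effect for cohort {self.cohort!r}")
        if not (self.se > 0):
            raise ValueError(f"standard error must be > 0 (cohort {self.cohort!r})")

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect across cohorts.

    ``tau2`` is the between-study variance; identically 0 under the fixed
    model.  ``p`` is the two-sided normal p-value of ``z = beta / se``.
    """

    beta: float
    se: float
    z: float
    p: float
    tau2: float
    model: str  # "fixed" | "random"
    k: int
    studies: tuple[StudyEstimate, ...] = field(repr=False, default=())

    def summary(self) -> pd.DataFrame:
        rows = [
            {"cohort": s.cohort, "beta": s.beta, "se": s.se, "weight": s.weight}
            for s in self.studies
        ]
        rows.append(
            {
                "cohort": f"pooled ({self.model})",
                "beta": self.beta,
                "se": self.se,
                "weight": float("nan"),
            }
        )
        return pd.DataFrame(rows)


class MetaAnalysis:
    """Inverse-variance meta-analysis of per-cohort estimates for one probe.

    Parameters
    ----------
    studies:
        Per-cohort effect estimates with standard errors.  Weights are
        ``1 / SE^2``.
    """

    def __init__(self, studies: Sequence[StudyEstimate]):
        if len(studies) < 1:
            raise ValueError("at least one study required")
        self.studies = tuple(studies)

    @classmethod
    def from_arrays(
        cls, betas: Sequence[float], ses: Sequence[float], cohorts: Sequence[str] | None = None
    ) -> "MetaAnalysis":
        if cohorts is None:
            cohorts = [f"cohort{i + 1}" for i in range(len(betas))]
        return cls([StudyEstimate(c, float(b), float(s)) for c, b, s in zip(cohorts, betas, ses)])

    def fit(self, model: str = "fixed") -> MetaResult:
        if model == "fixed":
            return self._fit_fixed()
        if model == "random":
            return self._fit_random()
        raise ValueError(f"unknown model {model!r}")

    def _pool(self, w: np.ndarray, b: np.ndarray, tau2: float, model: str) -> MetaResult:
        sw = w.sum()
        beta = float((w * b).sum() / sw)
        se = float(sw**-0.5)
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        return MetaResult(beta, se, z, p, tau2, model, len(b), self.studies)

    def _fit_fixed(self) -> MetaResult:
        b = np.array([s.beta for s in self.studies])
        w = np.array([s.weight for s in self.studies])
        return self._pool(w, b, 0.0, "fixed")

    def _fit_random(self) -> MetaResult:
        # DerSimonian-Laird: tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
        if len(self.studies) < 2:
            raise ValueError("random-effects model requires >= 2 studies")
        b = np.array([s.beta for s in self.studies])
        w = np.array([s.weight for s in self.studies])
        beta_fixed = (w * b).sum() / w.sum()
        q = float((w * (b - beta_fixed) ** 2).sum())
        k = len(b)
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (np.array([s.se for s in self.studies]) ** 2 + tau2)
        return self._pool(w_star, b, tau2, "random")


def sign_test(s: int, n: int) -> float:
    """Exact one-sided binomial tail ``P(X >= s | n, 1/2)``.

    Computed by log-space summation of binomial point masses so that tails
    far below double-precision rounding of individual terms (n in the
    thousands) remain accurate.
    """
    if not (0 <= s <= n) or n < 1:
        raise ValueError("require 0 <= s <= n and n >= 1")
    if s == 0:
        return 1.0
    k = np.arange(s, n + 1)
    log_terms = (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        - n * np.log(2.0)
    )
    return float(np.exp(special.logsumexp(log_terms)))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact enumeration when the smaller sample has <= 8 observations and the
    data are tie-free; otherwise the tie-corrected normal approximation
    without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("equal-length inputs with n >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def meta_analyse_table(long: pd.DataFrame) -> pd.DataFrame:
    """Meta-analyse a long-format table (columns probe, cohort, beta, se).

    Returns one row per probe with fixed- and random-effects columns.  Probes
    present in a single cohort get the fixed-model identity and NaN random
    columns.
    """
    out = []
    for probe, grp in long.groupby("probe", sort=False):
        ma = MetaAnalysis.from_arrays(grp["beta"], grp["se"], grp["cohort"].astype(str))
        fx = ma.fit("fixed")
        row = {
            "probe": probe,
            "k": fx.k,
            "beta_fixed": fx.beta,
            "se_fixed": fx.se,
            "z_fixed": fx.z,
            "p_fixed": fx.p,
        }
        if fx.k >= 2:
            rd = ma.fit("random")
            row.update(
                beta_random=rd.beta, se_random=rd.se, p_random=rd.p, tau2=rd.tau2
            )
        else:
            row.update(beta_random=np.nan, se_random=np.nan, p_random=np.nan, tau2=np.nan)
        out.append(row)
    return pd.DataFrame(out)
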