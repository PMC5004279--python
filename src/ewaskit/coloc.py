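"""Bayesian co-localization of two association signals over one region.

Given per-SNP summary statistics (effect, variance, allele frequency) for
two traits over the same SNPs, each SNP's evidence of association is
summarized by Wakefield's asymptotic Bayes factor

    log ABF = 1/2 [ ln(1 - r) + r z^2 ],   r = W / (V + W),  z = beta / sqrt(V),

with prior effect variance W depending on trait type.  Assuming at most one
causal variant per trait, the per-SNP ABFs combine into posterior
probabilities for five hypotheses: H0 no association with either trait,
H1/H2 association with one trait only, H3 two distinct causal variants,
H4 a single shared causal variant.  All sums run in log space.

Classification of a result follows the PP3+PP4 / PP4:PP3 gates: a
co-localized signal needs PP3 + PP4 > 0.99; it is driven by the same
variant when additionally PP4/PP3 > 1, and convincing when PP4/PP3 > 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ColocPriors",
    "ColocResult",
    "wakefield_log_abf",
    "coloc_abf",
    "classify_coloc",
]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities and prior effect standard deviations."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    sd_quant: float = 0.15
    sd_cc: float = 0.2

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0 or self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("priors must be positive with p1 + p2 + p12 < 1")

    def prior_w(self, trait_type: str) -> float:
        if trait_type == "quant":
            return self.sd_quant**2
        if trait_type == "cc":
            return self.sd_cc**2
        raise ValueError(f"unknown trait type {trait_type!r} (use 'quant' or 'cc')")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities PP0..PP4 over the five hypotheses."""

    nsnps: int
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float

    def __post_init__(self) -> None:
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors must sum to 1 (got {total!r})")

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    @property
    def pp3_plus_pp4(self) -> float:
        return self.pp3 + self.pp4

    @property
    def pp4_over_pp3(self) -> float:
        if self.pp3 == 0:
            return float("inf") if self.pp4 > 0 else float("nan")
        return self.pp4 / self.pp3

    @property
    def classification(self) -> str:
        return classify_coloc(self)

    def summary(self) -> str:
        return (
            f"coloc over {self.nsnps} SNPs: "
            + " ".join(f"PP{i}={v:.4f}" for i, v in enumerate(self.pp))
            + f" | PP3+PP4={self.pp3_plus_pp4:.4f} PP4/PP3={self.pp4_over_pp3:.3f}"
            + f" -> {self.classification}"
        )


def wakefield_log_abf(beta: float, varbeta: float, w: float) -> float:
    """Wakefield's log asymptotic Bayes factor for one SNP.

    ``w`` is the prior effect variance; the no-information limit
    (varbeta -> inf) gives 0, and beta = 0 gives the negative shrinkage
    term ln(1 - r)/2.
    """
    if varbeta <= 0:
        raise ValueError("varbeta must be > 0")
    r = w / (varbeta + w)
    z2 = beta**2 / varbeta
    return 0.5 * (np.log1p(-r) + r * z2)


def _log_abfs(stats_df: pd.DataFrame, priors: ColocPriors) -> np.ndarray:
    beta = stats_df["beta"].to_numpy(dtype=float)
    varbeta = stats_df["varbeta"].to_numpy(dtype=float)
    if (varbeta <= 0).any():
        raise ValueError("all varbeta must be > 0")
    types = stats_df["type"] if "type" in stats_df else pd.Series("quant", index=stats_df.index)
    w = np.array([priors.prior_w(t) for t in types])
    r = w / (varbeta + w)
    return 0.5 * (np.log1p(-r) + r * beta**2 / varbeta)


def coloc_abf(
    trait1: pd.DataFrame, trait2: pd.DataFrame, priors: ColocPriors = ColocPriors()
) -> ColocResult:
    """Posterior probabilities of the five co-localization hypotheses.

    Both frames need columns snp, beta, varbeta (and optionally type);
    the SNP sets must be identical and aligned — no silent intersection.
    """
    if len(trait1) < 2:
        raise ValueError("need >= 2 SNPs")
    if list(trait1["snp"]) != list(trait2["snp"]):
        raise ValueError("SNP sets must be identical and aligned across traits")
    l1 = _log_abfs(trait1, priors)
    l2 = _log_abfs(trait2, priors)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum_{i != j} ABF1_i ABF2_j = (sum_i ABF1_i)(sum_j ABF2_j) - sum_i ABF1_i ABF2_i
    both = s1 + s2
    if both - s12 < 1e-12:
        l3_core = -np.inf  # degenerate: all cross mass on the diagonal
    else:
        l3_core = both + np.log1p(-np.exp(s12 - both))
    lh = np.array(
        [
            0.0,
            np.log(priors.p1) + s1,
            np.log(priors.p2) + s2,
            np.log(priors.p1) + np.log(priors.p2) + l3_core,
            np.log(priors.p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(len(trait1), *map(float, pp))


def classify_coloc(result: ColocResult) -> str:
    """Gate a coloc result: none, co-localized-signal, same-variant, convincing."""
    if not result.pp3_plus_pp4 > 0.99:
        return "none"
    ratio = result.pp4_over_pp3
    if np.isnan(ratio):
        return "co-localized-signal"
    if ratio > 5:
        return "convincing"
    if ratio > 1:
        return "same-variant"
    return "co-localized-signal"


def coloc_table(results: dict[str, ColocResult]) -> pd.DataFrame:
    """Flatten named coloc results into a report table."""
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "region": name,
                "nsnps": r.nsnps,
                "PP0": r.pp0,
                "PP1": r.pp1,
                "PP2": r.pp2,
                "PP3": r.pp3,
                "PP4": r.pp4,
                "PP3_plus_PP4": r.pp3_plus_pp4,
                "PP4_over_PP3": r.pp4_over_pp3,
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)
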