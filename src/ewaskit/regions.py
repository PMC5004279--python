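"""Correlation-aware region statistics.

Brown's method generalizes Fisher's combined-probability test to dependent
tests: with psi = -2 sum ln p_i, E[psi] = 2k and Var[psi] = 4k +
2 sum_{i<j} cov_ij, where each covariance term is the Kost-McDermott
polynomial in the pairwise probe correlation, psi / c is referred to a
chi-square with f = 2 E^2 / Var effective degrees of freedom
(c = Var / 2E).  At zero correlation this is exactly Fisher's method; as
the correlations approach one it collapses to the single-test p-value.

On top of that statistic sit the two region callers: a multi-scale sliding
window over the probe map (each probe seeds windows of half-width 100 to
5000 bp; windows with >= 2 probes get a combined p, per-window-size
permutation thresholds, and a greedy non-overlapping reduction), and a scan
over externally supplied candidate regions (e.g. GWAS-nominated intervals)
with Bonferroni and empirical permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .permutation import PermutationSummary, empirical_region_p, fwer_threshold

__all__ = [
    "BrownStatistic",
    "brown_combined_p",
    "SlidingWindowScanner",
    "sliding_window_scan",
    "window_thresholds",
    "reduce_nonoverlapping",
    "gwas_region_scan",
    "DEFAULT_WINDOW_SIZES",
]

DEFAULT_WINDOW_SIZES = (100, 200, 500, 1000, 2000, 5000)

# Kost-McDermott polynomial approximating cov(-2 ln p_i, -2 ln p_j)
_KM = (3.263, 0.710, 0.027)


@dataclass(frozen=True)
class BrownStatistic:
    """Brown's combined test over k correlated p-values."""

    k: int
    psi: float  # -2 sum ln p
    c: float  # scale factor Var / 2E
    f: float  # effective degrees of freedom 2 E^2 / Var
    p: float
    fisher_fallback: bool = False


def _km_cov(rho: np.ndarray) -> np.ndarray:
    return _KM[0] * rho + _KM[1] * rho**2 + _KM[2] * rho**3


def _brown_scale(correlations: np.ndarray) -> tuple[float, float, bool]:
    """(c, f) from a correlation matrix; falls back to Fisher if Var <= 4k.

    Summed pairwise covariance is floored at zero so the effective degrees
    of freedom never exceed 2k.
    """
    k = correlations.shape[0]
    iu = np.triu_indices(k, 1)
    cov_sum = float(_km_cov(correlations[iu]).sum())
    fallback = cov_sum <= 0
    cov_sum = max(cov_sum, 0.0)
    e = 2.0 * k
    var = 4.0 * k + 2.0 * cov_sum
    f = 2.0 * e**2 / var
    c = var / (2.0 * e)
    return c, f, fallback


def brown_combined_p(
    p_values: Sequence[float], correlations: np.ndarray | None = None
) -> BrownStatistic:
    """Combine correlated p-values with Brown's method.

    ``correlations`` is the k x k pairwise correlation matrix of the
    underlying scores (unit diagonal); omit it (or pass zeros) for Fisher's
    method.  Zero p-values are clamped to the smallest positive double.
    """
    p = np.asarray(p_values, dtype=float)
    k = p.size
    if k < 1:
        raise ValueError("need at least one p-value")
    if (p <= 0).any():
        warnings.warn("p-value of 0 clamped to the smallest positive double", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if correlations is None:
        correlations = np.eye(k)
    correlations = np.asarray(correlations, dtype=float)
    if correlations.shape != (k, k):
        raise ValueError("correlation matrix dimension mismatch")
    if not np.allclose(correlations, correlations.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    psi = float(-2.0 * np.log(p).sum())
    c, f, fallback = _brown_scale(correlations)
    combined = float(stats.chi2.sf(psi / c, f))
    return BrownStatistic(k, psi, c, f, max(combined, np.finfo(float).tiny), fallback)


class SlidingWindowScanner:
    """Multi-scale sliding-window region machinery over a probe map.

    Windows are enumerated once (every probe seeds a closed interval
    [pos - w, pos + w] per half-width w, same chromosome, deduplicated by
    probe-set identity within each w); each window's Brown scale factors
    are precomputed from the pairwise Pearson correlations of beta values
    across samples, so scanning an observed or permuted p-vector is a cheap
    vectorised pass.
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        manifest: pd.DataFrame,
        window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
        probes: Sequence[str] | None = None,
    ):
        self.window_sizes = tuple(sorted(window_sizes))
        idx = manifest.index.intersection(beta.index)
        if probes is not None:
            idx = idx.intersection(pd.Index(probes))
        man = manifest.loc[idx, ["chr", "pos"]].copy()
        man["chr"] = man["chr"].astype(str)
        man = man.sort_values(["chr", "pos"])
        self.probes = man.index.to_numpy()
        self.chrom = man["chr"].to_numpy()
        self.pos = man["pos"].to_numpy(dtype=int)
        x = beta.loc[self.probes].to_numpy(dtype=float)
        x = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((x**2).sum(axis=1))
        norms[norms == 0] = 1.0
        self._rows = x / norms[:, None]
        self._build_windows()

    def _build_windows(self) -> None:
        windows: list[tuple[int, tuple[int, ...]]] = []
        seen: set[tuple[int, tuple[int, ...]]] = set()
        for chrom in pd.unique(self.chrom):
            mask = self.chrom == chrom
            gidx = np.flatnonzero(mask)
            pos = self.pos[gidx]
            order = np.argsort(pos)
            pos = pos[order]
            gidx = gidx[order]
            for w in self.window_sizes:
                lo = np.searchsorted(pos, pos - w, side="left")
                hi = np.searchsorted(pos, pos + w, side="right")
                for i in range(len(pos)):
                    if hi[i] - lo[i] < 2:
                        continue
                    members = tuple(gidx[lo[i] : hi[i]])
                    key = (w, members)
                    if key not in seen:
                        seen.add(key)
                        windows.append(key)
        self.windows = windows
        self._scales = []
        for w, members in windows:
            r = self._rows[list(members)]
            corr = np.clip(r @ r.T, -1.0, 1.0)
            np.fill_diagonal(corr, 1.0)
            self._scales.append(_brown_scale(corr)[:2])

    def combined_p(self, pvalues: Mapping[str, float] | pd.Series) -> pd.DataFrame:
        """Brown combined p for every window, given per-probe p-values."""
        pv = pd.Series(pvalues).reindex(self.probes).to_numpy(dtype=float)
        pv = np.maximum(pv, np.finfo(float).tiny)
        logs = np.log(pv)
        rows = []
        for (w, members), (c, f) in zip(self.windows, self._scales):
            mem = list(members)
            psi = -2.0 * logs[mem].sum()
            p = float(stats.chi2.sf(psi / c, f))
            rows.append(
                {
                    "chr": self.chrom[mem[0]],
                    "start": int(self.pos[mem[0]]),
                    "end": int(self.pos[mem[-1]]),
                    "window": w,
                    "n_probes": len(mem),
                    "probes": tuple(self.probes[mem]),
                    "p": max(p, np.finfo(float).tiny),
                    "provenance": "sliding_window",
                }
            )
        return pd.DataFrame(
            rows,
            columns=["chr", "start", "end", "window", "n_probes", "probes", "p", "provenance"],
        )

    def min_p_per_permutation(self, full_p: np.ndarray, perm_probes: np.ndarray) -> dict[int, np.ndarray]:
        """Per-window-size minimum combined p for each permuted p-vector."""
        col = {p: j for j, p in enumerate(perm_probes)}
        take = np.array([col[p] for p in self.probes])
        logs = np.log(np.maximum(full_p[:, take], np.finfo(float).tiny))  # perms x probes
        n_perm = logs.shape[0]
        mins = {w: np.ones(n_perm) for w in self.window_sizes}
        for (w, members), (c, f) in zip(self.windows, self._scales):
            psi = -2.0 * logs[:, list(members)].sum(axis=1)
            p = stats.chi2.sf(psi / c, f)
            np.minimum(mins[w], p, out=mins[w])
        return mins

    def thresholds(self, perm: PermutationSummary, alpha: float = 0.05) -> dict[int, float]:
        """Per-window-size family-wise thresholds from stored permutations."""
        if perm.full_p is None or perm.probes is None:
            raise ValueError("permutation summary lacks stored full p-vectors")
        mins = self.min_p_per_permutation(perm.full_p, perm.probes)
        return {
            w: fwer_threshold(PermutationSummary(v, alpha), alpha) for w, v in mins.items()
        }


def sliding_window_scan(
    ewas_pvalues: pd.Series,
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
) -> pd.DataFrame:
    """Candidate regions from the multi-scale sliding-window scan."""
    scanner = SlidingWindowScanner(beta, manifest, window_sizes, probes=ewas_pvalues.index)
    return scanner.combined_p(ewas_pvalues)


def window_thresholds(
    perm: PermutationSummary,
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    alpha: float = 0.05,
) -> dict[int, float]:
    """Per-window-size 5 % family-wise thresholds from permuted EWASs."""
    scanner = SlidingWindowScanner(beta, manifest, window_sizes)
    return scanner.thresholds(perm, alpha)


def reduce_nonoverlapping(regions: pd.DataFrame) -> pd.DataFrame:
    """Greedy reduction to probe-disjoint regions, most significant first.

    A candidate is dropped iff it shares at least one probe id with an
    already retained region.  Output is sorted by p.
    """
    if regions.empty:
        return regions.copy()
    ordered = regions.sort_values("p", kind="stable")
    taken: set[str] = set()
    keep = []
    for i, row in ordered.iterrows():
        ps = set(row["probes"])
        if ps & taken:
            continue
        taken |= ps
        keep.append(i)
    return ordered.loc[keep].reset_index(drop=True)


def _region_probe_sets(
    regions_bed: pd.DataFrame, manifest: pd.DataFrame, probes: pd.Index
) -> list[tuple[str, str, int, int, list[str]]]:
    man = manifest.loc[manifest.index.intersection(probes), ["chr", "pos"]]
    out = []
    for rid, row in regions_bed.iterrows():
        sel = man[
            (man["chr"].astype(str) == str(row["chr"]))
            & (man["pos"] >= row["start"])
            & (man["pos"] <= row["end"])
        ]
        name = str(row["name"]) if "name" in row and pd.notna(row.get("name")) else str(rid)
        out.append((name, str(row["chr"]), int(row["start"]), int(row["end"]), list(sel.index)))
    return out


def gwas_region_scan(
    ewas_cc_p: pd.Series,
    ewas_prs_p: pd.Series | None,
    regions_bed: pd.DataFrame,
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    perm_cc: PermutationSummary | None = None,
    perm_prs: PermutationSummary | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combined differential-methylation p-values over candidate regions.

    ``regions_bed`` must carry 1-based inclusive ``start``/``end`` columns
    (BED files are converted on read).  Regions with fewer than two probes
    are reported untestable (NaN p).  Brown combined p-values are computed
    for the case-control EWAS and, when given, the polygenic-score EWAS;
    the Bonferroni threshold is alpha / (number of testable regions), and
    empirical p-values come from re-combining stored permutation p-vectors.
    """
    common = ewas_cc_p.index
    if ewas_prs_p is not None:
        if not ewas_cc_p.index.equals(ewas_prs_p.index):
            common = ewas_cc_p.index.intersection(ewas_prs_p.index)
    entries = _region_probe_sets(regions_bed, manifest, pd.Index(common).intersection(beta.index))
    rows = []
    for name, chrom, start, end, probes in entries:
        row = {
            "region": name,
            "chr": chrom,
            "start": start,
            "end": end,
            "n_probes": len(probes),
            "testable": len(probes) >= 2,
            "p_cc": np.nan,
            "p_prs": np.nan,
            "emp_p_cc": np.nan,
            "emp_p_prs": np.nan,
            "provenance": "gwas_region",
        }
        if len(probes) >= 2:
            x = beta.loc[probes].to_numpy(dtype=float)
            corr = np.corrcoef(x)
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
            c, f, _ = _brown_scale(corr)
            for tag, pser, perm in (
                ("cc", ewas_cc_p, perm_cc),
                ("prs", ewas_prs_p, perm_prs),
            ):
                if pser is None:
                    continue
                pv = np.maximum(pser.reindex(probes).to_numpy(dtype=float), np.finfo(float).tiny)
                psi = float(-2.0 * np.log(pv).sum())
                row[f"p_{tag}"] = max(float(stats.chi2.sf(psi / c, f)), np.finfo(float).tiny)
                if perm is not None and perm.full_p is not None:
                    col = {p: j for j, p in enumerate(perm.probes)}
                    take = np.array([col[p] for p in probes if p in col])
                    if len(take) == len(probes):
                        logs = np.log(
                            np.maximum(perm.full_p[:, take], np.finfo(float).tiny)
                        )
                        psis = -2.0 * logs.sum(axis=1)
                        perm_ps = stats.chi2.sf(psis / c, f)
                        row[f"emp_p_{tag}"] = empirical_region_p(row[f"p_{tag}"], perm_ps)
        rows.append(row)
    table = pd.DataFrame(rows)
    n_testable = int(table["testable"].sum())
    table["bonferroni_alpha"] = alpha / n_testable if n_testable else np.nan
    table["significant_cc"] = table["p_cc"] < table["bonferroni_alpha"]
    return table
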