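"""Permutation calibration of family-wise error.

Case/control labels are reshuffled (group sizes preserved, covariates
staying attached to their samples), the probe-wise EWAS is rerun, and the
minimum p-value of each permutation is recorded.  The empirical alpha
quantile of those minima is the family-wise significance threshold.  Full
per-permutation p-vectors can be retained for region-level statistics,
where the same machinery yields per-window thresholds and empirical region
p-values.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ewas import EWAS, ModelSpec

__all__ = [
    "PermutationSummary",
    "run_permutations",
    "fwer_threshold",
    "empirical_region_p",
]


@dataclass
class PermutationSummary:
    """Minimum-p vector (and optionally full p-matrices) over permutations."""

    min_p: np.ndarray  # (n_perm,)
    alpha: float = 0.05
    seed: int | None = None
    probes: np.ndarray | None = None
    full_p: np.ndarray | None = field(default=None, repr=False)  # (n_perm, m)

    @property
    def n_perm(self) -> int:
        return len(self.min_p)

    @property
    def threshold(self) -> float:
        return fwer_threshold(self, self.alpha)

    def save(self, outdir) -> None:
        """Write min-p TSV, JSON summary, and (if kept) the full p-matrix as
        little-endian float64 with a JSON header sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.Series(self.min_p, name="min_p").to_csv(
            outdir / "min_p.tsv", sep="\t", index=False, float_format="%.17g"
        )
        meta = {
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "seed": self.seed,
            "threshold": self.threshold,
        }
        (outdir / "permutations.json").write_text(json.dumps(meta, indent=1))
        if self.full_p is not None:
            arr = np.ascontiguousarray(self.full_p, dtype="<f8")
            arr.tofile(outdir / "full_p.f64le")
            header = {
                "dtype": "float64-little-endian",
                "shape": list(arr.shape),
                "order": "C (permutation-major)",
                "probes": list(map(str, self.probes)) if self.probes is not None else None,
            }
            (outdir / "full_p.json").write_text(json.dumps(header))

    @classmethod
    def load(cls, outdir) -> "PermutationSummary":
        outdir = Path(outdir)
        meta = json.loads((outdir / "permutations.json").read_text())
        min_p = pd.read_csv(
            outdir / "min_p.tsv", sep="\t", float_precision="round_trip"
        )["min_p"].to_numpy()
        full_p = None
        probes = None
        if (outdir / "full_p.f64le").exists():
            header = json.loads((outdir / "full_p.json").read_text())
            full_p = np.fromfile(outdir / "full_p.f64le", dtype="<f8").reshape(
                header["shape"]
            )
            if header.get("probes"):
                probes = np.array(header["probes"])
        return cls(min_p, meta["alpha"], meta.get("seed"), probes, full_p)


def run_permutations(
    beta: pd.DataFrame,
    covs: pd.DataFrame,
    spec: ModelSpec,
    n_perm: int,
    seed: int = 0,
    store_full: bool = False,
    alpha: float = 0.05,
) -> PermutationSummary:
    """Label-permutation null distribution of the minimum EWAS p-value.

    Only the predictor column is permuted; all covariates stay attached to
    their samples, so each permutation reruns the identical model under a
    randomly reassigned case/control split of the original sizes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm * alpha < 1:
        warnings.warn(
            f"{n_perm} permutations cannot resolve the alpha={alpha} quantile; "
            "threshold will be the smallest observed minimum",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    labels = covs.loc[beta.columns, spec.predictor].to_numpy()
    min_p = np.empty(n_perm)
    full = np.empty((n_perm, beta.shape[0])) if store_full else None
    covs_perm = covs.loc[beta.columns].copy()
    for b in range(n_perm):
        covs_perm[spec.predictor] = rng.permutation(labels)
        res = EWAS(beta, covs_perm, spec).fit()
        p = res.table.set_index("probe")["p"].reindex(beta.index).to_numpy()
        min_p[b] = np.nanmin(p)
        if store_full:
            full[b] = p
    probes = beta.index.to_numpy() if store_full else None
    return PermutationSummary(min_p, alpha, seed, probes, full)


def fwer_threshold(summary: PermutationSummary, alpha: float = 0.05) -> float:
    """Empirical alpha-quantile of the minimum-p vector.

    Lower order statistic at rank ``ceil(alpha * n_perm)`` of the ascending
    minima (no interpolation), so the threshold is always one of the
    observed values and exactly reproducible.
    """
    v = np.sort(np.asarray(summary.min_p, dtype=float))
    if v.size == 0:
        raise ValueError("empty minimum-p vector")
    rank = max(1, math.ceil(alpha * v.size))
    return float(v[rank - 1])


def empirical_region_p(
    observed: float, permuted: np.ndarray, pseudo_count: bool = False
) -> float:
    """Fraction of permutations more significant than the observed value.

    Default is the plain proportion ``#(perm < observed) / n_perm`` (an
    observed value smaller than every permutation reports 0, to be read as
    "< 1/n_perm"); ``pseudo_count`` switches to the conservative
    ``(count + 1) / (n_perm + 1)`` variant.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("empty permutation vector")
    count = int((permuted < observed).sum())
    if pseudo_count:
        return (count + 1) / (permuted.size + 1)
    return count / permuted.size
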