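"""Brown's method, the sliding-window DMR caller, and the region scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ewaskit import EWAS, PlantedEffect, SimulationConfig, generate_cohort
from ewaskit.permutation import PermutationSummary, run_permutations
from ewaskit.regions import (
    SlidingWindowScanner,
    brown_combined_p,
    gwas_region_scan,
    reduce_nonoverlapping,
    sliding_window_scan,
)

from conftest import base_spec


class TestBrown:
    def test_single_test_identity(self):
        assert brown_combined_p([0.03]).p == pytest.approx(0.03, rel=1e-12)

    def test_zero_correlation_equals_fisher(self):
        p = [0.01, 0.5, 0.2]
        got = brown_combined_p(p, np.eye(3))
        expected = stats.combine_pvalues(p, method="fisher").pvalue
        assert got.p == pytest.approx(expected, abs=1e-12)
        assert got.f == pytest.approx(6.0)
        assert got.c == pytest.approx(1.0)

    def test_perfect_correlation_limit(self):
        k = 5
        corr = np.full((k, k), 0.999)
        np.fill_diagonal(corr, 1.0)
        got = brown_combined_p([0.04] * k, corr)
        assert got.p == pytest.approx(0.04, abs=2e-3)

    def test_f_bounded_by_2k(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 8))
            a = rng.normal(size=(k, k + 3))
            corr = np.corrcoef(a)
            p = rng.uniform(0.001, 1, k)
            got = brown_combined_p(p, corr)
            assert got.f <= 2 * k + 1e-9
            assert got.p > 0

    def test_zero_pvalue_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            got = brown_combined_p([0.0, 0.5], np.eye(2))
        assert 0 < got.p <= 1

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            brown_combined_p([0.1, 0.2], m)


class TestSlidingWindows:
    def _toy(self, positions, n_samples=30, seed=0):
        rng = np.random.default_rng(seed)
        probes = [f"p{i}" for i in range(len(positions))]
        manifest = pd.DataFrame(
            {"chr": "1", "pos": positions}, index=pd.Index(probes, name="probe")
        )
        beta = pd.DataFrame(
            np.clip(rng.normal(0.5, 0.1, (len(probes), n_samples)), 0, 1),
            index=probes, columns=[f"s{j}" for j in range(n_samples)],
        )
        pvals = pd.Series(rng.uniform(0.001, 1, len(probes)), index=probes)
        return beta, manifest, pvals

    def test_isolated_probe_emits_no_region(self):
        beta, manifest, pvals = self._toy([1000, 100000, 100200])
        out = sliding_window_scan(pvals, beta, manifest, window_sizes=[500])
        assert all("p0" not in r for r in out["probes"])
        assert len(out) == 1  # the p1/p2 pair, deduplicated

    def test_boundary_probe_at_exact_distance_included(self):
        beta, manifest, pvals = self._toy([1000, 1500])
        out = sliding_window_scan(pvals, beta, manifest, window_sizes=[500])
        assert len(out) == 1
        assert set(out["probes"].iloc[0]) == {"p0", "p1"}
        out2 = sliding_window_scan(pvals, beta, manifest, window_sizes=[499])
        assert len(out2) == 0

    def test_windows_deduplicated_by_probe_set(self):
        beta, manifest, pvals = self._toy([1000, 1100, 1200])
        out = sliding_window_scan(pvals, beta, manifest, window_sizes=[5000])
        assert len(out) == 1  # all three seeds produce the same probe set

    def test_cross_chromosome_never_collated(self):
        rng = np.random.default_rng(1)
        probes = ["a", "b"]
        manifest = pd.DataFrame(
            {"chr": ["1", "2"], "pos": [1000, 1100]}, index=probes
        )
        beta = pd.DataFrame(
            rng.random((2, 20)), index=probes, columns=[f"s{j}" for j in range(20)]
        )
        pvals = pd.Series([0.01, 0.01], index=probes)
        out = sliding_window_scan(pvals, beta, manifest, window_sizes=[5000])
        assert len(out) == 0

    def test_planted_block_detected_below_threshold(self):
        block = tuple(f"cg{i:07d}" for i in range(20, 25))
        cfg = SimulationConfig(n_cases=200, n_controls=200, n_probes=120,
                               probe_spacing_bp=100, seed=31)
        coh = generate_cohort(cfg, [PlantedEffect("dmr_block", block, 4.0, 0.5)])
        spec = base_spec(coh)
        res = EWAS(coh.beta, coh.sheet, spec).fit()
        scanner = SlidingWindowScanner(coh.beta, coh.manifest, (100, 200, 500))
        candidates = scanner.combined_p(res.pvalues())
        perm = run_permutations(coh.beta, coh.sheet, spec, 60, seed=1, store_full=True)
        thresholds = scanner.thresholds(perm)
        hits = candidates[
            candidates.apply(lambda r: r["p"] < thresholds[r["window"]], axis=1)
        ]
        hit_probes = set().union(*hits["probes"]) if len(hits) else set()
        assert set(block) & hit_probes

    def test_thresholds_decrease_with_window_count(self, null_cohort):
        spec = base_spec(null_cohort)
        perm = run_permutations(
            null_cohort.beta, null_cohort.sheet, spec, 50, seed=2, store_full=True
        )
        scanner = SlidingWindowScanner(
            null_cohort.beta, null_cohort.manifest, (100, 2000)
        )
        thr = scanner.thresholds(perm)
        n_small = sum(1 for w, _ in scanner.windows if w == 100)
        n_large = sum(1 for w, _ in scanner.windows if w == 2000)
        assert n_large > n_small
        assert thr[2000] < 0.05
        assert thr[2000] <= thr[100]

    def test_missing_full_vectors_error(self, null_cohort):
        scanner = SlidingWindowScanner(null_cohort.beta, null_cohort.manifest, (500,))
        with pytest.raises(ValueError, match="full p-vectors"):
            scanner.thresholds(PermutationSummary(np.array([0.1, 0.2])))


class TestReduceNonoverlapping:
    def _regions(self, rows):
        return pd.DataFrame(rows, columns=["chr", "start", "end", "window",
                                           "n_probes", "probes", "p", "provenance"])

    def test_disjoint_regions_all_retained(self):
        regs = self._regions([
            ("1", 1, 2, 100, 2, ("a", "b"), 1e-5, "sliding_window"),
            ("1", 5, 6, 100, 2, ("c", "d"), 1e-4, "sliding_window"),
        ])
        assert len(reduce_nonoverlapping(regs)) == 2

    def test_nested_keeps_most_significant(self):
        regs = self._regions([
            ("1", 1, 3, 100, 3, ("a", "b", "c"), 1e-6, "sliding_window"),
            ("1", 1, 2, 100, 2, ("a", "b"), 1e-9, "sliding_window"),
        ])
        out = reduce_nonoverlapping(regs)
        assert len(out) == 1
        assert out["p"].iloc[0] == 1e-9

    def test_matches_bruteforce_greedy_oracle(self, rng):
        probes = [f"x{i}" for i in range(30)]
        rows = []
        for _ in range(40):
            k = int(rng.integers(2, 6))
            members = tuple(rng.choice(probes, size=k, replace=False))
            rows.append(("1", 1, 2, 100, k, members, float(rng.uniform()), "sliding_window"))
        regs = self._regions(rows)
        out = reduce_nonoverlapping(regs)
        # brute-force oracle
        ordered = sorted(rows, key=lambda r: r[6])
        taken, keep = set(), []
        for r in ordered:
            if set(r[5]) & taken:
                continue
            taken |= set(r[5])
            keep.append(r[5])
        assert list(out["probes"]) == keep
        # output regions are pairwise probe-disjoint
        seen = set()
        for ps in out["probes"]:
            assert not (set(ps) & seen)
            seen |= set(ps)

    def test_empty_input(self):
        regs = self._regions([])
        assert reduce_nonoverlapping(regs).empty


class TestGwasRegionScan:
    def test_bonferroni_over_testable_regions(self, null_cohort):
        spec = base_spec(null_cohort)
        res = EWAS(null_cohort.beta, null_cohort.sheet, spec).fit()
        man = null_cohort.manifest
        # 76 tiny regions of >=2 probes each -> alpha 0.05/76 = 0.000658
        rows = []
        per_chr = man.groupby("chr")
        made = 0
        for chrom, grp in per_chr:
            pos = grp["pos"].to_numpy()
            for i in range(0, len(pos) - 1, 2):
                if made == 76:
                    break
                rows.append({"chr": chrom, "start": pos[i], "end": pos[i + 1],
                             "name": f"r{made}"})
                made += 1
        bed = pd.DataFrame(rows)
        out = gwas_region_scan(res.pvalues(), None, bed, null_cohort.beta, man)
        assert int(out["testable"].sum()) == 76
        assert out["bonferroni_alpha"].iloc[0] == pytest.approx(0.000658, abs=5e-7)

    def test_single_probe_region_untestable(self, null_cohort):
        man = null_cohort.manifest
        spec = base_spec(null_cohort)
        res = EWAS(null_cohort.beta, null_cohort.sheet, spec).fit()
        pos0 = int(man["pos"].iloc[0])
        bed = pd.DataFrame([{"chr": man["chr"].iloc[0], "start": pos0, "end": pos0,
                             "name": "solo"}])
        out = gwas_region_scan(res.pvalues(), None, bed, null_cohort.beta, man)
        assert not out["testable"].iloc[0]
        assert np.isnan(out["p_cc"].iloc[0])

    def test_all_pvalues_one_gives_combined_near_one(self, null_cohort):
        man = null_cohort.manifest
        probes = null_cohort.beta.index[:5]
        pvals = pd.Series(1.0, index=null_cohort.beta.index)
        bed = pd.DataFrame([{
            "chr": man.loc[probes[0], "chr"],
            "start": int(man.loc[probes, "pos"].min()),
            "end": int(man.loc[probes, "pos"].max()),
            "name": "flat",
        }])
        out = gwas_region_scan(pvals, None, bed, null_cohort.beta, man)
        assert out["p_cc"].iloc[0] > 0.99

    def test_agreeing_moderate_probes_beat_best_single(self):
        # several modestly associated, weakly correlated probes combine to a
        # more significant region p than any single probe
        rng = np.random.default_rng(0)
        probes = [f"p{i}" for i in range(4)]
        man = pd.DataFrame({"chr": "1", "pos": [100, 200, 300, 400]}, index=probes)
        beta = pd.DataFrame(rng.random((4, 50)), index=probes,
                            columns=[f"s{j}" for j in range(50)])
        pvals = pd.Series([0.01, 0.02, 0.015, 0.03], index=probes)
        bed = pd.DataFrame([{"chr": "1", "start": 100, "end": 400, "name": "r"}])
        out = gwas_region_scan(pvals, None, bed, beta, man)
        assert out["p_cc"].iloc[0] < pvals.min()

    def test_empirical_p_from_permutations(self, null_cohort):
        spec = base_spec(null_cohort)
        res = EWAS(null_cohort.beta, null_cohort.sheet, spec).fit()
        perm = run_permutations(null_cohort.beta, null_cohort.sheet, spec, 40,
                                seed=9, store_full=True)
        man = null_cohort.manifest
        grp = man[man["chr"] == man["chr"].iloc[0]]
        bed = pd.DataFrame([{
            "chr": grp["chr"].iloc[0], "start": int(grp["pos"].iloc[0]),
            "end": int(grp["pos"].iloc[9]), "name": "r0",
        }])
        out = gwas_region_scan(res.pvalues(), None, bed, null_cohort.beta, man,
                               perm_cc=perm)
        emp = out["emp_p_cc"].iloc[0]
        assert 0.0 <= emp <= 1.0
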