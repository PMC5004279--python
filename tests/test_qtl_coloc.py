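"""Genotype QC, cis-mQTL scanning, polygenic scores and co-localization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ewaskit import (
    ColocPriors,
    GenotypeQcParams,
    Genotypes,
    PlantedEffect,
    SimulationConfig,
    cis_mqtl_scan,
    classify_coloc,
    coloc_abf,
    generate_cohort,
    generate_genotypes,
    genotype_qc,
    hwe_chisq_p,
    polygenic_score,
    wakefield_log_abf,
)
from ewaskit.coloc import ColocResult
from ewaskit.ewas import fit_probe


def _genotypes(dosages: dict, chrom="1", pos=None, ref="A", alt="G"):
    df = pd.DataFrame(dosages).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    man = pd.DataFrame(
        {
            "chr": chrom,
            "pos": pos or range(1, len(df) + 1),
            "ref": ref,
            "alt": alt,
            "maf": [min(m, 1 - m) for m in np.nanmean(df.to_numpy(), axis=1) / 2],
        },
        index=df.index,
    )
    return Genotypes(df, man)


class TestHwe:
    def test_perfect_hwe_retained(self):
        # MAF 0.3, n=1000 at exact HWE proportions
        counts = (490, 420, 90)
        assert hwe_chisq_p(*counts) > 0.9

    def test_extreme_disequilibrium_removed(self):
        # no heterozygotes at all: chi-square p far below 0.001
        p = hwe_chisq_p(400, 0, 600)
        # oracle: explicit chi-square computation
        n = 1000
        q = (2 * 400 + 0) / (2 * n)
        exp = np.array([n * q**2, 2 * n * q * (1 - q), n * (1 - q) ** 2])
        chi2 = (((np.array([400, 0, 600]) - exp) ** 2) / exp).sum()
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
        assert p < 1e-100

    def test_agrees_with_likelihood_ratio_decision(self, rng):
        """Chi-square and multinomial LRT agree on reject/retain at p=0.001
        for n >= 500 in >99% of simulated SNPs."""
        disagree = 0
        trials = 1000
        for _ in range(trials):
            f = rng.uniform(0.05, 0.5)
            g = rng.binomial(2, f, size=500)
            counts = [(g == k).sum() for k in (0, 1, 2)]
            n = 500
            q = (2 * counts[0] + counts[1]) / (2 * n)
            exp = np.array([n * q**2, 2 * n * q * (1 - q), n * (1 - q) ** 2])
            obs = np.array(counts, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
            lrt = 2 * terms.sum()
            p_lrt = stats.chi2.sf(lrt, 1)
            if (hwe_chisq_p(*counts) < 0.001) != (p_lrt < 0.001):
                disagree += 1
        assert disagree / trials < 0.01


class TestGenotypeQc:
    def test_good_snp_retained(self, rng):
        g = rng.binomial(2, 0.3, size=1000).astype(float)
        gt = _genotypes({"rs1": g})
        out, report = genotype_qc(gt)
        assert "rs1" in out.dosages.index

    def test_hwe_failure_removed(self, rng):
        g = np.array([0.0] * 400 + [2.0] * 600)
        good = rng.binomial(2, 0.3, size=1000).astype(float)
        gt = _genotypes({"bad": g, "good": good})
        out, report = genotype_qc(gt)
        assert report.removed_hwe == ["bad"]
        assert list(out.dosages.index) == ["good"]

    def test_group_count_rule(self, rng):
        g = np.array([0.0] * 990 + [1.0] * 6 + [2.0] * 4)
        rng.shuffle(g)
        good = rng.binomial(2, 0.3, size=1000).astype(float)
        gt = _genotypes({"rare": g, "good": good})
        out, report = genotype_qc(gt, GenotypeQcParams(maf_floor=0.0, hwe_p_floor=0.0))
        assert "rare" in report.removed_group_count

    def test_absent_rare_homozygote_collapses_to_two_groups(self, rng):
        # no hom-alt at all, but both observed groups >= 5: retained
        g = np.array([0.0] * 900 + [1.0] * 100)
        rng.shuffle(g)
        gt = _genotypes({"rs1": g})
        out, _ = genotype_qc(gt, GenotypeQcParams(maf_floor=0.04, hwe_p_floor=1e-12))
        assert "rs1" in out.dosages.index

    def test_maf_floor(self, rng):
        g = np.array([0.0] * 980 + [1.0] * 20)  # MAF 1%
        good = rng.binomial(2, 0.3, size=1000).astype(float)
        gt = _genotypes({"lowmaf": g, "good": good})
        out, report = genotype_qc(gt, GenotypeQcParams(hwe_p_floor=0.0, min_group_count=0))
        assert report.removed_maf == ["lowmaf"]

    def test_missingness_filters_samples_then_snps(self, rng):
        # 40 SNPs x 40 samples: one missing call is 2.5% of a sample's SNPs,
        # so the SNP-level rule is exercised on retained samples
        good = rng.binomial(2, 0.3, size=(40, 40)).astype(float)
        snp_ids = ["a"] + [f"s{i}" for i in range(1, 40)]
        d = pd.DataFrame(good, index=snp_ids,
                         columns=[f"S{i}" for i in range(40)])
        d.iloc[:, 0] = np.nan  # sample S0 fully missing
        d.iloc[0, 1:4] = np.nan  # snp a: 3/39 = 7.7% missing among retained
        gt = Genotypes(d, pd.DataFrame({"chr": "1", "pos": range(1, 41), "ref": "A",
                                        "alt": "G", "maf": 0.3}, index=d.index))
        out, report = genotype_qc(gt, GenotypeQcParams(min_group_count=0,
                                                       hwe_p_floor=0.0, maf_floor=0.0))
        assert report.removed_samples == ["S0"]
        assert "a" in report.removed_missing

    def test_all_removed_raises_with_counts(self, rng):
        g = np.array([0.0] * 400 + [2.0] * 600)
        gt = _genotypes({"bad": g})
        with pytest.raises(ValueError, match="removed"):
            genotype_qc(gt)


class TestCisMqtl:
    def test_planted_slope_recovered(self):
        cfg = SimulationConfig(n_cases=250, n_controls=250, n_probes=30, seed=19)
        eff = [PlantedEffect("mqtl", ("cg0000012",), 3.0, snp_id="rs_q")]
        coh = generate_cohort(cfg, eff)
        # enough background SNPs that genotype PCs are not collinear with rs_q
        gt = generate_genotypes(cfg, (0.2, 0.5), eff, cohort=coh, n_background_snps=30)
        out = cis_mqtl_scan(coh.beta, gt, coh.sheet, coh.manifest)
        hit = out[(out["snp"] == "rs_q") & (out["probe"] == "cg0000012")].iloc[0]
        assert abs(hit["slope"] - 3.0) < 1.96 * hit["se"]
        assert hit["p"] < 1e-4

    def test_cross_chromosome_never_paired(self):
        cfg = SimulationConfig(n_cases=50, n_controls=50, n_probes=40,
                               n_chromosomes=2, seed=23)
        coh = generate_cohort(cfg)
        gt = generate_genotypes(cfg, cohort=coh, n_background_snps=10)
        out = cis_mqtl_scan(coh.beta, gt, coh.sheet, coh.manifest, window_bp=10**9)
        merged = out.merge(
            gt.manifest["chr"].rename("snp_chr"), left_on="snp", right_index=True
        ).merge(
            coh.manifest["chr"].rename("probe_chr"), left_on="probe", right_index=True
        )
        assert (merged["snp_chr"] == merged["probe_chr"]).all()

    def test_null_pairs_uniform_p(self):
        cfg = SimulationConfig(n_cases=100, n_controls=100, n_probes=60, seed=29)
        coh = generate_cohort(cfg)
        gt = generate_genotypes(cfg, cohort=coh, n_background_snps=15)
        out = cis_mqtl_scan(coh.beta, gt, coh.sheet, coh.manifest, window_bp=10**7)
        assert len(out) > 100
        assert stats.kstest(out["p"], "uniform").pvalue > 0.001

    def test_matches_simple_regression_with_constant_covariates(self, rng):
        # covariates constant across samples are dropped from identification;
        # compare against the closed-form simple regression oracle
        n = 120
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.4 + 0.02 * g + rng.normal(0, 0.05, n)
        beta = pd.DataFrame([np.clip(y, 0, 1)], index=["p1"],
                            columns=[f"S{i}" for i in range(n)])
        man = pd.DataFrame({"chr": "1", "pos": [500]}, index=["p1"])
        gt = _genotypes({"rs1": g})
        covs = pd.DataFrame({"age": 40.0, "sex": 1}, index=beta.columns)
        out = cis_mqtl_scan(beta, gt, covs, man, covariate_names=(),
                            n_genotype_pcs=0)
        row = fit_probe(y * 100, g)
        assert out["slope"].iloc[0] == pytest.approx(row.beta, rel=1e-8)
        assert out["se"].iloc[0] == pytest.approx(row.se, rel=1e-8)

    def test_empty_window_warns(self, rng):
        beta = pd.DataFrame([[0.5] * 4], index=["p1"],
                            columns=[f"S{i}" for i in range(4)])
        man = pd.DataFrame({"chr": "1", "pos": [10**9]}, index=["p1"])
        gt = _genotypes({"rs1": np.array([0.0, 1, 2, 1])})
        covs = pd.DataFrame({"age": [40.0] * 4, "sex": [0, 1, 0, 1]}, index=beta.columns)
        with pytest.warns(UserWarning, match="cis window"):
            out = cis_mqtl_scan(beta, gt, covs, man, window_bp=100)
        assert out.empty


class TestPolygenicScore:
    def test_hand_arithmetic(self):
        gt = _genotypes({"rs1": np.array([0.0, 1.0, 2.0])})
        w = pd.DataFrame({"snp": ["rs1"], "effect_allele": ["G"], "weight": [0.5]})
        score, report = polygenic_score(gt, w)
        np.testing.assert_allclose(score, [0.0, 0.5, 1.0])
        assert report["n_used"] == 1

    def test_zero_weights(self):
        gt = _genotypes({"rs1": np.array([0.0, 1.0, 2.0])})
        w = pd.DataFrame({"snp": ["rs1"], "effect_allele": ["G"], "weight": [0.0]})
        score, _ = polygenic_score(gt, w)
        assert (score == 0).all()

    def test_reference_effect_allele_flips_dosage(self):
        gt = _genotypes({"rs1": np.array([0.0, 1.0, 2.0])})
        w = pd.DataFrame({"snp": ["rs1"], "effect_allele": ["A"], "weight": [1.0]})
        score, _ = polygenic_score(gt, w)
        np.testing.assert_allclose(score, [2.0, 1.0, 0.0])

    def test_mismatched_allele_dropped_with_warning(self):
        gt = _genotypes({"rs1": np.array([0.0, 1.0]), "rs2": np.array([2.0, 0.0])})
        w = pd.DataFrame({"snp": ["rs1", "rs2"], "effect_allele": ["T", "G"],
                          "weight": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="mismatch"):
            score, report = polygenic_score(gt, w)
        assert report["n_unresolvable"] == 1
        np.testing.assert_allclose(score, [2.0, 0.0])

    def test_risk_allele_enrichment_separates_cases(self, rng):
        """Planting risk alleles more often in cases yields higher case scores."""
        n_arm = 200
        status = np.r_[np.ones(n_arm), np.zeros(n_arm)]
        snps = {}
        weights = []
        for j in range(50):
            f_case, f_ctrl = 0.35, 0.25
            g = np.r_[rng.binomial(2, f_case, n_arm), rng.binomial(2, f_ctrl, n_arm)]
            snps[f"rs{j}"] = g.astype(float)
            weights.append({"snp": f"rs{j}", "effect_allele": "G", "weight": 0.1})
        gt = _genotypes(snps)
        score, _ = polygenic_score(gt, pd.DataFrame(weights))
        from ewaskit.metastats import mann_whitney

        _, p = mann_whitney(score[status == 1], score[status == 0])
        assert score[status == 1].mean() > score[status == 0].mean()
        assert p < 0.01


class TestWakefieldAbf:
    def test_null_effect_negative_log_abf(self):
        w = 0.15**2
        v = 0.02
        r = w / (v + w)
        assert wakefield_log_abf(0.0, v, w) == pytest.approx(0.5 * np.log(1 - r))
        assert wakefield_log_abf(0.0, v, w) < 0

    def test_no_information_limit(self):
        assert wakefield_log_abf(1.0, 1e12, 0.0225) == pytest.approx(0.0, abs=1e-10)

    def test_direct_arithmetic_oracle(self):
        v, w = 0.02, 0.0225
        z = 5.0
        beta = z * np.sqrt(v)
        r = w / (v + w)
        expected = 0.5 * (np.log(1 - r) + r * z**2)
        assert wakefield_log_abf(beta, v, w) == pytest.approx(expected, rel=1e-12)


class TestColocAbf:
    def _stats(self, betas, varbeta=0.01, trait="quant"):
        m = len(betas)
        return pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(m)],
                "beta": betas,
                "varbeta": varbeta,
                "maf": 0.3,
                "type": trait,
                "n": 1000,
            }
        )

    def test_posteriors_sum_to_one(self, rng):
        t1 = self._stats(rng.normal(0, 0.2, 25))
        t2 = self._stats(rng.normal(0, 0.2, 25))
        res = coloc_abf(t1, t2)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_h3_matches_bruteforce_double_sum(self, rng):
        from ewaskit.coloc import _log_abfs
        from scipy.special import logsumexp

        priors = ColocPriors()
        for _ in range(5):
            t1 = self._stats(rng.normal(0, 0.3, 20))
            t2 = self._stats(rng.normal(0, 0.3, 20))
            res = coloc_abf(t1, t2, priors)
            l1 = _log_abfs(t1, priors)
            l2 = _log_abfs(t2, priors)
            cross = np.array(
                [l1[i] + l2[j] for i in range(20) for j in range(20) if i != j]
            )
            lh = np.array([
                0.0,
                np.log(priors.p1) + logsumexp(l1),
                np.log(priors.p2) + logsumexp(l2),
                np.log(priors.p1 * priors.p2) + logsumexp(cross),
                np.log(priors.p12) + logsumexp(l1 + l2),
            ])
            pp3_brute = np.exp(lh - logsumexp(lh))[3]
            assert res.pp3 == pytest.approx(pp3_brute, rel=1e-9, abs=1e-12)

    def test_snp_order_invariance(self, rng):
        t1 = self._stats(rng.normal(0, 0.3, 15))
        t2 = self._stats(rng.normal(0, 0.3, 15))
        res = coloc_abf(t1, t2)
        perm = rng.permutation(15)
        res_p = coloc_abf(t1.iloc[perm].reset_index(drop=True),
                          t2.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(res.pp, res_p.pp, rtol=1e-10)

    def test_misaligned_snps_rejected(self, rng):
        t1 = self._stats(rng.normal(0, 0.3, 10))
        t2 = self._stats(rng.normal(0, 0.3, 10))
        t2.loc[3, "snp"] = "other"
        with pytest.raises(ValueError, match="identical"):
            coloc_abf(t1, t2)

    def test_larger_prior_w_favors_association_at_large_z(self):
        # beyond a crossover in |z|, doubling W raises the single-SNP ABF
        v = 0.01
        for z in (3.0, 5.0, 8.0):
            b = z * np.sqrt(v)
            assert wakefield_log_abf(b, v, 2 * 0.0225) > wakefield_log_abf(b, v, 0.0225)
        # at z ~ 0 the ordering reverses (shrinkage dominates)
        assert wakefield_log_abf(0.0, v, 2 * 0.0225) < wakefield_log_abf(0.0, v, 0.0225)

    def test_trait_type_changes_prior(self, rng):
        betas = rng.normal(0, 0.3, 12)
        res_q = coloc_abf(self._stats(betas), self._stats(betas))
        res_cc = coloc_abf(self._stats(betas, trait="cc"),
                           self._stats(betas, trait="cc"))
        assert not np.allclose(res_q.pp, res_cc.pp)


class TestClassification:
    def _result(self, pp3, pp4):
        rest = 1.0 - pp3 - pp4
        return ColocResult(100, rest / 3, rest / 3, rest / 3, pp3, pp4)

    def test_printed_convincing_entry(self):
        # PP3 + PP4 = 0.9986 with PP4/PP3 = 36.510
        ratio = 36.510
        pp3 = 0.9986 / (1 + ratio)
        pp4 = 0.9986 - pp3
        res = self._result(pp3, pp4)
        assert res.pp3_plus_pp4 == pytest.approx(0.9986)
        assert res.pp4_over_pp3 == pytest.approx(36.510)
        assert classify_coloc(res) == "convincing"

    def test_below_gate_none(self):
        assert classify_coloc(self._result(0.49, 0.49)) == "none"

    def test_same_variant_but_not_convincing(self):
        res = self._result(0.995 / 3, 0.995 * 2 / 3)  # ratio 2
        assert classify_coloc(res) == "same-variant"

    def test_colocalized_signal_when_pp3_dominates(self):
        assert classify_coloc(self._result(0.9, 0.095)) == "co-localized-signal"

    def test_zero_pp3_with_high_pp4_convincing(self):
        res = ColocResult(10, 0.0, 0.0, 0.0, 0.0, 1.0)
        assert classify_coloc(res) == "convincing"

    def test_priors_validation(self):
        with pytest.raises(ValueError):
            ColocPriors(p1=0.5, p2=0.5, p12=0.2)
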