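"""Risk models and reclassification statistics, checked against
independent oracles: brute-force pair counting for AUC, unpenalized
Newton-Raphson (statsmodels) for the logistic fit, a nonparametric
bootstrap for the IDI standard error, and R's pROC for the paired DeLong
test (frozen fixture)."""

from pathlib import Path

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import kstest

import vusnet as vn
from tests.conftest import make_phenotypes, make_risk_vector

DATA = Path(__file__).parent / "data"


def brute_force_auc(risks, labels):
    """Pair-counting oracle: P(case > control) + 0.5 P(tie)."""
    cases = risks[labels == 1]
    controls = risks[labels == 0]
    wins = ties = 0
    for c in cases:
        for d in controls:
            wins += c > d
            ties += c == d
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def random_cohort(rng, n_variants, n_samples, maf=0.3, balanced=True):
    variants = [vn.VariantRecord(f"v{i}", f"G{i}") for i in range(n_variants)]
    dosages = rng.binomial(2, maf, size=(n_variants, n_samples)).astype(float)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    g = vn.GenotypeMatrix(variants, samples, dosages)
    half = n_samples // 2
    labels = np.array([1] * half + [0] * (n_samples - half))
    return g, make_phenotypes(labels)


class TestFitRiskModel:
    def test_empty_subset_intercept_only_gives_prevalence(self, tiny_matrix):
        y = vn.PhenotypeVector(
            {"S1": "case", "S2": "control", "S3": "control", "S4": "control"}
        )
        m = vn.fit_risk_model(tiny_matrix, y, [])
        risks = vn.predict_risk(m, tiny_matrix)
        assert np.allclose(risks.risks, 0.25, atol=1e-8)

    def test_perfect_separation_stays_finite(self):
        variants = [vn.VariantRecord("sep", "A")]
        dosages = np.array([[2.0, 2.0, 0.0, 0.0]])
        g = vn.GenotypeMatrix(variants, ["S1", "S2", "S3", "S4"], dosages)
        y = make_phenotypes([1, 1, 0, 0])
        m = vn.fit_risk_model(g, y, ["sep"])
        assert np.isfinite(m.coefficients).all()
        risks = vn.predict_risk(m, g)
        assert ((risks.risks > 0) & (risks.risks < 1)).all()

    def test_matches_unpenalized_ml_as_lambda_vanishes(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 300
        x = rng.binomial(2, 0.4, size=n).astype(float)
        p = expit(-0.3 + 0.7 * x)
        labels = rng.binomial(1, p)
        if labels.sum() in (0, n):
            pytest.skip("degenerate draw")
        oracle = sm.Logit(labels, sm.add_constant(x)).fit(disp=0).params
        res = vn.RidgeLogit(labels, x[:, None], ridge_lambda=1e-10).fit()
        assert np.allclose(res.params, oracle, atol=1e-4)

    def test_coefficient_in_oracle_sampling_band(self):
        """n=400 balanced draw with true log-odds 1.0: the ridge fit at the
        default lambda sits inside the unpenalized oracle's 95% Wald band."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 400
        x = rng.binomial(2, 0.3, size=n).astype(float)
        labels = rng.binomial(1, expit(-0.6 + 1.0 * (x - 0.6)))
        fit = sm.Logit(labels, sm.add_constant(x)).fit(disp=0)
        lo, hi = fit.conf_int()[1]
        g = vn.GenotypeMatrix(
            [vn.VariantRecord("v", "G")], [f"S{i + 1}" for i in range(n)], x[None, :]
        )
        m = vn.fit_risk_model(g, make_phenotypes(labels), ["v"])
        assert lo <= m.coefficients[0] <= hi
        assert lo <= 1.0 <= hi  # the band covers the truth in this draw

    def test_unknown_subset_variant(self, tiny_matrix, tiny_phenotypes):
        with pytest.raises(KeyError):
            vn.fit_risk_model(tiny_matrix, tiny_phenotypes, ["nope"])

    def test_single_class_rejected(self, tiny_matrix):
        y = vn.PhenotypeVector({s: "case" for s in tiny_matrix.samples})
        with pytest.raises(ValueError):
            vn.fit_risk_model(tiny_matrix, y, ["rs1"])


class TestPredictRisk:
    def test_closed_forms(self):
        g = vn.GenotypeMatrix(
            [vn.VariantRecord("v", "G")], ["S1"], np.array([[2.0]])
        )
        m = vn.RiskModel(["v"], np.array([0.0]), 0.0, 1e-3)
        assert vn.predict_risk(m, g).risks[0] == pytest.approx(0.5)
        m = vn.RiskModel(["v"], np.array([0.0]), float(logit(0.3)), 1e-3)
        assert vn.predict_risk(m, g).risks[0] == pytest.approx(0.3)
        m = vn.RiskModel(["v"], np.array([0.5]), -1.0, 1e-3)
        assert vn.predict_risk(m, g).risks[0] == pytest.approx(0.5)  # logistic(0)


class TestLoocv:
    def test_contract_one_risk_per_sample_in_open_interval(self):
        g, y = random_cohort(np.random.default_rng(0), 5, 40)
        r = vn.loocv_risks(g, y, g.variant_ids)
        assert len(r.risks) == g.n_samples
        assert r.provenance == "loocv"
        assert ((r.risks > 0) & (r.risks < 1)).all()

    def test_null_genotypes_mean_auc_near_half(self):
        """Phenotype-independent genotypes: mean LOOCV AUC over seeds sits
        in the 0.5 +/- 0.08 band (single seeds scatter more widely)."""
        aucs = []
        for seed in range(20):
            g, y = random_cohort(np.random.default_rng(seed), 10, 200)
            aucs.append(vn.auc(vn.loocv_risks(g, y, g.variant_ids), y))
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_informative_set_close_to_in_sample(self, sim_cohort):
        g, y, truth = sim_cohort
        ids = truth.informative_ids
        m = vn.fit_risk_model(g, y, ids)
        in_sample = vn.auc(vn.predict_risk(m, g), y)
        loocv = vn.auc(vn.loocv_risks(g, y, ids), y)
        assert in_sample > 0.75
        assert abs(in_sample - loocv) < 0.05

    def test_single_class_fold_rejected(self):
        g, _ = random_cohort(np.random.default_rng(1), 3, 4)
        y = make_phenotypes([1, 0, 0, 0])  # leaving out S1 removes every case
        with pytest.raises(ValueError, match="single-class"):
            vn.loocv_risks(g, y, g.variant_ids)


class TestAuc:
    def test_perfect_and_tied(self):
        y = make_phenotypes([1, 1, 0, 0])
        assert vn.auc(make_risk_vector([0.9, 0.9, 0.1, 0.1]), y) == 1.0
        assert vn.auc(make_risk_vector([0.4, 0.4, 0.4, 0.4]), y) == 0.5

    def test_hand_counted_example(self):
        y = make_phenotypes([0, 1, 0, 1])
        assert vn.auc(make_risk_vector([0.2, 0.4, 0.6, 0.8]), y) == pytest.approx(0.75)

    def test_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            risks = np.round(rng.random(n) * 0.8 + 0.1, 2)  # forces ties
            rv = make_risk_vector(risks)
            y = make_phenotypes(labels)
            assert vn.auc(rv, y) == pytest.approx(
                brute_force_auc(risks, labels), abs=1e-12
            )

    def test_complement_symmetry(self):
        rng = np.random.default_rng(7)
        risks = rng.random(30) * 0.8 + 0.1
        labels = np.array([1] * 15 + [0] * 15)
        y = make_phenotypes(labels)
        assert vn.auc(make_risk_vector(risks), y) + vn.auc(
            make_risk_vector(1 - risks), y
        ) == pytest.approx(1.0)


class TestDiscriminationSlope:
    def test_arithmetic(self):
        y = make_phenotypes([1, 1, 0, 0])
        rv = make_risk_vector([0.8, 0.6, 0.3, 0.1])
        assert vn.discrimination_slope(rv, y) == pytest.approx(0.5)

    def test_identical_distributions_zero(self):
        y = make_phenotypes([1, 0, 1, 0])
        rv = make_risk_vector([0.4, 0.4, 0.6, 0.6])
        assert vn.discrimination_slope(rv, y) == pytest.approx(0.0)

    def test_reversed_risks_negative(self):
        y = make_phenotypes([1, 1, 0, 0])
        rv = make_risk_vector([0.1, 0.2, 0.8, 0.9])
        assert vn.discrimination_slope(rv, y) < 0


def bootstrap_idi(r_new, r_old, labels, n_boot=10_000, seed=0):
    """Nonparametric bootstrap oracle for the IDI and its SE: resample
    cases and controls separately, recompute the slope difference."""
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(labels == 1)
    ctrl_idx = np.flatnonzero(labels == 0)
    d = r_new - r_old
    ci = rng.choice(case_idx, size=(n_boot, len(case_idx)), replace=True)
    xi = rng.choice(ctrl_idx, size=(n_boot, len(ctrl_idx)), replace=True)
    idis = d[ci].mean(axis=1) - d[xi].mean(axis=1)
    return float(np.mean(idis)), float(np.std(idis, ddof=1))


class TestReclassification:
    def test_identical_vectors_null_result(self):
        y = make_phenotypes([1, 1, 0, 0])
        rv = make_risk_vector([0.7, 0.6, 0.3, 0.2])
        stats = vn.reclassification_stats(rv, rv, y)
        assert stats.idi == 0.0 and stats.nri_continuous == 0.0 and stats.idi_p == 1.0

    def test_idi_is_slope_difference_with_printed_slopes(self):
        """Two models whose slopes are 0.482 and 0.426 give IDI 0.056; an
        unrounded pair consistent with those printed slopes gives 0.0562."""
        y = make_phenotypes([1, 1, 0, 0])
        new = make_risk_vector([0.9, 0.546, 0.241, 0.241])
        old = make_risk_vector([0.85, 0.535, 0.2405, 0.2925])
        stats = vn.reclassification_stats(new, old, y)
        assert stats.slope_new == pytest.approx(0.482, abs=1e-9)
        assert stats.slope_old == pytest.approx(0.426, abs=1e-9)
        assert stats.idi == pytest.approx(0.056, abs=1e-9)
        unrounded = vn.reclassification_stats(
            make_risk_vector([0.9004, 0.5460, 0.2409, 0.2411]),
            make_risk_vector([0.85, 0.535, 0.2405, 0.2925]),
            y,
        )
        assert unrounded.idi == pytest.approx(0.0562, abs=5e-4)

    def test_idi_identity_and_ci_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            labels = np.concatenate([[1, 0], rng.integers(0, 2, size=n - 2)])
            new = rng.random(n) * 0.8 + 0.1
            old = rng.random(n) * 0.8 + 0.1
            y = make_phenotypes(labels)
            s = vn.reclassification_stats(
                make_risk_vector(new), make_risk_vector(old), y
            )
            assert s.idi == pytest.approx(s.slope_new - s.slope_old, abs=1e-12)
            lo, hi = s.idi_ci95
            assert lo <= s.idi <= hi
            assert lo == pytest.approx(s.idi - 1.96 * s.idi_se, abs=1e-12)
            assert -2.0 <= s.nri_continuous <= 2.0
            assert 0.0 <= s.idi_p <= 1.0

    @pytest.mark.parametrize("case_n,ctrl_n,seed", [(30, 30, 1), (40, 25, 2), (25, 40, 3)])
    def test_se_matches_bootstrap_oracle(self, case_n, ctrl_n, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * case_n + [0] * ctrl_n)
        base = rng.random(case_n + ctrl_n) * 0.6 + 0.2
        new = np.clip(base + rng.normal(0.02 * labels, 0.05), 0.01, 0.99)
        y = make_phenotypes(labels)
        s = vn.reclassification_stats(
            make_risk_vector(new), make_risk_vector(base), y
        )
        boot_idi, boot_se = bootstrap_idi(new, base, labels, seed=seed)
        assert s.idi == pytest.approx(boot_idi, abs=4 * boot_se / np.sqrt(case_n))
        assert s.idi_se == pytest.approx(boot_se, rel=0.25)


class TestCompareAuc:
    def test_identical_vectors(self):
        y = make_phenotypes([1, 1, 0, 0])
        rv = make_risk_vector([0.8, 0.7, 0.3, 0.2])
        out = vn.compare_auc(rv, rv, y)
        assert out["delta_auc"] == 0.0 and out["p"] == 1.0

    def test_matches_frozen_proc_reference(self):
        """Frozen fixture scored by R pROC roc.test(method='delong'):
        AUCs 0.7875 / 0.66625, p = 0.0294545751."""
        data = np.loadtxt(DATA / "delong_paired_synthetic.tsv", skiprows=1)
        labels, ra, rb = data[:, 0].astype(int), data[:, 1], data[:, 2]
        y = make_phenotypes(labels)
        out = vn.compare_auc(make_risk_vector(ra), make_risk_vector(rb), y)
        assert out["auc_a"] == pytest.approx(0.7875, abs=1e-10)
        assert out["auc_b"] == pytest.approx(0.66625, abs=1e-10)
        assert out["p"] == pytest.approx(0.0294545751, abs=1e-8)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(123)
        n = 500
        labels = np.array([1] * 250 + [0] * 250)
        y = make_phenotypes(labels)
        pvals = []
        for _ in range(1000):
            ra = rng.random(n) * 0.98 + 0.01
            rb = rng.random(n) * 0.98 + 0.01
            pvals.append(vn.compare_auc(make_risk_vector(ra), make_risk_vector(rb), y)["p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_planted_difference(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            n = 300
            labels = np.array([1] * 150 + [0] * 150)
            signal = rng.normal(labels * 1.2, 1.0)
            strong = expit(signal)
            weak = expit(0.2 * signal + rng.normal(0, 1.0, n))
            y = make_phenotypes(labels)
            out = vn.compare_auc(make_risk_vector(strong), make_risk_vector(weak), y)
            hits += out["p"] < 0.05
        assert hits >= 19


class TestUnivariateOddsRatios:
    def test_binary_carrier_matches_cross_product(self):
        # cases: 8 carriers / 2 non-carriers; controls: 2 / 8 -> OR 16
        dosages = np.array([[1.0] * 8 + [0.0] * 2 + [1.0] * 2 + [0.0] * 8])
        g = vn.GenotypeMatrix(
            [vn.VariantRecord("v", "G")], [f"S{i + 1}" for i in range(20)], dosages
        )
        y = make_phenotypes([1] * 10 + [0] * 10)
        table = vn.univariate_odds_ratios(g, y)
        assert table.loc["v", "or"] == pytest.approx(16.0, rel=0.01)
        assert table.loc["v", "direction"] == "high_risk"

    def test_balanced_variant_near_null(self):
        dosages = np.array([[0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2]], dtype=float)
        g = vn.GenotypeMatrix(
            [vn.VariantRecord("v", "G")], [f"S{i + 1}" for i in range(12)], dosages
        )
        y = make_phenotypes([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        table = vn.univariate_odds_ratios(g, y)
        assert table.loc["v", "or"] == pytest.approx(1.0, abs=0.05)

    def test_case_only_carrier_finite_high_risk(self):
        dosages = np.array([[1.0, 1.0, 0.0, 0.0, 0.0, 0.0]])
        g = vn.GenotypeMatrix(
            [vn.VariantRecord("v", "G")], [f"S{i + 1}" for i in range(6)], dosages
        )
        y = make_phenotypes([1, 1, 1, 0, 0, 0])
        table = vn.univariate_odds_ratios(g, y)
        assert np.isfinite(table.loc["v", "beta"])
        assert table.loc["v", "direction"] == "high_risk"

    def test_monomorphic_flagged_or_one(self):
        dosages = np.array([[1.0, 1.0, 1.0, 1.0]])
        g = vn.GenotypeMatrix(
            [vn.VariantRecord("v", "G")], ["S1", "S2", "S3", "S4"], dosages
        )
        y = make_phenotypes([1, 1, 0, 0])
        table = vn.univariate_odds_ratios(g, y)
        assert table.loc["v", "or"] == 1.0
        assert bool(table.loc["v", "monomorphic"])
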