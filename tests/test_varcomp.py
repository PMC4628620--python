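"""Polygenic ML/REML fitter: oracle equivalence, boundary behaviour, tests."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ecgherit.pedigree import compute_kinship
from ecgherit.synthetic_data import SimulationConfig, simulate_pedigree, simulate_phenotype
from ecgherit.varcomp import (
    IdentifiabilityError,
    KinshipEigen,
    OptimizerError,
    VCFit,
    fit_polygenic,
    lrt_h2_zero,
    lrt_nested,
)
from ecgherit.varcomp import _profile


@pytest.fixture(scope="module")
def tiny():
    """Pedigree small enough for dense-matrix likelihood evaluation."""
    rows = [
        ("A", "0", "0", "1"), ("B", "0", "0", "2"),
        ("C", "A", "B", "1"), ("D", "A", "B", "2"),
        ("E", "0", "0", "2"), ("F", "C", "E", "1"),
        ("G", "C", "E", "2"), ("H", "0", "0", "1"),
        ("I", "H", "D", "1"), ("J", "H", "D", "2"),
    ]
    from ecgherit.pedigree import validate_pedigree

    ped = validate_pedigree(rows)
    kin = compute_kinship(ped)
    return kin, KinshipEigen.from_kinship(kin)


@pytest.fixture(scope="module")
def midsize():
    cfg = SimulationConfig(n_founders=24, n_generations=3, seed=21)
    ped = simulate_pedigree(cfg, np.random.default_rng(21))
    kin = compute_kinship(ped)
    return kin, KinshipEigen.from_kinship(kin)


class TestLikelihood:
    def test_eigen_rotated_equals_dense_oracle(self, tiny):
        kin, eig = tiny
        n = len(kin.ids)
        A = 2 * kin.phi
        rng = np.random.default_rng(17)
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        yt, Xt = eig.U.T @ y, eig.U.T @ X
        for _ in range(100):
            h2 = rng.uniform(0.01, 0.99)
            ll, beta, s2 = _profile(h2, eig.d, yt, Xt, reml=False)
            V = s2 * (h2 * A + (1 - h2) * np.eye(n))
            direct = multivariate_normal.logpdf(y, mean=X @ beta, cov=V)
            assert ll == pytest.approx(direct, abs=1e-8)

    def test_optimum_beats_random_feasible_points(self, midsize):
        kin, eig = midsize
        rng = np.random.default_rng(3)
        y, _ = simulate_phenotype(eig, None, SimulationConfig(sigma2_g=0.5, sigma2_e=0.5), rng)
        fit = fit_polygenic(y.to_numpy(), None, eig)
        yt = eig.U.T @ y.to_numpy()
        Xt = eig.U.T @ np.ones((len(yt), 1))
        for h2 in rng.uniform(0, 1, 50):
            assert fit.loglik >= _profile(h2, eig.d, yt, Xt, False)[0] - 1e-9

    def test_extra_uncorrelated_column_never_decreases_loglik(self, midsize):
        kin, eig = midsize
        rng = np.random.default_rng(5)
        n = len(kin.ids)
        y, _ = simulate_phenotype(eig, None, SimulationConfig(sigma2_g=0.4, sigma2_e=0.6), rng)
        base = fit_polygenic(y.to_numpy(), None, eig, compute_se=False)
        for _ in range(5):
            X = rng.standard_normal((n, 1))
            aug = fit_polygenic(y.to_numpy(), X, eig, compute_se=False)
            assert aug.loglik >= base.loglik - 1e-8


class TestFitting:
    def test_identity_relatedness_unidentifiable(self):
        with pytest.raises(IdentifiabilityError):
            KinshipEigen.from_kinship(0.5 * np.eye(30))

    def test_boundary_h2_one(self, midsize):
        kin, eig = midsize
        rng = np.random.default_rng(11)
        n = len(kin.ids)
        g = eig.U @ (np.sqrt(eig.d) * rng.standard_normal(n))
        fit = fit_polygenic(g + 1e-6 * rng.standard_normal(n), None, eig, compute_se=False)
        assert fit.h2 > 0.98

    def test_zero_heritability_data(self, midsize):
        kin, eig = midsize
        rng = np.random.default_rng(13)
        h2s = [
            fit_polygenic(rng.standard_normal(len(kin.ids)), None, eig, compute_se=False).h2
            for _ in range(10)
        ]
        assert np.mean(h2s) < 0.1

    def test_sample_size_guard(self, tiny):
        kin, eig = tiny
        y = np.arange(len(kin.ids), dtype=float)
        with pytest.raises(ValueError):
            fit_polygenic(y, np.random.default_rng(0).standard_normal((len(y), 8)), eig)

    def test_invariants_of_converged_fit(self, midsize):
        kin, eig = midsize
        rng = np.random.default_rng(19)
        y, _ = simulate_phenotype(eig, None, SimulationConfig(sigma2_g=0.5, sigma2_e=0.5), rng)
        fit = fit_polygenic(y.to_numpy(), None, eig)
        assert fit.converged
        assert fit.sigma2_g >= 0 and fit.sigma2_e > 0
        assert 0 <= fit.h2 <= 1
        assert np.isfinite(fit.loglik)
        assert fit.h2_se > 0

    def test_reml_close_to_ml_intercept_only(self, midsize):
        kin, eig = midsize
        rng = np.random.default_rng(23)
        y, _ = simulate_phenotype(eig, None, SimulationConfig(sigma2_g=0.5, sigma2_e=0.5), rng)
        ml = fit_polygenic(y.to_numpy(), None, eig, compute_se=False)
        reml = fit_polygenic(y.to_numpy(), None, eig, reml=True, compute_se=False)
        assert reml.h2 == pytest.approx(ml.h2, abs=0.02)


class TestStandardError:
    def test_se_shrinks_with_sample_size(self):
        ses = {}
        for nf, gens, seed in ((16, 3, 31), (40, 4, 33)):
            cfg = SimulationConfig(n_founders=nf, n_generations=gens, seed=seed,
                                   sigma2_g=0.5, sigma2_e=0.5)
            ped = simulate_pedigree(cfg, np.random.default_rng(seed))
            kin = compute_kinship(ped)
            eig = KinshipEigen.from_kinship(kin)
            se = []
            for r in range(8):
                y, _ = simulate_phenotype(eig, None, cfg, np.random.default_rng(100 + r))
                f = fit_polygenic(y.to_numpy(), None, eig)
                if np.isfinite(f.h2_se):
                    se.append(f.h2_se)
            ses[len(ped)] = np.mean(se)
        n_small, n_big = sorted(ses)
        expected_ratio = np.sqrt(n_small / n_big)
        assert ses[n_big] / ses[n_small] == pytest.approx(expected_ratio, rel=0.5)

    def test_boundary_fit_has_undefined_se(self, midsize):
        # an unstructured null draw whose ML optimum sits at h2 = 0
        kin, eig = midsize
        y = np.random.default_rng(0).standard_normal(len(kin.ids))
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_polygenic(y, None, eig)
        assert fit.h2 == 0.0
        assert np.isnan(fit.h2_se)

    def test_se_magnitude_at_study_scale(self, study_scale_se):
        # ~1500-person pedigree at h2 = 0.4: SE of the estimate ~ 0.06
        assert 0.02 < study_scale_se < 0.12


@pytest.fixture(scope="session")
def study_scale_se():
    from ecgherit.recovery import prepare_pedigree

    cfg = SimulationConfig(sigma2_g=0.4, sigma2_e=0.6, seed=41)
    ped, kin, eig = prepare_pedigree(41, cfg)
    y, _ = simulate_phenotype(eig, None, cfg, np.random.default_rng(41))
    return fit_polygenic(y.to_numpy(), None, eig).h2_se


def _mkfit(loglik, n=100, ids=()):
    return VCFit(
        sigma2_g=0.4, sigma2_e=0.6, beta=np.zeros(1), loglik=loglik, h2=0.4,
        h2_se=0.05, converged=True, n=n, var_fixed=0.0, h2_total=0.4, ids=tuple(ids),
    )


class TestLikelihoodRatioTests:
    def test_equal_logliks_give_half(self):
        assert lrt_h2_zero(_mkfit(-100.0), -100.0) == 0.5

    def test_boundary_mixture_value(self):
        # Lambda = 3.84 -> half the chi2_1 tail of ~0.05
        p = lrt_h2_zero(_mkfit(-100.0 + 3.84 / 2), -100.0)
        assert p == pytest.approx(0.025, abs=5e-4)

    def test_negative_lambda_raises(self):
        with pytest.raises(OptimizerError):
            lrt_h2_zero(_mkfit(-101.0), -100.0)

    def test_nested_identical_models(self):
        assert lrt_nested(_mkfit(-50.0), _mkfit(-50.0), df=3) == 1.0

    def test_nested_differing_samples_refused(self):
        with pytest.raises(ValueError):
            lrt_nested(_mkfit(-49.0, n=100), _mkfit(-50.0, n=90), df=1)

    def test_nested_power_with_strong_snp(self, midsize):
        kin, eig = midsize
        n = len(kin.ids)
        hits = 0
        for r in range(20):
            rng = np.random.default_rng(500 + r)
            snp = rng.binomial(2, 0.3, n).astype(float)
            y = 0.8 * snp + rng.standard_normal(n)
            full = fit_polygenic(y, snp[:, None], eig, compute_se=False)
            red = fit_polygenic(y, None, eig, compute_se=False)
            if lrt_nested(full, red, df=1) < 1e-4:
                hits += 1
        assert hits >= 19  # >95% power at this effect size

    def test_nested_null_calibration(self, midsize):
        kin, eig = midsize
        n = len(kin.ids)
        cfg = SimulationConfig(sigma2_g=0.4, sigma2_e=0.6)
        pvals = []
        for r in range(300):
            rng = np.random.default_rng(900 + r)
            y, _ = simulate_phenotype(eig, None, cfg, rng)
            snp = rng.binomial(2, 0.3, n).astype(float)  # pure-noise SNP
            full = fit_polygenic(y.to_numpy(), snp[:, None], eig, compute_se=False)
            red = fit_polygenic(y.to_numpy(), None, eig, compute_se=False)
            pvals.append(lrt_nested(full, red, df=1))
        rate = np.mean(np.array(pvals) < 0.05)
        assert rate == pytest.approx(0.05, abs=0.035)
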