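"""Sampler correctness: conjugate oracles, determinism, block conditionals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from willham.gibbs import (
    ChainSettings,
    CovarianceComponents,
    GibbsState,
    PriorSpec,
    _System,
    augment_missing,
    run_chain,
    sample_covariances,
    read_samples,
    write_samples,
)
from willham.model import ModelSpec, build_design
from willham.pedigree import UNKNOWN, a_inverse, validate_pedigree


def _intercept_only(n, y):
    df = pd.DataFrame({
        "animal": [f"A{i}" for i in range(n)], "sire": "0", "dam": "0",
        "sex": "M", "dam_age": 5.0, "cg": "g1", "w120": y,
    })
    ped = validate_pedigree([(f"A{i}", UNKNOWN, UNKNOWN) for i in range(n)])
    spec = ModelSpec(traits=("w120",), maternal_traits=(), pe_traits=(),
                     covariate_traits=(), direct=False)
    return build_design(df, ped, spec), a_inverse(ped)


class TestChainMechanics:
    def test_burn_in_equals_iterations_gives_empty(self):
        mats, ai = _intercept_only(20, np.random.default_rng(0).normal(100, 10, 20))
        s = run_chain(mats, ai, settings=ChainSettings(iterations=50, burn_in=50, thin=1, seed=0))
        assert s.n_samples == 0

    def test_same_seed_identical(self):
        mats, ai = _intercept_only(20, np.random.default_rng(0).normal(100, 10, 20))
        st = ChainSettings(iterations=200, burn_in=50, thin=2, seed=5)
        s1 = run_chain(mats, ai, settings=st)
        s2 = run_chain(mats, ai, settings=st)
        np.testing.assert_array_equal(s1.R, s2.R)

    def test_double_thin_is_subsequence(self):
        mats, ai = _intercept_only(20, np.random.default_rng(0).normal(100, 10, 20))
        s1 = run_chain(mats, ai, settings=ChainSettings(iterations=200, burn_in=40, thin=2, seed=9))
        s2 = run_chain(mats, ai, settings=ChainSettings(iterations=200, burn_in=40, thin=4, seed=9))
        np.testing.assert_array_equal(s2.R[:, 0, 0], s1.R[1::2, 0, 0])

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            ChainSettings(iterations=10, burn_in=20)
        with pytest.raises(ValueError):
            ChainSettings(thin=0)

    def test_retained_samples_positive_definite(self):
        rng = np.random.default_rng(3)
        ped_rows = [(f"F{i}", UNKNOWN, UNKNOWN) for i in range(6)]
        ped_rows += [(f"A{i}", f"F{i % 3}", f"F{3 + i % 3}") for i in range(30)]
        ped = validate_pedigree(ped_rows)
        df = pd.DataFrame({
            "animal": [f"A{i}" for i in range(30)],
            "sire": [f"F{i % 3}" for i in range(30)],
            "dam": [f"F{3 + i % 3}" for i in range(30)],
            "sex": ["M", "F"] * 15, "dam_age": 5.0, "cg": ["g1", "g2"] * 15,
            "w120": rng.normal(100, 10, 30), "w240": rng.normal(180, 15, 30),
        })
        df.loc[::5, "w240"] = np.nan  # trait-wise missingness
        spec = ModelSpec(traits=("w120", "w240"), maternal_traits=("w120",),
                         pe_traits=("w120",), covariate_traits=())
        mats = build_design(df, ped, spec)
        prior = PriorSpec.weak(3, 1, 2)
        s = run_chain(mats, a_inverse(ped), prior=prior,
                      settings=ChainSettings(iterations=300, burn_in=100, thin=2, seed=1))
        for i in range(s.n_samples):
            np.linalg.cholesky(s.G[i])
            np.linalg.cholesky(s.P[i])
            np.linalg.cholesky(s.R[i])

    def test_improper_conditional_rejected_at_setup(self):
        mats, ai = _intercept_only(2, np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="improper"):
            run_chain(mats, ai, settings=ChainSettings(iterations=10, burn_in=0, thin=1, seed=0))


class TestConjugateOracle:
    """Univariate intercept-only model vs the closed-form posterior."""

    def test_residual_variance_matches_scaled_inv_chi2(self):
        rng = np.random.default_rng(7)
        n = 50
        y = rng.normal(100, 15, n)
        mats, ai = _intercept_only(n, y)
        s = run_chain(mats, ai, keep_location=True,
                      settings=ChainSettings(iterations=16_000, burn_in=1_000, thin=3, seed=11))
        assert s.n_samples == 5000
        sig2 = s.R[:, 0, 0]
        # flat prior: sigma2 | y ~ Inv-Gamma((n-3)/2, (n-1) s^2 / 2)
        s2 = y.var(ddof=1)
        ref = stats.invgamma(a=(n - 3) / 2, scale=(n - 1) * s2 / 2)
        ks = stats.kstest(sig2, ref.cdf).statistic
        assert ks < 0.05
        # intercept marginal mean vs the GLS (here: plain mean) solution
        mu = s.location[:, 0]
        mcse = mu.std(ddof=1) / np.sqrt(len(mu))
        assert abs(mu.mean() - y.mean()) < 3 * mcse


class TestCovarianceConditional:
    def _tiny_system(self):
        rng = np.random.default_rng(5)
        n = 12
        ped = validate_pedigree([(f"A{i}", UNKNOWN, UNKNOWN) for i in range(n)])
        df = pd.DataFrame({
            "animal": [f"A{i}" for i in range(n)], "sire": "0", "dam": "0",
            "sex": "M", "dam_age": 5.0, "cg": "g1",
            "w120": rng.normal(100, 10, n),
        })
        spec = ModelSpec(traits=("w120",), maternal_traits=(), pe_traits=(),
                         covariate_traits=())
        mats = build_design(df, ped, spec)
        return mats, a_inverse(ped)

    def test_g_draws_match_inverse_wishart_mean(self):
        """With effects held fixed, G | a is IW with known mean."""
        mats, ai = self._tiny_system()
        sys = _System(mats, ai)
        rng = np.random.default_rng(2)
        a_true = rng.normal(0, 3, sys.n_ped)
        prior = PriorSpec.weak(1, 0, 1, scale=1.0)
        comp = CovarianceComponents(
            G=np.eye(1), P=np.zeros((0, 0)), R=np.eye(1),
            g_labels=[("w120", "direct")], pe_traits=(), traits=("w120",),
        )
        theta = np.zeros(sys.n_eq)
        theta[sys.geq_start:sys.peq_start] = a_true
        state = GibbsState(theta=theta, e=np.zeros_like(mats.y), comp=comp)
        draws = np.empty(20_000)
        for i in range(len(draws)):
            state.theta = theta  # effects held at truth
            sample_covariances(state, sys, prior, rng)
            draws[i] = state.comp.G[0, 0]
        S = float(a_true @ (ai.matrix @ a_true)) + prior.g_scale[0, 0]
        expected = S / (sys.n_ped + prior.g_df - 1 - 1)
        assert draws.mean() == pytest.approx(expected, rel=0.02)

    def test_univariate_reduces_to_scaled_inv_chi2(self):
        mats, ai = self._tiny_system()
        sys = _System(mats, ai)
        rng = np.random.default_rng(4)
        a_true = np.arange(1.0, sys.n_ped + 1)
        prior = PriorSpec.flat(1, 0, 1)
        comp = CovarianceComponents(
            G=np.eye(1), P=np.zeros((0, 0)), R=np.eye(1),
            g_labels=[("w120", "direct")], pe_traits=(), traits=("w120",),
        )
        theta = np.zeros(sys.n_eq)
        theta[sys.geq_start:] = a_true
        state = GibbsState(theta=theta, e=rng.normal(size=mats.y.shape), comp=comp)
        draws = np.empty(8000)
        for i in range(len(draws)):
            state.theta = theta
            sample_covariances(state, sys, prior, rng)
            draws[i] = state.comp.G[0, 0]
        S = float(a_true @ (ai.matrix @ a_true))
        ref = stats.invgamma(a=(sys.n_ped - 2) / 2, scale=S / 2)
        assert stats.kstest(draws, ref.cdf).statistic < 0.03


class TestAugmentation:
    def _bivariate_state(self, corr):
        rng = np.random.default_rng(8)
        n = 4000
        R = np.array([[4.0, corr * 2 * 3], [corr * 2 * 3, 9.0]])
        comp = CovarianceComponents(
            G=np.zeros((0, 0)), P=np.zeros((0, 0)), R=R,
            g_labels=[], pe_traits=(), traits=("w120", "w240"),
        )
        e = np.zeros((n, 2))
        e[:, 0] = rng.normal(0, 2, n)  # observed trait residuals
        return comp, e, rng

    def test_conditional_slope(self):
        """Missing-trait draw has conditional mean slope r * s2/s1."""
        comp, e, rng = self._bivariate_state(0.8)

        class Sys:
            patterns = [((True, False), np.arange(len(e)))]

        state = GibbsState(theta=np.zeros(1), e=e, comp=comp)
        augment_missing(state, Sys(), rng)
        slope = np.polyfit(e[:, 0], e[:, 1], 1)[0]
        assert slope == pytest.approx(0.8 * 3 / 2, abs=0.1)

    def test_diagonal_r_gives_independent_draw(self):
        comp, e, rng = self._bivariate_state(0.0)

        class Sys:
            patterns = [((True, False), np.arange(len(e)))]

        state = GibbsState(theta=np.zeros(1), e=e, comp=comp)
        augment_missing(state, Sys(), rng)
        assert abs(np.corrcoef(e[:, 0], e[:, 1])[0, 1]) < 0.05
        assert e[:, 1].std() == pytest.approx(3.0, rel=0.05)

    def test_fully_observed_unchanged(self):
        comp, e, rng = self._bivariate_state(0.5)
        before = e.copy()

        class Sys:
            patterns = [((True, True), np.arange(len(e)))]

        augment_missing(GibbsState(theta=np.zeros(1), e=e, comp=comp), Sys(), rng)
        np.testing.assert_array_equal(e, before)


def test_samples_file_roundtrip(tmp_path):
    mats, ai = _intercept_only(20, np.random.default_rng(0).normal(100, 10, 20))
    s = run_chain(mats, ai, settings=ChainSettings(iterations=100, burn_in=20, thin=2, seed=3))
    path = tmp_path / "samples.csv"
    write_samples(s, path)
    frame = read_samples(path)
    assert list(frame.columns) == ["R_w120_w120"]
    np.testing.assert_allclose(frame["R_w120_w120"], s.R[:, 0, 0])
    header = path.read_text().splitlines()[0]
    assert header.startswith("#") and "seed=3" in header
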