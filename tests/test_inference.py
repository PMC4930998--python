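"""Likelihood, fitting, model selection, LRT and bootstraps."""

import numpy as np
import pytest

from newtflow.engine import expected_sfs
from newtflow.inference import (BootstrapSummary, FitResult,
                                conventional_bootstrap, fit_model,
                                godambe_adjusted_lrt, parametric_gof,
                                poisson_loglik, rank_models_bic)
from newtflow.sfs import Spectrum
from newtflow.simulate import sample_sfs


@pytest.fixture(scope="module")
def si_spec():
    return expected_sfs("SI", [1.0, 0.5, 0.6], 4, 4)


# -- composite Poisson likelihood ------------------------------------------

def test_theta_closed_form(si_spec):
    data = Spectrum(2.0 * si_spec.data, si_spec.mask.copy())
    ll, theta = poisson_loglik(si_spec, data)
    assert theta == pytest.approx(2.0)
    exp = Spectrum(np.full((5, 5), 10 / 23.0))   # 23 unmasked cells sum to 10
    dat = Spectrum(np.full((5, 5), 20 / 23.0))
    _, th = poisson_loglik(exp, dat)
    assert th == pytest.approx(2.0)


def test_profiled_theta_maximizes_likelihood(si_spec):
    data = sample_sfs(si_spec, 100.0, seed=1)
    ll_hat, theta_hat = poisson_loglik(si_spec, data)
    for theta in theta_hat * np.array([0.5, 0.9, 1.1, 2.0]):
        ll, _ = poisson_loglik(si_spec, data, theta=theta)
        assert ll < ll_hat
    # closed form matches a fine numeric grid to high relative accuracy
    grid = theta_hat * (1 + np.linspace(-1e-3, 1e-3, 2001))
    lls = [poisson_loglik(si_spec, data, theta=t)[0] for t in grid]
    assert abs(grid[int(np.argmax(lls))] - theta_hat) / theta_hat < 1e-5


def test_zero_expectation_with_observations_is_minus_inf(si_spec):
    exp = si_spec.copy()
    exp.data[1, 0] = 0.0
    data = sample_sfs(si_spec, 50.0, seed=2)
    data.data[1, 0] = 3.0
    ll, _ = poisson_loglik(exp, data)
    assert ll == -np.inf


def test_likelihood_invariant_under_joint_permutation(si_spec):
    data = sample_sfs(si_spec, 80.0, seed=3)
    ll0, _ = poisson_loglik(si_spec, data)
    rng = np.random.default_rng(0)
    perm = rng.permutation(si_spec.data.size).reshape(si_spec.shape)
    exp_p = Spectrum(si_spec.data.ravel()[perm], si_spec.mask.ravel()[perm])
    dat_p = Spectrum(data.data.ravel()[perm], data.mask.ravel()[perm])
    ll1, _ = poisson_loglik(exp_p, dat_p)
    assert ll1 == pytest.approx(ll0)


# -- fitting ----------------------------------------------------------------

TRUE_SC = np.array([1.0, 0.4, 0.3, 0.4, 1.2, 0.4])


def test_fit_recovers_high_information_optimum():
    """At theta = 1e5 the fitted likelihood is at least that of the
    generating parameters."""
    truth = expected_sfs("SC", TRUE_SC, 6, 6)
    data = sample_sfs(truth, 1e5, seed=4)
    fit = fit_model("SC", data, n_starts=2, seed=0, start=TRUE_SC, maxiter=60)
    ll_truth, _ = poisson_loglik(truth, data)
    assert fit.loglik >= ll_truth - 1e-3
    # parameters stay close to truth with this much information
    assert np.allclose(fit.params, TRUE_SC, rtol=0.2)


def test_fit_is_deterministic():
    truth = expected_sfs("SI", [1.0, 0.5, 0.6], 4, 4)
    data = sample_sfs(truth, 500.0, seed=5)
    a = fit_model("SI", data, n_starts=3, seed=42, maxiter=40)
    b = fit_model("SI", data, n_starts=3, seed=42, maxiter=40)
    assert np.array_equal(a.params, b.params) and a.loglik == b.loglik


def test_fit_with_fixed_parameters():
    truth = expected_sfs("IM", [0.4, 0.8, 0.6, 0.6], 6, 6)
    data = sample_sfs(truth, 2000.0, seed=6)
    fit = fit_model("IM", data, n_starts=2, seed=1,
                    start=np.array([0.4, 0.8, 0.6, 0.6]),
                    fixed={"m12": 0.6, "m21": 0.6}, maxiter=60)
    i = ["s", "T", "m12", "m21"].index("m12")
    assert fit.params[2] == 0.6 and fit.params[3] == 0.6
    assert fit.n_free == 2


def test_het_class_relabeling():
    """Fits of heterogeneous models report class 1 as the weaker-migration
    class (the mixture is invariant under class swap + P -> 1-P)."""
    p = [1.0, 0.5, 0.3, 0.4, 3.0, 2.5, 0.2, 0.1, 0.3]  # class 1 stronger here
    truth = expected_sfs("SCHET", p, 6, 6)
    data = sample_sfs(truth, 5e4, seed=7)
    fit = fit_model("SCHET", data, n_starts=1, seed=0, start=np.array(p),
                    maxiter=40)
    i = {"m12_1": 4, "m21_1": 5, "m12_2": 6, "m21_2": 7, "P": 8}
    assert (fit.params[i["m12_1"]] + fit.params[i["m21_1"]]
            <= fit.params[i["m12_2"]] + fit.params[i["m21_2"]])


# -- model selection --------------------------------------------------------

def test_bic_algebra():
    mk = lambda m, ll, k: FitResult(model=m, params=np.zeros(k - 1),
                                    theta=1.0, loglik=ll, n_starts=1,
                                    converged=True)
    # equal likelihood: fewer parameters win
    t = rank_models_bic([mk("SI", -100.0, 5), mk("SC", -100.0, 7)], n_obs=1000)
    assert t.model.iloc[0] == "SI"
    # a likelihood gain above (dk/2) ln n flips the ranking
    gain = 0.5 * 2 * np.log(1000) + 1.0
    t = rank_models_bic([mk("SI", -100.0, 5), mk("SC", -100.0 + gain, 7)],
                        n_obs=1000)
    assert t.model.iloc[0] == "SC"


def test_bic_prefers_migration_model_on_migration_data():
    truth = expected_sfs("SC", [1.0, 0.5, 0.3, 0.5, 3.0, 2.0], 6, 6)
    data = sample_sfs(truth, 3e4, seed=8)
    fit_sc = fit_model("SC", data, n_starts=2, seed=0,
                       start=np.array([1.0, 0.5, 0.3, 0.5, 3.0, 2.0]),
                       maxiter=60)
    fit_si = fit_model("SI", data, n_starts=4, seed=0, maxiter=60)
    table = rank_models_bic([fit_si, fit_sc], data=data)
    assert table.model.iloc[0] == "SC"


# -- Godambe LRT ------------------------------------------------------------

def test_lrt_equal_likelihood_gives_p_one(si_spec):
    data = sample_sfs(si_spec, 100.0, seed=9)
    boots = [sample_sfs(si_spec, 100.0, seed=s) for s in range(4)]
    nested = FitResult(model="SI", params=np.array([1.0, 0.5, 0.6]),
                       theta=100.0, loglik=-50.0, n_starts=1, converged=True,
                       fixed={"nu1": 1.0})
    full = FitResult(model="SI", params=np.array([1.0, 0.5, 0.6]),
                     theta=100.0, loglik=-50.0, n_starts=1, converged=True)
    out = godambe_adjusted_lrt(nested, full, boots, data, df=1)
    assert out["D"] == 0.0 and out["D_adj"] == 0.0 and out["p"] == 1.0


def test_lrt_negative_d_flagged(si_spec):
    data = sample_sfs(si_spec, 100.0, seed=10)
    nested = FitResult(model="SI", params=np.array([1.0, 0.5, 0.6]),
                       theta=1.0, loglik=-49.0, n_starts=1, converged=True,
                       fixed={"nu1": 1.0})
    full = FitResult(model="SI", params=np.array([1.0, 0.5, 0.6]),
                     theta=1.0, loglik=-50.0, n_starts=1, converged=True)
    out = godambe_adjusted_lrt(nested, full, [data], data)
    assert out["p"] is None and "negative" in out["flag"]


def test_lrt_requires_same_model_and_constraints(si_spec):
    data = sample_sfs(si_spec, 10.0, seed=11)
    a = FitResult(model="SI", params=np.zeros(3), theta=1, loglik=0,
                  n_starts=1, converged=True)
    b = FitResult(model="SC", params=np.zeros(6), theta=1, loglik=0,
                  n_starts=1, converged=True)
    with pytest.raises(ValueError):
        godambe_adjusted_lrt(a, b, [data], data)
    with pytest.raises(ValueError):
        godambe_adjusted_lrt(a, a, [data], data)


# -- bootstraps -------------------------------------------------------------

def test_bootstrap_summary_arithmetic():
    s = BootstrapSummary(model="SI", param_names=("nu1", "nu2"),
                         replicates=np.array([[1.0, 5], [2.0, 5], [3.0, 5]]),
                         n_failed=0)
    assert s.mean[0] == pytest.approx(2.0)
    assert s.sd[0] == pytest.approx(1.0)
    lo, hi = s.ci
    assert lo[0] == pytest.approx(2 - 1.96) and hi[0] == pytest.approx(2 + 1.96)
    # zero-variance column collapses to the point
    assert lo[1] == hi[1] == 5.0


def test_bootstrap_defaults_and_interval_identity():
    import inspect
    assert inspect.signature(conventional_bootstrap).parameters["B"].default == 120
    assert inspect.signature(parametric_gof).parameters["B"].default == 100


def test_conventional_bootstrap_over_loci():
    """Resampled refits scatter around the generating parameters."""
    truth = expected_sfs("SI", [1.0, 0.5, 0.6], 4, 4)
    rng = np.random.default_rng(0)
    loci = [sample_sfs(truth, 30.0, seed=int(rng.integers(2**31)))
            for _ in range(25)]
    summary = conventional_bootstrap(loci, "SI", B=8, seed=1,
                                     start=np.array([1.0, 0.5, 0.6]),
                                     n_starts=1, maxiter=30)
    assert summary.replicates.shape[0] + summary.n_failed == 8
    table = summary.table()
    assert list(table.parameter) == ["nu1", "nu2", "T", "theta"]
    lo, hi = summary.ci
    assert np.all(lo <= summary.mean) and np.all(summary.mean <= hi)


# -- parametric goodness of fit --------------------------------------------

def test_gof_calibrated_under_truth():
    truth = expected_sfs("SC", TRUE_SC, 6, 6)
    data = sample_sfs(truth, 5000.0, seed=12)
    fit = FitResult(model="SC", params=TRUE_SC, theta=5000.0, loglik=0.0,
                    n_starts=1, converged=True)
    report = parametric_gof(fit, data, B=60, seed=3)
    assert 0.02 < report["p_chi2_upper"] < 0.98


def test_gof_detects_misspecification():
    """Deeply diverged isolation data scored against a strong-migration
    model lands in the extreme tail of the simulated chi-square."""
    iso = expected_sfs("SI", [1.0, 1.0, 2.0], 6, 6)
    data = sample_sfs(iso, 5000.0, seed=13)
    wrong = FitResult(model="SC",
                      params=np.array([1.0, 1.0, 0.1, 1.9, 4.0, 4.0]),
                      theta=5000.0, loglik=0.0, n_starts=1, converged=True)
    report = parametric_gof(wrong, data, B=60, seed=4)
    assert report["p_chi2_upper"] < 0.02
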