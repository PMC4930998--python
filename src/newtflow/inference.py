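"""Composite-likelihood fitting, model selection and uncertainty.

The observed joint SFS is scored against a model's expected spectrum with a
composite Poisson likelihood: each unmasked cell is an independent Poisson
count with mean ``theta * Phi_cell``, where ``Phi`` is the per-unit-theta
expected spectrum and ``theta`` has a closed-form profile maximizer.
Because linkage among sites is ignored, the likelihood is composite:
likelihood-ratio statistics are rescaled with the Godambe information
(sandwich) estimated from bootstrap spectra before comparison to chi-square.

Fitting is quasi-Newton (L-BFGS-B) in log-parameter space from multiple
randomly perturbed starts; model ranking uses BIC; uncertainty comes from a
conventional bootstrap over loci and model adequacy from a parametric
goodness-of-fit bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .engine import expected_sfs
from .models import DemographicModel, model_registry
from .sfs import Spectrum

__all__ = [
    "FitResult",
    "BootstrapSummary",
    "poisson_loglik",
    "fit_model",
    "rank_models_bic",
    "godambe_adjusted_lrt",
    "conventional_bootstrap",
    "parametric_gof",
]


# ---------------------------------------------------------------------------
# Composite Poisson likelihood
# ---------------------------------------------------------------------------

def poisson_loglik(expected: Spectrum, data: Spectrum,
                   theta: float | None = None) -> tuple[float, float]:
    """Composite Poisson log-likelihood of ``data`` given a unit spectrum.

    If ``theta`` is not supplied it is profiled out analytically:
    ``theta_hat = sum(data) / sum(expected)`` over jointly unmasked cells.
    Returns ``(loglik, theta)``.  A cell with zero expectation but positive
    count yields ``-inf`` (reported explicitly, never silently dropped).
    """
    if expected.shape != data.shape:
        raise ValueError("expected and data spectra have different shapes")
    m = ~(expected.mask | data.mask)
    e = expected.data[m]
    d = data.data[m]
    if theta is None:
        denom = e.sum()
        if denom <= 0:
            raise ValueError("expected spectrum sums to zero")
        theta = d.sum() / denom
    elif theta < 0:
        raise ValueError("theta must be nonnegative")
    lam = theta * e
    bad = (lam == 0) & (d > 0)
    if bad.any():
        return -np.inf, float(theta)
    pos = lam > 0
    ll = float(np.sum(d[pos] * np.log(lam[pos]) - lam[pos] - gammaln(d[pos] + 1.0))
               - lam[~pos].sum())
    return ll, float(theta)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a multi-start maximum-composite-likelihood fit."""

    model: str
    params: np.ndarray
    theta: float
    loglik: float
    n_starts: int
    converged: bool
    fixed: dict = field(default_factory=dict)   # name -> fixed value
    starts: list = field(default_factory=list)  # per-start (params, loglik, ok)
    segments: int = 24
    bic: float | None = None

    @property
    def n_free(self) -> int:
        return len(self.params) - len(self.fixed)

    def as_dict(self) -> dict:
        m = model_registry(self.model)
        out = dict(zip(m.param_names, map(float, self.params)))
        out["theta"] = self.theta
        out["loglik"] = self.loglik
        if self.bic is not None:
            out["bic"] = self.bic
        return out


def _relabel_het_classes(model: DemographicModel, params: np.ndarray) -> np.ndarray:
    """Order migration classes so class 1 is the lower-total-migration class.

    The two-class mixture is invariant under swapping the classes and
    replacing ``P`` by ``1 - P``; fits are reported with class 1 (weight
    ``P``) as the class with the smaller ``m12 + m21``, matching the
    category ordering of the newt study.
    """
    if not model.het:
        return params
    idx = {n: i for i, n in enumerate(model.param_names)}
    p = params.copy()
    tot1 = p[idx["m12_1"]] + p[idx["m21_1"]]
    tot2 = p[idx["m12_2"]] + p[idx["m21_2"]]
    if tot1 > tot2:
        for a, b in (("m12_1", "m12_2"), ("m21_1", "m21_2")):
            p[idx[a]], p[idx[b]] = p[idx[b]], p[idx[a]]
        p[idx["P"]] = 1.0 - p[idx["P"]]
    return p


def fit_model(model: DemographicModel | str, data: Spectrum, n_starts: int = 50,
              seed: int = 0, start: np.ndarray | None = None,
              fixed: dict | None = None, segments: int = 24,
              maxiter: int = 200, perturb_fold: float = 2.0,
              relabel_het: bool = True) -> FitResult:
    """Fit a registry model to an observed spectrum by L-BFGS-B multi-start.

    Optimization runs in log-parameter space with bound clipping; starts
    after the first are perturbed multiplicatively by log-uniform noise up to
    ``perturb_fold``-fold.  ``fixed`` maps parameter names to frozen values
    (used for nested models in likelihood-ratio testing).  ``theta`` is
    profiled analytically inside the objective.  Deterministic for a given
    seed.
    """
    if isinstance(model, str):
        model = model_registry(model)
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in model.param_names:
            raise ValueError(f"unknown fixed parameter {name!r} for {model.name}")
    rng = np.random.default_rng(seed)
    # optimization runs in log space: rates with a zero lower bound get a
    # tiny positive floor (migration below ~1e-6 is indistinguishable from 0)
    lower = np.where(np.asarray(model.lower) <= 0, 1e-6, np.asarray(model.lower))
    upper = np.asarray(model.upper)
    names = model.param_names
    free = np.array([n not in fixed for n in names])
    if start is None:
        start = np.sqrt(lower * np.minimum(upper, 10.0))  # geometric mid, tempered
    start = np.clip(np.asarray(start, dtype=float), lower, upper)
    for i, n in enumerate(names):  # fixed values are honoured exactly
        if n in fixed:
            start[i] = fixed[n]

    def full_params(x_free_log):
        p = start.copy()
        p[free] = np.exp(x_free_log)
        return p

    def objective(x_free_log):
        p = full_params(x_free_log)
        try:
            exp_spec = expected_sfs(model, p, data.n1, data.n2, segments=segments)
            ll, _ = poisson_loglik(exp_spec, data)
        except Exception:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    bounds = list(zip(np.log(lower[free]), np.log(upper[free])))
    x0 = np.log(start[free])
    results = []
    for k in range(n_starts):
        if k == 0:
            xk = x0
        else:
            xk = x0 + np.log(perturb_fold) * rng.uniform(-1, 1, size=x0.size)
        xk = np.clip(xk, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = minimize(objective, xk, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter})
            ok = bool(np.isfinite(res.fun)) and res.fun < 1e11
            results.append((full_params(res.x), -float(res.fun), ok))
        except Exception:  # pragma: no cover - defensive
            results.append((full_params(xk), -np.inf, False))
    if not any(ok for _, _, ok in results):
        raise RuntimeError(f"all {n_starts} optimization starts failed for {model.name}")
    best_params, best_ll, _ = max(
        (r for r in results if r[2]), key=lambda r: r[1])
    exp_spec = expected_sfs(model, best_params, data.n1, data.n2, segments=segments)
    ll, theta = poisson_loglik(exp_spec, data)
    if relabel_het:
        best_params = _relabel_het_classes(model, best_params)
    return FitResult(model=model.name, params=np.asarray(best_params),
                     theta=theta, loglik=ll, n_starts=n_starts,
                     converged=True, fixed=fixed, starts=results,
                     segments=segments)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def rank_models_bic(fits: list[FitResult], n_obs: float | None = None,
                    data: Spectrum | None = None) -> pd.DataFrame:
    """BIC table, ascending (best first).

    ``BIC = -2 loglik + k ln(n_obs)`` with ``k`` the number of free
    demographic parameters plus one for ``theta``.  ``n_obs`` defaults to
    the total SNP count of ``data`` (sum of unmasked cells).
    """
    if n_obs is None:
        if data is None:
            raise ValueError("provide n_obs or data")
        n_obs = data.sum()
    rows = []
    for fit in fits:
        k = fit.n_free + 1
        fit.bic = -2.0 * fit.loglik + k * np.log(n_obs)
        rows.append({"model": fit.model, "k": k, "loglik": fit.loglik,
                     "bic": fit.bic})
    table = pd.DataFrame(rows).sort_values("bic", ignore_index=True)
    table["delta_bic"] = table["bic"] - table["bic"].iloc[0]
    return table


# ---------------------------------------------------------------------------
# Godambe-adjusted likelihood-ratio test
# ---------------------------------------------------------------------------

def _score(model, params, idx, data, segments, eps):
    """Finite-difference composite score over parameter indices ``idx``."""
    g = np.zeros(len(idx))
    for k, i in enumerate(idx):
        h = eps * max(abs(params[i]), 1e-8)
        up, dn = params.copy(), params.copy()
        up[i] += h
        dn[i] -= h
        ll_up, _ = poisson_loglik(expected_sfs(model, up, data.n1, data.n2,
                                               segments=segments), data)
        ll_dn, _ = poisson_loglik(expected_sfs(model, dn, data.n1, data.n2,
                                               segments=segments), data)
        g[k] = (ll_up - ll_dn) / (2.0 * h)
    return g


def _hessian(model, params, idx, data, segments, eps):
    n = len(idx)
    H = np.zeros((n, n))
    f0, _ = poisson_loglik(expected_sfs(model, params, data.n1, data.n2,
                                        segments=segments), data)

    def f(shift):
        p = params.copy()
        for i, s in shift:
            p[i] += s
        ll, _ = poisson_loglik(expected_sfs(model, p, data.n1, data.n2,
                                            segments=segments), data)
        return ll

    hs = [eps * max(abs(params[i]), 1e-8) for i in idx]
    for a in range(n):
        ia, ha = idx[a], hs[a]
        H[a, a] = (f([(ia, ha)]) - 2 * f0 + f([(ia, -ha)])) / ha**2
        for b in range(a + 1, n):
            ib, hb = idx[b], hs[b]
            H[a, b] = H[b, a] = (
                f([(ia, ha), (ib, hb)]) - f([(ia, ha), (ib, -hb)])
                - f([(ia, -ha), (ib, hb)]) + f([(ia, -ha), (ib, -hb)])
            ) / (4 * ha * hb)
    return H


def godambe_adjusted_lrt(nested: FitResult, full: FitResult,
                         boot_spectra: list[Spectrum], data: Spectrum,
                         df: int | None = None, eps: float = 0.01) -> dict:
    """Likelihood-ratio test between nested composite-likelihood fits.

    ``nested`` must be a fit of the same model as ``full`` with some
    parameters frozen (its ``fixed`` dict names the constrained ones).  The
    raw statistic ``D = 2 (ll_full - ll_nested)`` does not follow chi-square
    under a composite likelihood; it is rescaled by the first-moment-matching
    factor ``df / tr(H^{-1} J)`` where, over the constrained directions at
    the null optimum, ``H`` is the observed information and ``J`` the score
    covariance across bootstrap spectra (sandwich/Godambe adjustment).
    The adjusted statistic is compared to chi-square with ``df`` degrees of
    freedom (default: the number of constrained parameters).
    """
    if nested.model != full.model:
        raise ValueError(
            "nested fit must be the same registry model as the full fit, "
            "with constrained parameters in `fixed`")
    if not nested.fixed:
        raise ValueError("nested fit has no constrained parameters")
    model = model_registry(full.model)
    idx = [model.param_names.index(n) for n in nested.fixed]
    if df is None:
        df = len(idx)
    D = 2.0 * (full.loglik - nested.loglik)
    if D < 0:
        return {"D": D, "D_adj": None, "p": None, "adjust": None,
                "flag": "negative D: optimization failure"}
    p0 = nested.params.copy()
    scores = np.array([_score(model, p0, idx, b, nested.segments, eps)
                       for b in boot_spectra])
    # centered covariance: the constrained-direction score has a nonzero
    # mean at the null optimum; only its variability estimates J
    centered = scores - scores.mean(axis=0)
    J = centered.T @ centered / (len(boot_spectra) - 1)
    # expected (Fisher) information: curvature evaluated with the data
    # replaced by the fitted expectation, smoother than the observed Hessian
    exp0 = expected_sfs(model, p0, data.n1, data.n2, segments=nested.segments)
    _, theta0 = poisson_loglik(exp0, data)
    fisher_data = Spectrum(theta0 * exp0.data, data.mask.copy(), data.pop_ids)
    H = -_hessian(model, p0, idx, fisher_data, nested.segments, eps)
    try:
        tr = float(np.trace(np.linalg.solve(H, J)))
    except np.linalg.LinAlgError:
        return {"D": D, "D_adj": None, "p": None, "adjust": None,
                "flag": "singular information matrix"}
    if tr <= 0:
        return {"D": D, "D_adj": None, "p": None, "adjust": None,
                "flag": "non-positive trace adjustment"}
    adjust = df / tr
    D_adj = adjust * D
    return {"D": D, "D_adj": D_adj, "p": float(chi2.sf(D_adj, df)),
            "adjust": adjust, "df": df, "flag": None}


# ---------------------------------------------------------------------------
# Bootstraps
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Per-parameter replicate estimates with mean +/- 1.96 SD intervals."""

    model: str
    param_names: tuple
    replicates: np.ndarray          # (B_ok, k) incl. theta as last column
    n_failed: int

    @property
    def mean(self) -> np.ndarray:
        return self.replicates.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.replicates.std(axis=0, ddof=1) if len(self.replicates) > 1 \
            else np.zeros(self.replicates.shape[1])

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        m, s = self.mean, self.sd
        return m - 1.96 * s, m + 1.96 * s

    def table(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame({
            "parameter": list(self.param_names) + ["theta"],
            "mean": self.mean, "sd": self.sd, "lci": lo, "hci": hi,
        })


def conventional_bootstrap(locus_spectra: list[Spectrum],
                           model: DemographicModel | str, B: int = 120,
                           seed: int = 0, start: np.ndarray | None = None,
                           n_starts: int = 2, segments: int = 24,
                           fixed: dict | None = None,
                           maxiter: int = 200) -> BootstrapSummary:
    """Bootstrap over loci: resample, rebuild the SFS, refit, summarize.

    ``locus_spectra`` are per-locus observed spectra (their cellwise sum is
    the full dataset).  ``B`` defaults to 120 resampled datasets.  Refits
    start from ``start`` (typically the full-data ML estimate) with a small
    number of perturbed starts.  Failed replicates are excluded and counted.
    """
    if isinstance(model, str):
        model = model_registry(model)
    rng = np.random.default_rng(seed)
    n_loci = len(locus_spectra)
    if n_loci == 0:
        raise ValueError("no loci to resample")
    stack = np.stack([s.data for s in locus_spectra])
    mask = locus_spectra[0].mask
    reps, failed = [], 0
    for b in range(B):
        pick = rng.integers(0, n_loci, size=n_loci)
        data = Spectrum(stack[pick].sum(axis=0), mask.copy(),
                        locus_spectra[0].pop_ids)
        try:
            fit = fit_model(model, data, n_starts=n_starts,
                            seed=int(rng.integers(2**31 - 1)), start=start,
                            fixed=fixed, segments=segments, maxiter=maxiter)
            reps.append(np.append(fit.params, fit.theta))
        except RuntimeError:
            failed += 1
    if not reps:
        raise RuntimeError("every bootstrap replicate failed")
    return BootstrapSummary(model=model.name, param_names=model.param_names,
                            replicates=np.array(reps), n_failed=failed)


def parametric_gof(fit: FitResult, data: Spectrum, B: int = 100, seed: int = 0,
                   simulator=None) -> dict:
    """Parametric-bootstrap goodness of fit of a fitted model.

    ``B`` datasets are generated under the fitted model (by default Poisson
    sampling of the fitted expectation; pass ``simulator(seed) -> Spectrum``
    to use e.g. full coalescent simulation) and scored, like the data, by
    composite log-likelihood and Pearson's chi-square
    ``sum (d - theta Phi)^2 / (theta Phi)`` over unmasked cells, with theta
    re-profiled per dataset.  Reports the observed statistics, the simulated
    distributions and empirical tail probabilities.
    """
    from .simulate import sample_sfs

    model = model_registry(fit.model)
    exp_spec = expected_sfs(model, fit.params, data.n1, data.n2,
                            segments=fit.segments)

    def scores(obs: Spectrum):
        ll, th = poisson_loglik(exp_spec, obs)
        m = ~(exp_spec.mask | obs.mask)
        lam = th * exp_spec.data[m]
        pos = lam > 0
        chi = float(np.sum((obs.data[m][pos] - lam[pos]) ** 2 / lam[pos]))
        return ll, chi

    obs_ll, obs_chi = scores(data)
    rng = np.random.default_rng(seed)
    sims = []
    for b in range(B):
        s = int(rng.integers(2**31 - 1))
        sim = simulator(s) if simulator is not None else \
            sample_sfs(exp_spec, fit.theta, s)
        sims.append(scores(sim))
    sim_ll = np.array([x[0] for x in sims])
    sim_chi = np.array([x[1] for x in sims])
    return {
        "observed_loglik": obs_ll,
        "observed_chi2": obs_chi,
        "sim_loglik": sim_ll,
        "sim_chi2": sim_chi,
        "p_loglik_lower": float(np.mean(sim_ll <= obs_ll)),
        "p_chi2_upper": float(np.mean(sim_chi >= obs_chi)),
    }
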