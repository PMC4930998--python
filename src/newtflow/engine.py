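"""Deterministic expected joint SFS under the divergence-model registry.

The engine evolves the *sample* site-frequency spectrum directly: the vector
of expected counts ``Phi[i, j]`` (derived-allele count ``i`` of ``n1`` in
population 1, ``j`` of ``n2`` in population 2) obeys a closed linear ODE
system under drift and mutation, obtained by integrating the two-population
Wright-Fisher diffusion against Bernstein sampling polynomials:

* genetic drift in each population is an exact tridiagonal operator in the
  corresponding index, scaled by ``1 / nu(t)``;
* an infinite-sites mutation source injects new singletons at constant rate
  ``n1/2`` into cell ``(1, 0)`` and ``n2/2`` into ``(0, 1)`` per unit theta;
* migration couples the populations; its exact expression involves the
  spectrum at sample size ``n + 1`` in the source population, which is closed
  with a quadratic-interpolation ("jackknife") estimate, the one approximation
  in the system.

Time is measured in units of ``2 N_A`` generations and spectra are computed
per unit ``theta = 4 N_A mu L``; at stationarity with ``nu = 1`` the
one-population spectrum is exactly ``theta / i``.  Epochs with constant
coefficients are integrated with a single matrix exponential (the constant
mutation source is handled by augmenting the system with one steady
coordinate); exponential-size epochs are cut into segments using the exact
per-segment average of ``1 / nu(t)`` (exponential-midpoint rule).

The ancestral population contributes standing variation: integration starts
from the ancestral equilibrium spectrum of the pooled sample, redistributed
hypergeometrically over the two descendant samples at the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaln

from .models import DemographicModel, Epoch, model_registry
from .sfs import Spectrum

__all__ = ["expected_sfs", "heterogeneous_sfs", "EngineError"]


class EngineError(RuntimeError):
    """Raised when the numerical integration produces an invalid spectrum."""


# ---------------------------------------------------------------------------
# Operator construction (cached per sample-size pair)
# ---------------------------------------------------------------------------

def _drift_1d(n: int) -> np.ndarray:
    """Tridiagonal drift operator at sample size ``n`` (to be scaled by 1/(2 nu)).

    Row ``i``: ``(i-1)(n-i+1) Phi[i-1] - 2 i (n-i) Phi[i] + (i+1)(n-i-1) Phi[i+1]``.
    Both absorbing ends (0 and n) receive no inflow coefficients, so fixation
    mass accumulates in the corners without feeding back.
    """
    D = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        if i - 1 >= 0:
            D[i, i - 1] = (i - 1) * (n - i + 1)
        D[i, i] = -2.0 * i * (n - i)
        if i + 1 <= n:
            D[i, i + 1] = (i + 1) * (n - i - 1)
    return D


def _moments_quadratic(n: int, i: int) -> np.ndarray:
    """First three moments of the Bernstein sampling kernel ``b_{n,i}``."""
    return np.array(
        [
            1.0 / (n + 1),
            (i + 1.0) / ((n + 1) * (n + 2)),
            (i + 1.0) * (i + 2.0) / ((n + 1) * (n + 2) * (n + 3)),
        ]
    )


def _quadratic_jackknife(n: int) -> np.ndarray:
    """Estimate the size ``n+1`` spectrum from size ``n`` (quadratic closure).

    For each target entry the underlying allele-frequency density is treated
    as locally quadratic; three neighbouring entries of the size-``n``
    spectrum are combined with weights chosen to reproduce the first three
    moments of the target sampling kernel exactly.
    """
    J = np.zeros((n + 2, n + 1))
    for ip in range(n + 2):
        center = int(round(ip * n / (n + 1.0)))
        center = min(max(center, 1), n - 1)
        idx = [center - 1, center, center + 1]
        A = np.column_stack([_moments_quadratic(n, i) for i in idx])
        b = _moments_quadratic(n + 1, ip)
        J[ip, idx] = np.linalg.solve(A, b)
    return J


def _jackknife_1d(n: int) -> np.ndarray:
    """Atom-aware, projection-consistent closure raising sample size by one.

    The allele-frequency measure behind a spectrum is a smooth interior
    density plus point masses ("atoms") at frequencies 0 and 1 (classes lost
    or fixed in that population).  Atoms contribute only to the extreme
    entries of a spectrum, so:

    * interior raised entries are estimated by quadratic interpolation fitted
      exclusively through interior source entries (never 0 or ``n``, which
      are atom-contaminated);
    * the extreme raised entries carry the source extreme entry (the atom)
      plus a quadratic correction for the change in the sampling kernel.

    Finally the estimate is corrected to satisfy subsampling consistency --
    hypergeometric projection of the size ``n+1`` spectrum must reproduce the
    size ``n`` spectrum -- which holds exactly for any underlying measure and
    removes the component of closure error visible to the projection.
    """
    from .sfs import _projection_matrix

    if n < 4:
        # too few interior entries for atom-aware fitting; fall back to the
        # plain quadratic estimate plus the projection-consistency correction
        J = _quadratic_jackknife(n)
        P = _projection_matrix(n + 1, n)
        J -= np.linalg.pinv(P) @ (P @ J - np.eye(n + 1))
        return J
    J = np.zeros((n + 2, n + 1))
    # interior targets: quadratic fit through interior windows
    for ip in range(1, n + 1):
        center = int(round(ip * n / (n + 1.0)))
        center = min(max(center, 2), n - 2)
        idx = [center - 1, center, center + 1]
        A = np.column_stack([_moments_quadratic(n, i) for i in idx])
        b = _moments_quadratic(n + 1, ip)
        J[ip, idx] = np.linalg.solve(A, b)
    # extreme targets: atom plus kernel-change correction
    for ip, src, idx in ((0, 0, [1, 2, 3]), (n + 1, n, [n - 3, n - 2, n - 1])):
        A = np.column_stack([_moments_quadratic(n, i) for i in idx])
        b = _moments_quadratic(n + 1, ip) - _moments_quadratic(n, src)
        J[ip, src] = 1.0
        J[ip, idx] += np.linalg.solve(A, b)
    # exact projection-consistency correction
    P = _projection_matrix(n + 1, n)  # (n+1, n+2)
    J -= np.linalg.pinv(P) @ (P @ J - np.eye(n + 1))
    return J


def _flat(i: int, j: int, n2: int) -> int:
    return i * (n2 + 1) + j


@dataclass(frozen=True)
class _Operators:
    """Precomputed dense operators for one sample-size pair."""

    n1: int
    n2: int
    drift1: np.ndarray  # scale by 1/(2 nu1)
    drift2: np.ndarray  # scale by 1/(2 nu2)
    mig1: np.ndarray    # scale by M12 (into pop 1 from pop 2)
    mig2: np.ndarray    # scale by M21
    source: np.ndarray  # constant, per unit theta


def _migration_operator(n_a: int, n_b: int, transpose: bool) -> np.ndarray:
    """Operator for migration into population A from population B.

    Derived from the advection term ``-d/dx_a [ M (x_b - x_a) phi ]`` of the
    two-population diffusion.  ``x_b`` raises the population-B sampling degree
    by one; that size-``(n_b + 1)`` spectrum is closed with the jackknife.
    With ``transpose=False`` population A indexes rows (axis 0) of the
    spectrum; with ``transpose=True`` roles are swapped.
    """
    NA, NB = n_a + 1, n_b + 1
    jack = _jackknife_1d(n_b)  # (n_b+2, n_b+1)

    def cell(i, j):
        # flat index in the (A-axis, B-axis) layout used locally
        return i * NB + j

    size = NA * NB
    # local operator in (A, B) layout
    raised = np.zeros((NA * (NB + 1), size))  # spectrum with B raised to n_b+1
    for i in range(NA):
        raised[i * (NB + 1): (i + 1) * (NB + 1), i * NB: (i + 1) * NB] = jack
    op_raised = np.zeros((size, NA * (NB + 1)))
    op_local = np.zeros((size, size))
    for i in range(NA):
        for j in range(NB):
            r = cell(i, j)
            # x_b * b_{n_b, j}(x_b) = ((j+1)/(n_b+1)) b_{n_b+1, j+1}(x_b)
            w = (j + 1.0) / (n_b + 1.0)
            jp = j + 1  # index in raised spectrum
            # d(b_{n_a, i})/dx_a expansion coefficients at degree n_a
            for k, c in ((i - 1, n_a - i + 1.0), (i, 2.0 * i - n_a), (i + 1, -(i + 1.0))):
                if 0 <= k <= n_a:
                    op_raised[r, k * (NB + 1) + jp] += w * c
            # minus x_a * d(b_{n_a, i})/dx_a  ->  local terms
            op_local[r, cell(i, j)] -= i
            if i + 1 <= n_a:
                op_local[r, cell(i + 1, j)] += i + 1.0
    op = op_raised @ raised + op_local
    if transpose:
        # convert from the local (A, B) layout to the canonical (pop1, pop2)
        # layout in which A is axis 1: canonical flat index j*NA + i
        P = np.zeros((size, size))
        for i in range(NA):
            for j in range(NB):
                P[cell(i, j), j * NA + i] = 1.0
        op = P.T @ op @ P
    return op


@lru_cache(maxsize=32)
def _operators(n1: int, n2: int) -> _Operators:
    N1, N2 = n1 + 1, n2 + 1
    drift1 = np.kron(_drift_1d(n1), np.eye(N2))
    drift2 = np.kron(np.eye(N1), _drift_1d(n2))
    mig1 = _migration_operator(n1, n2, transpose=False)
    mig2 = _migration_operator(n2, n1, transpose=True)
    source = np.zeros(N1 * N2)
    source[_flat(1, 0, n2)] = n1 / 2.0
    source[_flat(0, 1, n2)] = n2 / 2.0
    return _Operators(n1, n2, drift1, drift2, mig1, mig2, source)


# ---------------------------------------------------------------------------
# Initial condition: ancestral equilibrium + instantaneous split
# ---------------------------------------------------------------------------

def _equilibrium_1d(n: int) -> np.ndarray:
    phi = np.zeros(n + 1)
    phi[1:n] = 1.0 / np.arange(1, n)
    return phi


def _lnchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _split(phi_pool: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Redistribute a pooled sample spectrum over two descendant samples.

    At an instantaneous split both samples draw from the same ancestral pool,
    so ``Phi(i, j) = phi_pool[i + j] * C(n1,i) C(n2,j) / C(n1+n2, i+j)``.
    """
    out = np.zeros((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            k = i + j
            w = np.exp(_lnchoose(n1, i) + _lnchoose(n2, j) - _lnchoose(n1 + n2, k))
            out[i, j] = phi_pool[k] * w
    return out


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def _step_expm(A: np.ndarray, source: np.ndarray, phi: np.ndarray, dt: float) -> np.ndarray:
    """Advance ``dPhi/dt = A Phi + source`` exactly over ``dt``.

    The inhomogeneous system is embedded in a homogeneous one by appending a
    constant coordinate, so one matrix exponential does the whole step.
    """
    n = A.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A * dt
    aug[:n, n] = source * dt
    state = np.append(phi, 1.0)
    return (expm(aug) @ state)[:n]


def _mean_inv_nu(nu_start: float, nu_end: float, t0: float, t1: float, T: float) -> float:
    """Exact average of ``1/nu(t)`` over ``[t0, t1]`` for exponential change.

    ``nu(t) = nu_start * exp(r t)`` with ``r = ln(nu_end / nu_start) / T``.
    """
    r = np.log(nu_end / nu_start) / T
    if abs(r) < 1e-12:
        return 1.0 / nu_start
    return (np.exp(-r * t0) - np.exp(-r * t1)) / (r * (t1 - t0) * nu_start)


def _integrate_epoch(ops: _Operators, epoch: Epoch, phi: np.ndarray,
                     segments: int) -> np.ndarray:
    M12, M21 = epoch.mig
    mig = M12 * ops.mig1 + M21 * ops.mig2
    if not epoch.has_growth:
        A = ops.drift1 / (2.0 * epoch.start[0]) + ops.drift2 / (2.0 * epoch.start[1]) + mig
        return _step_expm(A, ops.source, phi, epoch.duration)
    T = epoch.duration
    bounds = np.linspace(0.0, T, segments + 1)
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        c1 = _mean_inv_nu(epoch.start[0], epoch.end[0], t0, t1, T)
        c2 = _mean_inv_nu(epoch.start[1], epoch.end[1], t0, t1, T)
        A = 0.5 * c1 * ops.drift1 + 0.5 * c2 * ops.drift2 + mig
        phi = _step_expm(A, ops.source, phi, t1 - t0)
    return phi


def _class_sfs(model: DemographicModel, params, n1: int, n2: int,
               rate_class: int, segments: int) -> np.ndarray:
    ops = _operators(n1, n2)
    phi = _split(_equilibrium_1d(n1 + n2), n1, n2).ravel()
    for epoch in model.epochs(params, rate_class):
        if epoch.duration < 0:
            raise ValueError("negative epoch duration")
        if epoch.duration > 0:
            phi = _integrate_epoch(ops, epoch, phi, segments)
    return phi.reshape(n1 + 1, n2 + 1)


def _validate(data: np.ndarray, model_name: str) -> np.ndarray:
    if not np.all(np.isfinite(data)):
        raise EngineError(
            f"non-finite entries in expected SFS for {model_name}: "
            f"{np.argwhere(~np.isfinite(data))[:5]}"
        )
    floor = -1e-6 * max(data.max(), 1.0)
    if data.min() < floor:
        raise EngineError(
            f"strongly negative entries in expected SFS for {model_name} "
            f"(min {data.min():.3g}); integration failed"
        )
    return np.clip(data, 0.0, None)


def expected_sfs(model: DemographicModel | str, params: Sequence[float],
                 n1: int, n2: int, segments: int = 24) -> Spectrum:
    """Expected unfolded joint SFS per unit theta at sample sizes ``(n1, n2)``.

    For heterogeneous (``*HET``) models the result is automatically the
    ``P : (1 - P)`` mixture of the two migration-class spectra.  ``segments``
    controls the time resolution inside exponential-growth epochs (constant
    epochs are integrated exactly); the value used is recorded on the result.
    """
    if isinstance(model, str):
        model = model_registry(model)
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be at least 2")
    if model.het:
        P = model.mixture_weight(params)
        data = (P * _class_sfs(model, params, n1, n2, 0, segments)
                + (1.0 - P) * _class_sfs(model, params, n1, n2, 1, segments))
    else:
        data = _class_sfs(model, params, n1, n2, 0, segments)
    spec = Spectrum(_validate(data, model.name))
    spec.segments = segments
    return spec


def heterogeneous_sfs(model: DemographicModel | str, params_shared: Sequence[float],
                      rates_class1: tuple[float, float],
                      rates_class2: tuple[float, float], P: float,
                      n1: int, n2: int, segments: int = 24) -> Spectrum:
    """Two-class mixture spectrum ``P * Phi(rates1) + (1 - P) * Phi(rates2)``.

    ``model`` is the heterogeneous registry member; ``params_shared`` are its
    parameters *without* the four migration rates and ``P`` (i.e. the shared
    demography), which are supplied separately.
    """
    if isinstance(model, str):
        model = model_registry(model)
    if not model.het:
        raise ValueError(f"{model.name} is not a heterogeneous model")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    full = list(params_shared) + [*rates_class1, *rates_class2, P]
    return expected_sfs(model, full, n1, n2, segments=segments)
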