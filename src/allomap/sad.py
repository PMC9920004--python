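"""First-order structured antedependence (SAD(1)) residual covariance.

Residuals along one density's week grid follow
``e(t_k) = phi^(t_k - t_{k-1}) e(t_{k-1}) + eps_k`` with independent
innovations ``eps_k ~ N(0, sigma2)``.  Stacking both densities gives the
joint covariance ``Sigma = Lambda Sigma_eps Lambda'`` where ``Lambda`` is
unit lower triangular with powers of phi below the diagonal and
``Sigma_eps`` is the innovation covariance.  Because ``Lambda`` is unit
triangular, ``det Sigma = det Sigma_eps`` regardless of phi, and the
assembly is positive definite for every real phi.

The two densities share sigma2 but have their own propagation coefficients
(phi_high, phi_low).  With the default ``rho = 0`` the innovation covariance
is diagonal and the two density blocks of Sigma are independent; ``rho``
optionally correlates innovations of the two densities at shared weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla


@dataclass
class SadParams:
    """Parameters of the two-density SAD(1) model.

    phi_high / phi_low: innovation-propagation coefficients (dimensionless,
    any real value — positive definiteness never constrains them).
    sigma2: innovation variance, in squared response-trait units.
    rho: innovation cross-correlation between densities at shared weeks.
    """

    phi_high: float
    phi_low: float
    sigma2: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        # sigma2 == 0 is allowed only as the noiseless simulation limit;
        # the covariance is then singular and has no density.
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")


def build_chain(times: np.ndarray, phi: float) -> np.ndarray:
    """Unit lower-triangular propagation matrix for one SAD(1) chain.

    Entry (k, l) below the diagonal is ``phi ** (t_k - t_l)``; the diagonal
    is 1 and the strict upper triangle 0.  Week differences need not be 1,
    but a negative phi requires integer differences for the power to be
    real.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    T = len(times)
    diff = times[:, None] - times[None, :]
    with np.errstate(invalid="ignore"):
        lam = np.where(diff > 0, np.power(float(phi), np.maximum(diff, 0.0)), 0.0)
    if np.any(~np.isfinite(lam)):
        raise ValueError("phi ** (t_k - t_l) is not real; negative phi needs integer week spacing")
    lam[np.arange(T), np.arange(T)] = 1.0
    return lam


@dataclass
class CovarianceAssembly:
    """Joint two-density covariance with its Cholesky factor cached."""

    times_high: np.ndarray
    times_low: np.ndarray
    lambda_matrix: np.ndarray
    sigma_eps: np.ndarray
    sigma: np.ndarray
    _chol: np.ndarray = field(repr=False, default=None)

    @property
    def dim(self) -> int:
        return self.sigma.shape[0]

    @property
    def t_high(self) -> int:
        return len(self.times_high)

    @property
    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.sigma)
        return self._chol

    def blocks(self) -> dict[str, np.ndarray]:
        th = self.t_high
        return {
            "hh": self.sigma[:th, :th],
            "hl": self.sigma[:th, th:],
            "lh": self.sigma[th:, :th],
            "ll": self.sigma[th:, th:],
        }


def assemble_joint_covariance(
    times_high: np.ndarray, times_low: np.ndarray, sad: SadParams
) -> CovarianceAssembly:
    """Assemble Sigma = Lambda Sigma_eps Lambda' over the stacked grids.

    The stacked order is (high weeks; low weeks).  Lambda is block diagonal
    with one chain per density; Sigma_eps is sigma2 * I plus, when rho != 0,
    cross-density entries rho * sigma2 at week values present in both grids.
    """
    times_high = np.asarray(times_high, dtype=float)
    times_low = np.asarray(times_low, dtype=float)
    lam_h = build_chain(times_high, sad.phi_high)
    lam_l = build_chain(times_low, sad.phi_low)
    lam = sla.block_diag(lam_h, lam_l)
    th, tl = len(times_high), len(times_low)
    eps = sad.sigma2 * np.eye(th + tl)
    if sad.rho != 0.0:
        for i, t in enumerate(times_high):
            j = np.nonzero(np.isclose(times_low, t))[0]
            if j.size:
                eps[i, th + j[0]] = eps[th + j[0], i] = sad.rho * sad.sigma2
    sigma = lam @ eps @ lam.T
    sigma = 0.5 * (sigma + sigma.T)
    return CovarianceAssembly(
        times_high=times_high,
        times_low=times_low,
        lambda_matrix=lam,
        sigma_eps=eps,
        sigma=sigma,
    )


def log_density(
    residual: np.ndarray,
    assembly: CovarianceAssembly,
    observed: np.ndarray | None = None,
) -> float:
    """Log multivariate-normal density of a stacked residual vector.

    ``observed`` is an optional boolean mask of length T_h + T_l selecting
    the weeks actually measured for this progeny; the covariance is reduced
    by row/column deletion, i.e. the exact marginal of the joint normal.
    """
    residual = np.asarray(residual, dtype=float)
    if observed is None:
        if residual.shape[0] != assembly.dim:
            raise ValueError(
                f"residual length {residual.shape[0]} != covariance dim {assembly.dim}"
            )
        chol = assembly.cholesky
    else:
        observed = np.asarray(observed, dtype=bool)
        if observed.shape[0] != assembly.dim:
            raise ValueError("observed mask length must equal covariance dim")
        if residual.shape[0] != int(observed.sum()):
            raise ValueError("residual length must match number of observed weeks")
        chol = np.linalg.cholesky(assembly.sigma[np.ix_(observed, observed)])
    z = sla.solve_triangular(chol, residual, lower=True)
    d = residual.shape[0]
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (d * np.log(2.0 * np.pi) + logdet + z @ z))


def sad_covariance_closed_form(times: np.ndarray, phi: float, sigma2: float) -> np.ndarray:
    """Closed-form single-chain covariance, cov(s, t) summed over shared ancestry.

    cov(t_s, t_t) = sigma2 * sum_{k <= min(s,t)} phi^((t_s - t_k) + (t_t - t_k)).
    Kept as an independent cross-check of the Lambda-based assembly.
    """
    times = np.asarray(times, dtype=float)
    T = len(times)
    cov = np.zeros((T, T))
    for s in range(T):
        for t in range(T):
            acc = 0.0
            for k in range(min(s, t) + 1):
                acc += phi ** ((times[s] - times[k]) + (times[t] - times[k]))
            cov[s, t] = sigma2 * acc
    return cov
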