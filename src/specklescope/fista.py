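"""FISTA solver for the single-image 3D inverse problem.

Recovers a sparse 3D object from one 2D scan image by minimizing

    F(x) = ||A x - b||^2 + lambda ||x||_1,

where A is the per-plane correlation operator built from the 3D speckle
response (shared, bit-identical with the forward imaging model).  The
objective carries no 1/2 factor, so the gradient is 2 A^T (A x - b) and the
Lipschitz constant of the gradient is L = 2 sigma_max(A)^2.  Because the
operator is diagonal per spatial frequency under the periodic model,
sigma_max is available in closed form,

    L = 2 max_k sum_z |Fhat_z(k)|^2,

which the ``auto`` step uses directly; a power-iteration estimator is also
provided.  The iteration is the Beck-Teboulle scheme with a monotone
safeguard: whenever the objective increases, the momentum is restarted,
which makes the non-increasing-objective invariant testable without
changing the fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._operators import correlate_adjoint, correlate_forward, response_spectrum
from .forward import ScanImage

__all__ = [
    "FistaParams",
    "FistaResult",
    "forward_A",
    "adjoint_At",
    "soft_threshold",
    "lipschitz_estimate",
    "lipschitz_spectral",
    "fista",
    "select_lambda",
]


@dataclass(frozen=True)
class FistaParams:
    """Solver parameters.

    ``lambda_reg`` is the l1 weight; ``step`` is either the literal string
    ``"auto"`` (1/L from the closed-form Lipschitz constant) or a numeric
    gradient step, which must satisfy step <= 1/L unless
    ``allow_large_step`` is set (the flag exists to reproduce externally
    fixed step regimes).  ``nonnegativity`` switches the proximal map to
    max(v - theta, 0); it is off by default since the objective has no such
    constraint, but fluorophore density is physically nonnegative.
    ``seed`` only feeds the randomized power iteration.
    """

    lambda_reg: float = 0.0
    step: float | str = "auto"
    n_iter: int = 200
    nonnegativity: bool = False
    seed: int = 0
    allow_large_step: bool = False
    convergence_rtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if isinstance(self.step, str):
            if self.step != "auto":
                raise ValueError("step must be a positive number or 'auto'")
        elif not (self.step > 0):
            raise ValueError("step must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be a positive integer")


@dataclass
class FistaResult:
    """Estimate plus diagnostics of one FISTA run."""

    estimate: np.ndarray
    objective_trace: np.ndarray
    residual_norm: float
    n_nonzero: int
    converged: bool
    step: float = 0.0
    lipschitz: float = 0.0


def forward_A(x: np.ndarray, response: np.ndarray) -> np.ndarray:
    """A x: identical (shared code) to the forward scan-image model."""
    x = x.density if hasattr(x, "density") else np.asarray(x, dtype=float)
    return correlate_forward(x, response_spectrum(response))


def adjoint_At(r: np.ndarray, response: np.ndarray) -> np.ndarray:
    """A^T r: per-plane convolution of a 2D image with the response stack."""
    return correlate_adjoint(np.asarray(r, dtype=float), response_spectrum(response))


def soft_threshold(v: np.ndarray, theta: float, nonnegativity: bool = False) -> np.ndarray:
    """Proximal map of theta ||.||_1: sign(v) max(|v| - theta, 0).

    With ``nonnegativity`` the map is max(v - theta, 0), the proximal
    operator of the l1 norm restricted to the nonnegative orthant.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    v = np.asarray(v, dtype=float)
    if nonnegativity:
        return np.maximum(v - theta, 0.0)
    return np.sign(v) * np.maximum(np.abs(v) - theta, 0.0)


def lipschitz_spectral(response: np.ndarray) -> float:
    """Closed-form gradient Lipschitz constant L = 2 max_k sum_z |Fhat_z(k)|^2."""
    spec = response_spectrum(response)
    return float(2.0 * np.max((np.abs(spec) ** 2).sum(axis=0)))


def lipschitz_estimate(response: np.ndarray, n_power_iter: int = 50, seed: int = 0) -> float:
    """Power-iteration estimate of L = 2 sigma_max(A)^2 on A^T A.

    Exact in the limit of many iterations; the spectral closed form
    (:func:`lipschitz_spectral`) is the analytic reference for the
    circular-correlation operator.
    """
    if n_power_iter < 5:
        raise ValueError("n_power_iter must be at least 5")
    spec = response_spectrum(response)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(spec.shape)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_power_iter):
        w = correlate_adjoint(correlate_forward(v, spec), spec)
        lam = float(np.vdot(v, w).real)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        v = w / nrm
    return 2.0 * lam


def fista(b, response: np.ndarray, params: FistaParams) -> FistaResult:
    """Beck-Teboulle iteration with momentum restart on objective increase.

    Starts from x0 = 0 with momentum alpha_1 = 1.  Per iteration: gradient
    step on the smooth term, soft threshold with theta = step * lambda_reg,
    momentum update alpha_{k+1} = (1 + sqrt(1 + 4 alpha_k^2))/2 and
    extrapolation y_{k+1} = x_{k+1} + ((alpha_k - 1)/alpha_{k+1})(x_{k+1} - x_k).
    One forward and one adjoint application per iteration (A y is obtained
    from A x by linearity).
    """
    b = b.values if isinstance(b, ScanImage) else np.asarray(b, dtype=float)
    response = np.asarray(response, dtype=float)
    spec = response_spectrum(response)
    if b.shape != response.shape[1:]:
        raise ValueError("image and response grids do not match")

    lip = lipschitz_spectral(response)
    if params.step == "auto":
        if not (lip > 0):
            raise ValueError("auto step requires a successful Lipschitz estimate")
        step = 1.0 / lip
    else:
        step = float(params.step)
        if lip > 0 and step > 1.0 / lip * (1 + 1e-12) and not params.allow_large_step:
            raise ValueError(
                f"step {step:g} exceeds 1/L = {1.0 / lip:g}; convergence requires "
                "step <= 1/L (set allow_large_step=True to override)"
            )

    x = np.zeros_like(response)
    y = x
    ax = np.zeros_like(b)
    ay = ax
    alpha = 1.0
    trace = np.empty(params.n_iter)
    obj_prev = np.inf
    n_rejected = 0
    for it in range(params.n_iter):
        grad = 2.0 * correlate_adjoint(ay - b, spec)
        x_new = soft_threshold(y - step * grad, step * params.lambda_reg,
                               params.nonnegativity)
        ax_new = correlate_forward(x_new, spec)
        resid = ax_new - b
        obj = float((resid**2).sum() + params.lambda_reg * np.abs(x_new).sum())
        if not np.isfinite(obj):
            raise RuntimeError(
                "FISTA diverged (objective is not finite); the step-size "
                "precondition step <= 1/L was likely violated"
            )
        alpha_new = (1.0 + np.sqrt(1.0 + 4.0 * alpha**2)) / 2.0
        if obj > obj_prev:
            # monotone safeguard: reject the increasing step, restart momentum;
            # the next iteration is a plain (non-increasing) proximal step
            # float jitter near convergence is rejected too, but only a
            # significant increase counts toward divergence detection
            if obj > obj_prev * (1.0 + 1e-9):
                n_rejected += 1
            if n_rejected >= 3:
                # a proximal step from y = x with step <= 1/L cannot increase
                # the objective, so repeated rejection proves divergence
                raise RuntimeError(
                    "FISTA diverged (objective increases even after momentum "
                    "restart); the step-size precondition step <= 1/L is violated"
                )
            obj = obj_prev
            alpha = 1.0
            y, ay = x, ax
        else:
            n_rejected = 0
            beta = (alpha - 1.0) / alpha_new
            y = x_new + beta * (x_new - x)
            ay = ax_new + beta * (ax_new - ax)
            alpha = alpha_new
            x, ax = x_new, ax_new
        trace[it] = obj
        obj_prev = obj

    rel_change = (abs(trace[-2] - trace[-1]) / max(abs(trace[-1]), 1e-300)
                  if params.n_iter > 1 else np.inf)
    return FistaResult(
        estimate=x,
        objective_trace=trace,
        residual_norm=float(np.linalg.norm(ax - b)),
        n_nonzero=int(np.count_nonzero(x)),
        converged=bool(rel_change < params.convergence_rtol),
        step=step,
        lipschitz=lip,
    )


def select_lambda(b, response: np.ndarray, truth: np.ndarray, lambdas,
                  params: FistaParams) -> dict:
    """Grid search of lambda_reg minimizing RMSE against a known ground truth.

    An a-posteriori helper for simulation studies only; user-facing
    reconstruction never sees the truth.
    """
    truth = truth.density if hasattr(truth, "density") else np.asarray(truth, dtype=float)
    best = None
    rmses = []
    for lam in lambdas:
        p = FistaParams(lambda_reg=float(lam), step=params.step, n_iter=params.n_iter,
                        nonnegativity=params.nonnegativity, seed=params.seed,
                        allow_large_step=params.allow_large_step)
        res = fista(b, response, p)
        rmse = float(np.sqrt(np.mean((res.estimate - truth) ** 2)))
        rmses.append(rmse)
        if best is None or rmse < best[1]:
            best = (float(lam), rmse, res)
    return {"lambda_reg": best[0], "rmse": best[1], "result": best[2],
            "grid": list(map(float, lambdas)), "rmses": rmses}
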