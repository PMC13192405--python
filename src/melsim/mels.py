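"""Mixed-effects location-scale (MELS) model with correlated random effects.

Model.  For subject i with observed outcomes y_ij:

    y_ij = beta0 + v_i + eps_ij,          eps_ij ~ N(0, sigma2_i)
    sigma2_i = exp(tau0 + omega_i)

with a random location effect v_i (deviation from the grand mean) and a
random scale effect omega_i (deviation of the log within-subject variance
from its grand intercept tau0).  The pair (v_i, omega_i) is bivariate
normal with SDs (sigma_v, sigma_w) and correlation rho_vw.

Estimation is marginal maximum likelihood.  Internally the random effects
are written through the Cholesky map

    v_i     = s11 * theta1_i
    omega_i = s21 * theta1_i + s22 * theta2_i,     theta_i ~ N(0, I2),

so every optimizer iterate yields a valid covariance, and the standardized
effects theta are the z-score-like quantities whose posterior means are the
empirical Bayes (EB) estimates reported per subject.  The per-subject
two-dimensional integral is evaluated by adaptive Gauss-Hermite quadrature
re-centered at each subject's posterior mode and scaled by the local
curvature; because the within-subject model is Gaussian with a constant
variance per subject, each subject enters the likelihood only through
(n_i, mean_i, SS_i), which keeps the whole computation vectorized across
subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .dataset import EmaDataset

__all__ = [
    "MelsParams",
    "MelsSettings",
    "MelsFit",
    "marginal_loglik",
    "fit_mels",
    "eb_estimates",
    "plausible_values",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MelsParams:
    """Population parameters of the location-scale model."""

    beta0: float
    tau0: float
    sigma_v: float
    sigma_w: float
    rho_vw: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_v <= 0 or self.sigma_w <= 0:
            raise ValueError("sigma_v and sigma_w must be > 0")
        if not -1.0 < self.rho_vw < 1.0:
            raise ValueError("rho_vw must lie in (-1, 1)")

    def cholesky(self) -> tuple[float, float, float]:
        """(s11, s21, s22) of the random-effect covariance."""
        s11 = self.sigma_v
        s21 = self.rho_vw * self.sigma_w
        s22 = self.sigma_w * math.sqrt(1.0 - self.rho_vw**2)
        return s11, s21, s22

    @classmethod
    def from_cholesky(cls, beta0, tau0, s11, s21, s22) -> "MelsParams":
        sigma_w = math.hypot(s21, s22)
        rho = s21 / sigma_w if sigma_w > 0 else 0.0
        return cls(beta0, tau0, s11, sigma_w, min(max(rho, -0.999999), 0.999999))


@dataclass(frozen=True)
class MelsSettings:
    """Optimizer and quadrature settings for :func:`fit_mels`.

    n_quad
        Adaptive Gauss-Hermite points per dimension for the reported
        log-likelihood and the EB estimates.
    n_quad_fit
        Points per dimension during optimization (defaults to ``n_quad``;
        Monte-Carlo drivers lower this to 5 for speed — with posterior-mode
        re-centering the quadrature is already accurate at 5 points).
    gtol / ftol / max_iter
        L-BFGS-B stopping rules on the mean per-subject negative
        log-likelihood.
    s_min
        Lower bound for the Cholesky diagonals during optimization; an
        estimate stuck at this bound marks the fit as boundary (counted as
        non-converged).
    """

    n_quad: int = 15
    n_quad_fit: int | None = None
    gtol: float = 1e-5
    ftol: float = 1e-12
    max_iter: int = 500
    s_min: float = 1e-4
    n_restarts: int = 2
    compute_se: bool = True


@dataclass
class MelsFit:
    """Result of :func:`fit_mels`."""

    params: MelsParams | None
    loglik: float
    converged: bool
    convergence_detail: dict
    n_quad: int
    eb: pd.DataFrame | None = None
    se: dict | None = None

    @property
    def boundary(self) -> bool:
        return bool(self.convergence_detail.get("boundary", False))


# ----------------------------------------------------------------------
# likelihood internals (vectorized over subjects on sufficient statistics)
# ----------------------------------------------------------------------


def _suff_arrays(data: EmaDataset):
    stats = data.suff_stats()
    return (
        stats.index.to_numpy(),
        stats["n"].to_numpy(),
        stats["ybar"].to_numpy(),
        stats["ss"].to_numpy(),
    )


def _log_joint(th1, th2, n, ybar, ss, beta0, tau0, s11, s21, s22):
    """log p(y_i | theta) + log p(theta) for arrays broadcast over nodes."""
    with np.errstate(over="ignore", invalid="ignore"):
        lv = tau0 + s21 * th1 + s22 * th2
        r = ybar - beta0 - s11 * th1
        quad = ss + n * r * r
        einv = np.exp(np.clip(-lv, None, 80.0))
        return (
            -0.5 * n * (_LOG2PI + lv)
            - 0.5 * quad * einv
            - 0.5 * (th1 * th1 + th2 * th2)
            - _LOG2PI
        )


def _posterior_mode(n, ybar, ss, beta0, tau0, s11, s21, s22, th_init=None, tol=1e-10, max_iter=60):
    """Damped Newton for the per-subject posterior mode of theta (vectorized)."""
    S = len(n)
    if th_init is None:
        th1 = np.zeros(S)
        th2 = np.zeros(S)
    else:
        th1 = th_init[0].copy()
        th2 = th_init[1].copy()
    h = _log_joint(th1, th2, n, ybar, ss, beta0, tau0, s11, s21, s22)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for _ in range(max_iter):
            lv = tau0 + s21 * th1 + s22 * th2
            r = ybar - beta0 - s11 * th1
            quad = ss + n * r * r
            einv = np.exp(np.clip(-lv, None, 80.0))
            nr = n * r * einv
            g1 = nr * s11 + 0.5 * quad * einv * s21 - 0.5 * n * s21 - th1
            g2 = 0.5 * quad * einv * s22 - 0.5 * n * s22 - th2
            if max(np.abs(g1).max(), np.abs(g2).max()) < tol:
                break
            H11 = (
                -n * s11 * s11 * einv
                - 2.0 * nr * s11 * s21
                - 0.5 * quad * einv * s21 * s21
                - 1.0
            )
            H12 = -nr * s11 * s22 - 0.5 * quad * einv * s21 * s22
            H22 = -0.5 * quad * einv * s22 * s22 - 1.0
            # Gershgorin safeguard: force negative definiteness before solving
            bound = np.maximum(H11 + np.abs(H12), H22 + np.abs(H12))
            ridge = np.where(np.isfinite(bound) & (bound > -1e-8), bound + 0.1, 0.0)
            H11 = H11 - ridge
            H22 = H22 - ridge
            det = H11 * H22 - H12 * H12
            d1 = -(H22 * g1 - H12 * g2) / det
            d2 = -(H11 * g2 - H12 * g1) / det
            # non-finite Newton directions (extreme line-search excursions of
            # the outer optimizer) fall back to a zero step for that subject
            ok = np.isfinite(d1) & np.isfinite(d2)
            d1 = np.where(ok, d1, 0.0)
            d2 = np.where(ok, d2, 0.0)
            step = np.ones(S)
            for _half in range(25):
                t1 = th1 + step * d1
                t2 = th2 + step * d2
                h_new = _log_joint(t1, t2, n, ybar, ss, beta0, tau0, s11, s21, s22)
                worse = h_new < h - 1e-12
                if not worse.any():
                    break
                step = np.where(worse, 0.5 * step, step)
            th1, th2, h = t1, t2, h_new
    return th1, th2


def _aghq(n, ybar, ss, beta0, tau0, s11, s21, s22, n_quad, th_init=None, return_grid=False):
    """Per-subject adaptive Gauss-Hermite marginal log-likelihoods."""
    m1, m2 = _posterior_mode(n, ybar, ss, beta0, tau0, s11, s21, s22, th_init=th_init)
    # curvature at the mode
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        lv = tau0 + s21 * m1 + s22 * m2
        r = ybar - beta0 - s11 * m1
        quad = ss + n * r * r
        einv = np.exp(np.clip(-lv, None, 80.0))
        nr = n * r * einv
        A11 = n * s11 * s11 * einv + 2.0 * nr * s11 * s21 + 0.5 * quad * einv * s21 * s21 + 1.0
        A12 = nr * s11 * s22 + 0.5 * quad * einv * s21 * s22
        A22 = 0.5 * quad * einv * s22 * s22 + 1.0
        # A = -Hessian; guard indefiniteness away from well-behaved optima
        det_a = A11 * A22 - A12 * A12
    bad = (det_a <= 0) | (A11 <= 0) | ~np.isfinite(det_a)
    if bad.any():
        A11 = np.where(np.isfinite(A11), A11, 1.0)
        A22 = np.where(np.isfinite(A22), A22, 1.0)
        A12 = np.where(np.isfinite(A12), A12, 0.0)
        fix = np.where(bad, np.abs(A12) + 1.0, 0.0)
        A11 = A11 + fix
        A22 = A22 + fix
        det_a = A11 * A22 - A12 * A12
    # closed-form Cholesky of A^{-1}
    i11 = A22 / det_a
    i21 = -A12 / det_a
    i22 = A11 / det_a
    l11 = np.sqrt(i11)
    l21 = i21 / l11
    l22 = np.sqrt(np.maximum(i22 - l21 * l21, 1e-300))

    t, w = np.polynomial.hermite.hermgauss(n_quad)
    T1 = np.repeat(t, n_quad)
    T2 = np.tile(t, n_quad)
    logW = np.log(np.outer(w, w).ravel())
    sq = T1 * T1 + T2 * T2

    rt2 = math.sqrt(2.0)
    th1 = m1[:, None] + rt2 * l11[:, None] * T1[None, :]
    th2 = m2[:, None] + rt2 * (l21[:, None] * T1[None, :] + l22[:, None] * T2[None, :])
    h = _log_joint(th1, th2, n[:, None], ybar[:, None], ss[:, None], beta0, tau0, s11, s21, s22)
    core = h + sq[None, :] + logW[None, :]
    ll = logsumexp(core, axis=1) + np.log(2.0 * l11 * l22)
    if not return_grid:
        return ll, (m1, m2)
    p = np.exp(core - logsumexp(core, axis=1, keepdims=True))
    grid = {
        "th1": th1,
        "th2": th2,
        "p": p,
        "mode": (m1, m2),
        "chol": (l11, l21, l22),
        "t_nodes": t,
    }
    return ll, (m1, m2), grid


def marginal_loglik(data: EmaDataset, params: MelsParams, n_quad: int = 15) -> float:
    """Marginal log-likelihood of the MELS model by adaptive quadrature.

    Sums over subjects the log of the double integral of the Gaussian
    within-subject likelihood against the bivariate-normal random-effect
    density, with ``n_quad`` Gauss-Hermite points per dimension re-centered
    at each subject's posterior mode.
    """
    if n_quad < 5:
        raise ValueError("n_quad must be >= 5")
    _, n, ybar, ss = _suff_arrays(data)
    s11, s21, s22 = params.cholesky()
    ll, _ = _aghq(n, ybar, ss, params.beta0, params.tau0, s11, s21, s22, n_quad)
    total = float(np.sum(ll))
    if not math.isfinite(total):
        raise FloatingPointError("non-finite marginal log-likelihood")
    return total


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------


def _mom_start(n, ybar, ss):
    """Method-of-moments starting values on the Cholesky scale."""
    s2 = ss / np.maximum(n - 1, 1.0)
    beta0 = float(ybar.mean())
    mean_s2 = max(float(s2.mean()), 1e-4)
    tau0 = math.log(mean_s2)
    between = float(ybar.var(ddof=1))
    sigma_v2 = max(between - mean_s2 / float(n.mean()), 1e-4)
    return np.array([beta0, tau0, math.sqrt(sigma_v2), 0.0, 0.3])


def fit_mels(data: EmaDataset, settings: MelsSettings | None = None) -> MelsFit:
    """Fit the MELS model by marginal maximum likelihood.

    Quasi-Newton (L-BFGS-B) on the Cholesky-parameterized space with
    method-of-moments starting values and jittered restarts on failure.
    Non-convergence never raises: the returned fit carries ``converged``,
    a boundary flag and the gradient/Hessian diagnostics so Monte-Carlo
    drivers can tally convergence fractions.  EB estimates are attached
    only for converged fits.
    """
    settings = settings or MelsSettings()
    ids, n, ybar, ss = _suff_arrays(data)
    S = len(n)
    if S < 10:
        import warnings

        warnings.warn(f"only {S} subjects; MELS estimates will be unstable", stacklevel=2)

    # A subject with zero within-person variation makes the marginal
    # likelihood unbounded in sigma_w (its contribution grows like
    # exp((n_i - 1)^2 sigma_w^2 / 8)), so no maximum-likelihood estimate
    # exists.  Declaring non-convergence outright is both exact and fast;
    # this is the instability that low-category ordinal responses induce.
    n_degenerate = int((ss == 0).sum())
    if n_degenerate > 0:
        return MelsFit(
            params=None,
            loglik=float("nan"),
            converged=False,
            convergence_detail={
                "grad_norm": float("inf"),
                "n_iter": 0,
                "hessian_pd": False,
                "boundary": False,
                "message": "likelihood unbounded: zero within-subject variance",
                "reason": "degenerate_subjects",
                "n_degenerate": n_degenerate,
            },
            n_quad=settings.n_quad,
        )
    nq_fit = settings.n_quad_fit or settings.n_quad

    mode_cache = {"th": None}

    def objective(x):
        b0, t0, s11, s21, s22 = x
        ll, modes = _aghq(n, ybar, ss, b0, t0, s11, s21, s22, nq_fit, th_init=mode_cache["th"])
        mode_cache["th"] = modes
        val = -float(np.mean(ll))
        if not math.isfinite(val):
            return 1e10
        return val

    bounds = [(None, None), (None, None), (settings.s_min, None), (None, None), (settings.s_min, None)]
    x_mom = _mom_start(n, ybar, ss)
    starts = [x_mom]
    for fac in (0.5, 2.0)[: settings.n_restarts]:
        j = x_mom.copy()
        j[2] *= fac
        j[4] *= fac
        j[1] += math.log(fac)
        starts.append(j)

    best = None
    detail = {}
    for k, x0 in enumerate(starts):
        mode_cache["th"] = None
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            jac=None,
            bounds=bounds,
            options={
                "maxiter": settings.max_iter,
                "ftol": settings.ftol,
                "gtol": settings.gtol,
            },
        )
        grad_inf = float(np.abs(res.jac).max())
        if best is None or res.fun < best[0].fun - 1e-12:
            best = (res, grad_inf, k)
        if grad_inf <= settings.gtol and res.fun <= best[0].fun + 1e-10:
            best = (res, grad_inf, k)
            break

    res, grad_inf, start_index = best
    x_hat = res.x
    boundary = bool(x_hat[2] <= 1.5 * settings.s_min or x_hat[4] <= 1.5 * settings.s_min)

    hess_pd = False
    se = None
    if grad_inf <= 10 * settings.gtol and not boundary:
        H = _numeric_hessian(objective, x_hat)
        eig = np.linalg.eigvalsh(H)
        hess_pd = bool(eig.min() > 0)
        if hess_pd and settings.compute_se:
            try:
                cov = np.linalg.inv(S * H)
                se = dict(zip(("beta0", "tau0", "s11", "s21", "s22"), np.sqrt(np.diag(cov))))
            except np.linalg.LinAlgError:  # pragma: no cover
                se = None

    converged = bool(
        grad_inf <= settings.gtol and hess_pd and not boundary and res.nit < settings.max_iter
    )
    detail = {
        "grad_norm": grad_inf,
        "n_iter": int(res.nit),
        "n_feval": int(res.nfev),
        "hessian_pd": hess_pd,
        "boundary": boundary,
        "message": str(res.message),
        "start_index": start_index,
    }

    params = None
    loglik = float("nan")
    eb = None
    try:
        params = MelsParams.from_cholesky(*x_hat)
        loglik = marginal_loglik(data, params, settings.n_quad)
        if converged:
            eb = eb_estimates(data, params, settings.n_quad)
    except (ValueError, FloatingPointError):
        converged = False
        detail["message"] += " | invalid final parameters"

    return MelsFit(
        params=params,
        loglik=loglik,
        converged=converged,
        convergence_detail=detail,
        n_quad=settings.n_quad,
        eb=eb,
        se=se,
    )


def _numeric_hessian(f, x, step=1e-4):
    k = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


# ----------------------------------------------------------------------
# empirical Bayes and plausible values
# ----------------------------------------------------------------------


def eb_estimates(data: EmaDataset, params: MelsParams, n_quad: int = 15) -> pd.DataFrame:
    """Posterior means and SDs of the standardized random effects.

    The returned ``theta_loc``/``theta_scale`` are posterior means of the
    Cholesky-standardized effects (z-score-like, prior N(0, 1)); their
    posterior SDs shrink toward 0 as a subject contributes more
    observations.
    """
    ids, n, ybar, ss = _suff_arrays(data)
    s11, s21, s22 = params.cholesky()
    _, _, grid = _aghq(
        n, ybar, ss, params.beta0, params.tau0, s11, s21, s22, n_quad, return_grid=True
    )
    p, th1, th2 = grid["p"], grid["th1"], grid["th2"]
    e1 = np.sum(p * th1, axis=1)
    e2 = np.sum(p * th2, axis=1)
    v1 = np.maximum(np.sum(p * th1 * th1, axis=1) - e1 * e1, 1e-300)
    v2 = np.maximum(np.sum(p * th2 * th2, axis=1) - e2 * e2, 1e-300)
    return pd.DataFrame(
        {
            "subject_id": ids,
            "n_obs": n.astype(int),
            "theta_loc": e1,
            "psd_loc": np.sqrt(v1),
            "theta_scale": e2,
            "psd_scale": np.sqrt(v2),
        }
    )


def plausible_values(
    data: EmaDataset,
    params: MelsParams,
    n_draws: int,
    seed: int | np.random.Generator | None = None,
    n_quad: int = 15,
    method: str = "grid",
) -> np.ndarray:
    """Draw (theta1, theta2) samples from each subject's posterior.

    ``method="grid"`` resamples the adaptive quadrature nodes with their
    normalized posterior weights, adding Gaussian jitter whose SD matches
    the local node spacing (uniform-cell equivalent, spacing/sqrt(12)), so
    draw moments converge to the EB moments.  ``method="laplace"`` samples
    the Gaussian approximation at the posterior mode instead.

    Returns an array of shape ``(n_subjects, n_draws, 2)``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids, n, ybar, ss = _suff_arrays(data)
    s11, s21, s22 = params.cholesky()
    _, _, grid = _aghq(
        n, ybar, ss, params.beta0, params.tau0, s11, s21, s22, n_quad, return_grid=True
    )
    S = len(n)
    out = np.empty((S, n_draws, 2))
    l11, l21, l22 = grid["chol"]
    if method == "laplace":
        m1, m2 = grid["mode"]
        z = rng.standard_normal((S, n_draws, 2))
        out[:, :, 0] = m1[:, None] + l11[:, None] * z[:, :, 0]
        out[:, :, 1] = m2[:, None] + l21[:, None] * z[:, :, 0] + l22[:, None] * z[:, :, 1]
        return out
    if method != "grid":
        raise ValueError("method must be 'grid' or 'laplace'")
    dt = float(np.median(np.diff(grid["t_nodes"])))
    jit_sd = math.sqrt(2.0) * dt / math.sqrt(12.0)
    p = grid["p"]
    th1, th2 = grid["th1"], grid["th2"]
    for i in range(S):
        cum = np.cumsum(p[i])
        cum[-1] = 1.0
        idx = np.searchsorted(cum, rng.random(n_draws))
        z = rng.standard_normal((n_draws, 2)) * jit_sd
        out[i, :, 0] = th1[i, idx] + l11[i] * z[:, 0]
        out[i, :, 1] = th2[i, idx] + l21[i] * z[:, 0] + l22[i] * z[:, 1]
    return out
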