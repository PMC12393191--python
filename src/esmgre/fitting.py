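"""Voxelwise estimation of M0, T2* and diffusivity from magnitude echo data.

The signal model for magnitude fitting is

    s(TE_n) = M0 exp(-TE_n / T2*) exp(-b(TE_n) D) exp((-1)^n delta)

where the steady-state factors (T1, flip angle) are folded into M0, ``b`` is
the per-echo diffusion weighting from the echo-shift gradients, and
``delta`` is the small even/odd amplitude alternation of the bipolar
readout, corrected by an iterative scheme (fit without delta, synthesise,
pick the delta minimising the discrepancy, demodulate, refit).

Magnitude data with complex Gaussian noise is Rician distributed; fitting
the noise floor at long TEs with a Gaussian objective biases T2* upward, so
the default objective is the Rician log-likelihood with the noise sigma
estimated from background corners and held fixed.  Fits with and without
the diffusion term are compared per voxel with the small-sample corrected
Akaike information criterion (AICc),

    cAIC = -2 logL + 2k + 2k(k+1) / (n - k - 1).

Two fitting paths are provided: a vectorised Levenberg-Marquardt /
damped-Newton engine used for maps and simulation grids, and a per-voxel
scipy reference path with multi-start (:func:`fit_voxel`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special

from .protocol import ProtocolError
from .sequence import EchoTrainTiming

__all__ = [
    "FitModel",
    "NoiseEstimate",
    "FitResult",
    "estimate_noise_sigma",
    "model_signal",
    "fit_voxel",
    "fit_map",
    "iterative_delta_correction",
    "caic",
    "caic_compare",
]

_EPS = 1e-12


@dataclass(frozen=True)
class FitModel:
    """Model/optimiser settings for the voxelwise fit."""

    include_diffusion: bool = True
    include_delta: bool = False
    noise_model: str = "rician"          # or "gaussian"
    t2_bounds: tuple[float, float] = (1.0, 5000.0)   # ms
    d_bounds: tuple[float, float] = (0.0, 10.0)      # um^2/ms
    delta_bound: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    delta_tol: float = 1e-4
    delta_max_iter: int = 10

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ProtocolError("noise_model must be 'gaussian' or 'rician'")

    @property
    def n_params(self) -> int:
        return 2 + int(self.include_diffusion) + int(self.include_delta)


@dataclass
class NoiseEstimate:
    """Background noise level estimated from corner ROIs."""

    sigma: float
    corner_means: np.ndarray
    corner_size: int
    suspicious: bool = False


@dataclass
class FitResult:
    """Voxelwise parameter maps (or scalars for a single voxel)."""

    m0: np.ndarray
    t2star: np.ndarray
    d: np.ndarray | None
    delta: np.ndarray | float | None
    sigma: float | None
    loglik: np.ndarray
    caic: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray
    model: FitModel
    n_echoes: int


# ---------------------------------------------------------------------------
# noise estimation


def estimate_noise_sigma(
    magnitude_image: np.ndarray,
    corner_size: int = 20,
    method: str = "mean",
) -> NoiseEstimate:
    """Noise sigma from four background-corner ROIs of a magnitude image.

    Pure-noise magnitude voxels follow a Rayleigh distribution, so
    ``sigma = mean / sqrt(pi/2)`` (``method='mean'``) or
    ``sigma = sqrt(mean(x^2)/2)`` (``method='second_moment'``).  A corner
    whose mean is far above the others suggests object overlap and is
    flagged (estimate still uses all corners).
    """
    img = np.asarray(magnitude_image, float)
    if img.ndim != 2:
        raise ProtocolError("expected a single 2D magnitude image")
    nx, ny = img.shape
    c = min(corner_size, nx // 2, ny // 2)
    if c < 1:
        raise ProtocolError("image too small for corner ROIs")
    corners = [
        img[:c, :c], img[:c, -c:], img[-c:, :c], img[-c:, -c:],
    ]
    pooled = np.concatenate([r.ravel() for r in corners])
    means = np.array([r.mean() for r in corners])
    suspicious = False
    med = np.median(means)
    if med > 0 and (means > 3.0 * med).any():
        suspicious = True
        warnings.warn(
            "a background corner ROI is much brighter than the others; it "
            "may overlap the object",
            stacklevel=2,
        )
    if pooled.max() == 0.0:
        warnings.warn("all-zero background corners; sigma = 0", stacklevel=2)
        return NoiseEstimate(0.0, means, c, suspicious)
    if method == "mean":
        sigma = pooled.mean() / np.sqrt(np.pi / 2.0)
    elif method == "second_moment":
        sigma = np.sqrt((pooled**2).mean() / 2.0)
    else:
        raise ProtocolError("method must be 'mean' or 'second_moment'")
    return NoiseEstimate(float(sigma), means, c, suspicious)


# ---------------------------------------------------------------------------
# forward model


def model_signal(
    m0: float | np.ndarray,
    t2star: float | np.ndarray,
    train: EchoTrainTiming,
    d: float | np.ndarray = 0.0,
    delta: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Noise-free magnitude per echo for the fit model.

    The alternating-sign exponent uses each echo's bipolar readout polarity;
    broadcasting over leading voxel dimensions is supported.
    """
    b = train.b if train.b is not None else np.zeros(train.n_echoes)
    te = train.te
    pol = train.polarity
    m0, t2star, d, delta = (np.asarray(v, float) for v in (m0, t2star, d, delta))
    shape = np.broadcast_shapes(m0.shape, t2star.shape, d.shape, delta.shape)
    m0, t2star, d, delta = (
        np.broadcast_to(v, shape)[..., None] for v in (m0, t2star, d, delta)
    )
    return (
        m0
        * np.exp(-te / t2star)
        * np.exp(-b * 1e-3 * d)
        * np.exp(pol * delta)
    )


# ---------------------------------------------------------------------------
# batched engine

def _nu(theta: np.ndarray, te: np.ndarray, bd: np.ndarray, with_d: bool) -> np.ndarray:
    """Model magnitude from theta = (log M0, R2*, [D]); shape (V, n)."""
    ex = theta[:, 0:1] - te[None, :] * theta[:, 1:2]
    if with_d:
        ex = ex - bd[None, :] * theta[:, 2:3]
    return np.exp(np.clip(ex, -700, 700))


def _init_theta(
    s: np.ndarray, train: EchoTrainTiming, with_d: bool, model: FitModel
) -> np.ndarray:
    """Log-linear initialisation: prompt echoes give (log M0, R2*), the
    shifted-block log-offset gives D."""
    te = train.te
    bd = (train.b if train.b is not None else np.zeros(te.size)) * 1e-3
    prompt = ~train.is_shifted
    y = np.log(np.maximum(s, _EPS))
    w = np.maximum(s, _EPS) ** 2
    tp, yp, wp = te[prompt], y[:, prompt], w[:, prompt]
    sw = wp.sum(1)
    mt = (wp * tp).sum(1) / sw
    my = (wp * yp).sum(1) / sw
    var = (wp * (tp - mt[:, None]) ** 2).sum(1) / sw
    cov = (wp * (tp - mt[:, None]) * (yp - my[:, None])).sum(1) / sw
    r2 = np.where(var > 0, -cov / np.maximum(var, _EPS), 1.0 / 50.0)
    r2 = np.clip(r2, 1.0 / model.t2_bounds[1], 1.0 / model.t2_bounds[0])
    c = my + r2 * mt
    if not with_d:
        return np.stack([c, r2], axis=1)
    shifted = train.is_shifted
    if shifted.any() and bd[shifted].mean() > 0:
        resid = (
            c[:, None] - te[shifted][None, :] * r2[:, None] - y[:, shifted]
        )
        d0 = resid.mean(1) / bd[shifted].mean()
    else:
        d0 = np.zeros(s.shape[0])
    d0 = np.clip(d0, model.d_bounds[0], model.d_bounds[1])
    return np.stack([c, r2, d0], axis=1)


def _clip_theta(theta: np.ndarray, with_d: bool, model: FitModel) -> np.ndarray:
    theta[:, 1] = np.clip(theta[:, 1], 1.0 / model.t2_bounds[1], 1.0 / model.t2_bounds[0])
    if with_d:
        theta[:, 2] = np.clip(theta[:, 2], model.d_bounds[0], model.d_bounds[1])
    return theta


def _basis(te: np.ndarray, bd: np.ndarray, with_d: bool) -> np.ndarray:
    """d(log nu)/d theta, shape (n, P)."""
    cols = [np.ones_like(te), -te]
    if with_d:
        cols.append(-bd)
    return np.stack(cols, axis=1)



def _lm_step(
    A: np.ndarray, g: np.ndarray, th: np.ndarray, with_d: bool, model: FitModel
) -> np.ndarray:
    """Damped-Newton step with active-bound handling.

    If the full step would push R2* or D past its bound, the parameter is
    pinned at the bound and the step is re-solved in the free subspace;
    plain clipping would otherwise leave the remaining parameters with an
    inconsistent step and stall convergence at the boundary.
    """
    step = np.linalg.solve(A, g[..., None])[..., 0]
    th_new = th + step
    r2lo, r2hi = 1.0 / model.t2_bounds[1], 1.0 / model.t2_bounds[0]
    viol_r2 = (th_new[:, 1] < r2lo) | (th_new[:, 1] > r2hi)
    if with_d:
        dlo, dhi = model.d_bounds
        viol_d = (th_new[:, 2] < dlo) | (th_new[:, 2] > dhi)
    else:
        viol_d = np.zeros(th.shape[0], bool)
    for pin_r2, pin_d in ((False, True), (True, False), (True, True)):
        m = (viol_r2 == pin_r2) & (viol_d == pin_d) & (viol_r2 | viol_d)
        if not m.any():
            continue
        free = [0]
        if not pin_r2:
            free.append(1)
        if with_d and not pin_d:
            free.append(2)
        sub = A[m][:, free, :][:, :, free]
        gs = g[m][:, free]
        st = np.linalg.solve(sub, gs[..., None])[..., 0]
        tmp = th[m].copy()
        if pin_r2:
            tmp[:, 1] = np.clip(th_new[m][:, 1], r2lo, r2hi)
        if pin_d:
            tmp[:, 2] = np.clip(th_new[m][:, 2], dlo, dhi)
        for j, col in enumerate(free):
            tmp[:, col] = th[m][:, col] + st[:, j]
        th_new[m] = tmp
    return _clip_theta(th_new, with_d, model)


def _batched_ls(
    s: np.ndarray, train: EchoTrainTiming, model: FitModel,
    theta0: np.ndarray | None = None, max_iter: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Levenberg-Marquardt least squares over voxels.

    Returns (theta, converged, n_iter)."""
    with_d = model.include_diffusion
    te = train.te
    bd = (train.b if train.b is not None else np.zeros(te.size)) * 1e-3
    W = _basis(te, bd, with_d)  # (n, P)
    theta = _init_theta(s, train, with_d, model) if theta0 is None else theta0.copy()
    theta = _clip_theta(theta, with_d, model)
    V, P = theta.shape
    lam = np.full(V, 1e-3)
    nu = _nu(theta, te, bd, with_d)
    sse = ((s - nu) ** 2).sum(1)
    n_iter = np.zeros(V, int)
    active = np.ones(V, bool)
    max_iter = model.max_iter if max_iter is None else max_iter
    eye = np.eye(P)
    for it in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        th = theta[idx]
        nv = nu[idx]
        r = s[idx] - nv
        J = nv[:, :, None] * W[None, :, :]          # (v, n, P)
        JTJ = np.einsum("vnp,vnq->vpq", J, J)
        g = np.einsum("vnp,vn->vp", J, r)
        A = JTJ + lam[idx, None, None] * (JTJ * eye + 1e-12 * eye)
        th_new = _lm_step(A, g, th, with_d, model)
        nu_new = _nu(th_new, te, bd, with_d)
        sse_new = ((s[idx] - nu_new) ** 2).sum(1)
        better = sse_new <= sse[idx]
        gain = sse[idx] - sse_new
        lam[idx] = np.where(better, lam[idx] / 5.0, lam[idx] * 10.0)
        lam[idx] = np.clip(lam[idx], 1e-10, 1e8)
        upd = idx[better]
        rel = np.abs(th_new[better] - th[better]) / (np.abs(th[better]) + 1e-8)
        theta[upd] = th_new[better]
        nu[upd] = nu_new[better]
        sse[upd] = sse_new[better]
        n_iter[idx] += 1
        done = np.zeros(idx.size, bool)
        done[better] = (rel.max(1) < model.tol) | (
            gain[better] < 1e-10 * (sse_new[better] + 1e-30)
        )
        done[~better] = lam[idx][~better] >= 1e7
        active[idx[done]] = False
    return theta, ~active, n_iter


def _rician_loglik(
    s: np.ndarray, nu: np.ndarray, sigma: float
) -> np.ndarray:
    """Per-voxel Rician log-likelihood (sums over echoes)."""
    s2 = sigma * sigma
    z = s * nu / s2
    ll = (
        np.log(np.maximum(s, _EPS) / s2)
        - (s * s + nu * nu) / (2 * s2)
        + np.log(special.i0e(z))
        + z
    )
    return ll.sum(axis=-1)


def _gaussian_loglik(s: np.ndarray, nu: np.ndarray, sigma: float) -> np.ndarray:
    s2 = sigma * sigma
    n = s.shape[-1]
    return -0.5 * n * np.log(2 * np.pi * s2) - ((s - nu) ** 2).sum(-1) / (2 * s2)


def _batched_rician(
    s: np.ndarray, train: EchoTrainTiming, model: FitModel, sigma: float,
    theta0: np.ndarray, max_iter: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped-Newton ascent of the Rician likelihood from a LS start."""
    with_d = model.include_diffusion
    te = train.te
    bd = (train.b if train.b is not None else np.zeros(te.size)) * 1e-3
    W = _basis(te, bd, with_d)
    theta = theta0.copy()
    V, P = theta.shape
    s2 = sigma * sigma
    nu = _nu(theta, te, bd, with_d)
    ll = _rician_loglik(s, nu, sigma)
    lam = np.full(V, 1e-3)
    n_iter = np.zeros(V, int)
    active = np.ones(V, bool)
    max_iter = model.max_iter if max_iter is None else max_iter
    eye = np.eye(P)
    for it in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        nv = nu[idx]
        sv = s[idx]
        z = sv * nv / s2
        R = special.i1e(z) / np.maximum(special.i0e(z), _EPS)
        dl_dnu = (sv * R - nv) / s2          # exact gradient wrt nu
        J = nv[:, :, None] * W[None, :, :]
        g = np.einsum("vnp,vn->vp", J, dl_dnu)
        H = np.einsum("vnp,vnq->vpq", J, J) / s2   # Gauss approximation
        A = H + lam[idx, None, None] * (H * eye + 1e-12 * eye)
        th_new = _lm_step(A, g, theta[idx], with_d, model)
        nu_new = _nu(th_new, te, bd, with_d)
        ll_new = _rician_loglik(sv, nu_new, sigma)
        better = ll_new >= ll[idx]
        gain = ll_new - ll[idx]
        lam[idx] = np.where(better, lam[idx] / 5.0, lam[idx] * 10.0)
        lam[idx] = np.clip(lam[idx], 1e-10, 1e8)
        rel = np.abs(th_new[better] - theta[idx][better]) / (
            np.abs(theta[idx][better]) + 1e-8
        )
        upd = idx[better]
        theta[upd] = th_new[better]
        nu[upd] = nu_new[better]
        ll[upd] = ll_new[better]
        n_iter[idx] += 1
        done = np.zeros(idx.size, bool)
        done[better] = (rel.max(1) < model.tol) | (
            gain[better] < 1e-10 * (np.abs(ll[upd]) + 1.0)
        )
        done[~better] = lam[idx][~better] >= 1e7
        active[idx[done]] = False
    return theta, ~active, n_iter


def _fit_batch(
    s: np.ndarray, train: EchoTrainTiming, model: FitModel,
    sigma: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit all voxels; returns (theta, loglik, converged, n_iter)."""
    if model.noise_model == "rician" and (sigma is None or sigma <= 0):
        raise ProtocolError("the Rician objective needs a positive noise sigma")
    theta, conv, n_it = _batched_ls(s, train, model)
    te = train.te
    bd = (train.b if train.b is not None else np.zeros(te.size)) * 1e-3
    if model.noise_model == "rician":
        theta, conv, n_it2 = _batched_rician(s, train, model, sigma, theta)
        n_it = n_it + n_it2
        ll = _rician_loglik(s, _nu(theta, te, bd, model.include_diffusion), sigma)
    else:
        sig = sigma if (sigma is not None and sigma > 0) else 1.0
        ll = _gaussian_loglik(
            s, _nu(theta, te, bd, model.include_diffusion), sig
        )
    return theta, ll, conv, n_it


# ---------------------------------------------------------------------------
# public fitting API


def caic(loglik: np.ndarray, k: int, n: int) -> np.ndarray:
    """Small-sample corrected Akaike information criterion."""
    loglik = np.asarray(loglik, float)
    if n - k - 1 <= 0:
        return np.full_like(loglik, np.nan)
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _theta_to_result(
    theta: np.ndarray, ll: np.ndarray, conv: np.ndarray, n_it: np.ndarray,
    model: FitModel, n_echoes: int, sigma: float | None,
    delta: np.ndarray | float | None = None,
) -> FitResult:
    with_d = model.include_diffusion
    k = model.n_params
    return FitResult(
        m0=np.exp(theta[:, 0]),
        t2star=1.0 / theta[:, 1],
        d=theta[:, 2].copy() if with_d else None,
        delta=delta,
        sigma=sigma,
        loglik=ll,
        caic=caic(ll, k, n_echoes),
        converged=conv,
        n_iter=n_it,
        model=model,
        n_echoes=n_echoes,
    )


def fit_voxel(
    signal: np.ndarray,
    train: EchoTrainTiming,
    model: FitModel = FitModel(),
    sigma: float | None = None,
) -> FitResult:
    """Reference per-voxel fit with a 3-point multi-start on T2*.

    Maximises the Rician likelihood (or minimises least squares) with
    scipy's bounded optimiser, starting from the log-linear initialisation
    and from T2* scaled by 0.5 and 2 to avoid local optima.  Deterministic
    for fixed data and settings.
    """
    s = np.asarray(signal, float).reshape(1, -1)
    if s.size < model.n_params:
        raise ProtocolError("need at least as many echoes as parameters")
    if model.noise_model == "rician" and (sigma is None or sigma <= 0):
        raise ProtocolError("the Rician objective needs a positive noise sigma")
    with_d = model.include_diffusion
    te = train.te
    bd = (train.b if train.b is not None else np.zeros(te.size)) * 1e-3

    def negobj(x):
        nu = _nu(x.reshape(1, -1), te, bd, with_d)
        if model.noise_model == "rician":
            return -float(_rician_loglik(s, nu, sigma)[0])
        return float(((s - nu) ** 2).sum())

    theta0 = _init_theta(s, train, with_d, model)[0]
    lo = [-50.0, 1.0 / model.t2_bounds[1]]
    hi = [50.0, 1.0 / model.t2_bounds[0]]
    if with_d:
        lo.append(model.d_bounds[0])
        hi.append(model.d_bounds[1])
    best = None
    n_ev = 0
    for f in (1.0, 0.5, 2.0):
        x0 = theta0.copy()
        x0[1] = np.clip(x0[1] * f, lo[1], hi[1])
        res = optimize.minimize(
            negobj, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": model.max_iter, "ftol": 1e-14, "gtol": 1e-12},
        )
        n_ev += res.nit
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x.reshape(1, -1)
    nu = _nu(theta, te, bd, with_d)
    if model.noise_model == "rician":
        ll = _rician_loglik(s, nu, sigma)
    else:
        sig = sigma if (sigma is not None and sigma > 0) else 1.0
        ll = _gaussian_loglik(s, nu, sig)
    return _theta_to_result(
        theta, ll, np.array([best.success]), np.array([n_ev]),
        model, te.size, sigma,
    )


def fit_map(
    image_stack: np.ndarray,
    train: EchoTrainTiming,
    models: dict[str, FitModel] | FitModel | None = None,
    sigma: float | None = None,
    mask: np.ndarray | None = None,
) -> dict[str, FitResult]:
    """Voxelwise fits over an image stack (n_echoes, nx, ny).

    ``models`` maps a name to a :class:`FitModel`; the default fits the
    model with and without the diffusion term for cAIC comparison.
    Background voxels (first-echo magnitude below 3 sigma) are masked; maps
    carry ``nan`` there.  Results are independent of voxel order.
    """
    stack = np.asarray(image_stack, float)
    if stack.ndim == 1:
        stack = stack.reshape(-1, 1, 1)
    if stack.ndim != 3 or stack.shape[0] != train.n_echoes:
        raise ProtocolError("image stack must be (n_echoes, nx, ny)")
    if models is None:
        models = {
            "with_diffusion": FitModel(include_diffusion=True),
            "without_diffusion": FitModel(include_diffusion=False),
        }
    elif isinstance(models, FitModel):
        models = {"fit": models}
    n, nx, ny = stack.shape
    flat = stack.reshape(n, -1).T  # (V, n)
    if mask is None:
        if sigma is not None and sigma > 0:
            mask = stack[0] >= 3.0 * sigma
        else:
            mask = np.ones((nx, ny), bool)
    mflat = mask.ravel()
    out: dict[str, FitResult] = {}
    for name, model in models.items():
        res_flat = {}
        if mflat.any():
            theta, ll, conv, n_it = _fit_batch(flat[mflat], train, model, sigma)
            r = _theta_to_result(theta, ll, conv, n_it, model, n, sigma)
        else:
            r = None

        def full(vec, fill=np.nan, dtype=float):
            outv = np.full(nx * ny, fill, dtype)
            if r is not None:
                outv[mflat] = vec
            return outv.reshape(nx, ny)

        out[name] = FitResult(
            m0=full(r.m0 if r else None),
            t2star=full(r.t2star if r else None),
            d=(full(r.d) if (r and r.d is not None) else None),
            delta=None,
            sigma=sigma,
            loglik=full(r.loglik if r else None),
            caic=full(r.caic if r else None),
            converged=full(r.converged if r else None, False, bool),
            n_iter=full(r.n_iter if r else None, 0, int),
            model=model,
            n_echoes=n,
        )
        out[name].mask = mask  # type: ignore[attr-defined]
    return out


def caic_compare(
    fit_with_d: FitResult, fit_without_d: FitResult, n_echoes: int | None = None
) -> dict[str, np.ndarray]:
    """Per-voxel model comparison between fits with and without diffusion.

    Returns the two cAIC maps and a boolean map that is True where the
    diffusion model attains the lower cAIC.  With equal likelihoods the
    model with fewer parameters wins through the smaller penalty.  Voxels
    where the correction term is undefined (n - k - 1 <= 0) are nan/False.
    """
    n = n_echoes if n_echoes is not None else fit_with_d.n_echoes
    c_with = caic(fit_with_d.loglik, fit_with_d.model.n_params, n)
    c_without = caic(fit_without_d.loglik, fit_without_d.model.n_params, n)
    with np.errstate(invalid="ignore"):
        prefer = c_with < c_without
    prefer = np.where(np.isnan(c_with) | np.isnan(c_without), False, prefer)
    return {
        "caic_with_diffusion": c_with,
        "caic_without_diffusion": c_without,
        "prefer_diffusion": prefer.astype(bool),
        "undefined": np.isnan(c_with) | np.isnan(c_without),
    }


# ---------------------------------------------------------------------------
# bipolar modulation


def _delta_step_global(s: np.ndarray, nu: np.ndarray, pol: np.ndarray) -> float:
    """Scalar delta minimising sum (s - nu exp(p delta))^2."""

    def f(dl):
        return float(((s - nu * np.exp(pol[None, :] * dl)) ** 2).sum())

    res = optimize.minimize_scalar(f, bounds=(-1.0, 1.0), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def _delta_step_voxelwise(
    s: np.ndarray, nu: np.ndarray, pol: np.ndarray, iters: int = 30
) -> np.ndarray:
    """Per-voxel Newton solve of d/d delta sum (s - nu e^{p delta})^2 = 0."""
    dl = np.zeros(s.shape[0])
    for _ in range(iters):
        m = nu * np.exp(pol[None, :] * dl[:, None])
        g = (pol[None, :] * m * (m - s)).sum(1)          # dF/d delta / 2
        h = (m * (2 * m - s)).sum(1)                     # d2F/d delta2 / 2
        step = -g / np.maximum(np.abs(h), _EPS) * np.sign(np.where(h == 0, 1, h))
        step = np.clip(step, -0.2, 0.2)
        dl = np.clip(dl + step, -1.0, 1.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    return dl


def iterative_delta_correction(
    images: np.ndarray,
    train: EchoTrainTiming,
    model: FitModel = FitModel(include_diffusion=True, noise_model="gaussian"),
    sigma: float | None = None,
    per_voxel: bool = False,
    snr_threshold: float = 10.0,
) -> tuple[np.ndarray | float, np.ndarray, dict]:
    """Estimate and remove the bipolar even/odd amplitude modulation.

    Iterates: fit the delta-free model, synthesise delta-free images, choose
    the delta minimising the acquired-vs-synthesised discrepancy, demodulate
    and refit, until the delta update falls below ``model.delta_tol`` or
    ``model.delta_max_iter`` iterations.  By default a single global delta
    is estimated from high-SNR voxels; ``per_voxel=True`` estimates a map.

    Returns ``(delta, corrected_images, info)``; corrected images have the
    modulation divided out.
    """
    stack = np.asarray(images, float)
    orig_shape = stack.shape
    n = train.n_echoes
    if stack.shape[0] != n:
        raise ProtocolError("image stack must have the echo axis first")
    flat = stack.reshape(n, -1).T.copy()  # (V, n)
    pol = train.polarity.astype(float)
    if sigma is not None and sigma > 0:
        hi = flat[:, 0] >= snr_threshold * sigma
        if not hi.any():
            hi = np.ones(flat.shape[0], bool)
    else:
        hi = np.ones(flat.shape[0], bool)
    fit_model = replace(model, include_delta=False)
    work = flat[hi].copy()
    te = train.te
    bd = (train.b if train.b is not None else np.zeros(n)) * 1e-3
    total: np.ndarray | float = (
        np.zeros(work.shape[0]) if per_voxel else 0.0
    )
    iters = 0
    converged = False
    for it in range(model.delta_max_iter):
        theta, _, _, _ = _fit_batch(work, train, fit_model, sigma)
        nu = _nu(theta, te, bd, fit_model.include_diffusion)
        if per_voxel:
            step = _delta_step_voxelwise(work, nu, pol)
            move = float(np.max(np.abs(step)))
        else:
            step = _delta_step_global(work, nu, pol)
            move = abs(step)
        total = total + step
        work = work * np.exp(
            -pol[None, :] * (step[:, None] if per_voxel else step)
        )
        iters = it + 1
        if move < model.delta_tol:
            converged = True
            break
    if not converged and iters == model.delta_max_iter:
        warnings.warn(
            "delta correction did not converge; returning the last iterate",
            stacklevel=2,
        )
    if per_voxel:
        delta_full = np.zeros(flat.shape[0])
        delta_full[hi] = total
        corrected = flat * np.exp(-pol[None, :] * delta_full[:, None])
        delta_out: np.ndarray | float = delta_full.reshape(orig_shape[1:])
    else:
        corrected = flat * np.exp(-pol[None, :] * float(total))
        delta_out = float(total)
    info = {"iterations": iters, "converged": converged}
    return delta_out, corrected.T.reshape(orig_shape), info
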