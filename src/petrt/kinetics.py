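"""Two-tissue compartment (2TC) modelling against an arterial input function.

The model has a free/non-specific compartment C1 and a specifically bound
compartment C2:

    dC1/dt = K1*Cp(t) - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

K1 (mL cm^-3 min^-1) is plasma-to-tissue delivery, k2, k3, k4 (min^-1) are
tissue efflux and the exchange into / out of the bound compartment.  The
tissue impulse response is a two-exponential

    h(t) = K1/(a2 - a1) * [(k3 + k4 - a1) e^{-a1 t} + (a2 - k3 - k4) e^{-a2 t}]

with eigenrates a1 <= a2 the roots of s^2 - (k2+k3+k4) s + k2 k4.  The
total distribution volume is V_T = (K1/k2)(1 + k3/k4).

Because the input function is piecewise linear before its peak and a sum of
decaying exponentials after it, the convolution Cp (*) h has a closed form;
the forward model evaluates it exactly and averages over frames with
Gauss-Legendre quadrature.  No ODE solver is involved (an independent stiff
integrator is used as an oracle in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .plasma import InputFunction

__all__ = ["TwoTissueParams", "FitResult", "forward_2tc", "fit_2tc", "compute_vt"]

# Fitting bounds: generous physiological ranges for a high-affinity
# D2/3 antagonist tracer.
K1_BOUNDS = (1e-6, 2.0)
K_BOUNDS = (1e-4, 2.0)

_GAUSS_NODES, _GAUSS_WEIGHTS = np.polynomial.legendre.leggauss(8)


class KineticsError(ValueError):
    """Raised on invalid kinetic parameters or a failed fit."""


@dataclass(frozen=True)
class TwoTissueParams:
    """Rate constants of the 2TC model, plus an optional blood-volume fraction."""

    K1: float   # mL cm^-3 min^-1
    k2: float   # min^-1
    k3: float   # min^-1
    k4: float   # min^-1
    vB: float = 0.0

    def __post_init__(self):
        if self.K1 < 0 or self.k2 <= 0 or self.k3 < 0 or self.k4 < 0:
            raise KineticsError("rate constants must be non-negative (k2 positive)")
        if not (0.0 <= self.vB <= 0.1):
            raise KineticsError("vB must lie in [0, 0.1]")

    @property
    def vt(self) -> float:
        return compute_vt(self)


def compute_vt(params: TwoTissueParams) -> float:
    """Total distribution volume V_T = (K1/k2)(1 + k3/k4), mL cm^-3."""
    if params.k4 == 0:
        if params.k3 == 0:
            return params.K1 / params.k2
        raise KineticsError("V_T undefined: k4 = 0 with k3 > 0 (irreversible binding)")
    return (params.K1 / params.k2) * (1.0 + params.k3 / params.k4)


def _impulse_terms(params: TwoTissueParams):
    """Eigenrates (a1, a2) and amplitudes (B1, B2) of h(t) = B1 e^{-a1 t} + B2 e^{-a2 t}."""
    k2, k3, k4 = params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    sq = np.sqrt(max(disc, 0.0))
    if sq < 1e-10 * s:
        # repeated eigenvalue: split symmetrically; error is O(eps^2 t^2)
        sq = 1e-7 * s
    a1 = 0.5 * (s - sq)
    a2 = 0.5 * (s + sq)
    B1 = params.K1 * (k3 + k4 - a1) / (a2 - a1)
    B2 = params.K1 * (a2 - k3 - k4) / (a2 - a1)
    return a1, a2, B1, B2


def _phi1(x):
    # (e^x - 1)/x, stable at 0
    out = np.ones_like(x)
    small = np.abs(x) < 1e-5
    xs = x[~small]
    out[~small] = np.expm1(xs) / xs
    xs = x[small]
    out[small] = 1.0 + xs / 2.0 + xs * xs / 6.0
    return out


def _phi2(x):
    # (e^x (x - 1) + 1)/x^2, stable at 0 (-> 1/2)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = (np.exp(xs) * (xs - 1.0) + 1.0) / (xs * xs)
    xs = x[small]
    out[small] = 0.5 + xs / 3.0 + xs * xs / 8.0 + xs ** 3 / 30.0
    return out


def _conv_exp(inp: InputFunction, alpha: float, t: np.ndarray) -> np.ndarray:
    """Exact convolution  integral_0^t Cp(s) e^{-alpha (t - s)} ds  at times t."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)

    # piecewise-linear pre-peak segments
    pt, pv = inp.prepeak_times, inp.prepeak_values
    if pt.size >= 2:
        a = pt[:-1][None, :]          # (1, ns)
        b = pt[1:][None, :]
        ya = pv[:-1][None, :]
        m = ((pv[1:] - pv[:-1]) / (pt[1:] - pt[:-1]))[None, :]
        tc = t[:, None]               # (nt, 1)
        upper = np.minimum(b, tc)
        U = np.clip(upper - a, 0.0, None)          # active length
        tau = tc - a
        # I(t) = e^{-alpha tau} [ ya U phi1(alpha U) + m U^2 phi2(alpha U) ]
        x = alpha * U
        seg = np.exp(-alpha * tau) * (ya * U * _phi1(x) + m * U * U * _phi2(x))
        seg[U <= 0] = 0.0
        out += seg.sum(axis=1)

    # exponential tail from the peak
    T = t - inp.peak_time
    post = T > 0
    if post.any():
        Tp = T[post]
        acc = np.zeros_like(Tp)
        for A, lam in zip(inp.amplitudes, inp.rates):
            if A == 0.0:
                continue
            d = alpha - lam
            if abs(d) < 1e-9 * max(alpha, lam):
                acc += A * Tp * np.exp(-0.5 * (alpha + lam) * Tp)
            else:
                acc += A * (np.exp(-lam * Tp) - np.exp(-alpha * Tp)) / d
        out[post] += acc
    return out


def tissue_curve(params: TwoTissueParams, inp: InputFunction, t) -> np.ndarray:
    """Continuous tissue concentration C(t) = Cp (*) h at arbitrary times."""
    t = np.asarray(t, dtype=float)
    a1, a2, B1, B2 = _impulse_terms(params)
    out = B1 * _conv_exp(inp, a1, t) + B2 * _conv_exp(inp, a2, t)
    if params.vB > 0:
        out = out + params.vB * np.atleast_1d(inp(t))
    return out


def forward_2tc(params: TwoTissueParams, inp: InputFunction, frames) -> np.ndarray:
    """Frame-averaged 2TC tissue curve.

    ``frames`` is an (n, 2) array of (start, end) minutes; the returned value
    per frame is the interval average of the continuous solution, computed
    with 8-point Gauss-Legendre quadrature on the exact convolution.
    """
    fr = np.asarray(frames, dtype=float)
    if fr.ndim != 2 or fr.shape[1] != 2:
        raise KineticsError("frames must be an (n, 2) array of (start, end) minutes")
    if np.any(fr[:, 1] <= fr[:, 0]) or np.any(fr[:, 0] < 0):
        raise KineticsError("frames must have positive duration and non-negative start")
    if fr[-1, 1] > inp.support + 1e-9:
        raise KineticsError(
            f"frames extend to {fr[-1, 1]:g} min, beyond the input-curve support ({inp.support:g} min)")
    mid = 0.5 * (fr[:, 0] + fr[:, 1])
    half = 0.5 * (fr[:, 1] - fr[:, 0])
    tq = (mid[:, None] + half[:, None] * _GAUSS_NODES[None, :]).ravel()
    if params.K1 == 0.0 and params.vB == 0.0:
        return np.zeros(fr.shape[0])
    c = tissue_curve(params, inp, tq).reshape(fr.shape[0], _GAUSS_NODES.size)
    return c @ (_GAUSS_WEIGHTS / 2.0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a weighted nonlinear 2TC fit to one regional TAC."""

    params: TwoTissueParams
    vt: float
    residual_norm: float
    converged: bool
    stderr: dict
    at_bounds: bool
    identifiability_flag: bool

    def __post_init__(self):
        # V_T is always the closed form of the fitted constants
        assert self.vt == compute_vt(self.params)


def _frame_weights(frames, scheme: str) -> np.ndarray:
    fr = np.asarray(frames, dtype=float)
    if scheme == "duration":
        w = fr[:, 1] - fr[:, 0]
    elif scheme == "uniform":
        w = np.ones(fr.shape[0])
    else:
        raise KineticsError(f"unknown weights scheme {scheme!r}")
    return w / w.sum()


def fit_2tc(tac, inp: InputFunction, frames, weights: str = "duration",
            starts: int = 10, seed: int = 0, fit_vb: bool = False) -> FitResult:
    """Weighted nonlinear least-squares 2TC fit, best of ``starts`` multistarts.

    Deterministic given the data, the input function and ``seed``.  Bounds:
    K1 in (0, 2], k2/k3/k4 in [1e-4, 2] min^-1.  Start points are log-uniform
    within bounds (the first start is a fixed physiological guess).
    """
    y = np.asarray(tac, dtype=float)
    fr = np.asarray(frames, dtype=float)
    if y.shape[0] != fr.shape[0]:
        raise KineticsError("TAC and frame schedule lengths differ")
    if y.shape[0] < 8:
        raise KineticsError("need at least 8 frames for a 2TC fit")
    sw = np.sqrt(_frame_weights(fr, weights))

    nb = 5 if fit_vb else 4
    lb = np.array([K1_BOUNDS[0], K_BOUNDS[0], K_BOUNDS[0], K_BOUNDS[0], 0.0])[:nb]
    ub = np.array([K1_BOUNDS[1], K_BOUNDS[1], K_BOUNDS[1], K_BOUNDS[1], 0.1])[:nb]

    def resid(x):
        p = TwoTissueParams(*x) if fit_vb else TwoTissueParams(x[0], x[1], x[2], x[3])
        return sw * (forward_2tc(p, inp, fr) - y)

    rng = np.random.default_rng(seed)
    x0s = [np.array([0.3, 0.15, 0.03, 0.025, 0.04])[:nb]]
    for _ in range(max(starts - 1, 0)):
        x0s.append(np.exp(rng.uniform(np.log(np.maximum(lb, 1e-6)), np.log(np.maximum(ub, 1e-6)))))

    best = None
    n_fail = 0
    for x0 in x0s:
        try:
            sol = least_squares(resid, x0=np.clip(x0, lb, ub), bounds=(lb, ub),
                                method="trf", x_scale="jac",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            n_fail += 1
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise KineticsError(f"2TC fit failed: all {len(x0s)} starts errored ({n_fail} failures)")

    x = best.x
    params = TwoTissueParams(*x) if fit_vb else TwoTissueParams(x[0], x[1], x[2], x[3])
    at_bounds = bool(np.any(np.isclose(x, lb, rtol=1e-3)) or np.any(np.isclose(x, ub, rtol=1e-3)))

    # approximate standard errors from the Jacobian at the solution
    names = ["K1", "k2", "k3", "k4", "vB"][:nb]
    dof = max(y.size - nb, 1)
    sse = 2.0 * best.cost
    try:
        JTJ = best.jac.T @ best.jac
        cov = np.linalg.pinv(JTJ) * sse / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(nb, np.nan)
    stderr = dict(zip(names, se))
    rel = {n: (stderr[n] / abs(v) if v != 0 else np.inf)
           for n, v in zip(names, x)}
    ident_flag = bool(rel.get("k3", 0) > 1.0 or rel.get("k4", 0) > 1.0)

    return FitResult(
        params=params, vt=compute_vt(params),
        residual_norm=float(np.sqrt(sse)),
        converged=bool(best.status > 0),
        stderr=stderr, at_bounds=at_bounds,
        identifiability_flag=ident_flag,
    )
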