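"""Arterial plasma processing: metabolite correction and the input function.

Raw arterial samples (total plasma activity) are converted into a
metabolite-corrected input function in three steps:

1. a Hill-type curve is fitted to the sparse parent-fraction measurements,
2. parent concentration = total activity x interpolated parent fraction,
   with a sum of three exponentials fitted from the time of peak parent
   activity (piecewise-linear interpolation before the peak),
3. plasma clearance C_L = injected dose / AUC of the input function,
   with the fitted tail extrapolated to infinity.

Internal units: time in minutes, activity in kBq/mL, dose in MBq.
Clearance is converted to L/h at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

__all__ = [
    "PlasmaTimeCourse",
    "HillParams",
    "InputFunction",
    "fit_parent_fraction",
    "fit_triexponential",
    "build_input",
    "compute_clearance",
]


class PlasmaError(ValueError):
    """Raised on invalid plasma data or a failed plasma fit."""


@dataclass(frozen=True)
class PlasmaTimeCourse:
    """Raw arterial samples plus per-scan plasma metadata.

    ``f_p`` (plasma free fraction) and amphetamine levels are measured
    quantities carried through for the reliability stage; they are never
    computed here.
    """

    sample_times: np.ndarray          # minutes, strictly increasing
    total_activity: np.ndarray        # kBq/mL plasma
    injected_dose: float              # MBq
    f_p: float | None = None          # fraction in [0, 1]
    amphetamine_levels: tuple[float, float, float] | None = None  # ng/mL at 0/45/90 min

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        a = np.asarray(self.total_activity, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise PlasmaError("sample_times and total_activity must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise PlasmaError("sample times must be strictly increasing")
        if np.any(a < 0):
            raise PlasmaError("activities must be non-negative")
        if self.injected_dose <= 0:
            raise PlasmaError("injected dose must be positive")
        if self.f_p is not None and not (0.0 <= self.f_p <= 1.0):
            raise PlasmaError("f_p must lie in [0, 1]")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "total_activity", a)


@dataclass(frozen=True)
class HillParams:
    """Hill-type parent-fraction curve f(t) = 1 - a * t^b / (c + t^b).

    ``a`` is the asymptotic metabolised fraction (0 <= a <= 1), ``b`` the
    Hill slope (> 0) and ``c`` the half-conversion constant (> 0, units
    min^b).  The implied parent fraction is monotone non-increasing with
    f(0) = 1.  ``degenerate`` flags the no-metabolism case a = 0, where b
    and c are unidentifiable.
    """

    a: float
    b: float
    c: float
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0):
            raise PlasmaError("Hill 'a' must lie in [0, 1]")
        if self.b <= 0 or self.c <= 0:
            raise PlasmaError("Hill 'b' and 'c' must be positive")

    def parent_fraction(self, t):
        t = np.asarray(t, dtype=float)
        tb = np.power(np.maximum(t, 0.0), self.b)
        return 1.0 - self.a * tb / (self.c + tb)

    __call__ = parent_fraction


def fit_parent_fraction(times, fractions) -> HillParams:
    """Least-squares Hill fit to measured parent fractions.

    Multistart over slope/half-time grids; raises on non-convergence with
    the best residual attached.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 3:
        raise PlasmaError("need at least 3 parent-fraction samples")
    if np.any((f < 0) | (f > 1)):
        raise PlasmaError("parent fractions must lie in [0, 1]")

    if np.allclose(f, 1.0):
        return HillParams(a=0.0, b=1.0, c=1.0, degenerate=True)

    def resid(p):
        a, b, c = p
        tb = np.power(t, b)
        return (1.0 - a * tb / (c + tb)) - f

    a0 = float(np.clip(1.0 - f.min(), 1e-3, 1.0))
    best = None
    for b0 in (0.5, 1.0, 1.5, 2.5, 4.0):
        for c0 in (5.0, 25.0, 120.0):
            try:
                sol = least_squares(
                    resid, x0=[a0, b0, c0],
                    bounds=([0.0, 1e-3, 1e-3], [1.0, 12.0, 1e6]),
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise PlasmaError("Hill fit failed to converge from every start")
    a, b, c = best.x
    return HillParams(a=float(a), b=float(b), c=float(c))


# ---------------------------------------------------------------------------
# Input function: piecewise-linear rise + multi-exponential decay


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected parent plasma concentration as a callable curve.

    Before ``peak_time`` the curve is linear interpolation through
    ``prepeak_times``/``prepeak_values`` (always anchored at (0, 0)); at and
    after the peak it is sum_i amplitudes[i] * exp(-rates[i] * (t - peak_time)).
    Rates are canonicalised in decreasing order; amplitudes are non-negative
    so the curve is non-negative everywhere.
    """

    peak_time: float
    amplitudes: np.ndarray            # kBq/mL, >= 0
    rates: np.ndarray                 # 1/min, > 0, decreasing
    prepeak_times: np.ndarray = field(default=None)   # includes 0 and peak_time
    prepeak_values: np.ndarray = field(default=None)
    hill: HillParams | None = None
    support: float = 90.0             # minutes of observed data

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if amps.shape != rates.shape:
            raise PlasmaError("amplitudes and rates must have equal length")
        if np.any(amps < 0) or np.any(rates <= 0):
            raise PlasmaError("amplitudes must be >= 0 and rates > 0")
        order = np.argsort(-rates)
        amps, rates = amps[order], rates[order]
        pt = self.prepeak_times
        pv = self.prepeak_values
        if pt is None:
            if self.peak_time > 0:
                pt = np.array([0.0, self.peak_time])
                pv = np.array([0.0, float(amps.sum())])
            else:
                pt = np.array([0.0])
                pv = np.array([float(amps.sum())])
        else:
            pt = np.asarray(pt, dtype=float)
            pv = np.asarray(pv, dtype=float)
            if pt[0] > 0.0:
                pt = np.concatenate([[0.0], pt])
                pv = np.concatenate([[0.0], pv])
            if not np.isclose(pt[-1], self.peak_time):
                raise PlasmaError("pre-peak knots must end at peak_time")
            if np.any(np.diff(pt) <= 0):
                raise PlasmaError("pre-peak knot times must be strictly increasing")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "prepeak_times", pt)
        object.__setattr__(self, "prepeak_values", pv)

    @property
    def peak_value(self) -> float:
        return float(self.amplitudes.sum())

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.empty_like(t)
        pre = t < self.peak_time
        if pre.any():
            out[pre] = np.interp(t[pre], self.prepeak_times, self.prepeak_values)
        post = ~pre
        if post.any():
            dt = t[post] - self.peak_time
            out[post] = np.exp(-np.outer(dt, self.rates)) @ self.amplitudes
        return float(out[0]) if scalar else out

    def auc(self, extrapolate: bool = True):
        """AUC from 0: exact pre-peak trapezoid + closed-form exponential tail.

        With ``extrapolate`` the tail runs to infinity (the clearance
        convention); otherwise it stops at ``support``.
        """
        pre = float(np.trapezoid(self.prepeak_values, self.prepeak_times))
        tail_inf = float(np.sum(self.amplitudes / self.rates))
        if extrapolate:
            return pre + tail_inf
        horizon = self.support - self.peak_time
        tail = float(np.sum(self.amplitudes / self.rates
                            * (1.0 - np.exp(-self.rates * horizon))))
        return pre + tail

    def tail_fraction_beyond_support(self) -> float:
        """Fraction of total (extrapolated) AUC lying beyond the observed span."""
        total = self.auc(extrapolate=True)
        if total <= 0:
            return 0.0
        return 1.0 - self.auc(extrapolate=False) / total


def _fit_k_exponentials(t, y, k, t0):
    """Best least-squares fit of sum of k decaying exponentials from t0.

    Residuals are relative (plasma counting noise is multiplicative), which
    keeps the slow tail component anchored by the small late samples.
    Variable-projection style multistart: non-negative amplitudes by
    weighted NNLS for log-spaced rate combinations, then a joint bounded
    refinement.
    """
    tt = t - t0
    span = max(tt[-1], 1e-6)
    rate_grid = np.geomspace(0.05 / span, 20.0 / span, 6)
    w = 1.0 / np.maximum(np.abs(y), 1e-6 * max(np.abs(y).max(), 1e-300))

    def model(params):
        lam = np.exp(params[:k])
        amp = params[k:]
        return np.exp(-np.outer(tt, lam)) @ amp

    def resid(params):
        return w * (model(params) - y)

    best = None
    starts = []
    from itertools import combinations
    for combo in combinations(range(len(rate_grid)), k):
        starts.append(rate_grid[list(combo)])
    for lam0 in starts:
        X = np.exp(-np.outer(tt, lam0))
        amp0, _ = nnls(X * w[:, None], y * w)
        x0 = np.concatenate([np.log(lam0), amp0])
        lb = np.concatenate([np.full(k, np.log(1e-6)), np.zeros(k)])
        ub = np.concatenate([np.full(k, np.log(1e3)), np.full(k, np.inf)])
        try:
            sol = least_squares(resid, x0=x0, bounds=(lb, ub),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise PlasmaError(f"{k}-exponential fit failed from every start")
    lam = np.exp(best.x[:k])
    amp = best.x[k:]
    return amp, lam, 2.0 * best.cost  # SSE


def fit_triexponential(times, values, t0=0.0):
    """Fit a (up to) three-term decaying exponential sum from time ``t0``.

    Fits 1-, 2- and 3-term models; the smallest model within a relative SSE
    tie of the best is preferred and padded with zero amplitudes, which makes
    degenerate inputs (true mono-exponentials) recover their single rate
    exactly.  Returns (amplitudes[3], rates[3]) with rates decreasing.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    fits = {}
    for k in (1, 2, 3):
        if t.size >= 2 * k:
            fits[k] = _fit_k_exponentials(t, y, k, t0)
    if not fits:
        raise PlasmaError("not enough samples for an exponential fit")
    best_sse = min(sse for _, _, sse in fits.values())
    tol = best_sse * (1.0 + 1e-6) + 1e-12 * y.size  # SSE is in relative units
    k_sel = min(k for k, (_, _, sse) in fits.items() if sse <= tol)
    amp, lam, _ = fits[k_sel]
    keep = amp > 1e-9 * max(amp.max(), 1e-300)
    amp, lam = amp[keep], lam[keep]
    amps = np.zeros(3)
    rates = np.full(3, 1e-6)
    order = np.argsort(-lam)
    amps[: amp.size] = amp[order]
    rates[: lam.size] = lam[order]
    if amp.size < 3:  # pad with inert terms at the slowest retained rate
        rates[amp.size:] = rates[max(amp.size - 1, 0)]
    return amps, rates


def build_input(raw: PlasmaTimeCourse, hill: HillParams, support: float | None = None) -> InputFunction:
    """Compose the metabolite-corrected input function from raw samples.

    Parent samples are total activity x fitted parent fraction; the peak is
    the maximum parent sample; a triexponential is fitted to samples at and
    after the peak and linear interpolation used before it.  The pre-peak
    segment is pinned to the fitted value at the peak so the composed curve
    is continuous.
    """
    t = raw.sample_times
    parent = raw.total_activity * hill.parent_fraction(t)
    ipk = int(np.argmax(parent))
    if ipk == t.size - 1:
        raise PlasmaError("no decay phase: parent activity peaks at the final sample")
    t_peak = float(t[ipk])
    amps, rates = fit_triexponential(t[ipk:], parent[ipk:], t0=t_peak)
    if t_peak > 0:
        pt = np.concatenate([t[:ipk], [t_peak]])
        pv = np.concatenate([parent[:ipk], [amps.sum()]])
    else:
        pt = np.array([0.0])
        pv = np.array([float(amps.sum())])
    return InputFunction(
        peak_time=t_peak, amplitudes=amps, rates=rates,
        prepeak_times=pt, prepeak_values=pv, hill=hill,
        support=float(support) if support is not None else float(t[-1]),
    )


def compute_clearance(injected_dose: float, inp: InputFunction,
                      tail_warn_fraction: float = 0.30) -> float:
    """Plasma clearance C_L = dose / AUC(0, inf) of the input function, L/h.

    Dose in MBq, curve in kBq/mL and minutes; 1 MBq / (1 kBq/mL * 1 min)
    = 1000 mL/min = 60 L/h.  Warns when the extrapolated tail beyond the
    observed span carries more than ``tail_warn_fraction`` of the AUC.
    """
    if injected_dose <= 0:
        raise PlasmaError("injected dose must be positive")
    auc = inp.auc(extrapolate=True)
    if auc <= 0:
        raise PlasmaError("input-function AUC is zero; clearance undefined")
    tail_frac = inp.tail_fraction_beyond_support()
    if tail_frac > tail_warn_fraction:
        warnings.warn(
            f"extrapolated AUC beyond the observed span is {tail_frac:.0%} of the total",
            RuntimeWarning, stacklevel=2,
        )
    return 60.0 * injected_dose / auc
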