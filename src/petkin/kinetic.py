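"""One- and two-tissue compartment models: forward simulation and fitting.

The reversible two-tissue model has plasma-to-tissue influx K1 (mL/cm³/min),
tissue-to-plasma efflux k2 (1/min) and exchange k3/k4 (1/min) with a specific
(bound) compartment.  Its impulse response is a sum of two exponentials, so

    C_T(t) = [phi1 e^(-theta1 t) + phi2 e^(-theta2 t)] ⊗ C_p(t)

with

    theta_{1,2} = ((k2+k3+k4) ± sqrt((k2+k3+k4)^2 - 4 k2 k4)) / 2
    phi1 = K1 (theta1 - k3 - k4) / (theta1 - theta2)
    phi2 = K1 (k3 + k4 - theta2) / (theta1 - theta2)

The one-tissue model is the k3 = k4 = 0 special case, K1 e^(-k2 t) ⊗ C_p.
Convolution is evaluated exactly for a piecewise-linear input on a fine
uniform grid (default step 0.05 min) via a first-order recursion, then
averaged over each acquisition frame.

Macroparameters: V_ND = K1/k2, BP_ND = k3/k4, V_T = V_ND (1 + BP_ND).

Fitting is bounded multi-start weighted nonlinear least squares, with frame
weights ∝ duration / activity (approximate count statistics).  Standard
errors come from the Gauss–Newton covariance at the optimum scaled by the
reduced chi-square; macroparameter SEs use the delta method.  Estimates with
%SE of V_T below 25% are flagged reliable.  The coupled variant fits all
regions simultaneously with a single shared V_ND (= K1/k2 ratio), region-wise
K1, k3, k4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter
from scipy.stats import qmc

from .blood import InputFunction
from .errors import DomainError, InsufficientDataError

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "CompartmentParams",
    "FitResult",
    "CoupledFitResult",
    "simulate_tissue",
    "fit_region",
    "fit_coupled",
    "compute_aic",
    "derive_fnd",
    "frame_weights",
]

FINE_DT = 0.05  # minutes; convolution grid step
RELIABLE_PCT_SE = 25.0  # %SE threshold below which an estimate counts as reliable
K4_BOUND_TOL = 1e-4  # k4 below this (e-folding ≫ scan length) counts as pinned at 0

# optimiser bounds: K1 in (0, 2] mL/cm³/min, rate constants in [0, 1] 1/min
_K1_BOUNDS = (1e-6, 2.0)
_RATE_BOUNDS = (1e-8, 1.0)
_K34_BOUNDS = (0.0, 1.0)
_VND_BOUNDS = (0.1, 50.0)


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frames as (start, end) times in minutes."""

    start_times: np.ndarray
    end_times: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.start_times, dtype=float)
        e = np.asarray(self.end_times, dtype=float)
        if s.ndim != 1 or len(s) != len(e) or len(s) == 0:
            raise DomainError("frame starts/ends must be 1-D of equal nonzero length")
        if np.any(e <= s):
            raise DomainError("every frame must end after it starts")
        if np.any(s[1:] < e[:-1] - 1e-9) or np.any(np.diff(s) <= 0):
            raise DomainError("frames must be increasing and non-overlapping")
        object.__setattr__(self, "start_times", s)
        object.__setattr__(self, "end_times", e)

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        d = np.asarray(durations, dtype=float)
        e = np.cumsum(d)
        return cls(e - d, e)

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.start_times + self.end_times)

    @property
    def durations(self) -> np.ndarray:
        return self.end_times - self.start_times

    def __len__(self) -> int:
        return len(self.start_times)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity (kBq/cc) for one region."""

    region: str
    frames: FrameSchedule
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.frames):
            raise DomainError("one value per frame required")
        if not np.all(np.isfinite(v)):
            raise DomainError("TAC values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CompartmentParams:
    """Microparameters of the tissue model (k3 = k4 = 0 for one-tissue)."""

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0

    def __post_init__(self):
        if self.K1 < 0:
            raise DomainError("K1 must be non-negative")
        if self.k2 <= 0:
            raise DomainError("k2 must be positive")
        if self.k3 < 0 or self.k4 < 0:
            raise DomainError("k3 and k4 must be non-negative")
        if not 0.0 <= self.vB < 1.0:
            raise DomainError("vB must be in [0, 1)")

    @property
    def VND(self) -> float:
        return self.K1 / self.k2

    @property
    def BPND(self) -> float | None:
        if self.k4 <= 0:
            return None if self.k3 > 0 else 0.0
        return self.k3 / self.k4

    @property
    def VT(self) -> float | None:
        bp = self.BPND
        return None if bp is None else self.VND * (1.0 + bp)


def _exp_conv(theta: float, u: np.ndarray, dt: float) -> np.ndarray:
    """y(t) = ∫_0^t e^{-theta (t-s)} u(s) ds for piecewise-linear u on a uniform grid.

    Exact per-step update y_{i+1} = E y_i + u_i f1 + (u_{i+1}-u_i) f2 with
    E = e^{-theta dt}, evaluated as a first-order IIR filter.
    """
    if theta * dt < 1e-12:
        # theta -> 0 limit: running trapezoid integral
        inc = np.zeros_like(u)
        inc[1:] = 0.5 * dt * (u[1:] + u[:-1])
        return np.cumsum(inc)
    E = math.exp(-theta * dt)
    f1 = (1.0 - E) / theta
    f2 = (dt - f1) / (theta * dt)
    d = np.zeros_like(u)
    d[1:] = u[:-1] * (f1 - f2) + u[1:] * f2
    return lfilter([1.0], [1.0, -E], d)


def _impulse_terms(p: CompartmentParams) -> list[tuple[float, float]]:
    """(coefficient, rate) pairs of the tissue impulse response."""
    if p.k3 <= 0.0:
        # one-tissue (a lone reversible compartment); k4 is irrelevant
        return [(p.K1, p.k2)]
    s = p.k2 + p.k3 + p.k4
    disc = s * s - 4.0 * p.k2 * p.k4
    assert disc >= -1e-12, "discriminant negative for non-negative rates"
    root = math.sqrt(max(disc, 0.0))
    th1 = 0.5 * (s + root)
    th2 = 0.5 * (s - root)
    if th1 - th2 < 1e-10:
        th2 = th1 - 1e-10  # repeated-root guard (measure-zero parameter set)
    phi1 = p.K1 * (th1 - p.k3 - p.k4) / (th1 - th2)
    phi2 = p.K1 * (p.k3 + p.k4 - th2) / (th1 - th2)
    return [(phi1, th1), (phi2, th2)]


def _frame_average(grid: np.ndarray, curve: np.ndarray, frames: FrameSchedule) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (curve[1:] + curve[:-1]) * np.diff(grid))])
    i_start = np.interp(frames.start_times, grid, cum)
    i_end = np.interp(frames.end_times, grid, cum)
    return (i_end - i_start) / frames.durations


def simulate_tissue(
    params: CompartmentParams,
    input_function: InputFunction,
    frames: FrameSchedule,
    dt: float = FINE_DT,
    whole_blood: InputFunction | None = None,
) -> TimeActivityCurve:
    """Forward-simulate the frame-averaged tissue curve for one region.

    The analytic exponential convolution is evaluated on a uniform grid of
    step ``dt`` and averaged over each frame.  With ``params.vB > 0`` the
    measured signal is (1-vB)·C_T + vB·C_wb and a whole-blood curve is
    required.
    """
    t_end = float(frames.end_times[-1])
    if not input_function.covers(t_end):
        raise DomainError(
            f"input function ends at {input_function.end_time:g} min but frames "
            f"extend to {t_end:g} min"
        )
    grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    cp = input_function.interpolate(grid)
    ct = np.zeros_like(grid)
    if params.K1 > 0:
        for coef, rate in _impulse_terms(params):
            ct += coef * _exp_conv(rate, cp, dt)
    values = _frame_average(grid, ct, frames)
    if params.vB > 0:
        if whole_blood is None:
            raise DomainError("vB > 0 requires a whole-blood curve")
        wb = whole_blood.interpolate(grid)
        values = (1.0 - params.vB) * values + params.vB * _frame_average(grid, wb, frames)
    return TimeActivityCurve(region="simulated", frames=frames, values=values)


def frame_weights(tac: TimeActivityCurve, eps_frac: float = 0.01) -> np.ndarray:
    """Weights ∝ frame duration / activity, guarding near-zero frames.

    Approximates count-statistics weighting: frame variance scales like
    activity divided by duration.  ``eps_frac`` floors the activity at a
    fraction of the curve maximum.
    """
    peak = float(np.max(np.abs(tac.values)))
    if peak <= 0:
        return tac.frames.durations.copy()
    floor = eps_frac * peak
    return tac.frames.durations / np.maximum(np.abs(tac.values), floor)


def compute_aic(rss: float, n_frames: int, n_params: int) -> float:
    """Akaike information criterion AIC = n ln(rss/n) + 2k for LS fits."""
    if rss <= 0:
        raise DomainError("rss must be positive")
    if n_frames <= n_params:
        raise DomainError("need more frames than parameters")
    return n_frames * math.log(rss / n_frames) + 2 * n_params


def derive_fnd(fp: float, vnd: float) -> float:
    """Tissue free fraction f_ND = f_p / V_ND."""
    if vnd <= 0:
        raise DomainError("V_ND must be positive")
    if not 0 < fp <= 1:
        raise DomainError("f_p must be in (0, 1]")
    return fp / vnd


@dataclass(frozen=True)
class FitResult:
    """One region's compartment-model fit with uncertainties and flags."""

    model: str  # "1T" or "2T"
    params: CompartmentParams
    se: dict
    percent_se: dict
    covariance: np.ndarray | None
    rss: float  # weighted residual sum of squares
    aic: float
    VT: float | None
    VND: float
    BPND: float | None
    macro_se: dict
    converged: bool
    irreversible_limit: bool = False
    region: str = ""
    n_frames: int = 0

    @property
    def reliable(self) -> bool:
        """%SE of V_T below the 25% reliability threshold (and converged)."""
        if not self.converged or self.VT is None:
            return False
        pse = self.macro_se.get("VT_percent")
        return pse is not None and np.isfinite(pse) and pse < RELIABLE_PCT_SE


@dataclass(frozen=True)
class CoupledFitResult:
    """Simultaneous all-region 2T fit with one shared V_ND = K1/k2."""

    shared_VND: float
    shared_VND_se: float
    per_region: dict
    joint_covariance: np.ndarray | None
    rss: float
    converged: bool

    @property
    def mean_bpnd(self) -> float:
        vals = [r.BPND for r in self.per_region.values() if r.BPND is not None]
        if not vals:
            raise DomainError("no region produced a defined BP_ND")
        return float(np.mean(vals))


def _lhs_starts(bounds_lo, bounds_hi, n: int, seed: int) -> np.ndarray:
    lo = np.asarray(bounds_lo)
    hi = np.asarray(bounds_hi)
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    u = sampler.random(n)
    # sample rate-like parameters on a log scale to spread starts over decades
    lo_s = np.log(np.maximum(lo, 1e-4))
    hi_s = np.log(hi)
    return np.exp(lo_s + u * (hi_s - lo_s))


def _gauss_newton_cov(jac: np.ndarray, wrss: float, n: int, p: int) -> np.ndarray | None:
    """Covariance = (JᵀJ)⁻¹ · s² with s² the reduced chi-square.

    ``jac`` is the Jacobian of the *weighted* residuals, so JᵀJ is the
    weighted normal matrix.
    """
    if n <= p:
        return None
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    return cov * (wrss / (n - p))


def _macro_delta_se(params: CompartmentParams, cov: np.ndarray | None, order) -> dict:
    """Delta-method SEs for V_T, V_ND, BP_ND.

    ``order`` maps parameter names ("K1", "k2", "k3", "k4") to covariance
    row indices; parameters absent from the map are treated as fixed.
    """
    out = {}
    if cov is None:
        return out
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4

    def grad_to_se(grad: dict) -> float:
        g = np.zeros(cov.shape[0])
        for name, val in grad.items():
            if name in order:
                g[order[name]] = val
        return float(np.sqrt(max(g @ cov @ g, 0.0)))

    vnd = K1 / k2
    out["VND"] = grad_to_se({"K1": 1.0 / k2, "k2": -K1 / k2**2})
    out["VND_percent"] = 100.0 * out["VND"] / vnd if vnd > 0 else np.inf
    if k4 > K4_BOUND_TOL:
        bp = k3 / k4
        vt = vnd * (1.0 + bp)
        out["BPND"] = grad_to_se({"k3": 1.0 / k4, "k4": -k3 / k4**2})
        out["BPND_percent"] = 100.0 * out["BPND"] / bp if bp > 0 else np.inf
        out["VT"] = grad_to_se(
            {
                "K1": vt / K1,
                "k2": -vt / k2,
                "k3": K1 / (k2 * k4),
                "k4": -K1 * k3 / (k2 * k4**2),
            }
        )
        out["VT_percent"] = 100.0 * out["VT"] / vt if vt > 0 else np.inf
    elif k3 <= K4_BOUND_TOL:
        # one-tissue: V_T = V_ND
        out["VT"] = out["VND"]
        out["VT_percent"] = out["VND_percent"]
    return out


def _build_fit_result(
    model: str,
    region: str,
    params: CompartmentParams,
    cov: np.ndarray | None,
    order: dict,
    names: list,
    wrss: float,
    n_frames: int,
    converged: bool,
) -> FitResult:
    se = {}
    pse = {}
    if cov is not None:
        for name in names:
            i = order[name]
            s = float(np.sqrt(max(cov[i, i], 0.0)))
            se[name] = s
            val = getattr(params, name)
            pse[name] = 100.0 * s / abs(val) if abs(val) > 0 else np.inf
    irreversible = model == "2T" and params.k4 <= K4_BOUND_TOL and params.k3 > K4_BOUND_TOL
    bp = None if irreversible else params.BPND
    vt = None if irreversible else params.VT
    macro = _macro_delta_se(params, cov, order)
    k = len(names)
    aic = compute_aic(max(wrss, 1e-300), n_frames, k) if n_frames > k else np.nan
    return FitResult(
        model=model,
        params=params,
        se=se,
        percent_se=pse,
        covariance=cov,
        rss=wrss,
        aic=aic,
        VT=vt,
        VND=params.VND,
        BPND=bp,
        macro_se=macro,
        converged=converged,
        irreversible_limit=irreversible,
        region=region,
        n_frames=n_frames,
    )


def fit_region(
    model: str,
    tac: TimeActivityCurve,
    input_function: InputFunction,
    *,
    weights: np.ndarray | None = None,
    n_starts: int = 10,
    seed: int = 20210407,
    dt: float = FINE_DT,
) -> FitResult:
    """Weighted NLS fit of a single region with one- or two-tissue kinetics.

    ``model`` is "1T" or "2T".  Multi-start from a deterministic Latin
    hypercube; the best (lowest weighted RSS) converged start wins.  A 2T fit
    whose k4 lands on the zero bound is reported converged but flagged
    ``irreversible_limit`` with BP_ND and V_T undefined.
    """
    model = model.upper().replace("CM", "").replace("TC", "T")
    if model not in ("1T", "2T"):
        raise DomainError(f"model must be '1T' or '2T', got {model!r}")
    if not input_function.covers(float(tac.frames.end_times[-1])):
        raise DomainError("input function does not cover the TAC frames")
    w = frame_weights(tac) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    data = tac.values
    n = len(data)

    if model == "1T":
        names = ["K1", "k2"]
        lo = [_K1_BOUNDS[0], _RATE_BOUNDS[0]]
        hi = [_K1_BOUNDS[1], _RATE_BOUNDS[1]]
        to_params = lambda x: CompartmentParams(K1=x[0], k2=x[1])
    else:
        names = ["K1", "k2", "k3", "k4"]
        lo = [_K1_BOUNDS[0], _RATE_BOUNDS[0], _K34_BOUNDS[0], _K34_BOUNDS[0]]
        hi = [_K1_BOUNDS[1], _RATE_BOUNDS[1], _K34_BOUNDS[1], _K34_BOUNDS[1]]
        to_params = lambda x: CompartmentParams(K1=x[0], k2=x[1], k3=x[2], k4=x[3])

    def resid(x):
        sim = simulate_tissue(to_params(x), input_function, tac.frames, dt=dt)
        return sw * (sim.values - data)

    starts = _lhs_starts(np.maximum(lo, 1e-4), hi, n_starts, seed)
    # deterministic mid-range start reflecting typical grey-matter kinetics
    starts = np.vstack([[0.3, 0.05, 0.03, 0.03][: len(names)], starts])
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                x_scale="jac", xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        params = to_params(np.clip(starts[0], lo, hi))
        return _build_fit_result(
            model, tac.region, params, None, {}, names, np.inf, n, converged=False
        )
    x = best.x.copy()
    if model == "2T" and x[3] <= K4_BOUND_TOL:
        x[3] = 0.0
    params = to_params(x)
    wrss = float(2 * best.cost)
    order = {name: i for i, name in enumerate(names)}
    cov = _gauss_newton_cov(best.jac, wrss, n, len(names))
    return _build_fit_result(model, tac.region, params, cov, order, names, wrss, n, True)


def fit_coupled(
    tacs,
    input_function: InputFunction,
    *,
    weights: dict | None = None,
    n_starts: int = 6,
    seed: int = 20210407,
    dt: float = FINE_DT,
) -> CoupledFitResult:
    """Simultaneous 2T fit of all regions with one shared V_ND (= K1/k2).

    Parameter vector: [V_ND, then (K1, k3, k4) per region]; each region's
    k2 is K1/V_ND.  Residuals from every region are stacked into a single
    weighted least-squares problem, so the joint covariance propagates the
    shared-parameter uncertainty into every region's %SE.
    """
    tacs = list(tacs)
    if len(tacs) < 2:
        raise InsufficientDataError("coupled fit needs at least 2 regions")
    frames = tacs[0].frames
    for tac in tacs:
        if not input_function.covers(float(tac.frames.end_times[-1])):
            raise DomainError(f"input function does not cover region {tac.region!r}")
    sw = {}
    for tac in tacs:
        w = (
            weights[tac.region]
            if weights is not None and tac.region in weights
            else frame_weights(tac)
        )
        sw[tac.region] = np.sqrt(np.asarray(w, dtype=float))

    R = len(tacs)

    def unpack(x):
        vnd = x[0]
        out = []
        for r in range(R):
            K1, k3, k4 = x[1 + 3 * r : 4 + 3 * r]
            out.append(CompartmentParams(K1=K1, k2=K1 / vnd, k3=k3, k4=max(k4, 0.0)))
        return vnd, out

    def resid(x):
        _, plist = unpack(x)
        parts = []
        for tac, p in zip(tacs, plist):
            sim = simulate_tissue(p, input_function, tac.frames, dt=dt)
            parts.append(sw[tac.region] * (sim.values - tac.values))
        return np.concatenate(parts)

    lo = [_VND_BOUNDS[0]] + [_K1_BOUNDS[0], 0.0, 0.0] * R
    hi = [_VND_BOUNDS[1]] + [_K1_BOUNDS[1], 1.0, 1.0] * R
    base = _lhs_starts([1.0, 0.05, 1e-3, 1e-3], [20.0, 1.0, 0.2, 0.2], n_starts, seed)
    starts = [np.concatenate([[b[0]], np.tile(b[1:], R)]) for b in base]
    starts.insert(0, np.concatenate([[8.0], np.tile([0.37, 0.03, 0.03], R)]))

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                x_scale="jac", xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return CoupledFitResult(
            shared_VND=np.nan, shared_VND_se=np.nan, per_region={},
            joint_covariance=None, rss=np.inf, converged=False,
        )

    vnd, plist = unpack(best.x)
    wrss = float(2 * best.cost)
    n_total = sum(len(t.values) for t in tacs)
    n_par = 1 + 3 * R
    cov = _gauss_newton_cov(best.jac, wrss, n_total, n_par)
    vnd_se = float(np.sqrt(max(cov[0, 0], 0.0))) if cov is not None else np.nan

    per_region = {}
    for r, (tac, p) in enumerate(zip(tacs, plist)):
        idx = [0, 1 + 3 * r, 2 + 3 * r, 3 + 3 * r]  # VND, K1, k3, k4
        sub = cov[np.ix_(idx, idx)] if cov is not None else None
        # transform (VND, K1, k3, k4) -> (K1, k2, k3, k4); k2 = K1/VND
        if sub is not None:
            J = np.zeros((4, 4))
            J[0, 1] = 1.0  # K1
            J[1, 0] = -p.K1 / vnd**2  # dk2/dVND
            J[1, 1] = 1.0 / vnd  # dk2/dK1
            J[2, 2] = 1.0
            J[3, 3] = 1.0
            sub = J @ sub @ J.T
        order = {"K1": 0, "k2": 1, "k3": 2, "k4": 3}
        n_frames = len(tac.values)
        sim = simulate_tissue(p, input_function, tac.frames, dt=dt)
        region_wrss = float(np.sum((sw[tac.region] * (sim.values - tac.values)) ** 2))
        fr = _build_fit_result(
            "2T", tac.region, p, sub, order, ["K1", "k2", "k3", "k4"],
            region_wrss, n_frames, converged=True,
        )
        per_region[tac.region] = fr

    return CoupledFitResult(
        shared_VND=float(vnd),
        shared_VND_se=vnd_se,
        per_region=per_region,
        joint_covariance=cov,
        rss=wrss,
        converged=True,
    )
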