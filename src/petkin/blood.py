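"""Arterial blood processing: metabolite correction and blood-derived scalars.

The arterial input to the kinetic models is the *metabolite-corrected* plasma
activity C_p(t): total plasma activity multiplied by the fraction of activity
still attributable to intact parent ligand.  The parent fraction is modelled
as a two-exponential decay constrained to 1 at injection time,

    pf(t) = A1 exp(-lambda1 t) + (1 - A1) exp(-lambda2 t),

fitted to the HPLC parent-fraction measurements.  All times are minutes post
injection; all activities are assumed decay-corrected to injection time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitFailureError, InsufficientDataError

__all__ = [
    "BloodSeries",
    "ParentFractionModel",
    "InputFunction",
    "fit_parent_fraction",
    "build_mcaif",
    "free_fraction",
    "plasma_wb_ratio",
]


@dataclass(frozen=True)
class BloodSeries:
    """Whole-blood and plasma activity sampled at common times.

    times
        Minutes post injection, strictly increasing, starting at >= 0.
    whole_blood, plasma
        Activity concentrations in kBq/cc, non-negative, same length as times.
    """

    times: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        wb = np.asarray(self.whole_blood, dtype=float)
        pl = np.asarray(self.plasma, dtype=float)
        if not (t.ndim == wb.ndim == pl.ndim == 1):
            raise DomainError("blood series must be 1-D arrays")
        if not (len(t) == len(wb) == len(pl)):
            raise DomainError("times, whole_blood and plasma must have equal length")
        if len(t) and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise DomainError("sample times must be strictly increasing and start >= 0")
        if np.any(wb < 0) or np.any(pl < 0):
            raise DomainError("activities must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "whole_blood", wb)
        object.__setattr__(self, "plasma", pl)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ParentFractionModel:
    """Biexponential intact-parent fraction with pf(0) = 1.

    ``a1`` is the fast-component amplitude; the slow amplitude is 1 - a1 so
    the fraction is exactly 1 at injection.  ``lambda1``/``lambda2`` are decay
    rates in 1/min.  ``rss`` carries the residual sum of squares of the fit
    that produced the model (None for hand-constructed models).
    """

    a1: float
    lambda1: float
    lambda2: float
    rss: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if not 0.0 <= self.a1 <= 1.0:
            raise DomainError(f"a1 must be in [0, 1], got {self.a1}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise DomainError("decay rates must be non-negative")

    @property
    def a2(self) -> float:
        return 1.0 - self.a1

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-self.lambda1 * t) + self.a2 * np.exp(-self.lambda2 * t)


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected arterial plasma input function C_p(t).

    Values between samples are linearly interpolated; before the first sample
    the curve rises linearly from (0, 0).  The function is not defined beyond
    the last sample — callers must check :meth:`covers`.
    """

    times: np.ndarray
    values: np.ndarray
    source_blood: BloodSeries | None = None
    pf_model: ParentFractionModel | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v) or t.ndim != 1:
            raise DomainError("times and values must be 1-D of equal length")
        if len(t) and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise DomainError("times must be strictly increasing and start >= 0")
        if np.any(v < 0):
            raise DomainError("input-function values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    def covers(self, t_max: float, tol: float = 1e-9) -> bool:
        return t_max <= self.end_time + tol

    def _anchored(self) -> tuple[np.ndarray, np.ndarray]:
        if self.times[0] > 0:
            return np.concatenate([[0.0], self.times]), np.concatenate([[0.0], self.values])
        return self.times, self.values

    def interpolate(self, t) -> np.ndarray:
        """Piecewise-linear C_p at arbitrary times (zero-anchored at t=0)."""
        ta, va = self._anchored()
        return np.interp(np.asarray(t, dtype=float), ta, va)

    def cumulative_integral(self, t) -> np.ndarray:
        """∫_0^t C_p dτ by exact trapezoid on the anchored polyline."""
        ta, va = self._anchored()
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (va[1:] + va[:-1]) * np.diff(ta))])
        t = np.asarray(t, dtype=float)
        # exact for the piecewise-linear curve: integral of the interpolant
        idx = np.clip(np.searchsorted(ta, t, side="right") - 1, 0, len(ta) - 2)
        t0, t1 = ta[idx], ta[idx + 1]
        v0, v1 = va[idx], va[idx + 1]
        frac = np.where(t1 > t0, (t - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
        vt = v0 + frac * (v1 - v0)
        return cum[idx] + 0.5 * (v0 + vt) * (t - t0)


def fit_parent_fraction(samples, n_starts: int = 8) -> ParentFractionModel:
    """Fit the constrained biexponential pf(t) to (time, fraction) samples.

    Ordinary (uniform-weight) least squares on the fraction scale with a
    multi-start over log-spaced decay-rate pairs to avoid local minima.
    Returns the model with its residual sum of squares attached.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 samples.
    DomainError
        Fractions outside [0, 1] or non-increasing times.
    FitFailureError
        No start converged; the best candidate is attached.
    """
    samples = [(float(t), float(f)) for t, f in samples]
    if len(samples) < 4:
        raise InsufficientDataError(
            f"need at least 4 parent-fraction samples, got {len(samples)}"
        )
    t = np.array([s[0] for s in samples])
    f = np.array([s[1] for s in samples])
    if np.any(np.diff(t) <= 0):
        raise DomainError("sample times must be distinct and increasing")
    if np.any((f < 0) | (f > 1)):
        raise DomainError("fractions must lie in [0, 1]")

    def resid(p):
        a1, l1, l2 = p
        return a1 * np.exp(-l1 * t) + (1 - a1) * np.exp(-l2 * t) - f

    # Degenerate but valid data: constant fraction 1 everywhere.
    if np.allclose(f, 1.0):
        return ParentFractionModel(1.0, 0.0, 0.0, rss=float(np.sum((1.0 - f) ** 2)))

    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([1.0, 5.0, 5.0])
    # log-spaced (fast, slow) rate pairs spanning plausible metabolism speeds
    fast = np.geomspace(0.02, 1.0, max(2, n_starts // 2))
    slow = np.geomspace(1e-3, 0.05, 2)
    starts = [(0.6, lf, ls) for lf in fast for ls in slow][:n_starts]
    if len(starts) < n_starts:
        starts += [(0.3, lf, 0.01) for lf in fast][: n_starts - len(starts)]

    best = None
    for x0 in starts:
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        candidate = None
        if best is not None:
            a1, l1, l2 = _canonical(best.x)
            candidate = ParentFractionModel(a1, l1, l2, rss=float(2 * best.cost))
        raise FitFailureError("parent-fraction fit did not converge", best=candidate)
    a1, l1, l2 = _canonical(best.x)
    return ParentFractionModel(a1, l1, l2, rss=float(2 * best.cost))


def _canonical(p):
    """Order components so lambda1 >= lambda2 (fast component first)."""
    a1, l1, l2 = p
    if l2 > l1:
        a1, l1, l2 = 1.0 - a1, l2, l1
    return float(a1), float(l1), float(l2)


def build_mcaif(blood: BloodSeries, pf: ParentFractionModel) -> InputFunction:
    """Metabolite-corrected input: plasma activity × parent fraction, pointwise."""
    pf_vals = np.clip(pf(blood.times), 0.0, 1.0)
    return InputFunction(
        times=blood.times,
        values=blood.plasma * pf_vals,
        source_blood=blood,
        pf_model=pf,
    )


def free_fraction(ultrafiltrate_counts: float, plasma_counts: float, replicates=None):
    """Plasma free fraction f_p = CFP/CP from ultrafiltration counts.

    With ``replicates`` (an iterable of per-replicate ratios) the mean and the
    standard error of the mean (sd/sqrt(n)) are returned instead.
    """
    if replicates is not None:
        r = np.asarray(list(replicates), dtype=float)
        if len(r) < 1:
            raise DomainError("replicates must be non-empty")
        sem = float(np.std(r, ddof=1) / np.sqrt(len(r))) if len(r) > 1 else 0.0
        return float(np.mean(r)), sem
    if plasma_counts <= 0:
        raise DomainError("plasma counts must be positive")
    return float(ultrafiltrate_counts) / float(plasma_counts)


@dataclass(frozen=True)
class PlasmaWholeBloodRatio:
    times: np.ndarray
    ratios: np.ndarray
    mean: float
    sd: float


def plasma_wb_ratio(blood: BloodSeries) -> PlasmaWholeBloodRatio:
    """Pointwise plasma/whole-blood ratio with its time-averaged mean ± SD.

    Samples with zero whole-blood activity are excluded with a warning.
    """
    ok = blood.whole_blood > 0
    if not np.all(ok):
        warnings.warn(
            f"excluded {int(np.sum(~ok))} sample(s) with zero whole-blood activity",
            stacklevel=2,
        )
    t = blood.times[ok]
    r = blood.plasma[ok] / blood.whole_blood[ok]
    if len(r) == 0:
        raise DomainError("no usable samples for the plasma/whole-blood ratio")
    sd = float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
    return PlasmaWholeBloodRatio(times=t, ratios=r, mean=float(np.mean(r)), sd=sd)
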