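"""Graphical (linearized) estimation of the total distribution volume V_T.

Logan analysis regresses the running tissue integral normalized by the
instantaneous tissue activity against the similarly normalized plasma
integral; after an equilibration time t* the relation is linear with slope
V_T for reversible tracers:

    ∫_0^t C_T dτ / C_T(t)  =  V_T · ∫_0^t C_p dτ / C_T(t)  +  b,   t >= t*

MA1 is the multilinear rearrangement, regressing C_T(t) itself on the two
integrals (no intercept), which reduces the noise-induced negative bias of
the Logan slope:

    C_T(t) = -V_T/b · ∫_0^t C_p dτ  +  1/b · ∫_0^t C_T dτ,   V_T = -β1/β2.

Frame time for the t* threshold is the frame mid-time; tissue integrals use
trapezoids over the mid-time nodes with a (0, 0) anchor, plasma integrals the
exact integral of the interpolated input function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .blood import InputFunction
from .errors import DomainError, InsufficientDataError
from .kinetic import TimeActivityCurve

__all__ = ["GraphicalFit", "logan_fit", "ma1_fit"]


@dataclass(frozen=True)
class GraphicalFit:
    """Result of a graphical V_T estimate."""

    method: str
    VT: float
    intercept: float
    tstar: float
    r_squared: float
    n_points: int
    region: str = ""


def _late_window(tac: TimeActivityCurve, tstar: float):
    mid = tac.frames.mid_times
    mask = mid >= tstar
    pos = tac.values > 0
    if np.any(mask & ~pos):
        warnings.warn(
            f"excluded {int(np.sum(mask & ~pos))} non-positive frame(s) after t*",
            stacklevel=3,
        )
    mask &= pos
    if int(np.sum(mask)) < 3:
        raise InsufficientDataError(
            f"need at least 3 usable frames with mid-time >= t* = {tstar:g} min"
        )
    return mid, mask


def _integrals(tac: TimeActivityCurve, input_function: InputFunction, mid: np.ndarray):
    if not input_function.covers(float(tac.frames.end_times[-1])):
        raise DomainError("input function does not cover the TAC frames")
    # tissue integral: trapezoid over mid-time nodes anchored at (0, 0)
    t_nodes = np.concatenate([[0.0], mid])
    c_nodes = np.concatenate([[0.0], tac.values])
    int_ct = np.cumsum(0.5 * (c_nodes[1:] + c_nodes[:-1]) * np.diff(t_nodes))
    int_cp = input_function.cumulative_integral(mid)
    return int_ct, int_cp


def logan_fit(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    tstar: float = 60.0,
) -> GraphicalFit:
    """Logan graphical V_T (slope of the late linear segment)."""
    mid, mask = _late_window(tac, tstar)
    int_ct, int_cp = _integrals(tac, input_function, mid)
    ct = tac.values[mask]
    y = int_ct[mask] / ct
    x = int_cp[mask] / ct
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GraphicalFit(
        method="logan",
        VT=float(slope),
        intercept=float(intercept),
        tstar=float(tstar),
        r_squared=r2,
        n_points=int(np.sum(mask)),
        region=tac.region,
    )


def ma1_fit(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    tstar: float = 60.0,
) -> GraphicalFit:
    """MA1 multilinear V_T = -β1/β2 from C_T ~ β1·∫C_p + β2·∫C_T (t >= t*)."""
    mid, mask = _late_window(tac, tstar)
    int_ct, int_cp = _integrals(tac, input_function, mid)
    X = np.column_stack([int_cp[mask], int_ct[mask]])
    y = tac.values[mask]
    beta, res_ss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2 or abs(beta[1]) < 1e-300:
        raise DomainError("MA1 design matrix is rank-deficient")
    yhat = X @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GraphicalFit(
        method="ma1",
        VT=float(-beta[0] / beta[1]),
        intercept=float(1.0 / beta[1]),
        tstar=float(tstar),
        r_squared=r2,
        n_points=int(np.sum(mask)),
        region=tac.region,
    )
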