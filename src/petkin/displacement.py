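"""Displacement-study analysis and receptor-occupancy arithmetic.

A displacement scan administers a competitor at ``drug_time`` (90 min in the
reference design) during the acquisition.  Curves are converted to SUV,
normalized to the frame immediately preceding drug administration, baseline
curves are averaged pointwise, and percent displacement is

    100 · (B(t) − D(t)) / B(t)

evaluated at a chosen time post drug.  Occupancy arithmetic follows the
single-site binding isotherm occ = C/(C + K_D); the displaceable fraction f
of total uptake implies BP_ND = f/(1 − f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .kinetic import FrameSchedule, TimeActivityCurve

__all__ = [
    "DisplacementDesign",
    "NormalizedTAC",
    "to_suv",
    "normalize_at",
    "average_baselines",
    "percent_displacement",
    "occupancy_isotherm",
    "implied_bpnd",
    "occupancy_from_displacement",
]


@dataclass(frozen=True)
class DisplacementDesign:
    """When and what was administered, and when displacement is read out."""

    drug_time: float = 90.0  # minutes post tracer injection
    drug: str = ""
    dose: float = 0.0  # mass per kg (units given by the drug label)
    eval_time: float = 35.0  # minutes post drug administration

    def __post_init__(self):
        if self.drug_time <= 0:
            raise DomainError("drug_time must be positive")
        if self.eval_time <= 0:
            raise DomainError("eval_time must be positive")


@dataclass(frozen=True)
class NormalizedTAC:
    """SUV curve divided by its value at the normalization anchor frame."""

    frames: FrameSchedule
    values: np.ndarray
    anchor_index: int
    region: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.frames):
            raise DomainError("one value per frame required")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.frames.mid_times


def to_suv(tac: TimeActivityCurve, injected_dose_mbq: float, body_weight_kg: float) -> TimeActivityCurve:
    """Standardized uptake value: C(t)[kBq/cc] / (dose[kBq]/weight[g]).

    With dose in MBq and weight in kg the normalizer reduces to dose/weight,
    i.e. SUV(t) = C(t) · weight_kg / dose_MBq.
    """
    if injected_dose_mbq <= 0 or body_weight_kg <= 0:
        raise DomainError("injected dose and body weight must be positive")
    factor = (injected_dose_mbq * 1000.0) / (body_weight_kg * 1000.0)  # kBq/g
    return TimeActivityCurve(
        region=tac.region, frames=tac.frames, values=tac.values / factor
    )


def _anchor_frame(frames: FrameSchedule, t_norm: float) -> int:
    """Last frame ending at or before t_norm (the pre-drug frame)."""
    idx = np.nonzero(frames.end_times <= t_norm + 1e-9)[0]
    if len(idx) == 0:
        raise DomainError(f"no frame ends at or before t = {t_norm:g} min")
    return int(idx[-1])


def normalize_at(tac: TimeActivityCurve, t_norm: float = 90.0) -> NormalizedTAC:
    """Divide an SUV curve by its value in the last frame ending <= t_norm."""
    i = _anchor_frame(tac.frames, t_norm)
    anchor = tac.values[i]
    if anchor <= 0:
        raise DomainError("anchor frame value must be positive")
    return NormalizedTAC(
        frames=tac.frames, values=tac.values / anchor, anchor_index=i, region=tac.region
    )


def average_baselines(baselines) -> NormalizedTAC:
    """Pointwise average of >= 1 normalized baseline curves on a shared grid."""
    baselines = list(baselines)
    if not baselines:
        raise DomainError("need at least one baseline curve")
    ref = baselines[0]
    for b in baselines[1:]:
        if len(b.values) != len(ref.values) or not np.allclose(
            b.frames.mid_times, ref.frames.mid_times
        ):
            raise DomainError("baseline curves must share a frame grid")
    avg = np.mean([b.values for b in baselines], axis=0)
    return NormalizedTAC(
        frames=ref.frames, values=avg, anchor_index=ref.anchor_index, region=ref.region
    )


def percent_displacement(
    baselines,
    displaced: NormalizedTAC,
    eval_time: float,
    drug_time: float = 90.0,
):
    """Percent displacement at ``eval_time`` minutes post drug.

    Baselines are averaged pointwise first; the readout is taken from the
    frame covering drug_time + eval_time.  Returns (value_percent, series)
    where series is the full displacement-vs-time curve (percent, one entry
    per frame).
    """
    base = average_baselines(baselines)
    if len(displaced.values) != len(base.values) or not np.allclose(
        displaced.frames.mid_times, base.frames.mid_times
    ):
        raise DomainError("displaced curve must share the baseline frame grid")
    t_eval = drug_time + eval_time
    frames = base.frames
    if t_eval > frames.end_times[-1] + 1e-9 or t_eval < frames.start_times[0]:
        raise DomainError(
            f"evaluation time {t_eval:g} min is outside the scanned window"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        series = 100.0 * (base.values - displaced.values) / base.values
    cover = np.nonzero(
        (frames.start_times <= t_eval + 1e-9) & (t_eval <= frames.end_times + 1e-9)
    )[0]
    if len(cover) == 0:  # t_eval in a gap between frames: use the nearest mid-time
        cover = [int(np.argmin(np.abs(frames.mid_times - t_eval)))]
    return float(series[cover[0]]), series


def occupancy_isotherm(free_conc: float, kd: float) -> float:
    """Single-site occupancy C/(C + K_D); concentrations in the same units."""
    if kd <= 0:
        raise DomainError("K_D must be positive")
    if free_conc < 0:
        raise DomainError("free concentration must be non-negative")
    return free_conc / (free_conc + kd)


def implied_bpnd(max_displaceable_fraction: float) -> float:
    """BP_ND implied by the maximal displaceable fraction f of total uptake.

    At full target occupancy the specific signal V_S/V_T = BP/(1+BP) is
    removed, so f = BP/(1+BP) and BP_ND = f/(1 − f).
    """
    f = max_displaceable_fraction
    if not 0.0 <= f < 1.0:
        raise DomainError("displaceable fraction must be in [0, 1)")
    return f / (1.0 - f)


def occupancy_from_displacement(observed_pct: float, max_pct: float) -> float:
    """Occupancy (%) = observed displacement relative to the maximal one."""
    if not 0.0 < max_pct <= 100.0:
        raise DomainError("maximal displacement must be in (0, 100]")
    if observed_pct < 0.0 or observed_pct > max_pct:
        raise DomainError("observed displacement must be in [0, max]")
    return 100.0 * observed_pct / max_pct
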