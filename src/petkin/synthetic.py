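"""Synthetic PET studies with the reference design's statistical structure.

Generates complete studies — arterial blood tables, parent-fraction samples,
regional TACs for test/retest sessions, and displacement arms — from known
ground-truth kinetics, so every analysis stage can be validated without any
acquired data.

The emulated design: 7 brain regions (6 grey + white matter) plus whole
brain, two-tissue kinetics with a shared non-displaceable volume
V_ND = 7.89 mL/cm³, grey-matter influx K1 = 0.37 mL/cm³/min and regional
specific-binding ratios k3/k4 averaging 1.07; a 2-h frame schedule with fine
early frames (extendable to 4 h); 28 arterial samples for 2-h scans (34 for
4-h) front-loaded in the first 5 minutes; a biexponential intact-parent
fraction; a stable plasma/whole-blood ratio of 0.90; and displacement by a
competitor administered at 90 min.

The plasma input has an invented but physiologic shape (linear rise to an
early peak, three-exponential washout); TAC noise is zero-mean Gaussian with
variance proportional to activity over frame duration.  All randomness is
seeded; identical config + seed regenerates bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .blood import BloodSeries, InputFunction, ParentFractionModel, build_mcaif
from .errors import DomainError
from .kinetic import CompartmentParams, FrameSchedule, TimeActivityCurve, simulate_tissue

__all__ = [
    "RegionTruth",
    "StudyConfig",
    "SyntheticStudy",
    "two_hour_frames",
    "four_hour_frames",
    "blood_sample_times",
    "make_input_function",
    "make_tacs",
    "make_displacement_arm",
    "make_occupancy_profile",
    "make_study",
]


@dataclass(frozen=True)
class RegionTruth:
    """Ground-truth microparameters for one region (k2 = K1/V_ND is implied)."""

    name: str
    K1: float  # mL/cm³/min
    bpnd: float  # k3/k4
    k4: float = 0.028  # 1/min
    grey: bool = True

    @property
    def k3(self) -> float:
        return self.bpnd * self.k4


def _default_regions() -> tuple:
    # regional k3/k4 spread chosen to average exactly 1.07; grey-matter K1
    # uniform at 0.37, white matter with lower perfusion
    return (
        RegionTruth("striatum", 0.37, 1.19),
        RegionTruth("thalamus", 0.37, 1.10),
        RegionTruth("cerebellum", 0.37, 1.15),
        RegionTruth("white_matter", 0.30, 0.95, grey=False),
        RegionTruth("frontal_cortex", 0.37, 1.07),
        RegionTruth("temporal_cortex", 0.37, 1.00),
        RegionTruth("parietal_cortex", 0.37, 1.03),
    )


def two_hour_frames() -> FrameSchedule:
    """2-h dynamic schedule: fine early frames coarsening to 5-min frames."""
    durations = [0.25] * 4 + [0.5] * 4 + [1.0] * 3 + [2.0] * 2 + [4.0] * 5 + [5.0] * 18
    return FrameSchedule.from_durations(durations)


def four_hour_frames() -> FrameSchedule:
    """4-h schedule: the 2-h schedule extended with 10-min frames."""
    durations = (
        [0.25] * 4 + [0.5] * 4 + [1.0] * 3 + [2.0] * 2 + [4.0] * 5 + [5.0] * 18
        + [10.0] * 12
    )
    return FrameSchedule.from_durations(durations)


def blood_sample_times(duration: str = "2h") -> np.ndarray:
    """Arterial sampling protocol: 28 samples over 2 h, 34 over 4 h.

    Front-loaded: 15 samples in the first 5 min, 3 every 5 min, then every
    10 min to the end of the 2-h window; 4-h scans add 6 samples every 20 min.
    """
    early = np.linspace(1.0 / 3.0, 5.0, 15)
    mid = np.array([10.0, 15.0, 20.0])
    late = np.arange(30.0, 121.0, 10.0)
    t = np.concatenate([early, mid, late])
    if duration == "4h":
        t = np.concatenate([t, np.arange(140.0, 241.0, 20.0)])
    elif duration != "2h":
        raise DomainError(f"duration must be '2h' or '4h', got {duration!r}")
    return t


@dataclass(frozen=True)
class StudyConfig:
    """Ground truth and design knobs for a synthetic study."""

    n_subjects: int = 4
    regions: tuple = field(default_factory=_default_regions)
    vnd: float = 7.89  # mL/cm³, shared across regions
    # parent-fraction truth pf(t) = a1 e^(-l1 t) + (1-a1) e^(-l2 t)
    pf_a1: float = 0.7
    pf_lambda1: float = 0.08
    pf_lambda2: float = 0.005
    pf_jitter_sd: float = 0.01  # additive sd on sampled fractions
    # plasma shape: linear rise to (peak_time, peak) then 3-exp washout
    peak_time: float = 1.0  # min
    peak_amplitude: float = 120.0  # kBq/cc
    washout_fractions: tuple = (0.72, 0.2, 0.08)
    washout_rates: tuple = (1.5, 0.2, 0.004)  # 1/min
    plasma_wb_ratio: float = 0.90
    # measurement noise: TAC sd = noise_scale * sqrt(value / frame_duration)
    noise_scale: float = 1.5
    session_k1_sd: float = 0.04  # multiplicative test-retest K1 perturbation
    subject_k1_sd: float = 0.08  # between-subject lognormal-ish spread
    subject_vnd_sd: float = 0.20
    subject_bp_sd: float = 0.10
    # scan metadata used for SUV conversion
    injected_dose_mbq: float = 170.0
    body_weight_kg: float = 5.2
    duration: str = "2h"

    def __post_init__(self):
        if self.n_subjects < 1:
            raise DomainError("need at least one subject")
        if self.vnd <= 0 or self.peak_amplitude <= 0 or self.peak_time <= 0:
            raise DomainError("rates and amplitudes must be positive")
        if any(r <= 0 for r in self.washout_rates) or any(
            f <= 0 for f in self.washout_fractions
        ):
            raise DomainError("washout components must be positive")
        if self.noise_scale < 0 or self.pf_jitter_sd < 0:
            raise DomainError("noise scales must be non-negative")

    @property
    def frames(self) -> FrameSchedule:
        return four_hour_frames() if self.duration == "4h" else two_hour_frames()

    @property
    def pf_truth(self) -> ParentFractionModel:
        return ParentFractionModel(self.pf_a1, self.pf_lambda1, self.pf_lambda2)

    def region_params(self, region: RegionTruth, k1_scale=1.0, vnd_scale=1.0, bp_scale=1.0) -> CompartmentParams:
        K1 = region.K1 * k1_scale
        vnd = self.vnd * vnd_scale
        bp = region.bpnd * bp_scale
        return CompartmentParams(K1=K1, k2=K1 / vnd, k3=bp * region.k4, k4=region.k4)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _rng(seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in streams])


def _plasma_shape(cfg: StudyConfig, t: np.ndarray) -> np.ndarray:
    """Total plasma activity: linear rise to the peak, then 3-exp washout."""
    t = np.asarray(t, dtype=float)
    amps = np.array(cfg.washout_fractions) * cfg.peak_amplitude
    rates = np.array(cfg.washout_rates)
    washout = np.sum(
        amps[:, None] * np.exp(-rates[:, None] * (t - cfg.peak_time)[None, :]), axis=0
    )
    rise = cfg.peak_amplitude * np.sum(cfg.washout_fractions) * t / cfg.peak_time
    return np.where(t < cfg.peak_time, rise, washout)


def make_input_function(cfg: StudyConfig, subject: int, seed: int):
    """One subject's blood table and parent-fraction samples.

    Returns (BloodSeries, pf_samples) where pf_samples is a list of
    (time_min, fraction) pairs at the metabolite-assay times.  The plasma to
    whole-blood ratio is held at the configured constant; parent-fraction
    samples get small Gaussian jitter (clipped to [0, 1]).
    """
    rng = _rng(seed, subject, 0)
    t = blood_sample_times(cfg.duration)
    plasma = _plasma_shape(cfg, t)
    whole_blood = plasma / cfg.plasma_wb_ratio
    blood = BloodSeries(times=t, whole_blood=whole_blood, plasma=plasma)

    pf_times = np.array([5.0, 15.0, 30.0, 60.0, 90.0, 120.0])
    if cfg.duration == "4h":
        pf_times = np.concatenate([pf_times, [180.0, 240.0]])
    pf_true = cfg.pf_truth(pf_times)
    jitter = rng.normal(0.0, cfg.pf_jitter_sd, size=len(pf_times)) if cfg.pf_jitter_sd > 0 else 0.0
    pf_vals = np.clip(pf_true + jitter, 0.0, 1.0)
    return blood, list(zip(pf_times.tolist(), pf_vals.tolist()))


def _subject_scales(cfg: StudyConfig, subject: int, seed: int):
    rng = _rng(seed, subject, 1)
    k1 = float(np.exp(rng.normal(0.0, cfg.subject_k1_sd)))
    vnd = float(np.exp(rng.normal(0.0, cfg.subject_vnd_sd)))
    bp = float(np.exp(rng.normal(0.0, cfg.subject_bp_sd)))
    return k1, vnd, bp


def make_tacs(
    cfg: StudyConfig,
    input_function: InputFunction,
    session: str,
    seed: int,
    subject: int = 0,
    noise_scale: float | None = None,
    subject_scales: tuple | None = None,
) -> dict:
    """Per-region TACs for one session: 2T forward model plus frame noise.

    ``session`` is "test" or "retest"; retest applies a small multiplicative
    K1 perturbation (sd ``session_k1_sd``) on top of the subject effects, so
    the two sessions differ only by noise realization and that perturbation.
    """
    if session not in ("test", "retest"):
        raise DomainError("session must be 'test' or 'retest'")
    noise = cfg.noise_scale if noise_scale is None else noise_scale
    k1s, vnds, bps = (
        subject_scales if subject_scales is not None else _subject_scales(cfg, subject, seed)
    )
    sess_code = 2 if session == "test" else 3
    rng = _rng(seed, subject, sess_code)
    sess_k1 = 1.0
    if session == "retest" and cfg.session_k1_sd > 0:
        sess_k1 = float(np.clip(np.exp(rng.normal(0.0, cfg.session_k1_sd)), 0.95, 1.05))
    frames = cfg.frames
    out = {}
    for region in cfg.regions:
        params = cfg.region_params(region, k1s, vnds, bps)
        if sess_k1 != 1.0:
            # session effect perturbs delivery (K1) at fixed k2, so it carries
            # through to V_ND and V_T like a physiological flow change
            params = CompartmentParams(
                K1=params.K1 * sess_k1, k2=params.k2, k3=params.k3, k4=params.k4
            )
        clean = simulate_tissue(params, input_function, frames)
        values = clean.values
        if noise > 0:
            sd = noise * np.sqrt(np.maximum(values, 0.0) / frames.durations)
            values = values + rng.normal(0.0, 1.0, size=len(values)) * sd
        out[region.name] = TimeActivityCurve(
            region=region.name, frames=frames, values=values
        )
    return out


def make_occupancy_profile(
    occ_max: float, drug_time: float = 90.0, rate: float | None = None
):
    """Competitor occupancy occ(t): 0 before drug_time, then a 1-exp rise.

    ``rate`` None means instantaneous occupancy (fast-penetrant competitor);
    a finite rate (1/min) models slow brain penetrance.
    """
    if not 0.0 <= occ_max <= 1.0:
        raise DomainError("occ_max must be in [0, 1]")

    def occ(t):
        t = np.asarray(t, dtype=float)
        post = t - drug_time
        if rate is None:
            val = np.where(post >= 0.0, occ_max, 0.0)
        else:
            val = np.where(post >= 0.0, occ_max * (1.0 - np.exp(-rate * np.maximum(post, 0.0))), 0.0)
        return val if val.ndim else float(val)

    return occ


def make_displacement_arm(
    cfg: StudyConfig,
    input_function: InputFunction,
    occupancy_profile,
    seed: int,
    subject: int = 0,
    noise_scale: float | None = None,
) -> dict:
    """Regional TACs with time-varying k3(t) = k3·(1 − occ(t)).

    The two-compartment mass balance is integrated numerically (the analytic
    convolution no longer applies once k3 depends on time).  occ(t) must lie
    in [0, 1]; with occ ≡ 0 the arm reproduces the baseline arm bit-for-bit
    under the same seed.
    """
    noise = cfg.noise_scale if noise_scale is None else noise_scale
    frames = cfg.frames
    t_end = float(frames.end_times[-1])
    grid = np.arange(0.0, t_end + 0.025, 0.05)
    occ_grid = np.asarray(occupancy_profile(grid), dtype=float)
    if np.any((occ_grid < -1e-9) | (occ_grid > 1.0 + 1e-9)):
        raise DomainError("occupancy profile must lie in [0, 1]")
    cp_grid = input_function.interpolate(grid)
    k1s, vnds, bps = _subject_scales(cfg, subject, seed)
    rng = _rng(seed, subject, 2)  # same stream as the "test" baseline session
    out = {}
    for region in cfg.regions:
        p = cfg.region_params(region, k1s, vnds, bps)

        def rhs(t, y, p=p):
            cp = np.interp(t, grid, cp_grid)
            occ = np.interp(t, grid, occ_grid)
            k3t = p.k3 * (1.0 - occ)
            cf, cb = y
            return [p.K1 * cp - (p.k2 + k3t) * cf + p.k4 * cb, k3t * cf - p.k4 * cb]

        sol = solve_ivp(
            rhs, (0.0, t_end), [0.0, 0.0], t_eval=grid, method="LSODA",
            rtol=1e-8, atol=1e-10, max_step=1.0,
        )
        ct = sol.y[0] + sol.y[1]
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (ct[1:] + ct[:-1]) * np.diff(grid))])
        i0 = np.interp(frames.start_times, grid, cum)
        i1 = np.interp(frames.end_times, grid, cum)
        values = (i1 - i0) / frames.durations
        if noise > 0:
            sd = noise * np.sqrt(np.maximum(values, 0.0) / frames.durations)
            values = values + rng.normal(0.0, 1.0, size=len(values)) * sd
        out[region.name] = TimeActivityCurve(
            region=region.name, frames=frames, values=values
        )
    return out


@dataclass(frozen=True)
class SubjectData:
    """One subject's generated tables (per session)."""

    blood: BloodSeries
    pf_samples: list
    input_function: InputFunction  # built from blood × true parent fraction
    tacs: dict  # session -> {region -> TimeActivityCurve}
    truth_scales: tuple  # (k1_scale, vnd_scale, bp_scale)


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete generated study plus its provenance."""

    config: StudyConfig
    seed: int
    subjects: dict  # subject index -> SubjectData
    config_hash: str


def make_study(cfg: StudyConfig, seed: int, sessions=("test", "retest")) -> SyntheticStudy:
    """Generate the full multi-subject test–retest study."""
    subjects = {}
    for s in range(cfg.n_subjects):
        blood, pf_samples = make_input_function(cfg, s, seed)
        input_fn = build_mcaif(blood, cfg.pf_truth)
        scales = _subject_scales(cfg, s, seed)
        tacs = {
            sess: make_tacs(cfg, input_fn, sess, seed, subject=s, subject_scales=scales)
            for sess in sessions
        }
        subjects[s] = SubjectData(
            blood=blood,
            pf_samples=pf_samples,
            input_function=input_fn,
            tacs=tacs,
            truth_scales=scales,
        )
    return SyntheticStudy(
        config=cfg, seed=int(seed), subjects=subjects, config_hash=cfg.config_hash()
    )
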