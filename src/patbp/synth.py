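"""Synthetic cohort generator for post-exercise ECG/PPG/cuff-BP recordings.

Emulates the study design the analysis assumes: subjects climb stairs for
about five minutes, then sit for a ~15-minute recording during which blood
pressure and heart rate relax back to rest.  PAT is the primary stochastic
process: each subject's per-beat pulse arrival time recovers exponentially
from an exercise-shortened value toward its resting baseline with additive
Gaussian jitter, and "true" beat-wise blood pressure is derived from PAT
through that subject's generating BP-PAT model.  This guarantees exact
model-consistency, so calibration and evaluation can be tested against
known ground truth (inverting the nonlinear models instead would only be
numeric).

Waveforms are rendered at 1 kHz: the ECG channel is a train of narrow
Gaussian R-like spikes, and the PPG channel one pulse per beat whose
rising-edge maximum slope falls exactly ``pat_true`` after the R-peak.
Morphology beyond those two fiducial points is deliberately schematic.
Cuff readings average the true pressures over a 30-s measurement window
and add Gaussian device error (default sd 2.5 mmHg, emulating an automatic
monitor of ~3 mmHg stated accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .models import MODEL_IDS, DEFAULT_GAMMA, ModelParams, estimate_bp

__all__ = [
    "SubjectProfile",
    "PATTrajectory",
    "TrueBPTrajectory",
    "WaveformRecord",
    "CuffReading",
    "CohortConfig",
    "make_cohort",
    "simulate_pat_trajectory",
    "derive_true_bp",
    "generating_params",
    "render_waveforms",
    "simulate_cuff_readings",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generative state for one synthetic subject.

    ``pat0`` is the resting pulse arrival time the subject relaxes toward;
    immediately after exercise PAT is shorter by ``pat_drop_exercise`` and
    recovers with time constant ``decay_tau`` (shared with heart rate).
    """

    subject_id: str
    sbp0: float  # resting systolic BP, mmHg
    dbp0: float  # resting diastolic BP, mmHg
    pat0: float  # resting PAT, s
    gamma: float = DEFAULT_GAMMA  # vascular-state constant, mmHg^-1
    heart_rate_rest: float = 70.0  # beats/min
    heart_rate_peak: float = 110.0  # beats/min, just after exercise
    pat_drop_exercise: float = 0.04  # s
    decay_tau: float = 360.0  # s
    pat_jitter_sd: float = 0.005  # s
    # slow mean-reverting PAT variability (vasomotion / autonomic tone):
    # BP is genuinely non-constant even at rest, which is what makes
    # repeated calibration rounds informative rather than redundant
    pat_slow_sd: float = 0.004  # s, stationary sd of the slow component
    pat_slow_tau: float = 60.0  # s, correlation time
    generating_model: str = "dMK-BH"

    def __post_init__(self) -> None:
        if not (self.sbp0 > self.dbp0 > 0):
            raise ValueError("need sbp0 > dbp0 > 0")
        if self.pat0 <= 0 or self.gamma <= 0:
            raise ValueError("pat0 and gamma must be positive")
        if self.pat_drop_exercise < 0 or self.pat0 - self.pat_drop_exercise <= 0:
            raise ValueError("pat_drop_exercise must be in [0, pat0)")
        if not (self.heart_rate_peak >= self.heart_rate_rest > 0):
            raise ValueError("need heart_rate_peak >= heart_rate_rest > 0")
        if self.generating_model not in MODEL_IDS:
            raise ValueError(f"unknown generating model {self.generating_model!r}")


@dataclass(frozen=True)
class PATTrajectory:
    """Per-beat ground-truth PAT series."""

    beat_times: np.ndarray  # s, strictly increasing
    pat_true: np.ndarray  # s, positive

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, float)
        pt = np.asarray(self.pat_true, float)
        if bt.shape != pt.shape:
            raise ValueError("beat_times and pat_true must have equal length")
        if bt.size and np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(pt <= 0):
            raise ValueError("pat_true must be positive")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "pat_true", pt)


@dataclass(frozen=True)
class TrueBPTrajectory:
    """Per-beat ground-truth blood pressure derived from PAT."""

    beat_times: np.ndarray
    sbp_true: np.ndarray
    dbp_true: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sbp_true) <= np.asarray(self.dbp_true)):
            raise ValueError("sbp_true must exceed dbp_true elementwise")


@dataclass(frozen=True)
class WaveformRecord:
    """Synchronously sampled ECG + PPG channels."""

    fs: float  # Hz
    ecg: np.ndarray
    ppg: np.ndarray
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.ecg)) / self.fs


@dataclass(frozen=True)
class CuffReading:
    """One automatic cuff measurement over [t_start, t_end]."""

    t_start: float
    t_end: float
    sbp_cuf: float
    dbp_cuf: float


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions (mean, sd) for each profile field.

    Defaults reproduce the target cohort: twelve healthy young adults with
    resting SBP 118.37 +/- 12.95 mmHg and DBP 69.40 +/- 8.79 mmHg.  The
    vascular constant gamma is fixed at 0.031 mmHg^-1 (sd 0) because the
    analysis treats it as a population constant.  Post-exercise peak heart
    rate and the size of the exercise PAT drop are not reported for the
    cohort; the defaults are plausible values for five minutes of stair
    climbing in young healthy subjects.
    """

    sbp0: tuple[float, float] = (118.37, 12.95)
    dbp0: tuple[float, float] = (69.40, 8.79)
    pat0: tuple[float, float] = (0.25, 0.02)
    gamma: tuple[float, float] = (DEFAULT_GAMMA, 0.0)
    heart_rate_rest: tuple[float, float] = (70.0, 8.0)
    heart_rate_peak: tuple[float, float] = (110.0, 10.0)
    pat_drop_exercise: tuple[float, float] = (0.04, 0.008)
    decay_tau: tuple[float, float] = (360.0, 45.0)
    pat_jitter_sd: float = 0.005
    pat_slow_sd: float = 0.004
    pat_slow_tau: float = 60.0
    # resting pulse pressure below ~20 mmHg is not physiologic for healthy
    # young adults; independent SBP/DBP draws that land closer are redrawn
    min_pulse_pressure: float = 20.0
    generating_model: str = "dMK-BH"
    max_redraws: int = 1000

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   max_redraws: int, what: str) -> float:
    for _ in range(max_redraws + 1):
        x = rng.normal(mean, sd) if sd > 0 else mean
        if x > 0:
            return float(x)
    raise ValueError(f"could not draw a positive {what} from N({mean}, {sd})")


def make_cohort(n_subjects: int, config: CohortConfig | None = None,
                seed: int = 0) -> list[SubjectProfile]:
    """Draw a reproducible cohort of subject profiles.

    Non-positive draws (and SBP<=DBP or infeasible PAT-drop combinations)
    are re-drawn up to ``config.max_redraws`` times before the config is
    declared invalid.  Identical seeds yield identical cohorts.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    cohort: list[SubjectProfile] = []
    for i in range(n_subjects):
        for _ in range(cfg.max_redraws + 1):
            sbp0 = _draw_positive(rng, *cfg.sbp0, cfg.max_redraws, "sbp0")
            dbp0 = _draw_positive(rng, *cfg.dbp0, cfg.max_redraws, "dbp0")
            if sbp0 - dbp0 < cfg.min_pulse_pressure:
                continue
            try:
                profile = SubjectProfile(
                    subject_id=f"S{i + 1:02d}",
                    sbp0=sbp0,
                    dbp0=dbp0,
                    pat0=_draw_positive(rng, *cfg.pat0, cfg.max_redraws, "pat0"),
                    gamma=_draw_positive(rng, *cfg.gamma, cfg.max_redraws, "gamma"),
                    heart_rate_rest=_draw_positive(
                        rng, *cfg.heart_rate_rest, cfg.max_redraws, "heart_rate_rest"),
                    heart_rate_peak=_draw_positive(
                        rng, *cfg.heart_rate_peak, cfg.max_redraws, "heart_rate_peak"),
                    pat_drop_exercise=abs(rng.normal(*cfg.pat_drop_exercise))
                    if cfg.pat_drop_exercise[1] > 0 else cfg.pat_drop_exercise[0],
                    decay_tau=_draw_positive(
                        rng, *cfg.decay_tau, cfg.max_redraws, "decay_tau"),
                    pat_jitter_sd=cfg.pat_jitter_sd,
                    pat_slow_sd=cfg.pat_slow_sd,
                    pat_slow_tau=cfg.pat_slow_tau,
                    generating_model=cfg.generating_model,
                )
                break
            except ValueError:
                continue
        else:
            raise ValueError("invalid cohort config: feasible profile not found "
                             f"after {cfg.max_redraws} redraws")
        cohort.append(profile)
    return cohort


def simulate_pat_trajectory(profile: SubjectProfile, duration: float = 900.0,
                            seed: int = 0,
                            exercise_onset: float = 0.0) -> PATTrajectory:
    """Simulate per-beat PAT over ``duration`` seconds.

    From ``exercise_onset`` onward, heart rate recovers exponentially from
    ``heart_rate_peak`` to ``heart_rate_rest`` and PAT from
    ``pat0 - pat_drop_exercise`` to ``pat0``, both with time constant
    ``decay_tau``; before the onset the subject is at rest (HR and PAT at
    their resting values).  Beat-wise Gaussian jitter of sd
    ``pat_jitter_sd`` is added to PAT.  An onset of 0 (default) starts the
    recording right after exercise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    times = []
    t = 0.0
    while t < duration:
        times.append(t)
        decay = np.exp(-(t - exercise_onset) / profile.decay_tau) if t >= exercise_onset else 0.0
        hr = (profile.heart_rate_rest
              + (profile.heart_rate_peak - profile.heart_rate_rest) * decay)
        t += 60.0 / hr
    beat_times = np.asarray(times)
    decay = np.where(beat_times >= exercise_onset,
                     np.exp(-np.maximum(beat_times - exercise_onset, 0.0)
                            / profile.decay_tau), 0.0)
    pat = profile.pat0 - profile.pat_drop_exercise * decay
    if profile.pat_slow_sd > 0:
        # Ornstein-Uhlenbeck slow component, exact discretization on the
        # (irregular) beat grid; models vasomotion-scale BP variability
        slow = np.empty(pat.size)
        slow[0] = rng.normal(0.0, profile.pat_slow_sd)
        for i in range(1, pat.size):
            rho = np.exp(-(beat_times[i] - beat_times[i - 1]) / profile.pat_slow_tau)
            slow[i] = slow[i - 1] * rho + rng.normal(
                0.0, profile.pat_slow_sd * np.sqrt(1.0 - rho * rho))
        pat = pat + slow
    if profile.pat_jitter_sd > 0:
        pat = pat + rng.normal(0.0, profile.pat_jitter_sd, size=pat.size)
    if profile.pat_slow_sd > 0 or profile.pat_jitter_sd > 0:
        pat = np.clip(pat, 1e-3, None)  # noise must not push PAT negative
    return PATTrajectory(beat_times=beat_times, pat_true=pat)


def generating_params(profile: SubjectProfile) -> ModelParams:
    """Ground-truth parameters of the subject's generating model.

    For the baseline-anchored models these are the resting baselines; for
    the coefficient models, coefficients chosen so the model passes through
    the resting state with physiologically-signed slopes (BP falls as PAT
    lengthens), scaled by the subject's own pressures.
    """
    m = profile.generating_model
    if m in ("MK-BH", "dMK-BH"):
        from .models import BaselineState
        return ModelParams(m, baseline=BaselineState(
            sbp0=profile.sbp0, dbp0=profile.dbp0, pat0=profile.pat0,
            gamma=profile.gamma))
    if m == "MK-EE":
        # slope matched to dMK-BH's local sensitivity d(BP)/d(ln PAT) = -2/gamma
        a_s = -2.0 / profile.gamma
        a_d = -2.0 / profile.gamma
        return ModelParams(m,
                           (a_s, profile.sbp0 - a_s * np.log(profile.pat0)),
                           (a_d, profile.dbp0 - a_d * np.log(profile.pat0)))
    if m == "L-MK":
        b_s = -2.0 / (profile.gamma * profile.pat0)
        return ModelParams(m,
                           (profile.sbp0 - b_s * profile.pat0, b_s),
                           (profile.dbp0 - b_s * profile.pat0, b_s))
    # M-M: anchored so BP(pat0) = baseline with the same local sensitivity
    # dBP/dPAT = -2/(gamma*pat0) as the VE models, and b > 0 so the curve
    # is bounded below by a + sqrt(b).
    s = 2.2 / profile.gamma  # sqrt of the radicand at pat0
    c = 2.0 * profile.pat0**2 * s / profile.gamma
    b = s * s - c / profile.pat0**2  # = s*(s - 2/gamma) > 0
    return ModelParams(m, (profile.sbp0 - s, b, c), (profile.dbp0 - s, b, c))


def derive_true_bp(pat_traj: PATTrajectory, profile: SubjectProfile,
                   params: ModelParams | None = None) -> TrueBPTrajectory:
    """Derive beat-wise true BP from PAT through the generating model.

    Ground truth is exactly model-consistent by construction, which makes
    noiseless full-pipeline round trips possible.
    """
    params = params if params is not None else generating_params(profile)
    if params.model != profile.generating_model:
        raise ValueError(f"params are for {params.model}, profile generates "
                         f"{profile.generating_model}")
    est = estimate_bp(params, pat_traj.pat_true)
    return TrueBPTrajectory(beat_times=pat_traj.beat_times,
                            sbp_true=np.asarray(est.sbp_est),
                            dbp_true=np.asarray(est.dbp_est))


_ECG_SPIKE_SD = 0.008  # s, width of the R-like Gaussian spike
_PPG_RISE = 0.10  # s, raised-cosine rising-edge duration
_PPG_DECAY = 0.12  # s, exponential decay constant after the pulse peak


def render_waveforms(pat_traj: PATTrajectory, fs: float = 1000.0,
                     noise_sd: float = 0.0, seed: int = 0,
                     lead: float = 0.5, tail: float = 1.0) -> WaveformRecord:
    """Render schematic ECG and PPG channels from a PAT trajectory.

    Each beat contributes one narrow Gaussian R-spike to the ECG at its
    beat time, and one PPG pulse whose rising edge is a raised cosine of
    duration ``_PPG_RISE`` centred (and hence steepest) exactly at
    ``beat_time + pat_true``, followed by a shifted exponential decay that
    reaches zero smoothly (a truncated decay would put a step
    discontinuity under a later beat's rising edge and bias its
    maximum-slope point).  The record starts ``lead`` seconds before the
    first beat so boundary beats are rendered whole.  Additive white
    Gaussian noise of ``noise_sd`` goes on both channels.
    """
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")
    bt, pat = pat_traj.beat_times, pat_traj.pat_true
    if bt.size == 0:
        raise ValueError("empty trajectory")
    ibi = np.diff(bt)
    min_gap = float(np.max(pat)) + _PPG_RISE
    if ibi.size and np.min(ibi) <= min_gap:
        raise ValueError(
            f"inter-beat interval {np.min(ibi):.3f}s too short for PAT + pulse "
            f"width {min_gap:.3f}s")
    t0 = float(bt[0]) - lead
    t_end = bt[-1] + pat[-1] + tail
    n = int(np.ceil((t_end - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    ecg = np.zeros(n)
    ppg = np.zeros(n)
    decay_span = 10.0 * _PPG_DECAY  # residual exp(-10) ~ 5e-5, shifted to 0
    decay_floor = np.exp(-10.0)
    for tb, tp in zip(bt, pat):
        # ECG: Gaussian spike, support +/- 5 sd
        i0 = max(0, int((tb - 5 * _ECG_SPIKE_SD - t0) * fs))
        i1 = min(n, int((tb + 5 * _ECG_SPIKE_SD - t0) * fs) + 1)
        ecg[i0:i1] += np.exp(-0.5 * ((t[i0:i1] - tb) / _ECG_SPIKE_SD) ** 2)
        # PPG: raised-cosine rise centred at the max-slope point tb+tp
        t_ms = tb + tp
        rise0 = t_ms - _PPG_RISE / 2
        peak = t_ms + _PPG_RISE / 2
        j0 = max(0, int((rise0 - t0) * fs))
        j1 = min(n, int((peak - t0) * fs) + 1)
        phase = np.clip((t[j0:j1] - rise0) / _PPG_RISE, 0.0, 1.0)
        ppg[j0:j1] += 0.5 * (1 - np.cos(np.pi * phase))
        k0 = j1
        k1 = min(n, int((peak + decay_span - t0) * fs) + 1)
        if k0 < k1:
            ppg[k0:k1] += np.maximum(
                np.exp(-(t[k0:k1] - peak) / _PPG_DECAY) - decay_floor, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ecg = ecg + rng.normal(0.0, noise_sd, n)
        ppg = ppg + rng.normal(0.0, noise_sd, n)
    return WaveformRecord(fs=fs, ecg=ecg, ppg=ppg, t0=t0)


def simulate_cuff_readings(bp_traj: TrueBPTrajectory, interval: float = 30.0,
                           meas_duration: float = 30.0, device_sd: float = 2.5,
                           seed: int = 0, t_start: float = 0.0,
                           t_stop: float | None = None) -> list[CuffReading]:
    """Simulate automatic cuff readings on a fixed schedule.

    Each reading covers ``[t, t + meas_duration]`` with window starts every
    ``interval`` seconds; the reported pressures are the means of the true
    beat-wise pressures inside the window plus independent Gaussian device
    error of sd ``device_sd`` mmHg.
    """
    if not (interval >= meas_duration > 0):
        raise ValueError("need interval >= meas_duration > 0")
    rng = np.random.default_rng(seed)
    stop = t_stop if t_stop is not None else float(bp_traj.beat_times[-1])
    readings: list[CuffReading] = []
    t = t_start
    while t + meas_duration <= stop + 1e-9:
        mask = (bp_traj.beat_times >= t) & (bp_traj.beat_times < t + meas_duration)
        if not np.any(mask):
            raise ValueError(
                f"cuff window [{t}, {t + meas_duration}] contains no beats: "
                "schedule/trajectory mismatch")
        sbp = float(np.mean(bp_traj.sbp_true[mask])) + rng.normal(0.0, device_sd)
        dbp = float(np.mean(bp_traj.dbp_true[mask])) + rng.normal(0.0, device_sd)
        readings.append(CuffReading(t_start=t, t_end=t + meas_duration,
                                    sbp_cuf=sbp, dbp_cuf=dbp))
        t += interval
    return readings
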