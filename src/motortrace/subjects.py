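"""Synthetic subjects tracking the target: cursor and stylus-force simulation.

The study's patient data are not shipped with the package, so downstream
stages are exercised on simulated subjects.  A subject is a
:class:`SubjectProfile` whose pathological components are scaled by a single
``severity`` knob:

* **control** — near-perfect pursuit plus a small isotropic jitter;
* **pd** — heterogeneous mixture of 3–10 Hz tremor, tracking lag, reduced
  gain, slowed movement (capped step size) and raised force variance;
* **et** — dominated by a large action tremor, everything else at control
  levels.

The cursor follows a first-order pursuit model: at each 10 ms step it moves
toward the (lagged) target position with a fractional gain, with the step
length capped at ``speed_scale`` times the target speed.  Tremor is a single
sinusoid per trial along a random direction (which makes its amplitude
analytically recoverable by the tremor metric); a band-limited-noise tremor
is available behind a flag.  This is explicitly a stand-in for patients, not
a biophysical model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .paths import PathConfig, TargetTrace, generate_path, sample_constant_speed

__all__ = [
    "SubjectProfile",
    "Trial",
    "SessionData",
    "CONTROL_PROFILE",
    "PD_PROFILE",
    "ET_PROFILE",
    "DEFAULT_PROFILES",
    "effective_profile",
    "simulate_cursor",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "default_profile_sampler",
]

# control-level baselines that pathological components are scaled away from
BASELINE_NOISE_SD = 0.02   # cm
BASELINE_FORCE_VAR = 0.01  # device units^2
BASELINE_FORCE_MEAN = 1.0  # device units


@dataclass(frozen=True)
class SubjectProfile:
    """Simulation parameters of one synthetic subject.

    ``severity`` rescales every pathological component linearly between the
    control baseline (severity 0) and the profile's stated value
    (severity 1); values above 1 extrapolate.
    """

    label: str = "control"
    tremor_amplitude: float = 0.0  # cm
    tremor_freq: float = 5.0       # Hz, within the 3-10 Hz band
    tracking_lag: float = 0.0      # s
    tracking_gain: float = 1.0     # (0, 1]
    noise_sd: float = BASELINE_NOISE_SD     # cm
    speed_scale: float = 1.0       # <= 1 models slowing
    force_mean: float = BASELINE_FORCE_MEAN
    force_var: float = BASELINE_FORCE_VAR
    severity: float = 1.0
    tremor_mode: str = "sinusoid"  # or "bandnoise"

    def __post_init__(self) -> None:
        if self.severity < 0:
            raise ValueError("severity must be >= 0")
        if not (0.0 < self.tracking_gain <= 1.0):
            raise ValueError("tracking_gain must be in (0, 1]")
        if self.tremor_mode not in ("sinusoid", "bandnoise"):
            raise ValueError("tremor_mode must be 'sinusoid' or 'bandnoise'")


CONTROL_PROFILE = SubjectProfile(label="control")
PD_PROFILE = SubjectProfile(
    label="pd",
    tremor_amplitude=0.1,
    tremor_freq=5.0,
    tracking_lag=0.12,
    tracking_gain=0.85,
    noise_sd=0.08,
    speed_scale=0.8,
    force_var=4.0 * BASELINE_FORCE_VAR,
)
ET_PROFILE = SubjectProfile(label="et", tremor_amplitude=0.35, tremor_freq=6.0)

DEFAULT_PROFILES = {"control": CONTROL_PROFILE, "pd": PD_PROFILE, "et": ET_PROFILE}


def effective_profile(profile: SubjectProfile) -> SubjectProfile:
    """Resolve ``severity`` into concrete parameters (severity folded to 1)."""
    s = profile.severity
    clip = lambda v, lo: max(v, lo)
    return dataclasses.replace(
        profile,
        tremor_amplitude=clip(s * profile.tremor_amplitude, 0.0),
        tracking_lag=clip(s * profile.tracking_lag, 0.0),
        tracking_gain=min(1.0, clip(1.0 - s * (1.0 - profile.tracking_gain), 0.05)),
        noise_sd=clip(BASELINE_NOISE_SD + s * (profile.noise_sd - BASELINE_NOISE_SD), 0.0),
        speed_scale=clip(1.0 - s * (1.0 - profile.speed_scale), 0.05),
        force_var=clip(
            BASELINE_FORCE_VAR + s * (profile.force_var - BASELINE_FORCE_VAR), 0.0
        ),
        severity=1.0,
    )


@dataclass
class Trial:
    """One trial of paired target/cursor/force samples on a uniform grid."""

    trial_id: int
    t: np.ndarray
    target: np.ndarray               # (n, 2) cm
    cursor: np.ndarray | None = None  # (n, 2) cm, None for target-only data
    force: np.ndarray | None = None   # (n,) device units

    def __post_init__(self) -> None:
        n = len(self.t)
        if len(self.target) != n:
            raise ValueError("target and timestamps length mismatch")
        if self.cursor is not None and len(self.cursor) != n:
            raise ValueError("cursor and timestamps length mismatch")
        if self.force is not None and len(self.force) != n:
            raise ValueError("force and timestamps length mismatch")
        if n > 1:
            dt = np.diff(self.t)
            if dt.min() <= 0:
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ValueError("sampling interval must be uniform within 1e-9 s")


@dataclass
class SessionData:
    """A subject's session: trials plus identifying metadata."""

    subject_id: str
    group_label: str
    sampling_rate: float
    trials: list[Trial]
    profile: SubjectProfile | None = None
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return sum(len(tr.t) for tr in self.trials)


def _pursuit(target: np.ndarray, dt: float, prof: SubjectProfile, target_speed: float) -> np.ndarray:
    lag_steps = int(round(prof.tracking_lag / dt))
    cap = prof.speed_scale * target_speed * dt
    gain = prof.tracking_gain
    n = len(target)
    out = np.empty_like(target)
    out[0] = target[0]
    cx, cy = float(target[0, 0]), float(target[0, 1])
    tx, ty = target[:, 0], target[:, 1]
    for k in range(1, n):
        j = k - lag_steps if k >= lag_steps else 0
        sx = gain * (tx[j] - cx)
        sy = gain * (ty[j] - cy)
        nrm = (sx * sx + sy * sy) ** 0.5
        if nrm > cap:
            f = cap / nrm
            sx *= f
            sy *= f
        cx += sx
        cy += sy
        out[k, 0] = cx
        out[k, 1] = cy
    return out


def _tremor(t: np.ndarray, prof: SubjectProfile, fs: float, rng: np.random.Generator) -> np.ndarray:
    a = prof.tremor_amplitude
    if a == 0.0:
        return np.zeros((len(t), 2))
    psi = rng.uniform(0.0, 2.0 * np.pi)   # spatial direction, once per trial
    u = np.array([np.cos(psi), np.sin(psi)])
    if prof.tremor_mode == "sinusoid":
        phi = rng.uniform(0.0, 2.0 * np.pi)
        osc = a * np.sin(2.0 * np.pi * prof.tremor_freq * t + phi)
    else:
        # band-limited noise centred on tremor_freq (+-1 Hz), RMS-matched to
        # the sinusoid's RMS a/sqrt(2)
        white = rng.standard_normal(len(t))
        lo = max(0.5, prof.tremor_freq - 1.0)
        hi = min(0.499 * fs, prof.tremor_freq + 1.0)
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        osc = signal.sosfiltfilt(sos, white)
        rms = np.sqrt(np.mean(osc**2))
        osc = osc / rms * (a / np.sqrt(2.0)) if rms > 0 else osc
    return np.outer(osc, u)


def simulate_trial(
    target: TargetTrace,
    profile: SubjectProfile,
    rng: np.random.Generator,
    trial_id: int = 0,
) -> Trial:
    """Simulate one trial of cursor + force for a subject tracking ``target``."""
    if len(target) == 0:
        raise ValueError("target trace is empty")
    prof = effective_profile(profile)
    dt = 1.0 / target.sampling_rate
    cursor = _pursuit(target.positions, dt, prof, target.speed)
    cursor = cursor + _tremor(target.timestamps, prof, target.sampling_rate, rng)
    if prof.noise_sd > 0:
        cursor = cursor + rng.normal(0.0, prof.noise_sd, size=cursor.shape)
    force = prof.force_mean + rng.normal(0.0, np.sqrt(prof.force_var), size=len(target))
    return Trial(trial_id, target.timestamps.copy(), target.positions.copy(), cursor, force)


def simulate_cursor(
    target: TargetTrace,
    profile: SubjectProfile,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
    group_label: str | None = None,
) -> SessionData:
    """Single-trial session for a subject tracking one target trace."""
    trial = simulate_trial(target, profile, rng)
    return SessionData(
        subject_id=subject_id,
        group_label=group_label or profile.label,
        sampling_rate=target.sampling_rate,
        trials=[trial],
        profile=profile,
    )


def simulate_session(
    profile: SubjectProfile,
    cfg: PathConfig,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
    group_label: str | None = None,
    seed: int | None = None,
) -> SessionData:
    """Full session: ``cfg.n_trials`` trials, each on a fresh stochastic path.

    A 20-segment path at 4.25 cm/s lasts roughly 25 s, so one path per trial
    realises the task's "15 trials of approximately 25 seconds" layout.
    """
    trials = []
    for i in range(cfg.n_trials):
        path = generate_path(cfg, rng)
        trace = sample_constant_speed(path, cfg)
        trials.append(simulate_trial(trace, profile, rng, trial_id=i))
    return SessionData(
        subject_id=subject_id,
        group_label=group_label or profile.label,
        sampling_rate=cfg.sampling_rate,
        trials=trials,
        profile=profile,
        seed=seed,
    )


def default_profile_sampler(group: str, rng: np.random.Generator) -> SubjectProfile:
    """Default per-subject profile draw: severity jitter for patient groups.

    PD severity ~ U(0.5, 1.5) and ET severity ~ U(0.7, 1.3) express the
    between-patient heterogeneity the cohorts are meant to emulate; control
    profiles are fixed.
    """
    base = DEFAULT_PROFILES[group]
    if group == "pd":
        return dataclasses.replace(base, severity=float(rng.uniform(0.5, 1.5)))
    if group == "et":
        return dataclasses.replace(base, severity=float(rng.uniform(0.7, 1.3)))
    return base


def simulate_cohort(
    n_per_group: dict[str, int],
    cfg: PathConfig | None = None,
    seed: int = 0,
    profiles: dict[str, SubjectProfile] | None = None,
    profile_sampler=None,
) -> list[SessionData]:
    """Simulate a cohort; each subject gets an independent seed and paths.

    ``n_per_group`` maps group label -> count (e.g. the study-sized cohort
    ``{"control": 20, "pd": 26, "et": 12}``).  Fixed ``profiles`` override the
    defaults; a ``profile_sampler(group, rng)`` callable draws an independent
    profile per subject (pass :func:`default_profile_sampler` for jittered
    patient severities).  Reproducible byte-for-byte from ``seed``.
    """
    cfg = cfg or PathConfig()
    for g, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"group {g!r} needs at least one subject")
    order = [(g, i) for g in n_per_group for i in range(n_per_group[g])]
    children = np.random.SeedSequence(seed).spawn(len(order))
    sessions = []
    for (group, i), ss in zip(order, children):
        rng = np.random.default_rng(ss)
        if profile_sampler is not None:
            prof = profile_sampler(group, rng)
        elif profiles is not None and group in profiles:
            prof = profiles[group]
        else:
            prof = DEFAULT_PROFILES[group]
        sid = f"{group}_{i:03d}"
        sessions.append(
            simulate_session(prof, cfg, rng, subject_id=sid, group_label=group)
        )
    return sessions
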