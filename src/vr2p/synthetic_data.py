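"""Synthetic sessions, velocity, transients and chessboard movies.

In the emulated experiment a head-fixed mouse runs in an infinite virtual
corridor.  At random times it is teleported into zones whose walls carry
grating patterns: the 0-degree zone is aversive (airpuffs start after a
3.5-s grace period, a 0.4-s pulse every 0.8 s, until the mouse exits),
45/135-degree zones are control.  Every grating zone is followed by the
neutral corridor; an immobile mouse (no movement for 8 s) is teleported
into a random zone.  Treadmill velocity is sampled every 3 ms and may be
negative.  Calcium activity of layer-2/3 neurons is recorded with 3D
chessboard scanning (~97 somata, one per subfield, at ~14.31 Hz).

The generator produces all of this with known ground truth: per-neuron
latent amplitudes (visual ON, zone-end ramp, two-component reinforcement,
locomotion coupling), hub flags, 3D soma positions, per-trial high/low-ramp
classes and a planted neural-vs-running lead.  Downstream modules are
tested by recovering these planted quantities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging_pipeline import ChessboardMovie, Roi, RoiSet
from .behavior import VelocityTrace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SessionLog",
    "TransientSet",
    "generate_session",
    "sample_ground_truth",
    "generate_transients",
    "generate_chessboard_movie",
    "generate_abyss_runs",
]

ZONES = ("AVER_0", "CTRL_45", "CTRL_135")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated experiment.

    Defaults follow the recorded protocol: ~97 ROIs per animal, imaging at
    14.31 Hz (range 11.2--20.5), treadmill sampling every 3 ms, a 3.5-s
    grace period before 0.4-s airpuff pulses every 0.8 s, teleportation of
    immobile mice after 8 s, and teleports on average every 20 s.  The 60%
    neuropil mixing fraction matches the subtraction used in the pipeline.
    """

    seed: int = 0
    n_neurons: int = 97
    imaging_rate: float = 14.31          # Hz
    behavior_dt: float = 0.003           # s
    n_trials_per_zone: int = 16
    zone_grace: float = 3.5              # s before the first airpuff
    puff_duration: float = 0.4           # s
    puff_period: float = 0.8             # s between pulse onsets
    immobility_timeout: float = 8.0      # s of no movement before teleport
    mean_interteleport: float = 20.0     # s
    noise_sd: float = 0.05               # dF/F units
    neuropil_mix: float = 0.6
    grid_shape: tuple[int, int] = (10, 10)
    hub_fraction: float = 0.1
    # mouse locomotion model
    baseline_speed: float = 12.0         # cm/s, OU mean
    speed_sd: float = 2.0                # cm/s, OU stationary s.d.
    escape_speedup_sd: float = 3.0       # end-of-zone speed-up, in speed_sd units
    puff_reaction: float = 5.0           # cm/s added after the first airpuff
    p_immobility: float = 0.05           # chance of an immobility episode per neutral period
    zone_dwell_min: float = 1.5          # s beyond grace always spent in the zone
    zone_exit_mean: float = 1.5          # s, mean extra dwell beyond the minimum
    lick_rate: float = 0.5               # Hz baseline Poisson licking
    # latent kernel timing
    ramp_onset: float = 3.0              # s before zone end where the ramp starts

    def __post_init__(self) -> None:
        positive = (
            "imaging_rate", "behavior_dt", "zone_grace", "puff_duration",
            "puff_period", "immobility_timeout", "mean_interteleport",
            "baseline_speed", "speed_sd", "zone_dwell_min", "zone_exit_mean",
            "ramp_onset",
        )
        for name in positive:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"SimConfig.{name} must be finite and > 0, got {value}")
        for name in ("noise_sd", "escape_speedup_sd", "puff_reaction", "lick_rate"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"SimConfig.{name} must be finite and >= 0, got {value}")
        for name in ("neuropil_mix", "hub_fraction", "p_immobility"):
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValueError(f"SimConfig.{name} must be in [0, 1], got {value}")
        if self.n_neurons < 1 or self.n_trials_per_zone < 1:
            raise ValueError("n_neurons and n_trials_per_zone must be >= 1")
        rows, cols = self.grid_shape
        if self.n_neurons > rows * cols:
            raise ValueError(
                f"SimConfig.n_neurons={self.n_neurons} exceeds grid capacity "
                f"{rows}x{cols} (one soma per subfield)"
            )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


# --------------------------------------------------------------------------
# Session log
# --------------------------------------------------------------------------

@dataclass
class SessionLog:
    """Timestamped events plus the 3-ms velocity/position trace.

    Events carry (time, kind, zone) with kind in {teleport_in, zone_exit,
    airpuff_pulse, reward, lick, abyss_edge}.  The trial table summarizes
    grating-zone visits with entry/exit times, the scheduled first-airpuff
    time (entry + grace, defined for control trials too) and whether the
    simulated mouse escaped before it.
    """

    events: pd.DataFrame
    velocity: np.ndarray
    position: np.ndarray
    dt: float
    duration: float
    config: SimConfig | None = None

    def trials(self) -> pd.DataFrame:
        ev = self.events
        rows = []
        entries = ev[(ev.kind == "teleport_in") & (ev.zone != "NEUTRAL")]
        exits = ev[ev.kind == "zone_exit"]
        grace = self.config.zone_grace if self.config else 3.5
        for _, ent in entries.iterrows():
            later = exits[exits.time > ent.time]
            if later.empty:
                continue
            t_exit = float(later.iloc[0].time)
            puffs = ev[(ev.kind == "airpuff_pulse")
                       & (ev.time >= ent.time) & (ev.time < t_exit)]
            rows.append({
                "zone": ent.zone,
                "t_enter": float(ent.time),
                "t_exit": t_exit,
                "scheduled_first_puff": float(ent.time) + grace,
                "n_puffs": len(puffs),
                "escaped": t_exit < float(ent.time) + grace,
            })
        return pd.DataFrame(rows)

    def pre_airpuff_curves(self, pre_window: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
        """Per-trial velocity curves in the window before the scheduled first puff.

        Returns (curves, labels) ready for the shuffle bootstrap, with label
        1 for control and 2 for aversive trials.  The window for control
        trials ends where the airpuff would fall given the same schedule.
        """
        n = int(round(pre_window / self.dt))
        curves, labels = [], []
        for _, tr in self.trials().iterrows():
            end = int(round(tr.scheduled_first_puff / self.dt))
            start = end - n
            if start < 0 or end > len(self.velocity):
                continue
            curves.append(self.velocity[start:end])
            labels.append(2 if tr.zone == "AVER_0" else 1)
        return np.array(curves), np.array(labels)

    def zone_intervals(self, zone_prefix: str = "AVER") -> list[tuple[float, float]]:
        out = []
        for _, tr in self.trials().iterrows():
            if tr.zone.startswith(zone_prefix):
                out.append((tr.t_enter, tr.t_exit))
        return out


def _smooth_bump(t: np.ndarray, start: float, rise: float, hold: float, fall: float) -> np.ndarray:
    """Cosine-ramped bump used for speed-ups: 0 -> 1 over rise, hold, decay."""
    out = np.zeros_like(t)
    up = (t >= start) & (t < start + rise)
    out[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / rise))
    flat = (t >= start + rise) & (t < start + rise + hold)
    out[flat] = 1.0
    down = (t >= start + rise + hold) & (t < start + rise + hold + fall)
    out[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - start - rise - hold) / fall))
    return out


def generate_session(
    config: SimConfig,
    learning_curve=None,
    ctrl_learning_curve=None,
    n_zones: int = 2,
) -> SessionLog:
    """Simulate one trial-structured session.

    ``learning_curve`` maps session time (s) to the probability that the
    simulated mouse speeds up and escapes the aversive zone before the
    first scheduled airpuff; None means never.  ``ctrl_learning_curve``
    plays the same role for control zones (a mouse that cannot discriminate
    speeds up in both).  Velocity is an Ornstein--Uhlenbeck process around
    ``baseline_speed`` with escape and airpuff-reaction bumps added, plus
    occasional immobility episodes in the neutral corridor that trigger the
    8-s teleport rule.  The same (config, seed) always produces the same log.
    """
    if learning_curve is None:
        learning_curve = lambda t: 0.0
    if ctrl_learning_curve is None:
        ctrl_learning_curve = lambda t: 0.0
    rng = np.random.default_rng(config.seed)
    dt = config.behavior_dt

    zone_list = list(ZONES[:n_zones]) * config.n_trials_per_zone
    rng.shuffle(zone_list)

    events: list[tuple[float, str, str]] = []
    # visit bookkeeping for velocity bumps: (start_time, amplitude, rise, hold, fall)
    bumps: list[tuple[float, float, float, float, float]] = []
    immobility: list[tuple[float, float]] = []

    t = 0.0
    for zone in zone_list:
        neutral = min(max(rng.exponential(config.mean_interteleport), 4.0), 60.0)
        if rng.random() < config.p_immobility and neutral > config.immobility_timeout + 2.0:
            onset = t + rng.uniform(1.0, neutral - config.immobility_timeout - 1.0)
            immobility.append((onset, onset + config.immobility_timeout))
            t = onset + config.immobility_timeout
        else:
            t = t + neutral
        t_enter = t
        events.append((t_enter, "teleport_in", zone))
        if zone == "AVER_0":
            p_escape = float(learning_curve(t_enter))
        else:
            p_escape = float(ctrl_learning_curve(t_enter))
        escaped = rng.random() < p_escape
        if escaped:
            t_exit = t_enter + rng.uniform(0.6 * config.zone_grace, config.zone_grace)
            amp = config.escape_speedup_sd * config.speed_sd
            bumps.append((t_exit - 1.5, amp, 1.0, 0.5, 1.0))
        else:
            t_exit = t_enter + config.zone_grace + config.zone_dwell_min + min(
                rng.exponential(config.zone_exit_mean), 6.5
            )
            if zone == "AVER_0":
                t_puff = t_enter + config.zone_grace
                while t_puff < t_exit:
                    events.append((t_puff, "airpuff_pulse", zone))
                    t_puff += config.puff_period
                if config.puff_reaction > 0:
                    bumps.append((t_enter + config.zone_grace,
                                  config.puff_reaction, 0.5, 1.0, 1.5))
        events.append((t_exit, "zone_exit", zone))
        t = t_exit
    duration = t + 5.0

    n = int(np.ceil(duration / dt))
    times = np.arange(n) * dt
    # Ornstein-Uhlenbeck velocity: theta = 1/s relaxation, stationary sd = speed_sd
    theta = 1.0
    sigma = config.speed_sd * np.sqrt(2 * theta)
    noise = rng.standard_normal(n)
    a = np.exp(-theta * dt)
    b = sigma * np.sqrt((1 - a**2) / (2 * theta))
    from scipy.signal import lfilter
    noise[0] = 0.0
    fluct = lfilter([b], [1.0, -a], noise)   # AR(1) deviation from the mean
    v = config.baseline_speed + fluct
    for start, amp, rise, hold, fall in bumps:
        v += amp * _smooth_bump(times, start, rise, hold, fall)
    for lo, hi in immobility:
        # the zone teleport scheduled at `hi` doubles as the immobility teleport
        v[(times >= lo) & (times < hi)] = 0.0
    position = np.cumsum(v) * dt

    n_licks = rng.poisson(config.lick_rate * duration)
    for lt in np.sort(rng.uniform(0, duration, n_licks)):
        events.append((float(lt), "lick", "NEUTRAL"))

    ev = pd.DataFrame(events, columns=["time", "kind", "zone"])
    ev = ev.sort_values("time", kind="stable").reset_index(drop=True)
    return SessionLog(ev, v, position, dt, duration, config)


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted per-neuron and per-trial latent structure.

    Hub neurons carry zone-end ramp amplitudes well above the rest (bimodal
    distribution); the reinforcement response has a fast exponential first
    component and a slower second component whose integral is linearly
    coupled to the late ramp amplitude (the learning correlation).
    ``planted_lead`` (s) shifts the neural locomotion coupling earlier than
    running, planting a V1-leads-motor delay.
    """

    on_amp: np.ndarray
    ramp_amp_aver: np.ndarray
    ramp_amp_ctrl: np.ndarray
    reinf_first_amp: np.ndarray
    reinf_second_amp: np.ndarray
    reinf_tau: np.ndarray
    locomotion_gain: np.ndarray
    hub_flag: np.ndarray
    soma_xyz: np.ndarray
    trial_class: dict[int, str] = field(default_factory=dict)  # AVER trial idx -> high/low
    planted_lead: float = 0.0
    zone_pref: np.ndarray | None = None   # 'AVER' | 'CTRL' | 'none'

    def __post_init__(self) -> None:
        for name in ("on_amp", "ramp_amp_aver", "ramp_amp_ctrl",
                     "reinf_first_amp", "reinf_second_amp", "locomotion_gain"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"GroundTruth.{name} must be >= 0")


def sample_ground_truth(
    config: SimConfig,
    seed: int | None = None,
    field_size: float = 650.0,
    hub_cluster_radius: float | None = None,
    hub_ramp: float = 1.0,
    hub_ramp_sd: float = 0.05,
    nonhub_ramp: float = 0.1,
    nonhub_ramp_sd: float = 0.02,
    frac_aver_pref: float = 0.44,
    frac_ctrl_pref: float = 0.14,
    reinf_slope: float = 0.5,
    reinf_noise_frac: float = 0.2,
    planted_lead: float = 0.0,
    high_trial_fraction: float = 0.5,
    low_trial_scale: float = 0.3,
) -> GroundTruth:
    """Draw planted latent amplitudes and geometry for a population.

    Hub cells (fraction ``hub_fraction``) get aversive ramp amplitudes near
    ``hub_ramp``, the rest near ``nonhub_ramp`` (a bimodal distribution with
    a clear jump).  Zone preference splits the population into
    aversive-dominant / control-dominant / neutral fractions.  The second
    reinforcement component is ``reinf_slope * ramp_amp_aver`` plus
    proportional noise, planting the reinforcement-learning correlation.
    Somata are uniform in a ``field_size``-micron cube unless
    ``hub_cluster_radius`` places hubs in a tight ball.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_neurons
    n_hub = max(int(round(config.hub_fraction * n)), 0)
    hub = np.zeros(n, dtype=bool)
    hub[rng.choice(n, size=n_hub, replace=False)] = True

    ramp_aver = np.where(
        hub,
        rng.normal(hub_ramp, hub_ramp_sd, n),
        rng.normal(nonhub_ramp, nonhub_ramp_sd, n),
    )
    ramp_aver = np.clip(ramp_aver, 0.0, None)

    pref = rng.choice(
        ["AVER", "CTRL", "none"], size=n,
        p=[frac_aver_pref, frac_ctrl_pref, 1 - frac_aver_pref - frac_ctrl_pref],
    )
    ramp_ctrl = ramp_aver.copy()
    ramp_ctrl[pref == "AVER"] *= 0.3
    ramp_ctrl[pref == "CTRL"] /= 0.3

    on_amp = np.clip(rng.normal(0.3, 0.1, n), 0.0, None)
    reinf_first = np.clip(rng.normal(0.5, 0.2, n), 0.0, None)
    reinf_second = np.clip(
        reinf_slope * ramp_aver * (1 + reinf_noise_frac * rng.standard_normal(n)),
        0.0, None,
    )
    reinf_tau = rng.uniform(0.4, 0.8, n)
    loco = np.clip(rng.normal(0.2, 0.1, n), 0.0, None)

    xyz = rng.uniform(0, field_size, size=(n, 3))
    if hub_cluster_radius is not None and n_hub > 0:
        center = rng.uniform(0.3 * field_size, 0.7 * field_size, size=3)
        # uniform in a ball of the given radius
        dirs = rng.standard_normal((n_hub, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = hub_cluster_radius * rng.random(n_hub) ** (1 / 3)
        xyz[hub] = center + dirs * radii[:, None]
        xyz = np.clip(xyz, 0, field_size)

    trial_class = {
        i: ("high" if rng.random() < high_trial_fraction else "low")
        for i in range(config.n_trials_per_zone)
    }
    return GroundTruth(
        on_amp=on_amp, ramp_amp_aver=ramp_aver, ramp_amp_ctrl=ramp_ctrl,
        reinf_first_amp=reinf_first, reinf_second_amp=reinf_second,
        reinf_tau=reinf_tau, locomotion_gain=loco, hub_flag=hub,
        soma_xyz=xyz, trial_class=trial_class, planted_lead=planted_lead,
        zone_pref=pref,
    )


# --------------------------------------------------------------------------
# Transients
# --------------------------------------------------------------------------

@dataclass
class TransientSet:
    """Ground-truth dF/F with per-component time courses kept separate."""

    total: np.ndarray                      # neurons x frames
    components: dict[str, np.ndarray]      # each neurons x frames
    frame_times: np.ndarray
    frame_rate: float
    low_trial_scale: float = 0.3


def _on_kernel(t: np.ndarray, tau: float = 0.3) -> np.ndarray:
    """Alpha kernel peaking at 1.0 at t = tau (visual ON transient shape)."""
    k = np.zeros_like(t)
    pos = t >= 0
    k[pos] = (t[pos] / tau) * np.exp(1 - t[pos] / tau)
    return k


def generate_transients(
    session: SessionLog,
    truth: GroundTruth,
    config: SimConfig,
    low_trial_scale: float = 0.3,
) -> TransientSet:
    """Compose per-neuron dF/F from the planted latent components.

    trace = on_amp * (stimulus-onset kernel at zone entries)
          + ramp_amp * (linear rise over the last ``ramp_onset`` s of the zone)
          + reinforcement first (exponential) + second (delayed bump) at the
            first airpuff of non-escaped aversive trials
          + locomotion_gain * normalized velocity envelope (shifted earlier
            by ``planted_lead``)
          + Gaussian noise of s.d. ``noise_sd``.

    Aversive-trial ramps are scaled by the planted high/low trial class.
    All component matrices are returned separately for oracle tests.
    """
    if not np.isclose(session.dt, config.behavior_dt):
        raise ValueError(
            f"time base mismatch: session at {1/session.dt:.1f} Hz, "
            f"config expects {1/config.behavior_dt:.1f} Hz"
        )
    trials = session.trials()
    n_aver = int((trials.zone == "AVER_0").sum())
    if truth.trial_class and n_aver > len(truth.trial_class):
        raise ValueError(
            f"trial structure mismatch: session has {n_aver} aversive trials, "
            f"ground truth classes cover {len(truth.trial_class)}"
        )
    rate = config.imaging_rate
    n_frames = int(np.ceil(session.duration * rate))
    ft = np.arange(n_frames) / rate
    n = config.n_neurons
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    on = np.zeros(n_frames)
    ramp_aver = np.zeros(n_frames)
    ramp_ctrl = np.zeros(n_frames)
    reinf1_shapes = np.zeros((n, n_frames))
    reinf2 = np.zeros(n_frames)

    aver_idx = 0
    for _, tr in trials.iterrows():
        on += _on_kernel(ft - tr.t_enter)
        dur = min(config.ramp_onset, tr.t_exit - tr.t_enter)
        in_ramp = (ft >= tr.t_exit - dur) & (ft <= tr.t_exit)
        shape = np.zeros(n_frames)
        shape[in_ramp] = (ft[in_ramp] - (tr.t_exit - dur)) / dur
        if tr.zone == "AVER_0":
            scale = 1.0
            if truth.trial_class:
                cls = truth.trial_class.get(aver_idx, "high")
                scale = 1.0 if cls == "high" else low_trial_scale
            ramp_aver += scale * shape
            if tr.n_puffs > 0:
                t_puff = tr.scheduled_first_puff
                post = ft - t_puff
                mask = post >= 0
                for i in range(n):
                    reinf1_shapes[i, mask] += np.exp(-post[mask] / truth.reinf_tau[i])
                bump = np.zeros(n_frames)
                sigma = 0.5
                bump[mask] = np.exp(-0.5 * ((post[mask] - 1.5) / sigma) ** 2)
                reinf2 += bump / (sigma * np.sqrt(2 * np.pi))   # unit integral
            aver_idx += 1
        else:
            ramp_ctrl += shape

    env = np.interp(ft + truth.planted_lead, np.arange(len(session.velocity)) * session.dt,
                    session.velocity)
    # smooth (0.2 s) and normalize to peak 1 so locomotion_gain is in dF/F units
    from scipy.ndimage import gaussian_filter1d
    env = gaussian_filter1d(env, sigma=max(0.2 * rate, 1e-6))
    peak = np.max(np.abs(env))
    if peak > 0:
        env = env / peak

    comps = {
        "on": truth.on_amp[:, None] * on[None, :],
        "ramp": (truth.ramp_amp_aver[:, None] * ramp_aver[None, :]
                 + truth.ramp_amp_ctrl[:, None] * ramp_ctrl[None, :]),
        "reinf_first": truth.reinf_first_amp[:, None] * reinf1_shapes,
        "reinf_second": truth.reinf_second_amp[:, None] * reinf2[None, :],
        "locomotion": truth.locomotion_gain[:, None] * env[None, :],
        "noise": config.noise_sd * rng.standard_normal((n, n_frames)),
    }
    total = sum(comps.values())
    return TransientSet(total, comps, ft, rate, low_trial_scale)


# --------------------------------------------------------------------------
# Chessboard movie rendering
# --------------------------------------------------------------------------

def generate_chessboard_movie(
    truth: GroundTruth,
    traces: TransientSet,
    config: SimConfig,
    motion: np.ndarray | None = None,
    subfield_shape: tuple[int, int] = (16, 16),
    soma_radius: float = 3.0,
    neuropil_radii: tuple[float, float] = (4.5, 7.0),
    base_intensity: float = 100.0,
    gain: float = 50.0,
    shot_noise: float = 0.0,
    fill_value: float = 0.0,
    neuropil_trace: np.ndarray | None = None,
) -> tuple[ChessboardMovie, RoiSet]:
    """Render per-neuron traces into a chessboard-scan movie.

    One soma disk per occupied subfield; pixel intensity is
    ``base + gain * (trace + neuropil_mix * b(t))`` inside the soma and
    ``base + gain * b(t)`` in the annular neuropil, where ``b(t)`` is a
    shared background trace.  Every frame is shifted by the per-frame
    ``motion`` (dy, dx) with uncovered pixels set to ``fill_value``;
    shot-like noise has s.d. ``shot_noise * sqrt(intensity)``.  The returned
    RoiSet records the true soma/neuropil pixels, weights, home subfields
    and 3D soma positions.
    """
    h, w = subfield_shape
    n_frames = traces.total.shape[1]
    n = config.n_neurons
    rows, cols = config.grid_shape
    if motion is None:
        motion = np.zeros((n_frames, 2))
    motion = np.asarray(motion, dtype=float)
    bound = min(h, w) / 4
    if np.any(np.abs(motion) > bound):
        raise ValueError(
            f"motion shifts exceed subfield_size/4 = {bound}; registration "
            "would be ill-posed"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if neuropil_trace is None:
        from scipy.ndimage import gaussian_filter1d
        neuropil_trace = 0.5 + 0.2 * gaussian_filter1d(
            rng.standard_normal(n_frames), sigma=5.0
        )
    b = np.asarray(neuropil_trace, dtype=float)

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    dist = np.hypot(yy - cy, xx - cx)
    soma_mask = dist <= soma_radius
    np_mask = (dist >= neuropil_radii[0]) & (dist <= neuropil_radii[1])

    frames: dict[tuple[int, int], np.ndarray] = {}
    centers: dict[tuple[int, int], np.ndarray] = {}
    rois: list[Roi] = []
    mix = config.neuropil_mix
    positions = [(r, c) for r in range(rows) for c in range(cols)][:n]
    integer_motion = np.all(motion == np.round(motion))
    from .imaging_pipeline import _shift_frame

    for i, pos in enumerate(positions):
        stack = np.empty((n_frames, h, w))
        soma_tr = traces.total[i]
        base = np.full((h, w), base_intensity)
        for f in range(n_frames):
            img = base.copy()
            img[soma_mask] = base_intensity + gain * (soma_tr[f] + mix * b[f])
            img[np_mask] = base_intensity + gain * b[f]
            dy, dx = motion[f]
            if dy != 0 or dx != 0:
                img = _shift_frame(img, (dy, dx), fill_value)
            if shot_noise > 0:
                img = img + shot_noise * np.sqrt(np.clip(img, 0, None)) \
                    * rng.standard_normal((h, w))
            stack[f] = img
        frames[pos] = stack
        centers[pos] = truth.soma_xyz[i]
        soma_px = np.argwhere(soma_mask)
        np_px = np.argwhere(np_mask)
        rois.append(Roi(
            soma_pixels=soma_px,
            soma_weights=np.ones(len(soma_px)),
            neuropil_pixels=np_px,
            neuropil_weights=np.ones(len(np_px)),
            home_subfield=pos,
            soma_xyz=truth.soma_xyz[i],
        ))
    movie = ChessboardMovie(
        grid_shape=config.grid_shape, frames=frames,
        frame_rate=traces.frame_rate, subfield_center_xyz=centers,
        fill_value=fill_value,
    )
    return movie, RoiSet(rois)


# --------------------------------------------------------------------------
# Abyss runs
# --------------------------------------------------------------------------

def generate_abyss_runs(
    config: SimConfig,
    immersion: str = "headset",
    seed: int = 0,
    n_runs: int = 10,
    recoil_fraction: float = 0.3,
    fail_fraction: float = 0.0,
    edge_coord: float = 100.0,
    visibility_offset: float = 30.0,
    run_duration: float = 30.0,
) -> list[VelocityTrace]:
    """Simulate runs toward a virtual cliff edge under two display regimes.

    ``immersion='headset'`` emulates full depth perception: the mouse
    decelerates approaching the edge and stops (a ``recoil_fraction`` of
    runs briefly runs backward) at a point where the edge is visible.
    ``'monitor'`` emulates flat-screen presentation: the mouse crosses the
    edge at unchanged speed.  A ``fail_fraction`` of runs stalls well before
    edge visibility for longer than the 20-s timeout, exercising the failed
    classification.
    """
    if immersion not in ("headset", "monitor"):
        raise ValueError(f"immersion must be 'headset' or 'monitor', got {immersion!r}")
    rng = np.random.default_rng(seed)
    dt = config.behavior_dt
    n = int(round(run_duration / dt))
    times = np.arange(n) * dt
    out: list[VelocityTrace] = []
    visibility = edge_coord - visibility_offset
    for k in range(n_runs):
        base = config.baseline_speed * rng.uniform(0.8, 1.2)
        fail = rng.random() < fail_fraction
        recoil = (not fail) and rng.random() < recoil_fraction
        v = np.empty(n)
        x = np.empty(n)
        pos = 0.0
        stop_at = edge_coord - rng.uniform(1.0, 3.0)
        for i in range(n):
            if fail:
                # stall 30+ units before edge visibility and stay put
                speed = base if pos < visibility - 30.0 else 0.0
            elif immersion == "monitor":
                speed = base
            else:
                if pos < stop_at - 15.0:
                    speed = base
                elif pos < stop_at:
                    speed = base * (stop_at - pos) / 15.0
                    if speed < 0.02 * base:   # full stop once nearly there
                        speed = 0.0
                else:
                    speed = 0.0
            v[i] = speed
            pos += speed * dt
            x[i] = pos
        if recoil:
            # after stopping, briefly back away from the edge
            stopped = np.flatnonzero(v == 0.0)
            if stopped.size:
                j0 = stopped[0]
                j1 = min(j0 + int(1.0 / dt), n)
                v[j0:j1] = -0.2 * base
                x[:] = np.cumsum(v) * dt
        v += 0.05 * rng.standard_normal(n) * (v != 0)
        out.append(VelocityTrace(times, v, x, edge_coord=edge_coord))
    return out
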