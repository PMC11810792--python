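"""Zone-end alignment and learning quantities.

The learning readout of the task is a ramp-like rise of calcium activity
over the final seconds of a grating zone.  This module aligns dF/F traces
to zone ends, quantifies the ramp amplitude in a short pre-end window
(mean dF/F over (-1, -0.4) s by default, with (-1, -0.3) s as the
alternative endpoint), computes population activation ratios, classifies
per-neuron zone preference, and decomposes responses to the first airpuff
into a fast exponential component plus a slower second component whose
strength predicts later learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AlignedResponses",
    "RampTable",
    "ReinforcementDecomposition",
    "align_to_zone_end",
    "ramp_amplitude",
    "activation_ratio",
    "classify_zone_preference",
    "decompose_reinforcement",
    "correlate_learning",
]


@dataclass
class AlignedResponses:
    """neurons x time x trials dF/F aligned so that t = 0 is the zone end.

    ``time`` is negative and ends at 0 (right-closed: the last sample is the
    frame at the zone end).  ``velocity`` holds the treadmill speed
    resampled to the imaging rate on the same axis, one column per trial.
    """

    data: np.ndarray          # neurons x time x trials
    time: np.ndarray          # s, <= 0
    labels: np.ndarray        # per trial: 'AVER' | 'CTRL'
    velocity: np.ndarray      # time x trials
    frame_rate: float
    n_dropped: int = 0
    trial_index: np.ndarray | None = None   # per-zone trial counter

    def __post_init__(self) -> None:
        if self.data.shape[1] != self.time.shape[0]:
            raise ValueError("time axis length mismatch")
        if self.data.shape[2] != self.labels.shape[0]:
            raise ValueError("one label per trial required")

    def select(self, label: str) -> np.ndarray:
        return self.data[:, :, self.labels == label]

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        start, end = window
        if not start < end:
            raise ValueError(f"window start must precede end, got {window}")
        mask = (self.time > start) & (self.time <= end)
        if not mask.any():
            raise ValueError(f"window {window} is empty on the aligned time axis")
        return mask


def align_to_zone_end(
    dff: np.ndarray,
    session,
    pre_window: float,
    frame_rate: float,
    zones: tuple[str, ...] = ("AVER_0", "CTRL_45", "CTRL_135"),
    end_event: str = "exit",
    min_trial_duration: float | None = None,
) -> AlignedResponses:
    """Cut per-trial segments of ``pre_window`` seconds ending at zone end.

    ``end_event='exit'`` aligns to the actual zone exit; ``'scheduled_puff'``
    caps aversive trials at the scheduled first-airpuff time (zone entry +
    grace), the convention used when quantifying learning so the airpuff's
    direct effect is excluded.  Velocity is resampled to the imaging rate
    and aligned identically.  Trials shorter than ``min_trial_duration``
    (the full window by default; pass 0 to keep short trials whose aligned
    window reaches back into the preceding neutral period) or windows not
    covered by the recording are dropped and counted.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if min_trial_duration is None:
        min_trial_duration = pre_window
    n_samples = int(round(pre_window * frame_rate))
    if n_samples < 1:
        raise ValueError("pre_window too short for the imaging rate")
    trials = session.trials()
    t_vel = np.arange(len(session.velocity)) * session.dt

    segs, vels, labels, idx_in_zone = [], [], [], []
    counters: dict[str, int] = {}
    n_dropped = 0
    for _, tr in trials.iterrows():
        if tr.zone not in zones:
            continue
        counters[tr.zone] = counters.get(tr.zone, 0)
        if end_event == "scheduled_puff" and tr.zone == "AVER_0":
            t_end = min(tr.t_exit, tr.scheduled_first_puff)
        else:
            t_end = tr.t_exit
        end_idx = int(np.floor(t_end * frame_rate))   # last frame at/before end
        start_idx = end_idx - n_samples + 1
        too_short = t_end - tr.t_enter < min_trial_duration
        if start_idx < 0 or end_idx >= dff.shape[1] or too_short:
            n_dropped += 1
            counters[tr.zone] += 1
            continue
        segs.append(dff[:, start_idx:end_idx + 1])
        frame_t = (np.arange(start_idx, end_idx + 1)) / frame_rate
        vels.append(np.interp(frame_t, t_vel, session.velocity))
        labels.append("AVER" if tr.zone.startswith("AVER") else "CTRL")
        idx_in_zone.append(counters[tr.zone])
        counters[tr.zone] += 1
    if not segs:
        raise ValueError("no trial long enough for the requested pre_window")
    data = np.stack(segs, axis=2)
    velocity = np.stack(vels, axis=1)
    time = (np.arange(n_samples) - (n_samples - 1)) / frame_rate
    return AlignedResponses(
        data=data, time=time, labels=np.array(labels), velocity=velocity,
        frame_rate=frame_rate, n_dropped=n_dropped,
        trial_index=np.array(idx_in_zone),
    )


# --------------------------------------------------------------------------
# Ramp amplitude
# --------------------------------------------------------------------------

@dataclass
class RampTable:
    """Per-neuron (and per-trial) ramp amplitudes in a pre-end window."""

    per_trial: np.ndarray     # neurons x trials
    per_neuron: pd.DataFrame  # columns AVER / CTRL (trial-averaged)
    window: tuple[float, float]
    mode: str

    def __post_init__(self) -> None:
        start, end = self.window
        if not (start < end <= 0):
            raise ValueError(f"ramp window must satisfy start < end <= 0, got {self.window}")


def ramp_amplitude(
    aligned: AlignedResponses,
    window: tuple[float, float] = (-1.0, -0.4),
    mode: str = "mean",
    baseline_window: tuple[float, float] | None = None,
) -> RampTable:
    """Ramp amplitude as the windowed mean (or raw integral) of dF/F.

    The default reports the time-integral over ``window`` divided by the
    window length, i.e. the mean dF/F, which makes the two conventional
    windows (-1, -0.4) and (-1, -0.3) directly comparable; ``mode='integral'``
    returns the raw integral in dF/F * s.  ``baseline_window`` subtracts the
    mean over an early reference window of the same segment, isolating the
    ramp from tonic and locomotion-coupled offsets.  Linear in the input.
    """
    mask = aligned.window_mask(window)
    seg = aligned.data[:, mask, :]
    per_trial = seg.mean(axis=1)
    if baseline_window is not None:
        bmask = aligned.window_mask(baseline_window)
        per_trial = per_trial - aligned.data[:, bmask, :].mean(axis=1)
    if mode == "integral":
        per_trial = per_trial * (window[1] - window[0])
    elif mode != "mean":
        raise ValueError(f"mode must be 'mean' or 'integral', got {mode!r}")
    cols = {}
    for label in ("AVER", "CTRL"):
        sel = aligned.labels == label
        cols[label] = per_trial[:, sel].mean(axis=1) if sel.any() else np.nan
    return RampTable(per_trial, pd.DataFrame(cols), window, mode)


# --------------------------------------------------------------------------
# Activation ratio
# --------------------------------------------------------------------------

def activation_ratio(
    aligned: AlignedResponses,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
    method: str = "threshold_2sem",
    alpha: float = 0.05,
    test: str = "t",
) -> dict:
    """Fraction of neurons active in the response window vs a baseline.

    ``threshold_2sem``: a neuron is active if its trial-mean response
    exceeds the baseline mean by more than twice the baseline s.e.m.
    across trials.  ``paired_test``: per-neuron one-tailed paired test of
    response vs baseline across trials (Student's t by default,
    ``test='wilcoxon'`` for the signed-rank variant) at level ``alpha``.

    Returns the fraction, per-neuron flags, and (for tests) raw and
    Benjamini--Hochberg-adjusted flags.
    """
    base = aligned.data[:, aligned.window_mask(baseline_window), :].mean(axis=1)
    resp = aligned.data[:, aligned.window_mask(response_window), :].mean(axis=1)
    n_trials = base.shape[1]
    if n_trials < 2:
        raise ValueError("activation_ratio needs >= 2 trials")
    if method == "threshold_2sem":
        sem = base.std(axis=1, ddof=1) / np.sqrt(n_trials)
        active = resp.mean(axis=1) > base.mean(axis=1) + 2 * sem
        return {"fraction": float(active.mean()), "active": active}
    if method == "paired_test":
        pvals = np.empty(base.shape[0])
        for i in range(base.shape[0]):
            if test == "t":
                pvals[i] = stats.ttest_rel(resp[i], base[i], alternative="greater").pvalue
            elif test == "wilcoxon":
                diff = resp[i] - base[i]
                if np.all(diff == 0):
                    pvals[i] = 1.0
                else:
                    pvals[i] = stats.wilcoxon(diff, alternative="greater").pvalue
            else:
                raise ValueError(f"unknown test {test!r}")
        active = pvals < alpha
        adj = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        return {
            "fraction": float(active.mean()),
            "active": active,
            "p_values": pvals,
            "fraction_adjusted": float(adj.mean()),
            "active_adjusted": adj,
        }
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# Zone preference
# --------------------------------------------------------------------------

def classify_zone_preference(
    aligned: AlignedResponses,
    window: tuple[float, float] = (-1.0, -0.4),
    alpha: float = 0.05,
) -> dict:
    """Label neurons as aversive-coding, control-coding or neither.

    The per-neuron statistic is the difference of mean ramp amplitudes
    between aversive and control trials; the label follows the sign where a
    two-tailed two-sample t-test across trials rejects at ``alpha``
    (trials are independent between zones, so the comparison is unpaired).
    Reports per-neuron labels and population fractions.
    """
    for label in ("AVER", "CTRL"):
        if not (aligned.labels == label).any():
            raise ValueError(f"no {label} trials present")
    table = ramp_amplitude(aligned, window=window)
    amp = table.per_trial
    aver = amp[:, aligned.labels == "AVER"]
    ctrl = amp[:, aligned.labels == "CTRL"]
    diffs = aver.mean(axis=1) - ctrl.mean(axis=1)
    labels = np.full(amp.shape[0], "none", dtype=object)
    pvals = np.empty(amp.shape[0])
    for i in range(amp.shape[0]):
        pvals[i] = stats.ttest_ind(aver[i], ctrl[i], equal_var=False).pvalue
        if pvals[i] < alpha:
            labels[i] = "AVER" if diffs[i] > 0 else "CTRL"
    fractions = {
        "AVER": float(np.mean(labels == "AVER")),
        "CTRL": float(np.mean(labels == "CTRL")),
        "none": float(np.mean(labels == "none")),
    }
    return {"labels": labels, "difference": diffs, "p_values": pvals,
            "fractions": fractions}


# --------------------------------------------------------------------------
# Reinforcement decomposition
# --------------------------------------------------------------------------

@dataclass
class ReinforcementDecomposition:
    """Two-component split of post-airpuff responses.

    The first component is the fast exponential plus the velocity-matched
    part (what a pure motor/arousal response would look like); the second
    component is the integral of the nonnegative residual, the signature of
    good learners.
    """

    first_amplitude: np.ndarray
    tau: np.ndarray
    velocity_gain: np.ndarray
    second_component: np.ndarray      # dF/F * s, integral of residual
    first_velocity_corr: np.ndarray
    second_velocity_corr: np.ndarray
    failed: np.ndarray                # neurons where the fit did not converge

    def __post_init__(self) -> None:
        ok = ~self.failed
        if np.any(self.tau[ok] <= 0):
            raise ValueError("fitted tau must be > 0")


def decompose_reinforcement(
    response: np.ndarray,
    velocity: np.ndarray,
    dt: float,
    tau_grid: np.ndarray | None = None,
) -> ReinforcementDecomposition:
    """Fit amplitude*exp(-t/tau) + gain*velocity to post-airpuff responses.

    ``response`` is neurons x time aligned to the first airpuff (t = 0 at
    the pulse); ``velocity`` is the identically aligned running speed,
    normalized internally to peak 1.  For each neuron the exponential decay
    constant is scanned over ``tau_grid`` (with local refinement) and
    nonnegative (amplitude, gain) solved by least squares at each candidate
    -- a multi-start scheme that cannot diverge.  The fit is made robust to
    the second component itself by iteratively excluding samples with large
    positive excess over the current model and refitting, so a delayed bump
    is not absorbed into a stretched exponential.  The second component is
    the time-integral of the positive part of the residual.
    """
    response = np.atleast_2d(np.asarray(response, dtype=float))
    n_neurons, n_t = response.shape
    if n_t * dt < 3.0:
        raise ValueError("post-airpuff window must cover >= 3 s")
    t = np.arange(n_t) * dt
    v = np.asarray(velocity, dtype=float)
    vmax = np.max(np.abs(v))
    vnorm = v / vmax if vmax > 0 else v
    if tau_grid is None:
        tau_grid = np.geomspace(0.1, 3.0, 25)

    first_amp = np.zeros(n_neurons)
    taus = np.full(n_neurons, tau_grid[0])
    gains = np.zeros(n_neurons)
    second = np.zeros(n_neurons)
    corr1 = np.zeros(n_neurons)
    corr2 = np.zeros(n_neurons)
    failed = np.zeros(n_neurons, dtype=bool)
    for i in range(n_neurons):
        y = response[i]
        if np.allclose(y, 0):
            continue
        def sse(tau: float, mask: np.ndarray):
            basis = np.column_stack([np.exp(-t / tau), vnorm])
            coef, err = optimize.nnls(basis[mask], y[mask])
            return err, coef

        mask = np.ones(n_t, dtype=bool)
        tau, a, g = tau_grid[0], 0.0, 0.0
        for _ in range(6):
            errs = [sse(tau_c, mask)[0] for tau_c in tau_grid]
            j = int(np.argmin(errs))
            lo = tau_grid[max(j - 1, 0)]
            hi = tau_grid[min(j + 1, len(tau_grid) - 1)]
            res = optimize.minimize_scalar(lambda tau_c: sse(tau_c, mask)[0],
                                           bounds=(lo, hi), method="bounded")
            tau = float(res.x)
            a, g = sse(tau, mask)[1]
            model = a * np.exp(-t / tau) + g * vnorm
            resid_all = y - model
            sd = float(np.sqrt(np.mean(resid_all[mask] ** 2)))
            # keep samples the model explains; large positive excess is the
            # putative second component and must not steer the exponential
            new_mask = resid_all <= 0.5 * sd
            if new_mask.sum() < 5 or np.array_equal(new_mask, mask):
                break
            mask = new_mask
        first = a * np.exp(-t / tau) + g * vnorm
        resid = y - first
        first_amp[i], taus[i], gains[i] = a, tau, g
        second[i] = float(np.sum(np.clip(resid, 0, None)) * dt)
        if np.std(first) > 0 and np.std(vnorm) > 0:
            corr1[i] = float(np.corrcoef(first, vnorm)[0, 1])
        pos = np.clip(resid, 0, None)
        if np.std(pos) > 0 and np.std(vnorm) > 0:
            corr2[i] = float(np.corrcoef(pos, vnorm)[0, 1])
    return ReinforcementDecomposition(
        first_amplitude=first_amp, tau=taus, velocity_gain=gains,
        second_component=second, first_velocity_corr=corr1,
        second_velocity_corr=corr2, failed=failed,
    )


def correlate_learning(
    second_components: np.ndarray,
    late_ramp: np.ndarray,
) -> dict:
    """Correlate early reinforcement second components with late ramps.

    Pearson correlation and least-squares slope across neurons of the late
    (30--40 min) ramp amplitude against the second reinforcement component
    measured ~30 min earlier.  Quantifies how strongly early reinforcement
    signaling predicts subsequent learning at single-cell level.
    """
    x = np.asarray(second_components, dtype=float)
    y = np.asarray(late_ramp, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must cover the same neuron set")
    if x.size < 3:
        raise ValueError("need >= 3 neurons")
    res = stats.linregress(x, y)
    return {"r": float(res.rvalue), "slope": float(res.slope),
            "p": float(res.pvalue), "intercept": float(res.intercept)}
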